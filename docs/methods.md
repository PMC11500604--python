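# Methods

## Cellular electrophysiology

The cell model is the 1998 Courtemanche–Ramirez–Nattel (CRN) human atrial
myocyte model: 21 state variables (membrane voltage, 15 Hodgkin–Huxley-type
gates, and intracellular Na+, K+, Ca2+ plus SR uptake/release compartment
Ca2+). Currents are implemented as densities (pA/pF ≡ µA/cm² at 1 µF/cm²),
so the voltage equation is `dV/dt = −I_ion + J_stim` and a printed stimulus
strength such as 30 µA/cm² maps directly onto the model. Stimulus charge is
not attributed to any ionic species (standard practice; the alternative —
adding it to K+ — changes intracellular K+ by <1.5 mM over 100 beats and
the paced APD by a few ms).

Implementation is validated against the published model's canonical
single-cell metrics with its native 2 nA / 2 ms stimulus: resting potential
−81.2 mV, maximum upstroke velocity ≈ 203 mV/ms (0.1 ms sampling),
overshoot ≈ +25 mV, amplitude ≈ 106 mV, APD90 ≈ 306 ms for the first beat
from the published resting state. The tests assert the resting equilibrium,
the limit-cycle APD range at BCL 500 ms, and term-by-term linearity of the
nine scalable conductances (g_Na, g_K1, g_to, g_Kur, g_Kr, g_Ks, g_CaL,
I_pCa, I_NaCa).

**Numerics.** Gates advance by Rush–Larsen updates whose voltage-dependent
steady states and decay factors exp(−dt/τ(V)) are pre-tabulated on a 0.05 mV
grid over [−120, 80] mV and linearly interpolated (verified against the
exact rate functions to ≤2·10⁻⁵ absolute). Voltage and concentrations use
forward Euler. The reference step is dt = 20 µs; sheet simulations use
dt = 50 µs, which changes the cable ERP by ≤ 2 ms and tuned CV by < 1% —
a deliberate accuracy/runtime trade at desk scale.

## Tissue propagation

Monodomain reaction–diffusion on 1D cables (second-order differences) and
triangulated surfaces (linear finite elements, lumped mass) with per-element
anisotropic diffusivity `D = D_t I + (D_l − D_t) f fᵀ` from the element
fiber `f`. Conductivity converts to diffusivity through β·C_m with
β = 0.14 µm⁻¹ and C_m = 1 µF/cm². Time stepping is a single fused explicit
step (diffusion + reaction); the explicit diffusion stability bound is never
binding at the resolutions used. Non-conductive elements (replacement
fibrosis, ablation lesions) carry σ = 10⁻⁷ S/m exactly, which blocks
propagation (verified). Activation is detected as an upward crossing of
−20 mV with dV/dt > 20 mV/ms.

**Resolution and conduction velocity.** At 0.3 m/s the CRN wavefront is
under-resolved at practical grid spacings, so absolute conductivity values
are renormalized by the grid. The package therefore treats the *CV target*
as the contract: `tune_conductivity` bisects the longitudinal conductivity
until the measured cable CV (activation-time regression over the central
50% of a 40 mm cable) hits the target within 0.01 m/s, separately per
(dx, dt). Tuned values used throughout: σ_l = 0.0962 S/m at dx = 0.4 mm
(dt 20 µs) and 0.2616 S/m at dx = 1.25 mm (dt 50 µs) for 0.3 m/s. The
√σ CV law and the √r anisotropy law hold on grid-resolved configurations
(verified at dx = 0.2 mm and at high conductivity respectively); dt-halving
changes CV by < 2%.

## Cable ERP and the remodeling ladder

ERP of a cellular parameterization is measured on the 40 mm / 0.4 mm cable:
the cell is pre-paced 100 beats at BCL 500 ms in isolation, the cable is
initialized from that limit cycle and paced with 7 S1 (30 µA/cm², 3 ms, 1 mm
end electrode) at BCL 500 ms, and S2 is scanned on a 1 ms grid from 350 ms
downward. ERP = the longest S1S2 interval without capture, capture meaning
an S2-elicited activation ≥ 30 mm from the electrode within 200 ms of S2.
The 200 ms window accommodates decrementally conducting premature waves
(near the ERP the transition is sharp — e.g. block at 300 ms, full
conduction with ~140 ms transit at 301 ms — so the measured ERP is
insensitive to the window). Because capture is monotone in the coupling
interval, the scan is a bisection, verified equal to the descending scan.

Under this protocol the control model's cable ERP is **300 ms** (this
implementation; 292–301 ms across dt 5–20 µs, dx 0.1–0.4 mm, electrode and
CV variations), and the clinical-emulation protocol (S2 300→200 ms in 10 ms
steps) reproduces the 1 ms-grid ERP rounded down to its grid.

Chronic-AF remodeling scales eight maxima (g_K1, g_to, g_Kur, g_Kr, g_Ks,
g_CaL, I_pCa, I_NaCa) along a literature-consensus direction (I_K1 up 2×,
I_to down to 35%, I_Kur to 50%, I_CaL to 35%, I_Ks up 2×, I_Kr up 1.6×,
pump/exchanger up 1.5×/1.6×). The terminal magnitude is *calibrated*: the
endpoint is `1 + α(direction − 1)` with α bisected until the cable ERP is
157 ± 1 ms (α ≈ 0.70 here). The remodeling ladder interpolates every
multiplier linearly from control to this endpoint (50 levels at full scale;
the test suite uses a 10-level ladder, which already makes the inverse
lookup exact to ≤ 1 ms) and tabulates each level's cable ERP; ladder ERPs
are monotone non-increasing up to 1 ms scan quantization, which is resolved
by a running minimum so the inverse map is well defined. The inverse
`erp_to_scale` interpolates multipliers linearly between the two bracketing
levels; round-trip error (target → multipliers → re-measured cable ERP) is
≤ 1 ms at probe targets across [170, 300] ms.

## ERP scenarios and substrate

* **A (homogeneous):** the ladder endpoint everywhere.
* **B (heterogeneous):** structure-wise literature ERPs per anatomical
  region. The shipped table is a reconstructed placeholder spanning
  140–180 ms (mean ≈ 159 ms) and is editable JSON; values below the ladder
  floor clamp with a warning.
* **C (regional):** each region takes its spatially closest measurement's
  ERP, averaging when a region holds several; unmeasured regions inherit the
  geodesically nearest measurement (a choice — the clinical protocol leaves
  this case open).
* **D (continuous):** measurements are snapped to nearest nodes (ties to the
  lowest id) and fixed as Dirichlet values of a uniform-weight graph
  Laplacian over conductive edges. Uniform non-negative weights guarantee
  the discrete maximum principle (raw cotangent weights would not on obtuse
  triangles), so the field interpolates exactly and never leaves the
  measured range; unmeasured connected components are an error. Mesh holes
  get natural (zero-flux) boundaries.

Per-node conductance multipliers then come from `erp_to_scale` applied to
the field. Substrate rules from the bipolar voltage map: ablation lesion
< 0.1 mV ≤ native fibrosis < 0.5 mV ≤ healthy (node classes; element class
by node majority, ties resolved toward the more severe class). Of the
fibrosis elements, 30% (rounded half-up, seeded i.i.d. sampling without
replacement — spatial clustering is not modeled) become non-conductive; the
nodes of the remaining 70% compose the inflammation preset (g_CaL ×0.225,
g_Na ×0.6, g_Kur ×0.5, g_to ×0.35, g_Ks ×2, I_pCa ×1.5, I_NaCa ×1.6)
multiplicatively (commutative) with their scenario scaling. Lesions are
non-conductive in `lesions_and_fibrosis` mode and left healthy in
`fibrosis_only` (pre-ablation) mode.

## Vulnerability assessment

Stimulation sites: greedy farthest-point sampling on the conductive surface
at 20 mm geodesic spacing, deterministic per seed, identical across the
scenarios of a patient. Tissue initial state: either 4 global beats at BCL
500 ms from a fixed earliest-activation node, or (desk-scale default) every
node set to the 100-beat limit cycle of its nearest ladder level — the two
differ by a decaying transient.

Per site: 2 local S1 at BCL 500 ms, then an S2 scan on a 10 ms grid. In 2D
the local capture threshold exceeds the cable-calibrated cell ERP because of
source–sink loading (by up to ~60–80 ms at coarse resolution), and substrate
remodeling can push it far *below* the scenario's nominal field value, so
the grid spans [ERP_hint − 120, ERP_hint + 150] ms and the threshold — the
end of the local effective refractory period — is located by bisection using
short capture-test runs (capture = new activation on a 3–8 mm ring around
the electrode). Full induction trials then cover [threshold,
threshold + 40] ms from most premature upward. Re-entry = any activation
later than 500 ms (clearance; > sheet traversal at 0.3 m/s) after the last
stimulus, requiring the record to extend ≥ 1 s past it at full scale.
Sites whose S1 fails to capture are excluded from the denominator with a
warning. The electrode is a ~1 mm disc, widened to two grid spacings on
meshes coarser than that so the 2D liminal area is resolved.

TCL of an induced re-entry: mean interval between dV/dt peaks
(threshold 10 mV/ms, 50 ms dead time) in the 1 s site recording.

**Desk-scale re-entry fixtures.** Flat sheets at the sizes used here poorly
sustain functional re-entry at atrial wavelengths, so the qualitative
comparisons use two constructed geometries:
(1) a 70 × 70 mm sheet with a 15 mm-radius long-ERP island (300 ms in a
160 ms background), where premature stimulation near the island border
induces wrap-around re-entry at 0.3 m/s but not at 0.7 m/s (wavelength);
(2) annulus geometry (70 × 70 mm, 8 mm hole) where a cut plane wave anchors
to the hole. On (2), re-entry around the homogeneous remodeled 157 ms field
cycles faster than around personalized continuous fields with ~254 ms mean
(orbit limited by refractoriness in the latter). TCLs in these fixtures are
geometry-inflated relative to full atrial models — the *difference* between
field types, not the absolute cycle length, is the reproducible quantity at
this scale — and single-site induction outcomes sit near threshold, so
count-based comparisons are reported as inequalities over a handful of
sites rather than percentages.

## Sensitivity analysis

Each measured ERP receives an independent uniform perturbation on [−r, +r],
r ∈ {2, 5, 10, 20, 50} ms, ten fresh sets per range (50 sets), seeded and
reproducible; perturbations are continuous (not snapped to the 10 ms
clinical grid) and positions are left untouched. Each set re-interpolates
scenario D and reruns the assessment; per-range aggregates are the mean/SD
of the induction ratio and the mean inducing-site count. At the reduced test
scale the per-range SD ordering (±50 ms ≥ ±2 ms) is checked; with few sites
and a smooth field both can be degenerate (zero), which the inequality
admits.

Statistics: mean ± sample SD (n−1); two-sample t-test, Welch by default
with a pooled-variance option (the variant is a choice, both exposed);
identical-sample and zero-variance-equal-mean degeneracies return p = 1.

## Synthetic patients

The generator stands in for electroanatomically mapped atria. Geometry: a
flat 100 × 100 mm default sheet (or annulus with hole "ostia"), structured
triangulation at a chosen mean edge length — no anatomical realism
(appendage shapes, CT/PM/BB bundle geometry) beyond optional labeled patches
with CV multipliers ×2/×3 applied as squared conductivity factors.
Anatomical-style regions are geodesic Voronoi cells of farthest-point seeds
(6 by default). The latent ERP field is Gaussian-filtered white noise
(30 mm correlation length) scaled to a patient mean drawn from
[222, 295] ms and within-patient SD from [11, 21] ms, clipped to the ladder
range; 4–8 measurements (round(N(5.7, 1.4)) clipped) are sampled ≥ 10 mm
apart by farthest-point sampling. The bipolar voltage map is a rank-mapped
smoothed noise field calibrated so the realized low-voltage fraction
(< 0.5 mV) matches a target drawn from N(42.8, 16.4)% clipped to [10, 80]%,
with a configurable share of the low-voltage area below the 0.1 mV lesion
cutoff (default 40%). All draws derive from one seed; regeneration is
byte-identical.

What passing tests on these patients do *not* show: behavior on real
bilayer atrial anatomies (endo/epi dissociation, interatrial connections,
fiber disarray), absolute vulnerability percentages at clinical mesh
resolution, or rate dependence of ERP beyond the single 500 ms S1 cycle
length.

## Problem sizes

Desk-scale defaults used by the tests and analysis scripts: 101-node
calibration cable; 10-level ladder; sheets of 50–70 mm at 1.25 mm edge
length (≈2.4–3.3 k nodes) at dt 50 µs; 2–6 stimulation sites per scenario;
3 re-entry replicates per TCL group; sensitivity at 2 ranges × 3 sets.
The analysis scripts expose the full-scale settings (50 ladder levels,
2 cm site sets, 5 × 10 perturbation sets) as flags.

## Known limitations

* Tissue-level refractoriness at coarse grids is inflated relative to the
  cellular calibration (discrete source–sink effects), so 2D capture
  thresholds exceed cable ERPs by tens of ms; conclusions are drawn from
  within-study contrasts, not absolute thresholds.
* The control cable ERP of this implementation is 300 ms under the stated
  protocol; the remodeled endpoint is calibrated to 157 ms by construction.
* Anchored-re-entry TCL depends on orbit geometry as well as
  refractoriness; the annulus fixture compresses (but preserves the sign
  of) ERP-driven TCL differences.
* Flat single-layer sheets with edges absorb spiral waves; whether this
  biases vulnerability up or down relative to closed atrial surfaces is
  not resolved here.
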