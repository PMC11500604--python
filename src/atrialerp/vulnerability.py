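"""Virtual S1S2 vulnerability assessment.

Stimulation sites are spread over the conductive surface by farthest-point
sampling at ~2 cm spacing and kept identical across the scenarios of one
patient.  At each site, after global pre-pacing of the tissue (4 beats at
BCL 500 ms from a fixed earliest-activation node), two local S1 are
delivered and a premature S2 is scanned on a 10 ms grid: the local capture
threshold (end of the local effective refractory period) is bisected with
short capture-test runs, then full induction trials cover the vulnerable
window starting at the most premature capturing interval.  Re-entry =
self-sustained activity outliving the paced wave: some
node activates later than a clearance window (default 500 ms) after the
last stimulus.  For every induced site the transmembrane voltage at the
site is recorded for 1 s and the tachycardia cycle length (TCL) is the mean
interval between dV/dt upstroke peaks.

The vulnerability ratio of a scenario is (# inducing sites) / (# evaluable
sites); sites whose S1 fails to capture are excluded from the denominator
with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import engine
from .monodomain import TissueMesh, StimulusEvent, run_monodomain

__all__ = [
    "StimulationSiteSet", "SiteOutcome", "VulnerabilityResult",
    "select_sites", "induce_at_site", "detect_reentry", "compute_tcl",
    "assess", "prepace_tissue", "NoSustainedActivity",
]

#: re-entry clearance window (ms): paced activity must have died out this
#: long after the last stimulus; exceeds sheet traversal time at 0.3 m/s
CLEARANCE_MS = 500.0

#: post-induction recording length (ms)
RECORD_MS = 1000.0

#: dV/dt peak detection for TCL: threshold (mV/ms) and deadtime (ms)
TCL_DVDT_THRESHOLD = 10.0
TCL_DEADTIME = 50.0


class NoSustainedActivity(Exception):
    """Fewer than two upstroke peaks in the analysis window."""


@dataclass
class StimulationSiteSet:
    node_ids: np.ndarray
    spacing: float
    seed: int = 0

    def __len__(self):
        return len(self.node_ids)


@dataclass
class SiteOutcome:
    site: int
    evaluable: bool
    induced: bool
    inducing_s2: float | None = None
    tcl: float | None = None
    n_s2_tested: int = 0
    capture_threshold: float | None = None


@dataclass
class VulnerabilityResult:
    scenario: str
    outcomes: list[SiteOutcome] = field(default_factory=list)

    @property
    def n_evaluable(self) -> int:
        return sum(o.evaluable for o in self.outcomes)

    @property
    def n_induced(self) -> int:
        return sum(o.induced for o in self.outcomes)

    @property
    def ratio(self) -> float:
        n = self.n_evaluable
        return self.n_induced / n if n else float("nan")

    @property
    def tcls(self) -> np.ndarray:
        return np.array([o.tcl for o in self.outcomes
                         if o.induced and o.tcl is not None])

    def summary(self) -> dict:
        tcls = self.tcls
        return {
            "scenario": self.scenario,
            "n_sites": len(self.outcomes),
            "n_evaluable": self.n_evaluable,
            "n_induced": self.n_induced,
            "ratio": self.ratio,
            "mean_tcl": float(tcls.mean()) if tcls.size else None,
            "sd_tcl": float(tcls.std(ddof=1)) if tcls.size > 1 else None,
        }


def select_sites(mesh: TissueMesh, spacing: float = 20.0, seed: int = 0
                 ) -> StimulationSiteSet:
    """Farthest-point sampling on the conductive surface.

    Sites are added greedily (maximizing the minimal geodesic distance to
    the chosen set) until no candidate is >= ``spacing`` away, which
    guarantees pairwise distances >= spacing.  Deterministic given seed.
    """
    cond = mesh.conductive_nodes()
    cand = np.nonzero(cond)[0]
    if cand.size == 0:
        raise ValueError("empty conductive surface")
    rng = np.random.default_rng(seed)
    start = int(rng.choice(cand))
    chosen = [start]
    dmin = mesh.geodesic_distances([start])
    while True:
        sub = np.where(cond, dmin, -np.inf)
        best = int(np.argmax(sub))
        if not np.isfinite(sub[best]) or sub[best] < spacing:
            break
        chosen.append(best)
        dmin = np.minimum(dmin, mesh.geodesic_distances([best]))
    return StimulationSiteSet(node_ids=np.array(chosen), spacing=spacing,
                              seed=seed)


def detect_reentry(last_activation: np.ndarray, t_last_stim: float,
                   record_end: float, clearance: float = CLEARANCE_MS,
                   min_record: float = 1000.0) -> bool:
    """True iff any node activated later than ``t_last_stim + clearance``.

    Requires the simulation to extend at least ``min_record`` ms past the
    last stimulus so a slowly circulating wave is not missed.
    """
    if record_end < t_last_stim + min_record - 1e-9:
        raise ValueError(
            f"record ends {record_end - t_last_stim:.0f} ms after the last "
            f"stimulus; need >= {min_record:.0f} ms")
    la = np.asarray(last_activation)
    finite = la[np.isfinite(la)]
    return bool(finite.size and finite.max() > t_last_stim + clearance)


def compute_tcl(t: np.ndarray, V: np.ndarray,
                threshold: float = TCL_DVDT_THRESHOLD,
                deadtime: float = TCL_DEADTIME) -> float:
    """Tachycardia cycle length: mean interval between dV/dt peaks (ms)."""
    t = np.asarray(t, dtype=float)
    V = np.asarray(V, dtype=float)
    dvdt = np.diff(V) / np.diff(t)
    peaks = []
    i = 0
    while i < dvdt.size:
        if dvdt[i] > threshold:
            # local maximum of this suprathreshold excursion
            j = i
            while j + 1 < dvdt.size and t[j + 1] - t[i] < deadtime:
                j += 1
            seg = dvdt[i:j + 1]
            peaks.append(t[i + int(np.argmax(seg))])
            i = j + 1
        else:
            i += 1
    if len(peaks) < 2:
        raise NoSustainedActivity(
            f"{len(peaks)} upstroke peak(s) in window; no sustained activity")
    return float(np.mean(np.diff(peaks)))


def prepace_tissue(mesh: TissueMesh, stim_node: int | None = None,
                   n_beats: int = 4, bcl: float = 500.0,
                   dt: float = engine.DT_DEFAULT) -> np.ndarray:
    """Global pre-pacing: ``n_beats`` beats at ``bcl`` from one site.

    Returns the tissue state at ``n_beats * bcl`` (diastole after the last
    paced wave).  ``stim_node`` defaults to the first conductive node (the
    synthetic stand-in for the earliest-activation site).
    """
    from .courtemanche import rest_state

    if stim_node is None:
        stim_node = int(np.nonzero(mesh.conductive_nodes())[0][0])
    stim = _stim_disc(mesh, stim_node)
    states = np.tile(rest_state(), (mesh.n_nodes, 1))
    stimuli = [StimulusEvent(stim, onset=k * bcl) for k in range(n_beats)]
    run_monodomain(mesh, stimuli, duration=n_beats * bcl, dt=dt,
                   states=states)
    return states


def _stim_disc(mesh: TissueMesh, node: int, radius: float = 1.0) -> np.ndarray:
    """Stimulation electrode: nodes within ``radius`` mm.

    On meshes coarser than the electrode the disc is widened to two grid
    spacings so the source is resolved (the liminal area for 2D capture
    needs more than a single-node source)."""
    d = np.linalg.norm(mesh.nodes - mesh.nodes[node], axis=1)
    r = max(radius, 2.01 * mesh.metadata.get("dx", radius))
    return np.nonzero(d <= r)[0]


def induce_at_site(mesh: TissueMesh, site: int,
                   prepaced: np.ndarray,
                   erp_hint: float | None = None,
                   s2_step: float = 10.0, s2_span: float = 40.0,
                   s2_margin: float = 150.0,
                   n_s1: int = 2, bcl: float = 500.0,
                   stim_amplitude: float = 30.0, stim_duration: float = 3.0,
                   clearance: float = CLEARANCE_MS,
                   record_ms: float = RECORD_MS,
                   dt: float = engine.DT_DEFAULT,
                   rec_dt: float = 0.5) -> SiteOutcome:
    """S1S2 scan at one site; returns the outcome (with TCL when induced).

    The local tissue capture threshold (the end of the local effective
    refractory period, which in 2D exceeds the cable-calibrated cell ERP
    because of source-sink loading) is first located by bisection on the
    ``s2_step`` grid using short capture-test runs; full induction trials
    are then run at the earliest capturing interval and upward across the
    vulnerable window ``[threshold, threshold + s2_span]`` until a re-entry
    is induced or the window is exhausted.  ``erp_hint`` (the scenario's
    per-node ERP at the site by default) centers the searched interval
    range ``[erp_hint - s2_step, erp_hint + s2_margin]``.
    """
    if erp_hint is None:
        ef = mesh.metadata.get("erp_field")
        erp_hint = float(ef[site]) if ef is not None else 200.0
    stim = _stim_disc(mesh, site)
    t_s1 = (n_s1 - 1) * bcl

    # ring of control nodes 3-8 mm away judges local propagated capture
    d = np.linalg.norm(mesh.nodes - mesh.nodes[site], axis=1)
    ring = np.nonzero((d >= 3.0) & (d <= 8.0) & mesh.conductive_nodes())[0]
    if ring.size == 0:
        return SiteOutcome(site=site, evaluable=False, induced=False)

    # run the local S1 train, snapshotting at every S2 candidate time; the
    # grid floor sits far below the nominal ERP hint because substrate
    # remodeling (inflammation) can shorten local refractoriness well below
    # the scenario's ERP field value
    grid = np.arange(max(60.0, erp_hint - 120.0),
                     erp_hint + s2_margin + s2_step / 2, s2_step)
    states = prepaced.copy()
    la = np.full(mesh.n_nodes, -np.inf)
    ac = np.zeros(mesh.n_nodes, dtype=np.int64)
    stimuli = [StimulusEvent(stim, onset=k * bcl, duration=stim_duration,
                             amplitude=stim_amplitude) for k in range(n_s1)]
    run_monodomain(mesh, stimuli, duration=t_s1 + stim_duration + 1.0,
                   dt=dt, states=states, last_activation=la,
                   activation_count=ac)
    if not np.any(ac[ring] >= 1):
        warnings.warn(f"site {site}: S1 did not capture; excluded")
        return SiteOutcome(site=site, evaluable=False, induced=False)

    snapshots = {}
    t_now = t_s1 + stim_duration + 1.0
    for x in grid:
        t_snap = t_s1 + x
        if t_snap < t_now:
            continue
        if t_snap > t_now:
            run_monodomain(mesh, [], duration=t_snap - t_now, dt=dt,
                           states=states, t0=t_now, last_activation=la,
                           activation_count=ac)
            t_now = t_snap
        snapshots[round(float(x), 6)] = (states.copy(), la.copy(), ac.copy())

    xs = np.array(sorted(snapshots))
    outcome = SiteOutcome(site=site, evaluable=True, induced=False)

    def trial(x, full: bool):
        """(captured, induced, record).  Short run unless ``full``."""
        st, la0, ac0 = snapshots[round(float(x), 6)]
        st = st.copy()
        la1, ac1 = la0.copy(), ac0.copy()
        t_s2 = t_s1 + float(x)
        duration = stim_duration + (record_ms + 100.0 if full else 250.0)
        rec = run_monodomain(
            mesh, [StimulusEvent(stim, onset=t_s2, duration=stim_duration,
                                 amplitude=stim_amplitude)],
            duration=duration, dt=dt, states=st, t0=t_s2,
            probes=[site], rec_dt=rec_dt,
            last_activation=la1, activation_count=ac1)
        captured = bool(np.any(ac1[ring] > ac0[ring]))
        induced = full and detect_reentry(
            la1, t_s2 + stim_duration, t_s2 + duration, clearance=clearance,
            min_record=record_ms)
        return captured, induced, (rec, t_s2)

    # bisect the capture threshold on the grid
    lo, hi = 0, xs.size - 1
    cap_hi, _, _ = trial(xs[hi], full=False)
    if not cap_hi:
        warnings.warn(f"site {site}: no capture up to "
                      f"{xs[hi]:.0f} ms; excluded")
        return SiteOutcome(site=site, evaluable=False, induced=False)
    cap_lo, _, _ = trial(xs[lo], full=False)
    if cap_lo:
        threshold = xs[lo]
    else:
        while hi - lo > 1:
            mid = (lo + hi) // 2
            cap, _, _ = trial(xs[mid], full=False)
            if cap:
                hi = mid
            else:
                lo = mid
        threshold = xs[hi]
    outcome.capture_threshold = float(threshold)

    # induction trials across the vulnerable window, most premature first
    for x in xs[(xs >= threshold) & (xs <= threshold + s2_span)]:
        captured, induced, (rec, t_s2) = trial(x, full=True)
        outcome.n_s2_tested += 1
        if not captured:
            continue  # threshold jitter; try the next interval
        if induced:
            outcome.induced = True
            outcome.inducing_s2 = float(x)
            try:
                tt, vv = rec.trace(0)
                sel = tt <= t_s2 + stim_duration + record_ms
                outcome.tcl = compute_tcl(tt[sel], vv[sel])
            except NoSustainedActivity:
                outcome.tcl = None
            break
    return outcome


def anchored_reentry_tcl(mesh: TissueMesh, ladder,
                         cv_est: float = 0.3,
                         record_ms: float = 1600.0, skip_ms: float = 500.0,
                         probe_offset: float = 3.0,
                         dt: float = engine.DT_SHEET):
    """Initiate re-entry anchored to a mesh hole and measure its TCL.

    The tissue starts at the per-node single-cell limit cycle; a plane wave
    is launched from the y-min edge and, once its front passes the hole,
    the half-domain beyond the hole center (x > cx) is reset to the limit
    cycle, leaving a free wave end that curls around the hole and keeps
    circulating if the orbit outlasts local refractoriness.  TCL is the
    mean upstroke-peak interval at a probe just outside the hole over the
    recording window after ``skip_ms`` of transient.

    Returns the TCL in ms, or None when the re-entry self-terminates.
    """
    from .calibration import paced_tissue_states

    holes = mesh.metadata.get("holes") or ()
    if len(holes) != 1:
        raise ValueError("anchored_reentry_tcl expects a mesh with one hole")
    cx, cy, r = holes[0]
    x, y = mesh.nodes[:, 0], mesh.nodes[:, 1]

    init = paced_tissue_states(mesh, ladder, dt=dt)
    states = init.copy()
    s1 = np.nonzero(y <= y.min() + 1.01 * mesh.metadata.get("dx", 1.0))[0]
    t_cut = cy / cv_est
    run_monodomain(mesh, [StimulusEvent(s1, onset=0.0)], duration=t_cut,
                   dt=dt, states=states)
    states[x > cx] = init[x > cx]

    probe = mesh.nearest_node([cx, cy + r + probe_offset, 0.0])
    la = np.full(mesh.n_nodes, -np.inf)
    ac = np.zeros(mesh.n_nodes, dtype=np.int64)
    rec = run_monodomain(mesh, [], duration=record_ms, dt=dt, states=states,
                         t0=t_cut, probes=[probe],
                         last_activation=la, activation_count=ac)
    try:
        tt, vv = rec.trace(0)
        sel = tt >= t_cut + skip_ms
        return compute_tcl(tt[sel], vv[sel])
    except NoSustainedActivity:
        return None


def induce_cross_field(mesh: TissueMesh, s2_delay: float,
                       probe=None, record_ms: float = RECORD_MS,
                       stim_amplitude: float = 30.0,
                       stim_duration: float = 3.0,
                       dt: float = engine.DT_DEFAULT, rec_dt: float = 0.5):
    """Cross-field (S1 x S2) spiral-wave initiation on a sheet.

    S1 is a plane wave from the x-min edge at t = 0; S2 excites the lower-
    left quadrant at ``s2_delay`` ms, so its wavefront breaks on the S1
    repolarization tail and curls into a spiral.  Records ``record_ms`` ms
    at ``probe`` (sheet center by default) after S2.

    Returns (record, reentry_flag) where reentry_flag uses the standard
    clearance criterion relative to the S2 stimulus.
    """
    from .courtemanche import rest_state

    x, y = mesh.nodes[:, 0], mesh.nodes[:, 1]
    xmid = 0.5 * (x.min() + x.max())
    ymid = 0.5 * (y.min() + y.max())
    s1_nodes = np.nonzero(x <= x.min() + 1.0)[0]
    s2_nodes = np.nonzero((x <= xmid) & (y <= ymid))[0]
    if probe is None:
        probe = mesh.nearest_node([xmid, ymid, 0.0])

    states = np.tile(rest_state(), (mesh.n_nodes, 1))
    la = np.full(mesh.n_nodes, -np.inf)
    ac = np.zeros(mesh.n_nodes, dtype=np.int64)
    duration = s2_delay + stim_duration + record_ms + 100.0
    rec = run_monodomain(
        mesh,
        [StimulusEvent(s1_nodes, onset=0.0, duration=stim_duration,
                       amplitude=stim_amplitude),
         StimulusEvent(s2_nodes, onset=s2_delay, duration=stim_duration,
                       amplitude=stim_amplitude)],
        duration=duration, dt=dt, states=states, probes=[probe],
        rec_dt=rec_dt, last_activation=la, activation_count=ac)
    flag = detect_reentry(la, s2_delay + stim_duration, duration,
                          min_record=record_ms)
    return rec, flag


def assess(scenarios: dict[str, TissueMesh], sites: StimulationSiteSet,
           prepace_node: int | None = None, ladder=None,
           dt: float = engine.DT_DEFAULT, **kwargs
           ) -> dict[str, VulnerabilityResult]:
    """Run the full site scan for each scenario with shared site locations.

    Tissue is pre-paced with 4 global beats at BCL 500 ms; passing
    ``ladder`` instead initializes every node at its own cell-level limit
    cycle (the cheap desk-scale equivalent).  Returns a dict of
    per-scenario results; see :func:`summary_table` for CSV export.
    """
    from .calibration import paced_tissue_states

    results = {}
    for name, mesh in scenarios.items():
        if ladder is not None:
            prepaced = paced_tissue_states(mesh, ladder, dt=dt)
        else:
            prepaced = prepace_tissue(mesh, stim_node=prepace_node, dt=dt)
        res = VulnerabilityResult(scenario=name)
        for site in sites.node_ids:
            res.outcomes.append(
                induce_at_site(mesh, int(site), prepaced.copy(), dt=dt,
                               **kwargs))
        results[name] = res
    return results


def summary_table(results: dict[str, VulnerabilityResult]):
    import pandas as pd
    return pd.DataFrame([r.summary() for r in results.values()])
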