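"""Synthetic patients: desk-scale stand-ins for mapped atrial anatomies.

Real inputs to the pipeline are an endocardial surface with region labels
and fibers, a handful of catheter ERP measurements, and a bipolar voltage
map.  This module generates statistically comparable bundles: a flat
triangulated sheet (or an annulus with holes standing in for vein/valve
ostia), contiguous anatomical-style regions, a smoothly varying fiber
field, a spatially correlated ERP field sampled at a few
catheter-spacing-apart points, and a voltage map whose low-voltage-area
(LVA) fraction is calibrated to a target.

Cohort defaults reproduce the clinical summary statistics of the seven
mapped patients (per-patient ERP mean 222-295 ms, within-patient SD
11-21 ms, 4-8 measurements, LVA fraction ~ N(42.8, 16.4)%), so that every
downstream stage runs with no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import importlib.resources

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .monodomain import TissueMesh

__all__ = [
    "SyntheticPatientSpec", "PatientBundle", "ERPMeasurementSet",
    "make_patient", "make_fixture_cable", "make_sheet", "make_cohort",
    "clinical_cohort_table", "REGION_NAMES",
]

REGION_NAMES = ("anterior", "posterior", "lateral", "septal", "inferior",
                "appendage", "veins")

#: cable ERP range spanned by the remodeling ladder (ms); synthetic
#: measurement values are clipped into it
LADDER_ERP_RANGE = (157.0, 320.0)

#: longitudinal conductivities (S/m) giving 0.3 m/s cable CV at the listed
#: mesh resolution (mm); tuned with calibration.tune_conductivity (dt 20 us
#: at 0.4 mm, 50 us at sheet resolutions) and verified by the test suite
DEFAULT_SIGMA_03 = {0.4: 0.0962, 1.0: 0.2037, 1.25: 0.2616}


def clinical_cohort_table() -> pd.DataFrame:
    """Per-patient clinical summary table (inputs to the study).

    Columns: patient, chamber, area_cm2, lva_pct, erp_mean_ms, erp_sd_ms,
    n_measurements, diagnosis.
    """
    with importlib.resources.files("atrialerp.data").joinpath(
            "cohort_summary.csv").open() as f:
        return pd.read_csv(f)


@dataclass
class ERPMeasurementSet:
    """Sparse catheter ERP measurements on (or snapped to) a mesh."""

    positions: np.ndarray        # (k, 3) mm
    erp_ms: np.ndarray           # (k,)
    patient_id: str = "synthetic"
    node_ids: np.ndarray | None = None
    region: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.erp_ms = np.asarray(self.erp_ms, dtype=float)
        if self.erp_ms.size < 1:
            raise ValueError("measurement set needs >= 1 point")
        if np.any(self.erp_ms < 100) or np.any(self.erp_ms > 400):
            raise ValueError("ERP measurements outside plausible [100, 400] ms")

    def snapped(self, mesh: TissueMesh) -> "ERPMeasurementSet":
        """Snap points to nearest mesh nodes (ties -> lowest node id)."""
        ids = np.array([mesh.nearest_node(p) for p in self.positions])
        return ERPMeasurementSet(
            positions=mesh.nodes[ids], erp_ms=self.erp_ms.copy(),
            patient_id=self.patient_id, node_ids=ids,
            region=None if self.region is None else self.region.copy())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.positions, columns=["x_mm", "y_mm", "z_mm"])
        df.insert(0, "patient_id", self.patient_id)
        df["erp_ms"] = self.erp_ms
        if self.node_ids is not None:
            df["node_id"] = self.node_ids
        if self.region is not None:
            df["region"] = self.region
        return df


@dataclass
class SyntheticPatientSpec:
    """Recipe for one virtual patient."""

    geometry: str = "sheet"            # "sheet" | "annulus"
    width: float = 100.0               # mm
    height: float = 100.0
    dx: float = 1.0                    # target mean edge length, mm
    n_regions: int = 6
    erp_mean: float | None = None      # ms; None -> drawn from [222, 295]
    erp_sd: float | None = None        # ms; None -> drawn from [11, 21]
    corr_length: float = 30.0          # mm, ERP field correlation length
    n_measurements: int | None = None  # None -> round(N(5.7, 1.4)) clip [4, 8]
    min_meas_spacing: float = 10.0     # mm
    lva_fraction: float | None = None  # None -> N(42.8, 16.4)% clip [10, 80]
    ablation_fraction_of_lva: float = 0.4
    sigma_l: float = 0.2037            # S/m (0.3 m/s at dx=1.0)
    cv_anisotropy: float = 1.0         # CV_l / CV_t; sigma_t = sigma_l/r^2
    fiber_angle_jitter: float = 0.0    # radians, smooth field amplitude
    seed: int = 0


@dataclass
class PatientBundle:
    mesh: TissueMesh
    measurements: ERPMeasurementSet
    voltage_map: np.ndarray            # per-node bipolar voltage, mV
    erp_field_true: np.ndarray         # generator's latent per-node field
    spec: SyntheticPatientSpec = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def make_sheet(width=100.0, height=100.0, dx=1.0, sigma_l=0.2037,
               cv_anisotropy=1.0, fiber_angle=0.0, holes=()) -> TissueMesh:
    """Structured triangulated sheet in the z=0 plane.

    ``holes`` is a sequence of (cx, cy, radius): triangles whose centroid
    falls inside any hole are removed (mesh openings, e.g. vein ostia).
    """
    nx = int(round(width / dx)) + 1
    ny = int(round(height / dx)) + 1
    xs = np.linspace(0, width, nx)
    ys = np.linspace(0, height, ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])

    idx = np.arange(nx * ny).reshape(nx, ny)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    tris = np.vstack([np.column_stack([a, b, c]), np.column_stack([a, c, d])])

    if holes:
        cent = nodes[tris].mean(axis=1)
        keep = np.ones(len(tris), dtype=bool)
        for (cx, cy, r) in holes:
            keep &= (cent[:, 0] - cx) ** 2 + (cent[:, 1] - cy) ** 2 > r ** 2
        tris = tris[keep]
        used = np.unique(tris)
        remap = -np.ones(nodes.shape[0], dtype=np.int64)
        remap[used] = np.arange(used.size)
        tris = remap[tris]
        nodes = nodes[used]

    m = len(tris)
    fibers = np.tile([np.cos(fiber_angle), np.sin(fiber_angle), 0.0], (m, 1))
    sigma_t = sigma_l / cv_anisotropy ** 2
    return TissueMesh(
        nodes=nodes, elements=tris, fibers=fibers,
        sigma_l=np.full(m, float(sigma_l)), sigma_t=np.full(m, sigma_t),
        conductive=np.ones(m, dtype=bool),
        region=np.zeros(nodes.shape[0], dtype=np.int64),
        metadata={"geometry": "sheet", "dx": dx, "width": width,
                  "height": height, "holes": tuple(holes)})


def make_fixture_cable(length=40.0, dx=0.4, sigma_l=0.0962) -> TissueMesh:
    """The ERP-calibration cable: 40 mm at 0.4 mm resolution (101 nodes)."""
    n = int(round(length / dx)) + 1
    nodes = np.column_stack([np.linspace(0, length, n),
                             np.zeros(n), np.zeros(n)])
    els = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    m = n - 1
    fibers = np.tile([1.0, 0.0, 0.0], (m, 1))
    return TissueMesh(
        nodes=nodes, elements=els, fibers=fibers,
        sigma_l=np.full(m, float(sigma_l)), sigma_t=np.full(m, float(sigma_l)),
        conductive=np.ones(m, dtype=bool),
        region=np.zeros(n, dtype=np.int64),
        metadata={"geometry": "cable", "dx": dx, "length": length})


# ---------------------------------------------------------------------------
# fields
# ---------------------------------------------------------------------------

def _smooth_field(mesh: TissueMesh, corr_length: float, rng) -> np.ndarray:
    """Zero-mean, unit-variance spatially correlated field on mesh nodes.

    Gaussian-filtered white noise on the bounding grid, sampled at nodes
    (the sheet/annulus nodes lie on that grid).
    """
    dx = mesh.metadata.get("dx", 1.0)
    x, y = mesh.nodes[:, 0], mesh.nodes[:, 1]
    nx = int(round((x.max() - x.min()) / dx)) + 1
    ny = int(round((y.max() - y.min()) / dx)) + 1
    noise = rng.standard_normal((nx, ny))
    f = gaussian_filter(noise, sigma=corr_length / dx / 2.0, mode="reflect")
    f = (f - f.mean()) / (f.std() + 1e-30)
    ix = np.clip(np.round((x - x.min()) / dx).astype(int), 0, nx - 1)
    iy = np.clip(np.round((y - y.min()) / dx).astype(int), 0, ny - 1)
    return f[ix, iy]


def _farthest_point_nodes(mesh: TissueMesh, k: int, min_spacing: float,
                          rng, candidates=None) -> np.ndarray:
    """k nodes pairwise >= min_spacing apart (graph geodesic), greedy FPS."""
    mask = mesh.conductive_nodes() if candidates is None else candidates
    cand = np.nonzero(mask)[0]
    start = int(rng.choice(cand))
    chosen = [start]
    dmin = mesh.geodesic_distances([start])
    while len(chosen) < k:
        sub = dmin[cand]
        best = cand[int(np.argmax(sub))]
        if dmin[best] < min_spacing:
            raise ValueError(
                f"cannot place {k} points >= {min_spacing} mm apart "
                f"(managed {len(chosen)})")
        chosen.append(int(best))
        dmin = np.minimum(dmin, mesh.geodesic_distances([best]))
    return np.array(chosen)


def _partition_regions(mesh: TissueMesh, n_regions: int, rng) -> np.ndarray:
    """Contiguous regions: geodesic Voronoi cells of FPS-sampled seeds."""
    from scipy.sparse.csgraph import dijkstra
    seeds = _farthest_point_nodes(mesh, n_regions, 0.0, rng)
    d = dijkstra(mesh.adjacency(conductive_only=False), directed=False,
                 indices=seeds)
    return np.argmin(d, axis=0).astype(np.int64)


def make_patient(spec: SyntheticPatientSpec) -> PatientBundle:
    """Generate one synthetic patient bundle (deterministic given the seed)."""
    rng = np.random.default_rng(spec.seed)

    holes = ()
    if spec.geometry == "annulus":
        w, h = spec.width, spec.height
        holes = ((0.3 * w, 0.7 * h, 0.08 * w), (0.7 * w, 0.7 * h, 0.08 * w),
                 (0.5 * w, 0.25 * h, 0.10 * w))
    elif spec.geometry != "sheet":
        raise ValueError(f"unknown geometry {spec.geometry!r}")

    jitter = spec.fiber_angle_jitter
    mesh = make_sheet(spec.width, spec.height, spec.dx, spec.sigma_l,
                      spec.cv_anisotropy, holes=holes)

    if jitter:
        ang = jitter * _smooth_field(mesh, spec.corr_length, rng)
        cent = mesh.nodes[mesh.elements].mean(axis=1)
        ix = np.array([mesh.nearest_node(p) for p in cent])
        a = ang[ix]
        mesh.fibers = np.column_stack([np.cos(a), np.sin(a), np.zeros(a.size)])

    mesh.region = _partition_regions(mesh, spec.n_regions, rng)
    mesh.metadata["region_names"] = {
        i: REGION_NAMES[i % len(REGION_NAMES)] for i in range(spec.n_regions)}

    # latent spatially correlated ERP field
    mean = (spec.erp_mean if spec.erp_mean is not None
            else rng.uniform(222.0, 295.0))
    sd = spec.erp_sd if spec.erp_sd is not None else rng.uniform(11.0, 21.0)
    g = _smooth_field(mesh, spec.corr_length, rng)
    erp_field = np.clip(mean + sd * g, *LADDER_ERP_RANGE)

    # sparse measurements
    if spec.n_measurements is None:
        n_meas = int(np.clip(round(rng.normal(5.7, 1.4)), 4, 8))
    else:
        n_meas = spec.n_measurements
    meas_nodes = _farthest_point_nodes(mesh, n_meas, spec.min_meas_spacing, rng)
    measurements = ERPMeasurementSet(
        positions=mesh.nodes[meas_nodes],
        erp_ms=erp_field[meas_nodes],
        patient_id=f"synthetic-{spec.seed}",
        node_ids=meas_nodes,
        region=mesh.region[meas_nodes])

    # voltage map calibrated to the LVA target via rank mapping
    target = (spec.lva_fraction if spec.lva_fraction is not None
              else float(np.clip(rng.normal(42.8, 16.4), 10.0, 80.0))) / 100.0
    u = _smooth_field(mesh, spec.corr_length / 2.0, rng)
    ranks = np.argsort(np.argsort(u)) / (u.size - 1.0)
    f_abl = target * spec.ablation_fraction_of_lva
    voltage = np.interp(ranks, [0.0, f_abl, target, 1.0],
                        [0.02, 0.1, 0.5, 5.0])
    realized = float(np.mean(voltage < 0.5))
    if abs(realized - target) > 0.03:
        raise RuntimeError("voltage-map calibration failed")

    mesh.metadata.update({
        "patient_id": measurements.patient_id, "seed": spec.seed,
        "erp_mean_target": mean, "erp_sd_target": sd,
        "lva_target": target, "lva_realized": realized})
    return PatientBundle(mesh=mesh, measurements=measurements,
                         voltage_map=voltage, erp_field_true=erp_field,
                         spec=spec)


def make_cohort(n=7, seed=0, **overrides) -> list[PatientBundle]:
    """Cohort of synthetic patients with per-patient seeds derived from seed."""
    out = []
    for i in range(n):
        spec = SyntheticPatientSpec(seed=seed * 1000 + i, **overrides)
        out.append(make_patient(spec))
    return out
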