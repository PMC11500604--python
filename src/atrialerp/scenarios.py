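"""Per-node ERP scenario construction and low-voltage-informed substrate.

Four ways of prescribing the refractoriness field on a tissue model:

* **A** (homogeneous): one chronic-AF remodeled cell model everywhere; the
  non-personalized literature baseline.
* **B** (heterogeneous): structure-wise literature ERPs per anatomical
  region.  The shipped table is a *reconstructed* placeholder spanning
  140-180 ms (non-personalized mean ~159 ms), editable via JSON.
* **C** (regional): each anatomical region takes the ERP of the spatially
  closest catheter measurement (average when a region holds several).
* **D** (continuous): measured ERPs fixed as Dirichlet boundary values and
  harmonically interpolated over the conductive surface, so the field never
  leaves the measured range (discrete maximum principle with non-negative
  graph-Laplacian weights).

Substrate rules driven by the bipolar voltage map: ablation lesions
(< 0.1 mV) are non-conductive; native fibrosis (0.1-0.5 mV) splits into 30%
randomly selected non-conductive elements (replacement fibrosis) and 70%
inflammation-remodeled elements; in ``fibrosis_only`` mode lesions are
treated as healthy (pre-ablation state).
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .courtemanche import INFLAMMATION, ConductanceScale
from .calibration import RemodelingLadder, erp_to_scale_array
from .monodomain import TissueMesh
from .synthetic import ERPMeasurementSet

__all__ = [
    "HEALTHY", "FIBROSIS", "ABLATION",
    "VOLTAGE_LESION_MV", "VOLTAGE_LVA_MV",
    "classify_voltage", "lva_fraction", "regional_assign",
    "laplace_interpolate", "ScenarioSpec", "build_scenario",
    "apply_substrate", "default_literature_table",
]

# voltage classes
HEALTHY, FIBROSIS, ABLATION = 0, 1, 2

#: bipolar voltage thresholds (mV): lesion < 0.1 <= fibrosis < 0.5 <= healthy
VOLTAGE_LESION_MV = 0.1
VOLTAGE_LVA_MV = 0.5

#: fraction of native-fibrosis elements set non-conductive (replacement
#: fibrosis); the rest are inflammation-remodeled
REPLACEMENT_FRACTION = 0.30


def classify_voltage(voltage: np.ndarray, mesh: TissueMesh | None = None
                     ) -> np.ndarray:
    """Per-node substrate class from bipolar voltage (mV).

    Boundary convention: ablation iff v < 0.1; fibrosis iff 0.1 <= v < 0.5;
    healthy iff v >= 0.5.
    """
    v = np.asarray(voltage, dtype=float)
    if mesh is not None and v.shape[0] != mesh.n_nodes:
        raise ValueError(
            f"voltage map covers {v.shape[0]} nodes, mesh has {mesh.n_nodes}")
    if np.any(v < 0):
        raise ValueError("bipolar voltage must be non-negative")
    out = np.full(v.shape, HEALTHY, dtype=np.int64)
    out[v < VOLTAGE_LVA_MV] = FIBROSIS
    out[v < VOLTAGE_LESION_MV] = ABLATION
    return out


def lva_fraction(voltage: np.ndarray) -> float:
    """Fraction of nodes with bipolar voltage below the 0.5 mV LVA cutoff."""
    v = np.asarray(voltage, dtype=float)
    return float(np.mean(v < VOLTAGE_LVA_MV))


def regional_assign(mesh: TissueMesh, measurements: ERPMeasurementSet,
                    regions: np.ndarray | None = None) -> np.ndarray:
    """Region-constant ERP field from sparse measurements.

    Each region takes the value of its spatially closest measurement; when a
    region contains several measurements their mean is used.  Regions
    without any measurement inherit the geodesically nearest measurement's
    value (logged via warning metadata, not an error).
    """
    meas = measurements if measurements.node_ids is not None \
        else measurements.snapped(mesh)
    regions = mesh.region if regions is None else np.asarray(regions)
    field = np.empty(mesh.n_nodes)
    dists = np.vstack([mesh.geodesic_distances([n]) for n in meas.node_ids])
    for r in np.unique(regions):
        sel = regions == r
        inside = np.nonzero(regions[meas.node_ids] == r)[0]
        if inside.size:
            field[sel] = meas.erp_ms[inside].mean()
        else:
            # nearest measurement by geodesic distance to the region
            k = int(np.argmin(dists[:, sel].min(axis=1)))
            field[sel] = meas.erp_ms[k]
    return field


def laplace_interpolate(mesh: TissueMesh, measurements: ERPMeasurementSet
                        ) -> np.ndarray:
    """Harmonic interpolation of measurements over the conductive surface.

    Solves the graph-Laplace equation with measurement nodes as Dirichlet
    boundary conditions, using uniform non-negative edge weights so the
    discrete maximum principle holds: the field interpolates the
    measurements exactly and stays within their range.  Nodes outside the
    conductive subgraph keep the nearest measured value.
    """
    meas = measurements if measurements.node_ids is not None \
        else measurements.snapped(mesh)
    ids, inv = np.unique(meas.node_ids, return_inverse=True)
    vals = np.full(ids.size, np.nan)
    for k, i in enumerate(inv):
        if np.isnan(vals[i]):
            vals[i] = meas.erp_ms[k]
        elif abs(vals[i] - meas.erp_ms[k]) > 1e-9:
            raise ValueError(
                f"conflicting measurements snapped to node {ids[i]}")

    n = mesh.n_nodes
    ncomp, comp = mesh.conductive_components()
    for c in range(ncomp):
        if not np.any(comp[ids] == c):
            raise ValueError(
                f"conductive component {c} contains no measurement; "
                "cannot interpolate")

    pairs, _ = mesh.edges(conductive_only=True)
    w = np.ones(pairs.shape[0])
    A = sp.coo_matrix((w, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    A = (A + A.T).tocsr()
    deg = np.asarray(A.sum(axis=1)).ravel()
    L = sp.diags(deg) - A

    field = np.empty(n)
    fixed = np.zeros(n, dtype=bool)
    fixed[ids] = True
    field[ids] = vals
    free = np.nonzero(~fixed & (comp >= 0))[0]
    if free.size:
        Lff = L[free][:, free].tocsc()
        rhs = -L[free][:, ids] @ vals
        field[free] = spla.spsolve(Lff, rhs)
    # isolated (non-conductive) nodes: nearest measured value by euclid
    rest = np.nonzero(~fixed & (comp < 0))[0]
    if rest.size:
        for i in rest:
            d = np.linalg.norm(mesh.nodes[ids] - mesh.nodes[i], axis=1)
            field[i] = vals[int(np.argmin(d))]
    # clamp round-off so the maximum principle holds exactly
    field = np.clip(field, vals.min(), vals.max())
    field[ids] = vals
    return field


def default_literature_table() -> dict:
    """Reconstructed structure-wise ERP table (ms) for scenario B."""
    with importlib.resources.files("atrialerp.data").joinpath(
            "literature_erp_table.json").open() as f:
        return json.load(f)


@dataclass
class ScenarioSpec:
    """What ERP field to build and which substrate rules to apply."""

    kind: str                               # "A" | "B" | "C" | "D"
    substrate: str = "none"                 # none|lesions_and_fibrosis|fibrosis_only
    literature_table: dict | None = None    # region name -> ERP ms (B)
    cv_target: float = 0.3                  # m/s, bookkeeping only

    def __post_init__(self):
        if self.kind not in "ABCD" or len(self.kind) != 1:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.substrate not in ("none", "lesions_and_fibrosis",
                                  "fibrosis_only"):
            raise ValueError(f"unknown substrate mode {self.substrate!r}")


def _ladder_hash(ladder: RemodelingLadder) -> str:
    h = hashlib.sha1()
    h.update(np.array([lv.as_array() for lv in ladder.levels]).tobytes())
    h.update(ladder.erp_ms.tobytes())
    return h.hexdigest()[:12]


def build_scenario(mesh: TissueMesh, spec: ScenarioSpec,
                   ladder: RemodelingLadder,
                   measurements: ERPMeasurementSet | None = None,
                   voltage_map: np.ndarray | None = None,
                   seed: int = 0) -> TissueMesh:
    """Return a copy of ``mesh`` with per-node conductance multipliers (and
    substrate) realizing the scenario.

    The per-node ERP field used is stored in ``metadata["erp_field"]``.
    """
    if spec.kind in "CD" and measurements is None:
        raise ValueError(f"scenario {spec.kind} requires an ERP measurement set")
    if spec.substrate != "none" and voltage_map is None:
        raise ValueError("substrate modeling requires a voltage map")

    out = mesh.copy()
    if measurements is not None:
        # (re-)snap onto this mesh: node ids from another mesh are invalid
        measurements = measurements.snapped(out)
    if spec.kind == "A":
        field = np.full(out.n_nodes, ladder.erp_ms[-1])
        out.scales[:] = ladder.levels[-1].as_array()
    elif spec.kind == "B":
        table = spec.literature_table or default_literature_table()
        names = out.metadata.get("region_names", {})
        field = np.empty(out.n_nodes)
        for r in np.unique(out.region):
            name = names.get(int(r), str(int(r)))
            if name not in table and "default" not in table:
                raise ValueError(f"literature table lacks region {name!r}")
            field[out.region == r] = table.get(name, table.get("default"))
        out.scales[:] = erp_to_scale_array(field, ladder)
    elif spec.kind == "C":
        field = regional_assign(out, measurements)
        out.scales[:] = erp_to_scale_array(field, ladder)
    else:  # D
        field = laplace_interpolate(out, measurements)
        out.scales[:] = erp_to_scale_array(field, ladder)

    out.metadata.update({
        "scenario": spec.kind, "substrate": spec.substrate,
        "erp_field": field, "ladder_hash": _ladder_hash(ladder),
        "seed": seed,
    })
    if spec.substrate != "none":
        classes = classify_voltage(voltage_map, out)
        out = apply_substrate(out, classes, spec.substrate, seed=seed)
    return out


def _element_classes(mesh: TissueMesh, node_classes: np.ndarray) -> np.ndarray:
    """Element class by node-majority vote; ties resolved to the more severe
    class (ablation > fibrosis > healthy)."""
    nc = node_classes[mesh.elements]          # (m, 2 or 3)
    counts = np.stack([(nc == k).sum(axis=1) for k in (HEALTHY, FIBROSIS,
                                                       ABLATION)], axis=1)
    # argmax of (count, severity): scan severity descending
    best = np.full(mesh.n_elements, HEALTHY, dtype=np.int64)
    bestc = counts[:, HEALTHY].copy()
    for k in (FIBROSIS, ABLATION):
        take = counts[:, k] >= bestc
        best[take] = k
        bestc[take] = counts[take, k]
    return best


def apply_substrate(mesh: TissueMesh, classes: np.ndarray, mode: str,
                    seed: int = 0,
                    inflammation: ConductanceScale = INFLAMMATION.scale
                    ) -> TissueMesh:
    """Apply low-voltage substrate rules in place of a fresh copy.

    ``classes`` is the per-node output of :func:`classify_voltage`.  In
    ``lesions_and_fibrosis`` mode ablation-class elements become
    non-conductive; in ``fibrosis_only`` mode they stay healthy.  Of the
    fibrosis-class elements, 30% (rounded half up, seeded uniform sampling
    without replacement) become non-conductive; the nodes of the remaining
    70% compose the inflammation remodeling multiplicatively with their
    scenario scaling.
    """
    if mode not in ("lesions_and_fibrosis", "fibrosis_only"):
        raise ValueError(f"unknown substrate mode {mode!r}")
    out = mesh.copy()
    ec = _element_classes(out, np.asarray(classes))

    abl_el = np.nonzero(ec == ABLATION)[0]
    fib_el = np.nonzero(ec == FIBROSIS)[0]
    if mode == "lesions_and_fibrosis":
        if abl_el.size == 0:
            warnings.warn("lesions_and_fibrosis mode but no ablation-class "
                          "elements present")
        out.conductive[abl_el] = False

    rng = np.random.default_rng(seed)
    n_replace = int(np.floor(REPLACEMENT_FRACTION * fib_el.size + 0.5))
    replaced = rng.choice(fib_el, size=n_replace, replace=False) \
        if n_replace else np.empty(0, dtype=np.int64)
    out.conductive[replaced] = False

    inflamed_el = np.setdiff1d(fib_el, replaced)
    inflamed_nodes = np.unique(out.elements[inflamed_el]) \
        if inflamed_el.size else np.empty(0, dtype=np.int64)
    out.scales[inflamed_nodes] *= inflammation.as_array()

    out.metadata.update({
        "substrate_mode": mode, "substrate_seed": seed,
        "n_ablation_elements": int(abl_el.size if mode == "lesions_and_fibrosis" else 0),
        "n_fibrosis_elements": int(fib_el.size),
        "n_replacement_elements": int(n_replace),
        "inflamed_nodes": inflamed_nodes,
    })
    out.invalidate_operator()
    return out
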