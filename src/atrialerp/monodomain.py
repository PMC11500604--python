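"""Monodomain propagation on 1D cables and triangulated surfaces.

The transmembrane voltage obeys a reaction-diffusion equation

    dV/dt = div(D grad V) - I_ion + J_stim,

with a per-element anisotropic diffusivity tensor
``D = D_t I + (D_l - D_t) f f^T`` built from the element fiber direction
``f``.  Diffusivities derive from monodomain conductivities via
``D = sigma / (beta * C_m)`` with the membrane surface-to-volume ratio
``beta = 0.14 um^-1`` and specific capacitance ``C_m = 1 uF/cm^2``; since
conductivities are always tuned to conduction-velocity targets, only the
product matters.  Spatial discretization is linear finite elements (exact
second-order differences on uniform cables) with lumped mass; time stepping
is a fused explicit step with Rush-Larsen gates (see
:mod:`atrialerp.engine`).

Distances are mm, times ms, so velocities come out in mm/ms = m/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra

from . import engine

__all__ = [
    "TissueMesh", "StimulusEvent", "SimulationRecord",
    "run_monodomain", "measure_cv", "ConductionBlock",
    "SIGMA_NONCONDUCTIVE", "sigma_to_diffusivity",
]

#: conductivity assigned to non-conductive (replacement fibrosis / lesion)
#: elements, S/m
SIGMA_NONCONDUCTIVE = 1e-7

#: beta * C_m in units turning sigma [S/m] into D [mm^2/ms]
_BETA_CM = 1.4


def sigma_to_diffusivity(sigma):
    """Monodomain conductivity (S/m) -> diffusivity (mm^2/ms)."""
    return np.asarray(sigma, dtype=float) / _BETA_CM


class ConductionBlock(Exception):
    """Raised when a propagation measurement finds no propagated wave."""


@dataclass
class TissueMesh:
    """Nodes, elements and per-element/per-node attributes of a tissue model.

    Elements are index pairs (cable segments) or triplets (surface
    triangles).  ``fibers`` are unit vectors per element; ``sigma_l`` /
    ``sigma_t`` longitudinal/transverse conductivities in S/m;
    ``conductive`` flags replacement-fibrosis or lesion elements (False ->
    conductivity clamped to :data:`SIGMA_NONCONDUCTIVE`); ``region`` is a
    per-node anatomical label and ``scales`` the per-node conductance
    multipliers of the cell model.
    """

    nodes: np.ndarray
    elements: np.ndarray
    fibers: np.ndarray
    sigma_l: np.ndarray
    sigma_t: np.ndarray
    conductive: np.ndarray
    region: np.ndarray
    scales: np.ndarray = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        n = self.n_nodes
        if self.scales is None:
            self.scales = np.ones((n, 9))
        norms = np.linalg.norm(self.fibers, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("fiber vectors must be unit length")
        if np.any(self.sigma_l < 0) or np.any(self.sigma_t < 0):
            raise ValueError("conductivities must be >= 0")
        self._op_cache = None

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def is_cable(self) -> bool:
        return self.elements.shape[1] == 2

    def copy(self) -> "TissueMesh":
        return TissueMesh(
            nodes=self.nodes.copy(), elements=self.elements.copy(),
            fibers=self.fibers.copy(), sigma_l=self.sigma_l.copy(),
            sigma_t=self.sigma_t.copy(), conductive=self.conductive.copy(),
            region=self.region.copy(), scales=self.scales.copy(),
            metadata=dict(self.metadata))

    # -- connectivity ------------------------------------------------------

    def effective_sigma(self):
        """(sigma_l, sigma_t) with non-conductive elements clamped."""
        sl = np.where(self.conductive, self.sigma_l, SIGMA_NONCONDUCTIVE)
        st = np.where(self.conductive, self.sigma_t, SIGMA_NONCONDUCTIVE)
        return sl, st

    def conductive_nodes(self) -> np.ndarray:
        """Boolean mask of nodes incident to >= 1 conductive element."""
        mask = np.zeros(self.n_nodes, dtype=bool)
        mask[np.unique(self.elements[self.conductive])] = True
        return mask

    def edges(self, conductive_only: bool = False):
        """Unique undirected node-index edges (and their lengths)."""
        els = self.elements[self.conductive] if conductive_only else self.elements
        if self.is_cable:
            pairs = els
        else:
            pairs = np.vstack([els[:, [0, 1]], els[:, [1, 2]], els[:, [0, 2]]])
        pairs = np.sort(pairs, axis=1)
        pairs = np.unique(pairs, axis=0)
        lengths = np.linalg.norm(self.nodes[pairs[:, 0]] - self.nodes[pairs[:, 1]],
                                 axis=1)
        return pairs, lengths

    def adjacency(self, conductive_only: bool = True) -> sp.csr_matrix:
        pairs, lengths = self.edges(conductive_only)
        n = self.n_nodes
        a = sp.coo_matrix((lengths, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
        return (a + a.T).tocsr()

    def conductive_components(self):
        """Connected components of the conductive subgraph.

        Returns (n_components, labels) over conductive nodes only; nodes
        outside the conductive subgraph get label -1.
        """
        mask = self.conductive_nodes()
        adj = self.adjacency(conductive_only=True)
        ncomp, labels = connected_components(adj, directed=False)
        labels = labels.copy()
        labels[~mask] = -1
        # renumber components restricted to conductive nodes
        uniq = np.unique(labels[mask])
        remap = {int(u): i for i, u in enumerate(uniq)}
        out = np.array([remap.get(int(l), -1) for l in labels])
        return len(uniq), out

    def geodesic_distances(self, sources) -> np.ndarray:
        """Graph geodesic distance (mm) from ``sources`` over conductive edges."""
        adj = self.adjacency(conductive_only=True)
        d = dijkstra(adj, directed=False, indices=np.atleast_1d(sources))
        return d.min(axis=0) if d.ndim == 2 else d

    def nearest_node(self, point) -> int:
        """Mesh node closest to ``point`` (ties -> lowest node id)."""
        d = np.linalg.norm(self.nodes - np.asarray(point, dtype=float), axis=1)
        return int(np.argmin(d))  # argmin takes the first (lowest id) on ties

    # -- discrete operator -------------------------------------------------

    def operator(self):
        """Assembled (indptr, indices, data, inv_lumped_mass) for the engine."""
        if self._op_cache is None:
            self._op_cache = _assemble(self)
        return self._op_cache

    def invalidate_operator(self):
        self._op_cache = None


def _assemble(mesh: TissueMesh):
    sl, st = mesh.effective_sigma()
    Dl = sigma_to_diffusivity(sl)
    Dt = sigma_to_diffusivity(st)
    n = mesh.n_nodes
    rows, cols, vals = [], [], []
    mass = np.zeros(n)

    if mesh.is_cable:
        i, j = mesh.elements[:, 0], mesh.elements[:, 1]
        h = np.linalg.norm(mesh.nodes[j] - mesh.nodes[i], axis=1)
        w = Dl / h
        rows = np.concatenate([i, j, i, j])
        cols = np.concatenate([i, j, j, i])
        vals = np.concatenate([w, w, -w, -w])
        np.add.at(mass, i, h / 2)
        np.add.at(mass, j, h / 2)
    else:
        tri = mesh.elements
        p0, p1, p2 = (mesh.nodes[tri[:, k]] for k in range(3))
        e1 = p1 - p0
        e2 = p2 - p0
        # local orthonormal in-plane frame
        u = e1 / np.linalg.norm(e1, axis=1, keepdims=True)
        nrm = np.cross(e1, e2)
        area2 = np.linalg.norm(nrm, axis=1)
        if np.any(area2 <= 0):
            raise ValueError("degenerate triangle in mesh")
        nrm = nrm / area2[:, None]
        v = np.cross(nrm, u)
        # 2D coordinates of the three vertices
        x = np.zeros((len(tri), 3, 2))
        x[:, 1, 0] = np.einsum("ij,ij->i", e1, u)
        x[:, 2, 0] = np.einsum("ij,ij->i", e2, u)
        x[:, 2, 1] = np.einsum("ij,ij->i", e2, v)
        area = area2 / 2
        # P1 gradients: grad phi_k = rot of opposite edge / (2 area)
        b = np.empty((len(tri), 3))
        c = np.empty((len(tri), 3))
        for k in range(3):
            k1, k2 = (k + 1) % 3, (k + 2) % 3
            b[:, k] = x[:, k1, 1] - x[:, k2, 1]
            c[:, k] = x[:, k2, 0] - x[:, k1, 0]
        b /= (2 * area)[:, None]
        c /= (2 * area)[:, None]
        # project fibers into the element plane
        f_u = np.einsum("ij,ij->i", mesh.fibers, u)
        f_v = np.einsum("ij,ij->i", mesh.fibers, v)
        fn = np.hypot(f_u, f_v)
        small = fn < 1e-8
        f_u = np.where(small, 1.0, f_u / np.where(small, 1.0, fn))
        f_v = np.where(small, 0.0, f_v / np.where(small, 1.0, fn))
        d11 = Dt + (Dl - Dt) * f_u * f_u
        d22 = Dt + (Dl - Dt) * f_v * f_v
        d12 = (Dl - Dt) * f_u * f_v
        rows, cols, vals = [], [], []
        for a_ in range(3):
            for b_ in range(3):
                k_ab = area * (
                    d11 * b[:, a_] * b[:, b_] + d22 * c[:, a_] * c[:, b_]
                    + d12 * (b[:, a_] * c[:, b_] + c[:, a_] * b[:, b_]))
                rows.append(tri[:, a_])
                cols.append(tri[:, b_])
                vals.append(k_ab)
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        for k in range(3):
            np.add.at(mass, tri[:, k], area / 3)

    K = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    K.sum_duplicates()
    inv_mass = 1.0 / mass
    return (K.indptr.astype(np.int64), K.indices.astype(np.int64),
            np.ascontiguousarray(K.data), np.ascontiguousarray(inv_mass))


@dataclass
class StimulusEvent:
    """Transmembrane current injection on a node set."""

    nodes: np.ndarray
    onset: float
    duration: float = 3.0      # ms
    amplitude: float = 30.0    # uA/cm^2, depolarizing

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("stimulus duration must be > 0")
        self.nodes = np.asarray(self.nodes, dtype=np.int64)


@dataclass
class SimulationRecord:
    """Probe traces plus per-node activation bookkeeping."""

    t: np.ndarray
    probes: np.ndarray
    V: np.ndarray              # (n_samples, n_probes)
    last_activation: np.ndarray
    activation_count: np.ndarray
    duration: float

    def trace(self, probe_index: int = 0):
        return self.t, self.V[:, probe_index]


def run_monodomain(mesh: TissueMesh, stimuli, duration, probes=None,
                   dt: float = engine.DT_DEFAULT, rec_dt: float = 0.5,
                   states: np.ndarray | None = None, t0: float = 0.0,
                   last_activation=None, activation_count=None
                   ) -> SimulationRecord:
    """Run the monodomain model for ``duration`` ms (state advanced in place
    when ``states`` is supplied).

    Raises ``FloatingPointError`` on numerical divergence (|V| > 200 mV) and
    warns when a stimulus targets only non-conductive nodes.
    """
    from .courtemanche import rest_state

    if states is None:
        states = np.tile(rest_state(), (mesh.n_nodes, 1))
    cond = mesh.conductive_nodes()
    for s in stimuli:
        if s.onset + s.duration > t0 + duration + 1e-9:
            raise ValueError("stimulus extends beyond simulation duration")
        if s.nodes.size and not cond[s.nodes].any():
            warnings.warn("stimulus delivered entirely on non-conductive nodes")
    events = [(s.onset, s.duration, s.amplitude, s.nodes) for s in stimuli]
    probes = np.asarray([] if probes is None else probes, dtype=np.int64)
    t, V, last_act, act_count, code = engine.run_tissue(
        states, mesh.scales, mesh.operator(), events, dt, duration, t0=t0,
        probes=probes, rec_dt=rec_dt,
        last_act=last_activation, act_count=activation_count)
    if code != 0:
        raise FloatingPointError(
            "monodomain integration diverged (|V| > 200 mV or non-finite)")
    return SimulationRecord(t=t, probes=probes, V=V, last_activation=last_act,
                            activation_count=act_count, duration=duration)


def measure_cv(mesh: TissueMesh, dt: float = engine.DT_DEFAULT,
               stim_nodes=None, states: np.ndarray | None = None,
               timeout: float = 400.0) -> float:
    """Conduction velocity (m/s) on a cable paced at one end.

    Activation times over the central 50% of the cable (boundary effects
    excluded) are regressed against distance.  Raises
    :class:`ConductionBlock` when the far end never activates.
    """
    if not mesh.is_cable:
        raise ValueError("measure_cv expects a cable mesh")
    n = mesh.n_nodes
    xs = mesh.nodes[:, 0]
    if stim_nodes is None:
        w = max(1.0, 2.01 * mesh.metadata.get("dx", 0.5))
        stim_nodes = np.nonzero(xs <= xs.min() + w)[0]
    st = None if states is None else states.copy()
    rec = run_monodomain(mesh, [StimulusEvent(stim_nodes, onset=1.0)],
                         duration=timeout, dt=dt, states=st)
    central = (xs >= xs.min() + 0.25 * (xs.max() - xs.min())) & \
              (xs <= xs.min() + 0.75 * (xs.max() - xs.min()))
    ta = rec.last_activation[central]
    if np.any(~np.isfinite(ta)):
        raise ConductionBlock("no propagation across the central cable segment")
    slope = np.polyfit(xs[central], ta, 1)[0]   # ms / mm
    if slope <= 0:
        raise ConductionBlock("non-positive activation-time gradient")
    return float(1.0 / slope)                    # mm/ms == m/s
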