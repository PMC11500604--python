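"""Cable S1S2 ERP measurement, conductivity tuning, and the remodeling ladder.

The effective refractory period (ERP) of a cellular parameterization is
measured on a 40 mm, 0.4 mm-resolution tissue cable: the cell is paced to
its limit cycle (100 beats at BCL 500 ms), the cable is paced with a train
of S1 stimuli at one end, and a premature S2 is scanned over coupling
intervals on a 1 ms grid.  ERP is the longest S1S2 interval that fails to
produce a propagated response ("capture" = an S2-elicited activation
reaching the distal cable half).  Because capture is monotone in the
coupling interval, the scan is performed by bisection on the interval grid
(equivalent to, and verified against, a descending scan with early exit).

The remodeling ladder linearly interpolates each conductance multiplier
from control to a calibrated chronic-AF endpoint over 50 levels and tabul-
ates the cable ERP of every level; its inverse maps a target ERP to a
multiplier set by linear interpolation between the bracketing levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import engine
from .courtemanche import (ConductanceScale, AF_DIRECTION, pace_to_limit_cycle)
from .monodomain import (TissueMesh, StimulusEvent, run_monodomain,
                         measure_cv, ConductionBlock)
from .synthetic import make_fixture_cable

__all__ = [
    "S1S2Protocol", "RemodelingLadder", "cable_erp", "build_ladder",
    "erp_to_scale", "erp_to_scale_array", "tune_conductivity",
    "calibrate_af_endpoint", "ErpOutOfRange", "NoS1Capture",
    "IN_SILICO_PROTOCOL", "CLINICAL_PROTOCOL",
]


class ErpOutOfRange(Exception):
    """ERP lies outside the scanned S2 interval range."""


class NoS1Capture(Exception):
    """The S1 train itself failed to propagate."""


@dataclass(frozen=True)
class S1S2Protocol:
    """Extra-stimulus pacing protocol parameters (ms / uA/cm^2)."""

    n_s1: int = 7
    bcl: float = 500.0
    s2_start: float = 350.0
    s2_stop: float = 140.0
    s2_step: float = 1.0
    stim_duration: float = 3.0
    stim_amplitude: float = 30.0

    def s2_grid(self) -> np.ndarray:
        """Descending S2 coupling intervals."""
        return np.arange(self.s2_start, self.s2_stop - 1e-9, -self.s2_step)


#: in-silico ERP identification: S2 from 350 ms down in 1 ms steps
IN_SILICO_PROTOCOL = S1S2Protocol()
#: emulation of the clinical protocol: S2 between 300 and 200 ms, 10 ms steps
CLINICAL_PROTOCOL = S1S2Protocol(s2_start=300.0, s2_stop=200.0, s2_step=10.0)

#: capture window after S2 onset (ms): generous enough for a decrementally
#: conducting premature wave to cross 30 mm at slow CV
CAPTURE_WINDOW = 200.0

_CABLE_CACHE: dict = {}
_CELL_CACHE: dict = {}


def _paced_cell(scale_arr: np.ndarray, bcl: float, dt: float) -> np.ndarray:
    key = (scale_arr.tobytes(), bcl, dt)
    if key not in _CELL_CACHE:
        res = pace_to_limit_cycle(scale_arr, bcl=bcl, n_beats=100, dt=dt)
        _CELL_CACHE[key] = res.state
    return _CELL_CACHE[key]


def _cable_after_s1(scale_arr, protocol: S1S2Protocol, cable: TissueMesh,
                    dt: float):
    """State of the cable immediately before the last S1 of the train,
    plus the stimulated node set.  Cached per (scale, protocol, cable, dt).
    """
    key = (scale_arr.tobytes(), protocol, float(cable.sigma_l[0]),
           cable.n_nodes, dt)
    if key in _CABLE_CACHE:
        return _CABLE_CACHE[key]
    cell = _paced_cell(scale_arr, protocol.bcl, dt)
    cable = cable.copy()
    cable.scales[:] = scale_arr
    states = np.tile(cell, (cable.n_nodes, 1))
    xs = cable.nodes[:, 0]
    w = max(1.0, 2.01 * cable.metadata.get("dx", 0.5))
    stim_nodes = np.nonzero(xs <= xs.min() + w)[0]
    t_last = (protocol.n_s1 - 1) * protocol.bcl
    if t_last > 0:
        stimuli = [StimulusEvent(stim_nodes, onset=k * protocol.bcl,
                                 duration=protocol.stim_duration,
                                 amplitude=protocol.stim_amplitude)
                   for k in range(protocol.n_s1 - 1)]
        run_monodomain(cable, stimuli, duration=t_last, dt=dt, states=states)
    _CABLE_CACHE[key] = (cable, states, stim_nodes)
    return _CABLE_CACHE[key]


def _s2_trial(states0, stim_nodes, cable: TissueMesh, s2: float,
              protocol: S1S2Protocol, dt: float):
    """Deliver the final S1 plus one S2 at coupling interval ``s2``.

    Returns (s1_captured, s2_captured) judged at nodes >= 30 mm from the
    stimulated end.
    """
    states = states0.copy()
    stimuli = [
        StimulusEvent(stim_nodes, onset=0.0, duration=protocol.stim_duration,
                      amplitude=protocol.stim_amplitude),
        StimulusEvent(stim_nodes, onset=s2, duration=protocol.stim_duration,
                      amplitude=protocol.stim_amplitude),
    ]
    duration = s2 + protocol.stim_duration + CAPTURE_WINDOW + 5.0
    rec = run_monodomain(cable, stimuli, duration=duration, dt=dt,
                         states=states)
    xs = cable.nodes[:, 0]
    far = xs >= xs.min() + 30.0
    la = rec.last_activation[far]
    ac = rec.activation_count[far]
    s2_ok = bool(np.any((ac >= 2) & (la > s2 + dt)
                        & (la <= s2 + protocol.stim_duration + CAPTURE_WINDOW)))
    s1_ok = bool(np.any((ac == 1) & (la <= s2))) or s2_ok
    return s1_ok, s2_ok


def cable_erp(scale: ConductanceScale | np.ndarray,
              protocol: S1S2Protocol = IN_SILICO_PROTOCOL,
              cable: TissueMesh | None = None,
              dt: float = engine.DT_DEFAULT,
              method: str = "bisect") -> float:
    """Cable ERP (ms): the longest S1S2 interval without capture.

    ``method`` is "bisect" (default; valid because capture is monotone in
    the coupling interval) or "scan" (descending with early exit).
    """
    s = (scale.as_array() if isinstance(scale, ConductanceScale)
         else np.asarray(scale, dtype=float))
    if cable is None:
        cable = make_fixture_cable()
    cable, states0, stim_nodes = _cable_after_s1(s, protocol, cable, dt)
    grid = protocol.s2_grid()
    if grid.size == 0:
        raise ValueError("empty S2 grid")

    def trial(x):
        s1_ok, s2_ok = _s2_trial(states0, stim_nodes, cable, x, protocol, dt)
        if not s1_ok:
            raise NoS1Capture("S1 train did not propagate to the distal half")
        return s2_ok

    if method == "scan":
        seen_capture = False
        for x in grid:
            if trial(x):
                seen_capture = True
            else:
                if not seen_capture:
                    raise ErpOutOfRange(
                        f"no capture at S2 start {grid[0]} ms: ERP at or "
                        "above scan range")
                return float(x)
        raise ErpOutOfRange(
            f"capture at every tested S2 down to {grid[-1]} ms: ERP below "
            "scan range")

    # bisection on the descending grid: find the first non-capturing index
    if not trial(grid[0]):
        raise ErpOutOfRange(f"no capture at S2 start {grid[0]} ms: ERP at or "
                            "above scan range")
    if trial(grid[-1]):
        raise ErpOutOfRange(f"capture at every tested S2 down to "
                            f"{grid[-1]} ms: ERP below scan range")
    lo, hi = 0, grid.size - 1          # grid[lo] captures, grid[hi] does not
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if trial(grid[mid]):
            lo = mid
        else:
            hi = mid
    return float(grid[hi])


# ---------------------------------------------------------------------------
# conductivity tuning
# ---------------------------------------------------------------------------

def tune_conductivity(target_cv: float, dx: float = 0.4, length: float = 40.0,
                      dt: float = engine.DT_DEFAULT,
                      scale: ConductanceScale | np.ndarray | None = None,
                      tol: float = 0.01, bounds=(1e-3, 3.0)) -> float:
    """Longitudinal conductivity (S/m) giving cable CV = ``target_cv`` m/s.

    Bisection on log-conductivity; |CV - target| < ``tol`` at return.
    """
    if target_cv <= 0:
        raise ValueError("target_cv must be positive")
    s = (np.ones(9) if scale is None
         else scale.as_array() if isinstance(scale, ConductanceScale)
         else np.asarray(scale, dtype=float))
    cell = _paced_cell(s, 500.0, dt)

    def cv_of(sigma):
        cable = make_fixture_cable(length=length, dx=dx, sigma_l=sigma)
        cable.scales[:] = s
        states = np.tile(cell, (cable.n_nodes, 1))
        try:
            return measure_cv(cable, dt=dt, states=states)
        except ConductionBlock:
            return 0.0

    # cap the bracket at the explicit-diffusion stability limit for (dx, dt)
    sigma_stable = 0.45 * 1.4 * dx * dx / dt
    lo, hi = bounds[0], min(bounds[1], sigma_stable)
    cv_lo, cv_hi = cv_of(lo), cv_of(hi)
    if not (cv_lo < target_cv < cv_hi):
        raise ValueError(
            f"target CV {target_cv} m/s not bracketed by conductivities "
            f"{bounds} (CV range [{cv_lo:.3f}, {cv_hi:.3f}])")
    for _ in range(60):
        mid = np.sqrt(lo * hi)
        cv = cv_of(mid)
        if abs(cv - target_cv) < tol:
            return float(mid)
        if cv < target_cv:
            lo = mid
        else:
            hi = mid
    raise RuntimeError("conductivity tuning did not converge")


# ---------------------------------------------------------------------------
# remodeling ladder
# ---------------------------------------------------------------------------

@dataclass
class RemodelingLadder:
    """Ordered cell-model family from control (level 0) to the AF endpoint."""

    levels: list                 # list[ConductanceScale]
    erp_ms: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.erp_ms = np.asarray(self.erp_ms, dtype=float)
        if len(self.levels) != self.erp_ms.size:
            raise ValueError("levels and erp_ms must have equal length")
        d = np.diff(self.erp_ms)
        if np.any(d > 1.0 + 1e-9):
            raise ValueError(
                "ladder ERP not monotone non-increasing (beyond 1 ms "
                "step-quantization tolerance): mis-specified endpoint?")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def erp_range(self):
        return float(self.erp_ms.min()), float(self.erp_ms.max())

    def to_frame(self) -> pd.DataFrame:
        from .courtemanche import SCALE_NAMES
        rows = [lv.as_array() for lv in self.levels]
        df = pd.DataFrame(rows, columns=list(SCALE_NAMES))
        df.insert(0, "level", np.arange(self.n_levels))
        df["erp_ms"] = self.erp_ms
        return df

    def save_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def load_csv(path) -> "RemodelingLadder":
        from .courtemanche import SCALE_NAMES
        df = pd.read_csv(path)
        levels = [ConductanceScale.from_array(row)
                  for row in df[list(SCALE_NAMES)].to_numpy()]
        return RemodelingLadder(levels=levels,
                                erp_ms=df["erp_ms"].to_numpy())


def paced_tissue_states(mesh: TissueMesh, ladder: "RemodelingLadder" = None,
                        bcl: float = 500.0,
                        dt: float = engine.DT_DEFAULT) -> np.ndarray:
    """Per-node initial states at the single-cell limit cycle.

    Nodes are initialized from the 100-beat limit cycle of the nearest
    ladder level (by the scenario's per-node ERP field) or, without a
    ladder, of their exact scale when homogeneous.  This stands in for long
    tissue pre-pacing when only a diastolic starting state is needed.
    """
    n = mesh.n_nodes
    states = np.empty((n, 21))
    field = mesh.metadata.get("erp_field")
    if ladder is not None and field is not None:
        idx = np.abs(field[:, None] - ladder.erp_ms[None, :]).argmin(axis=1)
        for k in np.unique(idx):
            cell = _paced_cell(ladder.levels[int(k)].as_array(), bcl, dt)
            states[idx == k] = cell
    else:
        uniq, inv = np.unique(mesh.scales, axis=0, return_inverse=True)
        for k in range(uniq.shape[0]):
            cell = _paced_cell(uniq[k], bcl, dt)
            states[inv == k] = cell
    return states


def interpolate_scales(endpoint: ConductanceScale, n_levels: int):
    """Linear multiplier-space interpolation control -> endpoint."""
    a0 = np.ones(9)
    a1 = endpoint.as_array()
    fr = np.linspace(0.0, 1.0, n_levels)
    return [ConductanceScale.from_array(a0 + f * (a1 - a0)) for f in fr]


def calibrate_af_endpoint(target_erp: float = 157.0,
                          direction: ConductanceScale = AF_DIRECTION,
                          protocol: S1S2Protocol = IN_SILICO_PROTOCOL,
                          dt: float = engine.DT_DEFAULT,
                          cable: TissueMesh | None = None,
                          tol: float = 1.0,
                          alpha_bounds=(0.2, 2.5)):
    """Chronic-AF endpoint: scale along ``direction`` until the cable ERP
    equals ``target_erp``.

    The endpoint is ``1 + alpha * (direction - 1)`` per multiplier; alpha is
    found by bisection on the measured cable ERP (monotone decreasing in
    alpha).  Returns (ConductanceScale, alpha, erp).
    """
    def scale_at(alpha):
        return ConductanceScale.from_array(
            np.maximum(1.0 + alpha * (direction.as_array() - 1.0), 0.0))

    def erp_at(alpha):
        try:
            return cable_erp(scale_at(alpha), protocol, cable=cable, dt=dt)
        except ErpOutOfRange as e:
            # treat out-of-scan ERPs as pseudo-values for bracketing
            if "below scan range" in str(e):
                return protocol.s2_stop - 1.0
            return protocol.s2_start + 1.0

    lo, hi = alpha_bounds
    e_lo, e_hi = erp_at(lo), erp_at(hi)
    if not (e_hi - tol <= target_erp <= e_lo + tol):
        raise ValueError(
            f"target ERP {target_erp} ms not bracketed: alpha {alpha_bounds} "
            f"gives ERP [{e_hi}, {e_lo}] ms")
    best = (lo, e_lo)
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        e = erp_at(mid)
        if abs(e - target_erp) < abs(best[1] - target_erp):
            best = (mid, e)
        if abs(e - target_erp) <= tol:
            best = (mid, e)
            break
        if e > target_erp:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-4:
            break
    alpha, erp = best
    return scale_at(alpha), float(alpha), float(erp)


def build_ladder(n_levels: int = 50,
                 endpoint: ConductanceScale | None = None,
                 protocol: S1S2Protocol = IN_SILICO_PROTOCOL,
                 dt: float = engine.DT_DEFAULT,
                 cable: TissueMesh | None = None,
                 target_erp: float = 157.0) -> RemodelingLadder:
    """Measure the cable ERP of ``n_levels`` linearly interpolated models.

    When ``endpoint`` is None the AF endpoint is first calibrated to
    ``target_erp``.  Raises if the resulting ERPs are not monotone
    non-increasing beyond the 1 ms quantization tolerance.
    """
    meta = {}
    if endpoint is None:
        endpoint, alpha, erp_end = calibrate_af_endpoint(
            target_erp, protocol=protocol, dt=dt, cable=cable)
        meta.update({"endpoint_provenance": "calibrated", "alpha": alpha,
                     "endpoint_erp": erp_end, "target_erp": target_erp})
    levels = interpolate_scales(endpoint, n_levels)
    erps = np.array([cable_erp(lv, protocol, cable=cable, dt=dt)
                     for lv in levels])
    # break 1 ms quantization ties so the inverse lookup is well defined
    erps_mono = np.minimum.accumulate(erps)
    meta["quantization_ties"] = int(np.sum(erps_mono != erps))
    return RemodelingLadder(levels=levels, erp_ms=erps_mono, metadata=meta)


def erp_to_scale_array(target_erp, ladder: RemodelingLadder) -> np.ndarray:
    """Vectorized inverse lookup: ERP (ms) -> (n, 9) multiplier array.

    Linear interpolation between the two bracketing ladder levels in
    multiplier space; targets outside the ladder range are clamped with a
    warning.
    """
    if ladder.n_levels == 0:
        raise ValueError("empty ladder")
    t = np.atleast_1d(np.asarray(target_erp, dtype=float))
    lo, hi = ladder.erp_range
    if np.any(t < lo - 1e-9) or np.any(t > hi + 1e-9):
        warnings.warn("target ERP outside ladder range; clamped")
        t = np.clip(t, lo, hi)
    # erp_ms is non-increasing with level; interpolate the fractional level
    erp_rev = ladder.erp_ms[::-1]
    lev_rev = np.arange(ladder.n_levels - 1, -1, -1, dtype=float)
    frac_level = np.interp(t, erp_rev, lev_rev)
    k0 = np.floor(frac_level).astype(int)
    k1 = np.minimum(k0 + 1, ladder.n_levels - 1)
    w = (frac_level - k0)[:, None]
    arr = np.array([lv.as_array() for lv in ladder.levels])
    return (1.0 - w) * arr[k0] + w * arr[k1]


def erp_to_scale(target_erp: float, ladder: RemodelingLadder) -> ConductanceScale:
    """Scalar inverse lookup, exact at tabulated ladder ERPs."""
    exact = np.nonzero(np.abs(ladder.erp_ms - target_erp) < 1e-9)[0]
    if exact.size:
        return ladder.levels[int(exact[0])]
    return ConductanceScale.from_array(
        erp_to_scale_array([target_erp], ladder)[0])
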