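"""Import/export of tissue bundles and simulation records.

Geometry travels as PLY (via trimesh) for triangulated surfaces; per-node
and per-element attributes (region, ERP field, voltage map, fibers,
conductivities, conductive flags, conductance multipliers) as CSV tables;
provenance (scenario kind, seeds, ladder hash) as a JSON sidecar.  Probe
traces export as long-format CSV (time_ms, node_id, V_mV).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .courtemanche import SCALE_NAMES
from .monodomain import TissueMesh, SimulationRecord

__all__ = ["save_bundle", "load_bundle", "save_record_csv"]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    return obj


def save_bundle(directory, mesh: TissueMesh, voltage_map=None,
                measurements=None) -> Path:
    """Write a mesh (plus optional voltage map / measurements) to a folder."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    if not mesh.is_cable:
        import trimesh
        tm = trimesh.Trimesh(vertices=mesh.nodes, faces=mesh.elements,
                             process=False)
        tm.export(d / "surface.ply", file_type="ply", encoding="ascii")

    nodes = pd.DataFrame(mesh.nodes, columns=["x_mm", "y_mm", "z_mm"])
    nodes["region"] = mesh.region
    erp = mesh.metadata.get("erp_field")
    if erp is not None:
        nodes["erp_ms"] = erp
    if voltage_map is not None:
        nodes["voltage_mV"] = voltage_map
    for k, name in enumerate(SCALE_NAMES):
        nodes[f"scale_{name}"] = mesh.scales[:, k]
    nodes.to_csv(d / "nodes.csv", index=False)

    els = pd.DataFrame(mesh.elements,
                       columns=[f"n{i}" for i in range(mesh.elements.shape[1])])
    els[["fiber_x", "fiber_y", "fiber_z"]] = mesh.fibers
    els["sigma_l_S_per_m"] = mesh.sigma_l
    els["sigma_t_S_per_m"] = mesh.sigma_t
    els["conductive"] = mesh.conductive.astype(int)
    els.to_csv(d / "elements.csv", index=False)

    if measurements is not None:
        measurements.to_frame().to_csv(d / "erp_measurements.csv", index=False)

    meta = {k: _jsonable(v) for k, v in mesh.metadata.items()
            if k not in ("erp_field", "inflamed_nodes")}
    (d / "bundle.json").write_text(json.dumps(meta, indent=2))
    return d


def load_bundle(directory) -> TissueMesh:
    """Rebuild a :class:`TissueMesh` from :func:`save_bundle` output."""
    d = Path(directory)
    nodes = pd.read_csv(d / "nodes.csv")
    els = pd.read_csv(d / "elements.csv")
    el_cols = [c for c in els.columns if c.startswith("n") and c[1:].isdigit()]
    elements = els[el_cols].to_numpy()
    meta = json.loads((d / "bundle.json").read_text())
    mesh = TissueMesh(
        nodes=nodes[["x_mm", "y_mm", "z_mm"]].to_numpy(),
        elements=elements,
        fibers=els[["fiber_x", "fiber_y", "fiber_z"]].to_numpy(),
        sigma_l=els["sigma_l_S_per_m"].to_numpy(),
        sigma_t=els["sigma_t_S_per_m"].to_numpy(),
        conductive=els["conductive"].to_numpy().astype(bool),
        region=nodes["region"].to_numpy(),
        scales=nodes[[f"scale_{n}" for n in SCALE_NAMES]].to_numpy(),
        metadata=meta)
    if "erp_ms" in nodes:
        mesh.metadata["erp_field"] = nodes["erp_ms"].to_numpy()
    return mesh


def save_record_csv(record: SimulationRecord, path) -> Path:
    """Probe traces as long-format CSV (time_ms, node_id, V_mV)."""
    rows = []
    for k, node in enumerate(record.probes):
        rows.append(pd.DataFrame({
            "time_ms": record.t, "node_id": int(node),
            "V_mV": record.V[:, k]}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    return Path(path)
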