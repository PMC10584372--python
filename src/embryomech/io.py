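"""File formats: YAML configs, legacy-VTK and PLY mesh export, record CSV,
run manifests."""
from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import COMPARTMENT_NAMES, EmbryoGeometrySpec, EmbryoMesh
from .records import SimulationRecord


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def spec_from_config(cfg: dict) -> EmbryoGeometrySpec:
    """Build a geometry spec from a flat key-value mapping (field names match)."""
    fields = EmbryoGeometrySpec.__dataclass_fields__
    unknown = set(cfg) - set(fields)
    if unknown:
        raise ValueError(f"unknown geometry config keys: {sorted(unknown)}")
    return EmbryoGeometrySpec(**cfg)


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_manifest(cfg: dict, seed: int | None) -> dict:
    import scipy

    return {
        "config_hash": config_hash(cfg),
        "config": cfg,
        "seed": seed,
        "versions": {
            "embryomech": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "python": platform.python_version(),
        },
    }


def write_manifest(cfg: dict, seed: int | None, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(run_manifest(cfg, seed), fh, indent=2, default=str)
    return path


def write_vtk(path, mesh: EmbryoMesh, positions=None, edge_scalars: dict | None = None) -> Path:
    """Legacy ASCII VTK unstructured grid: springs as line cells with the
    compartment label (and optional per-spring scalars, e.g. stress)."""
    path = Path(path)
    pos = mesh.nodes if positions is None else positions
    n_pts, n_cells = len(pos), len(mesh.edges)
    lines = [
        "# vtk DataFile Version 3.0",
        "embryomech spring network",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n_pts} double",
    ]
    lines += [f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}" for p in pos]
    lines.append(f"CELLS {n_cells} {3 * n_cells}")
    lines += [f"2 {e[0]} {e[1]}" for e in mesh.edges]
    lines.append(f"CELL_TYPES {n_cells}")
    lines += ["3"] * n_cells  # VTK_LINE
    lines.append(f"CELL_DATA {n_cells}")
    lines.append("SCALARS compartment int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(int(c)) for c in mesh.compartment]
    for name, values in (edge_scalars or {}).items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.9g}" for v in values]
    path.write_text("\n".join(lines) + "\n")
    return path


def write_ply(path, mesh: EmbryoMesh, positions=None) -> Path:
    """Triangulated apical+lateral surface as PLY (via trimesh)."""
    import trimesh

    pos = mesh.nodes if positions is None else positions
    tm = trimesh.Trimesh(vertices=pos, faces=mesh.faces, process=False)
    data = tm.export(file_type="ply", encoding="ascii")
    Path(path).write_bytes(data if isinstance(data, bytes) else data.encode())
    return Path(path)


def record_to_frame(record: SimulationRecord) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "time_s": record.times,
            "displacement_um": record.displacement,
            "force_nN": record.force,
            "phase": record.phase,
        }
    )
    for name, series in record.extras.items():
        if len(series) == len(df):
            df[name] = series
    return df


def write_record(record: SimulationRecord, out_dir, mesh: EmbryoMesh | None = None) -> Path:
    """Record as a directory of CSV series plus VTK snapshots."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record_to_frame(record).to_csv(out_dir / "series.csv", index=False)
    if mesh is not None:
        for t, pos in record.snapshots.items():
            write_vtk(out_dir / f"snapshot_t{t:08.2f}.vtk", mesh, positions=pos)
    return out_dir


def compartment_name(code: int) -> str:
    return COMPARTMENT_NAMES[int(code)]


def spec_to_config(spec: EmbryoGeometrySpec) -> dict:
    return asdict(spec)
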