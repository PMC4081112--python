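"""File formats: landmark tables, pairing documents, run configuration, meshes.

Landmark files are plain CSV with columns ``label,x,y,z,present``; absent
landmarks carry empty coordinate fields and ``present = 0`` (never sentinel
numbers).  Pairing and run-configuration files are YAML.  Meshes are ASCII
PLY or OBJ, read and written through trimesh with vertex order preserved.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

from .containers import BilateralPairing, LandmarkConfiguration, Mesh

__all__ = [
    "read_landmarks", "write_landmarks",
    "read_pairing", "write_pairing",
    "read_mesh", "write_mesh",
    "read_run_config",
]


def read_landmarks(path: str | os.PathLike) -> LandmarkConfiguration:
    """Read a landmark CSV (label, x, y, z, present)."""
    df = pd.read_csv(path, dtype={"label": str},
                     float_precision="round_trip")
    required = {"label", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: landmark file needs columns {sorted(required)}")
    dupes = df["label"][df["label"].duplicated()].tolist()
    if dupes:
        lines = (df.index[df["label"].isin(dupes)] + 2).tolist()
        raise ValueError(f"{path}: duplicate labels {sorted(set(dupes))} "
                         f"(lines {lines})")
    if "present" in df.columns:
        present = df["present"].fillna(0).astype(int).astype(bool).to_numpy()
    else:
        present = ~df[["x", "y", "z"]].isna().any(axis=1).to_numpy()
    coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    bad = present & ~np.isfinite(coords).all(axis=1)
    if bad.any():
        lines = (np.flatnonzero(bad) + 2).tolist()
        raise ValueError(f"{path}: present landmarks with missing/non-finite "
                         f"coordinates at lines {lines}")
    return LandmarkConfiguration(df["label"].tolist(), coords, present)


def write_landmarks(config: LandmarkConfiguration,
                    path: str | os.PathLike) -> None:
    """Write a landmark CSV at full precision (lossless round trip)."""
    rows = []
    for lab, xyz, pres in zip(config.labels, config.coords,
                              config.present_mask):
        if pres:
            rows.append({"label": lab, "x": repr(float(xyz[0])),
                         "y": repr(float(xyz[1])), "z": repr(float(xyz[2])),
                         "present": 1})
        else:
            rows.append({"label": lab, "x": "", "y": "", "z": "", "present": 0})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_pairing(path: str | os.PathLike) -> BilateralPairing:
    """Read a YAML pairing document: {pairs: [[L, R], ...], midline: [...]}."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "pairs" not in doc:
        raise ValueError(f"{path}: pairing document must map 'pairs' "
                         "(and optionally 'midline')")
    pairs = [tuple(p) for p in doc["pairs"]]
    if any(len(p) != 2 for p in pairs):
        raise ValueError(f"{path}: every pair must have exactly two labels")
    return BilateralPairing(pairs=pairs, midline=list(doc.get("midline", [])))


def write_pairing(pairing: BilateralPairing, path: str | os.PathLike) -> None:
    doc = {"pairs": [list(p) for p in pairing.pairs],
           "midline": list(pairing.midline)}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _check_ascii_ply(path: Path) -> None:
    with open(path, "rb") as fh:
        header = fh.read(256)
    if b"format" in header and b"ascii" not in header.split(b"\n")[1]:
        dialect = header.split(b"\n")[1].decode(errors="replace").strip()
        raise ValueError(f"{path}: unsupported PLY dialect ({dialect}); "
                         "only ASCII PLY is supported")


def read_mesh(path: str | os.PathLike) -> Mesh:
    """Read an ASCII PLY or OBJ triangle mesh (vertex order preserved)."""
    p = Path(path)
    ext = p.suffix.lower().lstrip(".")
    if ext not in ("ply", "obj"):
        raise ValueError(f"{path}: unsupported mesh dialect '.{ext}' "
                         "(PLY or OBJ ASCII only)")
    if ext == "ply":
        _check_ascii_ply(p)
    tm = trimesh.load(str(p), file_type=ext, process=False)
    return Mesh(np.asarray(tm.vertices, float), np.asarray(tm.faces, int))


def write_mesh(mesh: Mesh, path: str | os.PathLike) -> None:
    """Write an ASCII PLY or OBJ mesh at full float precision."""
    p = Path(path)
    ext = p.suffix.lower().lstrip(".")
    if ext not in ("ply", "obj"):
        raise ValueError(f"{path}: unsupported mesh dialect '.{ext}' "
                         "(PLY or OBJ ASCII only)")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces,
                         process=False)
    if ext == "ply":
        data = tm.export(file_type="ply", encoding="ascii")
    else:
        data = tm.export(file_type="obj")
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(p, mode) as fh:
        fh.write(data)


_RUN_CONFIG_DEFAULTS = {
    "method": "algorithmic",
    "neighborhood_size": 8,
    "direction_grid_resolution": 5.0,
    "stretch_penalty": 0.1,
    "final_reflection_average": True,
    "seed": 0,
    "output_dir": ".",
    "verbosity": 1,
    "presets": {},
}


def read_run_config(path: str | os.PathLike) -> dict:
    """Load a YAML run configuration with all defaults materialized."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: run config must be a mapping")
    unknown = set(doc) - set(_RUN_CONFIG_DEFAULTS)
    if unknown:
        raise ValueError(f"{path}: unknown run-config keys {sorted(unknown)}")
    out = dict(_RUN_CONFIG_DEFAULTS)
    out.update(doc)
    return out
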