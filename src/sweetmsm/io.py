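"""Deterministic serialization helpers.

Array archives are written through :func:`save_arrays` rather than
``numpy.savez`` so that the zip member timestamps are fixed and two runs with
the same seed produce byte-identical files.
"""

from __future__ import annotations

import io as _io
import json
import zipfile
from pathlib import Path

import numpy as np

# fixed DOS timestamp for reproducible archives
_EPOCH = (1980, 1, 1, 0, 0, 0)


def save_arrays(path: str | Path, **arrays: np.ndarray) -> None:
    """Write named arrays to an uncompressed ``.npz``-compatible archive
    with deterministic bytes (fixed timestamps, sorted member order)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for name in sorted(arrays):
            buf = _io.BytesIO()
            np.lib.format.write_array(buf, np.asarray(arrays[name]))
            info = zipfile.ZipInfo(name + ".npy", date_time=_EPOCH)
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, buf.getvalue())


def load_arrays(path: str | Path) -> dict[str, np.ndarray]:
    with np.load(path) as data:
        return {k: data[k] for k in data.files}


def save_json(path: str | Path, obj) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def load_json(path: str | Path):
    return json.loads(Path(path).read_text())


def write_pdb_multiframe(topology, coords: np.ndarray, path: str | Path) -> None:
    """Write a multi-MODEL PDB (one MODEL per frame) for a toy topology."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    lines: list[str] = []
    for m, frame in enumerate(coords, start=1):
        lines.append(f"MODEL     {m:4d}")
        for i in range(frame.shape[0]):
            x, y, z = frame[i]
            name = topology.atom_name[i][:4]
            resn = topology.resname[i][:3]
            lines.append(
                f"ATOM  {i + 1:5d} {name:<4s} {resn:<3s} A{topology.resid[i]:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            )
        lines.append("ENDMDL")
    lines.append("END")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(lines) + "\n")
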