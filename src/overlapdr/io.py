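"""Serialization: TSV / NIfTI matrices and run manifests.

TSV files are tab-separated with a one-line header and written at full
double precision (17 significant digits), so a write/read round-trip is
lossless.  NIfTI data use a 1-D spatial layout — a ``(timepoints, voxels)``
matrix becomes a ``(voxels, 1, 1, timepoints)`` image — and native 3-D/4-D
volumes are vectorised row-major on read.  A run manifest (JSON) records the
configuration, seeds, and an inventory of emitted files with checksums;
re-running from a manifest reproduces the outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import NetMat

__all__ = [
    "read_data",
    "write_data",
    "read_netmat",
    "write_netmat",
    "RunManifest",
]

_TSV_FMT = "%.17g"


def write_data(path: str | Path, matrix: np.ndarray, *,
               axis_name: str = "mode") -> Path:
    """Write a 2-D matrix as TSV (by suffix) or NIfTI (.nii/.nii.gz)."""
    path = Path(path)
    matrix = np.asarray(matrix)
    if matrix.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if path.suffix in (".nii", ".gz"):
        # rows become the 4th axis; columns are unraveled voxels
        img = nib.Nifti1Image(
            np.ascontiguousarray(matrix.T).reshape(matrix.shape[1], 1, 1, matrix.shape[0]),
            affine=np.eye(4),
        )
        nib.save(img, str(path))
    else:
        header = "\t".join(f"{axis_name}{i}" for i in range(matrix.shape[1]))
        np.savetxt(path, matrix, fmt=_TSV_FMT, delimiter="\t",
                   header=header, comments="")
    return path


def read_data(path: str | Path, expected_shape: tuple[int, int] | None = None
              ) -> np.ndarray:
    """Read a matrix written by :func:`write_data` (or a native NIfTI volume)."""
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj)
        if arr.ndim == 4:
            arr = arr.reshape(-1, arr.shape[3], order="C")
        else:
            arr = arr.reshape(-1, order="C")[:, None]
        out = arr.T
    else:
        out = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    if expected_shape is not None and tuple(out.shape) != tuple(expected_shape):
        raise ValueError(f"{path}: shape {out.shape} does not match manifest "
                         f"{expected_shape}")
    return out


def write_netmat(path: str | Path, netmat: NetMat,
                 labels: list[str] | None = None) -> Path:
    """NetMat TSV with mode labels as header and first column."""
    labels = labels or [f"mode{i}" for i in range(netmat.n_modes)]
    df = pd.DataFrame(netmat.values, index=labels, columns=labels)
    df.to_csv(path, sep="\t", float_format=_TSV_FMT, index_label=netmat.kind)
    return Path(path)


def read_netmat(path: str | Path) -> NetMat:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    kind = df.index.name if df.index.name in ("temporal", "spatial") else "temporal"
    v = df.to_numpy(dtype=float)
    if not np.allclose(v, v.T, atol=1e-12):
        raise ValueError(f"{path}: netmat not symmetric within 1e-12")
    return NetMat(0.5 * (v + v.T), kind, source=str(path))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


class RunManifest:
    """Config snapshot + seeds + file inventory with checksums."""

    def __init__(self, command: str, config, seed: int):
        self.command = command
        self.config = config
        self.seed = seed
        self.files: dict[str, dict] = {}

    def add_file(self, path: str | Path, role: str = "") -> None:
        path = Path(path)
        self.files[path.name] = {
            "sha256": _sha256(path),
            "bytes": path.stat().st_size,
            "role": role,
        }

    def save(self, path: str | Path) -> Path:
        from . import __version__
        payload = {
            "command": self.command,
            "seed": self.seed,
            "version": __version__,
            "config": _jsonable(self.config),
            "files": self.files,
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return path

    @staticmethod
    def load(path: str | Path) -> dict:
        return json.loads(Path(path).read_text())
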