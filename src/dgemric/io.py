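"""Readers and writers for the on-disk study formats.

Formats
-------
- IR series: NIfTI volume of shape (rows, cols, n_ti), float64, with a
  JSON sidecar ``<stem>.json`` holding the acquisition protocol, series
  metadata and the normalization flag.
- T1 / dT1 maps: NIfTI (rows, cols, k) with a JSON provenance sidecar.
- Landmarks: JSON ``{"points": [[row, col], ...], "anterior_index": i}``.
- Masks / label maps: NIfTI integer volumes.
- Tables: TSV with documented column names.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError
from .relaxometry import (
    AcquisitionProtocol,
    IRSeries,
    SeriesMeta,
    T1Map,
    T1_VALID_MAX_MS,
    T1_VALID_MIN_MS,
)

__all__ = [
    "write_series", "read_series",
    "write_landmarks", "read_landmarks",
    "write_mask", "read_mask",
    "write_t1_map", "read_t1_map",
    "write_table", "read_table",
]

_AFFINE = np.eye(4)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_series(path: str | Path, series: IRSeries) -> Path:
    """Write one IR series as NIfTI + JSON sidecar; returns the NIfTI path."""
    path = Path(path)
    data = np.moveaxis(series.images, 0, -1).astype(np.float64)
    nib.save(nib.Nifti1Image(data, _AFFINE), str(path))
    sidecar = {
        "protocol": series.protocol.to_dict(),
        "meta": series.meta.to_dict(),
        "normalization_applied": series.normalization_applied,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_series(path: str | Path) -> IRSeries:
    """Read an IR series written by :func:`write_series`.

    Raises :class:`FormatError` on a missing sidecar, missing required
    sidecar fields, or a TI-count/volume-count mismatch.
    """
    path = Path(path)
    sc_path = _sidecar_path(path)
    if not sc_path.exists():
        raise FormatError(f"missing JSON sidecar: {sc_path}")
    sidecar = json.loads(sc_path.read_text())
    if "protocol" not in sidecar:
        raise FormatError(f"sidecar {sc_path} missing field 'protocol'")
    if "ti_ms" not in sidecar["protocol"]:
        raise FormatError(f"sidecar {sc_path} missing field 'protocol.ti_ms'")
    protocol = AcquisitionProtocol.from_dict(sidecar["protocol"])
    data = np.asanyarray(nib.load(str(path)).dataobj).astype(np.float64)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    if data.shape[-1] != protocol.n_ti:
        raise FormatError(
            f"{path}: {data.shape[-1]} volumes but sidecar lists "
            f"{protocol.n_ti} inversion times"
        )
    return IRSeries(
        images=np.moveaxis(data, -1, 0),
        protocol=protocol,
        meta=SeriesMeta.from_dict(sidecar.get("meta", {})),
        normalization_applied=bool(sidecar.get("normalization_applied", False)),
    )


def write_landmarks(path: str | Path, points: np.ndarray, anterior_index: int = 0) -> Path:
    path = Path(path)
    path.write_text(json.dumps(
        {"points": np.asarray(points, dtype=float).tolist(),
         "anterior_index": int(anterior_index)},
        indent=1,
    ))
    return path


def read_landmarks(
    path: str | Path, min_points: int = 8, allow_fewer: bool = False
) -> tuple[np.ndarray, int]:
    """Read landmarks; by default requires the full 8-point placement.

    ``allow_fewer=True`` relaxes the requirement to the 5 points an
    ellipse fit mathematically needs.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read landmark file {path}: {exc}") from exc
    if "points" not in payload:
        raise FormatError(f"landmark file {path} missing field 'points'")
    pts = np.asarray(payload["points"], dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise FormatError(f"landmark file {path}: points must be (n, 2)")
    required = 5 if allow_fewer else min_points
    if pts.shape[0] < required:
        raise FormatError(
            f"landmark file {path} has {pts.shape[0]} points; the protocol "
            f"requires eight points (pass allow_fewer=True to accept >= 5)"
        )
    return pts, int(payload.get("anterior_index", 0))


def write_mask(path: str | Path, mask: np.ndarray) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(mask).astype(np.uint8), _AFFINE), str(path))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    return np.asanyarray(nib.load(str(Path(path))).dataobj).astype(bool)


def write_t1_map(path: str | Path, t1map: T1Map) -> Path:
    """T1 map as a 4-layer NIfTI (t1, s0, rss, valid) + provenance sidecar."""
    path = Path(path)
    data = np.stack(
        [t1map.t1_ms, t1map.s0, t1map.rss, t1map.valid.astype(np.float64)], axis=-1
    )
    nib.save(nib.Nifti1Image(data, _AFFINE), str(path))
    sidecar = {
        "layers": ["t1_ms", "s0", "rss", "valid"],
        "meta": t1map.meta.to_dict(),
        "protocol": t1map.protocol.to_dict() if t1map.protocol else None,
        "validity_window_ms": [T1_VALID_MIN_MS, T1_VALID_MAX_MS],
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_t1_map(path: str | Path) -> T1Map:
    path = Path(path)
    sc_path = _sidecar_path(path)
    if not sc_path.exists():
        raise FormatError(f"missing JSON sidecar: {sc_path}")
    sidecar = json.loads(sc_path.read_text())
    data = np.asanyarray(nib.load(str(path)).dataobj).astype(np.float64)
    if data.ndim != 3 or data.shape[-1] != 4:
        raise FormatError(f"{path}: expected (rows, cols, 4) layers")
    protocol = (
        AcquisitionProtocol.from_dict(sidecar["protocol"])
        if sidecar.get("protocol") else None
    )
    return T1Map(
        t1_ms=data[..., 0], s0=data[..., 1], rss=data[..., 2],
        valid=data[..., 3] > 0.5,
        meta=SeriesMeta.from_dict(sidecar.get("meta", {})),
        protocol=protocol,
    )


def write_table(path: str | Path, table: pd.DataFrame) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t")
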