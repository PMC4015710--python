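"""File formats: NIfTI volumes, CSV washout curves, CSV cohort tables.

NIfTI carries voxel spacing in its header, which is mandatory for a
:class:`~airtrap.densitometry.CTVolume`; a plain ``.npy`` array is also
accepted when accompanied by a ``<stem>.spacing.json`` sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .densitometry import CTVolume
from .sbnt import SBNTCurve

__all__ = [
    "MetadataError",
    "read_volume",
    "write_volume",
    "write_mask",
    "read_curve",
    "write_curve",
    "read_cohort",
    "write_cohort",
]

CURVE_COLUMNS = ("expired_volume_L", "n2_pct", "flow_Lps")


class MetadataError(ValueError):
    """Raised when a volume lacks usable spacing metadata."""


def read_volume(path: str | Path) -> CTVolume:
    """Read a CT volume from NIfTI (.nii/.nii.gz) or .npy + spacing sidecar."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".npy":
        sidecar = path.with_suffix(".spacing.json")
        if not sidecar.exists():
            raise MetadataError(f"{path} has no spacing metadata ({sidecar} missing)")
        spacing = tuple(json.loads(sidecar.read_text())["spacing_mm"])
        return CTVolume(np.load(path), spacing)
    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        if len(zooms) != 3 or any(not z or z <= 0 for z in zooms):
            raise MetadataError(f"{path} header carries no positive voxel spacing")
        data = np.asarray(img.dataobj, dtype=np.float32)
        return CTVolume(data, tuple(float(z) for z in zooms))
    raise ValueError(f"unrecognized volume format: {path.name}")


def write_volume(path: str | Path, volume: CTVolume) -> Path:
    """Write a volume as NIfTI (spacing encoded in the affine/header)."""
    path = Path(path)
    affine = np.diag([*volume.spacing, 1.0])
    img = nib.Nifti1Image(np.asarray(volume.values, np.float32), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
    return path


def write_mask(path: str | Path, mask: np.ndarray, spacing: tuple[float, float, float]) -> Path:
    path = Path(path)
    affine = np.diag([*spacing, 1.0])
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))
    return path


def read_curve(path: str | Path, vital_capacity: float | None = None) -> SBNTCurve:
    """Read a washout trace CSV (expired_volume_L, n2_pct[, flow_Lps]).

    If ``vital_capacity`` is not given, a ``vital_capacity_L`` column (a
    repeated scalar) is used when present, else the final expired volume.
    """
    df = pd.read_csv(path)
    for col in CURVE_COLUMNS[:2]:
        if col not in df.columns:
            raise ValueError(f"curve file {path} lacks required column {col!r}")
    if vital_capacity is None:
        if "vital_capacity_L" in df.columns:
            vital_capacity = float(df["vital_capacity_L"].iloc[0])
        else:
            vital_capacity = float(df["expired_volume_L"].iloc[-1])
    flow = df["flow_Lps"].to_numpy(float) if "flow_Lps" in df.columns else None
    return SBNTCurve(
        expired_volume=df["expired_volume_L"].to_numpy(float),
        n2=df["n2_pct"].to_numpy(float),
        vital_capacity=vital_capacity,
        flow=flow,
    )


def write_curve(path: str | Path, curve: SBNTCurve) -> Path:
    path = Path(path)
    data = {
        "expired_volume_L": curve.expired_volume,
        "n2_pct": curve.n2,
        "vital_capacity_L": np.full(len(curve), curve.vital_capacity),
    }
    if curve.flow is not None:
        data["flow_Lps"] = curve.flow
    pd.DataFrame(data).to_csv(path, index=False)
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_cohort(path: str | Path, table: pd.DataFrame) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path
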