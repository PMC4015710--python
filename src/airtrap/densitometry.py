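"""Lung segmentation and CT densitometry (MLD, LAA%).

Attenuation is in Hounsfield units (HU): air ≈ −1000, water = 0, soft
tissue > 0.  Lung parenchyma on CT falls in roughly [−1024, −500] HU, so a
pure threshold plus connected-component analysis separates it from the
chest wall and mediastinum; the air column of the trachea/bronchi reaches
the most cranial slice and is excluded by that property.

Volumes are 3-D arrays whose **last axis is cranio-caudal**, index 0 being
the most cranial (apex) slice.  All densitometric summaries pool voxels
from both lungs ("combining the values found for both sides").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "CTVolume",
    "LungMask",
    "QuantConfig",
    "DensitySummary",
    "LevelSelection",
    "LungNotFoundError",
    "EmptyMaskError",
    "segment_lung",
    "remove_airway",
    "mean_lung_density",
    "laa_percent",
    "summarize_level",
    "summarize_volume",
]


class LungNotFoundError(RuntimeError):
    """Raised when no connected parenchymal component qualifies as lung."""


class EmptyMaskError(ValueError):
    """Raised when a densitometric summary is requested over zero voxels."""


@dataclass(frozen=True)
class CTVolume:
    """A CT attenuation volume.

    Parameters
    ----------
    values
        3-D array of attenuation in HU; the last axis is cranio-caudal
        (index 0 = most cranial slice).
    spacing
        Voxel spacing in mm per axis, all strictly positive.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            raise ValueError("volume contains non-finite attenuation values")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive numbers, got {self.spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_slices(self) -> int:
        """Number of cranio-caudal slices."""
        return self.values.shape[2]


@dataclass(frozen=True)
class QuantConfig:
    """Thresholds and component rules for lung segmentation/densitometry.

    The three HU ranges are nested: the narrow low-attenuation range
    (default [−910, −850], excluding very low densities that would flag
    emphysematous or cystic lesions) lies inside the full low-attenuation
    range [−1024, −850], which lies inside the parenchyma range
    [−1024, −500].  All bounds are inclusive.
    """

    parenchyma_range: tuple[float, float] = (-1024.0, -500.0)
    laa_full_range: tuple[float, float] = (-1024.0, -850.0)
    laa_narrow_range: tuple[float, float] = (-910.0, -850.0)
    airway_hu_max: float = -970.0
    min_component_voxels: int = 100

    def __post_init__(self) -> None:
        for name in ("parenchyma_range", "laa_full_range", "laa_narrow_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must satisfy lo < hi, got ({lo}, {hi})")
        p, f, n = self.parenchyma_range, self.laa_full_range, self.laa_narrow_range
        if not (p[0] <= f[0] and f[1] <= p[1]):
            raise ValueError("laa_full_range must nest inside parenchyma_range")
        if not (f[0] <= n[0] and n[1] <= f[1]):
            raise ValueError("laa_narrow_range must nest inside laa_full_range")
        if self.min_component_voxels < 1:
            raise ValueError("min_component_voxels must be >= 1")


@dataclass(frozen=True)
class LungMask:
    """Boolean lung-parenchyma mask congruent with its source volume.

    ``labels`` assigns 1, 2, ... to the retained connected components in
    decreasing size order (normally 1 = larger lung, 2 = smaller lung);
    voxels attributed to the airway are already excluded.
    """

    mask: np.ndarray
    labels: np.ndarray
    n_components: int

    def __post_init__(self) -> None:
        if self.mask.shape != self.labels.shape:
            raise ValueError("mask and labels must share a shape")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class DensitySummary:
    """Densitometric summary over a set of lung voxels.

    ``mld`` is the mean attenuation (HU); ``laa_full_pct`` and
    ``laa_narrow_pct`` are the percentages of voxels inside the full and
    narrow low-attenuation ranges.  ``level_id`` is 1–4 for a single
    anatomical level, the string ``"mean"`` for the across-level average,
    or None for a whole-volume summary.
    """

    mld: float
    laa_full_pct: float
    laa_narrow_pct: float
    n_voxels: int
    level_id: int | str | None = None


@dataclass(frozen=True)
class LevelSelection:
    """The four expiratory sampling levels as cranio-caudal slice indices.

    By convention: one through the upper lobes, one through the tracheal
    carina and two between the carina and the diaphragm — i.e. strictly
    increasing slice indices (index 0 = apex).
    """

    level_z: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        z = tuple(int(v) for v in self.level_z)
        if len(z) != 4:
            raise ValueError("exactly four levels are required")
        if any(b <= a for a, b in zip(z, z[1:])):
            raise ValueError(f"levels must be strictly increasing cranio-caudally: {z}")
        if z[0] < 0:
            raise ValueError("level indices must be non-negative")
        object.__setattr__(self, "level_z", z)


def _labelled_components(mask: np.ndarray) -> tuple[np.ndarray, int]:
    labels, n = ndimage.label(mask)
    return labels, n


def _finalize_mask(keep: np.ndarray, min_voxels: int = 1) -> LungMask:
    """Relabel retained voxels 1..m in decreasing component-size order."""
    labels, n = _labelled_components(keep)
    if n == 0:
        return LungMask(mask=keep, labels=labels.astype(np.int32), n_components=0)
    counts = np.bincount(labels.ravel())
    good = [i for i in range(1, n + 1) if counts[i] >= min_voxels]
    good.sort(key=lambda i: -counts[i])
    out_labels = np.zeros_like(labels, dtype=np.int32)
    for rank, i in enumerate(good, start=1):
        out_labels[labels == i] = rank
    mask = out_labels > 0
    return LungMask(mask=mask, labels=out_labels, n_components=len(good))


def remove_airway(mask: LungMask, volume: CTVolume, config: QuantConfig | None = None) -> LungMask:
    """Exclude the tracheal/bronchial air column from a lung mask.

    Any connected component of voxels at or below ``airway_hu_max`` that
    touches the most cranial slice is treated as conducting-airway air
    (only the trachea reaches the lung apex boundary) and removed from the
    mask.  If no such component exists the mask is returned unchanged.
    """
    config = config or QuantConfig()
    if not mask.mask.any():
        raise ValueError("cannot remove airway from an empty mask")
    low = volume.values <= config.airway_hu_max
    labels, n = _labelled_components(low)
    if n == 0:
        return mask
    top = np.unique(labels[:, :, 0])
    top = top[top > 0]
    if top.size == 0:
        return mask
    excluded = np.isin(labels, top)
    if not (mask.mask & excluded).any():
        return mask
    return _finalize_mask(mask.mask & ~excluded)


def segment_lung(volume: CTVolume, config: QuantConfig | None = None) -> LungMask:
    """Segment lung parenchyma by thresholding and connected components.

    Steps: (1) candidate voxels inside ``parenchyma_range``; (2) drop
    components touching the lateral (x/y) image border — outside-body air
    and anything continuous with it; (3) drop the airway component(s)
    reaching the most cranial slice (:func:`remove_airway`); (4) keep the
    remaining components of at least ``min_component_voxels`` voxels.

    Raises :class:`LungNotFoundError` if no component qualifies and warns
    if only a single component (one lung) is found.
    """
    config = config or QuantConfig()
    lo, hi = config.parenchyma_range
    cand = (volume.values >= lo) & (volume.values <= hi)
    if int(cand.sum()) < config.min_component_voxels:
        raise LungNotFoundError(
            "no lung found: fewer candidate voxels than min_component_voxels"
        )

    labels, n = _labelled_components(cand)
    border = np.concatenate(
        [
            labels[0, :, :].ravel(),
            labels[-1, :, :].ravel(),
            labels[:, 0, :].ravel(),
            labels[:, -1, :].ravel(),
        ]
    )
    border_ids = np.unique(border)
    border_ids = border_ids[border_ids > 0]
    keep = cand & ~np.isin(labels, border_ids)

    interim = _finalize_mask(keep)
    if interim.n_components == 0:
        raise LungNotFoundError("no lung found: all components touch the lateral border")
    interim = remove_airway(interim, volume, config)

    final = _finalize_mask(interim.mask, min_voxels=config.min_component_voxels)
    if final.n_components == 0:
        raise LungNotFoundError("no lung found after airway exclusion and size filtering")
    if final.n_components == 1:
        warnings.warn(
            "only one lung component found; proceeding with a single lung",
            UserWarning,
            stacklevel=2,
        )
    return final


def _masked_values(volume: CTVolume, mask: LungMask | np.ndarray) -> np.ndarray:
    m = mask.mask if isinstance(mask, LungMask) else np.asarray(mask, bool)
    if m.shape != volume.values.shape:
        raise ValueError("mask shape does not match volume shape")
    vals = volume.values[m]
    if vals.size == 0:
        raise EmptyMaskError("mask selects no voxels")
    return vals


def mean_lung_density(volume: CTVolume, mask: LungMask | np.ndarray) -> float:
    """Mean lung density (MLD): arithmetic mean HU over the masked voxels."""
    return float(_masked_values(volume, mask).mean())


def laa_percent(
    volume: CTVolume, mask: LungMask | np.ndarray, hu_range: tuple[float, float]
) -> float:
    """Low-attenuation-area percentage: % of masked voxels with HU in range.

    Bounds are inclusive at both ends.
    """
    lo, hi = hu_range
    if not lo < hi:
        raise ValueError(f"hu_range must satisfy lo < hi, got ({lo}, {hi})")
    vals = _masked_values(volume, mask)
    inside = (vals >= lo) & (vals <= hi)
    return float(100.0 * inside.mean())


def _summarize(vals: np.ndarray, config: QuantConfig, level_id) -> DensitySummary:
    full_lo, full_hi = config.laa_full_range
    nar_lo, nar_hi = config.laa_narrow_range
    return DensitySummary(
        mld=float(vals.mean()),
        laa_full_pct=float(100.0 * ((vals >= full_lo) & (vals <= full_hi)).mean()),
        laa_narrow_pct=float(100.0 * ((vals >= nar_lo) & (vals <= nar_hi)).mean()),
        n_voxels=int(vals.size),
        level_id=level_id,
    )


def summarize_level(
    volume: CTVolume,
    mask: LungMask,
    level_z: int,
    config: QuantConfig | None = None,
    level_id: int | str | None = None,
) -> DensitySummary:
    """Summarize a single axial level, pooling left and right lung voxels."""
    config = config or QuantConfig()
    if not 0 <= level_z < volume.n_slices:
        raise ValueError(f"level z={level_z} outside volume with {volume.n_slices} slices")
    m = mask.mask[:, :, level_z]
    if not m.any():
        raise EmptyMaskError(f"no lung voxels at level {level_id if level_id is not None else level_z}")
    vals = volume.values[:, :, level_z][m]
    return _summarize(vals, config, level_id if level_id is not None else level_z)


def summarize_volume(
    volume: CTVolume,
    mask: LungMask,
    levels: LevelSelection,
    config: QuantConfig | None = None,
) -> tuple[list[DensitySummary], DensitySummary]:
    """Per-level summaries at the four sampling levels plus their mean.

    The across-level summary is the unweighted mean of the four level
    values (levels are single slices of differing lung area; no area
    weighting is applied).
    """
    config = config or QuantConfig()
    if levels.level_z[-1] >= volume.n_slices:
        raise ValueError("level selection extends beyond the volume")
    per_level = [
        summarize_level(volume, mask, z, config, level_id=i + 1)
        for i, z in enumerate(levels.level_z)
    ]
    mean = DensitySummary(
        mld=float(np.mean([s.mld for s in per_level])),
        laa_full_pct=float(np.mean([s.laa_full_pct for s in per_level])),
        laa_narrow_pct=float(np.mean([s.laa_narrow_pct for s in per_level])),
        n_voxels=int(sum(s.n_voxels for s in per_level)),
        level_id="mean",
    )
    return per_level, mean


def summarize_mask(
    volume: CTVolume, mask: LungMask, config: QuantConfig | None = None
) -> DensitySummary:
    """Whole-mask densitometric summary (all masked voxels pooled)."""
    config = config or QuantConfig()
    return _summarize(_masked_values(volume, mask), config, None)
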