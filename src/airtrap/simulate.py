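"""Synthetic data with known ground truth: digital CT phantoms, nitrogen
washout curves, reader pairs, and whole cohorts.

The phantom is the simplest geometry that exercises every rule of the
densitometry layer: a soft-tissue body cylinder surrounded by air, two
lung ellipsoids whose voxels follow Gaussian HU distributions that shift
between inspiration and expiration, focal "trapped" regions that keep
inspiratory-like density on expiration, and a vertical near −1000 HU
airway tube entering from the apex slice.  Trapped regions are carved by
thresholding a smoothed Gaussian random field at the quantile matching
the requested trapped fraction, so they are spatially coherent blobs and
the realised fraction is exact to within one voxel; the field is
independent of the HU noise, so expiratory lung attenuation is an exact
two-Gaussian mixture with the requested weights.

All generators are pure functions of (spec, seed): the same spec yields
bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.stats import norm

from .densitometry import CTVolume, LevelSelection
from .indices import BASES, CRITERIA
from .sbnt import SBNTCurve

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "SBNTSpec",
    "CohortSpec",
    "PhantomSizingError",
    "generate_phantom",
    "generate_sbnt_curve",
    "generate_reader_pair",
    "generate_cohort",
    "analytic_mixture_summary",
]


class PhantomSizingError(ValueError):
    """Raised when the grid cannot contain the lung ellipsoids and airway."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a paired inspiratory/expiratory digital thorax phantom.

    HU distributions: normal parenchyma is drawn from
    N(lung_insp_mean, lung_insp_sd) at inspiration and
    N(lung_exp_mean, lung_exp_sd) at expiration; trapped voxels stay at
    inspiratory-like density N(trapped_exp_mean, trapped_exp_sd) on the
    expiratory acquisition.  ``trapped_fraction`` of lung voxels are
    trapped; ``trapped_gradient`` > 0 biases trapped regions caudally
    (toward larger z) without changing the overall fraction.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 96)
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    body_hu: float = 40.0
    body_sd: float = 15.0
    lung_insp_mean: float = -880.0
    lung_insp_sd: float = 20.0
    lung_exp_mean: float = -750.0
    lung_exp_sd: float = 20.0
    trapped_fraction: float = 0.3
    trapped_exp_mean: float = -880.0
    trapped_exp_sd: float = 15.0
    airway_radius_mm: float = 4.0
    air_hu: float = -1000.0
    air_sd: float = 10.0
    trapped_gradient: float = 0.0
    trapped_smoothness_vox: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.trapped_fraction <= 1.0:
            raise ValueError("trapped_fraction must lie in [0, 1]")
        for name in ("lung_insp_mean", "lung_exp_mean", "trapped_exp_mean"):
            if getattr(self, name) >= -500.0:
                raise ValueError(f"{name} must be below -500 HU (parenchymal density)")
        if self.body_hu <= -500.0:
            raise ValueError("body_hu must be above -500 HU (soft tissue)")
        if len(self.grid_shape) != 3 or any(int(s) < 1 for s in self.grid_shape):
            raise ValueError("grid_shape must be three positive integers")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        object.__setattr__(self, "grid_shape", tuple(int(s) for s in self.grid_shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    def default_levels(self) -> LevelSelection:
        """Four sampling levels spread through the lung span (cranio-caudal)."""
        nz = self.grid_shape[2]
        return LevelSelection(tuple(int(round(f * nz)) for f in (0.30, 0.45, 0.60, 0.75)))


@dataclass(frozen=True)
class PhantomTruth:
    """Ground-truth masks for a generated phantom (synthetic by design)."""

    lung_mask: np.ndarray
    trapped_mask: np.ndarray
    airway_mask: np.ndarray
    true_trapped_fraction: float

    def __post_init__(self) -> None:
        if (self.trapped_mask & ~self.lung_mask).any():
            raise ValueError("trapped_mask must be contained in lung_mask")
        if (self.airway_mask & self.lung_mask).any():
            raise ValueError("airway_mask must be disjoint from lung_mask")


def _phantom_geometry(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    nx, ny, nz = spec.grid_shape
    if min(nx, ny) < 32 or nz < 16:
        raise PhantomSizingError(
            f"grid {spec.grid_shape} too small: need at least 32×32 laterally and 16 slices"
        )
    x = np.arange(nx)[:, None, None]
    y = np.arange(ny)[None, :, None]
    z = np.arange(nz)[None, None, :]
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0

    body_r = 0.46 * min(nx, ny)
    body = np.broadcast_to(
        ((x - cx) ** 2 + (y - cy) ** 2) <= body_r**2, spec.grid_shape
    )

    lung = np.zeros(spec.grid_shape, bool)
    ax_, ay_, az_ = 0.16 * nx, 0.30 * ny, 0.35 * nz
    cz = 0.55 * nz
    for side in (-1.0, 1.0):
        lcx = cx + side * 0.22 * nx
        lung |= (
            ((x - lcx) / ax_) ** 2 + ((y - cy) / ay_) ** 2 + ((z - cz) / az_) ** 2
        ) <= 1.0

    r_air = spec.airway_radius_mm / float(np.mean(spec.spacing[:2]))
    gap = 0.06 * nx  # lateral clearance between lung ellipsoids and midline
    if r_air + 1.0 > gap:
        raise PhantomSizingError(
            f"airway radius {spec.airway_radius_mm} mm does not fit between the lungs "
            f"on a {nx}-voxel grid at {spec.spacing[0]} mm spacing"
        )
    airway = (((x - cx) ** 2 + (y - cy) ** 2) <= r_air**2) & (z <= 0.45 * nz)
    airway &= body & ~lung
    return body, lung, airway


def _trapped_mask(spec: PhantomSpec, lung: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if spec.trapped_fraction <= 0.0:
        return np.zeros_like(lung)
    if spec.trapped_fraction >= 1.0:
        return lung.copy()
    field = ndimage.gaussian_filter(
        rng.standard_normal(spec.grid_shape).astype(np.float32),
        sigma=spec.trapped_smoothness_vox,
    )
    # normalise so the caudal bias is on the scale of the field itself
    field /= max(float(field[lung].std()), 1e-12)
    if spec.trapped_gradient != 0.0:
        nz = spec.grid_shape[2]
        field += spec.trapped_gradient * (np.arange(nz) / max(nz - 1, 1))[None, None, :]
    vals = field[lung]
    thr = float(np.quantile(vals, 1.0 - spec.trapped_fraction))
    return lung & (field > thr)


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, CTVolume, PhantomTruth]:
    """Generate paired inspiratory/expiratory volumes plus ground truth.

    The two volumes are identical outside the lungs (body, airway and
    surrounding air voxels share the same noise realisation); inside the
    lungs each acquisition gets its own Gaussian draw.
    """
    rng = np.random.default_rng(spec.seed)
    body, lung, airway = _phantom_geometry(spec)
    trapped = _trapped_mask(spec, lung, rng)

    common = np.empty(spec.grid_shape, np.float32)
    outside = ~body
    tissue = body & ~lung & ~airway
    common[outside] = rng.normal(spec.air_hu, spec.air_sd, int(outside.sum()))
    common[tissue] = rng.normal(spec.body_hu, spec.body_sd, int(tissue.sum()))
    common[airway] = rng.normal(spec.air_hu, spec.air_sd, int(airway.sum()))

    n_lung = int(lung.sum())
    insp = common.copy()
    insp[lung] = rng.normal(spec.lung_insp_mean, spec.lung_insp_sd, n_lung)

    exp = common
    normal_lung = lung & ~trapped
    exp[normal_lung] = rng.normal(spec.lung_exp_mean, spec.lung_exp_sd, int(normal_lung.sum()))
    exp[trapped] = rng.normal(spec.trapped_exp_mean, spec.trapped_exp_sd, int(trapped.sum()))

    truth = PhantomTruth(
        lung_mask=lung,
        trapped_mask=trapped,
        airway_mask=airway,
        true_trapped_fraction=float(trapped.sum()) / n_lung if n_lung else 0.0,
    )
    return (
        CTVolume(insp, spec.spacing),
        CTVolume(exp, spec.spacing),
        truth,
    )


# --------------------------------------------------------------------------
# nitrogen washout curves


@dataclass(frozen=True)
class SBNTSpec:
    """Parameters of a simulated single-breath nitrogen washout curve.

    Volumes in litres of expired gas: phase I (pure dead-space O2) ends at
    ``phase1_end``; phase II (sigmoid rise to ``n2_at_phase3_start`` %N2)
    ends at ``phase2_end``; phase III rises linearly at ``phase3_slope``
    %N2/L until the phase-IV onset at ``vital_capacity − closing_volume``;
    phase IV continues at the steeper ``phase4_slope``.  Gaussian noise of
    ``noise_sd`` %N2 is added pointwise.
    """

    vital_capacity: float = 4.0
    phase1_end: float = 0.3
    phase2_end: float = 0.8
    closing_volume: float = 0.8
    phase3_slope: float = 2.0
    phase4_slope: float = 10.0
    n2_at_phase3_start: float = 25.0
    noise_sd: float = 0.05
    sample_step: float = 0.01
    flow_lps: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        vb = self.vital_capacity - self.closing_volume
        if not 0.0 < self.phase1_end < self.phase2_end < vb < self.vital_capacity:
            raise ValueError(
                "need 0 < phase1_end < phase2_end < vital_capacity - closing_volume "
                "< vital_capacity"
            )
        if not 0.0 <= self.phase3_slope <= self.phase4_slope:
            raise ValueError("need phase4_slope >= phase3_slope >= 0")
        if self.noise_sd < 0 or self.sample_step <= 0:
            raise ValueError("noise_sd must be >= 0 and sample_step > 0")
        min_phase = min(
            self.phase1_end,
            self.phase2_end - self.phase1_end,
            vb - self.phase2_end,
            self.closing_volume,
        )
        if self.sample_step >= min_phase:
            raise ValueError(
                f"sample_step {self.sample_step} L cannot resolve the shortest phase "
                f"({min_phase:.3g} L)"
            )

    @property
    def breakpoint(self) -> float:
        """Expired volume at phase-IV onset (L)."""
        return self.vital_capacity - self.closing_volume


def _sbnt_noiseless(spec: SBNTSpec, v: np.ndarray) -> np.ndarray:
    p1, p2, vb = spec.phase1_end, spec.phase2_end, spec.breakpoint
    n2 = np.zeros_like(v)

    # phase II: logistic rescaled to hit 0 at p1 and n2_at_phase3_start at p2
    in2 = (v > p1) & (v <= p2)
    k = 10.0 / (p2 - p1)
    mid = 0.5 * (p1 + p2)
    sig = lambda u: 1.0 / (1.0 + np.exp(-u))  # noqa: E731
    lo, hi = sig(k * (p1 - mid)), sig(k * (p2 - mid))
    n2[in2] = spec.n2_at_phase3_start * (sig(k * (v[in2] - mid)) - lo) / (hi - lo)

    in3 = (v > p2) & (v <= vb)
    n2[in3] = spec.n2_at_phase3_start + spec.phase3_slope * (v[in3] - p2)

    in4 = v > vb
    n2_at_vb = spec.n2_at_phase3_start + spec.phase3_slope * (vb - p2)
    n2[in4] = n2_at_vb + spec.phase4_slope * (v[in4] - vb)
    return n2


def generate_sbnt_curve(spec: SBNTSpec) -> tuple[SBNTCurve, float, float]:
    """Simulate a washout trace; returns (curve, true dN2, true CV)."""
    rng = np.random.default_rng(spec.seed)
    v = np.arange(0.0, spec.vital_capacity + 0.5 * spec.sample_step, spec.sample_step)
    v = v[v <= spec.vital_capacity + 1e-12]
    n2 = _sbnt_noiseless(spec, v)
    if spec.noise_sd > 0:
        n2 = n2 + rng.normal(0.0, spec.noise_sd, v.size)
    flow = np.full(v.size, spec.flow_lps)
    curve = SBNTCurve(expired_volume=v, n2=n2, vital_capacity=spec.vital_capacity, flow=flow)
    return curve, spec.phase3_slope, spec.closing_volume


# --------------------------------------------------------------------------
# reader pairs and cohorts


def generate_reader_pair(
    true_values: Sequence[float],
    subject_sd: float,
    error_sd: float | tuple[float, float],
    seed: int,
    reader_bias: tuple[float, float] = (0.0, 0.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Two readers measuring the same subjects with independent noise.

    Each subject's latent value is ``true_values[i]`` plus a shared
    N(0, subject_sd) subject effect; each reader adds its own bias and
    independent N(0, error_sd) measurement error.  With subject variance
    σs² and error variance σe², the population ICC(2,1) is σs²/(σs²+σe²)
    (minus a penalty for any between-reader bias).
    """
    if subject_sd < 0:
        raise ValueError("subject_sd must be >= 0")
    sd_a, sd_b = (error_sd, error_sd) if np.isscalar(error_sd) else error_sd
    if sd_a < 0 or sd_b < 0:
        raise ValueError("error_sd must be >= 0")
    rng = np.random.default_rng(seed)
    base = np.asarray(true_values, float)
    subj = base + rng.normal(0.0, subject_sd, base.size)
    a = subj + reader_bias[0] + rng.normal(0.0, sd_a, base.size)
    b = subj + reader_bias[1] + rng.normal(0.0, sd_b, base.size)
    return a, b


def _gauss_prob(mean: float, sd: float, hu_range: tuple[float, float]) -> float:
    lo, hi = hu_range
    return float(norm.cdf(hi, mean, sd) - norm.cdf(lo, mean, sd))


def analytic_mixture_summary(
    f: float | np.ndarray,
    normal_mean: float,
    normal_sd: float,
    trapped_mean: float,
    trapped_sd: float,
    laa_full_range: tuple[float, float] = (-1024.0, -850.0),
    laa_narrow_range: tuple[float, float] = (-910.0, -850.0),
) -> dict[str, np.ndarray]:
    """Noise-free densitometry of a two-Gaussian lung mixture.

    Returns MLD and the two LAA percentages for a lung whose voxels are a
    fraction ``f`` from N(trapped_mean, trapped_sd) and ``1−f`` from
    N(normal_mean, normal_sd).  This is the closed-form counterpart of
    measuring a large phantom.
    """
    f = np.asarray(f, float)
    p_full = (1 - f) * _gauss_prob(normal_mean, normal_sd, laa_full_range) + f * _gauss_prob(
        trapped_mean, trapped_sd, laa_full_range
    )
    p_narrow = (1 - f) * _gauss_prob(normal_mean, normal_sd, laa_narrow_range) + f * _gauss_prob(
        trapped_mean, trapped_sd, laa_narrow_range
    )
    return {
        "mld": (1 - f) * normal_mean + f * trapped_mean,
        "laa_full_pct": 100.0 * p_full,
        "laa_narrow_pct": 100.0 * p_narrow,
    }


#: default relative measurement noise per criterion; the E/I MLD ratio is
#: the best-measured criterion (smallest relative noise), giving the cohort
#: one criterion with a deliberately strongest link to the washout outcome.
DEFAULT_RELATIVE_NOISE: Mapping[str, float] = {c: 1.2 for c in CRITERIA} | {
    "e_over_i_mld": 0.1
}

#: multiplicative cranio-caudal heterogeneity of trapping across the four
#: sampling levels (dependent regions trap more)
DEFAULT_LEVEL_FACTORS = (0.85, 0.95, 1.05, 1.15)


@dataclass(frozen=True)
class CohortSpec:
    """A simulated cohort linking CT indices and washout dN2.

    Each subject has a latent trapped fraction drawn uniformly from
    ``trapped_fraction_range``; the nine CT criteria at four levels are
    deterministic functions of it (via the two-Gaussian mixture closed
    form) plus Gaussian measurement noise, and
    dN2 = intercept + gain·fraction + noise with gain > 0, inducing a
    positive monotone link between trapping and the washout outcome.
    """

    n_subjects: int = 89
    trapped_fraction_range: tuple[float, float] = (0.05, 0.75)
    dn2_intercept: float = 0.5
    dn2_gain: float = 5.0
    dn2_noise_sd: float = 0.4
    index_noise_sd: float = 0.3
    relative_noise: Mapping[str, float] | None = None
    level_factors: tuple[float, float, float, float] = DEFAULT_LEVEL_FACTORS
    insp_mean: float = -880.0
    insp_sd: float = 20.0
    exp_mean: float = -750.0
    exp_sd: float = 20.0
    trapped_mean: float = -880.0
    trapped_sd: float = 15.0
    dn2_cutoff: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        lo, hi = self.trapped_fraction_range
        if not 0.0 <= lo < hi <= 1.0:
            raise ValueError("trapped_fraction_range must be an interval within [0, 1]")
        if self.dn2_gain <= 0:
            raise ValueError("dn2_gain must be > 0 (positive trapping–dN2 link)")
        if self.dn2_noise_sd < 0 or self.index_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")


def _noiseless_criteria(spec: CohortSpec, f: np.ndarray) -> dict[str, np.ndarray]:
    """The nine criteria as deterministic functions of trapped fraction."""
    exp_s = analytic_mixture_summary(
        f, spec.exp_mean, spec.exp_sd, spec.trapped_mean, spec.trapped_sd
    )
    insp_s = analytic_mixture_summary(
        np.zeros_like(f), spec.insp_mean, spec.insp_sd, spec.insp_mean, spec.insp_sd
    )
    e = {"mld": exp_s["mld"], "laa850_1024": exp_s["laa_full_pct"], "laa850_910": exp_s["laa_narrow_pct"]}
    i = {"mld": insp_s["mld"], "laa850_1024": insp_s["laa_full_pct"], "laa850_910": insp_s["laa_narrow_pct"]}
    out: dict[str, np.ndarray] = {}
    for basis in BASES:
        out[f"e_over_i_{basis}"] = e[basis] / i[basis]
        out[f"e_minus_i_{basis}"] = e[basis] - i[basis]
        out[f"rel_diff_{basis}"] = e[basis] / i[basis] - 1.0
    return out


def generate_cohort(spec: CohortSpec) -> "pd.DataFrame":
    """Simulate a cohort table: dN2, obstruction label, 9 criteria × levels.

    Columns: ``subject_id``, ``true_trapped_fraction``, ``dn2``,
    ``obstructed``, then for every criterion ``<crit>_l1``…``<crit>_l4``
    (per level) and ``<crit>_mean`` (unweighted mean of the four measured
    levels, mirroring how paired CT indices are averaged).
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.trapped_fraction_range
    f = rng.uniform(lo, hi, spec.n_subjects)
    dn2 = spec.dn2_intercept + spec.dn2_gain * f
    if spec.dn2_noise_sd > 0:
        dn2 = dn2 + rng.normal(0.0, spec.dn2_noise_sd, spec.n_subjects)

    rel = dict(DEFAULT_RELATIVE_NOISE)
    if spec.relative_noise:
        rel.update(spec.relative_noise)

    # dynamic range of each criterion over f in [0, 1] sets its noise scale
    span = _noiseless_criteria(spec, np.array([0.0, 1.0]))
    scale = {c: abs(span[c][1] - span[c][0]) for c in CRITERIA}

    data: dict[str, np.ndarray] = {
        "subject_id": np.array([f"S{i + 1:03d}" for i in range(spec.n_subjects)]),
        "true_trapped_fraction": f,
        "dn2": dn2,
        "obstructed": dn2 > spec.dn2_cutoff,
    }
    level_values: dict[str, list[np.ndarray]] = {c: [] for c in CRITERIA}
    for lvl, factor in enumerate(spec.level_factors, start=1):
        f_lvl = np.clip(f * factor, 0.0, 1.0)
        clean = _noiseless_criteria(spec, f_lvl)
        for c in CRITERIA:
            sd = spec.index_noise_sd * rel[c] * scale[c]
            noisy = clean[c] + (rng.normal(0.0, sd, spec.n_subjects) if sd > 0 else 0.0)
            data[f"{c}_l{lvl}"] = noisy
            level_values[c].append(noisy)
    for c in CRITERIA:
        data[f"{c}_mean"] = np.mean(level_values[c], axis=0)
    return pd.DataFrame(data)
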