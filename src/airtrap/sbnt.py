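"""Single-breath nitrogen washout (SBNT) curve analysis.

After a vital-capacity inhalation of 100% O2 the exhaled N2 concentration
is recorded against expired volume.  The curve shows four phases: I
(dead-space gas, ≈0% N2), II (bronchial/alveolar transition, sigmoid
rise), III (alveolar plateau, gently rising line whose slope is dN2 in
%N2 per litre), and IV (an abrupt steepening when dependent small airways
close; the volume from its onset to full expiration is the closing
volume, CV).

dN2 above 2.5 %N2/L is the conventional marker of small airway
obstruction and is the classification cutoff used here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SBNTCurve",
    "SBNTResult",
    "FlowCheck",
    "Phase3Fit",
    "validate_flow",
    "detect_closing_volume",
    "fit_phase3",
    "classify_obstruction",
    "analyze_curve",
    "DN2_CUTOFF",
]

#: conventional dN2 cutoff for small airway obstruction, %N2 per litre
DN2_CUTOFF = 2.5


@dataclass(frozen=True)
class SBNTCurve:
    """A nitrogen washout trace.

    ``expired_volume`` (L, strictly increasing), ``n2`` (%N2), optional
    ``flow`` (L/s), and the manoeuvre's ``vital_capacity`` (L).
    """

    expired_volume: np.ndarray
    n2: np.ndarray
    vital_capacity: float
    flow: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.expired_volume, float)
        n2 = np.asarray(self.n2, float)
        if v.ndim != 1 or v.shape != n2.shape:
            raise ValueError("expired_volume and n2 must be equal-length 1-D arrays")
        if np.any(np.diff(v) <= 0):
            raise ValueError("expired_volume must be strictly increasing")
        vc = float(self.vital_capacity)
        if vc <= 0:
            raise ValueError("vital_capacity must be positive")
        if v[0] < -1e-9 or v[-1] > vc + 1e-9:
            raise ValueError("expired volumes must lie within [0, vital_capacity]")
        flow = self.flow
        if flow is not None:
            flow = np.asarray(flow, float)
            if flow.shape != v.shape:
                raise ValueError("flow must match the sample count")
        object.__setattr__(self, "expired_volume", v)
        object.__setattr__(self, "n2", n2)
        object.__setattr__(self, "vital_capacity", vc)
        object.__setattr__(self, "flow", flow)

    def __len__(self) -> int:
        return self.expired_volume.size


@dataclass(frozen=True)
class FlowCheck:
    """Expiratory-flow quality control result.

    ``ok`` is None when no flow trace was recorded ("not assessed").
    ``fraction_in_range`` is the fraction of mid-expiration samples within
    the target flow band.
    """

    ok: bool | None
    fraction_in_range: float


@dataclass(frozen=True)
class Phase3Fit:
    dn2: float
    interval: tuple[float, float]
    r2: float


@dataclass(frozen=True)
class SBNTResult:
    """Full analysis of one washout curve."""

    dn2: float
    closing_volume: float
    phase3_interval: tuple[float, float]
    fit_r2: float
    flow_ok: bool | None
    obstructed: bool
    breakpoint: float


def validate_flow(
    curve: SBNTCurve, lo: float = 0.3, hi: float = 0.5, min_fraction: float = 0.9
) -> FlowCheck:
    """Check that expiratory flow stayed in the [lo, hi] L/s target band.

    Only mid-expiration samples (25–75% of expired vital capacity) are
    assessed; the manoeuvre passes when at least ``min_fraction`` of them
    lie inside the band.  Returns ``ok=None`` if no flow was recorded.
    """
    if curve.flow is None:
        return FlowCheck(ok=None, fraction_in_range=float("nan"))
    v = curve.expired_volume
    mid = (v >= 0.25 * curve.vital_capacity) & (v <= 0.75 * curve.vital_capacity)
    if not mid.any():
        return FlowCheck(ok=None, fraction_in_range=float("nan"))
    f = curve.flow[mid]
    frac = float(((f >= lo) & (f <= hi)).mean())
    return FlowCheck(ok=frac >= min_fraction, fraction_in_range=frac)


def _two_segment_sse(v: np.ndarray, y: np.ndarray, vb: float) -> tuple[float, float, float]:
    """Continuous two-segment linear LSQ with hinge at vb.

    Model y = a + b·v + c·max(v − vb, 0).  Returns (sse, slope1, slope2).
    """
    hinge = np.maximum(v - vb, 0.0)
    X = np.column_stack([np.ones_like(v), v, hinge])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), float(coef[1]), float(coef[1] + coef[2])


def detect_closing_volume(
    curve: SBNTCurve,
    search_start_frac: float = 0.5,
    slope_ratio: float = 2.0,
    min_samples: int = 10,
    min_side_samples: int = 3,
) -> tuple[float, float]:
    """Locate the phase-IV onset and the closing volume.

    A continuous two-segment line is fitted over the terminal search
    window (expired volume ≥ ``search_start_frac``·VC) at every candidate
    breakpoint; the breakpoint minimising total squared error wins.  A
    phase IV is only accepted when the terminal slope exceeds the
    first-segment (phase III) slope by at least ``slope_ratio``×,
    otherwise the curve is judged to have no phase IV and CV = 0.

    Returns ``(closing_volume, breakpoint_volume)`` in litres; with no
    phase IV the breakpoint is the end of expiration.
    """
    if not 60.0 * curve.vital_capacity / 100.0 <= curve.expired_volume[-1] + 1e-9:
        raise ValueError("curve must span at least 60% of vital capacity")
    v = curve.expired_volume
    y = curve.n2
    window = v >= search_start_frac * curve.vital_capacity
    vw, yw = v[window], y[window]
    if vw.size < min_samples:
        raise ValueError(
            f"only {vw.size} samples in the closing-volume search window (need {min_samples})"
        )

    candidates = range(min_side_samples, vw.size - min_side_samples)
    best = None
    for idx in candidates:
        sse, s1, s2 = _two_segment_sse(vw, yw, float(vw[idx]))
        if best is None or sse < best[0]:
            best = (sse, float(vw[idx]), s1, s2)
    assert best is not None
    _, vb, s1, s2 = best

    accepted = (s2 > 0) and (s2 > slope_ratio * s1)
    if not accepted:
        return 0.0, float(v[-1])
    return float(curve.vital_capacity - vb), vb


def fit_phase3(
    curve: SBNTCurve,
    closing_volume: float = 0.0,
    start_frac: float = 0.3,
    min_length: float = 0.5,
) -> Phase3Fit:
    """Ordinary least-squares fit of the alveolar plateau (phase III).

    The plateau window runs from ``start_frac``·VC of expired volume to
    the phase-IV breakpoint (VC − closing_volume); its slope is dN2 in
    %N2 per litre.  R² is 1 for an exact fit (including a flat plateau).
    """
    v_lo = start_frac * curve.vital_capacity
    v_hi = curve.vital_capacity - closing_volume
    if v_hi - v_lo < min_length:
        raise ValueError(
            f"phase III too short: [{v_lo:.2f}, {v_hi:.2f}] L spans less than {min_length} L"
        )
    sel = (curve.expired_volume >= v_lo) & (curve.expired_volume <= v_hi)
    if sel.sum() < 3:
        raise ValueError("phase III too short: fewer than 3 samples in the window")
    v = curve.expired_volume[sel]
    y = curve.n2[sel]
    slope, intercept = np.polyfit(v, y, 1)
    resid = y - (slope * v + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    # scale-aware floor so an exactly flat plateau reads as a perfect fit
    tol = y.size * (1e-12 * max(1.0, float(np.abs(y).max()))) ** 2
    if ss_tot <= tol:
        r2 = 1.0 if ss_res <= tol else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return Phase3Fit(dn2=float(slope), interval=(float(v_lo), float(v_hi)), r2=r2)


def classify_obstruction(dn2: float, cutoff: float = DN2_CUTOFF) -> bool:
    """Small airway obstruction iff dN2 strictly exceeds the cutoff."""
    if not np.isfinite(dn2):
        raise ValueError("dn2 must be finite")
    return bool(dn2 > cutoff)


def analyze_curve(
    curve: SBNTCurve,
    cutoff: float = DN2_CUTOFF,
    phase3_start_frac: float = 0.3,
    cv_search_start_frac: float = 0.5,
    slope_ratio: float = 2.0,
) -> SBNTResult:
    """Full SBNT pipeline: flow QC → closing volume → dN2 → classification."""
    flow = validate_flow(curve)
    cv, vb = detect_closing_volume(
        curve, search_start_frac=cv_search_start_frac, slope_ratio=slope_ratio
    )
    fit = fit_phase3(curve, closing_volume=cv, start_frac=phase3_start_frac)
    return SBNTResult(
        dn2=fit.dn2,
        closing_volume=cv,
        phase3_interval=fit.interval,
        fit_r2=fit.r2,
        flow_ok=flow.ok,
        obstructed=classify_obstruction(fit.dn2, cutoff=cutoff),
        breakpoint=vb,
    )
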