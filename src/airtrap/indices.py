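"""Paired expiratory/inspiratory air-trapping indices.

For each density basis — mean lung density (MLD, HU) and the two
low-attenuation-area percentages LAA%[−850,−1024] and LAA%[−850,−910] —
three paired criteria are derived from the expiratory value E and the
inspiratory value I:

    E/I          ratio, computed on raw signed values
    E − I        difference (HU for MLD, percentage points for LAA)
    (E − I)/I    relative difference, identically E/I − 1

Ratios use signed HU on purpose: MLD is negative on both acquisitions, so
E/I_MLD lands near 0.8–1.0 (air trapping pushes it toward 1), which is the
scale on which E/I_MLD discrimination thresholds such as 0.89 live.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "BasisPair",
    "AirTrappingIndices",
    "compute_indices",
    "indices_to_row",
    "BASES",
    "CRITERIA",
    "EXPECTED_SIGN",
]

#: density bases, in canonical order
BASES = ("mld", "laa850_1024", "laa850_910")

#: the nine paired criteria: 3 measures × 3 bases
CRITERIA = tuple(
    f"{measure}_{basis}" for basis in BASES for measure in ("e_over_i", "e_minus_i", "rel_diff")
)

#: expected sign of the association between each criterion and the degree of
#: air trapping.  More trapping lowers expiratory MLD (toward inspiratory
#: values), so E−I on the MLD basis *decreases* while E/I and (E−I)/I
#: increase; all LAA-based criteria increase.
EXPECTED_SIGN = {c: (-1 if c == "e_minus_i_mld" else +1) for c in CRITERIA}


@dataclass(frozen=True)
class BasisPair:
    """E/I criteria for one density basis.

    ``ratio_defined`` is False when I = 0 (possible on an LAA basis), in
    which case ``e_over_i`` and ``rel_diff`` are NaN but ``e_minus_i`` is
    still valid.
    """

    e_value: float
    i_value: float
    e_over_i: float
    e_minus_i: float
    rel_diff: float
    ratio_defined: bool = True


@dataclass(frozen=True)
class AirTrappingIndices:
    """The nine paired criteria at one level (or the across-level mean)."""

    mld: BasisPair
    laa_full: BasisPair
    laa_narrow: BasisPair
    level_id: int | str | None = None

    def basis(self, name: str) -> BasisPair:
        return {"mld": self.mld, "laa850_1024": self.laa_full, "laa850_910": self.laa_narrow}[name]


def _pair(e: float, i: float) -> BasisPair:
    e = float(e)
    i = float(i)
    if i == 0.0:
        return BasisPair(e, i, math.nan, e - i, math.nan, ratio_defined=False)
    ratio = e / i
    return BasisPair(e, i, ratio, e - i, ratio - 1.0)


def compute_indices(exp_summary, insp_summary) -> AirTrappingIndices:
    """Compute the nine paired criteria from two density summaries.

    Parameters
    ----------
    exp_summary, insp_summary
        :class:`~airtrap.densitometry.DensitySummary` objects for the
        expiratory and inspiratory acquisition at the same level
        (``level_id`` must agree).
    """
    if exp_summary.level_id != insp_summary.level_id:
        raise ValueError(
            f"summaries refer to different levels: {exp_summary.level_id!r} vs "
            f"{insp_summary.level_id!r}"
        )
    return AirTrappingIndices(
        mld=_pair(exp_summary.mld, insp_summary.mld),
        laa_full=_pair(exp_summary.laa_full_pct, insp_summary.laa_full_pct),
        laa_narrow=_pair(exp_summary.laa_narrow_pct, insp_summary.laa_narrow_pct),
        level_id=exp_summary.level_id,
    )


def indices_to_row(indices: AirTrappingIndices, suffix: str = "") -> dict[str, float]:
    """Flatten to a dict of 15 columns (3 bases × {e, i, E/I, E−I, (E−I)/I}).

    ``suffix`` (e.g. ``"_l2"`` or ``"_mean"``) is appended to every key, so
    rows for several levels can be merged into one subject record.
    """
    row: dict[str, float] = {}
    for basis in BASES:
        p = indices.basis(basis)
        row[f"e_{basis}{suffix}"] = p.e_value
        row[f"i_{basis}{suffix}"] = p.i_value
        row[f"e_over_i_{basis}{suffix}"] = p.e_over_i
        row[f"e_minus_i_{basis}{suffix}"] = p.e_minus_i
        row[f"rel_diff_{basis}{suffix}"] = p.rel_diff
    return row
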