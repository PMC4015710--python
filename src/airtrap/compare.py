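"""Statistical comparison of CT air-trapping criteria against washout dN2.

The workflow mirrors how a criterion-selection study proceeds: Spearman
rank correlation of every criterion with dN2, a hierarchical dendrogram
(distance 1 − |rho|, average linkage) to find the criteria closest to
dN2, ROC analysis of those criteria against the dN2 > 2.5 %N2/L
obstruction label (AUC with DeLong 95% CI, Youden-optimal threshold),
inter-reader agreement via ICC(2,1), and a Friedman test for
heterogeneity of trapping across the four anatomical levels.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import roc_curve as _sk_roc_curve

from .indices import CRITERIA
from .sbnt import DN2_CUTOFF

__all__ = [
    "SpearmanResult",
    "ROCResult",
    "ICCResult",
    "FriedmanResult",
    "Dendrogram",
    "ComparisonReport",
    "spearman_vs_dn2",
    "build_dendrogram",
    "roc_analysis",
    "delong_auc_ci",
    "icc_two_readers",
    "level_heterogeneity_test",
    "run_comparison",
    "validate_cohort",
]


# --------------------------------------------------------------------------
# Spearman


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    defined: bool = True


def spearman_vs_dn2(
    table: pd.DataFrame, criterion: str, dn2_col: str = "dn2"
) -> SpearmanResult:
    """Spearman rank correlation (mid-ranks for ties, two-sided p).

    A constant column has no rank ordering; the result is returned with
    ``defined=False`` and NaN statistics rather than raising.
    """
    sub = table[[dn2_col, criterion]].dropna()
    if len(sub) < 5:
        raise ValueError(f"need at least 5 complete pairs, got {len(sub)}")
    x = sub[dn2_col].to_numpy(float)
    y = sub[criterion].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(math.nan, math.nan, len(sub), defined=False)
    rho, p = sps.spearmanr(x, y)
    return SpearmanResult(float(rho), float(p), len(sub))


# --------------------------------------------------------------------------
# dendrogram


@dataclass(frozen=True)
class Dendrogram:
    """Average-linkage tree over variables with distance 1 − |Spearman rho|."""

    linkage: np.ndarray
    labels: tuple[str, ...]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cophenetic_distances(self, label: str) -> dict[str, float]:
        """Tree (cophenetic) distance from one leaf to every other leaf."""
        idx = self.labels.index(label)
        d = squareform(hierarchy.cophenet(self.linkage))
        return {
            lab: float(d[idx, j]) for j, lab in enumerate(self.labels) if j != idx
        }

    def closest_to(self, label: str = "dn2", k: int = 3) -> list[str]:
        """The k leaves nearest ``label`` in the tree (the closest branches)."""
        d = self.cophenetic_distances(label)
        return sorted(d, key=d.get)[:k]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_height:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return rec(tree, tree.dist).rsplit(":", 1)[0] + ";"


def build_dendrogram(
    table: pd.DataFrame, variables: Sequence[str], method: str = "average"
) -> Dendrogram:
    """Agglomerative clustering of variables by rank-correlation distance.

    Distance d(u, v) = 1 − |Spearman rho(u, v)|, so tightly (anti)correlated
    variables merge low.  Raises if any pairwise rho is undefined.
    """
    if len(variables) < 3:
        raise ValueError("need at least 3 variables to build a dendrogram")
    sub = table[list(variables)].dropna()
    rho = sub.corr(method="spearman").to_numpy()
    bad = [v for v, row in zip(variables, rho) if np.isnan(row).any()]
    if bad:
        raise ValueError(f"undefined pairwise correlations for: {', '.join(bad)}")
    d = 1.0 - np.abs(rho)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(d, checks=False), method=method)
    return Dendrogram(linkage=Z, labels=tuple(variables))


# --------------------------------------------------------------------------
# ROC / AUC with DeLong CI


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def delong_auc_ci(
    pos: np.ndarray, neg: np.ndarray, alpha: float = 0.95
) -> tuple[float, tuple[float, float], float]:
    """AUC, its DeLong variance, and a normal-approximation CI.

    Implements the structural-components form of the DeLong estimator:
    V10_i = (rank of positive i among all − rank among positives)/n_neg,
    V01_j symmetrically; var(AUC) = S10/m + S01/n.
    """
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("both classes must be non-empty")
    allv = np.concatenate([pos, neg])
    rk_all = _midrank(allv)
    rk_pos = _midrank(pos)
    rk_neg = _midrank(neg)
    auc = (rk_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (rk_all[:m] - rk_pos) / n
    v01 = 1.0 - (rk_all[m:] - rk_neg) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    z = sps.norm.ppf(0.5 + alpha / 2.0)
    half = z * math.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return float(auc), (float(ci[0]), float(ci[1])), float(var)


@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC summary for one criterion.

    ``direction`` is "higher" when larger values indicate obstruction,
    "lower" otherwise (chosen automatically so AUC ≥ 0.5 unless forced).
    ``best_threshold`` is on the original value scale; a case is called
    positive when the value is ≥ the threshold ("higher") or ≤ it
    ("lower").
    """

    auc: float
    auc_ci: tuple[float, float]
    best_threshold: float
    sensitivity: float
    specificity: float
    direction: str
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    n_pos: int
    n_neg: int


def roc_analysis(
    values: Sequence[float],
    labels: Sequence[bool],
    direction: str = "auto",
    ci_alpha: float = 0.95,
) -> ROCResult:
    """Empirical ROC over all observed thresholds with Youden-J optimum.

    AUC by the trapezoidal rule (equals the rank/Mann–Whitney statistic),
    95% CI by DeLong.  The optimal threshold maximises Youden's
    J = sensitivity + specificity − 1; ties break toward higher
    specificity.
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels, bool)
    if values.shape != labels.shape:
        raise ValueError("values and labels must align")
    if labels.all() or not labels.any():
        raise ValueError("ROC requires both classes present")

    if direction not in ("auto", "higher", "lower"):
        raise ValueError("direction must be 'auto', 'higher' or 'lower'")
    if direction == "auto":
        auc_raw, *_ = delong_auc_ci(values[labels], values[~labels])
        direction = "higher" if auc_raw >= 0.5 else "lower"
    score = values if direction == "higher" else -values

    fpr, tpr, thr = _sk_roc_curve(labels, score)
    auc, ci, _ = delong_auc_ci(score[labels], score[~labels], alpha=ci_alpha)

    j = tpr - fpr
    jmax = j.max()
    tied = np.flatnonzero(j >= jmax - 1e-12)
    best = tied[np.argmin(fpr[tied])]
    best_thr = thr[best]
    if np.isinf(best_thr):  # sklearn's sentinel point (0, 0)
        finite = thr[np.isfinite(thr)]
        best_thr = finite[0] if finite.size else math.nan
    thresholds = thr if direction == "higher" else -thr
    return ROCResult(
        auc=float(auc),
        auc_ci=ci,
        best_threshold=float(best_thr if direction == "higher" else -best_thr),
        sensitivity=float(tpr[best]),
        specificity=float(1.0 - fpr[best]),
        direction=direction,
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        n_pos=int(labels.sum()),
        n_neg=int((~labels).sum()),
    )


# --------------------------------------------------------------------------
# ICC


@dataclass(frozen=True)
class ICCResult:
    icc: float
    model: str
    n_subjects: int
    defined: bool = True


def icc_two_readers(
    reader_a: Sequence[float], reader_b: Sequence[float], model: str = "icc2_1"
) -> ICCResult:
    """Intraclass correlation between two paired readers.

    Default is the two-way random-effects, absolute-agreement,
    single-measure coefficient ICC(2,1) =
    (MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n),
    which penalises systematic between-reader bias.  ``model`` may also
    be ``"icc3_1"`` (consistency, bias ignored) or ``"icc1"`` (one-way).
    """
    a = np.asarray(reader_a, float)
    b = np.asarray(reader_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("readers must be equal-length 1-D measurement lists")
    n = a.size
    if n < 5:
        raise ValueError(f"need at least 5 paired subjects, got {n}")
    x = np.column_stack([a, b])
    k = 2
    grand = x.mean()
    if np.allclose(x, grand):
        return ICCResult(math.nan, model, n, defined=False)
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if model == "icc2_1":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        icc = (msr - mse) / denom if denom != 0 else math.nan
    elif model == "icc3_1":
        denom = msr + (k - 1) * mse
        icc = (msr - mse) / denom if denom != 0 else math.nan
    elif model == "icc1":
        ssw = sst - ssr
        msw = ssw / (n * (k - 1))
        denom = msr + (k - 1) * msw
        icc = (msr - msw) / denom if denom != 0 else math.nan
    else:
        raise ValueError(f"unknown ICC model {model!r}")
    if not np.isfinite(icc):
        return ICCResult(math.nan, model, n, defined=False)
    return ICCResult(float(icc), model, n)


# --------------------------------------------------------------------------
# Friedman across levels


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    p_value: float
    n_subjects: int
    n_dropped: int
    method: str


def _friedman_statistic(ranks: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square from an n×k mid-rank matrix."""
    n, k = ranks.shape
    col_sums = ranks.sum(axis=0)
    s = ((col_sums - n * (k + 1) / 2.0) ** 2).sum()
    # per-row tie correction: sum of (t^3 - t) over tie groups; the
    # standard correction divides chi by (1 - tie_total/(n k (k^2-1)))
    tie = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        tie += float((counts**3 - counts).sum())
    chi = 12.0 * s / (n * k * (k + 1))
    corr = 1.0 - tie / (n * k * (k**2 - 1))
    if corr <= 0:
        return 0.0
    return chi / corr


def level_heterogeneity_test(
    values: pd.DataFrame | np.ndarray,
    method: str = "auto",
    exact_limit: int = 1_000_000,
) -> FriedmanResult:
    """Friedman test for differences across repeated anatomical levels.

    ``values`` holds one row per subject and one column per level.  Rows
    with missing values are dropped (and counted).  ``method``:

    - ``"chisq"``: large-sample chi-square approximation (tie-corrected);
    - ``"exact"``: exact permutation p-value, enumerating all within-
      subject orderings (k!^n arrangements — small instances only);
    - ``"auto"``: exact when k!^n ≤ ``exact_limit``, else chi-square.
    """
    arr = values.to_numpy(float) if isinstance(values, pd.DataFrame) else np.asarray(values, float)
    if arr.ndim != 2 or arr.shape[1] < 3:
        raise ValueError("need an n_subjects × n_levels (>= 3) array")
    complete = ~np.isnan(arr).any(axis=1)
    n_dropped = int((~complete).sum())
    arr = arr[complete]
    n, k = arr.shape
    if n < 2:
        raise ValueError("need at least 2 complete subjects")
    if n < 5 and method == "chisq":
        raise ValueError("chi-square approximation needs at least 5 complete subjects")

    ranks = np.vstack([sps.rankdata(row) for row in arr])
    chi = _friedman_statistic(ranks)

    total = math.factorial(k) ** n
    use_exact = method == "exact" or (method == "auto" and total <= exact_limit)
    if use_exact:
        target = n * (k + 1) / 2.0
        s_obs = float(((ranks.sum(axis=0) - target) ** 2).sum())
        perms = np.array(list(itertools.permutations(range(k))))
        sums = np.zeros((1, k))
        for row in ranks:
            contrib = row[perms]  # (k!, k)
            sums = (sums[:, None, :] + contrib[None, :, :]).reshape(-1, k)
        s_all = ((sums - target) ** 2).sum(axis=1)
        p = float((s_all >= s_obs - 1e-9).mean())
        return FriedmanResult(chi, p, n, n_dropped, "exact")

    if chi == 0.0:
        return FriedmanResult(0.0, 1.0, n, n_dropped, "chisq")
    p = float(sps.chi2.sf(chi, k - 1))
    return FriedmanResult(chi, p, n, n_dropped, "chisq")


# --------------------------------------------------------------------------
# composite report


def validate_cohort(table: pd.DataFrame, dn2_col: str = "dn2", cutoff: float = DN2_CUTOFF) -> None:
    """Structural checks on a cohort table."""
    if "subject_id" in table.columns and table["subject_id"].duplicated().any():
        raise ValueError("duplicated subject_id in cohort table")
    if dn2_col not in table.columns:
        raise ValueError(f"cohort table lacks a {dn2_col!r} column")
    if "obstructed" in table.columns:
        expected = table[dn2_col] > cutoff
        if not (table["obstructed"].astype(bool) == expected).all():
            raise ValueError("obstructed column inconsistent with dn2 > cutoff")


@dataclass
class ComparisonReport:
    """Output of :func:`run_comparison`."""

    n_subjects: int
    prevalence: float
    spearman: pd.DataFrame
    dendrogram: Dendrogram | None
    top_branches: list[str]
    roc: dict[str, ROCResult]
    roc_ranking: list[str]
    messages: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            "n_subjects": self.n_subjects,
            "prevalence": self.prevalence,
            "spearman": self.spearman.to_dict(orient="index"),
            "top_branches": self.top_branches,
            "roc_ranking": self.roc_ranking,
            "roc": {
                name: {
                    "auc": r.auc,
                    "auc_ci": list(r.auc_ci),
                    "best_threshold": r.best_threshold,
                    "sensitivity": r.sensitivity,
                    "specificity": r.specificity,
                    "direction": r.direction,
                }
                for name, r in self.roc.items()
            },
            "messages": self.messages,
        }
        if self.dendrogram is not None:
            out["dendrogram_newick"] = self.dendrogram.to_newick()
        return out


def run_comparison(
    table: pd.DataFrame,
    criteria: Sequence[str] | None = None,
    dn2_col: str = "dn2",
    cutoff: float = DN2_CUTOFF,
    k_branches: int = 3,
    linkage_method: str = "average",
) -> ComparisonReport:
    """Correlate → cluster → ROC: the full criterion-selection workflow.

    Reports obstruction prevalence, the Spearman table for every
    criterion, the criterion–dN2 dendrogram, and ROC analyses of the
    ``k_branches`` criteria closest to dN2 in the tree, ranked by AUC.
    """
    validate_cohort(table, dn2_col=dn2_col, cutoff=cutoff)
    if criteria is None:
        if all(f"{c}_mean" in table.columns for c in CRITERIA):
            criteria = [f"{c}_mean" for c in CRITERIA]
        else:
            criteria = [c for c in CRITERIA if c in table.columns]
    if not criteria:
        raise ValueError("no criterion columns found in cohort table")

    messages: list[str] = []
    dn2 = table[dn2_col].to_numpy(float)
    labels = dn2 > cutoff
    prevalence = float(labels.mean())

    rows = {}
    for c in criteria:
        r = spearman_vs_dn2(table, c, dn2_col=dn2_col)
        rows[c] = {"rho": r.rho, "p_value": r.p_value, "n": r.n, "defined": r.defined}
    spearman_df = pd.DataFrame.from_dict(rows, orient="index")

    dendro: Dendrogram | None = None
    top: list[str] = []
    try:
        dendro = build_dendrogram(table, [dn2_col, *criteria], method=linkage_method)
        top = dendro.closest_to(dn2_col, k=k_branches)
    except ValueError as exc:
        messages.append(f"dendrogram skipped: {exc}")
        # fall back to the strongest absolute correlations
        top = spearman_df["rho"].abs().sort_values(ascending=False).index[:k_branches].tolist()

    roc: dict[str, ROCResult] = {}
    if labels.all() or not labels.any():
        messages.append("ROC skipped: only one obstruction class present")
    else:
        for c in top:
            roc[c] = roc_analysis(table[c].to_numpy(float), labels)
    ranking = sorted(roc, key=lambda c: -roc[c].auc)

    return ComparisonReport(
        n_subjects=len(table),
        prevalence=prevalence,
        spearman=spearman_df,
        dendrogram=dendro,
        top_branches=top,
        roc=roc,
        roc_ranking=ranking,
        messages=messages,
    )
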