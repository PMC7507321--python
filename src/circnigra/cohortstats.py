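"""Cohort-level statistics for circRNA count matrices.

Per-sample totals, two-group comparisons (Welch t / Wilcoxon rank-sum),
Benjamini-Hochberg correction, Pearson correlations (age trends, the
editing / circRNA-abundance anti-correlation), region sharing summaries,
median-of-ratios size factors, a transparent log-scale two-group
differential-expression test, and the cell-type expression-call rule.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .circdetect import CircCountMatrix, normalize_per_million

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# result types
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    feature: str
    group_a: str
    group_b: str
    statistic: float
    p_value: float
    method: str                       # 't' | 'wilcoxon'
    q_value: float = float("nan")
    effect: float = float("nan")
    flag: Optional[str] = None


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int
    method: str = "pearson"
    defined: bool = True


@dataclass
class SharingSummary:
    regions: list[str]
    cells: dict[frozenset, int]       # region combination -> feature count
    n_features: int
    feature_class: str = "circRNA"

    @property
    def unique_counts(self) -> dict[str, int]:
        return {r: self.cells.get(frozenset([r]), 0) for r in self.regions}

    @property
    def shared_all(self) -> int:
        return self.cells.get(frozenset(self.regions), 0)

    @property
    def pairwise_shared(self) -> dict[tuple[str, str], int]:
        """Features expressed in both regions of a pair (any cell containing both)."""
        out = {}
        for a, b in itertools.combinations(self.regions, 2):
            out[(a, b)] = sum(n for combo, n in self.cells.items()
                              if a in combo and b in combo)
        return out

    def fractions(self) -> dict[str, float]:
        tot = max(self.n_features, 1)
        d = {f"unique_{r}": c / tot for r, c in self.unique_counts.items()}
        d["shared_all"] = self.shared_all / tot
        return d


@dataclass
class CellTypeCall:
    gene: str
    expression: dict[str, float]
    called_types: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# totals
# ---------------------------------------------------------------------------

def circ_totals_per_sample(
    matrix: CircCountMatrix,
    mode: str = "distinct",
    normalized: bool = False,
) -> pd.Series:
    """Per-sample circRNA totals.

    mode 'distinct' counts junctions with count > 0; 'reads' sums supporting
    reads.  ``normalized`` divides by mapped reads in millions (per-million
    scale), mirroring normalization to library total reads.
    """
    if matrix.counts.shape[1] == 0:
        raise ValueError("empty matrix")
    if mode == "distinct":
        totals = (matrix.counts > 0).sum(axis=0).astype(float)
    elif mode == "reads":
        totals = matrix.counts.sum(axis=0).astype(float)
    else:
        raise ValueError("mode must be 'distinct' or 'reads'")
    if normalized:
        totals = totals / (matrix.mapped_totals.reindex(totals.index) / 1e6)
    return totals


# ---------------------------------------------------------------------------
# hypothesis tests
# ---------------------------------------------------------------------------

def two_group_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    method: str = "t",
    feature: str = "",
    group_a: str = "a",
    group_b: str = "b",
) -> GroupComparison:
    """Two-sided two-group test: Welch t or Wilcoxon rank-sum.

    The rank-sum test uses the exact small-sample null when min(n) <= 12 and
    there are no ties, otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    flag = None
    if method == "t":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("t-test needs n >= 2 per group")
        if np.var(a) == 0 and np.var(b) == 0:
            stat, p = 0.0, 1.0
            flag = "zero-variance"
        else:
            stat, p = stats.ttest_ind(a, b, equal_var=False)
    elif method == "wilcoxon":
        if len(a) < 1 or len(b) < 1:
            raise ValueError("rank-sum test needs n >= 1 per group")
        ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        use_exact = min(len(a), len(b)) <= 12 and not ties
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided",
            method="exact" if use_exact else "asymptotic")
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError("method must be 't' or 'wilcoxon'")
    return GroupComparison(
        feature=feature, group_a=group_a, group_b=group_b,
        statistic=float(stat), p_value=float(min(p, 1.0)),
        method=method, effect=float(np.mean(a) - np.mean(b)), flag=flag)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pearson_correlation(x: Sequence[float], y: Sequence[float]
                        ) -> CorrelationResult:
    """Sample Pearson correlation with the two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("Pearson p-value needs n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), n, defined=False)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), n)


# ---------------------------------------------------------------------------
# sharing across regions
# ---------------------------------------------------------------------------

def sharing_summary(
    expressed: pd.DataFrame,
    feature_class: str = "circRNA",
) -> SharingSummary:
    """Partition expressed features into region-combination cells.

    ``expressed`` is a boolean feature x region membership table (e.g. the
    ``tissue_expressed`` table produced by the per-tissue read filter for
    circRNAs, or count > 0 for mRNAs).  Regions with no expressed feature
    still count as regions; a feature expressed nowhere is not partitioned.
    """
    if expressed.shape[1] < 2:
        raise ValueError("need >= 2 regions")
    regions = list(expressed.columns)
    cells: dict[frozenset, int] = {}
    n_any = 0
    for _feat, row in expressed.iterrows():
        combo = frozenset(r for r in regions if bool(row[r]))
        if not combo:
            continue
        n_any += 1
        cells[combo] = cells.get(combo, 0) + 1
    return SharingSummary(regions=regions, cells=cells, n_features=n_any,
                          feature_class=feature_class)


def expressed_by_region(
    matrix: CircCountMatrix,
    meta: pd.DataFrame,
    rule: str = "tissue_reads",
    min_reads: int = 5,
    tissue_col: str = "region",
) -> pd.DataFrame:
    """Boolean feature x region table under the chosen expression rule.

    'tissue_reads': summed reads in the region's samples > min_reads (strict,
    the circRNA rule); 'any_count': any sample in the region has count > 0
    (the mRNA rule).
    """
    regions = sorted(meta[tissue_col].unique())
    missing = [r for r in regions
               if not (meta[tissue_col] == r).any()]
    if missing:
        raise ValueError(f"regions without samples: {missing}")
    out = pd.DataFrame(False, index=matrix.counts.index, columns=regions)
    for r in regions:
        cols = [s for s in matrix.counts.columns
                if s in meta.index and meta.at[s, tissue_col] == r]
        if not cols:
            raise ValueError(f"region {r!r} has no samples in the matrix")
        sub = matrix.counts[cols]
        if rule == "tissue_reads":
            out[r] = sub.sum(axis=1) > min_reads
        elif rule == "any_count":
            out[r] = (sub > 0).any(axis=1)
        else:
            raise ValueError("rule must be 'tissue_reads' or 'any_count'")
    return out


# ---------------------------------------------------------------------------
# normalization and differential expression
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the DESeq normalization step).

    factor_j = median over features i of count_ij / geomean_i, restricted to
    features whose geometric mean is positive (no zero in any sample).
    """
    arr = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(arr)
    loggeo = logs.mean(axis=1)
    usable = np.isfinite(loggeo)
    if not usable.any():
        raise ValueError(
            "no feature has nonzero counts in every sample; supply a "
            "pseudo-reference or filter samples first")
    ratios = logs[usable] - loggeo[usable, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def simple_de(
    matrix: CircCountMatrix,
    meta: pd.DataFrame,
    group_col: str = "condition",
    groups: Optional[tuple[str, str]] = None,
    method: str = "t",
    use_size_factors: bool = True,
) -> pd.DataFrame:
    """Transparent two-group differential test on log2(normalized count + 1).

    This is a documented simple replacement for a negative-binomial GLM: the
    counts are scaled by median-of-ratios size factors, log-transformed, and
    compared per feature with :func:`two_group_test`; q-values are BH across
    features and the effect size is the difference of group means of the log
    values.  All-zero features are flagged and excluded from testing.
    """
    samples = [s for s in matrix.counts.columns if s in meta.index]
    labels = meta.loc[samples, group_col]
    if groups is None:
        lv = sorted(labels.unique())
        if len(lv) != 2:
            raise ValueError(f"{group_col} must have exactly 2 levels, got {lv}")
        groups = (lv[0], lv[1])
    ga = [s for s in samples if labels[s] == groups[0]]
    gb = [s for s in samples if labels[s] == groups[1]]
    counts = matrix.counts[ga + gb]
    if use_size_factors:
        sf = size_factors(counts)
        norm = counts / sf
    else:
        norm = counts.astype(float)
    logx = np.log2(norm + 1.0)

    allzero = counts.sum(axis=1) == 0
    if allzero.any():
        logger.info("simple_de: excluding %d all-zero features",
                    int(allzero.sum()))
    tested = logx.loc[~allzero]

    if method == "t":
        A = tested[ga].to_numpy()
        B = tested[gb].to_numpy()
        stat, p = stats.ttest_ind(A, B, axis=1, equal_var=False)
        both_const = (A.var(axis=1) == 0) & (B.var(axis=1) == 0)
        stat = np.where(both_const, 0.0, stat)
        p = np.where(both_const, 1.0, p)
        effect = A.mean(axis=1) - B.mean(axis=1)
    else:
        res = [two_group_test(row[ga], row[gb], method=method)
               for _f, row in tested.iterrows()]
        stat = np.array([r.statistic for r in res])
        p = np.array([r.p_value for r in res])
        effect = np.array([r.effect for r in res])
    q = bh_adjust(p) if len(p) else np.array([])
    out = pd.DataFrame({
        "feature": tested.index,
        "group_a": groups[0],
        "group_b": groups[1],
        "statistic": stat,
        "p_value": p,
        "q_value": q,
        "effect_log2": effect,
        "method": method,
    }).set_index("feature")
    excluded = pd.DataFrame({
        "feature": counts.index[allzero],
    }).set_index("feature")
    out.attrs["excluded_all_zero"] = list(excluded.index)
    return out


# ---------------------------------------------------------------------------
# cell-type expression calls
# ---------------------------------------------------------------------------

def celltype_call(
    expression: dict[str, float],
    gene: str = "",
    fold: float = 10.0,
    sd_mult: float = 5.0,
    include_self: bool = False,
    combined: bool = False,
) -> CellTypeCall:
    """Cell-type expression calls from per-cell-type expression values.

    Default (leave-one-out conjunction): a gene is expressed in cell type c
    iff expr_c >= fold * mean(others) AND expr_c >= mean(others) +
    sd_mult * sd(others).  ``include_self`` computes mean/sd over all types;
    ``combined`` uses the single condition expr_c >= fold * (mean + sd_mult*sd).
    """
    if len(expression) < 2:
        raise ValueError("need >= 2 cell types")
    if any(v < 0 for v in expression.values()):
        raise ValueError("expression must be nonnegative")
    types = list(expression)
    called = []
    vals = np.array([expression[t] for t in types], dtype=float)
    for i, t in enumerate(types):
        ref = vals if include_self else np.delete(vals, i)
        mu = float(ref.mean())
        sd = float(ref.std(ddof=1)) if len(ref) > 1 else 0.0
        x = vals[i]
        if x == 0:
            continue
        if combined:
            ok = x >= fold * (mu + sd_mult * sd)
        else:
            ok = (x >= fold * mu) and (x >= mu + sd_mult * sd)
        if ok:
            called.append(t)
    return CellTypeCall(gene=gene, expression=dict(expression),
                        called_types=called)
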