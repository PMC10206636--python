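"""Agreement and comparison statistics for paired VDP measurements.

Bland–Altman agreement (bias and 95% limits of agreement), Spearman/Pearson
correlation with an exact permutation p-value at small n, a normality-gated
paired comparison (paired t vs Wilcoxon signed-rank), and a normality-gated
group comparison (one-way ANOVA + Tukey vs Kruskal–Wallis + Dunn).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: Normal deviate for 95% limits of agreement.
LOA_MULTIPLIER = 1.96

#: Shapiro–Wilk significance level for the parametric/non-parametric gate.
NORMALITY_ALPHA = 0.05

#: Largest n for which correlation p-values use exact permutation enumeration.
EXACT_PERM_MAX_N = 10


@dataclass
class AgreementResult:
    """Bland–Altman bias and 95% limits of agreement of paired differences."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int
    convention: str  # which series is subtracted from which, e.g. "y - x"

    def __post_init__(self) -> None:
        lo = self.bias - LOA_MULTIPLIER * self.sd_diff
        hi = self.bias + LOA_MULTIPLIER * self.sd_diff
        if abs(self.loa_low - lo) > 1e-9 or abs(self.loa_high - hi) > 1e-9:
            raise ValueError("limits of agreement inconsistent with bias +/- 1.96 sd")


@dataclass
class CorrelationResult:
    coefficient: float
    p_value: float
    method: str  # "spearman" | "pearson"
    n: int

    def __post_init__(self) -> None:
        if abs(self.coefficient) > 1 + 1e-12:
            raise ValueError(f"|coefficient| > 1: {self.coefficient}")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


@dataclass
class PairedCompareResult:
    p_value: float
    test: str  # "paired_t" | "wilcoxon" | "degenerate"
    statistic: float = float("nan")
    shapiro_p: float = float("nan")


@dataclass
class GroupCompareResult:
    omnibus_p: float
    pairwise_p: dict  # (group_a, group_b) -> adjusted p
    test: str  # "anova_tukey" | "kruskal_dunn" | "degenerate"
    shapiro_p: float = float("nan")


def _as_paired(x, y, min_n: int):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"paired samples differ in length: {x.size} vs {y.size}")
    if x.size < min_n:
        raise ValueError(f"need n >= {min_n} pairs, got {x.size}")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("missing or non-finite values in paired samples")
    return x, y


def bland_altman(x, y, convention: str = "y - x") -> AgreementResult:
    """Bland–Altman agreement of two paired series.

    Differences are ``d_i = y_i - x_i`` (the default convention; pass the
    series so that y is the one expected to read lower if you want the bias
    sign to match that expectation). bias = mean(d); sd with n-1; limits of
    agreement = bias +/- 1.96 sd.
    """
    x, y = _as_paired(x, y, min_n=2)
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - LOA_MULTIPLIER * sd,
        loa_high=bias + LOA_MULTIPLIER * sd,
        n=int(d.size),
        convention=convention,
    )


def _perm_pvalue_exact(xr: np.ndarray, yr: np.ndarray, observed: float) -> float:
    """Two-sided exact permutation p for a correlation of (possibly ranked) data.

    Enumerates all n! permutations of y against fixed x, in chunks. Exact and
    conditional on the observed tie pattern.
    """
    n = xr.size
    xc = xr - xr.mean()
    denom_x = np.sqrt((xc ** 2).sum())
    yc = yr - yr.mean()
    denom_y = np.sqrt((yc ** 2).sum())
    count = 0
    total = 0
    chunk = []
    chunk_size = 200_000
    thresh = abs(observed) - 1e-12

    def flush(chunk_arr):
        nonlocal count, total
        perm = yc[chunk_arr]  # (m, n) permuted centered y
        r = perm @ xc / (denom_x * denom_y)
        count += int(np.sum(np.abs(r) >= thresh))
        total += len(chunk_arr)

    for p in itertools.permutations(range(n)):
        chunk.append(p)
        if len(chunk) == chunk_size:
            flush(np.array(chunk))
            chunk = []
    if chunk:
        flush(np.array(chunk))
    return count / total


def correlate(x, y, method: str = "spearman") -> CorrelationResult:
    """Correlation of two samples with an exact small-n permutation p-value.

    Spearman is Pearson on average-ranked data (ties get average ranks). The
    p-value is by exact permutation for n <= 10 and by the t-approximation
    otherwise.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"method must be 'spearman' or 'pearson', got {method!r}")
    x, y = _as_paired(x, y, min_n=3)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a series: correlation undefined")
    if method == "spearman":
        xr = stats.rankdata(x)  # average ranks on ties
        yr = stats.rankdata(y)
    else:
        xr, yr = x, y
    coeff = float(stats.pearsonr(xr, yr).statistic)
    n = x.size
    if n <= EXACT_PERM_MAX_N:
        p = _perm_pvalue_exact(xr, yr, coeff)
    else:
        # t-approximation: t = r sqrt((n-2)/(1-r^2))
        r2 = min(coeff ** 2, 1.0)
        if r2 >= 1.0:
            p = 0.0
        else:
            t = coeff * math.sqrt((n - 2) / (1.0 - r2))
            p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return CorrelationResult(coefficient=coeff, p_value=float(min(p, 1.0)),
                             method=method, n=int(n))


def paired_compare(x, y) -> PairedCompareResult:
    """Normality-gated paired comparison.

    Shapiro–Wilk on the paired differences selects a paired t-test (normal)
    or a Wilcoxon signed-rank test (zero differences dropped, tie-corrected
    normal approximation). All-zero differences return p = 1 with the
    "degenerate" label. Constant nonzero differences cannot be gated (the
    Shapiro test is undefined on a constant sample) and raise.
    """
    x, y = _as_paired(x, y, min_n=5)
    d = y - x
    if np.all(d == 0):
        return PairedCompareResult(p_value=1.0, test="degenerate", statistic=0.0)
    if np.ptp(d) == 0:
        raise ValueError(
            "constant nonzero differences: normality gate undefined on a "
            "zero-variance sample"
        )
    sw = stats.shapiro(d)
    if sw.pvalue >= NORMALITY_ALPHA:
        res = stats.ttest_rel(x, y)
        return PairedCompareResult(
            p_value=float(res.pvalue), test="paired_t",
            statistic=float(res.statistic), shapiro_p=float(sw.pvalue),
        )
    dd = d[d != 0]
    res = stats.wilcoxon(dd, zero_method="wilcox", correction=False, method="approx")
    logger.info("paired_compare: non-normal differences (Shapiro p=%.3g), "
                "Wilcoxon signed-rank used", sw.pvalue)
    return PairedCompareResult(
        p_value=float(res.pvalue), test="wilcoxon",
        statistic=float(res.statistic), shapiro_p=float(sw.pvalue),
    )


def _dunn_pairwise(values: list[np.ndarray], names: list[str]) -> dict:
    """Dunn's post-hoc rank z-tests with tie correction, Bonferroni-adjusted."""
    all_vals = np.concatenate(values)
    ranks = stats.rankdata(all_vals)
    n_total = all_vals.size
    # tie correction term
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts))
    groups_ranks = []
    start = 0
    for v in values:
        groups_ranks.append(ranks[start:start + v.size])
        start += v.size
    mean_ranks = [g.mean() for g in groups_ranks]
    sizes = [g.size for g in groups_ranks]
    m = len(values) * (len(values) - 1) // 2
    out = {}
    for (i, j) in itertools.combinations(range(len(values)), 2):
        var = (n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))) \
            * (1.0 / sizes[i] + 1.0 / sizes[j])
        if var <= 0:
            p = 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(var)
            p = min(1.0, 2.0 * stats.norm.sf(abs(z)) * m)  # Bonferroni
        out[(names[i], names[j])] = float(p)
    return out


def group_compare(values, groups) -> GroupCompareResult:
    """Normality-gated multi-group comparison.

    Shapiro–Wilk on the pooled within-group residuals selects one-way ANOVA
    with Tukey's HSD (normal) or Kruskal–Wallis with Dunn's Bonferroni-adjusted
    pairwise tests. All-identical data short-circuit to the degenerate branch
    with omnibus p = 1.
    """
    values = np.asarray(values, dtype=float).ravel()
    groups = np.asarray(groups).ravel()
    if values.size != groups.size:
        raise ValueError("values and groups differ in length")
    names = [str(g) for g in dict.fromkeys(groups)]  # preserve first-seen order
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    by_group = [values[groups == g] for g in dict.fromkeys(groups)]
    for name, v in zip(names, by_group):
        if v.size < 3:
            raise ValueError(f"group {name!r} has {v.size} members; minimum is 3")

    if np.ptp(values) == 0:
        # all-tied ranks: no evidence of any difference
        pw = {pair: 1.0 for pair in itertools.combinations(names, 2)}
        return GroupCompareResult(omnibus_p=1.0, pairwise_p=pw, test="degenerate")

    residuals = np.concatenate([v - v.mean() for v in by_group])
    if np.ptp(residuals) == 0:
        sw_p = float("nan")
        normal = False  # constant residuals: gate undefined, use rank branch
    else:
        sw_p = float(stats.shapiro(residuals).pvalue)
        normal = sw_p >= NORMALITY_ALPHA

    if normal:
        omnibus = float(stats.f_oneway(*by_group).pvalue)
        tk = stats.tukey_hsd(*by_group)
        pw = {
            (names[i], names[j]): float(tk.pvalue[i, j])
            for (i, j) in itertools.combinations(range(len(names)), 2)
        }
        return GroupCompareResult(omnibus_p=omnibus, pairwise_p=pw,
                                  test="anova_tukey", shapiro_p=sw_p)
    try:
        omnibus = float(stats.kruskal(*by_group).pvalue)
    except ValueError:
        omnibus = 1.0  # all numbers identical within the test's tolerance
    pw = _dunn_pairwise(by_group, names)
    return GroupCompareResult(omnibus_p=omnibus, pairwise_p=pw,
                              test="kruskal_dunn", shapiro_p=sw_p)
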