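"""Statistical evaluation of comparative Monte Carlo results.

The testing ladder mirrors comparative footprinting practice: check the
per-run differences for normality; for two alternatives test the median
difference with the one-sample Wilcoxon signed-rank test (or the paired t
when normality holds); for three or more use the Friedman test with MC runs
as blocks, or a two-way ANOVA with a run block, followed by post-hoc
pairwise testing and grouping into clusters of mutually indistinguishable
alternatives (the basis for rank / traffic-light labels).

Interval summaries are distribution-free: the median confidence interval is
an order-statistic interval from binomial(n, 1/2) quantiles (conservative —
coverage at least the nominal level).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.libqsturng import psturng
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClusterAssignment",
    "ComparisonReport",
    "DegenerateStatisticsError",
    "friedman",
    "median_ci",
    "normality_check",
    "paired_t",
    "percentile_summary",
    "posthoc_cluster",
    "wilcoxon_signed_rank",
]

CLUSTER_LABELS = ("green", "yellow", "red")


class DegenerateStatisticsError(ValueError):
    """The data admit no meaningful test (e.g. all differences zero)."""


@dataclass
class ComparisonReport:
    """Outcome of one paired comparison."""

    test_name: str
    null_hypothesis: str
    statistic: float
    p_value: float
    median_difference: float
    ci_low: float
    ci_high: float
    ci_level: float
    alpha: float
    reject: bool
    n: int
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if not self.ci_low <= self.median_difference <= self.ci_high:
            raise ValueError("median outside its confidence interval")

    def to_dict(self) -> dict:
        return {
            "test": self.test_name,
            "null_hypothesis": self.null_hypothesis,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "median_difference": self.median_difference,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_level": self.ci_level,
            "alpha": self.alpha,
            "reject": self.reject,
            "n": self.n,
            **self.extra,
        }


@dataclass
class ClusterAssignment:
    """Alternatives grouped into clusters of indistinguishable footprints.

    Rank 1 is the cluster with the smallest median footprint; labels map
    ranks onto a traffic-light palette (green / yellow / red, with red
    reused beyond three clusters).
    """

    ranks: dict[str, int]
    labels: dict[str, str]
    omnibus_test: str
    omnibus_statistic: float
    omnibus_p: float
    pairwise_p: dict[tuple[str, str], float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "ranks": dict(self.ranks),
            "labels": dict(self.labels),
            "omnibus_test": self.omnibus_test,
            "omnibus_statistic": self.omnibus_statistic,
            "omnibus_p": self.omnibus_p,
            "pairwise_p": {f"{a}|{b}": p for (a, b), p in self.pairwise_p.items()},
        }


# ---------------------------------------------------------------------------
# univariate summaries
# ---------------------------------------------------------------------------


def normality_check(diffs, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Shapiro-Wilk test on the differences; gate for the parametric path."""
    d = np.asarray(diffs, dtype=float)
    if len(d) < 8:
        raise ValueError(
            f"normality check needs n >= 8 (got {len(d)}); "
            "use the nonparametric path instead"
        )
    stat, p = sps.shapiro(d)
    return float(stat), float(p), bool(p > alpha)


def percentile_summary(values) -> dict[str, float]:
    """Box-plot percentiles (10/25/50/75/90) with linear interpolation."""
    x = np.asarray(values, dtype=float)
    if len(x) < 10:
        raise ValueError(f"percentile summary needs n >= 10 (got {len(x)})")
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    return {
        "p10": float(p10),
        "p25": float(p25),
        "median": float(p50),
        "p75": float(p75),
        "p90": float(p90),
    }


def _median_ci_ranks(n: int, level: float) -> tuple[int, int]:
    """1-indexed order-statistic ranks for a conservative median CI."""
    alpha2 = (1.0 - level) / 2.0
    # largest m with P(X <= m-1) <= alpha/2, X ~ binomial(n, 1/2)
    m = int(sps.binom.ppf(alpha2, n, 0.5))
    while m >= 1 and sps.binom.cdf(m - 1, n, 0.5) > alpha2:
        m -= 1
    while sps.binom.cdf(m, n, 0.5) <= alpha2:
        m += 1
    if m < 1:
        raise ValueError(
            f"n = {n} is too small for a {level:.0%} order-statistic median CI"
        )
    return m, n + 1 - m


def median_ci(diffs, level: float = 0.95) -> tuple[float, float, float]:
    """Distribution-free median confidence interval by order statistics.

    The interval is spanned by the order statistics at the binomial(n, 1/2)
    quantiles of (1-level)/2 and 1-(1-level)/2; coverage is at least
    ``level`` for any continuous distribution.
    """
    x = np.sort(np.asarray(diffs, dtype=float))
    n = len(x)
    if n < 6:
        raise ValueError(f"median CI needs n >= 6 (got {n})")
    lo, hi = _median_ci_ranks(n, level)
    return float(np.median(x)), float(x[lo - 1]), float(x[hi - 1])


# ---------------------------------------------------------------------------
# paired two-alternative tests
# ---------------------------------------------------------------------------


def _signed_rank_statistic(d: np.ndarray) -> tuple[float, np.ndarray]:
    ranks = sps.rankdata(np.abs(d))
    return float(ranks[d > 0].sum()), ranks


def _exact_signed_rank_p(
    ranks: np.ndarray, w_plus: float, alternative: str
) -> float:
    """Exact null distribution of W+ over all 2^n sign assignments.

    Computed with the generating-polynomial dynamic program over doubled
    midranks (integers), equivalent to full sign enumeration.
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    denom = 2.0 ** len(ranks)
    w2 = int(round(2.0 * w_plus))
    p_le = counts[: w2 + 1].sum() / denom
    p_ge = counts[w2:].sum() / denom
    if alternative == "greater":
        return min(1.0, p_ge)
    if alternative == "less":
        return min(1.0, p_le)
    return min(1.0, 2.0 * min(p_le, p_ge))


def _approx_signed_rank_p(
    d: np.ndarray, w_plus: float, alternative: str
) -> float:
    """Normal approximation with tie and continuity corrections."""
    n = len(d)
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    dev = w_plus - mu
    if alternative == "greater":
        return float(sps.norm.sf((dev - 0.5) / sigma))
    if alternative == "less":
        return float(sps.norm.cdf((dev + 0.5) / sigma))
    if dev == 0.0:
        return 1.0
    z = (abs(dev) - 0.5) / sigma
    return float(min(1.0, 2.0 * sps.norm.sf(z)))


def wilcoxon_signed_rank(
    diffs,
    mu0: float = 0.0,
    alternative: str = "two-sided",
    alpha: float = 0.05,
    ci_level: float = 0.95,
    zero_method: str = "drop",
    exact_max_n: int = 25,
) -> ComparisonReport:
    """One-sample Wilcoxon signed-rank test of the median difference.

    Zero differences are dropped (classical; ``zero_method='pratt'`` keeps
    them in the ranking).  The exact null distribution over all 2^n sign
    assignments is used for n <= 25, the normal approximation with tie and
    continuity corrections otherwise.  The reported interval is the
    order-statistic median CI of the raw differences.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if zero_method not in ("drop", "pratt"):
        raise ValueError(f"unknown zero_method {zero_method!r}")
    x = np.asarray(diffs, dtype=float)
    d = x - mu0
    if np.all(d == 0.0):
        raise DegenerateStatisticsError(
            "all differences equal the null value; the alternatives are "
            "indistinguishable by construction"
        )
    if zero_method == "drop":
        d = d[d != 0.0]
        if len(d) < 5:
            raise ValueError(
                f"Wilcoxon needs n >= 5 nonzero differences (got {len(d)})"
            )
        w_plus, ranks = _signed_rank_statistic(d)
        eff = d
    else:  # pratt: rank zeros, drop them from the statistic
        ranks_all = sps.rankdata(np.abs(d))
        nz = d != 0.0
        if nz.sum() < 5:
            raise ValueError("Wilcoxon needs n >= 5 nonzero differences")
        w_plus = float(ranks_all[d > 0].sum())
        ranks = ranks_all[nz]
        eff = d[nz]
    if len(eff) <= exact_max_n and zero_method == "drop":
        p = _exact_signed_rank_p(ranks, w_plus, alternative)
        method = "exact"
    else:
        p = _approx_signed_rank_p(eff, w_plus, alternative)
        method = "normal-approximation"
    try:
        med, lo, hi = median_ci(x, ci_level)
    except ValueError:
        # n too small for the requested level: widest order-statistic bounds
        med = float(np.median(x))
        lo, hi = float(np.min(x)), float(np.max(x))
    return ComparisonReport(
        test_name="wilcoxon_signed_rank",
        null_hypothesis=f"median difference = {mu0}",
        statistic=w_plus,
        p_value=p,
        median_difference=med,
        ci_low=lo,
        ci_high=hi,
        ci_level=ci_level,
        alpha=alpha,
        reject=bool(p < alpha),
        n=len(eff),
        extra={"method": method, "alternative": alternative},
    )


def paired_t(
    diffs,
    mu0: float = 0.0,
    alternative: str = "two-sided",
    alpha: float = 0.05,
    ci_level: float = 0.95,
) -> ComparisonReport:
    """Classical one-sample t-test on the differences."""
    x = np.asarray(diffs, dtype=float)
    if len(x) < 2:
        raise ValueError("paired t needs n >= 2")
    if np.var(x) == 0.0:
        raise DegenerateStatisticsError("zero variance in the differences")
    alt = {"two-sided": "two-sided", "greater": "greater", "less": "less"}[alternative]
    res = sps.ttest_1samp(x, mu0, alternative=alt)
    try:
        med, lo, hi = median_ci(x, ci_level)
    except ValueError:
        med = float(np.median(x))
        lo = hi = med
    return ComparisonReport(
        test_name="paired_t",
        null_hypothesis=f"mean difference = {mu0}",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_difference=med,
        ci_low=min(lo, med),
        ci_high=max(hi, med),
        ci_level=ci_level,
        alpha=alpha,
        reject=bool(res.pvalue < alpha),
        n=len(x),
        extra={"mean_difference": float(np.mean(x)), "alternative": alternative},
    )


# ---------------------------------------------------------------------------
# multi-alternative path
# ---------------------------------------------------------------------------


def friedman(results) -> tuple[float, float]:
    """Friedman rank test with MC runs as blocks, tie-corrected.

    Within-run midranks; the chi-square statistic uses the general
    tie-corrected form, so identical columns give statistic 0 and p 1.
    """
    m = np.asarray(results, dtype=float)
    if m.ndim != 2:
        raise ValueError("results must be a runs x alternatives matrix")
    n, k = m.shape
    if k < 3:
        raise ValueError(
            "the Friedman test needs >= 3 alternatives; for 2 use "
            "wilcoxon_signed_rank on the per-run differences"
        )
    if n < 10:
        raise ValueError(f"Friedman needs >= 10 runs (got {n})")
    ranks = np.apply_along_axis(sps.rankdata, 1, m)
    col_sums = ranks.sum(axis=0)
    a = float((ranks**2).sum())
    correction = n * k * (k + 1) ** 2 / 4.0
    denom = a - correction
    if denom <= 0.0:
        return 0.0, 1.0
    statistic = (k - 1) * float(((col_sums - n * (k + 1) / 2.0) ** 2).sum()) / denom
    p = float(sps.chi2.sf(statistic, k - 1))
    return float(statistic), p


def _blocked_anova(m: np.ndarray) -> tuple[float, float, float, int]:
    """Two-way ANOVA (alternative + run block, no replication).

    Returns (F, p, MSE, residual df) for the alternative effect.
    """
    n, k = m.shape
    grand = m.mean()
    ss_treat = n * float(((m.mean(axis=0) - grand) ** 2).sum())
    ss_block = k * float(((m.mean(axis=1) - grand) ** 2).sum())
    ss_total = float(((m - grand) ** 2).sum())
    ss_resid = max(ss_total - ss_treat - ss_block, 0.0)
    df_treat = k - 1
    df_resid = (k - 1) * (n - 1)
    mse = ss_resid / df_resid
    if mse == 0.0:
        return (np.inf if ss_treat > 0 else 0.0), (0.0 if ss_treat > 0 else 1.0), 0.0, df_resid
    f = (ss_treat / df_treat) / mse
    return float(f), float(sps.f.sf(f, df_treat, df_resid)), mse, df_resid


def _greedy_clusters(
    order: list[str], distinguished: set[frozenset[str]]
) -> dict[str, int]:
    """Partition median-ordered alternatives into contiguous clusters whose
    members are pairwise non-distinguished."""
    ranks: dict[str, int] = {}
    current: list[str] = []
    rank = 0
    for alt in order:
        if current and any(
            frozenset((alt, member)) in distinguished for member in current
        ):
            rank += 1
            current = []
        elif not current:
            rank += 1
        current.append(alt)
        ranks[alt] = rank
    return ranks


def posthoc_cluster(
    results,
    alternative_ids: list[str],
    method: str = "nonparametric",
    alpha: float = 0.05,
) -> ClusterAssignment:
    """Omnibus test plus post-hoc pairwise grouping into clusters.

    ``nonparametric``: Friedman omnibus, then all pairwise Wilcoxon
    signed-rank tests with Holm correction.  ``parametric``: two-way ANOVA
    with the run as a block, then Tukey HSD on the blocked mean square
    error.  A non-significant omnibus yields a single cluster.  Clusters
    are ordered by median footprint (rank 1 = smallest).
    """
    m = np.asarray(results, dtype=float)
    if m.shape[1] != len(alternative_ids):
        raise ValueError("alternative_ids must match result columns")
    if method not in ("nonparametric", "parametric"):
        raise ValueError(f"unknown post-hoc method {method!r}")
    medians = {a: float(np.median(m[:, i])) for i, a in enumerate(alternative_ids)}
    order = sorted(alternative_ids, key=lambda a: (medians[a], a))

    if method == "nonparametric":
        omnibus_name = "friedman"
        omni_stat, omni_p = friedman(m)
    else:
        omnibus_name = "two-way-anova"
        omni_stat, omni_p, mse, df_resid = _blocked_anova(m)

    pairs = list(combinations(range(len(alternative_ids)), 2))
    pairwise_p: dict[tuple[str, str], float] = {}
    distinguished: set[frozenset[str]] = set()
    if omni_p < alpha:
        if method == "nonparametric":
            raw = []
            for i, j in pairs:
                d = m[:, i] - m[:, j]
                try:
                    rep = wilcoxon_signed_rank(d, alpha=alpha)
                    raw.append(rep.p_value)
                except DegenerateStatisticsError:
                    raw.append(1.0)
            reject, corrected, _, _ = multipletests(raw, alpha=alpha, method="holm")
            for (i, j), p, rej in zip(pairs, corrected, reject):
                key = (alternative_ids[i], alternative_ids[j])
                pairwise_p[key] = float(p)
                if rej:
                    distinguished.add(frozenset(key))
        else:
            n = m.shape[0]
            k = m.shape[1]
            means = m.mean(axis=0)
            se = np.sqrt(mse / n)
            for i, j in pairs:
                key = (alternative_ids[i], alternative_ids[j])
                if se == 0.0:
                    p = 0.0 if means[i] != means[j] else 1.0
                else:
                    q = abs(means[i] - means[j]) / se
                    p = float(np.atleast_1d(psturng(q, k, df_resid))[0])
                pairwise_p[key] = p
                if p < alpha:
                    distinguished.add(frozenset(key))

    ranks = _greedy_clusters(order, distinguished)
    labels = {
        a: CLUSTER_LABELS[min(r - 1, len(CLUSTER_LABELS) - 1)]
        for a, r in ranks.items()
    }
    return ClusterAssignment(
        ranks=ranks,
        labels=labels,
        omnibus_test=omnibus_name,
        omnibus_statistic=omni_stat,
        omnibus_p=omni_p,
        pairwise_p=pairwise_p,
    )
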