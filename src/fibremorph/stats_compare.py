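"""Group summaries and two-sample comparisons for fibre metrics.

Both the exact Mann-Whitney U test (the headline test: it is what the
published figure legends describe) and the equal-variance Student's t
are always computed, because study methods sections and figure legends
commonly disagree on which was used — the discrepancy is surfaced, not
resolved. Percent differences are reported in both conventions
(100·ratio and 100·(ratio − 1)) since "X% thicker" is ambiguous between
them. No multiple-testing correction is applied.

Note the small-sample limit: with n = 3 per group the exact two-sided
Mann-Whitney p cannot fall below 2/C(6,3) = 0.1, so no comparison at
n = 3 can be starred at the 0.05 level by an exact U test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

from fibremorph.volume_io import METRIC_FIELDS, MetricsRecord

#: Exact enumeration is used up to this pooled sample size; above it the
#: normal approximation with tie correction takes over.
EXACT_ENUMERATION_LIMIT = 12

SIGNIFICANCE_LEVELS = (0.05, 0.01, 0.005)


def _rankdata_mid(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _u_from_ranks(ranks_a: np.ndarray, n_a: int, n_b: int) -> float:
    r_a = float(ranks_a.sum())
    return r_a - n_a * (n_a + 1) / 2.0


def mann_whitney_exact(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U with an exact permutation p-value for small samples.

    U is computed from rank sums with midranks for ties. For pooled
    sample sizes up to 12 the p-value enumerates all C(n_a+n_b, n_a)
    group assignments of the observed (possibly tied) ranks; larger
    samples use the normal approximation with tie correction. Returns
    (U of group a, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([a, b])
    ranks = _rankdata_mid(pooled)
    u_a = _u_from_ranks(ranks[:n_a], n_a, n_b)

    n = n_a + n_b
    if n <= EXACT_ENUMERATION_LIMIT:
        mu = n_a * n_b / 2.0
        obs_dev = u_a - mu
        count_ge = count_le = count_two = 0
        total = 0
        idx_all = range(n)
        for comb in combinations(idx_all, n_a):
            u = float(ranks[list(comb)].sum()) - n_a * (n_a + 1) / 2.0
            total += 1
            if u >= u_a - 1e-12:
                count_ge += 1
            if u <= u_a + 1e-12:
                count_le += 1
            if abs(u - mu) >= abs(obs_dev) - 1e-12:
                count_two += 1
        if alternative == "greater":
            p = count_ge / total
        elif alternative == "less":
            p = count_le / total
        else:
            p = min(count_two / total, 1.0)
        return u_a, p

    # normal approximation with tie correction
    mu = n_a * n_b / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return u_a, 1.0
    z = (u_a - mu) / math.sqrt(sigma2)
    if alternative == "greater":
        p = sps.norm.sf(z)
    elif alternative == "less":
        p = sps.norm.cdf(z)
    else:
        p = 2 * sps.norm.sf(abs(z))
    return u_a, float(min(p, 1.0))


def students_t(a, b) -> tuple[float, float]:
    """Equal-variance two-sample Student's t with df = n_a + n_b − 2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 observations")
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2)
    if sp2 <= 0:
        raise ValueError("zero pooled variance")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def percent_difference(reference_mean: float, comparison_mean: float) -> tuple[float, float]:
    """Both percent conventions for mean_B relative to mean_A.

    Returns (percent_ratio, percent_change) = (100·B/A, 100·(B/A − 1));
    e.g. reference 10, comparison 16.5 → (165%, +65%).
    """
    if reference_mean == 0:
        raise ValueError("reference mean is zero")
    ratio = comparison_mean / reference_mean
    return 100.0 * ratio, 100.0 * (ratio - 1.0)


def stars(p: float, levels=SIGNIFICANCE_LEVELS) -> str:
    """Star annotation: one star per threshold crossed (0.05, 0.01, 0.005)."""
    return "*" * sum(p < lv for lv in sorted(levels, reverse=True))


@dataclass
class GroupComparison:
    """Two-group comparison of one metric."""

    metric: str
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    u_statistic: float
    p_mannwhitney: float
    t_statistic: float | None
    p_ttest: float | None
    percent_ratio: float | None
    percent_change: float | None
    stars: str = ""
    values_a: list[float] = field(default_factory=list)
    values_b: list[float] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if not k.startswith("values")}
        return d


def compare_groups(
    records: list[MetricsRecord],
    group_a: str,
    group_b: str,
    metrics: tuple[str, ...] = METRIC_FIELDS,
    levels=SIGNIFICANCE_LEVELS,
) -> list[GroupComparison]:
    """Compare two groups of analysed fields metric by metric.

    Group means are reported as mean ± SD; significance is annotated by
    the exact Mann-Whitney p at the given thresholds. Records with a
    metric absent are excluded from that metric only.
    """
    out = []
    for metric in metrics:
        va = [getattr(r, metric) for r in records if r.group == group_a]
        vb = [getattr(r, metric) for r in records if r.group == group_b]
        va = [v for v in va if v is not None]
        vb = [v for v in vb if v is not None]
        if not va and not vb:
            raise ValueError(f"metric {metric!r} absent from all records")
        if not va or not vb:
            continue
        a = np.asarray(va, dtype=float)
        b = np.asarray(vb, dtype=float)
        u, p_mwu = mann_whitney_exact(a, b)
        try:
            t, p_t = students_t(a, b)
        except ValueError:
            t, p_t = None, None
        try:
            pr, pc = percent_difference(float(a.mean()), float(b.mean()))
        except ValueError:
            pr, pc = None, None
        out.append(
            GroupComparison(
                metric=metric,
                group_a=group_a,
                group_b=group_b,
                mean_a=float(a.mean()),
                mean_b=float(b.mean()),
                sd_a=float(a.std(ddof=1)) if len(a) > 1 else 0.0,
                sd_b=float(b.std(ddof=1)) if len(b) > 1 else 0.0,
                n_a=len(a),
                n_b=len(b),
                u_statistic=u,
                p_mannwhitney=p_mwu,
                t_statistic=t,
                p_ttest=p_t,
                percent_ratio=pr,
                percent_change=pc,
                stars=stars(p_mwu, levels),
                values_a=list(map(float, a)),
                values_b=list(map(float, b)),
            )
        )
    return out
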