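"""Nonparametric comparison of exposure levels across site categories.

Concentrations (and hence exposures — the dose map is strictly monotone
in concentration, so rank tests give identical decisions on either scale)
are compared pairwise between site categories with the two-sided
Mann–Whitney U test. Rural and uncategorized sites are excluded by
default, mirroring their small sample sizes in compiled datasets.

The exact null distribution of U is used whenever ``n_a · n_b ≤ 400`` and
the pooled data have no ties, computed by the shift-algorithm recursion
over rank-sum counts; otherwise the tie-corrected normal approximation
(scipy) is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from soilrisk.dataset_io import ConcentrationRecord
from soilrisk.errors import DomainError
from soilrisk.exposure import ExposureScenario, average_daily_dose

DEFAULT_TEST_CATEGORIES = ("urban", "suburban", "industrial", "agricultural")


@dataclass(frozen=True)
class PairwiseComparison:
    """Result of one two-sided Mann–Whitney comparison.

    ``u_statistic`` is U for group a (number of (a, b) pairs with a > b,
    ties counted half). ``direction`` names the stochastically larger
    group when the null is rejected, else None.
    """

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    alpha: float
    reject: bool
    direction: str | None
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise DomainError("p-value outside [0, 1]")
        if not 0.0 <= self.u_statistic <= self.n_a * self.n_b:
            raise DomainError("U outside [0, n_a·n_b]")


def _exact_u_counts(n_a: int, n_b: int) -> np.ndarray:
    """Number of rank arrangements giving each U value, U = 0..n_a·n_b.

    Shift-algorithm recurrence on the largest pooled value: if it comes
    from group a it beats all n b-values (U gains n), otherwise it beats
    none, so N(u; m, n) = N(u−n; m−1, n) + N(u; m, n−1). Total mass is
    C(n_a + n_b, n_a).
    """
    max_u = n_a * n_b
    dp = np.zeros((n_a + 1, n_b + 1, max_u + 1), dtype=float)
    dp[0, :, 0] = 1.0
    dp[:, 0, 0] = 1.0
    for m in range(1, n_a + 1):
        for n in range(1, n_b + 1):
            dp[m, n, :] = dp[m, n - 1, :]
            dp[m, n, n:] += dp[m - 1, n, : max_u + 1 - n]
    return dp[n_a, n_b]


def exact_mann_whitney_p(u: float, n_a: int, n_b: int) -> float:
    """Two-sided exact p-value: 2·min(P(U ≤ u), P(U ≥ u)), capped at 1."""
    counts = _exact_u_counts(n_a, n_b)
    total = counts.sum()
    k = int(round(u))
    lower = counts[: k + 1].sum() / total
    upper = counts[k:].sum() / total
    return min(1.0, 2.0 * min(lower, upper))


def mann_whitney(
    a: Iterable[float],
    b: Iterable[float],
    alpha: float = 0.05,
    group_a: str = "a",
    group_b: str = "b",
) -> PairwiseComparison:
    """Two-sided Mann–Whitney U comparison of two samples.

    Requires at least 3 observations per group. Identical constant samples
    give p = 1 (no evidence of a difference). Direction is reported post
    hoc from the rank sums only when the null is rejected.
    """
    x = np.asarray(list(a), dtype=float)
    y = np.asarray(list(b), dtype=float)
    n_a, n_b = x.size, y.size
    if n_a < 3 or n_b < 3:
        raise DomainError(
            f"each group needs >= 3 values, got {n_a} and {n_b}"
        )

    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size

    # U for group a, ties counted half
    greater = (x[:, None] > y[None, :]).sum()
    equal = (x[:, None] == y[None, :]).sum()
    u_a = float(greater) + 0.5 * float(equal)

    if np.ptp(pooled) == 0:
        # all values identical in both groups: no information
        return PairwiseComparison(
            group_a=group_a, group_b=group_b, n_a=n_a, n_b=n_b,
            u_statistic=u_a, p_value=1.0, alpha=alpha,
            reject=False, direction=None, method="degenerate",
        )

    if not has_ties and n_a * n_b <= 400:
        p = exact_mann_whitney_p(u_a, n_a, n_b)
        method = "exact"
    else:
        p = float(
            stats.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic").pvalue
        )
        method = "asymptotic"

    reject = p < alpha
    direction = None
    if reject:
        direction = group_a if u_a > n_a * n_b / 2 else group_b
    return PairwiseComparison(
        group_a=group_a, group_b=group_b, n_a=n_a, n_b=n_b,
        u_statistic=u_a, p_value=p, alpha=alpha,
        reject=reject, direction=direction, method=method,
    )


def holm_adjust(comparisons: Sequence[PairwiseComparison]) -> list[PairwiseComparison]:
    """Holm step-down adjustment over a family of comparisons (optional;
    the default analysis reports per-pair α as-is)."""
    order = sorted(range(len(comparisons)), key=lambda i: comparisons[i].p_value)
    m = len(comparisons)
    adjusted = [None] * m
    running_max = 0.0
    for rank, idx in enumerate(order):
        c = comparisons[idx]
        p_adj = min(1.0, (m - rank) * c.p_value)
        running_max = max(running_max, p_adj)
        reject = running_max < c.alpha
        adjusted[idx] = PairwiseComparison(
            group_a=c.group_a, group_b=c.group_b, n_a=c.n_a, n_b=c.n_b,
            u_statistic=c.u_statistic, p_value=running_max, alpha=c.alpha,
            reject=reject,
            direction=c.direction if reject else None,
            method=c.method + "+holm",
        )
    return adjusted


def compare_site_categories(
    records: Iterable[ConcentrationRecord],
    element: str,
    scenario: ExposureScenario,
    alpha: float = 0.05,
    categories: Sequence[str] = DEFAULT_TEST_CATEGORIES,
    holm: bool = False,
) -> tuple[list[PairwiseComparison], list[tuple[tuple[str, str], str]]]:
    """All pairwise Mann–Whitney comparisons of exposure between categories.

    Records of ``element`` are transformed to average daily doses under
    ``scenario`` first; because that map is strictly increasing in
    concentration, decisions are identical to comparing raw
    concentrations. Categories with fewer than 3 records are skipped with
    a recorded reason rather than tested.

    Returns
    -------
    (comparisons, skipped)
        ``comparisons`` — completed :class:`PairwiseComparison` objects;
        ``skipped`` — ((group_a, group_b), reason) for pairs not tested.
    """
    exposures: dict[str, list[float]] = {c: [] for c in categories}
    for rec in records:
        if rec.element == element and rec.site_category in exposures:
            exposures[rec.site_category].append(
                average_daily_dose(rec.concentration, scenario)
            )

    comparisons: list[PairwiseComparison] = []
    skipped: list[tuple[tuple[str, str], str]] = []
    for cat_a, cat_b in combinations(categories, 2):
        small = [c for c in (cat_a, cat_b) if len(exposures[c]) < 3]
        if small:
            counts = ", ".join(f"{c}: n={len(exposures[c])}" for c in small)
            skipped.append(((cat_a, cat_b), f"undersized group(s) ({counts})"))
            continue
        comparisons.append(
            mann_whitney(
                exposures[cat_a], exposures[cat_b], alpha=alpha,
                group_a=cat_a, group_b=cat_b,
            )
        )
    if holm:
        comparisons = holm_adjust(comparisons)
    return comparisons, skipped
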