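"""Mann-Whitney comparisons and site-category analysis."""

from itertools import combinations

import numpy as np
import pytest

from soilrisk.dataset_io import ConcentrationRecord
from soilrisk.errors import DomainError
from soilrisk.exposure import ExposureScenario
from soilrisk.spatial import (
    compare_site_categories,
    exact_mann_whitney_p,
    holm_adjust,
    mann_whitney,
)

ADULT = ExposureScenario(
    label="adult", ir=20.0, ef=350.0, ed=75.0, at=75.0, lt=75.0, bw=80.8
)


def enumeration_p(x, y):
    """Brute-force two-sided exact p by enumerating every rank assignment."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n_a, n_b = len(x), len(y)
    u_obs = float((x[:, None] > y[None, :]).sum())
    pooled = np.concatenate([x, y])
    n = n_a + n_b
    us = []
    for a_idx in combinations(range(n), n_a):
        a = pooled[list(a_idx)]
        b = pooled[[i for i in range(n) if i not in a_idx]]
        us.append(float((a[:, None] > b[None, :]).sum()))
    us = np.array(us)
    lower = np.mean(us <= u_obs)
    upper = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(lower, upper))


class TestMannWhitney:
    def test_fully_separated_tiny_groups(self):
        result = mann_whitney([1, 2, 3], [4, 5, 6])
        assert result.u_statistic == 0.0
        # 2 of the 20 rank assignments are at least as extreme
        assert result.p_value == pytest.approx(0.1)
        assert result.method == "exact" and not result.reject

    def test_identical_samples_do_not_reject(self):
        result = mann_whitney([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert not result.reject and result.direction is None
        assert result.p_value > 0.5

    def test_constant_identical_groups_give_p_one(self):
        result = mann_whitney([5.0] * 4, [5.0] * 4)
        assert result.p_value == 1.0 and not result.reject
        assert result.method == "degenerate"

    def test_large_shift_rejects_with_direction(self, rng):
        a = rng.normal(loc=100.0, size=30)
        b = rng.normal(loc=0.0, size=30)
        result = mann_whitney(a, b, group_a="ind", group_b="agr")
        assert result.reject and result.direction == "ind"
        assert result.method == "asymptotic"  # 900 products > 400

    def test_undersized_group_rejected(self):
        with pytest.raises(DomainError):
            mann_whitney([1, 2], [3, 4, 5])

    def test_u_statistic_bounds_and_symmetry(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(size=6)
        r_ab = mann_whitney(a, b)
        r_ba = mann_whitney(b, a)
        assert 0 <= r_ab.u_statistic <= 48
        assert r_ab.u_statistic + r_ba.u_statistic == 48
        assert r_ab.p_value == pytest.approx(r_ba.p_value)

    @pytest.mark.parametrize(
        "n_a,n_b", [(3, 3), (3, 4), (3, 5), (3, 7), (4, 4), (4, 6), (5, 5)]
    )
    def test_exact_p_equals_full_enumeration(self, n_a, n_b, rng):
        # continuous draws -> no ties -> exact branch; compare with the
        # brute-force enumeration oracle over all C(n_a+n_b, n_a) splits
        for _ in range(5):
            a = rng.normal(size=n_a)
            b = rng.normal(loc=rng.uniform(-2, 2), size=n_b)
            result = mann_whitney(a, b)
            assert result.method == "exact"
            assert result.p_value == pytest.approx(enumeration_p(a, b), abs=1e-12)

    def test_ties_fall_back_to_corrected_asymptotic(self):
        a = [1.0, 2.0, 2.0, 3.0, 5.0]
        b = [2.0, 4.0, 4.0, 6.0, 7.0]
        result = mann_whitney(a, b)
        assert result.method == "asymptotic"
        assert 0 <= result.p_value <= 1

    def test_invariance_under_monotone_transform(self, rng):
        # rank decisions are unchanged by any strictly increasing map,
        # hence concentration vs exposure equivalence
        a = rng.lognormal(size=12)
        b = rng.lognormal(mean=1.0, size=9)
        r_raw = mann_whitney(a, b)
        r_log = mann_whitney(np.log(a), np.log(b))
        r_lin = mann_whitney(2.5e-7 * a, 2.5e-7 * b)
        assert r_raw.p_value == pytest.approx(r_log.p_value, abs=1e-12)
        assert r_raw.p_value == pytest.approx(r_lin.p_value, abs=1e-12)
        assert r_raw.u_statistic == r_log.u_statistic == r_lin.u_statistic


class TestTypeICalibration:
    def test_null_rejection_rate_near_alpha(self):
        rejections = 0
        n_sims = 400
        for seed in range(n_sims):
            r = np.random.default_rng(seed)
            a, b = r.normal(size=25), r.normal(size=25)
            if mann_whitney(a, b).reject:
                rejections += 1
        assert 0.02 <= rejections / n_sims <= 0.08


class TestCompareSiteCategories:
    @staticmethod
    def records_for(medians, n=30, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for cat, median in medians.items():
            for v in rng.lognormal(mean=np.log(median), sigma=0.5, size=n):
                out.append(
                    ConcentrationRecord("As", float(v), site_category=cat)
                )
        return out

    def test_industrial_dominance_detected(self):
        records = self.records_for(
            {"urban": 7.0, "suburban": 6.0, "industrial": 70.0,
             "agricultural": 5.0}
        )
        comparisons, skipped = compare_site_categories(records, "As", ADULT)
        assert len(comparisons) == 6 and not skipped
        by_pair = {(c.group_a, c.group_b): c for c in comparisons}
        ind_urb = by_pair[("urban", "industrial")]
        assert ind_urb.reject and ind_urb.direction == "industrial"

    def test_exposure_transform_does_not_change_decisions(self):
        records = self.records_for(
            {"urban": 7.0, "suburban": 6.0, "industrial": 70.0,
             "agricultural": 5.0}
        )
        comparisons, _ = compare_site_categories(records, "As", ADULT)
        raw = {}
        for c in ("urban", "suburban", "industrial", "agricultural"):
            raw[c] = [
                r.concentration for r in records if r.site_category == c
            ]
        for comp in comparisons:
            direct = mann_whitney(raw[comp.group_a], raw[comp.group_b])
            assert comp.p_value == pytest.approx(direct.p_value, abs=1e-12)
            assert comp.u_statistic == direct.u_statistic

    def test_undersized_category_skipped_with_reason(self):
        records = self.records_for(
            {"urban": 7.0, "suburban": 6.0, "industrial": 70.0}
        ) + [ConcentrationRecord("As", 5.0, site_category="agricultural")] * 2
        comparisons, skipped = compare_site_categories(records, "As", ADULT)
        assert len(comparisons) == 3
        assert len(skipped) == 3
        assert all("agricultural" in reason for _, reason in skipped)

    def test_other_elements_are_ignored(self):
        records = self.records_for({"urban": 7.0, "industrial": 70.0})
        records += [
            ConcentrationRecord("Pb", 1e6, site_category="urban")
        ] * 10
        comparisons, _ = compare_site_categories(records, "As", ADULT)
        by_pair = {(c.group_a, c.group_b): c for c in comparisons}
        assert by_pair[("urban", "industrial")].n_a == 30


class TestHolmOption:
    def test_adjusted_p_values_are_larger(self, rng):
        comps = []
        for _ in range(4):
            a = rng.normal(size=10)
            b = rng.normal(loc=1.0, size=10)
            comps.append(mann_whitney(a, b))
        adjusted = holm_adjust(comps)
        for raw, adj in zip(comps, adjusted):
            assert adj.p_value >= raw.p_value


def test_exact_null_distribution_mass():
    # P(U <= max) must be 1 for any group sizes
    assert exact_mann_whitney_p(0, 3, 3) == pytest.approx(2 / 20)
    for n_a, n_b in [(3, 3), (4, 5), (6, 4)]:
        assert exact_mann_whitney_p(n_a * n_b // 2, n_a, n_b) <= 1.0
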