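"""Dataset reading, descriptive statistics, exceedance and Cr speciation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from soilrisk.dataset_io import (
    TURKISH_LIMITS,
    ConcentrationRecord,
    exceedance_ratio,
    normalize_site_category,
    read_concentration_table,
    speciate_chromium,
    summaries_to_frame,
    summarize,
)
from soilrisk.errors import DomainError, SchemaError, ValidationError

HEADER = "element,concentration_mg_kg,province,site_category,source_id\n"


def _write(tmp_path, body, name="conc.csv"):
    p = tmp_path / name
    p.write_text(HEADER + body)
    return p


class TestReader:
    def test_well_formed_rows_become_records(self, tmp_path):
        path = _write(
            tmp_path,
            "As,10.5,Ankara,urban,smith2020\n"
            "Pb,78.7,Izmir,Industrial,kaya2019\n"
            "Cr,133,Konya,noncategorized,x\n",
        )
        records = read_concentration_table(path)
        assert len(records) == 3
        assert records[0] == ConcentrationRecord(
            "As", 10.5, "Ankara", "urban", "smith2020"
        )
        # category strings normalize case-insensitively; unknown -> uncategorized
        assert records[1].site_category == "industrial"
        assert records[2].site_category == "uncategorized"

    def test_negative_concentration_names_the_row(self, tmp_path):
        path = _write(tmp_path, "As,10,A,urban,s\nPb,-5,B,rural,s\n")
        with pytest.raises(ValidationError) as err:
            read_concentration_table(path)
        assert err.value.rows == [3]  # header is line 1

    def test_non_numeric_concentration_rejected(self, tmp_path):
        path = _write(tmp_path, "As,ten,A,urban,s\n")
        with pytest.raises(ValidationError) as err:
            read_concentration_table(path)
        assert err.value.rows == [2]

    def test_unknown_element_rejected(self, tmp_path):
        path = _write(tmp_path, "Xx,10,A,urban,s\n")
        with pytest.raises(ValidationError):
            read_concentration_table(path)

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("element,province\nAs,Ankara\n")
        with pytest.raises(SchemaError):
            read_concentration_table(p)

    def test_header_only_yields_empty_collection(self, tmp_path):
        path = _write(tmp_path, "")
        assert read_concentration_table(path) == []

    def test_censored_rows_substitute_half_detection_limit(self, tmp_path):
        p = tmp_path / "cens.csv"
        p.write_text(
            "element,concentration_mg_kg,province,site_category,source_id,censored\n"
            "As,0.4,A,urban,s,true\n"
            "As,10,A,urban,s,false\n"
        )
        records = read_concentration_table(p)
        assert records[0].censored and records[0].concentration == 0.2
        assert not records[1].censored and records[1].concentration == 10

    def test_dialect_maps_alternate_headers(self, tmp_path):
        p = tmp_path / "alt.csv"
        p.write_text("metal,value\nAs,3.0\n")
        records = read_concentration_table(
            p, dialect={"element": "metal", "concentration": "value"}
        )
        assert len(records) == 1 and records[0].concentration == 3.0


class TestSummarize:
    def test_single_record_collapses_all_statistics(self):
        (summary,) = summarize(
            [ConcentrationRecord("As", 10.0)], group_by=()
        ).values()
        assert (
            summary.mean == summary.median == summary.p25
            == summary.p75 == summary.p95 == 10.0
        )
        assert summary.cv == 0.0 and summary.n == 1

    def test_hand_arithmetic_oracle(self):
        records = [ConcentrationRecord("As", c) for c in (2, 4, 6, 8)]
        (summary,) = summarize(records).values()
        assert summary.mean == 5.0 and summary.median == 5.0
        # sample sd of {2,4,6,8} is sqrt(20/3)
        assert summary.cv == pytest.approx(math.sqrt(20 / 3) / 5.0)

    def test_lognormal_cv_matches_closed_form(self, rng):
        sigma = 0.8
        draws = rng.lognormal(mean=1.0, sigma=sigma, size=10_000)
        records = [ConcentrationRecord("Pb", float(v)) for v in draws]
        (summary,) = summarize(records).values()
        analytic = math.sqrt(math.exp(sigma**2) - 1.0)
        assert summary.cv == pytest.approx(analytic, rel=0.05)

    def test_grouping_keys_partition_records(self):
        records = [
            ConcentrationRecord("As", 1.0, site_category="urban"),
            ConcentrationRecord("As", 2.0, site_category="rural"),
            ConcentrationRecord("Pb", 3.0, site_category="urban"),
        ]
        by_elem = summarize(records, group_by=("element",))
        assert set(by_elem) == {("As",), ("Pb",)}
        assert by_elem[("As",)].n == 2
        both = summarize(records, group_by=("element", "site_category"))
        assert len(both) == 3
        # pooled count equals the sum of disjoint group counts
        (pooled,) = summarize(records).values()
        assert pooled.n == sum(s.n for s in both.values())

    def test_empty_input_gives_empty_mapping(self):
        assert summarize([]) == {}

    def test_unknown_group_key_rejected(self):
        with pytest.raises(DomainError):
            summarize([ConcentrationRecord("As", 1.0)], group_by=("color",))

    def test_frame_mirrors_summary_layout(self):
        records = [ConcentrationRecord("As", c) for c in (1.0, 2.0)]
        frame = summaries_to_frame(
            summarize(records, group_by=("element",)), group_by=("element",)
        )
        assert list(frame.columns) == [
            "element", "n", "mean", "median", "p25", "p75", "p95", "cv",
        ]

    @given(
        st.lists(
            st.floats(min_value=0.001, max_value=1e6, allow_nan=False),
            min_size=1,
            max_size=40,
        )
    )
    def test_percentile_monotonicity_property(self, values):
        records = [ConcentrationRecord("Zn", v) for v in values]
        (s,) = summarize(records).values()
        assert s.p25 <= s.median <= s.p75 <= s.p95
        assert s.cv is None or s.cv >= 0


class TestExceedance:
    def test_printed_ratio_pairs(self):
        assert exceedance_ratio(89.2, element="Ni") == pytest.approx(2.97, rel=2e-3)
        assert exceedance_ratio(20.0, element="As") == 1.0

    def test_unknown_element_is_lookup_error(self):
        with pytest.raises(KeyError):
            exceedance_ratio(10.0, element="Al")  # no regulatory limit for Al

    @given(
        mean=st.floats(min_value=0, max_value=1e6, allow_nan=False),
        scale=st.floats(min_value=0.01, max_value=100),
    )
    def test_linear_in_mean_and_scale_invariant(self, mean, scale):
        base = exceedance_ratio(mean, element="As")
        assert exceedance_ratio(scale * mean, element="As") == pytest.approx(
            scale * base
        )
        limit = TURKISH_LIMITS["As"]
        rescaled = exceedance_ratio(
            scale * mean, limits={"As": scale * limit}, element="As"
        )
        assert rescaled == pytest.approx(base, rel=1e-9, abs=1e-12)


class TestChromiumSpeciation:
    @pytest.mark.parametrize(
        "total,fraction,expected",
        [
            (133.0, 0.20, (106.4, 26.6)),
            (0.0, 0.20, (0.0, 0.0)),
            (100.0, 1.0, (0.0, 100.0)),
            (100.0, 0.0, (100.0, 0.0)),
        ],
    )
    def test_split_values(self, total, fraction, expected):
        cr3, cr6 = speciate_chromium(total, fraction)
        assert cr3 == pytest.approx(expected[0])
        assert cr6 == pytest.approx(expected[1])

    @given(
        total=st.floats(min_value=0, max_value=1e7, allow_nan=False),
        fraction=st.floats(min_value=0, max_value=1),
    )
    def test_mass_conserved(self, total, fraction):
        cr3, cr6 = speciate_chromium(total, fraction)
        # cr3 is defined as total - cr6, so the sum reconstructs the
        # input to within one floating-point rounding
        assert cr3 + cr6 == pytest.approx(total, rel=1e-15, abs=0.0)
        assert cr3 >= 0 and cr6 >= 0

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(DomainError):
            speciate_chromium(10.0, 1.5)
        with pytest.raises(DomainError):
            speciate_chromium(10.0, -0.1)


def test_normalize_site_category_variants():
    assert normalize_site_category("URBAN") == "urban"
    assert normalize_site_category("Noncategorized") == "uncategorized"
    assert normalize_site_category("seaside") == "uncategorized"
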