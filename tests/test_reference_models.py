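"""LMS transform, percentile lookup and threshold-resolution behavior."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from pedhtn.reference_models import (
    AgeOutOfRangeError,
    BPReferenceTable,
    GrowthReference,
    InvalidParameterError,
    TableIncompleteError,
    TableValidationError,
    ThresholdSet,
    bp_percentile_value,
    height_percentile,
    lms_zscore,
    percentile_from_z,
    resolve_thresholds,
    resolve_thresholds_bulk,
)

from conftest import make_flat_bp_table


class TestLMSZscore:
    @pytest.mark.parametrize("x,L,M,S,expected", [
        (15.0, 1.0, 15.0, 0.1, 0.0),          # x at the median
        (16.5, 1.0, 15.0, 0.1, 1.0),          # L=1 reduces to (x-M)/(M*S)
        (20.0, -1.5, 15.0, 0.12, 1.9471164),  # direct Box-Cox evaluation
    ])
    def test_known_values(self, x, L, M, S, expected):
        assert lms_zscore(x, L, M, S) == pytest.approx(expected, abs=1e-6)

    def test_log_limit_and_continuity_at_L0(self):
        # L = 0 is the log-normal case; tiny L must approach it smoothly
        z0 = lms_zscore(18.0, 0.0, 15.0, 0.1)
        assert z0 == pytest.approx(np.log(18.0 / 15.0) / 0.1)
        z_eps = lms_zscore(18.0, 1e-7, 15.0, 0.1)
        assert z_eps == pytest.approx(z0, rel=1e-5)

    @pytest.mark.parametrize("bad", [(-1, 1, 15, 0.1), (15, 1, 0, 0.1),
                                     (15, 1, 15, -0.1)])
    def test_nonpositive_inputs_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            lms_zscore(*bad)

    @given(st.floats(5.0, 50.0), st.floats(5.1, 50.1),
           st.floats(-2.0, 2.0), st.floats(0.02, 0.3))
    def test_strictly_increasing_in_x(self, x1, x2, L, S):
        if x1 == x2:
            return
        lo, hi = sorted((x1, x2))
        assert lms_zscore(lo, L, 20.0, S) < lms_zscore(hi, L, 20.0, S)

    @given(st.floats(-2.0, 2.0), st.floats(0.02, 0.3))
    def test_zero_at_median_for_all_L_S(self, L, S):
        assert lms_zscore(25.0, L, 25.0, S) == pytest.approx(0.0, abs=1e-12)


class TestPercentileFromZ:
    def test_median_maps_to_50(self):
        assert percentile_from_z(0.0) == pytest.approx(50.0)

    def test_95th_and_symmetry(self):
        assert percentile_from_z(1.6449) == pytest.approx(95.0, abs=0.01)
        assert percentile_from_z(-1.6449) == pytest.approx(5.0, abs=0.01)

    def test_strictly_increasing(self):
        zs = np.linspace(-4, 4, 41)
        ps = percentile_from_z(zs)
        assert np.all(np.diff(ps) > 0)


class TestHeightPercentile:
    @pytest.fixture
    def simple_ref(self):
        rows = []
        for age, M in ((90, 118.0), (96, 120.0), (102, 122.0)):
            rows.append(("male", age, "height_for_age", 1.0, M, 0.05))
        return GrowthReference(pd.DataFrame(
            rows, columns=["sex", "age_months", "measure", "L", "M", "S"]))

    def test_median_height_is_50th(self, simple_ref):
        assert height_percentile("male", 96, 120.0, simple_ref) == pytest.approx(50.0)

    def test_one_sd_above_is_84th(self, simple_ref):
        # L=1, S=0.05, M=120 at 96 mo: height 126 -> z=1 -> normal CDF 84.13
        assert height_percentile("male", 96, 126.0, simple_ref) == \
            pytest.approx(84.1345, abs=0.01)

    def test_interpolates_M_between_ages(self, simple_ref):
        # M at 93 months is (118+120)/2 = 119
        assert height_percentile("male", 93, 119.0, simple_ref) == pytest.approx(50.0)

    def test_age_outside_span_errors(self, simple_ref):
        with pytest.raises(AgeOutOfRangeError):
            height_percentile("male", 48, 100.0, simple_ref)


class TestBPPercentileValue:
    @pytest.fixture
    def grid_table(self):
        # values rise 2 mmHg per height column, 5 per bp percentile step
        rows = []
        base = {5: 100, 10: 102, 25: 104, 50: 108, 75: 110, 90: 112, 95: 114}
        for hp, v in base.items():
            for bp_pct, off in ((50, 0), (90, 10), (95, 15)):
                rows.append(("aap_2017", "male", 10, hp, "SBP", bp_pct, float(v + off)))
                rows.append(("aap_2017", "male", 10, hp, "DBP", bp_pct, float(v - 40 + off)))
        return BPReferenceTable(pd.DataFrame(rows, columns=[
            "guideline", "sex", "age_years", "height_percentile",
            "metric", "bp_percentile", "value"]))

    def test_grid_point_is_exact_cell(self, grid_table):
        assert grid_table.value("aap_2017", "male", 10, 75, "SBP", 50) == 110.0

    def test_midpoint_linear_interpolation(self, grid_table):
        # midway between the 50 (108) and 75 (110) columns -> 109
        assert grid_table.value("aap_2017", "male", 10, 62.5, "SBP", 50) == \
            pytest.approx(109.0)

    def test_clamps_below_5th_and_above_95th(self, grid_table):
        assert grid_table.value("aap_2017", "male", 10, 1, "SBP", 50) == 100.0
        assert grid_table.value("aap_2017", "male", 10, 99, "SBP", 50) == 114.0

    def test_missing_key_names_the_combination(self, grid_table):
        with pytest.raises(TableIncompleteError, match="age_years=11"):
            grid_table.value("aap_2017", "male", 11, 50, "SBP", 50)

    def test_monotone_in_height_and_bp_percentile(self, bp_table):
        hs = np.linspace(1, 99, 25)
        vals = [bp_table.value("fourth_2004", "female", 9, h, "SBP", 90) for h in hs]
        assert np.all(np.diff(vals) >= 0)
        for h in (5, 37.5, 95):
            v = [bp_table.value("fourth_2004", "female", 9, h, "SBP", p)
                 for p in (50, 90, 95)]
            assert v[0] < v[1] < v[2]


class TestTableValidation:
    def test_decreasing_bp_percentile_rejected(self):
        df = pd.DataFrame([
            ("aap_2017", "male", 5, 50, "SBP", 50, 110.0),
            ("aap_2017", "male", 5, 50, "SBP", 90, 105.0),
            ("aap_2017", "male", 5, 50, "SBP", 95, 120.0),
        ], columns=["guideline", "sex", "age_years", "height_percentile",
                    "metric", "bp_percentile", "value"])
        with pytest.raises(TableValidationError, match="bp_percentile"):
            BPReferenceTable(df)

    def test_growth_reference_requires_increasing_ages(self):
        df = pd.DataFrame([
            ("male", 24, "height_for_age", 1.0, 87.0, 0.04),
            ("male", 24, "height_for_age", 1.0, 88.0, 0.04),
        ], columns=["sex", "age_months", "measure", "L", "M", "S"])
        with pytest.raises(TableValidationError, match="strictly increasing"):
            GrowthReference(df)

    def test_growth_reference_rejects_nonpositive_S(self):
        df = pd.DataFrame([("male", 24, "height_for_age", 1.0, 87.0, 0.0)],
                          columns=["sex", "age_months", "measure", "L", "M", "S"])
        with pytest.raises(TableValidationError, match="S must be > 0"):
            GrowthReference(df)


class TestResolveThresholds:
    def test_aap_adolescent_static_band(self, bp_table):
        for h in (5, 50, 95):
            for sex in ("male", "female"):
                ts = resolve_thresholds("aap_2017", sex, 15, h, bp_table)
                assert (ts.elevated_sbp, ts.elevated_dbp, ts.htn_sbp, ts.htn_dbp) \
                    == (120.0, 80.0, 130.0, 80.0)
                assert ts.provenance == "static"

    def test_adult_rule_both_guidelines(self, bp_table):
        for g in ("fourth_2004", "aap_2017"):
            ts = resolve_thresholds(g, "male", 18, 50, bp_table)
            assert (ts.htn_sbp, ts.htn_dbp) == (140.0, 90.0)
            assert (ts.elevated_sbp, ts.elevated_dbp) == (120.0, 80.0)

    def test_fourth_report_htn_is_95th_plus_5(self):
        table = make_flat_bp_table(p95_sbp=115, p95_dbp=75)
        ts = resolve_thresholds("fourth_2004", "male", 10, 50, table)
        assert ts.htn_sbp == 120.0
        assert ts.htn_dbp == 80.0

    def test_elevated_capped_at_120_80(self):
        table = make_flat_bp_table(p90_sbp=125, p95_sbp=133, p90_dbp=85, p95_dbp=95)
        ts = resolve_thresholds("fourth_2004", "female", 12, 50, table)
        assert ts.elevated_sbp == 120.0 and ts.elevated_dbp == 80.0

    def test_aap_child_htn_capped_at_130_80(self):
        table = make_flat_bp_table(p90_sbp=125, p95_sbp=140, p90_dbp=78, p95_dbp=90)
        ts = resolve_thresholds("aap_2017", "male", 12, 50, table)
        assert ts.htn_sbp == 130.0 and ts.htn_dbp == 80.0

    def test_age_out_of_band_errors(self, bp_table):
        with pytest.raises(AgeOutOfRangeError):
            resolve_thresholds("aap_2017", "male", 0, 50, bp_table)
        with pytest.raises(AgeOutOfRangeError):
            resolve_thresholds("aap_2017", "male", 21, 50, bp_table)

    def test_elevated_never_exceeds_htn_across_grid(self, bp_table):
        for g in ("fourth_2004", "aap_2017"):
            for sex in ("male", "female"):
                for age in range(1, 21):
                    for h in (2, 5, 33, 50, 88, 95, 99):
                        ts = resolve_thresholds(g, sex, age, h, bp_table)
                        assert ts.elevated_sbp <= ts.htn_sbp
                        assert ts.elevated_dbp <= ts.htn_dbp

    def test_bulk_matches_scalar(self, bp_table):
        rng = np.random.default_rng(0)
        sex = rng.choice(["male", "female"], 50)
        age = rng.integers(1, 21, 50)
        hp = rng.uniform(1, 99, 50)
        for g in ("fourth_2004", "aap_2017"):
            bulk = resolve_thresholds_bulk(g, sex, age, hp, bp_table)
            for i in range(50):
                ts = resolve_thresholds(g, sex[i], int(age[i]), hp[i], bp_table)
                assert bulk["htn_sbp"].iloc[i] == pytest.approx(ts.htn_sbp)
                assert bulk["elevated_dbp"].iloc[i] == pytest.approx(ts.elevated_dbp)

    def test_invalid_thresholdset_rejected(self):
        with pytest.raises(ValueError):
            ThresholdSet(130, 80, 120, 80, "static")
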