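"""Rates, kappa agreement, BMI categories and odds-ratio estimation."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from pedhtn.bp_classify import CATEGORY_HTN, CATEGORY_NORMAL, classify_cohort
from pedhtn.cohort_qc import run_qc
from pedhtn.epi_stats import (
    KappaUndefinedError,
    SeparationError,
    UndefinedRateError,
    annual_rate,
    annual_rate_series,
    bmi_category,
    cohens_kappa,
    event_rate,
    guideline_agreement,
    htn_cases,
    kappa_band,
    logistic_or,
    participants_at_risk,
    rate_agreement_table,
    round_half_up,
)
from pedhtn.synthetic_data import SimConfig, gen_cohort


def _py_table(rows):
    """(person, age, guideline, category[, eligible]) -> person-year frame."""
    recs = []
    for r in rows:
        pid, age, g, cat = r[:4]
        eligible = r[4] if len(r) > 4 else True
        recs.append((pid, age, g, 3, 0, 0, 0, 0, eligible, cat))
    return pd.DataFrame(recs, columns=[
        "person_id", "age_years", "guideline", "n_occasions", "n_sbp_htn",
        "n_dbp_htn", "n_sbp_elev", "n_dbp_elev", "eligible", "category"])


class TestEventRate:
    @pytest.mark.parametrize("cases,participants,expected", [
        (375, 495962, 0.76), (387, 495962, 0.78),
        (523, 255615, 2.05), (573, 255615, 2.24),
        (1185, 218368, 5.43), (1300, 218368, 5.95),
    ])
    def test_reference_rate_pairs(self, cases, participants, expected):
        assert event_rate(cases, participants) == expected

    def test_zero_cases(self):
        assert event_rate(0, 1000) == 0.0

    def test_empty_denominator_errors(self):
        with pytest.raises(UndefinedRateError):
            event_rate(5, 0)

    def test_rounding_is_half_up(self):
        assert round_half_up(2.345, 2) == 2.35
        assert round_half_up(2.344, 2) == 2.34


class TestParticipantsAtRisk:
    def test_person_counts_once_per_age_year(self):
        rows = [("a", age, "aap_2017", CATEGORY_NORMAL) for age in (13, 14, 15)]
        rows += [("a", age, "fourth_2004", CATEGORY_NORMAL) for age in (13, 14, 15)]
        assert participants_at_risk(_py_table(rows), 13, 17) == 3

    def test_single_unit(self):
        assert participants_at_risk(
            _py_table([("a", 9, "aap_2017", CATEGORY_NORMAL)]), 8, 12) == 1

    def test_constructed_count(self):
        rows = [(f"p{i}", a, "aap_2017", CATEGORY_NORMAL)
                for i in range(20) for a in (9, 10)]
        assert participants_at_risk(_py_table(rows), 8, 12) == 40

    def test_empty_table(self):
        assert participants_at_risk(_py_table([]), 1, 7) == 0


class TestKappa:
    def test_perfect_diagonal(self):
        res = cohens_kappa(50, 0, 0, 50)
        assert res.kappa == 1.0 and res.pct_agreement == 100.0
        assert res.band == "almost_perfect"

    def test_independence_gives_zero(self):
        assert cohens_kappa(10, 10, 10, 10).kappa == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # po=0.9, pe=0.505 -> kappa = 0.395/0.495 = 0.7980
        res = cohens_kappa(40, 5, 5, 50)
        assert res.kappa == pytest.approx(0.79798, abs=1e-4)
        assert res.pct_agreement == pytest.approx(90.0)
        assert res.ci_low <= res.kappa <= res.ci_high

    def test_degenerate_margins_error_keeps_pct(self):
        with pytest.raises(KappaUndefinedError) as err:
            cohens_kappa(100, 0, 0, 0)
        assert err.value.pct_agreement == pytest.approx(100.0)

    @given(st.integers(0, 200), st.integers(0, 200),
           st.integers(0, 200), st.integers(0, 200))
    def test_transpose_invariance(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        try:
            k1 = cohens_kappa(a, b, c, d).kappa
            k2 = cohens_kappa(a, c, b, d).kappa
        except KappaUndefinedError:
            return
        assert k1 == pytest.approx(k2, abs=1e-12)

    @given(st.integers(1, 200), st.integers(0, 200),
           st.integers(0, 200), st.integers(1, 200))
    def test_kappa_one_iff_no_discordance(self, a, b, c, d):
        res = cohens_kappa(a, b, c, d)
        assert -1.0 <= res.kappa <= 1.0
        assert (res.kappa == pytest.approx(1.0)) == (b == 0 and c == 0)

    def test_se_matches_bootstrap(self):
        res = cohens_kappa(400, 50, 50, 500)
        rng = np.random.default_rng(0)
        N = 1000
        p = np.array([400, 50, 50, 500]) / N
        draws = rng.multinomial(N, p, size=4000)
        ks = []
        for n11, n10, n01, n00 in draws:
            try:
                ks.append(cohens_kappa(n11, n10, n01, n00).kappa)
            except KappaUndefinedError:
                pass
        assert res.se == pytest.approx(np.std(ks), rel=0.15)


class TestKappaBand:
    @pytest.mark.parametrize("kappa,band", [
        (0.85, "almost_perfect"), (0.20, "none"), (0.50, "moderate"),
        (0.204, "none"), (0.205, "fair"),   # rounds to 2 dp before banding
        (0.61, "substantial"), (0.40, "fair"), (-0.3, "none"), (1.0, "almost_perfect"),
    ])
    def test_breaks(self, kappa, band):
        assert kappa_band(kappa) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            kappa_band(1.2)


class TestGuidelineAgreement:
    def test_identical_classifications(self):
        rows = []
        for i in range(30):
            cat = CATEGORY_HTN if i < 4 else CATEGORY_NORMAL
            rows.append((f"p{i}", 14, "fourth_2004", cat))
            rows.append((f"p{i}", 14, "aap_2017", cat))
        res = guideline_agreement(_py_table(rows), 13, 17)
        assert res.kappa == 1.0 and res.n10 == res.n01 == 0

    def test_aap_superset_shows_one_sided_discordance(self):
        rows = []
        for i in range(30):
            aap = CATEGORY_HTN if i < 6 else CATEGORY_NORMAL
            fourth = CATEGORY_HTN if i < 3 else CATEGORY_NORMAL
            rows.append((f"p{i}", 14, "fourth_2004", fourth))
            rows.append((f"p{i}", 14, "aap_2017", aap))
        res = guideline_agreement(_py_table(rows), 13, 17)
        assert res.n10 == 0        # no 2004-only cases
        assert res.n01 == 3        # AAP-only cases
        assert 0 < res.kappa < 1

    def test_eligible_only_denominator(self):
        rows = [("a", 14, "fourth_2004", CATEGORY_NORMAL, False),
                ("a", 14, "aap_2017", CATEGORY_NORMAL, False),
                ("b", 14, "fourth_2004", CATEGORY_HTN, True),
                ("b", 14, "aap_2017", CATEGORY_HTN, True),
                ("c", 14, "fourth_2004", CATEGORY_NORMAL, True),
                ("c", 14, "aap_2017", CATEGORY_NORMAL, True)]
        res_all = guideline_agreement(_py_table(rows), 13, 17, denominator="any_obp")
        res_eli = guideline_agreement(_py_table(rows), 13, 17, denominator="eligible_only")
        assert res_all.n11 + res_all.n10 + res_all.n01 + res_all.n00 == 3
        assert res_eli.n11 + res_eli.n10 + res_eli.n01 + res_eli.n00 == 2

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            guideline_agreement(_py_table([("a", 14, "fourth_2004", CATEGORY_NORMAL),
                                           ("a", 14, "aap_2017", CATEGORY_NORMAL)]),
                                1, 7)

    def test_mismatched_units_error(self):
        rows = [("a", 14, "fourth_2004", CATEGORY_NORMAL),
                ("b", 14, "aap_2017", CATEGORY_NORMAL)]
        with pytest.raises(ValueError, match="mismatched"):
            guideline_agreement(_py_table(rows), 13, 17)


class TestBMICategory:
    @pytest.mark.parametrize("z,expected", [
        (0.0, "normal"),
        (-1.7, "underweight"),   # below the 5th percentile (z < -1.645)
        (1.1, "overweight"),     # between 85th and 95th
        (1.7, "obesity"),        # at/above the 95th
    ])
    def test_percentile_breaks(self, z, expected, growth_ref):
        sex, age_m = "female", 140
        _, M, S = growth_ref.lms_params(sex, age_m, "bmi_for_age")
        bmi = M * (1 + z * S)           # L=1 closed form
        height = 150.0
        weight = bmi * (height / 100.0) ** 2
        assert bmi_category(weight, height, sex, age_m, growth_ref) == expected

    def test_exact_95th_is_obesity(self, growth_ref):
        sex, age_m = "male", 120
        _, M, S = growth_ref.lms_params(sex, age_m, "bmi_for_age")
        z95 = 1.6448536269514722
        bmi = M * (1 + z95 * S) * (1 + 1e-9)
        weight = bmi * 1.5 ** 2
        assert bmi_category(weight, 150.0, sex, age_m, growth_ref) == "obesity"

    def test_rejects_nonpositive(self, growth_ref):
        with pytest.raises(ValueError):
            bmi_category(0.0, 150.0, "male", 120, growth_ref)


class TestAnnualRate:
    def _cohort(self, engine, **kw):
        cfg = SimConfig(n_persons=400, years_observed_mean=1.0,
                        visits_per_year_mean=4.0, missing_height_rate=0,
                        bp_outlier_rate=0, growth_outlier_rate=0, **kw)
        visits, _, truth = gen_cohort(cfg, engine)
        py = classify_cohort(visits, engine)
        return visits, py, truth

    def test_recovers_planted_annual_prevalence(self, engine):
        p = 0.05
        visits, py, truth = self._cohort(engine, htn_prevalence=p,
                                         elevated_prevalence=0.0, seed=21)
        series = annual_rate_series(py, visits, guidelines=["aap_2017"])
        total_cases = series["cases"].sum()
        total_n = series["participants"].sum()
        se = np.sqrt(p * (1 - p) / total_n) * 1000
        assert abs(1000 * total_cases / total_n - 1000 * p) < 3 * se

    def test_all_hypertensive_rate_1000(self, engine):
        visits, py, _ = self._cohort(engine, htn_prevalence=1.0,
                                     elevated_prevalence=0.0, seed=22)
        year = int(visits["visit_date"].dt.year.mode()[0])
        res = annual_rate(py, visits, year, "aap_2017")
        assert res.rate_per_1000 == 1000.0

    def test_year_without_visits_errors(self, engine):
        visits, py, _ = self._cohort(engine, seed=23)
        with pytest.raises(UndefinedRateError):
            annual_rate(py, visits, 1990, "aap_2017")


class TestLogisticOR:
    def test_binary_covariate_matches_cross_product_ratio(self):
        # aOR for a single binary covariate equals ad/bc from the 2x2
        a, b, c, d = 30, 70, 10, 90   # exposed-case, exposed-ctrl, unexp-case, unexp-ctrl
        y = np.array([1] * a + [0] * b + [1] * c + [0] * d)
        x = np.array([1] * (a + b) + [0] * (c + d))
        res = logistic_or(pd.DataFrame({"y": y, "x": x}), "y", ["x"])
        assert res["aor"].iloc[0] == pytest.approx((a * d) / (b * c), rel=1e-4)
        assert res["ci_low"].iloc[0] < res["aor"].iloc[0] < res["ci_high"].iloc[0]

    def test_null_covariate_ci_covers_one(self):
        rng = np.random.default_rng(3)
        covered = 0
        reps = 40
        for _ in range(reps):
            n = 800
            x = rng.normal(size=n)
            y = rng.binomial(1, 0.3, size=n)
            res = logistic_or(pd.DataFrame({"y": y, "x": x}), "y", ["x"])
            if res["ci_low"].iloc[0] <= 1.0 <= res["ci_high"].iloc[0]:
                covered += 1
        assert covered / reps >= 0.9

    def test_constant_outcome_errors(self):
        df = pd.DataFrame({"y": [1, 1, 1], "x": [0, 1, 0]})
        with pytest.raises(ValueError, match="constant"):
            logistic_or(df, "y", ["x"])

    def test_complete_separation_names_covariate(self):
        df = pd.DataFrame({"y": [0] * 20 + [1] * 20,
                           "x": list(range(20)) + list(range(30, 50))})
        with pytest.raises(SeparationError, match="x"):
            logistic_or(df, "y", ["x"])

    def test_grouped_fits(self):
        rng = np.random.default_rng(4)
        n = 600
        g = rng.choice(["8-12", "13-17"], n)
        x = rng.binomial(1, 0.4, n)
        logit = -2.0 + 1.0 * x
        y = rng.binomial(1, 1 / (1 + np.exp(-logit)))
        res = logistic_or(pd.DataFrame({"y": y, "x": x, "g": g}), "y", ["x"], group="g")
        assert set(res["group"]) == {"8-12", "13-17"}
        assert (res["aor"] > 0).all()


class TestRateAgreementTable:
    def test_full_report_on_synthetic_cohort(self, engine, growth_ref):
        cfg = SimConfig(n_persons=500, htn_prevalence=0.03, seed=31)
        visits, _, _ = gen_cohort(cfg, engine)
        clean, _ = run_qc(visits, growth_ref)
        py = classify_cohort(clean, engine)
        table = rate_agreement_table(py, age_groups=((1, 7), (8, 12), (13, 17)))
        assert list(table["age_group"]) == ["1-7", "8-12", "13-17"]
        assert (table["cases_aap_2017"] >= table["cases_fourth_2004"] - 1e-9).all()
        assert ((table["kappa"] >= -1) & (table["kappa"] <= 1)).all()
        assert (table["agreement_pct"] <= 100).all()
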