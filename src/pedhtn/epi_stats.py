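"""Rates, agreement, BMI categories and association analysis.

Event rates are expressed per 1000 persons at risk, where the unit at risk is
the person-year of age (one person contributes once per age-year inside an age
group; age groups need not be mutually exclusive).  Inter-guideline agreement
on the dichotomy hypertension vs not is summarized by percent agreement and
Cohen's kappa with an asymptotic (Fleiss–Cohen–Everitt) 95% CI and the usual
interpretation bands.  Associations between person-year covariates and
hypertension (vs elevated + normal pooled) are estimated with a
maximum-likelihood logistic model per age group, reported as adjusted odds
ratios with Wald CIs.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .bp_classify import CATEGORY_HTN
from .reference_models import GrowthReference, percentile_from_z


class UndefinedRateError(ZeroDivisionError):
    """Rate requested over an empty denominator."""


class KappaUndefinedError(ValueError):
    """Chance agreement is 1 (degenerate margins); kappa has no value."""

    def __init__(self, pct_agreement: float):
        super().__init__("kappa undefined: expected agreement is 1")
        self.pct_agreement = pct_agreement


class SeparationError(ValueError):
    """The logistic likelihood is unbounded (complete separation)."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (presentation rule)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateResult:
    stratum: str
    guideline: str
    cases: int
    participants: int
    rate_per_1000: float


def event_rate(cases: int, participants: int) -> float:
    """Cases per 1000 participants, rounded half-up to 2 decimals."""
    if participants <= 0:
        raise UndefinedRateError("participants must be > 0")
    if not 0 <= cases <= participants:
        raise ValueError("cases must lie in [0, participants]")
    return round_half_up(1000.0 * cases / participants, 2)


def participants_at_risk(person_years: pd.DataFrame, age_lo: int, age_hi: int) -> int:
    """Distinct (person, age-year) units with any OBP inside [age_lo, age_hi]."""
    if len(person_years) == 0:
        return 0
    sel = person_years[(person_years["age_years"] >= age_lo)
                       & (person_years["age_years"] <= age_hi)]
    return int(sel[["person_id", "age_years"]].drop_duplicates().shape[0])


def htn_cases(person_years: pd.DataFrame, guideline: str,
              age_lo: int, age_hi: int) -> int:
    """(person, age-year) units classified HTN under ``guideline`` in the group."""
    sel = person_years[(person_years["guideline"] == guideline)
                       & (person_years["age_years"] >= age_lo)
                       & (person_years["age_years"] <= age_hi)
                       & (person_years["category"] == CATEGORY_HTN)]
    return int(sel[["person_id", "age_years"]].drop_duplicates().shape[0])


def group_rate(person_years: pd.DataFrame, guideline: str,
               age_lo: int, age_hi: int) -> RateResult:
    cases = htn_cases(person_years, guideline, age_lo, age_hi)
    participants = participants_at_risk(person_years, age_lo, age_hi)
    if participants == 0:
        raise UndefinedRateError(f"no participants at risk in {age_lo}-{age_hi}")
    return RateResult(f"{age_lo}-{age_hi}", guideline, cases, participants,
                      event_rate(cases, participants))


def annual_rate(person_years: pd.DataFrame, visits: pd.DataFrame,
                calendar_year: int, guideline: str) -> RateResult:
    """Hypertension rate per 1000 persons among persons seen in one calendar year.

    Denominator: distinct persons with >=1 OBP visit dated in the year.
    Numerator: of those, persons with an HTN person-year any of whose visits
    falls in the year.
    """
    in_year = visits[visits["visit_date"].dt.year == calendar_year]
    if len(in_year) == 0:
        raise UndefinedRateError(f"no visits in calendar year {calendar_year}")
    denom_persons = set(in_year["person_id"].unique())
    df = in_year if "age_years" in in_year.columns else None
    if df is None:
        raise ValueError("visits need an age_years column (run add_age_columns)")
    htn_units = person_years[(person_years["guideline"] == guideline)
                             & (person_years["category"] == CATEGORY_HTN)]
    unit_key = set(zip(htn_units["person_id"], htn_units["age_years"]))
    vis_units = set(zip(df["person_id"], df["age_years"]))
    case_persons = {p for (p, a) in (unit_key & vis_units)}
    cases = len(case_persons & denom_persons)
    return RateResult(str(calendar_year), guideline, cases, len(denom_persons),
                      event_rate(cases, len(denom_persons)))


def annual_rate_series(person_years: pd.DataFrame, visits: pd.DataFrame,
                       guidelines=None) -> pd.DataFrame:
    """Per-guideline annual hypertension rate over the data's calendar span."""
    if guidelines is None:
        guidelines = sorted(person_years["guideline"].unique())
    years = sorted(visits["visit_date"].dt.year.unique())
    rows = []
    for g in guidelines:
        for y in years:
            r = annual_rate(person_years, visits, int(y), g)
            rows.append((int(y), g, r.cases, r.participants, r.rate_per_1000))
    return pd.DataFrame(rows, columns=["year", "guideline", "cases",
                                       "participants", "rate_per_1000"])


# ---------------------------------------------------------------------------
# Agreement
# ---------------------------------------------------------------------------

KAPPA_BANDS = ("none", "fair", "moderate", "substantial", "almost_perfect")


@dataclass(frozen=True)
class AgreementResult:
    n11: int
    n10: int
    n01: int
    n00: int
    kappa: float
    se: float
    ci_low: float
    ci_high: float
    pct_agreement: float
    band: str


def cohens_kappa(n11: int, n10: int, n01: int, n00: int) -> AgreementResult:
    """Cohen's kappa for a 2x2 concordance table with asymptotic 95% CI.

    The cells are (case/case, case/non-case, non-case/case, non-case/non-case)
    across the two classifications of the same units.  The standard error uses
    the large-sample variance of Fleiss, Cohen and Everitt; the CI is
    kappa +/- 1.96*SE truncated to [-1, 1].
    """
    n = np.array([[n11, n10], [n01, n00]], dtype=float)
    N = n.sum()
    if N <= 0:
        raise ValueError("empty 2x2 table")
    p = n / N
    po = float(np.trace(p))
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    pe = float(row @ col)
    pct = 100.0 * po
    if pe >= 1.0 - 1e-15:
        raise KappaUndefinedError(pct)
    kappa = (po - pe) / (1.0 - pe)

    # Fleiss-Cohen-Everitt asymptotic variance
    a = sum(p[i, i] * (1.0 - (row[i] + col[i]) * (1.0 - kappa)) ** 2
            for i in range(2))
    b = (1.0 - kappa) ** 2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2
        for i in range(2) for j in range(2) if i != j
    )
    c = (kappa - pe * (1.0 - kappa)) ** 2
    var = (a + b - c) / (N * (1.0 - pe) ** 2)
    se = float(np.sqrt(max(var, 0.0)))
    ci_low = max(kappa - 1.96 * se, -1.0)
    ci_high = min(kappa + 1.96 * se, 1.0)
    return AgreementResult(int(n11), int(n10), int(n01), int(n00),
                           float(kappa), se, ci_low, ci_high, pct,
                           kappa_band(kappa))


def kappa_band(kappa: float) -> str:
    """Interpretation band: <=0.20 none, 0.21-0.40 fair, 0.41-0.60 moderate,
    0.61-0.80 substantial, 0.81-1.00 almost perfect (kappa rounded to 2 dp)."""
    if not -1.0 - 1e-12 <= kappa <= 1.0 + 1e-12:
        raise ValueError("kappa outside [-1, 1]")
    k = round_half_up(kappa, 2)
    if k <= 0.20:
        return "none"
    if k <= 0.40:
        return "fair"
    if k <= 0.60:
        return "moderate"
    if k <= 0.80:
        return "substantial"
    return "almost_perfect"


def guideline_agreement(person_years: pd.DataFrame, age_lo: int, age_hi: int,
                        guideline_a: str = "fourth_2004",
                        guideline_b: str = "aap_2017",
                        denominator: str = "any_obp") -> AgreementResult:
    """Agreement on HTN vs not-HTN between the two guidelines in an age group.

    ``denominator`` chooses the unit set: ``any_obp`` uses every person-year
    with >=1 occasion, ``eligible_only`` restricts to person-years with >=3
    distinct-date occasions.
    """
    sel = person_years[(person_years["age_years"] >= age_lo)
                       & (person_years["age_years"] <= age_hi)]
    if denominator == "eligible_only":
        sel = sel[sel["eligible"]]
    elif denominator != "any_obp":
        raise ValueError(f"unknown denominator mode {denominator!r}")
    a = sel[sel["guideline"] == guideline_a].set_index(["person_id", "age_years"])
    b = sel[sel["guideline"] == guideline_b].set_index(["person_id", "age_years"])
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"no classified person-years in {age_lo}-{age_hi}")
    if not a.index.equals(b.index):
        if set(a.index) != set(b.index):
            raise ValueError("mismatched person-year units between guidelines")
        b = b.reindex(a.index)
    ca = (a["category"] == CATEGORY_HTN).to_numpy()
    cb = (b["category"] == CATEGORY_HTN).to_numpy()
    n11 = int(np.sum(ca & cb))
    n10 = int(np.sum(ca & ~cb))
    n01 = int(np.sum(~ca & cb))
    n00 = int(np.sum(~ca & ~cb))
    return cohens_kappa(n11, n10, n01, n00)


# ---------------------------------------------------------------------------
# BMI
# ---------------------------------------------------------------------------

BMI_CATEGORIES = ("underweight", "normal", "overweight", "obesity")


def bmi_category(weight_kg: float, height_cm: float, sex: str, age_months: float,
                 bmi_ref: GrowthReference) -> str:
    """BMI-for-age category with breaks at the 5th/85th/95th percentiles.

    underweight < 5th; overweight is [85th, 95th); obesity >= 95th.
    """
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    bmi = weight_kg / (height_cm / 100.0) ** 2
    z = bmi_ref.zscore(sex, age_months, "bmi_for_age", bmi)
    pct = percentile_from_z(z)
    if pct < 5.0:
        return "underweight"
    if pct < 85.0:
        return "normal"
    if pct < 95.0:
        return "overweight"
    return "obesity"


# ---------------------------------------------------------------------------
# Association analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ORResult:
    covariate: str
    aor: float
    ci_low: float
    ci_high: float
    p_value: float


def _check_separation(y: np.ndarray, X: pd.DataFrame) -> None:
    for col in X.columns:
        x = X[col].to_numpy(float)
        if x.std() == 0:
            continue
        if max(x[y == 1].min(), x[y == 0].min()) > \
           min(x[y == 1].max(), x[y == 0].max()):
            raise SeparationError(f"complete separation on covariate {col!r}")


def logistic_or(data: pd.DataFrame, outcome: str, covariates: list[str],
                group: str | None = None, maxiter: int = 100,
                tol: float = 1e-8) -> pd.DataFrame:
    """Adjusted odds ratios from an ML logistic fit, optionally per group.

    Outcome must be binary (hypertension vs elevated + normal pooled).
    Returns one row per (group, covariate) with aOR, Wald 95% CI and p-value.
    """
    frames = []
    groups = [(None, data)] if group is None else list(data.groupby(group))
    for gname, gdf in groups:
        y = gdf[outcome].to_numpy(float)
        if len(np.unique(y)) < 2:
            raise ValueError(
                f"outcome constant in group {gname!r}: need >=1 event and >=1 non-event"
            )
        X = gdf[covariates].astype(float)
        _check_separation(y, X)
        Xc = sm.add_constant(X, has_constant="add")
        if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
            raise ValueError("singular design matrix")
        model = sm.Logit(y, Xc)
        try:
            fit = model.fit(disp=0, maxiter=maxiter, method="newton", tol=tol)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise SeparationError(str(exc)) from exc
        params = fit.params
        ci = fit.conf_int(alpha=0.05)
        for cov in covariates:
            frames.append({
                "group": gname, "covariate": cov,
                "aor": float(np.exp(params[cov])),
                "ci_low": float(np.exp(ci.loc[cov, 0])),
                "ci_high": float(np.exp(ci.loc[cov, 1])),
                "p_value": float(fit.pvalues[cov]),
            })
    return pd.DataFrame(frames)


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def rate_agreement_table(person_years: pd.DataFrame,
                         age_groups=((1, 7), (8, 12), (13, 17)),
                         guidelines=("fourth_2004", "aap_2017"),
                         denominator: str = "any_obp") -> pd.DataFrame:
    """Comparison table: per age group, each guideline's cases and rate, plus
    kappa (95% CI), band and percent agreement between the two guidelines."""
    rows = []
    for lo, hi in age_groups:
        rec = {"age_group": f"{lo}-{hi}",
               "participants": participants_at_risk(person_years, lo, hi)}
        for g in guidelines:
            r = group_rate(person_years, g, lo, hi)
            rec[f"cases_{g}"] = r.cases
            rec[f"rate_per_1000_{g}"] = r.rate_per_1000
        agr = guideline_agreement(person_years, lo, hi, guidelines[0],
                                  guidelines[1], denominator)
        rec.update(kappa=round_half_up(agr.kappa, 2),
                   kappa_ci_low=round_half_up(agr.ci_low, 2),
                   kappa_ci_high=round_half_up(agr.ci_high, 2),
                   agreement_pct=round_half_up(agr.pct_agreement, 2),
                   band=agr.band)
        rows.append(rec)
    return pd.DataFrame(rows)
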