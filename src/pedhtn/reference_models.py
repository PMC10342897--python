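"""Normative reference models for pediatric blood-pressure classification.

This module houses the two table-driven engines everything downstream depends
on:

* **LMS growth references** — the skew-normal (Box–Cox) parameterization used
  by WHO/CDC growth charts.  A reference row carries, for one sex, one age in
  months and one measure (height-, weight- or BMI-for-age), the power ``L``,
  median ``M`` and coefficient of variation ``S``.  A measurement ``x`` maps to
  a z-score via

      z = ((x/M)**L - 1) / (L*S)     (L != 0)
      z = ln(x/M) / S                (L == 0)

  and a z-score maps to a percentile through the standard normal CDF.

* **Guideline BP reference tables** — normative SBP/DBP values indexed by
  guideline (2004 Fourth Report or 2017 AAP), sex, integer age in years,
  height percentile column (5/10/25/50/75/90/95) and BP percentile (50/90/95).
  ``resolve_thresholds`` turns these tables plus the guidelines' static rules
  (AAP >=13 y: elevated 120/80, hypertension 130/80; adult >=18 y: 140/90)
  into a concrete :class:`ThresholdSet` for one person-visit context.

The published guideline tables are not shipped; any delimited file conforming
to the documented schema can be loaded, and the package generates synthetic
tables (see :mod:`pedhtn.synthetic_data`) for tests and demonstrations.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

GUIDELINE_FOURTH = "fourth_2004"
GUIDELINE_AAP = "aap_2017"
GUIDELINES = (GUIDELINE_FOURTH, GUIDELINE_AAP)

SEXES = ("male", "female")
MEASURES = ("height_for_age", "weight_for_age", "bmi_for_age")
HEIGHT_PCT_GRID = (5, 10, 25, 50, 75, 90, 95)
BP_PCT_LEVELS = (50, 90, 95)
METRICS = ("SBP", "DBP")

GROWTH_REF_COLUMNS = ["sex", "age_months", "measure", "L", "M", "S"]
BP_REF_COLUMNS = [
    "guideline", "sex", "age_years", "height_percentile",
    "metric", "bp_percentile", "value",
]


class InvalidParameterError(ValueError):
    """A non-positive measurement or LMS parameter was supplied."""


class AgeOutOfRangeError(ValueError):
    """The requested age falls outside the reference's age span."""


class TableIncompleteError(KeyError):
    """A required (guideline, sex, age, metric, percentile) cell is missing."""


class TableValidationError(ValueError):
    """A reference table violates its schema or monotonicity invariants."""


# ---------------------------------------------------------------------------
# LMS transform
# ---------------------------------------------------------------------------

def lms_zscore(x, L, M, S):
    """Box–Cox (LMS) z-score of measurement ``x`` under parameters (L, M, S).

    Continuous in L at L = 0 (the log-normal limit).  Accepts scalars or
    numpy arrays; all of x, M, S must be strictly positive.
    """
    x = np.asarray(x, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(x <= 0) or np.any(M <= 0) or np.any(S <= 0):
        raise InvalidParameterError("x, M and S must be strictly positive")
    ratio = x / M
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(
            np.abs(L) < 1e-12,
            np.log(ratio) / S,
            (np.power(ratio, np.where(np.abs(L) < 1e-12, 1.0, L)) - 1.0)
            / (np.where(np.abs(L) < 1e-12, 1.0, L) * S),
        )
    if z.ndim == 0:
        return float(z)
    return z


def percentile_from_z(z):
    """Map a z-score to a percentile in (0, 100) via the normal CDF."""
    z = np.asarray(z, dtype=float)
    if np.any(~np.isfinite(z)):
        raise InvalidParameterError("z must be finite")
    p = norm.cdf(z) * 100.0
    if p.ndim == 0:
        return float(p)
    return p


# ---------------------------------------------------------------------------
# Growth reference
# ---------------------------------------------------------------------------

def load_growth_reference(path_or_df) -> pd.DataFrame:
    """Load and validate an LMS growth-reference table.

    Expects columns sex, age_months, measure, L, M, S.  Raises
    :class:`TableValidationError` naming the first offending row (1-based,
    excluding the header) on any invariant violation.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df)
    missing = [c for c in GROWTH_REF_COLUMNS if c not in df.columns]
    if missing:
        raise TableValidationError(f"growth reference missing columns {missing}")
    bad_sex = ~df["sex"].isin(SEXES)
    if bad_sex.any():
        row = int(np.flatnonzero(bad_sex.to_numpy())[0]) + 1
        raise TableValidationError(f"row {row}: unknown sex {df['sex'].iloc[row-1]!r}")
    bad_measure = ~df["measure"].isin(MEASURES)
    if bad_measure.any():
        row = int(np.flatnonzero(bad_measure.to_numpy())[0]) + 1
        raise TableValidationError(f"row {row}: unknown measure {df['measure'].iloc[row-1]!r}")
    for col, pred, msg in (("M", df["M"] <= 0, "M must be > 0"),
                           ("S", df["S"] <= 0, "S must be > 0")):
        if pred.any():
            row = int(np.flatnonzero(pred.to_numpy())[0]) + 1
            raise TableValidationError(f"row {row}: {msg}")
    for (sex, measure), grp in df.groupby(["sex", "measure"], sort=False):
        ages = grp["age_months"].to_numpy()
        if np.any(np.diff(ages) <= 0):
            raise TableValidationError(
                f"age_months not strictly increasing within ({sex}, {measure})"
            )
    return df.reset_index(drop=True)


class GrowthReference:
    """LMS growth reference with linear age interpolation in L, M and S."""

    def __init__(self, table: pd.DataFrame):
        self.table = load_growth_reference(table)
        self._grids: dict[tuple[str, str], tuple[np.ndarray, ...]] = {}
        for (sex, measure), grp in self.table.groupby(["sex", "measure"], sort=False):
            self._grids[(sex, measure)] = (
                grp["age_months"].to_numpy(float),
                grp["L"].to_numpy(float),
                grp["M"].to_numpy(float),
                grp["S"].to_numpy(float),
            )

    def age_span(self, sex: str, measure: str) -> tuple[float, float]:
        ages = self._grids[(sex, measure)][0]
        return float(ages[0]), float(ages[-1])

    def lms_params(self, sex: str, age_months: float, measure: str):
        """Interpolated (L, M, S) at ``age_months`` for one sex and measure."""
        L, M, S = self.lms_params_bulk(np.array([sex]), np.array([age_months]), measure)
        return float(L[0]), float(M[0]), float(S[0])

    def lms_params_bulk(self, sex: np.ndarray, age_months: np.ndarray, measure: str):
        sex = np.asarray(sex)
        age_months = np.asarray(age_months, dtype=float)
        L = np.empty_like(age_months)
        M = np.empty_like(age_months)
        S = np.empty_like(age_months)
        for s in np.unique(sex):
            key = (str(s), measure)
            if key not in self._grids:
                raise AgeOutOfRangeError(f"no reference rows for {key}")
            ages, Lg, Mg, Sg = self._grids[key]
            mask = sex == s
            a = age_months[mask]
            if np.any(a < ages[0]) or np.any(a > ages[-1]):
                raise AgeOutOfRangeError(
                    f"age outside reference span [{ages[0]}, {ages[-1]}] months for {key}"
                )
            L[mask] = np.interp(a, ages, Lg)
            M[mask] = np.interp(a, ages, Mg)
            S[mask] = np.interp(a, ages, Sg)
        return L, M, S

    def zscore(self, sex: str, age_months: float, measure: str, value: float) -> float:
        L, M, S = self.lms_params(sex, age_months, measure)
        return lms_zscore(value, L, M, S)

    def zscore_bulk(self, sex, age_months, measure: str, values) -> np.ndarray:
        L, M, S = self.lms_params_bulk(np.asarray(sex), np.asarray(age_months), measure)
        return np.asarray(lms_zscore(np.asarray(values, dtype=float), L, M, S))

    def height_percentile(self, sex: str, age_months: float, height_cm: float) -> float:
        z = self.zscore(sex, age_months, "height_for_age", height_cm)
        return percentile_from_z(z)

    def height_percentile_bulk(self, sex, age_months, height_cm) -> np.ndarray:
        z = self.zscore_bulk(sex, age_months, "height_for_age", height_cm)
        return np.asarray(percentile_from_z(z))


def height_percentile(sex, age_months, height_cm, growth_ref) -> float:
    """Height-for-age percentile via LMS interpolation and the normal CDF."""
    if not isinstance(growth_ref, GrowthReference):
        growth_ref = GrowthReference(growth_ref)
    return growth_ref.height_percentile(sex, age_months, height_cm)


# ---------------------------------------------------------------------------
# BP reference tables
# ---------------------------------------------------------------------------

def load_bp_reference(path_or_df) -> pd.DataFrame:
    """Load and validate a guideline BP reference table.

    Enforces: value strictly increasing in bp_percentile and non-decreasing in
    height_percentile at fixed other keys.  A violation is a table error.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df)
    missing = [c for c in BP_REF_COLUMNS if c not in df.columns]
    if missing:
        raise TableValidationError(f"BP reference missing columns {missing}")
    for col, allowed in (
        ("guideline", GUIDELINES),
        ("sex", SEXES),
        ("metric", METRICS),
        ("bp_percentile", BP_PCT_LEVELS),
        ("height_percentile", HEIGHT_PCT_GRID),
    ):
        bad = ~df[col].isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise TableValidationError(
                f"row {row}: {col}={df[col].iloc[row-1]!r} not in {allowed}"
            )
    key = ["guideline", "sex", "age_years", "metric"]
    srt = df.sort_values(key + ["height_percentile", "bp_percentile"])
    for keys, grp in srt.groupby(key + ["height_percentile"], sort=False):
        v = grp["value"].to_numpy(float)
        if np.any(np.diff(v) <= 0):
            raise TableValidationError(
                f"value not strictly increasing in bp_percentile at {keys}"
            )
    srt2 = df.sort_values(key + ["bp_percentile", "height_percentile"])
    for keys, grp in srt2.groupby(key + ["bp_percentile"], sort=False):
        v = grp["value"].to_numpy(float)
        if np.any(np.diff(v) < 0):
            raise TableValidationError(
                f"value decreasing in height_percentile at {keys}"
            )
    return df.reset_index(drop=True)


class BPReferenceTable:
    """Indexed guideline BP normative table with height-percentile interpolation."""

    def __init__(self, table: pd.DataFrame):
        self.table = load_bp_reference(table)
        # (guideline, sex, age, metric, bp_pct) -> value array over HEIGHT_PCT_GRID
        self._cells: dict[tuple, np.ndarray] = {}
        piv = self.table.pivot_table(
            index=["guideline", "sex", "age_years", "metric", "bp_percentile"],
            columns="height_percentile", values="value",
        )
        for idx, row in piv.iterrows():
            vals = row.reindex(HEIGHT_PCT_GRID).to_numpy(float)
            if np.any(np.isnan(vals)):
                raise TableValidationError(
                    f"incomplete height-percentile grid at {idx}"
                )
            self._cells[idx] = vals

    def value(self, guideline, sex, age_years, height_pct, metric, bp_pct) -> float:
        """Interpolated normative value; height_pct clamps to [5, 95]."""
        key = (guideline, sex, int(age_years), metric, int(bp_pct))
        if key not in self._cells:
            raise TableIncompleteError(
                f"BP reference has no rows for guideline={guideline!r}, sex={sex!r}, "
                f"age_years={age_years}, metric={metric!r}, bp_percentile={bp_pct}"
            )
        grid = np.asarray(HEIGHT_PCT_GRID, dtype=float)
        h = min(max(float(height_pct), grid[0]), grid[-1])
        return float(np.interp(h, grid, self._cells[key]))

    def value_bulk(self, guideline, sex, age_years, height_pct, metric, bp_pct):
        """Vectorized :meth:`value` over aligned arrays of sex/age/height_pct."""
        sex = np.asarray(sex)
        age_years = np.asarray(age_years, dtype=int)
        height_pct = np.asarray(height_pct, dtype=float)
        out = np.empty(len(height_pct), dtype=float)
        grid = np.asarray(HEIGHT_PCT_GRID, dtype=float)
        h = np.clip(height_pct, grid[0], grid[-1])
        combos = pd.DataFrame({"sex": sex, "age": age_years})
        for (s, a), idx in combos.groupby(["sex", "age"], sort=False).groups.items():
            key = (guideline, s, int(a), metric, int(bp_pct))
            if key not in self._cells:
                raise TableIncompleteError(
                    f"BP reference has no rows for guideline={guideline!r}, sex={s!r}, "
                    f"age_years={a}, metric={metric!r}, bp_percentile={bp_pct}"
                )
            out[np.asarray(idx)] = np.interp(h[np.asarray(idx)], grid, self._cells[key])
        return out


def bp_percentile_value(table, guideline, sex, age_years, height_pct, metric, bp_pct):
    """Normative BP value looked up from a table (DataFrame or BPReferenceTable)."""
    if not isinstance(table, BPReferenceTable):
        table = BPReferenceTable(table)
    return table.value(guideline, sex, age_years, height_pct, metric, bp_pct)


# ---------------------------------------------------------------------------
# Static rules and threshold resolution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StaticRule:
    guideline: str
    age_min_years: int
    age_max_years: int
    elevated_sbp: float
    elevated_dbp: float
    htn_sbp: float
    htn_dbp: float

    def __post_init__(self):
        if self.elevated_sbp > self.htn_sbp or self.elevated_dbp > self.htn_dbp:
            raise ValueError("elevated thresholds must not exceed hypertension thresholds")


@dataclass(frozen=True)
class ThresholdSet:
    """Resolved elevated/hypertension SBP+DBP cutoffs for one person-visit context."""
    elevated_sbp: float
    elevated_dbp: float
    htn_sbp: float
    htn_dbp: float
    provenance: str  # percentile | static | min_of_both

    def __post_init__(self):
        if self.elevated_sbp > self.htn_sbp or self.elevated_dbp > self.htn_dbp:
            raise ValueError(
                "invalid ThresholdSet: elevated exceeds hypertension cutoff"
            )


# Elevated/prehypertension static floor shared by both guidelines (120/80),
# AAP static band for adolescents >=13 y, and the adult (>=18 y) rule 140/90.
ELEVATED_FLOOR_SBP = 120.0
ELEVATED_FLOOR_DBP = 80.0
AAP_STATIC_HTN_SBP = 130.0
AAP_STATIC_HTN_DBP = 80.0
ADULT_HTN_SBP = 140.0
ADULT_HTN_DBP = 90.0


def default_static_rules() -> tuple[StaticRule, ...]:
    """The guidelines' printed static bands: AAP >=13 y and the adult rule."""
    return (
        StaticRule(GUIDELINE_AAP, 13, 17,
                   ELEVATED_FLOOR_SBP, ELEVATED_FLOOR_DBP,
                   AAP_STATIC_HTN_SBP, AAP_STATIC_HTN_DBP),
        StaticRule(GUIDELINE_FOURTH, 18, 20,
                   ELEVATED_FLOOR_SBP, ELEVATED_FLOOR_DBP,
                   ADULT_HTN_SBP, ADULT_HTN_DBP),
        StaticRule(GUIDELINE_AAP, 18, 20,
                   ELEVATED_FLOOR_SBP, ELEVATED_FLOOR_DBP,
                   ADULT_HTN_SBP, ADULT_HTN_DBP),
    )


def _static_rule_for(static_rules: Sequence[StaticRule], guideline: str, age: int):
    for rule in static_rules:
        if rule.guideline == guideline and rule.age_min_years <= age <= rule.age_max_years:
            return rule
    return None


def resolve_thresholds(guideline, sex, age_years, height_pct, tables,
                       static_rules: Sequence[StaticRule] | None = None) -> ThresholdSet:
    """Resolve the guideline's category boundaries for one person-visit context.

    * 2004 Fourth Report, ages 1–17: elevated (prehypertension) cutoffs are the
      minimum of the 90th-percentile value and the 120/80 static floor;
      hypertension is the 95th-percentile value + 5 mmHg.
    * AAP 2017, ages 1–12: elevated = min(90th percentile, 120/80);
      hypertension = min(95th percentile, 130/80).
    * AAP 2017, ages 13–17: static 120/80 elevated, 130/80 hypertension,
      independent of sex and height.
    * Both guidelines, ages 18–20: adult rule — hypertension 140/90, elevated
      keeps the 120/80 floor.
    """
    if static_rules is None:
        static_rules = default_static_rules()
    age = int(age_years)
    if not 1 <= age <= 20:
        raise AgeOutOfRangeError(f"age_years={age_years} outside [1, 20]")
    if guideline not in GUIDELINES:
        raise ValueError(f"unknown guideline {guideline!r}")

    rule = _static_rule_for(static_rules, guideline, age)
    if rule is not None:
        return ThresholdSet(rule.elevated_sbp, rule.elevated_dbp,
                            rule.htn_sbp, rule.htn_dbp, "static")

    if not isinstance(tables, BPReferenceTable):
        tables = BPReferenceTable(tables)
    p90_sbp = tables.value(guideline, sex, age, height_pct, "SBP", 90)
    p90_dbp = tables.value(guideline, sex, age, height_pct, "DBP", 90)
    p95_sbp = tables.value(guideline, sex, age, height_pct, "SBP", 95)
    p95_dbp = tables.value(guideline, sex, age, height_pct, "DBP", 95)

    elev_sbp = min(p90_sbp, ELEVATED_FLOOR_SBP)
    elev_dbp = min(p90_dbp, ELEVATED_FLOOR_DBP)
    if guideline == GUIDELINE_FOURTH:
        return ThresholdSet(elev_sbp, elev_dbp, p95_sbp + 5.0, p95_dbp + 5.0,
                            "min_of_both")
    # AAP 2017, ages 1-12
    return ThresholdSet(elev_sbp, elev_dbp,
                        min(p95_sbp, AAP_STATIC_HTN_SBP),
                        min(p95_dbp, AAP_STATIC_HTN_DBP),
                        "min_of_both")


def resolve_thresholds_bulk(guideline, sex, age_years, height_pct, tables,
                            static_rules: Sequence[StaticRule] | None = None) -> pd.DataFrame:
    """Vectorized :func:`resolve_thresholds` over aligned arrays.

    Returns a DataFrame with columns elevated_sbp, elevated_dbp, htn_sbp,
    htn_dbp aligned with the inputs.
    """
    if static_rules is None:
        static_rules = default_static_rules()
    sex = np.asarray(sex)
    age = np.asarray(age_years, dtype=int)
    hpct = np.asarray(height_pct, dtype=float)
    if np.any(age < 1) or np.any(age > 20):
        raise AgeOutOfRangeError("age_years outside [1, 20]")
    n = len(age)
    out = {k: np.full(n, np.nan) for k in
           ("elevated_sbp", "elevated_dbp", "htn_sbp", "htn_dbp")}

    static_mask = np.zeros(n, dtype=bool)
    for rule in static_rules:
        if rule.guideline != guideline:
            continue
        m = (age >= rule.age_min_years) & (age <= rule.age_max_years)
        out["elevated_sbp"][m] = rule.elevated_sbp
        out["elevated_dbp"][m] = rule.elevated_dbp
        out["htn_sbp"][m] = rule.htn_sbp
        out["htn_dbp"][m] = rule.htn_dbp
        static_mask |= m

    pct = ~static_mask
    if pct.any():
        if not isinstance(tables, BPReferenceTable):
            tables = BPReferenceTable(tables)
        p90s = tables.value_bulk(guideline, sex[pct], age[pct], hpct[pct], "SBP", 90)
        p90d = tables.value_bulk(guideline, sex[pct], age[pct], hpct[pct], "DBP", 90)
        p95s = tables.value_bulk(guideline, sex[pct], age[pct], hpct[pct], "SBP", 95)
        p95d = tables.value_bulk(guideline, sex[pct], age[pct], hpct[pct], "DBP", 95)
        out["elevated_sbp"][pct] = np.minimum(p90s, ELEVATED_FLOOR_SBP)
        out["elevated_dbp"][pct] = np.minimum(p90d, ELEVATED_FLOOR_DBP)
        if guideline == GUIDELINE_FOURTH:
            out["htn_sbp"][pct] = p95s + 5.0
            out["htn_dbp"][pct] = p95d + 5.0
        else:
            out["htn_sbp"][pct] = np.minimum(p95s, AAP_STATIC_HTN_SBP)
            out["htn_dbp"][pct] = np.minimum(p95d, AAP_STATIC_HTN_DBP)

    res = pd.DataFrame(out)
    if ((res["elevated_sbp"] > res["htn_sbp"]) | (res["elevated_dbp"] > res["htn_dbp"])).any():
        raise TableValidationError("resolved thresholds violate elevated <= htn")
    return res
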