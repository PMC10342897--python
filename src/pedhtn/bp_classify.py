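"""Guideline BP category assignment per visit and per person-year of age.

A *person-year* is one person's data inside a single year-of-age window
([k-th birthday, (k+1)-th birthday)).  Under each guideline, a person-year is

* HTN       if >=3 distinct-date occasions have SBP at/above the hypertension
            cutoff, or >=3 have DBP at/above it (the two metrics are tallied
            separately and OR-ed — a mixed 2-SBP + 2-DBP pattern does not
            qualify);
* ELEVATED  by the identical >=3-occasion logic against the elevated cutoffs
            (readings at hypertension level also count toward the elevated
            tally, since the cutoffs are nested);
* NORMAL    otherwise.

Person-years with fewer than 3 distinct-date occasions are *ineligible*: they
can never be classified HTN or ELEVATED, are reported with category NORMAL and
``eligible=False``, and whether they enter rate denominators is a downstream
configuration choice.

Thresholds are resolved per visit from the person's sex, age and height
percentile at that visit, so a person whose height crosses reference columns
mid-year is handled correctly.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_qc import add_age_columns
from .reference_models import (
    GUIDELINES,
    BPReferenceTable,
    GrowthReference,
    StaticRule,
    ThresholdSet,
    default_static_rules,
    resolve_thresholds,
    resolve_thresholds_bulk,
)

CATEGORY_NORMAL = "NORMAL"
CATEGORY_ELEVATED = "ELEVATED"
CATEGORY_HTN = "HTN"
CATEGORIES = (CATEGORY_NORMAL, CATEGORY_ELEVATED, CATEGORY_HTN)

PERSON_YEAR_COLUMNS = [
    "person_id", "age_years", "guideline", "n_occasions",
    "n_sbp_htn", "n_dbp_htn", "n_sbp_elev", "n_dbp_elev",
    "eligible", "category",
]


def classify_visit(sbp: float, dbp: float, thresholds: ThresholdSet) -> str:
    """Single-visit category: HTN beats ELEVATED beats NORMAL."""
    if sbp >= thresholds.htn_sbp or dbp >= thresholds.htn_dbp:
        return CATEGORY_HTN
    if sbp >= thresholds.elevated_sbp or dbp >= thresholds.elevated_dbp:
        return CATEGORY_ELEVATED
    return CATEGORY_NORMAL


@dataclass(frozen=True)
class PersonYearClass:
    person_id: object
    age_years: int
    guideline: str
    n_occasions: int
    n_sbp_htn: int
    n_dbp_htn: int
    n_sbp_elev: int
    n_dbp_elev: int
    eligible: bool
    category: str


class ClassificationEngine:
    """Bundles growth reference, BP tables and static rules for threshold resolution."""

    def __init__(self, growth_ref: GrowthReference, bp_table: BPReferenceTable,
                 static_rules: Sequence[StaticRule] | None = None):
        if not isinstance(growth_ref, GrowthReference):
            growth_ref = GrowthReference(growth_ref)
        if not isinstance(bp_table, BPReferenceTable):
            bp_table = BPReferenceTable(bp_table)
        self.growth_ref = growth_ref
        self.bp_table = bp_table
        self.static_rules = tuple(static_rules) if static_rules is not None \
            else default_static_rules()

    def thresholds_for(self, guideline: str, sex: str, age_years: int,
                       height_cm: float | None = None,
                       age_months: float | None = None,
                       height_pct: float | None = None) -> ThresholdSet:
        if height_pct is None:
            if height_cm is None or age_months is None:
                height_pct = 50.0  # static bands ignore height anyway
            else:
                height_pct = self.growth_ref.height_percentile(sex, age_months, height_cm)
        return resolve_thresholds(guideline, sex, age_years, height_pct,
                                  self.bp_table, self.static_rules)

    def thresholds_frame(self, visits: pd.DataFrame, guideline: str) -> pd.DataFrame:
        """Vectorized per-visit thresholds; visits need sex, age_years, age_months, height_cm."""
        hpct = self.growth_ref.height_percentile_bulk(
            visits["sex"].to_numpy(), visits["age_months"].to_numpy(),
            visits["height_cm"].to_numpy(),
        )
        res = resolve_thresholds_bulk(
            guideline, visits["sex"].to_numpy(), visits["age_years"].to_numpy(),
            hpct, self.bp_table, self.static_rules,
        )
        res.index = visits.index
        res["height_pct"] = hpct
        return res


def collapse_same_day(visits: pd.DataFrame, policy: str = "first") -> pd.DataFrame:
    """Collapse same-person same-date repeat readings to one occasion."""
    df = visits.sort_values(["person_id", "visit_date"])
    day = df["visit_date"].dt.normalize()
    if policy == "first":
        return df.loc[~pd.DataFrame({"p": df["person_id"], "d": day}).duplicated().to_numpy()]
    if policy == "mean":
        grp = df.groupby(["person_id", day.rename("day")], sort=False)
        first = grp.head(1).copy()
        means = grp[["sbp", "dbp"]].transform("mean")
        first[["sbp", "dbp"]] = means.loc[first.index]
        return first
    raise ValueError(f"unknown same-day policy {policy!r}")


def classify_person_year(visits: pd.DataFrame, guideline: str,
                         engine: ClassificationEngine,
                         min_occasions: int = 3,
                         same_day: str = "first") -> PersonYearClass:
    """Classify one person's visits within one year of age under one guideline."""
    if visits["person_id"].nunique() != 1:
        raise ValueError("classify_person_year expects a single person's visits")
    df = visits if "age_months" in visits.columns else add_age_columns(visits)
    if df["age_years"].nunique() != 1:
        raise ValueError("classify_person_year expects a single age-year of visits")
    df = collapse_same_day(df, same_day)
    thr = engine.thresholds_frame(df, guideline)
    n = len(df)
    sbp = df["sbp"].to_numpy(float)
    dbp = df["dbp"].to_numpy(float)
    n_sh = int((sbp >= thr["htn_sbp"].to_numpy()).sum())
    n_dh = int((dbp >= thr["htn_dbp"].to_numpy()).sum())
    n_se = int((sbp >= thr["elevated_sbp"].to_numpy()).sum())
    n_de = int((dbp >= thr["elevated_dbp"].to_numpy()).sum())
    eligible = n >= min_occasions
    if eligible and (n_sh >= min_occasions or n_dh >= min_occasions):
        cat = CATEGORY_HTN
    elif eligible and (n_se >= min_occasions or n_de >= min_occasions):
        cat = CATEGORY_ELEVATED
    else:
        cat = CATEGORY_NORMAL
    return PersonYearClass(df["person_id"].iloc[0], int(df["age_years"].iloc[0]),
                           guideline, n, n_sh, n_dh, n_se, n_de, eligible, cat)


def classify_cohort(records: pd.DataFrame, engine: ClassificationEngine,
                    guidelines: Sequence[str] = GUIDELINES,
                    min_occasions: int = 3,
                    same_day: str = "first") -> pd.DataFrame:
    """Person-year classification table for a cleaned cohort, both guidelines.

    One row per (person, age-year, guideline) with >=1 occasion; deterministic
    given input content (rows are sorted by person and date first).
    """
    if len(records) == 0:
        return pd.DataFrame(columns=PERSON_YEAR_COLUMNS)
    df = records if "age_months" in records.columns else add_age_columns(records)
    bad_sex = ~df["sex"].isin(("male", "female"))
    if bad_sex.any():
        rows = np.flatnonzero(bad_sex.to_numpy())[:5] + 1
        raise ValueError(f"unknown sex codes at record rows {list(rows)}")
    df = collapse_same_day(df.sort_values(["person_id", "visit_date"]), same_day)

    out_frames = []
    for guideline in guidelines:
        thr = engine.thresholds_frame(df, guideline)
        flags = pd.DataFrame({
            "person_id": df["person_id"].to_numpy(),
            "age_years": df["age_years"].to_numpy(),
            "sbp_htn": (df["sbp"].to_numpy(float) >= thr["htn_sbp"].to_numpy()),
            "dbp_htn": (df["dbp"].to_numpy(float) >= thr["htn_dbp"].to_numpy()),
            "sbp_elev": (df["sbp"].to_numpy(float) >= thr["elevated_sbp"].to_numpy()),
            "dbp_elev": (df["dbp"].to_numpy(float) >= thr["elevated_dbp"].to_numpy()),
        })
        agg = flags.groupby(["person_id", "age_years"], sort=True).agg(
            n_occasions=("sbp_htn", "size"),
            n_sbp_htn=("sbp_htn", "sum"),
            n_dbp_htn=("dbp_htn", "sum"),
            n_sbp_elev=("sbp_elev", "sum"),
            n_dbp_elev=("dbp_elev", "sum"),
        ).reset_index()
        agg["guideline"] = guideline
        agg["eligible"] = agg["n_occasions"] >= min_occasions
        htn = agg["eligible"] & ((agg["n_sbp_htn"] >= min_occasions)
                                 | (agg["n_dbp_htn"] >= min_occasions))
        elev = agg["eligible"] & ~htn & ((agg["n_sbp_elev"] >= min_occasions)
                                         | (agg["n_dbp_elev"] >= min_occasions))
        agg["category"] = np.select([htn, elev], [CATEGORY_HTN, CATEGORY_ELEVATED],
                                    default=CATEGORY_NORMAL)
        out_frames.append(agg)
    out = pd.concat(out_frames, ignore_index=True)
    return out[PERSON_YEAR_COLUMNS]
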