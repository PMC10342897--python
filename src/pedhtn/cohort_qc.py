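"""EHR cohort construction and quality filters with attrition accounting.

The cleaning pipeline mirrors a typical outpatient-BP surveillance flow:

1. keep only visits where both SBP and DBP were recorded at the same occasion;
2. keep only visits with a height measurement (height is the lookup key for
   the percentile-based BP thresholds);
3. drop visits whose height- or weight-for-age z-score falls outside +/-6 SD
   of the growth reference (EHR data-entry errors);
4. drop physiologically implausible BP readings
   (SBP > 240, SBP < 60, DBP > 160 or DBP < 30 mmHg);
5. drop persons with fewer than 3 separate measurement occasions at least one
   day apart over the study period.

All exclusion inequalities are strict exactly as printed in the source
guidance: a z-score of exactly +/-6.0, or a BP of exactly 240/60/160/30, is
retained.  Every stage's record- and person-level counts are accumulated in an
:class:`AttritionReport` whose conservation invariant
(input = kept + excluded) is asserted.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .reference_models import GrowthReference

VISIT_COLUMNS = [
    "person_id", "visit_date", "sex", "birth_date",
    "sbp", "dbp", "height_cm", "weight_kg", "setting",
]


@dataclass(frozen=True)
class QCConfig:
    """Bounds and toggles for the cleaning pipeline (defaults as printed)."""
    sbp_max: float = 240.0
    sbp_min: float = 60.0
    dbp_max: float = 160.0
    dbp_min: float = 30.0
    growth_z_bound: float = 6.0
    min_occasions: int = 3
    min_gap_days: int = 1
    height_exclusion: str = "visit"   # "visit" | "person"
    same_day: str = "first"           # "first" | "mean"


@dataclass
class StageCount:
    stage: str
    records_in: int
    records_excluded: int
    persons_in: int
    persons_excluded: int

    @property
    def records_out(self) -> int:
        return self.records_in - self.records_excluded

    @property
    def persons_out(self) -> int:
        return self.persons_in - self.persons_excluded


@dataclass
class AttritionReport:
    """Ordered stage-by-stage accounting of the QC exclusions."""
    stages: list[StageCount] = field(default_factory=list)

    def add(self, stage: str, df_in: pd.DataFrame, kept: pd.DataFrame,
            excluded: pd.DataFrame) -> None:
        n_in, n_kept, n_exc = len(df_in), len(kept), len(excluded)
        if n_in != n_kept + n_exc:
            raise AssertionError(
                f"stage {stage!r}: {n_in} records in != {n_kept} kept + {n_exc} excluded"
            )
        p_in = df_in["person_id"].nunique()
        p_out = kept["person_id"].nunique()
        self.stages.append(StageCount(stage, n_in, n_exc, p_in, p_in - p_out))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.stage, s.records_in, s.records_excluded, s.records_out,
              s.persons_in, s.persons_excluded, s.persons_out)
             for s in self.stages],
            columns=["stage", "records_in", "records_excluded", "records_out",
                     "persons_in", "persons_excluded", "persons_out"],
        )

    def log_lines(self) -> list[str]:
        return [
            f"{s.stage}: {s.records_in} records in, {s.records_excluded} excluded "
            f"({s.persons_in} persons in, {s.persons_excluded} dropped)"
            for s in self.stages
        ]


# ---------------------------------------------------------------------------
# Record loading / derived columns
# ---------------------------------------------------------------------------

def load_visits(path_or_df) -> pd.DataFrame:
    """Load a visit-record file (delimited text, ISO-8601 dates)."""
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df)
    missing = [c for c in VISIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"visit records missing columns {missing}")
    df["visit_date"] = pd.to_datetime(df["visit_date"])
    df["birth_date"] = pd.to_datetime(df["birth_date"])
    return df


def add_age_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Attach integer age attained (years and whole months) at each visit.

    Age in years k means the visit falls in [k-th birthday, (k+1)-th birthday).
    """
    df = df.copy()
    v = df["visit_date"]
    b = df["birth_date"]
    years = v.dt.year - b.dt.year
    before = (v.dt.month < b.dt.month) | ((v.dt.month == b.dt.month) & (v.dt.day < b.dt.day))
    df["age_years"] = (years - before.astype(int)).astype(int)
    months = (v.dt.year - b.dt.year) * 12 + (v.dt.month - b.dt.month)
    df["age_months"] = (months - (v.dt.day < b.dt.day).astype(int)).astype(int)
    return df


# ---------------------------------------------------------------------------
# Individual filters (each returns kept, excluded)
# ---------------------------------------------------------------------------

def require_complete_bp(records: pd.DataFrame):
    """Keep visits where both SBP and DBP were measured at the same occasion."""
    ok = records["sbp"].notna() & records["dbp"].notna()
    return records[ok], records[~ok]


def require_height(records: pd.DataFrame, level: str = "visit"):
    """Keep visits carrying a height measurement.

    ``level="visit"`` drops only height-less visits (a person vanishes when no
    visit survives); ``level="person"`` drops every visit of a person with any
    height-less visit.
    """
    has_h = records["height_cm"].notna()
    if level == "visit":
        return records[has_h], records[~has_h]
    if level == "person":
        bad_persons = set(records.loc[~has_h, "person_id"])
        ok = ~records["person_id"].isin(bad_persons)
        return records[ok], records[~ok]
    raise ValueError(f"unknown height_exclusion level {level!r}")


def filter_growth_outliers(records: pd.DataFrame, growth_ref: GrowthReference,
                           bound: float = 6.0):
    """Drop visits whose height- or weight-for-age z exceeds the +/-bound band.

    Exclusion is strict (< -bound or > +bound); a z of exactly +/-bound is kept.
    Weight is only checked where present.
    """
    if len(records) == 0:
        return records, records
    df = records if "age_months" in records.columns else add_age_columns(records)
    # strict boundary with a hair of numerical slack so a measurement that is
    # exactly +/-bound SD survives the float round-trip
    tol = bound * 1e-9
    zh = growth_ref.zscore_bulk(df["sex"].to_numpy(), df["age_months"].to_numpy(),
                                "height_for_age", df["height_cm"].to_numpy())
    bad = (zh < -(bound + tol)) | (zh > bound + tol)
    has_w = df["weight_kg"].notna().to_numpy()
    if has_w.any():
        zw = growth_ref.zscore_bulk(
            df.loc[has_w, "sex"].to_numpy(),
            df.loc[has_w, "age_months"].to_numpy(),
            "weight_for_age",
            df.loc[has_w, "weight_kg"].to_numpy(),
        )
        bad_w = np.zeros(len(df), dtype=bool)
        bad_w[has_w] = (zw < -(bound + tol)) | (zw > bound + tol)
        bad = bad | bad_w
    return records[~bad], records[bad]


def filter_bp_outliers(records: pd.DataFrame, config: QCConfig = QCConfig()):
    """Drop implausible BP readings; bounds are inclusive (strict exclusion)."""
    ok = (
        (records["sbp"] <= config.sbp_max) & (records["sbp"] >= config.sbp_min)
        & (records["dbp"] <= config.dbp_max) & (records["dbp"] >= config.dbp_min)
    )
    return records[ok], records[~ok]


def min_occasions_filter(records: pd.DataFrame, k: int = 3, min_gap_days: int = 1):
    """Keep persons with >= k measurement occasions pairwise >= min_gap_days apart.

    With the default 1-day gap this is simply >= k distinct calendar dates.
    For larger gaps the maximal qualifying subset is found greedily over the
    sorted distinct dates (greedy-earliest is optimal for interval spacing).
    """
    if len(records) == 0:
        return records, records

    def n_spaced(dates: np.ndarray) -> int:
        days = np.sort(np.unique(dates.astype("datetime64[D]")))
        if min_gap_days <= 1:
            return len(days)
        count, last = 0, None
        for d in days:
            if last is None or (d - last) >= np.timedelta64(min_gap_days, "D"):
                count += 1
                last = d
        return count

    counts = records.groupby("person_id")["visit_date"].agg(
        lambda s: n_spaced(s.to_numpy())
    )
    keep_ids = set(counts[counts >= k].index)
    ok = records["person_id"].isin(keep_ids)
    return records[ok], records[~ok]


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_qc(records: pd.DataFrame, growth_ref: GrowthReference,
           config: QCConfig = QCConfig()):
    """Apply all filters in the fixed order and account for every exclusion.

    Order: complete BP -> height present -> growth outliers -> BP outliers ->
    minimum occasions.  Returns (cleaned records, AttritionReport).
    """
    report = AttritionReport()
    df = records if "age_months" in records.columns else add_age_columns(load_visits(records))

    stages: list[tuple[str, Callable]] = [
        ("complete_bp", lambda d: require_complete_bp(d)),
        ("height_present", lambda d: require_height(d, config.height_exclusion)),
        ("growth_outliers", lambda d: filter_growth_outliers(d, growth_ref, config.growth_z_bound)),
        ("bp_outliers", lambda d: filter_bp_outliers(d, config)),
        ("min_occasions", lambda d: min_occasions_filter(d, config.min_occasions, config.min_gap_days)),
    ]
    for name, fn in stages:
        kept, excluded = fn(df)
        report.add(name, df, kept, excluded)
        df = kept
    return df.reset_index(drop=True), report
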