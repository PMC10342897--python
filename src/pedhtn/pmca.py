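"""Pediatric Medical Complexity Algorithm (conservative variant), code-map driven.

Each person-year's diagnosis history over the year preceding an index date is
reduced to a set of *qualified conditions*: a condition (a mapped body system,
possibly flagged progressive and/or malignant) qualifies when mapped ICD-9/10
codes appear on at least two distinct outpatient/emergency encounter dates
inside the lookback window, or on at least one inpatient-discharge record.
Matching is longest-prefix against a user-supplied code map; the published
PMCA v2.0 code lists are not bundled — the module ships only the documented
schema (and the synthetic map used by the tests).

The qualified set maps to three complexity levels:

* complex chronic disease      — >=2 distinct body systems, or any progressive
                                 condition, or malignancy;
* non-complex chronic disease  — exactly one body system, no flags;
* without chronic disease      — empty set.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

BODY_SYSTEMS = (
    "cardiac", "craniofacial", "dermatological", "endocrinological",
    "gastrointestinal", "genetic", "genitourinary", "hematological",
    "immunological", "malignancy", "mental_health", "metabolic",
    "musculoskeletal", "neurological", "ophthalmological", "otologic",
    "pulmonary_respiratory", "renal",
)

LEVEL_COMPLEX = "complex_cd"
LEVEL_NON_COMPLEX = "non_complex_cd"
LEVEL_WITHOUT = "without_cd"

CODE_MAP_COLUMNS = ["icd_version", "code_prefix", "body_system",
                    "progressive", "malignancy"]
ENCOUNTER_COLUMNS = ["person_id", "date", "setting", "icd_version", "code"]

OUTPATIENT_SETTINGS = frozenset({"outpatient", "emergency"})
INPATIENT_SETTING = "inpatient_discharge"


class QualifiedCondition(NamedTuple):
    body_system: str
    progressive: bool
    malignancy: bool


@dataclass
class ComplexityResult:
    person_id: object
    index_date: pd.Timestamp
    level: str
    body_systems: frozenset
    progressive: bool
    malignancy: bool


@dataclass
class CodeMap:
    """Longest-prefix ICD code matcher built from a delimited map file."""
    table: pd.DataFrame
    _by_version: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        df = self.table
        missing = [c for c in CODE_MAP_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"code map missing columns {missing}")
        if (df["code_prefix"].astype(str).str.len() == 0).any():
            raise ValueError("empty code_prefix in code map")
        dup = df.duplicated(subset=["icd_version", "code_prefix"])
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0]) + 1
            raise ValueError(f"row {row}: duplicate (icd_version, code_prefix)")
        bad = ~df["body_system"].isin(BODY_SYSTEMS)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ValueError(
                f"row {row}: unknown body_system {df['body_system'].iloc[row-1]!r}"
            )
        for ver, grp in df.groupby("icd_version"):
            entries = {
                str(r.code_prefix): QualifiedCondition(
                    r.body_system, bool(r.progressive), bool(r.malignancy))
                for r in grp.itertuples()
            }
            self._by_version[int(ver)] = (entries,
                                          max(len(p) for p in entries))

    def match(self, icd_version: int, code: str) -> QualifiedCondition | None:
        """Longest-prefix match of a diagnosis code; None when unmapped."""
        got = self._by_version.get(int(icd_version))
        if got is None:
            return None
        entries, maxlen = got
        code = str(code)
        for k in range(min(len(code), maxlen), 0, -1):
            hit = entries.get(code[:k])
            if hit is not None:
                return hit
        return None


def load_code_map(path_or_df) -> CodeMap:
    if isinstance(path_or_df, pd.DataFrame):
        return CodeMap(path_or_df.copy())
    return CodeMap(pd.read_csv(path_or_df))


def load_encounters(path_or_df) -> pd.DataFrame:
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df)
    missing = [c for c in ENCOUNTER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"encounter records missing columns {missing}")
    df["date"] = pd.to_datetime(df["date"])
    return df


def qualified_conditions(encounters: pd.DataFrame, code_map: CodeMap,
                         index_date, lookback_days: int = 365,
                         diagnostics: dict | None = None) -> frozenset:
    """Qualified (body_system, progressive, malignancy) set for one person.

    The lookback window is half-open: [index - lookback_days, index).
    Unmapped codes are ignored (tallied in ``diagnostics`` when provided).
    """
    index_date = pd.Timestamp(index_date)
    lo = index_date - pd.Timedelta(days=lookback_days)
    win = encounters[(encounters["date"] >= lo) & (encounters["date"] < index_date)]
    outpatient_dates: dict[QualifiedCondition, set] = {}
    inpatient_hits: set[QualifiedCondition] = set()
    unmapped = 0
    for row in win.itertuples():
        cond = code_map.match(row.icd_version, row.code)
        if cond is None:
            unmapped += 1
            continue
        if row.setting in OUTPATIENT_SETTINGS:
            outpatient_dates.setdefault(cond, set()).add(
                pd.Timestamp(row.date).normalize())
        elif row.setting == INPATIENT_SETTING:
            inpatient_hits.add(cond)
    qualified = {c for c, dates in outpatient_dates.items() if len(dates) >= 2}
    qualified |= inpatient_hits
    if diagnostics is not None:
        diagnostics["unmapped_codes"] = diagnostics.get("unmapped_codes", 0) + unmapped
    return frozenset(qualified)


def pmca_level(qualified: Iterable[QualifiedCondition],
               person_id=None, index_date=None) -> ComplexityResult:
    """Collapse a qualified-condition set into a complexity level."""
    qualified = frozenset(qualified)
    systems = frozenset(c.body_system for c in qualified)
    progressive = any(c.progressive for c in qualified)
    malignancy = any(c.malignancy for c in qualified)
    if len(systems) >= 2 or progressive or malignancy:
        level = LEVEL_COMPLEX
    elif len(systems) == 1:
        level = LEVEL_NON_COMPLEX
    else:
        level = LEVEL_WITHOUT
        systems = frozenset()
    return ComplexityResult(person_id, index_date, level, systems,
                            progressive, malignancy)


def classify_complexity(encounters: pd.DataFrame, code_map: CodeMap,
                        index_dates: pd.DataFrame,
                        lookback_days: int = 365) -> pd.DataFrame:
    """Complexity level per (person, index_date) row of ``index_dates``.

    ``index_dates`` needs columns person_id and index_date (typically the
    first OBP visit of each person's age-year).
    """
    by_person = dict(tuple(encounters.groupby("person_id")))
    empty = encounters.iloc[0:0]
    rows = []
    diagnostics: dict = {}
    for rec in index_dates.itertuples():
        enc = by_person.get(rec.person_id, empty)
        q = qualified_conditions(enc, code_map, rec.index_date,
                                 lookback_days, diagnostics)
        res = pmca_level(q, rec.person_id, rec.index_date)
        rows.append((rec.person_id, rec.index_date, res.level,
                     ";".join(sorted(res.body_systems)),
                     res.progressive, res.malignancy))
    out = pd.DataFrame(rows, columns=["person_id", "index_date", "level",
                                      "body_systems", "progressive", "malignancy"])
    out.attrs["unmapped_codes"] = diagnostics.get("unmapped_codes", 0)
    return out


def utilization_summary(encounters: pd.DataFrame, index_date,
                        lookback_days: int = 365) -> tuple[int, int, int]:
    """(outpatient visits, ED visits, hospitalizations) in [index - lookback, index).

    Hospitalizations are counted per discharge record on distinct dates.
    """
    index_date = pd.Timestamp(index_date)
    lo = index_date - pd.Timedelta(days=lookback_days)
    win = encounters[(encounters["date"] >= lo) & (encounters["date"] < index_date)]
    day = win["date"].dt.normalize()
    n_out = int(win.loc[win["setting"] == "outpatient"]
                .assign(day=day).drop_duplicates(["day"]).shape[0])
    n_ed = int(win.loc[win["setting"] == "emergency"]
               .assign(day=day).drop_duplicates(["day"]).shape[0])
    n_hosp = int(win.loc[win["setting"] == INPATIENT_SETTING]
                 .assign(day=day).drop_duplicates(["day"]).shape[0])
    return n_out, n_ed, n_hosp
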