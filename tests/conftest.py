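import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pedhtn.bp_classify import ClassificationEngine
from pedhtn.reference_models import (
    BP_PCT_LEVELS,
    HEIGHT_PCT_GRID,
    BPReferenceTable,
    GrowthReference,
)
from pedhtn.synthetic_data import gen_bp_reference, gen_code_map, gen_growth_reference

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def growth_ref() -> GrowthReference:
    return gen_growth_reference(0)


@pytest.fixture(scope="session")
def bp_table() -> BPReferenceTable:
    return gen_bp_reference(0)


@pytest.fixture(scope="session")
def engine(growth_ref, bp_table) -> ClassificationEngine:
    return ClassificationEngine(growth_ref, bp_table)


@pytest.fixture(scope="session")
def code_map():
    return gen_code_map(0)


def make_flat_bp_table(p50_sbp=100, p90_sbp=110, p95_sbp=115,
                       p50_dbp=60, p90_dbp=70, p95_dbp=75,
                       ages=range(1, 18)) -> BPReferenceTable:
    """Tiny valid table with height-constant percentile values, both guidelines."""
    rows = []
    vals = {("SBP", 50): p50_sbp, ("SBP", 90): p90_sbp, ("SBP", 95): p95_sbp,
            ("DBP", 50): p50_dbp, ("DBP", 90): p90_dbp, ("DBP", 95): p95_dbp}
    for g in ("fourth_2004", "aap_2017"):
        for sex in ("male", "female"):
            for age in ages:
                for hp in HEIGHT_PCT_GRID:
                    for metric in ("SBP", "DBP"):
                        for bp_pct in BP_PCT_LEVELS:
                            rows.append((g, sex, age, hp, metric, bp_pct,
                                         float(vals[(metric, bp_pct)])))
    return BPReferenceTable(pd.DataFrame(rows, columns=[
        "guideline", "sex", "age_years", "height_percentile",
        "metric", "bp_percentile", "value"]))


def make_visits(rows) -> pd.DataFrame:
    """Visit frame from (person_id, visit_date, sex, birth_date, sbp, dbp, height, weight) tuples."""
    df = pd.DataFrame(rows, columns=["person_id", "visit_date", "sex",
                                     "birth_date", "sbp", "dbp",
                                     "height_cm", "weight_kg"])
    df["visit_date"] = pd.to_datetime(df["visit_date"])
    df["birth_date"] = pd.to_datetime(df["birth_date"])
    df["setting"] = "outpatient"
    return df
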