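"""Synthetic EHR generator with known ground truth.

Everything the pipeline consumes can be generated here: LMS growth references,
guideline BP reference tables, multi-year outpatient visit panels, and ICD
diagnosis histories.  The generator is the package's test bed — it emulates
the *structure* of a pediatric outpatient EHR (age-dependent BP, heights and
weights with injected outliers and missingness, a controllable latent
hypertension prevalence per person-year, diagnosis code histories), not any
particular population's calibration.

Ground-truth person-year categories are planted relative to the thresholds the
classification engine itself resolves, jointly for both guidelines, and BP
values keep a configurable safety margin (default +/-2 mmHg) away from every
threshold so the intended label is unambiguous.  Labels are recorded before
defect injection; person-years touched by an injected defect are flagged.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bp_classify import (
    CATEGORY_ELEVATED,
    CATEGORY_HTN,
    CATEGORY_NORMAL,
    ClassificationEngine,
)
from .cohort_qc import add_age_columns
from .pmca import BODY_SYSTEMS, CodeMap
from .reference_models import (
    BP_PCT_LEVELS,
    GUIDELINE_AAP,
    GUIDELINE_FOURTH,
    GUIDELINES,
    HEIGHT_PCT_GRID,
    BPReferenceTable,
    GrowthReference,
)
from scipy.stats import norm


class ConfigError(ValueError):
    """An infeasible or inconsistent simulation configuration."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate a decade-long outpatient panel: ages 1-20, window
    2009-2018, ~2.8 visits per observed person-year and ~2-3 observed
    age-years per person, with hypertension/elevated planted per person-year
    at rates of a few per 1000.
    """
    n_persons: int = 2000
    study_start_year: int = 2009
    study_end_year: int = 2018
    age_range: tuple[int, int] = (1, 20)
    htn_prevalence: float = 0.005
    elevated_prevalence: float = 0.003
    visits_per_year_mean: float = 2.8
    years_observed_mean: float = 2.7
    missing_height_rate: float = 0.05
    bp_outlier_rate: float = 0.002
    growth_outlier_rate: float = 0.001
    condition_rates: dict = field(default_factory=lambda: {s: 0.02 for s in BODY_SYSTEMS})
    progressive_rate: float = 0.3   # P(progressive code | condition in a progressive-capable system)
    threshold_margin: float = 2.0   # mmHg clearance from every category boundary
    seed: int = 0

    def validate(self) -> None:
        for name in ("htn_prevalence", "elevated_prevalence", "missing_height_rate",
                     "bp_outlier_rate", "growth_outlier_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.htn_prevalence + self.elevated_prevalence > 1.0:
            raise ConfigError("htn_prevalence + elevated_prevalence > 1")
        if self.n_persons <= 0:
            raise ConfigError("n_persons must be > 0")
        if self.visits_per_year_mean <= 0:
            raise ConfigError("visits_per_year_mean must be > 0")
        if self.visits_per_year_mean < 3 and \
                (self.htn_prevalence > 0 or self.elevated_prevalence > 0) and \
                self.visits_per_year_mean < 1:
            raise ConfigError("cannot plant cases with <1 visit per year")
        lo, hi = self.age_range
        if not (1 <= lo <= hi <= 20):
            raise ConfigError("age_range must lie within [1, 20]")


@dataclass
class GroundTruth:
    """Planted labels, recorded before defect injection."""
    person_years: pd.DataFrame   # person_id, age_years, category, metric, defect
    conditions: pd.DataFrame     # person_id, body_system, progressive, malignancy
    complexity: pd.DataFrame     # person_id, level


# ---------------------------------------------------------------------------
# Growth reference
# ---------------------------------------------------------------------------

def gen_growth_reference(seed: int = 0) -> GrowthReference:
    """Smooth monotone synthetic LMS reference over ages 12-250 months.

    All rows use L = 1, so z = (x - M)/(M*S) in closed form, which makes
    hand-derivable test cases easy.  Deterministic for any seed.
    """
    ages = np.arange(12, 251, 2, dtype=float)
    rows = []
    for sex, (h_inf, h_amp, h_tau) in (("male", (172.0, 96.0, 75.0)),
                                       ("female", (162.0, 88.0, 72.0))):
        h_m = h_inf - h_amp * np.exp(-ages / h_tau)
        w_m = 9.0 + 0.12 * ages + 0.0004 * ages ** 2
        b_m = 15.2 + 0.000055 * (ages - 60.0) ** 2
        for a, m in zip(ages, h_m):
            rows.append((sex, int(a), "height_for_age", 1.0, round(m, 3), 0.045))
        for a, m in zip(ages, w_m):
            rows.append((sex, int(a), "weight_for_age", 1.0, round(m, 3), 0.11))
        for a, m in zip(ages, b_m):
            rows.append((sex, int(a), "bmi_for_age", 1.0, round(m, 3), 0.12))
    df = pd.DataFrame(rows, columns=["sex", "age_months", "measure", "L", "M", "S"])
    return GrowthReference(df)


# ---------------------------------------------------------------------------
# BP reference tables
# ---------------------------------------------------------------------------

# Gaussian normative model: BP percentile p at (sex, age, height z) is
# mu(age, sex) + c*z_height + z_p * sigma.  The same generating model feeds
# both guideline tables, so inter-guideline differences come purely from the
# guidelines' rules (95th+5 vs min(95th, 130/80), static bands).
_SBP_MODEL = dict(intercept=85.0, age_slope=2.4, height_coef=2.5, sigma=16.0,
                  sex_shift={"male": 0.5, "female": -0.5})
_DBP_MODEL = dict(intercept=45.0, age_slope=1.9, height_coef=1.2, sigma=12.0,
                  sex_shift={"male": 0.3, "female": -0.3})


def _normative_value(metric: str, sex: str, age: float, z_height: float,
                     bp_pct: float) -> float:
    m = _SBP_MODEL if metric == "SBP" else _DBP_MODEL
    mu = (m["intercept"] + m["age_slope"] * age + m["height_coef"] * z_height
          + m["sex_shift"][sex])
    return mu + norm.ppf(bp_pct / 100.0) * m["sigma"]


def gen_bp_reference(seed: int = 0, style: str = "aap_dominant") -> BPReferenceTable:
    """Synthetic guideline BP tables over ages 1-17 and the height grid.

    ``style="aap_dominant"`` guarantees that at ages 13-17 the AAP static
    hypertension cutoffs (130/80) sit at or below the 2004 rule's 95th
    percentile + 5 mmHg everywhere on the grid, so the AAP flags a superset of
    adolescents — the direction of reclassification seen in practice.
    Deterministic for any seed.
    """
    if style not in ("aap_dominant",):
        raise ConfigError(f"unknown table style {style!r}")
    rows = []
    for guideline in GUIDELINES:
        for sex in ("male", "female"):
            for age in range(1, 18):
                for hp in HEIGHT_PCT_GRID:
                    zh = norm.ppf(hp / 100.0)
                    for metric in ("SBP", "DBP"):
                        for bp_pct in BP_PCT_LEVELS:
                            v = _normative_value(metric, sex, age, zh, bp_pct)
                            rows.append((guideline, sex, age, hp, metric,
                                         bp_pct, round(v, 2)))
    table = BPReferenceTable(pd.DataFrame(rows, columns=[
        "guideline", "sex", "age_years", "height_percentile",
        "metric", "bp_percentile", "value"]))
    if style == "aap_dominant":
        _assert_aap_dominant(table)
    return table


def _assert_aap_dominant(table: BPReferenceTable) -> None:
    for sex in ("male", "female"):
        for age in range(13, 18):
            for hp in HEIGHT_PCT_GRID:
                p95s = table.value(GUIDELINE_FOURTH, sex, age, hp, "SBP", 95)
                p95d = table.value(GUIDELINE_FOURTH, sex, age, hp, "DBP", 95)
                if not (130.0 <= p95s + 5.0 and 80.0 <= p95d + 5.0):
                    raise ConfigError(
                        f"aap_dominant violated at ({sex}, {age}, {hp})"
                    )


# ---------------------------------------------------------------------------
# Code map
# ---------------------------------------------------------------------------

_CODE_MAP_SPEC = {
    # system: (icd10 prefixes, icd9 prefixes, progressive-capable, malignancy)
    "cardiac": (["I2", "I42", "Q21"], ["414", "425"], True, False),
    "craniofacial": (["Q35", "Q37"], ["749"], False, False),
    "dermatological": (["L10", "Q80"], ["694"], False, False),
    "endocrinological": (["E10", "E11", "E03"], ["250"], False, False),
    "gastrointestinal": (["K50", "K51", "K74"], ["555"], True, False),
    "genetic": (["Q90", "Q91"], ["758"], True, False),
    "genitourinary": (["N25", "Q64"], ["753"], False, False),
    "hematological": (["D56", "D57", "D61"], ["282"], True, False),
    "immunological": (["D80", "D81"], ["279"], True, False),
    "malignancy": (["C91", "C71", "C40"], ["204"], False, True),
    "mental_health": (["F20", "F84"], ["295"], False, False),
    "metabolic": (["E70", "E71", "E88"], ["270"], True, False),
    "musculoskeletal": (["M08", "Q77"], ["714"], False, False),
    "neurological": (["G40", "G71", "G80"], ["345"], True, False),
    "ophthalmological": (["H35", "Q12"], ["362"], False, False),
    "otologic": (["H90", "Q16"], ["389"], False, False),
    "pulmonary_respiratory": (["E84", "J44"], ["277"], True, False),
    "renal": (["N18", "Q61"], ["585"], True, False),
}


def gen_code_map(seed: int = 0) -> CodeMap:
    """Synthetic ICD prefix map covering all 18 PMCA body systems.

    For every progressive-capable system, the *last* ICD-10 prefix is flagged
    progressive, so generated histories can plant progressive disease
    deterministically.  Deterministic for any seed.
    """
    rows = []
    for system, (icd10, icd9, prog_capable, malig) in _CODE_MAP_SPEC.items():
        for i, pfx in enumerate(icd10):
            progressive = prog_capable and (i == len(icd10) - 1)
            rows.append((10, pfx, system, progressive, malig))
        for pfx in icd9:
            rows.append((9, pfx, system, False, malig))
    return CodeMap(pd.DataFrame(rows, columns=[
        "icd_version", "code_prefix", "body_system", "progressive", "malignancy"]))


def progressive_prefix(system: str) -> str | None:
    icd10, _, prog, _ = _CODE_MAP_SPEC[system]
    return icd10[-1] if prog else None


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

def _safe_dates(rng: np.random.Generator, n: int) -> np.ndarray:
    """n distinct day-of-year offsets in [0, 364] (>=1-day spacing built in)."""
    return np.sort(rng.choice(365, size=n, replace=False))


def gen_cohort(config: SimConfig, engine: ClassificationEngine | None = None):
    """Generate (visits, encounters, GroundTruth) for a SimConfig.

    Latent model: each person gets a stable height z-track; each observed
    person-year draws a category (HTN / ELEVATED / NORMAL) at the configured
    prevalences.  BP readings for flagged person-years are emitted so that
    >=3 distinct-date occasions clear the *joint* (both-guideline) threshold
    band by at least ``threshold_margin`` mmHg; normal person-years stay below
    every elevated cutoff by the same margin.  Defects (missing height, BP
    outliers, growth outliers) are injected afterwards at the configured
    per-visit rates.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if engine is None:
        engine = ClassificationEngine(gen_growth_reference(config.seed),
                                      gen_bp_reference(config.seed))
    growth = engine.growth_ref
    margin = config.threshold_margin

    lo_age, hi_age = config.age_range
    n = config.n_persons
    sexes = np.where(rng.random(n) < 0.5, "male", "female")
    height_z = np.clip(rng.normal(0.0, 1.0, n), -2.2, 2.2)

    n_window_years = config.study_end_year - config.study_start_year + 1
    years_obs = 1 + rng.poisson(max(config.years_observed_mean - 1.0, 0.0), n)
    years_obs = np.clip(years_obs, 1, min(hi_age - lo_age + 1, n_window_years))
    start_age = lo_age + (rng.random(n) * (hi_age - lo_age + 1 - years_obs)).astype(int)
    cal_start = config.study_start_year + (
        rng.random(n) * (n_window_years - years_obs + 1)).astype(int)
    birth_doy = rng.integers(0, 365, n)  # day offset into a non-leap year

    # --- visit skeleton -----------------------------------------------------
    pid_l, age_l, date_l, sex_l, hz_l = [], [], [], [], []
    py_pid, py_age, py_nvis = [], [], []
    ref_day0 = pd.Timestamp("2001-01-01")  # non-leap month/day template
    birth_dates = {}
    for i in range(n):
        pid = f"P{i:05d}"
        md = ref_day0 + pd.Timedelta(days=int(birth_doy[i]))
        birth_year = cal_start[i] - start_age[i]
        birth_dates[pid] = pd.Timestamp(year=birth_year, month=md.month, day=md.day)
        for k in range(years_obs[i]):
            age = int(start_age[i] + k)
            nv = int(rng.poisson(config.visits_per_year_mean))
            nv = max(nv, 1)
            py_pid.append(pid)
            py_age.append(age)
            py_nvis.append(nv)
    # person-year categories; cases are forced to >=3 visits so the planted
    # label is attainable
    n_py = len(py_pid)
    u = rng.random(n_py)
    cat = np.where(u < config.htn_prevalence, CATEGORY_HTN,
                   np.where(u < config.htn_prevalence + config.elevated_prevalence,
                            CATEGORY_ELEVATED, CATEGORY_NORMAL))
    idx_of_person = {f"P{i:05d}": i for i in range(n)}
    for j in range(n_py):
        if cat[j] != CATEGORY_NORMAL and py_nvis[j] < 3:
            py_nvis[j] = 3
        pid = py_pid[j]
        i = idx_of_person[pid]
        birthday_k = _birthday(birth_dates[pid], py_age[j])
        offs = _safe_dates(rng, py_nvis[j])
        for o in offs:
            pid_l.append(pid)
            age_l.append(py_age[j])
            date_l.append(birthday_k + pd.Timedelta(days=int(o)))
            sex_l.append(sexes[i])
            hz_l.append(height_z[i])

    visits = pd.DataFrame({
        "person_id": pid_l,
        "visit_date": pd.to_datetime(date_l),
        "sex": sex_l,
        "birth_date": [birth_dates[p] for p in pid_l],
        "setting": "outpatient",
    })
    visits = add_age_columns(visits)
    hz = np.asarray(hz_l)

    # anthropometrics from the growth reference (L=1 closed form)
    Lh, Mh, Sh = growth.lms_params_bulk(visits["sex"].to_numpy(),
                                        visits["age_months"].to_numpy(),
                                        "height_for_age")
    visits["height_cm"] = np.round(Mh * (1.0 + hz * Sh), 1)
    Lw, Mw, Sw = growth.lms_params_bulk(visits["sex"].to_numpy(),
                                        visits["age_months"].to_numpy(),
                                        "weight_for_age")
    wz = np.clip(0.6 * hz + rng.normal(0.0, 0.6, len(visits)), -3.5, 3.5)
    visits["weight_kg"] = np.round(Mw * (1.0 + wz * Sw), 1)

    # --- BP values against joint thresholds ---------------------------------
    thr = {g: engine.thresholds_frame(visits, g) for g in GUIDELINES}
    elev_sbp_hi = np.maximum(thr[GUIDELINE_FOURTH]["elevated_sbp"],
                             thr[GUIDELINE_AAP]["elevated_sbp"]).to_numpy()
    elev_sbp_lo = np.minimum(thr[GUIDELINE_FOURTH]["elevated_sbp"],
                             thr[GUIDELINE_AAP]["elevated_sbp"]).to_numpy()
    elev_dbp_lo = np.minimum(thr[GUIDELINE_FOURTH]["elevated_dbp"],
                             thr[GUIDELINE_AAP]["elevated_dbp"]).to_numpy()
    htn_sbp_lo = np.minimum(thr[GUIDELINE_FOURTH]["htn_sbp"],
                            thr[GUIDELINE_AAP]["htn_sbp"]).to_numpy()
    htn_sbp_hi = np.maximum(thr[GUIDELINE_FOURTH]["htn_sbp"],
                            thr[GUIDELINE_AAP]["htn_sbp"]).to_numpy()
    htn_dbp_hi = np.maximum(thr[GUIDELINE_FOURTH]["htn_dbp"],
                            thr[GUIDELINE_AAP]["htn_dbp"]).to_numpy()

    py_key = pd.MultiIndex.from_arrays([py_pid, py_age])
    cat_by_py = pd.Series(cat, index=py_key)
    visit_py = pd.MultiIndex.from_arrays([visits["person_id"], visits["age_years"]])
    vcat = cat_by_py.reindex(visit_py).to_numpy()

    # metric driving a hypertensive person-year: 70% SBP, 30% DBP
    metric_by_py = pd.Series(
        np.where(rng.random(n_py) < 0.7, "SBP", "DBP"), index=py_key)
    vmetric = metric_by_py.reindex(visit_py).to_numpy()

    nv = len(visits)
    sbp = np.empty(nv)
    dbp = np.empty(nv)
    # normal draws (also the non-driving metric of cases)
    sbp_norm = rng.uniform(np.maximum(72.0, elev_sbp_lo - margin - 22.0),
                           elev_sbp_lo - margin, nv)
    dbp_norm = rng.uniform(np.maximum(38.0, elev_dbp_lo - margin - 18.0),
                           elev_dbp_lo - margin, nv)
    sbp[:] = sbp_norm
    dbp[:] = dbp_norm

    m_htn = vcat == CATEGORY_HTN
    m_htn_s = m_htn & (vmetric == "SBP")
    m_htn_d = m_htn & (vmetric == "DBP")
    sbp[m_htn_s] = np.minimum(
        htn_sbp_hi[m_htn_s] + margin + rng.exponential(4.0, m_htn_s.sum()), 238.0)
    dbp[m_htn_d] = np.minimum(
        htn_dbp_hi[m_htn_d] + margin + rng.exponential(3.0, m_htn_d.sum()), 158.0)

    # Elevated readings sit strictly inside the joint band (above both
    # guidelines' elevated cutoffs, below both hypertension cutoffs).  The
    # band is always positive on a valid table, but can narrow below twice
    # the default margin where the 120 mmHg static floor crosses the
    # percentile curves; there the clearance adapts to a third of the width.
    m_elev = vcat == CATEGORY_ELEVATED
    band_lo = elev_sbp_hi[m_elev]
    band_hi = htn_sbp_lo[m_elev]
    width = band_hi - band_lo
    if np.any(width <= 0.5):
        raise ConfigError("degenerate elevated band in the BP reference table")
    clearance = np.minimum(margin, width / 3.0)
    sbp[m_elev] = rng.uniform(band_lo + clearance, band_hi - clearance)

    # integer rounding cannot cross a boundary: normals sit > margin below,
    # cases are ceiled upward, elevated readings keep 0.1 mmHg precision
    # (clearance >= 0.1 by construction)
    visits["sbp"] = np.round(sbp, 0)
    visits["dbp"] = np.round(dbp, 0)
    visits.loc[m_htn_s, "sbp"] = np.ceil(sbp[m_htn_s])
    visits.loc[m_htn_d, "dbp"] = np.ceil(dbp[m_htn_d])
    visits.loc[m_elev, "sbp"] = np.round(sbp[m_elev], 1)

    # --- defect injection ----------------------------------------------------
    d = rng.random(nv)
    p1, p2, p3 = (config.missing_height_rate, config.bp_outlier_rate,
                  config.growth_outlier_rate)
    miss_h = d < p1
    bp_out = (d >= p1) & (d < p1 + p2)
    gr_out = (d >= p1 + p2) & (d < p1 + p2 + p3)
    visits.loc[miss_h, "height_cm"] = np.nan
    half = rng.random(nv) < 0.5
    visits.loc[bp_out & half, "sbp"] = 250.0
    visits.loc[bp_out & ~half, "dbp"] = 25.0
    visits.loc[gr_out, "height_cm"] = np.round((Mh * (1.0 + 7.0 * Sh))[gr_out], 1)
    visits["defect"] = np.select(
        [miss_h, bp_out, gr_out],
        ["missing_height", "bp_outlier", "growth_outlier"], default="")

    defect_py = visits.loc[visits["defect"] != "", ["person_id", "age_years"]]
    defect_keys = set(map(tuple, defect_py.to_numpy()))
    truth_py = pd.DataFrame({
        "person_id": [p for p in py_pid],
        "age_years": py_age,
        "category": cat,
        "metric": metric_by_py.to_numpy(),
        "n_visits": py_nvis,
    })
    truth_py["defect"] = [
        (p, a) in defect_keys for p, a in zip(truth_py["person_id"],
                                              truth_py["age_years"])]

    # --- diagnosis histories -------------------------------------------------
    encounters, conditions, complexity = _gen_encounters(
        rng, visits, config, idx_of_person)

    truth = GroundTruth(truth_py, conditions, complexity)
    visit_cols = ["person_id", "visit_date", "sex", "birth_date", "sbp", "dbp",
                  "height_cm", "weight_kg", "setting", "defect"]
    return visits[visit_cols + ["age_years", "age_months"]], encounters, truth


def _birthday(birth_date: pd.Timestamp, age: int) -> pd.Timestamp:
    try:
        return birth_date.replace(year=birth_date.year + age)
    except ValueError:  # Feb 29 guard (birth template is non-leap, but be safe)
        return birth_date.replace(year=birth_date.year + age, day=28)


def _gen_encounters(rng, visits: pd.DataFrame, config: SimConfig,
                    idx_of_person: dict):
    """Plant per-person chronic conditions and emit qualifying encounters.

    Conditions anchor to the person's first OBP visit: qualifying encounters
    fall inside the 365-day lookback before it, so PMCA at that index date
    recovers the planted set exactly.
    """
    first_visit = visits.groupby("person_id")["visit_date"].min()
    rows = []
    cond_rows = []
    systems = list(config.condition_rates.keys())
    for pid, index_date in first_visit.items():
        planted = [s for s in systems
                   if rng.random() < config.condition_rates[s]]
        for system in planted:
            icd10, icd9, prog_capable, malig = _CODE_MAP_SPEC[system]
            progressive = prog_capable and rng.random() < config.progressive_rate
            pfx = icd10[-1] if progressive else icd10[0]
            code = pfx + str(rng.integers(0, 10))
            if rng.random() < 0.3:
                day = index_date - pd.Timedelta(days=int(rng.integers(10, 300)))
                rows.append((pid, day, "inpatient_discharge", 10, code))
            else:
                d1, d2 = rng.choice(np.arange(10, 300), size=2, replace=False)
                rows.append((pid, index_date - pd.Timedelta(days=int(d1)),
                             "outpatient", 10, code))
                rows.append((pid, index_date - pd.Timedelta(days=int(d2)),
                             "outpatient", 10, code))
            cond_rows.append((pid, system, progressive, malig))
        # background utilization with unmapped codes
        for _ in range(int(rng.poisson(1.5))):
            day = index_date - pd.Timedelta(days=int(rng.integers(1, 360)))
            rows.append((pid, day, "outpatient", 10,
                         "Z" + str(rng.integers(10, 99))))
    encounters = pd.DataFrame(rows, columns=["person_id", "date", "setting",
                                             "icd_version", "code"])
    conditions = pd.DataFrame(cond_rows, columns=["person_id", "body_system",
                                                  "progressive", "malignancy"])
    # planted complexity level per person (PMCA rules applied to the plan)
    lev_rows = []
    for pid in first_visit.index:
        sub = conditions[conditions["person_id"] == pid]
        n_sys = sub["body_system"].nunique()
        prog = bool(sub["progressive"].any())
        malig = bool(sub["malignancy"].any())
        if n_sys >= 2 or prog or malig:
            level = "complex_cd"
        elif n_sys == 1:
            level = "non_complex_cd"
        else:
            level = "without_cd"
        lev_rows.append((pid, level))
    complexity = pd.DataFrame(lev_rows, columns=["person_id", "level"])
    return encounters, conditions, complexity
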