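"""Generate the synthetic study inputs: references, visit panel, diagnoses.

Emulates a decade of outpatient pediatric care (2009-2018, ages 1-20) for
2000 persons with hypertension planted in 5 per 1000 person-years and
elevated BP in 3 per 1000, plus realistic data defects (missing heights, BP
and growth outliers).  Raw tables land under scratch/data/ (large,
regenerable); a small summary of what was generated lands in results/.
"""
import sys
from pathlib import Path

import pandas as pd

from pedhtn.bp_classify import ClassificationEngine
from pedhtn.synthetic_data import (
    SimConfig,
    gen_bp_reference,
    gen_code_map,
    gen_cohort,
    gen_growth_reference,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
DATA = Path("scratch/data")
RESULTS = Path("results")


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    growth = gen_growth_reference(SEED)
    bp = gen_bp_reference(SEED)
    engine = ClassificationEngine(growth, bp)
    cfg = SimConfig(seed=SEED)
    visits, encounters, truth = gen_cohort(cfg, engine)

    growth.table.to_csv(DATA / "growth_reference.csv", index=False)
    bp.table.to_csv(DATA / "bp_reference.csv", index=False)
    gen_code_map(SEED).table.to_csv(DATA / "code_map.csv", index=False)
    visits.to_csv(DATA / "visits.csv", index=False)
    encounters.to_csv(DATA / "encounters.csv", index=False)
    truth.person_years.to_csv(DATA / "truth_person_years.csv", index=False)
    truth.conditions.to_csv(DATA / "truth_conditions.csv", index=False)
    truth.complexity.to_csv(DATA / "truth_complexity.csv", index=False)

    summary = pd.DataFrame([
        ("persons", cfg.n_persons),
        ("person_years", len(truth.person_years)),
        ("visits", len(visits)),
        ("encounters", len(encounters)),
        ("planted_htn_person_years",
         int((truth.person_years["category"] == "HTN").sum())),
        ("planted_elevated_person_years",
         int((truth.person_years["category"] == "ELEVATED").sum())),
        ("seed", SEED),
    ], columns=["quantity", "value"])
    summary.to_csv(RESULTS / "01_simulation_summary.csv", index=False)
    print(summary.to_string(index=False))
    print(f"\nraw tables in {DATA}/")


if __name__ == "__main__":
    main()
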