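"""Clean the visit panel and account for every exclusion.

Applies the fixed filter order (complete BP, height present, +/-6 SD growth
z-scores, BP plausibility bounds, >=3 distinct-date occasions) and writes the
attrition table — the synthetic counterpart of a study-population flowchart.
"""
from pathlib import Path

import pandas as pd

from pedhtn.cohort_qc import load_visits, run_qc
from pedhtn.reference_models import GrowthReference

DATA = Path("scratch/data")
RESULTS = Path("results")


def main() -> None:
    visits = load_visits(DATA / "visits.csv")
    growth = GrowthReference(pd.read_csv(DATA / "growth_reference.csv"))
    clean, report = run_qc(visits, growth)
    clean.to_csv(DATA / "visits_clean.csv", index=False)
    frame = report.to_frame()
    frame.to_csv(RESULTS / "02_attrition.csv", index=False)
    print(frame.to_string(index=False))
    survivors = clean["person_id"].nunique()
    print(f"\n{survivors} persons with >=3 separate occasions retained; "
          f"cleaned visits in {DATA / 'visits_clean.csv'}")


if __name__ == "__main__":
    main()
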