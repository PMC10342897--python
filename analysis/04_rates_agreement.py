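"""Event rates per 1000 persons, inter-guideline agreement, annual trend.

Produces the comparison table (cases and rates per age group under each rule
set, Cohen's kappa with 95% CI, percent agreement) and the calendar-year rate
series for both guidelines.
"""
from pathlib import Path

import pandas as pd

from pedhtn.cohort_qc import add_age_columns, load_visits
from pedhtn.epi_stats import annual_rate_series, rate_agreement_table

DATA = Path("scratch/data")
RESULTS = Path("results")


def main() -> None:
    py = pd.read_csv(DATA / "person_years.csv")
    visits = add_age_columns(load_visits(DATA / "visits_clean.csv"))

    table = rate_agreement_table(py, age_groups=((1, 7), (8, 12), (13, 17), (18, 20)))
    table.to_csv(RESULTS / "04_rate_agreement.csv", index=False)
    print(table.to_string(index=False))

    series = annual_rate_series(py, visits)
    series.to_csv(RESULTS / "04_annual_rates.csv", index=False)
    print("\nannual hypertension rate per 1000 persons:")
    print(series.pivot(index="year", columns="guideline",
                       values="rate_per_1000").to_string())


if __name__ == "__main__":
    main()
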