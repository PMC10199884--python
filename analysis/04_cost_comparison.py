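#!/usr/bin/env python
"""Annual dermatological costs per person and per claim, by category.

Per-person means average over every person in an arm (non-claimants count
zero euros); differences use Welch two-sided t-tests with 95% CIs.
Writes costs.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from dermclaims import io
from dermclaims.cost_stats import cost_table
from dermclaims.matching import cohort_from_pairs

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    argparse.ArgumentParser().parse_args()
    data = RESULTS / "data"
    insurees = io.read_insurees(data / "insurees.csv")
    claims = io.read_claims(data / "claims.csv")
    pairs = pd.read_csv(RESULTS / "matched_cohort.csv")
    cohort = cohort_from_pairs(pairs, insurees)

    costs = cost_table(claims, cohort)
    costs.round(2).to_csv(RESULTS / "costs.csv", index=False)

    print("mean annual cost per person (users vs controls):")
    for row in costs.itertuples():
        print(f"  {row.category:<24} EUR {row.mean_per_person_users:7.2f} vs "
              f"EUR {row.mean_per_person_controls:7.2f}  "
              f"delta {row.delta:+7.2f} "
              f"({row.delta_ci_low:.2f} to {row.delta_ci_high:.2f}), "
              f"p={row.p_value:.3g}")


if __name__ == "__main__":
    main()
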