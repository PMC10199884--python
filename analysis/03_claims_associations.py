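#!/usr/bin/env python
"""Person-level claims associations: main table and risk-subgroup strata.

Computes, for each diagnosis category, the share of matched users and
controls with at least one claim, the odds ratio with 95% CI, Fisher exact
and two-proportion z p-values, and BH-adjusted p-values; then repeats the
analysis within the high-risk (>=1 high assessment) and low-risk user
subgroups, and the positive-history subcohort.  Writes table2.csv,
table4.csv and table_history.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from dermclaims import io
from dermclaims.claims_stats import (association_table, history_subgroup,
                                     intervention_table, subgroup_tables)
from dermclaims.matching import cohort_from_pairs

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    argparse.ArgumentParser().parse_args()
    data = RESULTS / "data"
    insurees, assessments, claims = io.read_tables(
        data / "insurees.csv", data / "assessments.csv", data / "claims.csv")
    pairs = pd.read_csv(RESULTS / "matched_cohort.csv")
    cohort = cohort_from_pairs(pairs, insurees)
    users = insurees[insurees["arm"] == "user"]

    t2 = association_table(cohort, claims)
    t2.round(2).to_csv(RESULTS / "table2.csv", index=False)
    print("main analysis (odds ratio [95% CI], BH-adjusted Fisher p):")
    for row in t2.itertuples():
        print(f"  {row.category:<24} {row.pct_users:5.2f}% vs "
              f"{row.pct_controls:5.2f}%  OR {row.odds_ratio:.2f} "
              f"({row.ci_low:.2f}-{row.ci_high:.2f})  p={row.p_adjusted:.3g}")

    t3 = intervention_table(cohort, claims)
    t3.round(2).to_csv(RESULTS / "table3.csv", index=False)
    gp = t3.set_index("intervention").loc["gp_biopsy_excision"]
    print(f"GP biopsy/excision: {gp.per1000_users:.2f} vs "
          f"{gp.per1000_controls:.2f} claims per 1000 persons "
          f"(delta {gp.per1000_delta:.2f})")

    t4 = subgroup_tables(cohort, claims, assessments, users)
    t4.round(2).to_csv(RESULTS / "table4.csv", index=False)
    nb = t4.set_index(["stratum", "category"])
    print("risk subgroups, nevi+benign tumors:")
    for stratum in ("high_risk", "low_risk"):
        row = nb.loc[(stratum, "nevus_benign")]
        print(f"  {stratum:<10} OR {row.odds_ratio:.2f} "
              f"({row.ci_low:.2f}-{row.ci_high:.2f})")

    hist = history_subgroup(insurees, cohort)
    th = association_table(hist, claims)
    th.round(2).to_csv(RESULTS / "table_history.csv", index=False)
    print(f"positive-history subcohort: {len(hist.matched_user_ids):,} users")


if __name__ == "__main__":
    main()
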