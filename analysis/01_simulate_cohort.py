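#!/usr/bin/env python
"""Simulate the study-scale synthetic population.

Generates ~2.2M insurees at the default (study) conditions — ~0.86% app
uptake, calibrated assessment-outcome and claim-probability structure —
and writes insurees.csv, assessments.csv and claims.csv under
results/data/.  Prints the cohort's headline marginals.
"""

import argparse
from pathlib import Path

from dermclaims import io
from dermclaims.config import GeneratorConfig
from dermclaims.synthetic import generate_all, high_risk_user_ids

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cfg = GeneratorConfig()
    insurees, assessments, claims = generate_all(cfg, args.seed)

    out = RESULTS / "data"
    out.mkdir(parents=True, exist_ok=True)
    io.write_insurees(insurees, out / "insurees.csv")
    io.write_assessments(assessments, out / "assessments.csv")
    io.write_claims(claims, out / "claims.csv")

    users = insurees[insurees["arm"] == "user"]
    n_high = len(high_risk_user_ids(assessments))
    print(f"population: {len(insurees):,} insurees, {len(users):,} app users "
          f"({100 * len(users) / len(insurees):.2f}%)")
    print(f"assessments: {len(assessments):,} "
          f"({len(assessments) / len(users):.2f} per user); "
          f"{100 * (assessments.cnn_result == 'high').mean():.1f}% CNN high, "
          f"{100 * (assessments.cnn_result == 'failed').mean():.1f}% failed")
    print(f"users with >=1 high-risk assessment: {n_high:,} "
          f"({100 * n_high / len(users):.1f}%)")
    print(f"claims: {len(claims):,}; tables written to {out}")


if __name__ == "__main__":
    main()
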