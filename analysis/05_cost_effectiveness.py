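#!/usr/bin/env python
"""Short-term cost-effectiveness: calibrated ICER surface.

Calibrates the detection-cascade model to the matched cohort's observed
incremental (pre)malignancy and benign claimant rates and costs at the
app's published accuracy (sensitivity 0.87, specificity 0.70), then
evaluates the ICER over a sensitivity x specificity grid.  Writes
icer_surface.csv and a two-panel heat map.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from dermclaims import io
from dermclaims.cea import (calibrate, icer_surface, observed_aggregates,
                            plot_surface)
from dermclaims.config import DEFAULT_APP_COST
from dermclaims.matching import cohort_from_pairs

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--app-cost", type=float, default=DEFAULT_APP_COST,
                    help="app subscription cost per user-year in euros "
                    "(demonstration default; the true price is not public)")
    args = ap.parse_args()

    data = RESULTS / "data"
    insurees = io.read_insurees(data / "insurees.csv")
    claims = io.read_claims(data / "claims.csv")
    pairs = pd.read_csv(RESULTS / "matched_cohort.csv")
    cohort = cohort_from_pairs(pairs, insurees)

    observed = observed_aggregates(cohort, claims)
    params = calibrate(observed, sens0=0.87, spec0=0.70,
                       app_cost_per_user=args.app_cost)
    grid = np.round(np.arange(0.50, 1.0001, 0.05), 10)
    surface = icer_surface(params, grid, grid)

    surface.to_long().round(2).to_csv(RESULTS / "icer_surface.csv",
                                      index=False)
    plot_surface(surface).savefig(RESULTS / "icer_surface.png", dpi=120)

    cal = icer_surface(params, [0.87], [0.70])
    perfect = icer_surface(params, [1.0], [1.0])
    d_det = observed.detected_rate_users - observed.detected_rate_controls
    print(f"incremental detections: {d_det:.4f} per user-year "
          f"(calibrated v*pi*alpha = {params.v_pi_alpha:.4f})")
    print(f"ICER at calibration accuracy (0.87, 0.70): "
          f"EUR {cal.icer_full[0, 0]:,.0f} per extra (pre)malignancy "
          f"detected (benign costs only: EUR {cal.icer_benign_only[0, 0]:,.0f})")
    print(f"ICER at perfect accuracy (1.00, 1.00): "
          f"EUR {perfect.icer_full[0, 0]:,.0f} "
          f"(benign costs only: EUR {perfect.icer_benign_only[0, 0]:,.0f})")
    print(f"surface range: EUR {surface.icer_full.min():,.0f} to "
          f"EUR {surface.icer_full.max():,.0f}")


if __name__ == "__main__":
    main()
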