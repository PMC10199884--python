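"""Short-term cost-effectiveness of the AI skin-check app.

The incremental cost-effectiveness ratio (ICER) is incremental cost over
incremental effectiveness, with the number of unique persons holding a
(pre)malignancy claim as the effectiveness proxy:

    ICER = (cost_intervention - cost_standard) / (eff_intervention - eff_standard)

The accuracy simulation rests on a calibrated detection cascade.  Per
user-year the app induces, on top of background care,

    dN_m(sens) = v * pi * alpha * sens        extra (pre)malignancy claimants
    dN_b(spec) = v * (1-pi) * alpha * (1-spec) extra benign/nevus claimants

where v is lesion volume, pi the prevalence of true (pre)malignancy among
submitted lesions and alpha adherence to the app's advice; only the
products are identifiable, and they are calibrated so that at the
published accuracy point the model reproduces the observed incremental
claimant rates.  Unit costs per incremental claimant come from the
observed incremental costs.  The two surfaces are then

    icer_full(s, q)        = (app_cost + dN_b(q)*c_b + dN_m(s)*c_m) / dN_m(s)
    icer_benign_only(s, q) = (app_cost + dN_b(q)*c_b) / dN_m(s)

i.e. intervention-minus-control arm costs in the numerator (the benign and
(pre)malignancy terms common to both arms cancel), including respectively
all lesion costs or only the false-positive benign costs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CalibrationError, DomainError

__all__ = ["ICERInput", "ICERResult", "ObservedAggregates", "CEAParams",
           "AccuracySurface", "icer", "calibrate", "icer_surface",
           "observed_aggregates", "plot_surface"]


@dataclass(frozen=True)
class ICERInput:
    """Costs and effectiveness per arm, in consistent units (totals or
    per-person)."""

    cost_intervention: float
    cost_standard: float
    eff_intervention: float
    eff_standard: float


@dataclass(frozen=True)
class ICERResult:
    value: float
    dominant: bool = False    # negative ICER (cheaper and more effective,
    #                           or costlier and less effective)
    undefined: bool = False   # zero incremental effectiveness


def icer(inp: ICERInput) -> ICERResult:
    """Incremental cost-effectiveness ratio, sign preserved."""
    d_eff = inp.eff_intervention - inp.eff_standard
    d_cost = inp.cost_intervention - inp.cost_standard
    if d_eff == 0:
        return ICERResult(np.nan, undefined=True)
    value = d_cost / d_eff
    return ICERResult(float(value), dominant=value < 0)


@dataclass(frozen=True)
class ObservedAggregates:
    """Arm-level observed quantities feeding the calibration, all per
    person-year: claimant rates for (pre)malignancies and benign
    lesions (nevi + benign tumors), and the matching per-person costs."""

    detected_rate_users: float
    detected_rate_controls: float
    benign_rate_users: float
    benign_rate_controls: float
    cost_pm_users: float
    cost_pm_controls: float
    cost_benign_users: float
    cost_benign_controls: float


@dataclass(frozen=True)
class CEAParams:
    """Calibrated detection-cascade parameters (see module docstring)."""

    app_cost_per_user: float
    v_pi_alpha: float        # v * pi * alpha
    v_1mpi_alpha: float      # v * (1 - pi) * alpha
    unit_cost_malignant: float
    unit_cost_benign: float
    sens0: float
    spec0: float

    def delta_detected(self, sens):
        return self.v_pi_alpha * np.asarray(sens, dtype=float)

    def delta_benign(self, spec):
        return self.v_1mpi_alpha * (1.0 - np.asarray(spec, dtype=float))


def observed_aggregates(cohort, claims) -> ObservedAggregates:
    """Compute the calibration aggregates from a matched cohort and its
    claims table."""
    from .claims_stats import persons_with_claim
    from .cost_stats import per_person_costs
    from .schema import BENIGN_NEVUS, PREMALIGNANT_MALIGNANT

    users = cohort.matched_user_ids
    controls = cohort.control_ids
    nu, nc = len(users), len(controls)
    if nu == 0 or nc == 0:
        raise DomainError("both arms must be non-empty")
    return ObservedAggregates(
        detected_rate_users=persons_with_claim(
            claims, users, PREMALIGNANT_MALIGNANT) / nu,
        detected_rate_controls=persons_with_claim(
            claims, controls, PREMALIGNANT_MALIGNANT) / nc,
        benign_rate_users=persons_with_claim(claims, users, BENIGN_NEVUS) / nu,
        benign_rate_controls=persons_with_claim(
            claims, controls, BENIGN_NEVUS) / nc,
        cost_pm_users=float(np.mean(per_person_costs(
            claims, users, PREMALIGNANT_MALIGNANT))),
        cost_pm_controls=float(np.mean(per_person_costs(
            claims, controls, PREMALIGNANT_MALIGNANT))),
        cost_benign_users=float(np.mean(per_person_costs(
            claims, users, BENIGN_NEVUS))),
        cost_benign_controls=float(np.mean(per_person_costs(
            claims, controls, BENIGN_NEVUS))),
    )


def calibrate(observed: ObservedAggregates, sens0: float, spec0: float,
              app_cost_per_user: float) -> CEAParams:
    """Solve the cascade products and unit costs from observed increments.

    At the calibration accuracy point (sens0, spec0) the model reproduces
    the observed incremental claimant rates and costs exactly.
    """
    if not (0 < sens0 <= 1) or not (0 <= spec0 < 1):
        raise CalibrationError(
            "calibration needs sens0 in (0, 1] and spec0 in [0, 1)")
    dn_m = observed.detected_rate_users - observed.detected_rate_controls
    dn_b = observed.benign_rate_users - observed.benign_rate_controls
    if dn_m <= 0 or dn_b <= 0:
        raise CalibrationError(
            "calibration requires positive incremental (pre)malignancy and "
            f"benign claimant rates (got {dn_m:.3g}, {dn_b:.3g})")
    d_cost_m = observed.cost_pm_users - observed.cost_pm_controls
    d_cost_b = observed.cost_benign_users - observed.cost_benign_controls
    return CEAParams(
        app_cost_per_user=app_cost_per_user,
        v_pi_alpha=dn_m / sens0,
        v_1mpi_alpha=dn_b / (1.0 - spec0),
        unit_cost_malignant=d_cost_m / dn_m,
        unit_cost_benign=d_cost_b / dn_b,
        sens0=sens0,
        spec0=spec0,
    )


@dataclass(frozen=True)
class AccuracySurface:
    """ICER grids over sensitivity (rows) and specificity (columns)."""

    sens: np.ndarray
    spec: np.ndarray
    icer_full: np.ndarray
    icer_benign_only: np.ndarray

    def to_long(self) -> pd.DataFrame:
        s, q = np.meshgrid(self.sens, self.spec, indexing="ij")
        return pd.DataFrame({
            "sens": s.ravel(), "spec": q.ravel(),
            "icer_full": self.icer_full.ravel(),
            "icer_benign_only": self.icer_benign_only.ravel(),
        })

    def at(self, sens: float, spec: float):
        i = int(np.argmin(np.abs(self.sens - sens)))
        j = int(np.argmin(np.abs(self.spec - spec)))
        return self.icer_full[i, j], self.icer_benign_only[i, j]


def icer_surface(params: CEAParams, sens_grid, spec_grid) -> AccuracySurface:
    """Evaluate both ICER surfaces on the sensitivity x specificity grid.

    Zero sensitivity yields no incremental detections: the ICER there is
    infinite (flagged by the value itself, not an error).
    """
    sens = np.asarray(sens_grid, dtype=float)
    spec = np.asarray(spec_grid, dtype=float)
    dn_m = params.delta_detected(sens)[:, None]
    dn_b = params.delta_benign(spec)[None, :]
    a = params.app_cost_per_user
    with np.errstate(divide="ignore"):
        num_b = a + dn_b * params.unit_cost_benign
        full = (num_b + dn_m * params.unit_cost_malignant) / dn_m
        benign_only = np.broadcast_to(num_b, full.shape) / dn_m
    return AccuracySurface(sens, spec, full, benign_only)


def plot_surface(surface: AccuracySurface):
    """Two-panel heat map of the ICER surfaces (all costs / benign-only)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(11, 4.5), constrained_layout=True)
    extent = [surface.spec[0], surface.spec[-1],
              surface.sens[0], surface.sens[-1]]
    for ax, grid, title in (
            (axes[0], surface.icer_full, "All lesion costs"),
            (axes[1], surface.icer_benign_only, "Benign lesion costs only")):
        im = ax.imshow(grid, origin="lower", aspect="auto", extent=extent,
                       cmap="viridis")
        ax.set_xlabel("Specificity")
        ax.set_ylabel("Sensitivity")
        ax.set_title(title)
        fig.colorbar(im, ax=ax, label="ICER (EUR per extra detection)")
    return fig
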