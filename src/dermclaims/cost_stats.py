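"""Annual dermatological cost comparisons between matched arms.

Per-person costs average over *all* persons in an arm (persons without
claims contribute zero), per the definition of average annual cost per
person; per-claim costs average over claims.  Group differences use the
Welch unequal-variance t-test by default (configurable to Student's).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError
from .matching import MatchedCohort
from .schema import CATEGORIES

__all__ = ["CostSummary", "per_person_costs", "annual_cost_per_person",
           "mean_cost_per_claim", "cost_table"]


@dataclass(frozen=True)
class CostSummary:
    category: str
    mean_per_person_users: float
    mean_per_person_controls: float
    delta: float
    delta_ci: tuple
    p_value: float
    mean_per_claim_users: float | None
    mean_per_claim_controls: float | None


def _category_mask(claims: pd.DataFrame, category):
    if category is None or category == "all":
        return np.ones(len(claims), dtype=bool)
    cats = (category,) if isinstance(category, str) else tuple(category)
    unknown = set(cats) - set(CATEGORIES)
    if unknown:
        raise DomainError(f"unknown claim categories: {sorted(unknown)}")
    return claims["category"].isin(cats).to_numpy()


def per_person_costs(claims: pd.DataFrame, person_ids,
                     category=None) -> np.ndarray:
    """Total annual cost per person over ``person_ids`` (zeros included)."""
    person_ids = np.asarray(person_ids)
    mask = _category_mask(claims, category)
    sub = claims[mask]
    totals = sub.groupby("person_id")["cost"].sum()
    return totals.reindex(person_ids, fill_value=0.0).to_numpy()


def _var(x):
    return x.var(ddof=1) if len(x) > 1 else 0.0


def _welch_ci(x, y, alpha=0.05):
    nx, ny = len(x), len(y)
    vx, vy = _var(x), _var(y)
    se2 = vx / nx + vy / ny
    if se2 == 0:
        return (0.0, 0.0)
    # a zero-variance arm contributes nothing to the Welch df denominator
    d1 = (vx / nx) ** 2 / (nx - 1) if nx > 1 else 0.0
    d2 = (vy / ny) ** 2 / (ny - 1) if ny > 1 else 0.0
    df = se2 ** 2 / (d1 + d2)
    t = stats.t.ppf(1 - alpha / 2, df)
    d = x.mean() - y.mean()
    half = t * np.sqrt(se2)
    return (float(d - half), float(d + half))


def annual_cost_per_person(claims: pd.DataFrame, cohort: MatchedCohort,
                           category=None, welch: bool = True) -> CostSummary:
    """Arm means of annual per-person cost with the difference's t-test."""
    users = cohort.matched_user_ids
    controls = cohort.control_ids
    if len(users) == 0 or len(controls) == 0:
        raise DomainError("both arms must be non-empty")
    x = per_person_costs(claims, users, category)
    y = per_person_costs(claims, controls, category)
    if _var(x) == 0 and _var(y) == 0:
        p = 1.0
        ci = (float(x.mean() - y.mean()),) * 2
    else:
        res = stats.ttest_ind(x, y, equal_var=not welch)
        p = float(res.pvalue)
        if welch:
            ci = _welch_ci(x, y)
        else:
            lo, hi = res.confidence_interval()
            ci = (float(lo), float(hi))
    per_claim = mean_cost_per_claim(claims, cohort, category)
    return CostSummary(
        category="all" if category is None else str(category),
        mean_per_person_users=float(x.mean()),
        mean_per_person_controls=float(y.mean()),
        delta=float(x.mean() - y.mean()),
        delta_ci=ci,
        p_value=p,
        mean_per_claim_users=per_claim[0],
        mean_per_claim_controls=per_claim[1],
    )


def mean_cost_per_claim(claims: pd.DataFrame, cohort: MatchedCohort,
                        category=None, welch: bool = True):
    """Claim-level arm means (and Welch p when both arms have claims).

    Returns ``(mean_users, mean_controls, p)``; a mean is None when the
    arm has no claims in the category, and p is None unless both exist.
    """
    mask = _category_mask(claims, category)
    sub = claims[mask]
    xu = sub[sub["person_id"].isin(cohort.matched_user_ids)]["cost"].to_numpy()
    xc = sub[sub["person_id"].isin(cohort.control_ids)]["cost"].to_numpy()
    mu = float(xu.mean()) if len(xu) else None
    mc = float(xc.mean()) if len(xc) else None
    p = None
    if len(xu) > 1 and len(xc) > 1 and (xu.var() > 0 or xc.var() > 0):
        p = float(stats.ttest_ind(xu, xc, equal_var=not welch).pvalue)
    return mu, mc, p


def cost_table(claims: pd.DataFrame, cohort: MatchedCohort,
               welch: bool = True) -> pd.DataFrame:
    """Per-category and overall cost summaries (supplementary-table
    layout: per-person and per-claim means per arm with Welch tests)."""
    rows = []
    for cat in list(CATEGORIES) + [None]:
        s = annual_cost_per_person(claims, cohort, cat, welch=welch)
        rows.append({
            "category": s.category,
            "mean_per_person_users": s.mean_per_person_users,
            "mean_per_person_controls": s.mean_per_person_controls,
            "delta": s.delta,
            "delta_ci_low": s.delta_ci[0],
            "delta_ci_high": s.delta_ci[1],
            "p_value": s.p_value,
            "mean_per_claim_users": s.mean_per_claim_users,
            "mean_per_claim_controls": s.mean_per_claim_controls,
        })
    return pd.DataFrame(rows)
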