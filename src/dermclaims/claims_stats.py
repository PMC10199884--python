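"""Person-level association analysis of dermatological claims.

Exposure is app use (matched users vs their controls); the outcome for a
category is having at least one claim in it during the study year, counted
at person level (multiple claims by one person count once).  Effects are
sample odds ratios with Woolf (log-normal) 95% confidence intervals,
two-sided Fisher exact p-values, two-proportion z-tests for claim-volume
proportions, and Benjamini-Hochberg adjustment within each results table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .errors import DomainError
from .matching import MatchedCohort
from .schema import BENIGN_NEVUS, CATEGORIES, PREMALIGNANT_MALIGNANT
from .synthetic import combined_high_mask

__all__ = [
    "ContingencyTable", "OddsRatioResult", "ZTestResult", "RatePer1000",
    "build_contingency", "odds_ratio", "fisher_exact_p", "two_proportion_z",
    "claims_per_1000", "bh_adjust", "subgroup_split", "history_subgroup",
    "persons_with_claim", "association_table", "intervention_table",
    "subgroup_tables",
]

Z975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 person-level table: a/b exposed with/without the outcome,
    c/d unexposed with/without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DomainError("contingency cells must be nonnegative")

    @property
    def n_exposed(self) -> int:
        return self.a + self.b

    @property
    def n_unexposed(self) -> int:
        return self.c + self.d

    @property
    def p_exposed(self) -> float:
        return self.a / self.n_exposed

    @property
    def p_unexposed(self) -> float:
        return self.c / self.n_unexposed

    def swap_exposure(self) -> "ContingencyTable":
        return ContingencyTable(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    haldane: bool = False  # 0.5 added to every cell because of a zero cell


@dataclass(frozen=True)
class ZTestResult:
    z: float
    p: float
    degenerate: bool = False  # pooled proportion was 0 or 1


@dataclass(frozen=True)
class RatePer1000:
    claims: int
    persons: int
    rate: float  # claims per 1000 persons, unrounded

    @property
    def rate_rounded(self) -> float:
        return float(np.round(self.rate, 2))


def _as_categories(category) -> tuple:
    cats = (category,) if isinstance(category, str) else tuple(category)
    unknown = set(cats) - set(CATEGORIES)
    if unknown:
        raise DomainError(f"unknown claim categories: {sorted(unknown)}")
    return cats


def persons_with_claim(claims: pd.DataFrame, person_ids, category) -> int:
    """Number of distinct persons among ``person_ids`` with >= 1 claim in
    the given category (or pooled categories)."""
    cats = _as_categories(category)
    hit = claims[claims["category"].isin(cats)]["person_id"].unique()
    return int(np.isin(np.asarray(person_ids), hit).sum())


def build_contingency(cohort: MatchedCohort, claims: pd.DataFrame,
                      category) -> ContingencyTable:
    """Person-level 2x2 table for matched users vs their controls."""
    users = cohort.matched_user_ids
    controls = cohort.control_ids
    a = persons_with_claim(claims, users, category)
    c = persons_with_claim(claims, controls, category)
    return ContingencyTable(a, len(users) - a, c, len(controls) - c)


def odds_ratio(table: ContingencyTable, alpha: float = 0.05) -> OddsRatioResult:
    """Sample cross-product odds ratio with the Woolf log-normal CI.

    A zero cell triggers the Haldane-Anscombe correction (0.5 added to all
    cells) for both the point estimate and the CI, flagged in the result.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    haldane = 0 in (a, b, c, d)
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatioResult(float(or_), float(or_ * np.exp(-z * se)),
                           float(or_ * np.exp(z * se)), haldane)


def fisher_exact_p(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value (sum of hypergeometric probabilities
    not exceeding the observed table's)."""
    res = stats.fisher_exact([[table.a, table.b], [table.c, table.d]],
                             alternative="two-sided")
    return float(res.pvalue)


def two_proportion_z(x1: int, n1: int, x2: int, n2: int,
                     continuity: bool = False) -> ZTestResult:
    """Two-sided two-proportion z-test with pooled variance.

    The default has no continuity correction; ``continuity=True`` applies
    the Yates-style correction to the numerator.
    """
    if n1 <= 0 or n2 <= 0:
        raise DomainError("both sample sizes must be positive")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return ZTestResult(0.0, 1.0, degenerate=True)
    if not continuity:
        z, p = proportions_ztest([x1, x2], [n1, n2], alternative="two-sided")
        return ZTestResult(float(z), float(p))
    diff = x1 / n1 - x2 / n2
    cc = 0.5 * (1 / n1 + 1 / n2)
    num = max(abs(diff) - cc, 0.0) * np.sign(diff)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = num / se
    return ZTestResult(float(z), float(2 * stats.norm.sf(abs(z))))


def claims_per_1000(claims: int, persons: int) -> RatePer1000:
    """Claim volume scaled to 1000 persons."""
    if persons <= 0:
        raise DomainError("persons must be positive")
    return RatePer1000(claims, persons, 1000.0 * claims / persons)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# subgroups


def subgroup_split(users: pd.DataFrame, assessments: pd.DataFrame):
    """Partition user ids into (>=1 combined-high, only-low) groups.

    Failed assessments are ignored; users whose assessments all failed
    violate the inclusion rule and are excluded with a warning.
    """
    if "arm" in users.columns:
        users = users[users["arm"] == "user"]
    user_ids = users["person_id"].to_numpy()
    assessments = assessments[assessments["person_id"].isin(user_ids)]

    ok = assessments.loc[assessments["cnn_result"] != "failed", "person_id"]
    valid = np.unique(ok.to_numpy())
    invalid = np.setdiff1d(user_ids, valid)
    if len(invalid):
        warnings.warn(
            f"excluding {len(invalid)} user(s) with only failed assessments",
            stacklevel=2)

    high = np.unique(
        assessments.loc[combined_high_mask(assessments), "person_id"])
    high = np.intersect1d(high, valid)
    low = np.setdiff1d(valid, high)
    return high, low


def history_subgroup(insurees: pd.DataFrame,
                     cohort: MatchedCohort) -> MatchedCohort:
    """Cohort restricted to users with a (pre)malignancy history, keeping
    their matched sets intact."""
    positive = insurees.loc[insurees["history_premalignancy"],
                            "person_id"].to_numpy()
    keep = np.intersect1d(cohort.matched_user_ids, positive)
    return cohort.subset(keep)


# ---------------------------------------------------------------------------
# report tables


@dataclass(frozen=True)
class _Row:
    label: str
    table: ContingencyTable


def _association_rows(rows, continuity=False) -> pd.DataFrame:
    recs = []
    for row in rows:
        t = row.table
        orr = odds_ratio(t)
        zres = two_proportion_z(t.a, t.n_exposed, t.c, t.n_unexposed,
                                continuity=continuity)
        recs.append({
            "category": row.label,
            "n_users": t.n_exposed, "users_with_claim": t.a,
            "pct_users": 100.0 * t.p_exposed,
            "n_controls": t.n_unexposed, "controls_with_claim": t.c,
            "pct_controls": 100.0 * t.p_unexposed,
            "odds_ratio": orr.odds_ratio,
            "ci_low": orr.ci_low, "ci_high": orr.ci_high,
            "p_fisher": fisher_exact_p(t),
            "p_zprop": zres.p,
        })
    out = pd.DataFrame(recs)
    out["p_adjusted"] = bh_adjust(out["p_fisher"].to_numpy())
    return out


ASSOCIATION_ROWS = (
    ("premalignant", ("premalignant",)),
    ("malignant", ("malignant",)),
    ("premalignant_malignant", PREMALIGNANT_MALIGNANT),
    ("nevus", ("nevus",)),
    ("benign_tumor", ("benign_tumor",)),
    ("nevus_benign", BENIGN_NEVUS),
    ("unrelated_dermatology", ("unrelated_dermatology",)),
)

SUBGROUP_ROWS = (
    ("premalignant", ("premalignant",)),
    ("malignant", ("malignant",)),
    ("nevus_benign", BENIGN_NEVUS),
    ("unrelated_dermatology", ("unrelated_dermatology",)),
)


def association_table(cohort: MatchedCohort, claims: pd.DataFrame,
                      rows=ASSOCIATION_ROWS, continuity=False) -> pd.DataFrame:
    """Per-category person-level associations (the main results table);
    BH adjustment spans the table's Fisher p-values as one family."""
    built = [_Row(label, build_contingency(cohort, claims, cats))
             for label, cats in rows]
    return _association_rows(built, continuity=continuity)


def subgroup_tables(cohort: MatchedCohort, claims: pd.DataFrame,
                    assessments: pd.DataFrame, users: pd.DataFrame,
                    continuity=False) -> pd.DataFrame:
    """Association tables stratified by the user risk subgroup (>=1
    high-risk assessment vs only-low), controls being each stratum's own
    matched controls; BH families are per stratum."""
    high, low = subgroup_split(users, assessments)
    frames = []
    for name, ids in (("high_risk", high), ("low_risk", low)):
        sub = cohort.subset(ids)
        tab = association_table(sub, claims, rows=SUBGROUP_ROWS,
                                continuity=continuity)
        tab.insert(0, "stratum", name)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


INTERVENTION_ROWS = (
    ("gp_biopsy_excision", "primary"),
    ("gp_teledermatology", "primary"),
    ("mohs", "secondary"),
    ("hospital_excision_benign", "secondary"),
    ("hospital_excision_premalignant", "secondary"),
)


def intervention_table(cohort: MatchedCohort, claims: pd.DataFrame,
                       continuity=False) -> pd.DataFrame:
    """Claim-volume comparison per intervention type.

    Rates are claims per 1000 persons per arm with their absolute
    difference; the z-test compares each intervention's share of the arm's
    total claim volume.  BH adjustment spans the table as one family.
    """
    users = cohort.matched_user_ids
    controls = cohort.control_ids
    uclaims = claims[claims["person_id"].isin(users)]
    cclaims = claims[claims["person_id"].isin(controls)]
    n_uclaims, n_cclaims = len(uclaims), len(cclaims)

    recs = []
    for interv, setting in INTERVENTION_ROWS:
        xu = int((uclaims["intervention"] == interv).sum())
        xc = int((cclaims["intervention"] == interv).sum())
        ru = claims_per_1000(xu, len(users))
        rc = claims_per_1000(xc, len(controls))
        zres = two_proportion_z(xu, max(n_uclaims, 1), xc, max(n_cclaims, 1),
                                continuity=continuity)
        recs.append({
            "intervention": interv, "setting": setting,
            "claims_users": xu, "claims_controls": xc,
            "pct_of_claims_users": 100.0 * xu / n_uclaims if n_uclaims else np.nan,
            "pct_of_claims_controls": 100.0 * xc / n_cclaims if n_cclaims else np.nan,
            "per1000_users": ru.rate, "per1000_controls": rc.rate,
            "per1000_delta": ru.rate - rc.rate,
            "p_zprop": zres.p,
        })
    out = pd.DataFrame(recs)
    out["p_adjusted"] = bh_adjust(out["p_zprop"].to_numpy())
    return out
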