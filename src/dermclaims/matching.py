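"""Tiered 1:k exact matching of app users to non-user controls.

Users are matched without replacement to controls that are identical on
six covariates: age band (10-year intervals), sex, socio-economic status
(missing matched to missing), residential region, skin-(pre)malignancy
history, and the exact comorbidity count.  Tier 1 requires all six; when a
user cannot fill all slots at tier 1, the remaining slots are filled at
tier 2, which drops the region criterion.  Users with no candidates at
either tier are flagged unmatched, excluded from analysis, and counted.

Selection among eligible controls is uniform at random behind a seed.  The
pool is canonicalised (sorted by person id) before shuffling, so permuting
the input row order does not change the selection for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError

__all__ = ["AgeBands", "assign_age_band", "MatchedCohort", "match_cohort",
           "matching_report", "standardized_differences"]

DEFAULT_AGE_EDGES = (18, 30, 40, 50, 60, 70, 80)

MATCH_COVARIATES = ("age_band", "sex", "ses", "region",
                    "history_premalignancy", "n_comorbidities")


@dataclass(frozen=True)
class AgeBands:
    """Partition of [min_age, inf) into 10-year bands, last band open."""

    edges: tuple = DEFAULT_AGE_EDGES

    def __post_init__(self):
        if list(self.edges) != sorted(set(self.edges)) or len(self.edges) < 1:
            raise ConfigError("age band edges must be strictly increasing")

    @property
    def labels(self) -> tuple:
        out = []
        for lo, hi in zip(self.edges[:-1], self.edges[1:]):
            out.append(f"{lo}-{hi - 1}")
        out.append(f"{self.edges[-1]}+")
        return tuple(out)

    def assign(self, age):
        """Vectorised band label lookup; ages below the first edge are a
        domain error."""
        age_arr = np.atleast_1d(np.asarray(age))
        if (age_arr < self.edges[0]).any():
            raise DomainError(
                f"age below {self.edges[0]} is outside the study population")
        idx = np.searchsorted(self.edges, age_arr, side="right") - 1
        labels = np.asarray(self.labels, dtype=object)
        out = labels[idx]
        return out[0] if np.isscalar(age) or np.asarray(age).ndim == 0 else out


def assign_age_band(age, bands: AgeBands | None = None):
    """Label the 10-year age band containing ``age`` (default bands
    18-29, 30-39, ..., 80+)."""
    return (bands or AgeBands()).assign(age)


@dataclass
class MatchedCohort:
    """Result of tiered exact matching.

    ``pairs`` has one row per (user, control) pair with the pair's tier;
    ``users`` has one row per input user with its tier classification
    (full / no_region / unmatched), number of controls, and match key.
    """

    pairs: pd.DataFrame
    users: pd.DataFrame
    ratio: int
    age_bands: AgeBands = field(default_factory=AgeBands)

    @property
    def matched_user_ids(self) -> np.ndarray:
        keep = self.users["tier"] != "unmatched"
        return self.users.loc[keep, "person_id"].to_numpy()

    @property
    def control_ids(self) -> np.ndarray:
        return self.pairs["control_id"].to_numpy()

    @property
    def n_unmatched(self) -> int:
        return int((self.users["tier"] == "unmatched").sum())

    def subset(self, user_ids) -> "MatchedCohort":
        """Restrict to the given users, preserving their matched sets."""
        user_ids = np.asarray(user_ids)
        users = self.users[self.users["person_id"].isin(user_ids)]
        pairs = self.pairs[self.pairs["user_id"].isin(user_ids)]
        return MatchedCohort(pairs.reset_index(drop=True),
                             users.reset_index(drop=True),
                             self.ratio, self.age_bands)


def _key_frame(df: pd.DataFrame, bands: AgeBands,
               comorbidity_cap: int | None) -> pd.DataFrame:
    out = pd.DataFrame({
        "person_id": df["person_id"].to_numpy(),
        "age_band": bands.assign(df["age"].to_numpy()),
        "sex": df["sex"].to_numpy(),
        "ses": df["ses"].to_numpy(),
        "region": df["region"].to_numpy(),
        "history_premalignancy": df["history_premalignancy"].to_numpy(),
        "n_comorbidities": df["n_comorbidities"].to_numpy(),
    })
    if comorbidity_cap is not None:
        out["n_comorbidities"] = np.minimum(out["n_comorbidities"],
                                            comorbidity_cap)
    return out


def match_cohort(users: pd.DataFrame, pool: pd.DataFrame, ratio: int = 3,
                 seed: int = 0, age_bands: AgeBands | None = None,
                 comorbidity_cap: int | None = None) -> MatchedCohort:
    """Match each user to up to ``ratio`` controls by tiered exact matching.

    ``users`` and ``pool`` are insuree tables (disjoint person ids).
    Controls are consumed without replacement, users processed in person-id
    order.  Tier-2 slots (region dropped) are only used when tier 1 cannot
    fill the quota.
    """
    if ratio < 1:
        raise ConfigError("matching ratio must be >= 1")
    bands = age_bands or AgeBands()
    overlap = np.intersect1d(users["person_id"], pool["person_id"])
    if len(overlap):
        raise DomainError("users and control pool must be disjoint")

    ukeys = _key_frame(users.sort_values("person_id"), bands, comorbidity_cap)
    pkeys = _key_frame(pool.sort_values("person_id"), bands, comorbidity_cap)

    full_cols = list(MATCH_COVARIATES)
    part_cols = [c for c in full_cols if c != "region"]

    rng = np.random.default_rng(seed)
    # canonical order (sorted ids), then one seeded permutation
    perm = rng.permutation(len(pkeys))
    pkeys_shuffled = pkeys.iloc[perm]

    tier1: dict = {}
    tier2: dict = {}
    for row in pkeys_shuffled.itertuples(index=False):
        k1 = (row.age_band, row.sex, row.ses, row.region,
              row.history_premalignancy, row.n_comorbidities)
        k2 = (row.age_band, row.sex, row.ses,
              row.history_premalignancy, row.n_comorbidities)
        tier1.setdefault(k1, []).append(row.person_id)
        tier2.setdefault(k2, []).append(row.person_id)

    used: set = set()
    pair_user, pair_control, pair_tier = [], [], []
    urows = []
    for row in ukeys.itertuples(index=False):
        k1 = (row.age_band, row.sex, row.ses, row.region,
              row.history_premalignancy, row.n_comorbidities)
        k2 = (row.age_band, row.sex, row.ses,
              row.history_premalignancy, row.n_comorbidities)
        picked_full, picked_part = [], []
        bucket = tier1.get(k1)
        while bucket and len(picked_full) < ratio:
            cid = bucket.pop()
            if cid not in used:
                picked_full.append(cid)
        bucket = tier2.get(k2)
        if bucket is not None and len(picked_full) < ratio:
            while bucket and len(picked_full) + len(picked_part) < ratio:
                cid = bucket.pop()
                if cid not in used and cid not in picked_full:
                    picked_part.append(cid)
        picked = picked_full + picked_part
        used.update(picked)
        if not picked:
            tier = "unmatched"
        elif picked_part:
            tier = "no_region"
        else:
            tier = "full"
        for cid in picked_full:
            pair_user.append(row.person_id)
            pair_control.append(cid)
            pair_tier.append("full")
        for cid in picked_part:
            pair_user.append(row.person_id)
            pair_control.append(cid)
            pair_tier.append("no_region")
        urows.append((row.person_id, tier, len(picked), row.age_band, row.sex,
                      row.ses, row.region, row.history_premalignancy,
                      row.n_comorbidities))

    pairs = pd.DataFrame({
        "user_id": np.asarray(pair_user, dtype=np.int64),
        "control_id": np.asarray(pair_control, dtype=np.int64),
        "tier": pair_tier,
    })
    users_out = pd.DataFrame(
        urows, columns=["person_id", "tier", "n_controls", "age_band", "sex",
                        "ses", "region", "history_premalignancy",
                        "n_comorbidities"])
    return MatchedCohort(pairs, users_out, ratio, bands)


def cohort_from_pairs(pairs: pd.DataFrame, insurees: pd.DataFrame,
                      ratio: int = 3,
                      age_bands: AgeBands | None = None) -> MatchedCohort:
    """Rebuild a MatchedCohort from a saved pairs table (user_id,
    control_id, tier) and the insuree table.  Unmatched users are not
    recoverable from the pairs table and are omitted, which leaves the
    analysis unchanged."""
    bands = age_bands or AgeBands()
    keyed = _key_frame(insurees, bands, None).set_index("person_id")
    per_user = pairs.groupby("user_id").agg(
        n_controls=("control_id", "size"),
        any_partial=("tier", lambda t: (t == "no_region").any()))
    users = keyed.loc[per_user.index.to_numpy()]
    users.index.name = "person_id"
    users = users.reset_index()
    users.insert(1, "tier", np.where(per_user["any_partial"].to_numpy(),
                                     "no_region", "full"))
    users.insert(2, "n_controls", per_user["n_controls"].to_numpy())
    return MatchedCohort(pairs.reset_index(drop=True), users, ratio, bands)


def standardized_differences(insurees: pd.DataFrame,
                             cohort: MatchedCohort) -> pd.Series:
    """Standardised mean differences (users minus controls) on the matching
    covariates, categorical covariates expanded to indicators.

    SMD = (mean_u - mean_c) / sqrt((var_u + var_c) / 2); defined as 0 when
    both variances are 0 and the means agree.
    """
    bands = cohort.age_bands
    keyed = _key_frame(insurees, bands, None).set_index("person_id")
    u = keyed.loc[cohort.matched_user_ids]
    c = keyed.loc[cohort.control_ids]

    def expand(df):
        cols = {}
        for cov in MATCH_COVARIATES:
            s = df[cov]
            if s.dtype == bool or np.issubdtype(s.dtype, np.number):
                cols[cov] = s.astype(float)
            else:
                for lvl in sorted(pd.unique(keyed[cov].astype(str))):
                    cols[f"{cov}={lvl}"] = (s.astype(str) == lvl).astype(float)
        return pd.DataFrame(cols)

    ue, ce = expand(u), expand(c)
    out = {}
    for col in ue.columns:
        mu, mc = ue[col].mean(), ce[col].mean()
        vu, vc = ue[col].var(ddof=1), ce[col].var(ddof=1)
        if len(ue) < 2:
            vu = 0.0
        if len(ce) < 2:
            vc = 0.0
        pooled = np.sqrt((vu + vc) / 2.0)
        out[col] = 0.0 if pooled == 0 and mu == mc else (mu - mc) / pooled
    return pd.Series(out, name="smd")


def matching_report(cohort: MatchedCohort,
                    insurees: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tier counts/fractions and, when insurees are given, the worst
    absolute standardised difference across matched covariates."""
    n = len(cohort.users)
    rows = []
    for tier in ("full", "no_region", "unmatched"):
        k = int((cohort.users["tier"] == tier).sum())
        rows.append({"metric": f"users_{tier}", "value": k,
                     "fraction": k / n if n else np.nan})
    partial = int(((cohort.users["n_controls"] > 0)
                   & (cohort.users["n_controls"] < cohort.ratio)).sum())
    rows.append({"metric": "users_partial_match", "value": partial,
                 "fraction": partial / n if n else np.nan})
    rows.append({"metric": "controls_selected", "value": len(cohort.pairs),
                 "fraction": np.nan})
    if insurees is not None and len(cohort.pairs):
        smd = standardized_differences(insurees, cohort)
        rows.append({"metric": "max_abs_smd",
                     "value": float(smd.abs().max()), "fraction": np.nan})
    return pd.DataFrame(rows)
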