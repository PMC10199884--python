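"""Synthetic insured population, app-usage logs, and dermatological claims.

The generator emulates the statistical structure of a population-based
evaluation of an AI skin-check app on insurance claims:

* a large adult population with ~0.86% app uptake;
* per-user assessment counts from a zero-truncated negative binomial;
* CNN photo outcomes (low / low-with-symptoms / high / failed) with
  teledermatologist upgrades of CNN-low photos and downgrades of CNN-high
  photos;
* a per-user beta-distributed high-risk propensity.  Users tend to submit
  repeat photos of the same lesion, so high-risk outcomes cluster within
  users; the beta concentration is calibrated so the share of users with
  at least one high-risk assessment matches the configured target (0.371
  by default) while the assessment-level outcome frequencies stay at their
  configured marginals;
* person-level claim probabilities per diagnosis category, conditional on
  arm and (for users) on the high/low-risk subgroup; claimants file
  ``1 + Poisson`` claims with log-normal costs and an intervention label.

All randomness flows through one ``numpy.random.Generator``; identical
config + seed reproduces byte-identical tables.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .config import GeneratorConfig
from .errors import CalibrationError, GeneratorError
from .schema import CATEGORIES, INTERVENTION_SETTING

__all__ = [
    "generate_population",
    "generate_assessments",
    "generate_claims",
    "generate_all",
    "calibrate_risk_concentration",
]


def _as_rng(seed) -> np.random.Generator:
    """Accept an integer seed or an existing Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@lru_cache(maxsize=64)
def _truncnorm_loc(mean: float, sd: float, lower: float) -> float:
    """Location parameter so the truncated normal has the requested mean."""

    def gap(loc):
        a = (lower - loc) / sd
        return truncnorm.mean(a, np.inf, loc=loc, scale=sd) - mean

    return brentq(gap, mean - 4 * sd, mean + sd, xtol=1e-10)


@lru_cache(maxsize=64)
def _ztnb_underlying_mean(mean: float, size: float) -> float:
    """Mean of the untruncated NB whose zero-truncation has mean ``mean``."""

    def p0(m):
        return (size / (size + m)) ** size

    def gap(m):
        return m / (1.0 - p0(m)) - mean

    return brentq(gap, 1e-9, mean, xtol=1e-12)


def _sample_ztnb(rng, n, mean, size, max_retries=1000):
    """Zero-truncated negative-binomial draws by vectorised rejection."""
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    m = _ztnb_underlying_mean(mean, size)
    p = size / (size + m)
    out = rng.negative_binomial(size, p, n)
    for _ in range(max_retries):
        zero = out == 0
        if not zero.any():
            return out
        out[zero] = rng.negative_binomial(size, p, int(zero.sum()))
    raise GeneratorError("zero-truncated NB rejection did not converge")


def _ztnb_pgf(s, mean, size):
    """E[s^K] for the zero-truncated negative binomial (vectorised in s)."""
    m = _ztnb_underlying_mean(mean, size)
    p = size / (size + m)
    g = (p / (1.0 - (1.0 - p) * s)) ** size
    g0 = p ** size
    return (g - g0) / (1.0 - g0)


@lru_cache(maxsize=64)
def calibrate_risk_concentration(p_high: float, p_low: float, p_low_sym: float,
                                 p_failed: float, p_upgrade: float,
                                 mean_assessments: float, nb_size: float,
                                 target_share: float) -> float:
    """Beta concentration of the per-user high-risk propensity.

    Each user draws a propensity ``h ~ Beta(p_high*c, (1-p_high)*c)``; each
    of their assessments is CNN-high with probability ``h`` and, if not
    high, may still be upgraded by the teledermatologist.  This solves for
    the concentration ``c`` such that ``P(user has >= 1 high assessment)``
    equals ``target_share``, keeping the assessment-level marginal at
    ``p_high`` by construction.  Raises :class:`CalibrationError` when the
    target is outside the range attainable at the given marginals.
    """
    p_nonhigh = p_low + p_low_sym + p_failed
    w = (p_low + p_low_sym) / p_nonhigh if p_nonhigh > 0 else 0.0

    nodes, weights = np.polynomial.legendre.leggauss(200)
    u = 0.5 * (nodes + 1.0)          # quantile grid on (0, 1)
    wq = 0.5 * weights

    from scipy.stats import beta as beta_dist

    def p_no_high(c):
        h = beta_dist.ppf(u, p_high * c, (1.0 - p_high) * c)
        s = 1.0 - (h + (1.0 - h) * w * p_upgrade)
        return float(np.sum(wq * _ztnb_pgf(s, mean_assessments, nb_size)))

    target = 1.0 - target_share
    lo, hi = -3.0, 4.0
    f_lo = p_no_high(10.0 ** lo) - target
    f_hi = p_no_high(10.0 ** hi) - target
    if f_lo * f_hi > 0:
        raise CalibrationError(
            "target high-risk user share is unattainable at the configured "
            "assessment marginals; adjust cnn_probs, the assessment-count "
            "distribution, or high_risk_user_share")
    log_c = brentq(lambda lc: p_no_high(10.0 ** lc) - target, lo, hi,
                   xtol=1e-10)
    return 10.0 ** log_c


# ---------------------------------------------------------------------------
# population


def _empty_insurees() -> pd.DataFrame:
    return pd.DataFrame({
        "person_id": pd.Series(dtype=np.int64),
        "age": pd.Series(dtype=np.int64),
        "sex": pd.Series(dtype=str),
        "ses": pd.Series(dtype=str),
        "region": pd.Series(dtype=np.int64),
        "history_premalignancy": pd.Series(dtype=bool),
        "n_comorbidities": pd.Series(dtype=np.int64),
        "arm": pd.Series(dtype=str),
    })


def generate_population(config: GeneratorConfig, seed) -> pd.DataFrame:
    """Generate the insured population with matching covariates and arm."""
    config.validate()
    rng = _as_rng(seed)
    n = config.n_population
    if n == 0:
        return _empty_insurees()

    is_user = rng.random(n) < config.uptake_rate

    lower = config.age_min - 0.5  # integer rounding keeps the mean on target
    loc = _truncnorm_loc(config.age_mean, config.age_sd, lower)
    a = (lower - loc) / config.age_sd
    age = truncnorm.rvs(a, np.inf, loc=loc, scale=config.age_sd, size=n,
                        random_state=rng)
    if config.control_age_shift != 0.0:
        loc_c = loc + config.control_age_shift
        a_c = (lower - loc_c) / config.age_sd
        n_ctrl = int((~is_user).sum())
        age[~is_user] = truncnorm.rvs(a_c, np.inf, loc=loc_c,
                                      scale=config.age_sd, size=n_ctrl,
                                      random_state=rng)
    age = np.maximum(np.rint(age).astype(np.int64), config.age_min)

    sex = np.where(rng.random(n) < config.p_female, "female", "male")

    ses = np.empty(n, dtype=object)
    missing = rng.random(n) < config.p_ses_missing
    ses[missing] = "missing"
    levels = np.array(["low", "middle", "high"], dtype=object)
    probs = np.asarray(config.ses_probs, dtype=float)
    probs = probs / probs.sum()
    n_obs = int((~missing).sum())
    ses[~missing] = rng.choice(levels, size=n_obs, p=probs)

    region = rng.integers(0, config.n_regions, n)
    history = rng.random(n) < config.p_history
    comorb = np.minimum(rng.poisson(config.comorbidity_mean, n),
                        config.comorbidity_cap)

    return pd.DataFrame({
        "person_id": np.arange(n, dtype=np.int64),
        "age": age,
        "sex": sex,
        "ses": ses,
        "region": region,
        "history_premalignancy": history,
        "n_comorbidities": comorb.astype(np.int64),
        "arm": np.where(is_user, "user", "control-pool"),
    })


# ---------------------------------------------------------------------------
# assessments


def _empty_assessments() -> pd.DataFrame:
    return pd.DataFrame({
        "person_id": pd.Series(dtype=np.int64),
        "assessment_index": pd.Series(dtype=np.int64),
        "cnn_result": pd.Series(dtype=str),
        "telederm_result": pd.Series(dtype=str),
    })


def generate_assessments(users: pd.DataFrame, config: GeneratorConfig,
                         seed) -> pd.DataFrame:
    """Generate per-photo CNN outcomes and teledermatologist overrides.

    Every user ends with at least one non-failed assessment (the study's
    inclusion rule); users whose draws all fail are redrawn up to
    ``config.max_retries`` times before a :class:`GeneratorError`.
    """
    config.validate()
    rng = _as_rng(seed)
    if "arm" in users.columns:
        users = users[users["arm"] == "user"]
    user_ids = users["person_id"].to_numpy()
    n_users = len(user_ids)
    if n_users == 0:
        return _empty_assessments()

    p_low, p_low_sym, p_high, p_failed = config.cnn_probs
    p_nonhigh = p_low + p_low_sym + p_failed

    counts = _sample_ztnb(rng, n_users, config.mean_assessments,
                          config.nb_size)
    total = int(counts.sum())
    owner = np.repeat(np.arange(n_users), counts)

    conc = config.high_risk_concentration
    if conc is None:
        if 0.0 < p_high < 1.0:
            conc = calibrate_risk_concentration(
                p_high, p_low, p_low_sym, p_failed, config.p_upgrade,
                config.mean_assessments, config.nb_size,
                config.high_risk_user_share)
        else:
            conc = np.inf
    if np.isinf(conc) or p_high in (0.0, 1.0):
        h_user = np.full(n_users, p_high)
    else:
        h_user = rng.beta(p_high * conc, (1.0 - p_high) * conc, n_users)

    nonhigh_labels = np.array(["low", "low_symptoms", "failed"], dtype=object)
    if p_nonhigh > 0:
        nonhigh_probs = np.array([p_low, p_low_sym, p_failed]) / p_nonhigh
    else:
        nonhigh_probs = np.array([1.0, 0.0, 0.0])

    def draw_outcomes(m, h):
        cnn = np.empty(m, dtype=object)
        high = rng.random(m) < h
        cnn[high] = "high"
        n_nh = int((~high).sum())
        cnn[~high] = rng.choice(nonhigh_labels, size=n_nh, p=nonhigh_probs)
        return cnn

    cnn = draw_outcomes(total, h_user[owner])

    # enforce >= 1 non-failed assessment per user
    starts = np.r_[0, np.cumsum(counts)[:-1]]
    for attempt in range(config.max_retries + 1):
        all_failed = np.logical_and.reduceat(cnn == "failed", starts)
        ok = ~all_failed
        if ok.all():
            break
        if attempt == config.max_retries:
            raise GeneratorError(
                "could not generate >= 1 successful assessment per user; "
                "is P(failed) too close to 1?")
        bad = np.isin(owner, np.flatnonzero(~ok))
        cnn[bad] = draw_outcomes(int(bad.sum()), h_user[owner[bad]])

    telederm = np.full(total, "none", dtype=object)
    low_mask = (cnn == "low") | (cnn == "low_symptoms")
    telederm[low_mask & (rng.random(total) < config.p_upgrade)] = "high"
    high_mask = cnn == "high"
    telederm[high_mask & (rng.random(total) < config.p_downgrade)] = "low"

    idx = np.concatenate([np.arange(k) for k in counts]) if total else \
        np.zeros(0, dtype=np.int64)

    return pd.DataFrame({
        "person_id": user_ids[owner],
        "assessment_index": idx.astype(np.int64),
        "cnn_result": cnn,
        "telederm_result": telederm,
    })


def combined_high_mask(assessments: pd.DataFrame) -> pd.Series:
    """Per-assessment combined risk: high iff the CNN or the
    teledermatologist assigned high risk (a downgraded CNN-high photo
    still counts as high)."""
    return (assessments["cnn_result"] == "high") | \
        (assessments["telederm_result"] == "high")


def high_risk_user_ids(assessments: pd.DataFrame) -> np.ndarray:
    """IDs of users with at least one combined-high assessment."""
    mask = combined_high_mask(assessments)
    return np.unique(assessments.loc[mask, "person_id"].to_numpy())


# ---------------------------------------------------------------------------
# claims


def _empty_claims(year: int) -> pd.DataFrame:
    return pd.DataFrame({
        "person_id": pd.Series(dtype=np.int64),
        "category": pd.Series(dtype=str),
        "intervention": pd.Series(dtype=str),
        "setting": pd.Series(dtype=str),
        "year": pd.Series(dtype=np.int64),
        "cost": pd.Series(dtype=float),
    })


def generate_claims(population: pd.DataFrame, assessments: pd.DataFrame,
                    config: GeneratorConfig, seed) -> pd.DataFrame:
    """Generate claim records for the whole population.

    Person-level claim probabilities depend on arm and, for users, on
    whether the person ever received a combined-high assessment.  Each
    claimant files ``1 + Poisson(extra_claims_mean)`` claims; per-claim
    costs are log-normal with the configured arithmetic mean, and each
    claim carries an intervention label (care setting follows from it).
    """
    config.validate()
    rng = _as_rng(seed)
    if len(population) == 0:
        return _empty_claims(config.year)

    is_user = (population["arm"] == "user").to_numpy()
    person_ids = population["person_id"].to_numpy()
    high_ids = high_risk_user_ids(assessments) if len(assessments) else \
        np.zeros(0, dtype=np.int64)
    is_high = np.isin(person_ids, high_ids)

    frames = []
    for cat in CATEGORIES:
        cc = config.categories[cat]
        p = np.where(is_user,
                     np.where(is_high, cc.p_user_high, cc.p_user_low),
                     cc.p_control)
        claimant = rng.random(len(p)) < p
        ids = person_ids[claimant]
        users_flag = is_user[claimant]
        if len(ids) == 0:
            continue
        n_claims = 1 + rng.poisson(cc.extra_claims_mean, len(ids))
        rep_ids = np.repeat(ids, n_claims)
        rep_user = np.repeat(users_flag, n_claims)
        m = len(rep_ids)

        interv = np.empty(m, dtype=object)
        for arm_flag, dist in ((True, cc.intervention_user),
                               (False, cc.intervention_control)):
            sel = rep_user == arm_flag
            k = int(sel.sum())
            if k == 0:
                continue
            if dist:
                labels = np.array(list(dist), dtype=object)
                probs = np.array([dist[x] for x in labels], dtype=float)
                interv[sel] = rng.choice(labels, size=k, p=probs)
            else:
                interv[sel] = "none"
        setting = np.array([INTERVENTION_SETTING[i] for i in interv],
                           dtype=object)

        cost = np.zeros(m)
        for arm_flag, mean in ((True, cc.cost_mean_user),
                               (False, cc.cost_mean_control)):
            sel = rep_user == arm_flag
            k = int(sel.sum())
            if k == 0 or mean == 0:
                continue
            sigma = config.cost_sigma
            mu = np.log(mean) - 0.5 * sigma * sigma
            cost[sel] = rng.lognormal(mu, sigma, k) if sigma > 0 else mean

        frames.append(pd.DataFrame({
            "person_id": rep_ids,
            "category": cat,
            "intervention": interv,
            "setting": setting,
            "year": config.year,
            "cost": np.round(cost, 2),
        }))

    if not frames:
        return _empty_claims(config.year)
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["person_id", "category"], kind="stable")
    return out.reset_index(drop=True)


def generate_all(config: GeneratorConfig, seed: int):
    """Run the full generator: population, assessments, claims."""
    rng = _as_rng(seed)
    population = generate_population(config, rng)
    assessments = generate_assessments(population, config, rng)
    claims = generate_claims(population, assessments, config, rng)
    return population, assessments, claims
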