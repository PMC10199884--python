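"""Tiered exact matching: band assignment, tier rules, selection
invariants, covariate balance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dermclaims.errors import ConfigError, DomainError
from dermclaims.matching import (assign_age_band, match_cohort,
                                 matching_report, standardized_differences)

from conftest import make_insurees


@pytest.mark.parametrize("age,label", [(18, "18-29"), (29, "18-29"),
                                       (30, "30-39"), (48, "40-49"),
                                       (79, "70-79"), (80, "80+"),
                                       (95, "80+")])
def test_age_band_assignment(age, label):
    assert assign_age_band(age) == label


def test_age_below_minimum_is_domain_error():
    with pytest.raises(DomainError):
        assign_age_band(17)


@settings(max_examples=200, derandomize=True)
@given(st.integers(min_value=18, max_value=120))
def test_age_bands_partition(age):
    label = assign_age_band(age)
    if label.endswith("+"):
        assert age >= int(label[:-1])
    else:
        lo, hi = map(int, label.split("-"))
        assert lo <= age <= hi


def _user(pid, region=1):
    return (pid, 45, "female", "middle", region, False, 0, "user")


def _ctrl(pid, region=1, age=45):
    return (pid, age, "female", "middle", region, False, 0, "control-pool")


def test_exact_pool_of_three_fully_used():
    users = make_insurees([_user(0)])
    pool = make_insurees([_ctrl(1), _ctrl(2), _ctrl(3)])
    cohort = match_cohort(users, pool, ratio=3, seed=0)
    assert set(cohort.control_ids) == {1, 2, 3}
    assert cohort.users["tier"].tolist() == ["full"]


def test_tier2_fills_remaining_slots():
    users = make_insurees([_user(0, region=1)])
    pool = make_insurees([_ctrl(1, region=1)]
                         + [_ctrl(i, region=9) for i in range(2, 7)])
    cohort = match_cohort(users, pool, ratio=3, seed=0)
    assert cohort.users["tier"].tolist() == ["no_region"]
    tiers = cohort.pairs["tier"].value_counts().to_dict()
    assert tiers == {"full": 1, "no_region": 2}
    assert 1 in set(cohort.control_ids)


def test_unmatched_user_excluded_and_counted():
    users = make_insurees([_user(0)])
    pool = make_insurees([(1, 80, "male", "low", 1, True, 2, "control-pool")])
    cohort = match_cohort(users, pool, ratio=3, seed=0)
    assert cohort.n_unmatched == 1
    assert len(cohort.matched_user_ids) == 0


def test_missing_ses_only_matches_missing_ses():
    users = make_insurees([(0, 45, "female", "missing", 1, False, 0, "user")])
    pool = make_insurees([_ctrl(1),
                          (2, 45, "female", "missing", 1, False, 0,
                           "control-pool")])
    cohort = match_cohort(users, pool, ratio=3, seed=0)
    assert set(cohort.control_ids) == {2}


def test_invalid_ratio_rejected():
    users = make_insurees([_user(0)])
    with pytest.raises(ConfigError):
        match_cohort(users, make_insurees([_ctrl(1)]), ratio=0, seed=0)


def test_overlapping_users_and_pool_rejected():
    users = make_insurees([_user(0)])
    pool = make_insurees([_ctrl(0)])
    with pytest.raises(DomainError):
        match_cohort(users, pool, ratio=3, seed=0)


def test_no_control_reuse(small_cohort):
    ids = small_cohort.control_ids
    assert len(ids) == len(np.unique(ids))


def test_match_key_equality_oracle(small_run, small_cohort):
    """Every matched pair literally shares the (tier-aware) match key."""
    insurees, _, _ = small_run
    from dermclaims.matching import MATCH_COVARIATES, _key_frame
    keyed = _key_frame(insurees, small_cohort.age_bands, None) \
        .set_index("person_id")
    pairs = small_cohort.pairs
    assert len(pairs) > 100
    ukeys = keyed.loc[pairs["user_id"]].reset_index(drop=True)
    ckeys = keyed.loc[pairs["control_id"]].reset_index(drop=True)
    for cov in MATCH_COVARIATES:
        same = (ukeys[cov].to_numpy() == ckeys[cov].to_numpy())
        if cov == "region":
            full = (pairs["tier"] == "full").to_numpy()
            assert same[full].all()
        else:
            assert same.all()


def test_pool_order_does_not_change_selection(small_run):
    insurees, _, _ = small_run
    users = insurees[insurees["arm"] == "user"]
    pool = insurees[insurees["arm"] == "control-pool"]
    shuffled = pool.sample(frac=1.0, random_state=99)
    a = match_cohort(users, pool, ratio=3, seed=7)
    b = match_cohort(users, shuffled, ratio=3, seed=7)
    assert a.pairs.equals(b.pairs)
    c = match_cohort(users, pool, ratio=3, seed=8)
    assert not a.pairs.equals(c.pairs)


def test_standardized_differences_zero_under_exact_full_matching():
    rows, pid = [], 0
    rng = np.random.default_rng(0)
    users = []
    for _ in range(40):
        age = int(rng.integers(18, 90))
        sex = rng.choice(["male", "female"])
        ses = rng.choice(["low", "middle", "high"])
        users.append((pid, age, sex, ses, 1, bool(rng.integers(2)),
                      int(rng.integers(3)), "user"))
        pid += 1
    pool = []
    for u in users:
        for _ in range(3):
            pool.append((pid, u[1], u[2], u[3], u[4], u[5], u[6],
                         "control-pool"))
            pid += 1
    insurees = make_insurees(users + pool)
    cohort = match_cohort(make_insurees(users), make_insurees(pool),
                          ratio=3, seed=1)
    assert (cohort.users["tier"] == "full").all()
    smd = standardized_differences(insurees, cohort)
    assert (smd.abs() == 0.0).all()


def test_matching_report_contents(small_run, small_cohort):
    insurees, _, _ = small_run
    rep = matching_report(small_cohort, insurees).set_index("metric")
    total = rep.loc[["users_full", "users_no_region", "users_unmatched"],
                    "fraction"].sum()
    assert total == pytest.approx(1.0)
    assert rep.loc["controls_selected", "value"] == len(small_cohort.pairs)


def test_matching_report_empty_cohort():
    users = make_insurees([])
    pool = make_insurees([])
    cohort = match_cohort(users, pool, ratio=3, seed=0)
    rep = matching_report(cohort)
    assert (rep["value"][:3] == 0).all()
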