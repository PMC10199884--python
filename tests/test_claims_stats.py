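"""Association statistics against independent oracles and published-count
spot checks."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from dermclaims.claims_stats import (ContingencyTable, bh_adjust,
                                     build_contingency, claims_per_1000,
                                     fisher_exact_p, history_subgroup,
                                     odds_ratio, persons_with_claim,
                                     subgroup_split, two_proportion_z)
from dermclaims.errors import DomainError

from conftest import trivial_cohort


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive)

def fisher_two_sided_enumeration(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    r1, r2, k = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, k)
    lo, hi = max(0, k - r2), min(r1, k)
    probs = [math.comb(r1, x) * math.comb(r2, k - x) / denom
             for x in range(lo, hi + 1)]
    p_obs = probs[a - lo]
    return sum(p for p in probs if p <= p_obs * (1 + 1e-9))


def ztest_formula(x1, n1, x2, n2):
    pp = (x1 + x2) / (n1 + n2)
    z = (x1 / n1 - x2 / n2) / math.sqrt(pp * (1 - pp) * (1 / n1 + 1 / n2))
    return z, 2 * sps.norm.sf(abs(z))


def bh_reference(pvals):
    """Quadratic-time step-up adjustment straight from the definition."""
    m = len(pvals)
    out = []
    for p_i in pvals:
        cands = []
        for p_j in pvals:
            if p_j >= p_i:
                rank = sum(1 for p_k in pvals if p_k <= p_j)
                cands.append(m * p_j / rank)
        out.append(min(1.0, min(cands)))
    return out


# ---------------------------------------------------------------------------
# contingency building

def _claims(rows):
    return pd.DataFrame(rows, columns=["person_id", "category",
                                       "intervention", "setting", "year",
                                       "cost"])


def test_multiple_claims_count_one_person():
    cohort = trivial_cohort([0], [1, 2, 3])
    claims = _claims([(0, "nevus", "none", "secondary", 2019, 50.0),
                      (0, "nevus", "none", "secondary", 2019, 60.0)])
    t = build_contingency(cohort, claims, "nevus")
    assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 3)


def test_no_claims_gives_zero_cases():
    cohort = trivial_cohort([0, 1], [2, 3, 4, 5, 6, 7])
    t = build_contingency(cohort, _claims([]), "nevus")
    assert (t.a, t.b, t.c, t.d) == (0, 2, 0, 6)


def test_unknown_category_is_domain_error():
    cohort = trivial_cohort([0], [1, 2, 3])
    with pytest.raises(DomainError):
        build_contingency(cohort, _claims([]), "verruca")


def test_pooled_categories_deduplicate_persons():
    cohort = trivial_cohort([0], [1, 2, 3])
    claims = _claims([(0, "premalignant", "none", "secondary", 2019, 10.0),
                      (0, "malignant", "none", "secondary", 2019, 10.0)])
    t = build_contingency(cohort, claims, ("premalignant", "malignant"))
    assert t.a == 1


# ---------------------------------------------------------------------------
# odds ratios

@pytest.mark.parametrize("cells,expected", [
    ((391, 18_569, 896, 55_984), 1.32),   # premalignant person counts
    ((850, 18_110, 667, 56_213), 3.96),   # nevi
    ((5, 5, 5, 5), 1.0),
])
def test_odds_ratio_point_estimates(cells, expected):
    res = odds_ratio(ContingencyTable(*cells))
    assert round(res.odds_ratio, 2) == expected


def test_woolf_ci_close_to_published():
    res = odds_ratio(ContingencyTable(391, 18_569, 896, 55_984))
    assert res.ci_low == pytest.approx(1.16, abs=0.02)
    assert res.ci_high == pytest.approx(1.49, abs=0.02)


def test_zero_cell_uses_haldane_correction():
    res = odds_ratio(ContingencyTable(0, 10, 5, 5))
    assert res.haldane
    assert np.isfinite(res.odds_ratio) and res.odds_ratio > 0
    assert res.ci_low <= res.odds_ratio <= res.ci_high


@settings(max_examples=150, derandomize=True)
@given(st.tuples(*[st.integers(min_value=1, max_value=60)] * 4))
def test_exposure_swap_reciprocity(cells):
    t = ContingencyTable(*cells)
    prod = odds_ratio(t).odds_ratio * odds_ratio(t.swap_exposure()).odds_ratio
    assert prod == pytest.approx(1.0, rel=1e-12)


def test_negative_cell_rejected():
    with pytest.raises(DomainError):
        ContingencyTable(-1, 1, 1, 1)


# ---------------------------------------------------------------------------
# fisher

def test_fisher_symmetric_table_is_one():
    assert fisher_exact_p(ContingencyTable(5, 5, 5, 5)) == pytest.approx(1.0)


@settings(max_examples=150, derandomize=True)
@given(st.tuples(*[st.integers(min_value=0, max_value=12)] * 4))
def test_fisher_matches_enumeration_on_small_tables(cells):
    t = ContingencyTable(*cells)
    expected = fisher_two_sided_enumeration(*cells)
    assert fisher_exact_p(t) == pytest.approx(expected, rel=1e-9, abs=1e-12)


def test_fisher_large_imbalance_significant():
    assert fisher_exact_p(ContingencyTable(391, 18_569, 896, 55_984)) < 0.001


# ---------------------------------------------------------------------------
# two-proportion z

def test_equal_proportions_give_z_zero():
    res = two_proportion_z(5, 50, 10, 100)
    assert res.z == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_gp_claim_share_difference_significant():
    assert two_proportion_z(1424, 18_960, 1913, 56_880).p < 0.001


def test_ztest_matches_formula_oracle():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n1, n2 = rng.integers(5, 500, 2)
        x1 = int(rng.integers(1, n1))
        x2 = int(rng.integers(1, n2))
        res = two_proportion_z(x1, int(n1), x2, int(n2))
        z, p = ztest_formula(x1, n1, x2, n2)
        assert res.z == pytest.approx(z, rel=1e-9)
        assert res.p == pytest.approx(p, rel=1e-9)


def test_degenerate_pooled_proportion_flagged():
    res = two_proportion_z(0, 10, 0, 20)
    assert res.degenerate and res.p == 1.0
    assert two_proportion_z(10, 10, 20, 20).degenerate


def test_zero_sample_size_rejected():
    with pytest.raises(DomainError):
        two_proportion_z(0, 0, 1, 10)


# ---------------------------------------------------------------------------
# rates

def test_claims_per_1000_published_rates():
    assert claims_per_1000(1424, 18_960).rate_rounded == 75.11
    assert claims_per_1000(1913, 56_880).rate_rounded == 33.63
    assert claims_per_1000(0, 1000).rate == 0.0


def test_claims_per_1000_zero_persons_rejected():
    with pytest.raises(DomainError):
        claims_per_1000(5, 0)


# ---------------------------------------------------------------------------
# BH

def test_bh_single_value_unchanged():
    assert bh_adjust([0.04])[0] == pytest.approx(0.04)


def test_bh_stepwise_example():
    assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])


@settings(max_examples=100, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                max_size=50))
def test_bh_matches_quadratic_reference(pvals):
    adj = bh_adjust(pvals)
    assert adj == pytest.approx(bh_reference(pvals), rel=1e-12, abs=1e-12)
    assert (adj >= np.asarray(pvals) - 1e-15).all()
    assert (adj <= 1.0).all()


def test_bh_rejects_out_of_range():
    with pytest.raises(DomainError):
        bh_adjust([0.5, 1.2])


# ---------------------------------------------------------------------------
# subgroups

def _assessments(rows):
    return pd.DataFrame(rows, columns=["person_id", "assessment_index",
                                       "cnn_result", "telederm_result"])


def test_subgroup_rules():
    users = pd.DataFrame({"person_id": [0, 1, 2], "arm": "user"})
    ass = _assessments([
        (0, 0, "low", "none"), (0, 1, "high", "low"),   # downgraded: high
        (1, 0, "low", "none"), (1, 1, "failed", "none"),
        (2, 0, "low", "high"),                          # upgraded: high
    ])
    high, low = subgroup_split(users, ass)
    assert set(high) == {0, 2} and set(low) == {1}


def test_only_failed_user_excluded_with_warning():
    users = pd.DataFrame({"person_id": [0, 1], "arm": "user"})
    ass = _assessments([(0, 0, "failed", "none"), (1, 0, "low", "none")])
    with pytest.warns(UserWarning):
        high, low = subgroup_split(users, ass)
    assert set(high) | set(low) == {1}


def test_high_risk_share_in_synthetic_cohort(small_run):
    insurees, assessments, _ = small_run
    users = insurees[insurees["arm"] == "user"]
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        high, low = subgroup_split(users, assessments)
    share = len(high) / (len(high) + len(low))
    assert share == pytest.approx(0.371, abs=0.035)


def test_history_subgroup_preserves_matched_sets(small_run, small_cohort):
    insurees, _, _ = small_run
    sub = history_subgroup(insurees, small_cohort)
    hist_ids = set(insurees.loc[insurees["history_premalignancy"],
                                "person_id"])
    assert set(sub.matched_user_ids) <= hist_ids
    # every kept user keeps exactly its original controls
    orig = small_cohort.pairs.set_index("user_id")
    for uid in sub.matched_user_ids[:20]:
        assert set(sub.pairs.loc[sub.pairs["user_id"] == uid, "control_id"]) \
            == set(np.atleast_1d(orig.loc[uid, "control_id"]))
    frac = len(sub.matched_user_ids) / len(small_cohort.matched_user_ids)
    assert frac == pytest.approx(0.047, abs=0.02)


def test_history_subgroup_empty_when_no_history(small_run, small_cohort):
    insurees, _, _ = small_run
    none = insurees.assign(history_premalignancy=False)
    sub = history_subgroup(none, small_cohort)
    assert len(sub.matched_user_ids) == 0


def test_persons_with_claim_counts_distinct(small_run):
    insurees, _, claims = small_run
    ids = insurees["person_id"].to_numpy()
    n = persons_with_claim(claims, ids, "nevus")
    assert n == claims.loc[claims["category"] == "nevus", "person_id"].nunique()
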