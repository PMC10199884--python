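"""Generator behaviour: determinism, marginal frequencies, invariants."""

import dataclasses

import numpy as np
import pytest

from dermclaims.config import CategoryConfig, GeneratorConfig
from dermclaims.errors import CalibrationError, ConfigError, GeneratorError
from dermclaims.synthetic import (calibrate_risk_concentration,
                                  combined_high_mask, generate_all,
                                  generate_assessments, generate_claims,
                                  generate_population, high_risk_user_ids)


def test_empty_population_gives_empty_tables():
    cfg = dataclasses.replace(GeneratorConfig(), n_population=0)
    pop, ass, claims = generate_all(cfg, seed=0)
    assert len(pop) == 0 and len(ass) == 0 and len(claims) == 0


def test_identical_seed_reproduces_byte_identical_tables(small_config):
    a = generate_all(small_config, seed=42)
    b = generate_all(small_config, seed=42)
    for ta, tb in zip(a, b):
        assert ta.to_csv(index=False) == tb.to_csv(index=False)


def test_different_seeds_differ(small_config):
    a = generate_all(small_config, seed=1)[0]
    b = generate_all(small_config, seed=2)[0]
    assert not a.equals(b)


def test_user_fraction_within_three_binomial_se():
    n, p = 10_000, 0.009
    cfg = dataclasses.replace(GeneratorConfig(), n_population=n, uptake_rate=p)
    pop = generate_population(cfg, seed=3)
    se = np.sqrt(p * (1 - p) / n)
    assert abs((pop["arm"] == "user").mean() - p) < 3 * se


def test_population_marginals_match_defaults(medium_run):
    insurees, _, _ = medium_run
    users = insurees[insurees["arm"] == "user"]
    n = len(users)
    assert n > 2000
    # three binomial SEs around the configured frequencies
    for col, p in (((users["sex"] == "female"), 0.532),
                   (users["history_premalignancy"], 0.047),
                   ((users["ses"] == "missing"), 0.011)):
        se = np.sqrt(p * (1 - p) / n)
        assert abs(col.mean() - p) < 3 * se
    assert abs(users["age"].mean() - 48.4) < 3 * 14.0 / np.sqrt(n)
    assert users["age"].min() >= 18


def test_invalid_probability_vector_rejected():
    with pytest.raises(ConfigError):
        dataclasses.replace(GeneratorConfig(),
                            cnn_probs=(0.5, 0.2, 0.2, 0.2)).validate()
    with pytest.raises(ConfigError):
        dataclasses.replace(GeneratorConfig(), uptake_rate=1.5).validate()


def test_every_user_has_a_successful_assessment(small_run):
    insurees, assessments, _ = small_run
    users = insurees.loc[insurees["arm"] == "user", "person_id"]
    ok = assessments.loc[assessments["cnn_result"] != "failed", "person_id"]
    assert set(users) == set(ok.unique())


def test_assessment_conservation(small_run):
    _, assessments, _ = small_run
    counts = assessments["cnn_result"].value_counts()
    assert counts.sum() == len(assessments)


def test_failed_assessment_has_no_telederm_rating(small_run):
    _, assessments, _ = small_run
    failed = assessments[assessments["cnn_result"] == "failed"]
    assert (failed["telederm_result"] == "none").all()


def test_cnn_outcome_frequencies(medium_run):
    _, assessments, _ = medium_run
    freq = assessments["cnn_result"].value_counts(normalize=True)
    # high-risk outcomes cluster within users, so allow a wider band than
    # the naive binomial SE
    assert abs(freq["high"] - 0.235) < 0.015
    assert abs(freq["failed"] - 0.048) < 0.01


def test_override_rates(medium_run):
    _, assessments, _ = medium_run
    low = assessments[assessments["cnn_result"].isin(["low", "low_symptoms"])]
    high = assessments[assessments["cnn_result"] == "high"]
    assert abs((low["telederm_result"] == "high").mean() - 0.028) < 0.005
    assert abs((high["telederm_result"] == "low").mean() - 0.338) < 0.02


def test_high_risk_user_share_calibrated(medium_run):
    insurees, assessments, _ = medium_run
    n_users = (insurees["arm"] == "user").sum()
    share = len(high_risk_user_ids(assessments)) / n_users
    assert abs(share - 0.371) < 0.03


def test_unattainable_high_risk_share_raises():
    with pytest.raises(CalibrationError):
        calibrate_risk_concentration(0.235, 0.585, 0.132, 0.048, 0.028,
                                     3.38, 1.0, 0.999)


def test_all_failed_config_raises(small_config):
    cfg = dataclasses.replace(small_config, cnn_probs=(0.0, 0.0, 0.0, 1.0),
                              max_retries=5)
    users = generate_population(
        dataclasses.replace(cfg, n_population=200, uptake_rate=0.5), seed=0)
    with pytest.raises(GeneratorError):
        generate_assessments(users, cfg, 0)


def test_no_overrides_means_combined_equals_cnn(small_config):
    cfg = dataclasses.replace(small_config, p_upgrade=0.0, p_downgrade=0.0)
    pop = generate_population(cfg, seed=9)
    ass = generate_assessments(pop, cfg, 9)
    assert (combined_high_mask(ass) == (ass["cnn_result"] == "high")).all()


def test_zero_claim_probabilities_give_empty_claims(small_config):
    cats = {name: dataclasses.replace(c, p_control=0.0, p_user_low=0.0,
                                      p_user_high=0.0)
            for name, c in small_config.categories.items()}
    cfg = dataclasses.replace(small_config, categories=cats)
    pop = generate_population(cfg, seed=1)
    ass = generate_assessments(pop, cfg, 1)
    assert len(generate_claims(pop, ass, cfg, 1)) == 0


def test_negative_cost_parameter_rejected():
    with pytest.raises(ConfigError):
        CategoryConfig(0.01, 0.01, 0.01, 1.0, -5.0, 10.0).validate("nevus")


def test_person_level_claim_proportions(medium_run):
    insurees, _, claims = medium_run
    users = insurees.loc[insurees["arm"] == "user", "person_id"]
    controls = insurees.loc[insurees["arm"] == "control-pool", "person_id"]
    nevus_ids = claims.loc[claims["category"] == "nevus", "person_id"].unique()
    p_user = np.isin(users, nevus_ids).mean()
    p_ctrl = np.isin(controls, nevus_ids).mean()
    se_u = np.sqrt(0.0448 * (1 - 0.0448) / len(users))
    assert abs(p_user - 0.0448) < 3 * se_u
    assert abs(p_ctrl - 0.0117) < 3 * np.sqrt(0.0117 * 0.9883 / len(controls))


def test_claim_costs_nonnegative_and_setting_consistent(small_run):
    _, _, claims = small_run
    assert (claims["cost"] >= 0).all()
    from dermclaims.schema import INTERVENTION_SETTING
    assert (claims["setting"]
            == claims["intervention"].map(INTERVENTION_SETTING)).all()
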