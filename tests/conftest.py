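import dataclasses

import numpy as np
import pandas as pd
import pytest

from dermclaims.config import GeneratorConfig
from dermclaims.matching import MatchedCohort, match_cohort
from dermclaims.synthetic import generate_all


@pytest.fixture(scope="session")
def small_config():
    """Fast generator config: 20k insurees, 5% uptake, coarse regions."""
    return dataclasses.replace(GeneratorConfig(), n_population=20_000,
                               uptake_rate=0.05, n_regions=8)


@pytest.fixture(scope="session")
def small_run(small_config):
    return generate_all(small_config, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_run):
    insurees, _, _ = small_run
    users = insurees[insurees["arm"] == "user"]
    pool = insurees[insurees["arm"] == "control-pool"]
    return match_cohort(users, pool, ratio=3, seed=11)


@pytest.fixture(scope="session")
def medium_run():
    """Study-default rates at 400k population (~3.4k users), for tests of
    marginal frequencies."""
    cfg = dataclasses.replace(GeneratorConfig(), n_population=400_000,
                              n_regions=64)
    return generate_all(cfg, seed=5)


def make_insurees(rows):
    """Build an insuree frame from (id, age, sex, ses, region, history,
    comorb, arm) tuples."""
    return pd.DataFrame(rows, columns=["person_id", "age", "sex", "ses",
                                       "region", "history_premalignancy",
                                       "n_comorbidities", "arm"])


def trivial_cohort(user_ids, control_ids):
    """A MatchedCohort linking each user to all given controls' id list
    positionally (len(control_ids) must be a multiple of len(user_ids))."""
    k = len(control_ids) // len(user_ids)
    pairs = pd.DataFrame({
        "user_id": np.repeat(np.asarray(user_ids), k),
        "control_id": np.asarray(control_ids),
        "tier": "full",
    })
    users = pd.DataFrame({
        "person_id": user_ids, "tier": "full", "n_controls": k,
        "age_band": "40-49", "sex": "female", "ses": "middle", "region": 0,
        "history_premalignancy": False, "n_comorbidities": 0,
    })
    return MatchedCohort(pairs, users, ratio=k)
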