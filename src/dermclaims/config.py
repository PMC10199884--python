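"""Configuration objects for the synthetic generator and the pipeline.

The generator defaults emulate the 2019 Dutch-insurer cohort this pipeline
was designed around: ~2.2 million adult insurees offered a free AI-based
skin-check app, ~1 in 116 completing at least one successful assessment,
with assessment-outcome frequencies, person-level claim probabilities and
per-person annual dermatological costs matching that cohort's published
aggregates.  Where only a per-person cost is known, the per-claim cost mean
is derived from it and the configured claims-per-claimant model; see
``docs/methods.md`` for the derivations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .errors import ConfigError
from .schema import CATEGORIES, INTERVENTIONS

_PROB_TOL = 1e-12

#: Fraction of app users whose assessments include at least one high-risk
#: rating (CNN or teledermatologist); used to calibrate the per-user
#: risk-propensity distribution and to mix the subgroup claim probabilities.
HIGH_RISK_USER_SHARE = 0.371

#: App subscription cost per user-year in euros.  Never published; this
#: demonstration default is reverse-engineered so that the calibrated
#: cost-effectiveness model reproduces the cohort's observed ICER of
#: ~EUR 2567 at the accuracy calibration point (sens 0.87, spec 0.70).
DEFAULT_APP_COST = 16.26


@dataclass(frozen=True)
class CategoryConfig:
    """Claim-generation parameters for one diagnosis category.

    Person-level claim probabilities are conditional on study arm and, for
    app users, on whether the person ever received a high-risk assessment.
    A claimant files ``1 + Poisson(extra_claims_mean)`` claims in the year;
    per-claim costs are log-normal with the given arithmetic mean.
    """

    p_control: float
    p_user_low: float
    p_user_high: float
    extra_claims_mean: float
    cost_mean_user: float
    cost_mean_control: float
    intervention_user: dict = field(default_factory=dict)
    intervention_control: dict = field(default_factory=dict)

    @property
    def p_user_marginal(self) -> float:
        s = HIGH_RISK_USER_SHARE
        return s * self.p_user_high + (1.0 - s) * self.p_user_low

    def validate(self, name: str) -> None:
        for fld in ("p_control", "p_user_low", "p_user_high"):
            v = getattr(self, fld)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"category {name}: {fld}={v} outside [0, 1]")
        if self.extra_claims_mean < 0:
            raise ConfigError(f"category {name}: negative extra_claims_mean")
        for fld in ("cost_mean_user", "cost_mean_control"):
            if getattr(self, fld) < 0:
                raise ConfigError(f"category {name}: negative {fld}")
        for arm, dist in (("user", self.intervention_user),
                          ("control", self.intervention_control)):
            if not dist:
                continue
            unknown = set(dist) - set(INTERVENTIONS)
            if unknown:
                raise ConfigError(
                    f"category {name}: unknown interventions {sorted(unknown)}")
            total = sum(dist.values())
            if any(p < 0 for p in dist.values()) or abs(total - 1.0) > _PROB_TOL:
                raise ConfigError(
                    f"category {name}: {arm} intervention probabilities "
                    f"must be nonnegative and sum to 1 (got {total!r})")


def _default_categories() -> dict:
    """Category defaults calibrated to the study cohort's aggregates.

    Person-level probabilities come from the published person counts
    (controls and the high/low-risk user subgroups); the pooled
    nevus+benign subgroup probabilities are split by the overall 850:267
    nevus:benign claimant ratio.  Per-claim cost means are chosen so the
    implied per-person annual costs match the published per-person means,
    holding the published malignant per-claim means fixed.
    """
    s = HIGH_RISK_USER_SHARE
    nevus_share = 850.0 / 1117.0

    p = {
        "premalignant": dict(p_control=0.0158, p_user_low=0.0154,
                             p_user_high=0.0295, extra=1.0),
        "malignant": dict(p_control=0.0314, p_user_low=0.0278,
                          p_user_high=0.0628, extra=0.2),
        "nevus": dict(p_control=0.0117, p_user_low=0.0352 * nevus_share,
                      p_user_high=0.0987 * nevus_share, extra=1.5),
        "benign_tumor": dict(p_control=0.0049,
                             p_user_low=0.0352 * (1 - nevus_share),
                             p_user_high=0.0987 * (1 - nevus_share), extra=1.0),
        "unrelated_dermatology": dict(p_control=0.0492, p_user_low=0.0483,
                                      p_user_high=0.0604, extra=2.5),
    }

    # Per-person annual cost anchors (euros). The benign-tumor values are
    # residuals of the published total against the published components.
    per_person_user = {"nevus": 11.05, "benign_tumor": 2.90,
                       "unrelated_dermatology": 20.01}
    per_person_control = {"nevus": 2.71, "benign_tumor": 1.03,
                          "unrelated_dermatology": 18.47}
    pm_per_person = {"user": 31.01, "control": 20.88}  # premalignant+malignant
    malignant_per_claim = {"user": 613.36, "control": 520.05}

    def marginal(cat, arm):
        if arm == "user":
            return s * p[cat]["p_user_high"] + (1 - s) * p[cat]["p_user_low"]
        return p[cat]["p_control"]

    def claims_pp(cat, arm):
        return marginal(cat, arm) * (1.0 + p[cat]["extra"])

    cost_mean = {}
    for arm in ("user", "control"):
        cm = malignant_per_claim[arm]
        resid = pm_per_person[arm] - claims_pp("malignant", arm) * cm
        cost_mean["malignant", arm] = cm
        cost_mean["premalignant", arm] = resid / claims_pp("premalignant", arm)
        for cat in ("nevus", "benign_tumor", "unrelated_dermatology"):
            anchor = per_person_user[cat] if arm == "user" else per_person_control[cat]
            cost_mean[cat, arm] = anchor / claims_pp(cat, arm)

    # Intervention mix per claim, tuned so intervention claim volumes per
    # 1000 persons land near the cohort's primary/secondary-care volumes.
    iv_user = {
        "premalignant": {"gp_biopsy_excision": 0.30,
                         "hospital_excision_premalignant": 0.25, "none": 0.45},
        "malignant": {"gp_biopsy_excision": 0.30, "mohs": 0.04,
                      "hospital_excision_premalignant": 0.50, "none": 0.16},
        "nevus": {"gp_biopsy_excision": 0.35, "gp_teledermatology": 0.047,
                  "hospital_excision_benign": 0.14, "none": 0.463},
        "benign_tumor": {"gp_biopsy_excision": 0.30,
                         "hospital_excision_benign": 0.14, "none": 0.56},
        "unrelated_dermatology": {"none": 1.0},
    }
    iv_control = {
        "premalignant": {"gp_biopsy_excision": 0.31,
                         "hospital_excision_premalignant": 0.15, "none": 0.54},
        "malignant": {"gp_biopsy_excision": 0.31, "mohs": 0.044,
                      "hospital_excision_premalignant": 0.40, "none": 0.246},
        "nevus": {"gp_biopsy_excision": 0.31, "gp_teledermatology": 0.079,
                  "hospital_excision_benign": 0.124, "none": 0.487},
        "benign_tumor": {"gp_biopsy_excision": 0.31,
                         "hospital_excision_benign": 0.124, "none": 0.566},
        "unrelated_dermatology": {"none": 1.0},
    }

    return {
        cat: CategoryConfig(
            p_control=p[cat]["p_control"],
            p_user_low=p[cat]["p_user_low"],
            p_user_high=p[cat]["p_user_high"],
            extra_claims_mean=p[cat]["extra"],
            cost_mean_user=round(cost_mean[cat, "user"], 2),
            cost_mean_control=round(cost_mean[cat, "control"], 2),
            intervention_user=iv_user[cat],
            intervention_control=iv_control[cat],
        )
        for cat in CATEGORIES
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic insured population.

    Defaults are the study conditions: a ~2.2M adult population with
    ~0.86% app uptake, CNN outcome frequencies (58.5 / 13.2 / 23.5 / 4.8 %
    for low / low-with-symptoms / high / failed), a 2.8% teledermatologist
    upgrade rate per CNN-low photo and a 33.8% downgrade rate per CNN-high
    photo, and per-category claim probabilities per arm and risk subgroup.
    """

    n_population: int = 2_213_212
    uptake_rate: float = 18_960 / 2_213_212

    # demographics
    age_mean: float = 48.4
    age_sd: float = 14.0
    age_min: int = 18
    p_female: float = 0.532
    # SES levels conditional on SES being observed (renormalised published
    # shares 23.0 / 42.6 / 33.2 %); missingness handled separately.
    ses_probs: tuple = (0.23 / 0.988, 0.426 / 0.988, 0.332 / 0.988)
    p_ses_missing: float = 0.011
    # residential area proxied by anonymised GP-practice codes; ~2500 codes
    # over 2.2M insurees gives realistic key fragmentation for matching
    n_regions: int = 2500
    p_history: float = 0.047
    comorbidity_mean: float = 0.25
    comorbidity_cap: int = 5

    # app usage
    mean_assessments: float = 64_128 / 18_960
    nb_size: float = 1.0  # negative-binomial dispersion of assessment counts
    cnn_probs: tuple = (0.585, 0.132, 0.235, 0.048)  # low, low_sympt, high, failed
    p_upgrade: float = 0.028
    p_downgrade: float = 0.338
    #: target share of users with >=1 high-risk assessment; drives the
    #: per-user risk-propensity calibration (None concentration = calibrate).
    high_risk_user_share: float = HIGH_RISK_USER_SHARE
    high_risk_concentration: float | None = None

    # claims
    categories: dict = field(default_factory=_default_categories)
    cost_sigma: float = 0.8  # log-normal shape, shared across categories
    year: int = 2019

    #: additive shift of the control-pool age mean; nonzero values create
    #: covariate shift to exercise matching fallback/failure paths.
    control_age_shift: float = 0.0

    max_retries: int = 100

    def validate(self) -> None:
        if self.n_population < 0:
            raise ConfigError("n_population must be >= 0")
        for fld in ("uptake_rate", "p_female", "p_ses_missing", "p_history",
                    "p_upgrade", "p_downgrade", "high_risk_user_share"):
            v = getattr(self, fld)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{fld}={v} outside [0, 1]")
        for name, vec in (("ses_probs", self.ses_probs),
                          ("cnn_probs", self.cnn_probs)):
            if any(p < 0 or p > 1 for p in vec):
                raise ConfigError(f"{name} entries must lie in [0, 1]")
            if abs(sum(vec) - 1.0) > _PROB_TOL:
                raise ConfigError(
                    f"{name} must sum to 1 within {_PROB_TOL} (got {sum(vec)!r})")
        if self.age_sd <= 0 or self.age_mean <= self.age_min:
            raise ConfigError("age distribution requires sd > 0 and mean > age_min")
        if self.n_regions < 1:
            raise ConfigError("n_regions must be >= 1")
        if self.comorbidity_mean < 0 or self.comorbidity_cap < 0:
            raise ConfigError("comorbidity parameters must be nonnegative")
        if self.mean_assessments < 1:
            raise ConfigError("mean_assessments must be >= 1 (every user has one)")
        if self.nb_size <= 0:
            raise ConfigError("nb_size must be > 0")
        if self.cost_sigma < 0:
            raise ConfigError("cost_sigma must be >= 0")
        if set(self.categories) != set(CATEGORIES):
            raise ConfigError(
                f"categories must be exactly {sorted(CATEGORIES)}")
        for name, cat in self.categories.items():
            cat.validate(name)

    def with_odds_ratios(self, odds_ratios: dict) -> "GeneratorConfig":
        """Return a config whose user claim probabilities imply the given
        person-level odds ratios versus the control probabilities.

        Both user subgroups get the same probability, so the configured OR
        holds marginally regardless of the subgroup split.
        """
        cats = dict(self.categories)
        for name, target in odds_ratios.items():
            if target <= 0:
                raise ConfigError(f"odds ratio for {name} must be > 0")
            base = cats[name]
            odds0 = base.p_control / (1.0 - base.p_control)
            p1 = target * odds0 / (1.0 + target * odds0)
            cats[name] = dataclasses.replace(
                base, p_user_low=p1, p_user_high=p1)
        return dataclasses.replace(self, categories=cats)


def _grid(start: float, stop: float, step: float) -> tuple:
    n = int(round((stop - start) / step)) + 1
    return tuple(round(start + i * step, 10) for i in range(n))


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline options: generator, matching, statistics, CEA."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    # matching
    ratio: int = 3
    age_band_edges: tuple = (18, 30, 40, 50, 60, 70, 80)
    match_comorbidity_cap: int | None = None

    # statistics
    z_continuity: bool = False
    welch: bool = True
    rounding_decimals: int = 2

    # cost-effectiveness
    app_cost_per_user: float = DEFAULT_APP_COST
    sens0: float = 0.87
    spec0: float = 0.70
    sens_grid: tuple = field(default_factory=lambda: _grid(0.50, 1.00, 0.05))
    spec_grid: tuple = field(default_factory=lambda: _grid(0.50, 1.00, 0.05))

    def validate(self) -> None:
        self.generator.validate()
        if self.ratio < 1:
            raise ConfigError("matching ratio must be >= 1")
        edges = self.age_band_edges
        if len(edges) < 1 or list(edges) != sorted(set(edges)):
            raise ConfigError("age_band_edges must be strictly increasing")
        if edges[0] != self.generator.age_min:
            raise ConfigError("first age band must start at the minimum age")
        for fld in ("sens0", "spec0"):
            if not 0.0 <= getattr(self, fld) <= 1.0:
                raise ConfigError(f"{fld} outside [0, 1]")
        if self.app_cost_per_user < 0:
            raise ConfigError("app_cost_per_user must be >= 0")
        for name, grid in (("sens_grid", self.sens_grid),
                           ("spec_grid", self.spec_grid)):
            if not grid or any(not 0.0 <= g <= 1.0 for g in grid):
                raise ConfigError(f"{name} values must lie in [0, 1]")


def _to_dict(cfg) -> dict:
    return dataclasses.asdict(cfg)


def config_to_yaml(cfg: PipelineConfig) -> str:
    return yaml.safe_dump(_to_dict(cfg), sort_keys=True)


def config_from_yaml(text: str) -> PipelineConfig:
    raw = yaml.safe_load(text) or {}
    gen_raw = raw.pop("generator", {})
    cats_raw = gen_raw.pop("categories", None)
    gen_kwargs = dict(gen_raw)
    for fld in ("ses_probs", "cnn_probs"):
        if fld in gen_kwargs:
            gen_kwargs[fld] = tuple(gen_kwargs[fld])
    if cats_raw is not None:
        gen_kwargs["categories"] = {
            name: CategoryConfig(**c) for name, c in cats_raw.items()}
    pipe_kwargs = dict(raw)
    for fld in ("age_band_edges", "sens_grid", "spec_grid"):
        if fld in pipe_kwargs:
            pipe_kwargs[fld] = tuple(pipe_kwargs[fld])
    cfg = PipelineConfig(generator=GeneratorConfig(**gen_kwargs), **pipe_kwargs)
    cfg.validate()
    return cfg


def config_hash(cfg: PipelineConfig) -> str:
    """Stable short hash of the full configuration, for run manifests."""
    blob = json.dumps(_to_dict(cfg), sort_keys=True, default=float)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
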