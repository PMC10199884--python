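"""End-to-end orchestration: simulate -> match -> analyze -> costs -> cea.

Every stage is deterministic given the configuration and seed, reads and
writes the documented CSV formats, and logs its record counts.  The run
manifest records the seed, a configuration hash, and per-stage counts, so
two runs with the same inputs produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import io
from .cea import calibrate, icer_surface, observed_aggregates, plot_surface
from .claims_stats import association_table, intervention_table, subgroup_tables
from .config import PipelineConfig, config_hash
from .cost_stats import cost_table
from .errors import DermClaimsError
from .matching import AgeBands, match_cohort, matching_report
from .synthetic import generate_all

__all__ = ["run_pipeline", "run_stage_simulate", "run_stage_match",
           "run_stage_analyze", "run_stage_costs", "run_stage_cea"]

log = logging.getLogger("dermclaims")


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except DermClaimsError:
                raise
            except Exception as exc:  # tag unexpected failures with the stage
                raise DermClaimsError(f"stage {name} failed: {exc}") from exc
        wrapper.__name__ = fn.__name__
        wrapper.__doc__ = fn.__doc__
        return wrapper
    return deco


@_stage("simulate")
def run_stage_simulate(config: PipelineConfig, seed: int, out: Path):
    insurees, assessments, claims = generate_all(config.generator, seed)
    io.write_insurees(insurees, out / "insurees.csv")
    io.write_assessments(assessments, out / "assessments.csv")
    io.write_claims(claims, out / "claims.csv")
    log.info("simulate: %d insurees, %d assessments, %d claims",
             len(insurees), len(assessments), len(claims))
    return insurees, assessments, claims


@_stage("match")
def run_stage_match(config: PipelineConfig, seed: int, insurees, out: Path):
    bands = AgeBands(config.age_band_edges)
    users = insurees[insurees["arm"] == "user"]
    pool = insurees[insurees["arm"] == "control-pool"]
    cohort = match_cohort(users, pool, ratio=config.ratio, seed=seed,
                          age_bands=bands,
                          comorbidity_cap=config.match_comorbidity_cap)
    cohort.pairs.to_csv(out / "matched_cohort.csv", index=False)
    report = matching_report(cohort, insurees)
    report.to_csv(out / "matching_report.csv", index=False)
    log.info("match: %d users, %d controls, %d unmatched",
             len(cohort.matched_user_ids), len(cohort.control_ids),
             cohort.n_unmatched)
    return cohort


@_stage("analyze")
def run_stage_analyze(config: PipelineConfig, cohort, insurees, assessments,
                      claims, out: Path):
    users = insurees[insurees["arm"] == "user"]
    t2 = association_table(cohort, claims, continuity=config.z_continuity)
    t3 = intervention_table(cohort, claims, continuity=config.z_continuity)
    t4 = subgroup_tables(cohort, claims, assessments, users,
                         continuity=config.z_continuity)
    dp = config.rounding_decimals
    for name, tab in (("table2", t2), ("table3", t3), ("table4", t4)):
        tab.round(dp).to_csv(out / f"{name}.csv", index=False)
    log.info("analyze: %d association rows, %d intervention rows, "
             "%d subgroup rows", len(t2), len(t3), len(t4))
    return t2, t3, t4


@_stage("costs")
def run_stage_costs(config: PipelineConfig, cohort, claims, out: Path):
    costs = cost_table(claims, cohort, welch=config.welch)
    costs.round(config.rounding_decimals).to_csv(out / "costs.csv", index=False)
    log.info("costs: %d category rows", len(costs))
    return costs


@_stage("cea")
def run_stage_cea(config: PipelineConfig, cohort, claims, out: Path,
                  figure: bool = True):
    observed = observed_aggregates(cohort, claims)
    params = calibrate(observed, config.sens0, config.spec0,
                       config.app_cost_per_user)
    surface = icer_surface(params, config.sens_grid, config.spec_grid)
    surface.to_long().round(config.rounding_decimals).to_csv(
        out / "icer_surface.csv", index=False)
    if figure:
        fig = plot_surface(surface)
        fig.savefig(out / "icer_surface.png", dpi=120)
    log.info("cea: calibrated v*pi*alpha=%.5f, v*(1-pi)*alpha=%.5f",
             params.v_pi_alpha, params.v_1mpi_alpha)
    return observed, params, surface


def run_pipeline(config: PipelineConfig, seed: int, out_dir,
                 inputs: tuple | None = None, figure: bool = False) -> dict:
    """Run the full pipeline and return a result bundle.

    ``inputs`` may name existing (insurees, assessments, claims) CSV paths
    to skip simulation; downstream behaviour is identical.  Returns a dict
    with the in-memory objects and the output directory.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if inputs is None:
        insurees, assessments, claims = run_stage_simulate(config, seed, out)
    else:
        insurees, assessments, claims = io.read_tables(*inputs)

    cohort = run_stage_match(config, seed, insurees, out)
    t2, t3, t4 = run_stage_analyze(config, cohort, insurees, assessments,
                                   claims, out)
    costs = run_stage_costs(config, cohort, claims, out)
    observed, params, surface = run_stage_cea(config, cohort, claims, out,
                                              figure=figure)

    n_users = len(cohort.matched_user_ids)
    tier_full = int((cohort.users["tier"] == "full").sum())
    dp = config.rounding_decimals
    all_costs = costs[costs["category"] == "all"].iloc[0]
    summary = {
        "n_users_analyzed": n_users,
        "n_controls_analyzed": int(len(cohort.control_ids)),
        "tier1_fraction": round(tier_full / max(len(cohort.users), 1), 4),
        "odds_ratios": {
            row.category: round(row.odds_ratio, dp)
            for row in t2.itertuples()},
        "cost_delta_per_person": round(float(all_costs["delta"]), dp),
        "icer_at_calibration": round(float(icer_surface(
            params, [config.sens0], [config.spec0]).icer_full[0, 0]), dp),
        "icer_full_perfect": round(float(surface.at(1.0, 1.0)[0]), dp),
        "icer_benign_only_perfect": round(float(surface.at(1.0, 1.0)[1]), dp),
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")

    io.write_manifest(out / "manifest.json", seed, config_hash(config), {
        "insurees": len(insurees),
        "assessments": len(assessments),
        "claims": len(claims),
        "matched_users": n_users,
        "controls": int(len(cohort.control_ids)),
        "unmatched_users": cohort.n_unmatched,
    })

    return {
        "out_dir": out,
        "insurees": insurees, "assessments": assessments, "claims": claims,
        "cohort": cohort,
        "table2": t2, "table3": t3, "table4": t4, "costs": costs,
        "observed": observed, "cea_params": params, "surface": surface,
        "summary": summary,
    }
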