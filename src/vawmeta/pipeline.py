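"""End-to-end convenience workflow tying the modules together.

``run_pipeline`` executes the full chain on in-memory inputs: preparation
(imputation, effective sample sizes), the two-dataset split, crosswalk
factor estimation, adjustment-vector sampling, model fitting (optionally
mixed over adjustment draws), and post-processed estimates.  The CLI and
the reproduction script are thin wrappers around it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crosswalk import (
    AdjustmentDrawSet,
    AdjustmentFactorSet,
    estimate_adjustment_factors,
    filter_adjustable,
    observation_offsets,
    sample_adjustment_vectors,
)
from .inference import McmcConfig, PosteriorDraws, fit, fit_mixed_over_adjustments
from .model_core import ModelSpec, build_model_spec
from .preprocess import build_datasets, prepare_observations
from .vaw_data import GeoHierarchy, PopulationWeights

OUTCOMES = ("lifetime", "past_year")


@dataclass
class PipelineResult:
    prepared: pd.DataFrame
    adjustment_dataset: pd.DataFrame
    modeling_dataset: pd.DataFrame
    factors: AdjustmentFactorSet
    draw_set: AdjustmentDrawSet
    X_by_outcome: dict
    spec: ModelSpec
    post: PosteriorDraws | None


def prepare_and_split(observations, pop2010, hierarchy,
                      design_effect: float = 2.5):
    prepared = prepare_observations(observations, pop2010, hierarchy,
                                    design_effect=design_effect)
    return build_datasets(prepared)


def spec_factory_for(modeling_dataset, hierarchy, pop2010, age_knots=(25,),
                     time_knot: float = 2011.0, constraints_enabled: bool = True):
    """A factory mapping an adjustment beta-vector to a ready ModelSpec."""

    def factory(beta_vector, draw_id=None):
        mod, _ = filter_adjustable(modeling_dataset, hierarchy, beta_vector)
        X = {o: observation_offsets(mod[mod.outcome == o], hierarchy, beta_vector)
             for o in sorted(mod.outcome.unique())}
        return build_model_spec(mod, hierarchy, pop2010, X, age_knots=age_knots,
                                time_knot=time_knot,
                                constraints_enabled=constraints_enabled,
                                adjustment_draw_id=draw_id)

    return factory


def run_pipeline(observations, hierarchy: GeoHierarchy,
                 pop2010: PopulationWeights, cfg: McmcConfig,
                 age_knots=(25,), time_knot: float = 2011.0,
                 mix_adjustment_draws: bool = False,
                 n_adjustment_draws: int | None = None,
                 design_effect: float = 2.5,
                 do_fit: bool = True, outcomes=None) -> PipelineResult:
    prepared = prepare_observations(observations, pop2010, hierarchy,
                                    design_effect=design_effect)
    adj, mod = build_datasets(prepared)
    factors = estimate_adjustment_factors(adj, hierarchy)
    D = n_adjustment_draws if n_adjustment_draws is not None else cfg.n_adjustment_draws
    draw_set = sample_adjustment_vectors(
        factors, OUTCOMES, hierarchy.super_regions, D=D, seed=cfg.seed)
    factory = spec_factory_for(mod, hierarchy, pop2010, age_knots, time_knot)
    point = draw_set.point_estimate_vector()
    spec = factory(point)
    mod_kept, _ = filter_adjustable(mod, hierarchy, point)
    X = {o: observation_offsets(mod_kept[mod_kept.outcome == o], hierarchy, point)
         for o in sorted(mod_kept.outcome.unique())}
    post = None
    if do_fit:
        if mix_adjustment_draws:
            post = fit_mixed_over_adjustments(factory, draw_set, cfg)
        else:
            post = fit(spec, cfg, outcomes=outcomes)
    return PipelineResult(prepared, adj, mod_kept, factors, draw_set, X, spec, post)
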