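"""Model validation: posterior predictive checks and held-out comparisons.

Three views of model performance:

* graphical posterior predictive checks — per observation, the observed
  prevalence against replicated survey prevalence drawn from
  Binomial(p_it, N_it) per posterior draw (on the observation's own
  instrument scale, i.e. including its study effect and X offset);
* in-sample summary metrics — median error ("observed − predicted", in
  percentage points), median absolute error, and the share of
  observations falling below / above the 95% interval;
* out-of-sample cross-validation — refit after excluding 20% of
  countries (or studies) and compare held-out observations with
  predictions, repeated (default 20 times) and summarized by medians.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .inference import McmcConfig, PosteriorDraws, fit
from .model_core import build_model_spec
from .postprocess import impute_country_logits, predict_country_logits
from .vaw_data import AGE_BAND_LOWER, GeoHierarchy, PopulationWeights, bands_in_range

logger = logging.getLogger(__name__)


@dataclass
class ValidationReport:
    """Summary of prediction errors for one comparison scope."""

    scope: str                 # in_sample | oos_countries | oos_studies
    outcome: str
    n_units: int
    median_error: float        # percentage points, observed - predicted
    median_abs_error: float
    pct_below_ci: float
    pct_above_ci: float
    n_repeats: int = 1

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _interval_and_median(p_draws: np.ndarray, n: np.ndarray | None, rng,
                         interval: str):
    """Median and 95% bounds per observation, credible or predictive."""
    if interval == "credible":
        arr = p_draws
    elif interval == "predictive":
        y_rep = rng.binomial(n.astype(int)[None, :], p_draws)
        arr = y_rep / n[None, :]
    else:
        raise ValueError(f"unknown interval type {interval!r}")
    return (np.median(arr, axis=0), np.quantile(arr, 0.025, axis=0),
            np.quantile(arr, 0.975, axis=0))


def posterior_predictive_check(post: PosteriorDraws, outcome: str,
                               seed: int = 0) -> pd.DataFrame:
    """Per-observation observed vs replicated prevalence with 95% intervals."""
    d = post.spec.outcome_data[outcome]
    p_draws = post.p_obs[outcome].reshape(-1, d.n_obs)
    rng = np.random.default_rng(seed)
    med, lo, hi = _interval_and_median(p_draws, d.n, rng, "predictive")
    obs_p = d.y / d.n
    regions = [post.spec.units.regions[i] for i in d.region_idx]
    return pd.DataFrame(dict(
        obs_id=d.obs_ids, region=regions, observed=obs_p,
        predicted=med, pi_lower=lo, pi_upper=hi,
        inside=(obs_p >= lo) & (obs_p <= hi)))


def plot_ppc(ppc: pd.DataFrame, path, max_regions: int = 16) -> None:
    """Faceted observed-vs-replicated plot, one panel per region."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    regions = sorted(ppc.region.unique())[:max_regions]
    ncol = min(4, len(regions))
    nrow = int(np.ceil(len(regions) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow), squeeze=False)
    for ax, region in zip(axes.flat, regions):
        sub = ppc[ppc.region == region].reset_index(drop=True)
        x = np.arange(len(sub))
        ax.errorbar(x, sub.predicted, yerr=[sub.predicted - sub.pi_lower,
                                            sub.pi_upper - sub.predicted],
                    fmt="o", color="goldenrod", ms=3, label="replicated")
        ax.plot(x, sub.observed, "^", color="grey", ms=4, label="observed")
        ax.set_title(region, fontsize=9)
        ax.set_ylim(0, 1)
    for ax in axes.flat[len(regions):]:
        ax.axis("off")
    axes.flat[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def in_sample_metrics(post: PosteriorDraws, outcome: str,
                      interval: str = "credible", seed: int = 0) -> ValidationReport:
    """In-sample comparison of fitted and observed prevalence."""
    d = post.spec.outcome_data[outcome]
    p_draws = post.p_obs[outcome].reshape(-1, d.n_obs)
    rng = np.random.default_rng(seed)
    med, lo, hi = _interval_and_median(p_draws, d.n, rng, interval)
    obs_p = d.y / d.n
    err = (obs_p - med) * 100.0
    return ValidationReport(
        scope="in_sample", outcome=outcome, n_units=d.n_obs,
        median_error=float(np.median(err)),
        median_abs_error=float(np.median(np.abs(err))),
        pct_below_ci=float(100.0 * np.mean(obs_p < lo)),
        pct_above_ci=float(100.0 * np.mean(obs_p > hi)))


# ---------------------------------------------------------------------------
# out-of-sample cross-validation

def _stratified_country_holdout(hierarchy: GeoHierarchy, countries, fraction,
                                rng) -> list:
    """Sample ~fraction of countries without emptying any region."""
    held = []
    by_region: dict[str, list] = {}
    for c in countries:
        by_region.setdefault(hierarchy.region_of(c), []).append(c)
    n_target = max(int(round(fraction * len(countries))), 1)
    pool = []
    for r, cs in by_region.items():
        cs = list(cs)
        rng.shuffle(cs)
        pool.extend(cs[:-1])  # always retain at least one country per region
    rng.shuffle(pool)
    held = pool[:n_target]
    return held


def _predict_heldout_obs(post: PosteriorDraws, row, outcome: str,
                         hierarchy: GeoHierarchy, pop2010: PopulationWeights,
                         X_i: float, rng, mode: str) -> np.ndarray:
    """Draws of the model-predicted prevalence for one held-out observation,
    standardized over its age band and shifted to its instrument scale."""
    if mode == "countries" or row.country_code not in post.spec.units.countries:
        logits = impute_country_logits(post, outcome, hierarchy.region_of(row.country_code),
                                       float(row.year_end), rng)
    else:
        logits = predict_country_logits(post, outcome, row.country_code,
                                        float(row.year_end))
    cells = bands_in_range(row.age_lower, row.age_upper)
    unit = hierarchy.region_of(row.country_code)
    if unit not in pop2010.units:
        unit = row.country_code
    w = (pop2010.shares_for(unit, AGE_BAND_LOWER[cells]) if len(cells) > 1
         else np.ones(1))
    p = expit(logits[:, cells] + X_i)
    return p @ w


def out_of_sample_cv(modeling_dataset: pd.DataFrame, hierarchy: GeoHierarchy,
                     pop2010: PopulationWeights, X_by_outcome: dict,
                     cfg: McmcConfig, mode: str = "countries",
                     fraction: float = 0.20, repeats: int = 20,
                     seed: int = 0, age_knots=(25,),
                     outcomes=None) -> list[ValidationReport]:
    """Hold out 20% of countries or studies, refit, and score predictions.

    Per repeat the held-out unit set is removed from the modeling dataset,
    the model refitted, and the held-out age-specific observations
    compared with predictions (country mode predicts through regional
    imputation; study mode through the study's country).  Reported metrics
    are medians across repeats.
    """
    if mode not in ("countries", "studies"):
        raise ValueError("mode must be 'countries' or 'studies'")
    outcomes = sorted(modeling_dataset.outcome.unique()) if outcomes is None else outcomes
    if fraction <= 0:
        return [ValidationReport(f"oos_{mode}", o, 0, 0.0, 0.0, 0.0, 0.0, 0)
                for o in outcomes]
    rng = np.random.default_rng(seed)
    keep_outcomes = modeling_dataset.outcome.isin(outcomes)
    X_by_outcome = {o: X_by_outcome[o] for o in outcomes}
    modeling_dataset = modeling_dataset[keep_outcomes].reset_index(drop=True)
    per_repeat: dict[str, list] = {o: [] for o in outcomes}
    for rep in range(repeats):
        if mode == "countries":
            held_units = _stratified_country_holdout(
                hierarchy, sorted(modeling_dataset.country_code.unique()), fraction, rng)
            held_mask = modeling_dataset.country_code.isin(held_units)
        else:
            studies = sorted(modeling_dataset.study_id.unique())
            rng.shuffle(studies)
            n_held = max(int(round(fraction * len(studies))), 1)
            held_units = studies[:n_held]
            held_mask = modeling_dataset.study_id.isin(held_units)
        train = modeling_dataset[~held_mask]
        test = modeling_dataset[held_mask]
        # X vectors are stored per outcome, aligned to that outcome's rows
        X_train, X_test = {}, {}
        for o in outcomes:
            o_mask = (modeling_dataset.outcome == o).to_numpy()
            held_o = held_mask.to_numpy()[o_mask]
            Xo = np.asarray(X_by_outcome[o])
            X_train[o] = Xo[~held_o]
            X_test[o] = Xo[held_o]
        spec = build_model_spec(train, hierarchy, pop2010,
                                {o: X_train[o] for o in outcomes},
                                age_knots=age_knots)
        post = fit(spec, cfg, outcomes=outcomes)
        for o in outcomes:
            sub = test[test.outcome == o].reset_index(drop=True)
            if len(sub) == 0:
                continue
            errs, below, above = [], [], []
            for i, row in enumerate(sub.itertuples()):
                p_draws = _predict_heldout_obs(post, row, o, hierarchy, pop2010,
                                               X_test[o][i], rng, mode)
                obs_p = row.y_adjusted / round(row.n_effective)
                lo, hi = np.quantile(p_draws, [0.025, 0.975])
                errs.append((obs_p - np.median(p_draws)) * 100.0)
                below.append(obs_p < lo)
                above.append(obs_p > hi)
            per_repeat[o].append(dict(
                n=len(sub), median_error=float(np.median(errs)),
                median_abs_error=float(np.median(np.abs(errs))),
                pct_below=float(100 * np.mean(below)),
                pct_above=float(100 * np.mean(above))))
    reports = []
    for o in outcomes:
        reps = per_repeat[o]
        reports.append(ValidationReport(
            scope=f"oos_{mode}", outcome=o,
            n_units=int(np.median([r["n"] for r in reps])),
            median_error=float(np.median([r["median_error"] for r in reps])),
            median_abs_error=float(np.median([r["median_abs_error"] for r in reps])),
            pct_below_ci=float(np.median([r["pct_below"] for r in reps])),
            pct_above_ci=float(np.median([r["pct_above"] for r in reps])),
            n_repeats=repeats))
    return reports
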