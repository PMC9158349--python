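"""The five-level Bayesian binomial meta-regression for IPV prevalence.

The observation model is

    y_it ~ Binomial(p_it, N_it)

with a logit-linear predictor built from four terms: a nested random
intercept (world + super-region + region + country + study), a
country-level age pattern expressed through hierarchical natural-cubic-
spline coefficients, a country-level time trend with the same hierarchical
spline structure, and a fixed offset X summing the crosswalk adjustment
log-ORs the observation requires:

    logit(p_it) = alpha_s[i] + gamma_c[i],a + delta_c[i],t + X_s[i]

Observations reporting a wide age band are age-standardized: p_it is the
population-weighted average over 5-year bands of the inverse-logit of the
linear predictor, with weights from the observation's region's 2010 female
age distribution.

Standard-deviation hyper-parameters carry half-Cauchy(0, 25) priors; the
global intercept and global spline coefficients carry diffuse N(0, 1000)
(variance-1000) priors.  Sub-national studies get a study-level SD
sigma_n + tau, never smaller than the national-study SD sigma_n.

Lifetime and past-year IPV are modelled jointly in the sense that their
posterior prediction draws are paired and filtered so that past-year
prevalence never exceeds lifetime prevalence, and the lifetime-to-past-
year ratio at ages 15-19 never exceeds 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .splines import SplineBasis, build_age_spline_basis, build_time_spline_basis
from .vaw_data import (
    AGE_BAND_LOWER,
    GeoHierarchy,
    PopulationWeights,
    ValidationError,
    bands_in_range,
)

# diffuse priors: N(0, 1000) read as variance 1000
GLOBAL_PRIOR_SD = float(np.sqrt(1000.0))
HALF_CAUCHY_SCALE = 25.0
RR_MAX_15_19 = 3.0


@dataclass
class UnitIndex:
    """Shared integer indexing of countries / regions / super-regions."""

    countries: list
    regions: list
    super_regions: list
    country_region: np.ndarray   # region index of each country
    country_super: np.ndarray    # super-region index of each country
    region_super: np.ndarray

    @classmethod
    def from_hierarchy(cls, hierarchy: GeoHierarchy, countries=None) -> "UnitIndex":
        countries = sorted(countries) if countries is not None else hierarchy.countries
        regions = hierarchy.regions
        supers = hierarchy.super_regions
        r_ix = {r: i for i, r in enumerate(regions)}
        z_ix = {z: i for i, z in enumerate(supers)}
        return cls(
            countries=countries, regions=regions, super_regions=supers,
            country_region=np.array([r_ix[hierarchy.region_of(c)] for c in countries]),
            country_super=np.array([z_ix[hierarchy.super_region_of(c)] for c in countries]),
            region_super=np.array([z_ix[hierarchy.super_region_of_region(r)] for r in regions]),
        )


@dataclass
class OutcomeData:
    """One outcome's modeling dataset in sampler-ready array form."""

    outcome: str
    obs_ids: np.ndarray
    y: np.ndarray                # adjusted binomial numerators
    n: np.ndarray                # effective sample sizes, rounded to int
    study_idx: np.ndarray        # per observation
    country_idx: np.ndarray
    region_idx: np.ndarray
    super_idx: np.ndarray
    X: np.ndarray                # adjustment offsets per observation
    T_obs: np.ndarray            # (n_obs, K_t) time-basis rows at each obs year
    year: np.ndarray
    # age-standardization cells: one row per (observation, 5-year band)
    pair_obs: np.ndarray
    pair_age: np.ndarray
    pair_w: np.ndarray           # normalized within each observation
    A_pair: np.ndarray           # (n_pairs, K_a) age-basis rows
    pair_country: np.ndarray
    studies: list
    study_subnational: np.ndarray  # per study: True if sub-national
    logbinom: np.ndarray         # log C(n, y) constants

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_studies(self) -> int:
        return len(self.studies)


@dataclass
class ModelSpec:
    """Everything one MCMC run needs, plus a serializable manifest."""

    units: UnitIndex
    age_basis: SplineBasis
    time_basis: SplineBasis
    outcome_data: dict            # outcome -> OutcomeData
    hierarchy: GeoHierarchy
    pop2010: PopulationWeights
    constraints_enabled: bool = True
    adjustment_draw_id: int | None = None

    def manifest(self) -> dict:
        return dict(
            age_knots=list(self.age_basis.knots),
            time_knots=list(self.time_basis.knots),
            age_boundary=list(self.age_basis.boundary),
            time_boundary=list(self.time_basis.boundary),
            outcomes=sorted(self.outcome_data),
            n_countries=len(self.units.countries),
            n_regions=len(self.units.regions),
            n_super_regions=len(self.units.super_regions),
            constraints_enabled=self.constraints_enabled,
            adjustment_draw_id=self.adjustment_draw_id,
            prior_global_sd=GLOBAL_PRIOR_SD,
            prior_half_cauchy_scale=HALF_CAUCHY_SCALE,
        )


def build_outcome_data(df: pd.DataFrame, hierarchy: GeoHierarchy, units: UnitIndex,
                       age_basis: SplineBasis, time_basis: SplineBasis,
                       pop2010: PopulationWeights, X: np.ndarray) -> OutcomeData:
    """Compile one outcome's modeling dataset into index/array form."""
    df = df.reset_index(drop=True)
    c_ix = {c: i for i, c in enumerate(units.countries)}
    missing = set(df.country_code) - set(c_ix)
    if missing:
        raise ValidationError(f"countries not in the unit index: {sorted(missing)}")
    studies = sorted(df.study_id.unique())
    s_ix = {s: i for i, s in enumerate(studies)}
    country_idx = df.country_code.map(c_ix).to_numpy()
    region_idx = units.country_region[country_idx]
    super_idx = units.country_super[country_idx]

    years = df.year_end.to_numpy(float)
    T_obs = time_basis.evaluate(years)

    pair_obs, pair_age, pair_w = [], [], []
    for i, row in enumerate(df.itertuples()):
        cells = bands_in_range(row.age_lower, row.age_upper)
        unit = hierarchy.region_of(row.country_code)
        if unit not in pop2010.units:
            unit = row.country_code
        if len(cells) == 1:
            w = np.ones(1)
        else:
            w = pop2010.shares_for(unit, AGE_BAND_LOWER[cells])
        pair_obs.extend([i] * len(cells))
        pair_age.extend(cells)
        pair_w.extend(w)
    pair_obs = np.array(pair_obs)
    pair_age = np.array(pair_age)
    pair_w = np.array(pair_w, dtype=float)

    n_int = df.n_effective.round().to_numpy()
    y = df.y_adjusted.to_numpy(float)
    if (y > n_int).any():
        raise ValidationError("adjusted numerators exceed effective denominators")
    # study is sub-national if none of its rows are nationally representative
    study_nat = df.groupby("study_id")["geo"].agg(lambda g: (g == "national").any())
    subnat = ~study_nat.loc[studies].to_numpy()

    return OutcomeData(
        outcome=df.outcome.iloc[0] if len(df) else "",
        obs_ids=df.obs_id.to_numpy(),
        y=y, n=n_int,
        study_idx=df.study_id.map(s_ix).to_numpy(),
        country_idx=country_idx, region_idx=region_idx, super_idx=super_idx,
        X=np.asarray(X, dtype=float), T_obs=T_obs, year=years,
        pair_obs=pair_obs, pair_age=pair_age, pair_w=pair_w,
        A_pair=age_basis.matrix[pair_age], pair_country=country_idx[pair_obs],
        studies=studies, study_subnational=subnat,
        logbinom=gammaln(n_int + 1) - gammaln(y + 1) - gammaln(n_int - y + 1),
    )


def build_model_spec(modeling_dataset: pd.DataFrame, hierarchy: GeoHierarchy,
                     pop2010: PopulationWeights, X_by_outcome: dict,
                     age_knots=(25,), time_knot: float = 2011.0,
                     year_range=None, constraints_enabled: bool = True,
                     adjustment_draw_id: int | None = None) -> ModelSpec:
    """Assemble a ModelSpec from the modeling dataset for all outcomes present."""
    countries = sorted(modeling_dataset.country_code.unique())
    units = UnitIndex.from_hierarchy(hierarchy, countries)
    age_basis = build_age_spline_basis(age_knots)
    if year_range is None:
        ys = modeling_dataset.year_end.astype(float)
        year_range = np.arange(min(ys.min(), 2000), max(ys.max(), 2018) + 1)
    time_basis = build_time_spline_basis(year_range, knot=time_knot)
    data = {}
    for outcome, g in modeling_dataset.groupby("outcome"):
        X = X_by_outcome[outcome]
        data[outcome] = build_outcome_data(g, hierarchy, units, age_basis,
                                           time_basis, pop2010, X)
    return ModelSpec(units=units, age_basis=age_basis, time_basis=time_basis,
                     outcome_data=data, hierarchy=hierarchy, pop2010=pop2010,
                     constraints_enabled=constraints_enabled,
                     adjustment_draw_id=adjustment_draw_id)


# ---------------------------------------------------------------------------
# parameter containers

PARAM_SCALARS = ("u_g", "sig_z", "sig_r", "sig_c", "sig_n", "tau")


def init_params(units: UnitIndex, d: OutcomeData, K_a: int, K_t: int) -> dict:
    """Starting state: empirical-logit global intercept, null effects, mild SDs."""
    p_hat = (d.y.sum() + 0.5) / (d.n.sum() + 1.0)
    n_z, n_r, n_c = len(units.super_regions), len(units.regions), len(units.countries)
    return {
        "u_g": float(np.log(p_hat / (1 - p_hat))),
        "u_z": np.zeros(n_z), "u_r": np.zeros(n_r), "u_c": np.zeros(n_c),
        "u_s": np.zeros(d.n_studies),
        "sig_z": 0.3, "sig_r": 0.3, "sig_c": 0.3, "sig_n": 0.3, "tau": 0.1,
        "eta_g": np.zeros(K_a), "eta_z": np.zeros((n_z, K_a)),
        "eta_r": np.zeros((n_r, K_a)), "eta_c": np.zeros((n_c, K_a)),
        "ups_z": np.full(K_a, 0.1), "ups_r": np.full(K_a, 0.1), "ups_c": np.full(K_a, 0.1),
        "phi_g": np.zeros(K_t), "phi_z": np.zeros((n_z, K_t)),
        "phi_r": np.zeros((n_r, K_t)), "phi_c": np.zeros((n_c, K_t)),
        "om_z": np.full(K_t, 0.1), "om_r": np.full(K_t, 0.1), "om_c": np.full(K_t, 0.1),
    }


def country_age_coefficients(params: dict, units: UnitIndex) -> np.ndarray:
    """lambda_{c,k} = eta_g + eta_z[c] + eta_r[c] + eta_c, shape (n_c, K_a)."""
    return (params["eta_g"][None, :] + params["eta_z"][units.country_super]
            + params["eta_r"][units.country_region] + params["eta_c"])


def country_time_coefficients(params: dict, units: UnitIndex) -> np.ndarray:
    return (params["phi_g"][None, :] + params["phi_z"][units.country_super]
            + params["phi_r"][units.country_region] + params["phi_c"])


def linear_predictor_cells(params: dict, units: UnitIndex, d: OutcomeData) -> np.ndarray:
    """Logit prevalence at every (observation, age-band) cell."""
    lam = country_age_coefficients(params, units)
    phi = country_time_coefficients(params, units)
    alpha = (params["u_g"] + params["u_z"][d.super_idx] + params["u_r"][d.region_idx]
             + params["u_c"][d.country_idx] + params["u_s"][d.study_idx])
    base = alpha + np.einsum("ij,ij->i", d.T_obs, phi[d.country_idx]) + d.X
    age_term = np.einsum("ij,ij->i", d.A_pair, lam[d.pair_country])
    return base[d.pair_obs] + age_term


def age_standardize(age_logits: np.ndarray, weights: np.ndarray) -> float:
    """Population-weighted average prevalence over an age band.

    ``age_logits`` are the linear predictors at each 5-year band in the
    observation's age range; ``weights`` the region's 2010 female counts.
    A single band reduces to the plain inverse-logit.
    """
    age_logits = np.atleast_1d(np.asarray(age_logits, dtype=float))
    weights = np.atleast_1d(np.asarray(weights, dtype=float))
    if weights.sum() <= 0:
        raise ValidationError("age-standardization weights sum to zero")
    return float(np.sum(expit(age_logits) * weights) / weights.sum())


def standardized_prevalence(params: dict, units: UnitIndex, d: OutcomeData) -> np.ndarray:
    """Age-standardized p_it for every observation (vectorized over cells)."""
    p_cells = expit(linear_predictor_cells(params, units, d))
    p = np.bincount(d.pair_obs, weights=d.pair_w * p_cells, minlength=d.n_obs)
    return np.clip(p, 1e-12, 1.0 - 1e-12)


def pointwise_log_likelihood(params: dict, units: UnitIndex, d: OutcomeData) -> np.ndarray:
    """Binomial log-pmf of each observation at its standardized prevalence."""
    p = standardized_prevalence(params, units, d)
    return d.y * np.log(p) + (d.n - d.y) * np.log1p(-p) + d.logbinom


def log_likelihood(params: dict, units: UnitIndex, d: OutcomeData) -> float:
    return float(pointwise_log_likelihood(params, units, d).sum())


# ---------------------------------------------------------------------------
# joint constraints

class ConstraintError(RuntimeError):
    """Too few prediction draws satisfy the lifetime/past-year constraints."""


def constraint_mask(pred_life: np.ndarray, pred_past: np.ndarray,
                    age_15_19_axis: np.ndarray | None = None,
                    rr_max: float = RR_MAX_15_19) -> np.ndarray:
    """Per-draw indicator that the joint constraints hold at every cell.

    ``pred_life`` / ``pred_past`` have draws on axis 0 and prediction cells
    on the remaining axes.  ``age_15_19_axis`` selects (boolean mask over
    cells, or integer index array) the cells belonging to the 15-19 age
    band, where additionally lifetime/past-year <= rr_max is required.
    """
    life = pred_life.reshape(pred_life.shape[0], -1)
    past = pred_past.reshape(pred_past.shape[0], -1)
    ok = (past <= life + 1e-12).all(axis=1)
    if age_15_19_axis is not None:
        sel = np.asarray(age_15_19_axis)
        if sel.dtype == bool:
            sel = np.where(sel.reshape(-1))[0]
        if len(sel):
            rr = life[:, sel] / np.clip(past[:, sel], 1e-12, None)
            ok &= (rr <= rr_max + 1e-9).all(axis=1)
    return ok


def apply_constraints(pred_life: np.ndarray, pred_past: np.ndarray,
                      age_15_19_axis=None, rr_max: float = RR_MAX_15_19,
                      min_acceptance: float = 0.01):
    """Joint rejection: keep only draw pairs satisfying both constraints.

    Returns (retained lifetime draws, retained past-year draws, kept index).
    Raises ``ConstraintError`` if fewer than ``min_acceptance`` of draws
    survive, which usually signals model misfit.
    """
    ok = constraint_mask(pred_life, pred_past, age_15_19_axis, rr_max)
    rate = ok.mean() if len(ok) else 0.0
    if rate < min_acceptance:
        raise ConstraintError(
            f"constraint acceptance rate {rate:.3%} below {min_acceptance:.0%}; "
            "the lifetime and past-year fits may be inconsistent")
    keep = np.where(ok)[0]
    return pred_life[keep], pred_past[keep], keep
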