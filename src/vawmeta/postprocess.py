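"""Country, regional, and global prevalence estimates from posterior draws.

Country predictions use the hierarchy intercepts plus the country's age
and time spline terms — study effects and instrument offsets are excluded,
so predictions are on the gold-standard instrument scale:

    logit(p_c,a,t) = u_g + u_z[c] + u_r[c] + u_c + gamma_c,a + delta_c,t

Countries without survey data are imputed from their region by drawing a
fresh country intercept from N(0, sigma_c) per posterior draw (and, in
"full" mode, fresh country-level spline deviations as well), which widens
their intervals relative to countries with data.

Broad-age-group and higher-level aggregates weight age-specific
prevalence by the 2018 female population times the proportion of women
who have ever had sex (the practical proxy for ever-partnered), summing
implied counts across countries for regional and global figures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .inference import PosteriorDraws
from .model_core import constraint_mask, apply_constraints
from .vaw_data import AGE_BAND_LOWER, N_AGE_BANDS, PopulationWeights, bands_in_range


def _flat(post: PosteriorDraws, outcome: str, name: str) -> np.ndarray:
    return post.flat(outcome, name)


def predict_country_logits(post: PosteriorDraws, outcome: str, country: str,
                           year: float) -> np.ndarray:
    """Per-draw logit prevalence on the full age grid, shape (n_draws, n_ages)."""
    u = post.spec.units
    if country not in u.countries:
        raise KeyError(f"country {country!r} has no data; use impute_country_logits")
    ci = u.countries.index(country)
    ri, zi = int(u.country_region[ci]), int(u.country_super[ci])
    ug = _flat(post, outcome, "u_g")
    icept = (ug + _flat(post, outcome, "u_z")[:, zi]
             + _flat(post, outcome, "u_r")[:, ri] + _flat(post, outcome, "u_c")[:, ci])
    lam = (_flat(post, outcome, "eta_g") + _flat(post, outcome, "eta_z")[:, zi]
           + _flat(post, outcome, "eta_r")[:, ri] + _flat(post, outcome, "eta_c")[:, ci])
    gamma = lam @ post.spec.age_basis.matrix.T                  # (n_draws, n_ages)
    phi = (_flat(post, outcome, "phi_g") + _flat(post, outcome, "phi_z")[:, zi]
           + _flat(post, outcome, "phi_r")[:, ri] + _flat(post, outcome, "phi_c")[:, ci])
    delta = phi @ post.spec.time_basis.evaluate(year)[0]        # (n_draws,)
    return icept[:, None] + gamma + delta[:, None]


def impute_country_logits(post: PosteriorDraws, outcome: str, region: str,
                          year: float, rng: np.random.Generator,
                          mode: str = "intercept") -> np.ndarray:
    """Prediction draws for a country with no data, imputed from its region.

    Per posterior draw a fresh country intercept u_c* ~ N(0, sigma_c) is
    sampled.  ``mode="full"`` additionally samples fresh country-level age
    and time spline deviations from their hyper-distributions; the default
    shares the regional age pattern and trend exactly.
    """
    u = post.spec.units
    ri = u.regions.index(region)
    zi = int(u.region_super[ri])
    ug = _flat(post, outcome, "u_g")
    n = len(ug)
    uc_star = rng.normal(0.0, 1.0, size=n) * _flat(post, outcome, "sig_c")
    icept = (ug + _flat(post, outcome, "u_z")[:, zi]
             + _flat(post, outcome, "u_r")[:, ri] + uc_star)
    lam = (_flat(post, outcome, "eta_g") + _flat(post, outcome, "eta_z")[:, zi]
           + _flat(post, outcome, "eta_r")[:, ri])
    phi = (_flat(post, outcome, "phi_g") + _flat(post, outcome, "phi_z")[:, zi]
           + _flat(post, outcome, "phi_r")[:, ri])
    if mode == "full":
        lam = lam + rng.normal(size=lam.shape) * _flat(post, outcome, "ups_c")
        phi = phi + rng.normal(size=phi.shape) * _flat(post, outcome, "om_c")
    elif mode != "intercept":
        raise ValueError(f"unknown imputation mode {mode!r}")
    gamma = lam @ post.spec.age_basis.matrix.T
    delta = phi @ post.spec.time_basis.evaluate(year)[0]
    return icept[:, None] + gamma + delta[:, None]


def predict_country(post: PosteriorDraws, outcome: str, country: str,
                    year: float) -> np.ndarray:
    """Prevalence draws (n_draws, n_ages) for a country with data."""
    return expit(predict_country_logits(post, outcome, country, year))


def impute_country(post: PosteriorDraws, outcome: str, region: str, year: float,
                   rng: np.random.Generator, mode: str = "intercept") -> np.ndarray:
    return expit(impute_country_logits(post, outcome, region, year, rng, mode))


def all_country_prevalence(post: PosteriorDraws, outcome: str, year: float,
                           rng: np.random.Generator,
                           impute_mode: str = "intercept") -> tuple[dict, dict]:
    """Prevalence draws for every country in the hierarchy.

    Returns (draws by country, imputed flag by country); countries absent
    from the fitted data are imputed from their region.
    """
    h = post.spec.hierarchy
    fitted = set(post.spec.units.countries)
    draws, imputed = {}, {}
    for c in h.countries:
        if c in fitted:
            draws[c] = predict_country(post, outcome, c, year)
            imputed[c] = False
        else:
            draws[c] = impute_country(post, outcome, h.region_of(c), year, rng,
                                      impute_mode)
            imputed[c] = True
    return draws, imputed


# ---------------------------------------------------------------------------
# aggregation

def broad_age_prevalence(country_draws: np.ndarray, weights: np.ndarray,
                         cells: np.ndarray) -> np.ndarray:
    """Within-country broad-age prevalence per draw: sum_a p_a W_a / sum_a W_a."""
    w = weights[cells]
    return country_draws[:, cells] @ w / w.sum()


def aggregate(country_draws: dict, weights2018: PopulationWeights,
              age_range=(15, 49), members=None) -> np.ndarray:
    """Aggregate member countries by summing implied case counts per draw.

    Country weights are the 2018 female population times the ever-had-sex
    proportion, summed over the target age range.
    """
    members = sorted(country_draws) if members is None else list(members)
    missing = [c for c in members if c not in country_draws]
    if missing:
        raise KeyError(f"no prevalence draws for member countries {missing}")
    cells = bands_in_range(*age_range)
    num = 0.0
    den = 0.0
    for c in members:
        W = weights2018.weights_for(c, AGE_BAND_LOWER[cells], ever_sex=True)
        num = num + country_draws[c][:, cells] @ W   # implied cases per draw
        den = den + W.sum()
    return num / den


def _summary(draws: np.ndarray, ci: float = 0.95) -> tuple[float, float, float]:
    lo, hi = (1 - ci) / 2, 1 - (1 - ci) / 2
    return (float(np.median(draws)), float(np.quantile(draws, lo)),
            float(np.quantile(draws, hi)))


def joint_country_predictions(post: PosteriorDraws, year: float, seed: int = 0,
                              constrain: str = "auto", impute_mode: str = "intercept",
                              rr_max: float = 3.0):
    """Paired lifetime / past-year country prevalence draws, constrained.

    Lifetime and past-year draws are paired (after an independent shuffle,
    since the two outcomes are fitted separately) and draw pairs violating
    past <= lifetime — or a lifetime/past ratio above ``rr_max`` in the
    15-19 band — at any constrained cell are rejected jointly.

    ``constrain``: "auto" applies the constraints at countries lacking data
    on at least one outcome (including imputed countries), "all" at every
    country, "none" disables rejection.
    """
    if sorted(post.outcomes) != ["lifetime", "past_year"]:
        raise ValueError("joint predictions need both lifetime and past_year fits")
    rng = np.random.default_rng(seed)
    per_outcome, imputed = {}, {}
    for outcome in ("lifetime", "past_year"):
        draws, imp = all_country_prevalence(post, outcome, year, rng, impute_mode)
        per_outcome[outcome] = draws
        imputed[outcome] = imp
    countries = sorted(per_outcome["lifetime"])
    n = min(next(iter(per_outcome["lifetime"].values())).shape[0],
            next(iter(per_outcome["past_year"].values())).shape[0])
    perm = {o: rng.permutation(n) for o in per_outcome}
    life = np.stack([per_outcome["lifetime"][c][perm["lifetime"][:n]] for c in countries], 1)
    past = np.stack([per_outcome["past_year"][c][perm["past_year"][:n]] for c in countries], 1)

    # which outcome actually has observations per country (a country can sit
    # in the unit index through one outcome while lacking data on the other)
    units = post.spec.units
    has_data = {}
    for o in per_outcome:
        with_obs = {units.countries[i]
                    for i in np.unique(post.spec.outcome_data[o].country_idx)}
        has_data[o] = {c: (c in with_obs) for c in countries}
    if constrain == "all":
        cidx = np.arange(len(countries))
    elif constrain == "auto":
        cidx = np.array([i for i, c in enumerate(countries)
                         if not (has_data["lifetime"][c] and has_data["past_year"][c])],
                        dtype=int)
    elif constrain == "none":
        cidx = np.array([], dtype=int)
    else:
        raise ValueError(f"unknown constrain mode {constrain!r}")

    keep = np.arange(n)
    if len(cidx):
        sub_life, sub_past = life[:, cidx, :], past[:, cidx, :]
        band_15_19 = np.zeros(sub_life.shape[1:], dtype=bool)
        band_15_19[:, 0] = True   # first grid cell is the 15-19 band
        _, _, keep = apply_constraints(sub_life, sub_past, band_15_19.reshape(-1),
                                       rr_max=rr_max)
        life, past = life[keep], past[keep]
    imputed_flags = {c: imputed["lifetime"][c] or imputed["past_year"][c]
                     for c in countries}
    return dict(countries=countries, lifetime=life, past_year=past,
                kept_draws=keep, imputed=imputed_flags,
                constrained_countries=[countries[i] for i in cidx])


def estimate_table(post: PosteriorDraws, weights2018: PopulationWeights, year: float,
                   seed: int = 0, age_range=(15, 49), constrain: str = "auto",
                   ci: float = 0.95) -> pd.DataFrame:
    """Tidy table of country / region / super-region / global estimates."""
    h = post.spec.hierarchy
    joint = joint_country_predictions(post, year, seed=seed, constrain=constrain)
    countries = joint["countries"]
    rows = []
    for outcome in ("lifetime", "past_year"):
        arr = joint[outcome]  # (n_draws, n_countries, n_ages)
        by_country = {c: arr[:, i, :] for i, c in enumerate(countries)}
        for c in countries:
            med, lo, hi = _summary(
                broad_age_prevalence(by_country[c],
                                     weights2018.weights_for(c, ever_sex=True),
                                     bands_in_range(*age_range)), ci)
            rows.append(dict(outcome=outcome, level="country", unit=c,
                             age_group=f"{age_range[0]}-{age_range[1]}", year=year,
                             median=med, ci_lower=lo, ci_upper=hi,
                             n_draws=arr.shape[0], imputed_country=joint["imputed"][c]))
        groups = (
            [("region", r, h.countries_in_region(r)) for r in h.regions]
            + [("super_region", z,
                [c for c in countries if h.super_region_of(c) == z])
               for z in h.super_regions]
            + [("global", "world", countries)])
        for level, unit, members in groups:
            agg = aggregate(by_country, weights2018, age_range, members)
            med, lo, hi = _summary(agg, ci)
            rows.append(dict(outcome=outcome, level=level, unit=unit,
                             age_group=f"{age_range[0]}-{age_range[1]}", year=year,
                             median=med, ci_lower=lo, ci_upper=hi,
                             n_draws=arr.shape[0], imputed_country=False))
    return pd.DataFrame(rows)
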