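"""Crosswalk adjustment factors estimated by exact matching within surveys.

Surveys that depart from the gold-standard instrument (e.g., measuring
physical violence only, or surveying all women rather than ever-partnered
women) are made comparable through adjustment log-odds-ratios.  To avoid
compositional bias these are estimated *outside* the main meta-regression:

1. within each survey, observations carrying the covariate are exactly
   matched to a reference observation identical on every other instrument
   dimension (if several references match, the one closest to the
   gold-standard "optimal set" is used);
2. each matched pair yields an odds ratio and its standard error from the
   implied 2x2 table;
3. pairs are pooled with DerSimonian-Laird random-effects meta-analysis,
   stratified by super-region; a super-region-specific factor is used only
   when more than three matched pairs inform it, otherwise the overall
   pooled factor applies.

Urban/rural factors are different: the geographic covariate has three
levels, so only surveys reporting national, urban *and* rural strata
qualify, and the pooling model is a random-effects logistic regression
(random survey intercepts, urban/rural slopes varying by super-region),
fitted here by penalized quasi-likelihood.

Uncertainty is propagated by Latin-hypercube sampling of the adjustment
vectors from (truncated) normal distributions on the log-OR scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from scipy.stats import qmc
from statsmodels.stats.meta_analysis import combine_effects

from .preprocess import optimal_distance, _optimal_rank
from .vaw_data import GeoHierarchy

logger = logging.getLogger(__name__)

#: matching keys per covariate (the covariate's own field is excluded)
_AGE = ["age_lower", "age_upper"]
COVARIATE_SPECS: dict[str, dict] = {
    "severe_only": dict(
        field="severity", exposed="severe_only", reference="all",
        match_on=["population", "violence_type", *_AGE, "geo", "partner_ref"]),
    "physical_only": dict(
        field="violence_type", exposed="physical_only", reference="physical_and_or_sexual",
        match_on=["population", *_AGE, "geo", "severity", "partner_ref"]),
    "sexual_only": dict(
        field="violence_type", exposed="sexual_only", reference="physical_and_or_sexual",
        match_on=["population", *_AGE, "geo", "severity", "partner_ref"]),
    "all_women": dict(
        field="population", exposed="all_women", reference="ever_partnered",
        match_on=["violence_type", *_AGE, "geo", "severity", "partner_ref"]),
    "currently_partnered": dict(
        field="population", exposed="currently_partnered", reference="ever_partnered",
        match_on=["violence_type", *_AGE, "geo", "severity", "partner_ref"]),
    "partner_current": dict(
        field="partner_ref", exposed="current_or_most_recent", reference="any_partner",
        match_on=["population", "violence_type", *_AGE, "geo", "severity"]),
}

#: covariates whose odds ratio is structurally bounded at the null
#: (a subset definition cannot yield a higher prevalence than its superset)
BOUND_AT_NULL = frozenset({"severe_only", "physical_only", "sexual_only", "all_women"})

GEO_COVARIATES = ("geo_urban", "geo_rural")
MIN_STRATUM_MATCHES = 3  # super-region factor used only with more matches than this


@dataclass(frozen=True)
class MatchedSet:
    """An exposed observation paired with its within-survey reference."""

    survey_id: str
    covariate: str
    exposed_obs: pd.Series
    reference_obs: pd.Series
    matched_on: tuple


@dataclass
class AdjustmentFactorSet:
    """Meta-analyzed log-ORs per covariate, outcome and stratum.

    ``entries`` columns: covariate, outcome, stratum ("overall" or a
    super-region id), log_or, se, n_matches, used_level.
    """

    entries: pd.DataFrame

    def lookup(self, covariate: str, outcome: str, super_region: str) -> tuple[float, float]:
        """Resolve the (log_or, se) applying the stratum-selection rule.

        The all-women factor for past-year outcomes reuses the lifetime
        factor when no past-year matches were available.
        """
        e = self.entries
        sub = e[(e.covariate == covariate) & (e.outcome == outcome)]
        if len(sub) == 0 and covariate == "all_women" and outcome == "past_year":
            return self.lookup(covariate, "lifetime", super_region)
        strat = sub[(sub.stratum == super_region) & (sub.used_level == "super_region")]
        if len(strat):
            row = strat.iloc[0]
        else:
            overall = sub[sub.stratum == "overall"]
            if len(overall) == 0:
                raise KeyError(
                    f"no adjustment factor for covariate={covariate!r} outcome={outcome!r}")
            row = overall.iloc[0]
        return float(row.log_or), float(row.se)

    def resolved_table(self, outcomes, super_regions) -> pd.DataFrame:
        """One resolved (covariate, outcome, super-region) row per needed entry."""
        rows = []
        for cov in list(COVARIATE_SPECS) + list(GEO_COVARIATES):
            for out in outcomes:
                for z in super_regions:
                    try:
                        lo, se = self.lookup(cov, out, z)
                    except KeyError:
                        continue
                    rows.append((cov, out, z, lo, se))
        return pd.DataFrame(rows, columns=["covariate", "outcome", "super_region",
                                           "log_or", "se"])


@dataclass
class AdjustmentDrawSet:
    """Latin-hypercube draws of the full adjustment vector.

    ``meta`` holds one row per (covariate, outcome, super_region) entry;
    ``draws`` is (D, n_entries) of sampled log-ORs aligned with ``meta``.
    """

    meta: pd.DataFrame
    draws: np.ndarray

    @property
    def D(self) -> int:
        return self.draws.shape[0]

    def vector(self, d: int) -> pd.DataFrame:
        out = self.meta.copy()
        out["log_or"] = self.draws[d]
        return out

    def point_estimate_vector(self) -> pd.DataFrame:
        """The meta-analyzed point estimates in the same layout as a draw."""
        return self.meta.copy()


# ---------------------------------------------------------------------------
# matching and pair odds ratios

def exact_match(adjustment_dataset: pd.DataFrame, covariate: str) -> list[MatchedSet]:
    """Form within-survey matched pairs for one adjustment covariate."""
    spec = COVARIATE_SPECS[covariate]
    fieldname, exposed_level, ref_level = spec["field"], spec["exposed"], spec["reference"]
    keys = spec["match_on"]
    matches: list[MatchedSet] = []
    for (study, _), g in adjustment_dataset.groupby(["study_id", "outcome"], sort=False):
        exposed = g[g[fieldname] == exposed_level]
        refs = g[g[fieldname] == ref_level]
        if len(exposed) == 0 or len(refs) == 0:
            continue
        for _, erow in exposed.iterrows():
            cand = refs
            for k in keys:
                cand = cand[cand[k] == erow[k]]
            if len(cand) == 0:
                continue
            if len(cand) > 1:
                cand = cand.copy()
                cand["_dist"] = optimal_distance(cand)
                cand["_rank"] = _optimal_rank(cand)
                cand = cand.sort_values(["_dist", "_rank", "obs_id"])
            matches.append(MatchedSet(
                survey_id=study, covariate=covariate,
                exposed_obs=erow, reference_obs=cand.iloc[0],
                matched_on=tuple(keys)))
    return matches


def pair_odds_ratio(m: MatchedSet) -> tuple[float, float]:
    """Log odds ratio (exposed vs reference) and its SE from the 2x2 table."""
    e, r = m.exposed_obs, m.reference_obs
    for row in (e, r):
        if not np.isfinite(row.get("n_effective", np.nan)):
            raise ValueError(f"matched observation {row.obs_id} has no effective N")
    a = float(e.y_adjusted)
    b = float(round(e.n_effective)) - a
    c = float(r.y_adjusted)
    d = float(round(r.n_effective)) - c
    if min(a, b, c, d) <= 0:
        logger.info("zero cell in matched pair (%s): adding 0.5 continuity correction",
                    m.survey_id)
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return log_or, se


def matched_pair_table(adjustment_dataset: pd.DataFrame, hierarchy: GeoHierarchy,
                       covariate: str) -> pd.DataFrame:
    """All matched pairs for a covariate with their log-ORs and strata."""
    rows = []
    for m in exact_match(adjustment_dataset, covariate):
        log_or, se = pair_odds_ratio(m)
        rows.append(dict(
            covariate=covariate,
            outcome=m.exposed_obs.outcome,
            survey_id=m.survey_id,
            super_region=hierarchy.super_region_of(m.exposed_obs.country_code),
            log_or=log_or, se=se,
            exposed_obs_id=m.exposed_obs.obs_id,
            reference_obs_id=m.reference_obs.obs_id))
    return pd.DataFrame(rows, columns=["covariate", "outcome", "survey_id",
                                       "super_region", "log_or", "se",
                                       "exposed_obs_id", "reference_obs_id"])


# ---------------------------------------------------------------------------
# random-effects pooling

def _dl_pool(log_ors: np.ndarray, ses: np.ndarray) -> tuple[float, float]:
    """DerSimonian-Laird random-effects pooled estimate and SE."""
    if len(log_ors) == 1:
        return float(log_ors[0]), float(ses[0])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = combine_effects(log_ors, ses ** 2, method_re="dl")
        if res.tau2 <= 0:
            # DL truncates tau^2 at zero, where RE pooling equals fixed-effect
            return float(res.mean_effect_fe), float(np.sqrt(res.var_eff_w_fe))
        est, var = float(res.mean_effect_re), float(res.var_eff_w_re)
    if not np.isfinite(var) or var <= 0:
        var = 1.0 / float(np.sum(1.0 / ses ** 2))
    return est, float(np.sqrt(var))


def meta_analyze(pairs: pd.DataFrame, method: str = "dl") -> AdjustmentFactorSet:
    """Pool matched-pair log-ORs per covariate and outcome.

    Stratified by super-region; a stratum-specific factor is emitted (and
    marked ``used_level = super_region``) only when it pools more than
    three pairs.  Bound-at-null covariates are clamped to log-OR <= 0.
    """
    if method != "dl":
        raise NotImplementedError("only DerSimonian-Laird pooling is implemented")
    entries = []
    for (cov, out), g in pairs.groupby(["covariate", "outcome"], sort=False):
        est, se = _dl_pool(g.log_or.to_numpy(), g.se.to_numpy())
        if cov in BOUND_AT_NULL:
            est = min(est, 0.0)
        entries.append(dict(covariate=cov, outcome=out, stratum="overall",
                            log_or=est, se=se, n_matches=len(g), used_level="overall"))
        for z, gz in g.groupby("super_region"):
            use_stratum = len(gz) > MIN_STRATUM_MATCHES
            estz, sez = _dl_pool(gz.log_or.to_numpy(), gz.se.to_numpy())
            if cov in BOUND_AT_NULL:
                estz = min(estz, 0.0)
            entries.append(dict(
                covariate=cov, outcome=out, stratum=z, log_or=estz, se=sez,
                n_matches=len(gz),
                used_level="super_region" if use_stratum else "overall"))
    cols = ["covariate", "outcome", "stratum", "log_or", "se", "n_matches", "used_level"]
    return AdjustmentFactorSet(pd.DataFrame(entries, columns=cols))


# ---------------------------------------------------------------------------
# geographic strata: three-level covariate, PQL mixed logistic

def _qualifying_geo_surveys(adjustment_dataset: pd.DataFrame) -> pd.DataFrame:
    """Rows of surveys reporting national, urban and rural strata that match
    on every other instrument dimension."""
    keys = ["study_id", "outcome", "population", "violence_type",
            "severity", "partner_ref", "age_lower", "age_upper"]
    df = adjustment_dataset[adjustment_dataset.geo.isin(["national", "urban", "rural"])]
    counts = df.groupby(keys)["geo"].agg(lambda s: len(set(s)))
    full = counts[counts == 3].index
    idx = pd.MultiIndex.from_frame(df[keys])
    return df[idx.isin(full)].copy()


def _pql_mixed_logistic(y, n, stratum, survey_idx, super_idx, n_surveys, n_supers,
                        max_iter=200, tol=1e-8):
    """Penalized quasi-likelihood fit of the geo-strata mixed logistic.

    Fixed effects: intercept, urban, rural. Random: survey intercepts and
    urban/rural slopes varying by super-region. Returns coefficient vector,
    covariance, layout offsets, and the three variance components.
    """
    n_obs = len(y)
    p_fixed = 3
    off_u = p_fixed                 # urban slopes by super-region
    off_r = off_u + n_supers        # rural slopes by super-region
    off_s = off_r + n_supers        # survey intercepts
    p = off_s + n_surveys
    X = np.zeros((n_obs, p))
    X[:, 0] = 1.0
    is_u = stratum == "urban"
    is_r = stratum == "rural"
    X[is_u, 1] = 1.0
    X[is_r, 2] = 1.0
    X[np.arange(n_obs)[is_u], off_u + super_idx[is_u]] = 1.0
    X[np.arange(n_obs)[is_r], off_r + super_idx[is_r]] = 1.0
    X[np.arange(n_obs), off_s + survey_idx] = 1.0

    theta = np.zeros(p)
    theta[0] = np.log((y.sum() + 0.5) / (n.sum() - y.sum() + 0.5))
    sig2 = dict(u=0.1, r=0.1, s=0.5)
    cov = None
    for _ in range(max_iter):
        pen = np.full(p, 1e-8)
        pen[off_u:off_r] = 1.0 / sig2["u"]
        pen[off_r:off_s] = 1.0 / sig2["r"]
        pen[off_s:] = 1.0 / sig2["s"]
        theta_old = theta.copy()
        for _ in range(50):  # inner penalized Newton
            eta = X @ theta
            mu = expit(eta)
            W = n * mu * (1 - mu)
            H = (X.T * W) @ X + np.diag(pen)
            g = X.T @ (y - n * mu) - pen * theta
            step = np.linalg.solve(H, g)
            theta = theta + step
            if np.max(np.abs(step)) < tol:
                break
        eta = X @ theta
        mu = expit(eta)
        W = n * mu * (1 - mu)
        cov = np.linalg.inv((X.T * W) @ X + np.diag(pen))
        for key, (a, b) in dict(u=(off_u, off_r), r=(off_r, off_s), s=(off_s, p)).items():
            q = b - a
            sig2[key] = max((theta[a:b] @ theta[a:b] + np.trace(cov[a:b, a:b])) / q, 1e-4)
        if np.max(np.abs(theta - theta_old)) < 1e-6:
            break
    return theta, cov, (off_u, off_r, off_s), sig2


def fit_geo_strata_factors(adjustment_dataset: pd.DataFrame,
                           hierarchy: GeoHierarchy) -> pd.DataFrame:
    """Urban- and rural-vs-national log-ORs by super-region.

    Uses only surveys reporting all three geographic strata.  With fewer
    than two qualifying surveys, falls back to a fixed-effect contrast of
    the pooled 2x2 tables (with a warning).
    """
    entries = []
    for outcome, df_out in _qualifying_geo_surveys(adjustment_dataset).groupby("outcome"):
        surveys = sorted(df_out.study_id.unique())
        if len(surveys) < 2:
            logger.warning("geo strata (%s): %d qualifying survey(s); "
                           "falling back to fixed-effect contrast", outcome, len(surveys))
            entries.extend(_geo_fixed_effect(df_out, outcome))
            continue
        supers = sorted({hierarchy.super_region_of(c) for c in df_out.country_code})
        s_idx = {s: i for i, s in enumerate(surveys)}
        z_idx = {z: i for i, z in enumerate(supers)}
        y = df_out.y_adjusted.to_numpy(float)
        n = df_out.n_effective.round().to_numpy(float)
        theta, cov, (off_u, off_r, off_s), _ = _pql_mixed_logistic(
            y, n, df_out.geo.to_numpy(), df_out.study_id.map(s_idx).to_numpy(),
            df_out.country_code.map(hierarchy.super_region_of).map(z_idx).to_numpy(),
            len(surveys), len(supers))
        n_by_super = df_out.groupby(
            df_out.country_code.map(hierarchy.super_region_of))["study_id"].nunique()
        for covname, fix_i, off in (("geo_urban", 1, off_u), ("geo_rural", 2, off_r)):
            entries.append(dict(covariate=covname, outcome=outcome, stratum="overall",
                                log_or=theta[fix_i], se=math.sqrt(cov[fix_i, fix_i]),
                                n_matches=len(surveys), used_level="overall"))
            for z, zi in z_idx.items():
                j = off + zi
                est = theta[fix_i] + theta[j]
                se = math.sqrt(cov[fix_i, fix_i] + cov[j, j] + 2 * cov[fix_i, j])
                entries.append(dict(covariate=covname, outcome=outcome, stratum=z,
                                    log_or=est, se=se,
                                    n_matches=int(n_by_super.get(z, 0)),
                                    used_level="super_region"))
    cols = ["covariate", "outcome", "stratum", "log_or", "se", "n_matches", "used_level"]
    return pd.DataFrame(entries, columns=cols)


def _geo_fixed_effect(df_out: pd.DataFrame, outcome: str) -> list[dict]:
    out = []
    nat = df_out[df_out.geo == "national"]
    if len(nat) == 0:
        return out
    for covname, level in (("geo_urban", "urban"), ("geo_rural", "rural")):
        sub = df_out[df_out.geo == level]
        if len(sub) == 0:
            continue
        a = sub.y_adjusted.sum() + 0.5
        b = sub.n_effective.round().sum() - sub.y_adjusted.sum() + 0.5
        c = nat.y_adjusted.sum() + 0.5
        d = nat.n_effective.round().sum() - nat.y_adjusted.sum() + 0.5
        out.append(dict(covariate=covname, outcome=outcome, stratum="overall",
                        log_or=math.log(a * d / (b * c)),
                        se=math.sqrt(1 / a + 1 / b + 1 / c + 1 / d),
                        n_matches=int(sub.study_id.nunique()), used_level="overall"))
    return out


def estimate_adjustment_factors(adjustment_dataset: pd.DataFrame,
                                hierarchy: GeoHierarchy) -> AdjustmentFactorSet:
    """Run the full crosswalk: matched pairs, pooling, and geo-strata model."""
    tables = [t for cov in COVARIATE_SPECS
              if len(t := matched_pair_table(adjustment_dataset, hierarchy, cov))]
    all_pairs = (pd.concat(tables, ignore_index=True) if tables
                 else pd.DataFrame(columns=["covariate", "outcome", "survey_id",
                                            "super_region", "log_or", "se"]))
    factors = meta_analyze(all_pairs) if len(all_pairs) else AdjustmentFactorSet(
        pd.DataFrame(columns=["covariate", "outcome", "stratum", "log_or", "se",
                              "n_matches", "used_level"]))
    geo = fit_geo_strata_factors(adjustment_dataset, hierarchy)
    factors.entries = pd.concat([factors.entries, geo], ignore_index=True)
    return factors


# ---------------------------------------------------------------------------
# uncertainty propagation

def sample_adjustment_vectors(factors: AdjustmentFactorSet, outcomes, super_regions,
                              D: int = 10, seed: int | None = None) -> AdjustmentDrawSet:
    """Latin-hypercube draws of every resolved adjustment log-OR.

    Each entry is drawn from Normal(log_or, se) — truncated from above at 0
    for covariates structurally bound at the null — with LHS stratification
    across the D draws for even coverage of the parameter space.
    """
    if D < 1:
        raise ValueError("number of adjustment draws D must be >= 1")
    meta = factors.resolved_table(outcomes, super_regions)
    n_entries = len(meta)
    draws = np.tile(meta.log_or.to_numpy(float), (D, 1))
    if n_entries == 0:
        return AdjustmentDrawSet(meta, draws)
    sampler = qmc.LatinHypercube(d=n_entries, seed=seed)
    u = sampler.random(n=D)
    for j, row in enumerate(meta.itertuples()):
        mu, se = row.log_or, row.se
        if not np.isfinite(se) or se <= 0:
            continue
        if row.covariate in BOUND_AT_NULL:
            b = (0.0 - mu) / se  # upper truncation at the null
            draws[:, j] = stats.truncnorm.ppf(u[:, j], -np.inf, b, loc=mu, scale=se)
        else:
            draws[:, j] = stats.norm.ppf(u[:, j], loc=mu, scale=se)
    return AdjustmentDrawSet(meta, draws)


def filter_adjustable(prepared: pd.DataFrame, hierarchy: GeoHierarchy,
                      beta_vector: pd.DataFrame):
    """Split observations into those whose required adjustments all have
    factors and those needing a factor that could not be estimated."""
    have = {(r.covariate, r.outcome, r.super_region)
            for r in beta_vector.itertuples()}
    ok_mask = []
    supers = prepared.country_code.map(hierarchy.super_region_of)
    for row, z in zip(prepared.itertuples(), supers):
        ok = all((cov, row.outcome, z) in have
                 for cov in list(COVARIATE_SPECS) + list(GEO_COVARIATES)
                 if getattr(row, f"adj_{cov}", 0) == 1)
        ok_mask.append(ok)
    ok_mask = np.array(ok_mask)
    dropped = prepared.loc[~ok_mask, "obs_id"].tolist()
    if dropped:
        logger.warning("%d observation(s) need adjustments with no estimated "
                       "factor and were excluded: %s", len(dropped), dropped[:10])
    return prepared[ok_mask].copy(), dropped


def observation_offsets(prepared: pd.DataFrame, hierarchy: GeoHierarchy,
                        beta_vector: pd.DataFrame) -> np.ndarray:
    """X offset per observation: sum of adjustment log-ORs its C vector selects."""
    lut: dict[tuple, float] = {}
    for row in beta_vector.itertuples():
        lut[(row.covariate, row.outcome, row.super_region)] = row.log_or
    X = np.zeros(len(prepared))
    supers = prepared.country_code.map(hierarchy.super_region_of)
    for i, (row, z) in enumerate(zip(prepared.itertuples(), supers)):
        total = 0.0
        for cov in list(COVARIATE_SPECS) + list(GEO_COVARIATES):
            if getattr(row, f"adj_{cov}", 0) == 1:
                key = (cov, row.outcome, z)
                if key not in lut:
                    raise KeyError(
                        f"observation {row.obs_id} needs adjustment {cov!r} "
                        f"but no factor was estimated")
                total += lut[key]
        X[i] = total
    return X
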