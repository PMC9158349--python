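"""Turn raw survey observations into analysis-ready datasets.

Two datasets come out of pre-processing:

* the **adjustment dataset** — broadest age band per study and instrument
  combination, used to estimate crosswalk adjustment factors by exact
  matching within surveys;
* the **modeling dataset** — one gold-standard ("optimal set" preferred)
  observation per study, outcome, and age stratum, with the most granular
  non-overlapping age bands retained so no woman is double-counted.

Along the way missing denominators are imputed from the 2010 female age
distribution, effective sample sizes are derived from design-adjusted
confidence intervals (Wilson-interval inversion), reported standard
errors, or a default design effect of 2.5, and missing end years / upper
ages are imputed.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .vaw_data import (
    OPEN_AGE,
    REFERENCE_LEVELS,
    GeoHierarchy,
    PopulationWeights,
    ValidationError,
    bands_in_range,
    AGE_BAND_LOWER,
)

logger = logging.getLogger(__name__)

DEFAULT_DESIGN_EFFECT = 2.5
DEFAULT_NATIONAL_N = 3000
DEFAULT_SUBNATIONAL_N = 1000

#: instrument-adjustment covariates, in the order used for the C vector.
ADJUSTMENT_COVARIATES = [
    "severe_only",          # severity: severe violence vs all severity
    "physical_only",        # type: physical IPV only vs physical and/or sexual
    "sexual_only",          # type: sexual IPV only vs physical and/or sexual
    "all_women",            # population: all women vs ever-partnered
    "currently_partnered",  # population: currently partnered vs ever-partnered
    "partner_current",      # perpetrator: current/most recent vs any partner
    "geo_urban",            # strata: urban vs national
    "geo_rural",            # strata: rural vs national
]

# preference order (lower = closer to the gold standard) for optimal-set rules
_SEVERITY_RANK = {"all": 0, "severe_only": 1}
_TYPE_RANK = {"physical_and_or_sexual": 0, "physical_only": 1, "sexual_only": 2}
_POP_RANK = {"ever_partnered": 0, "all_women": 1, "currently_partnered": 2}
_PARTNER_RANK = {"any_partner": 0, "current_or_most_recent": 1}

Z95 = 1.959963984540054


class InversionError(ValueError):
    """Wilson upper-limit inversion could not be performed for a row."""


# ---------------------------------------------------------------------------
# metadata imputation

def impute_metadata(obs: pd.DataFrame) -> pd.DataFrame:
    """Fill missing end years (from publication year) and open upper ages.

    Adds boolean flag columns ``imputed_end_year`` and ``imputed_upper_age``.
    """
    df = obs.copy()
    end = pd.to_numeric(df.year_end, errors="coerce")
    pub = pd.to_numeric(df.publication_year, errors="coerce")
    need_end = end.isna()
    unsalvageable = need_end & pub.isna()
    if unsalvageable.any():
        raise ValidationError(
            "rows missing both end year and publication year: "
            f"obs {list(df.loc[unsalvageable, 'obs_id'])}"
        )
    df["imputed_end_year"] = need_end
    df.loc[need_end, "year_end"] = pub[need_end]
    df["year_end"] = df.year_end.astype(int)
    df["imputed_upper_age"] = df.age_upper.isna() | (df.age_upper == OPEN_AGE)
    df["age_upper"] = df.age_upper.fillna(OPEN_AGE).astype(int)
    return df


# ---------------------------------------------------------------------------
# denominator imputation

def impute_denominators(
    obs: pd.DataFrame,
    pop2010: PopulationWeights,
    hierarchy: GeoHierarchy | None = None,
    national_default: float = DEFAULT_NATIONAL_N,
    subnational_default: float = DEFAULT_SUBNATIONAL_N,
) -> pd.DataFrame:
    """Impute missing age-specific denominators within each study.

    The study total (an optional ``study_n`` column, the default national /
    sub-national sample size when nothing is reported, or the sum of the
    known age-specific denominators) is allocated across age bands
    proportionally to the country's 2010 female age distribution, so the
    group total is preserved.
    """
    df = obs.copy()
    if "study_n" not in df.columns:
        df["study_n"] = np.nan
    df["denominator"] = pd.to_numeric(df.denominator, errors="coerce")
    df["imputed_denominator"] = df.denominator.isna()
    df["imputed_total_n"] = False

    def pop_share(row) -> float:
        unit = row.country_code
        if unit not in pop2010.units and hierarchy is not None:
            unit = hierarchy.region_of(row.country_code)
        idx = bands_in_range(row.age_lower, row.age_upper)
        w = pop2010.weights_for(unit, AGE_BAND_LOWER[idx])
        return float(w.sum())

    for (_, _), g in df.groupby(["study_id", "outcome"], sort=False):
        miss = g.denominator.isna()
        if not miss.any():
            continue
        shares = g.apply(pop_share, axis=1).astype(float)
        study_n = pd.to_numeric(g.study_n, errors="coerce").dropna()
        if len(study_n):
            total = float(study_n.iloc[0])
            # allocate the reported survey total across all bands
            alloc = total * shares / shares.sum()
            df.loc[g.index[miss], "denominator"] = alloc[miss]
        elif miss.all():
            national = (g.geo == "national").any()
            total = national_default if national else subnational_default
            df.loc[g.index, "imputed_total_n"] = True
            alloc = total * shares / shares.sum()
            df.loc[g.index, "denominator"] = alloc
        else:
            # extend the known rows' total proportionally to population
            known_total = float(g.loc[~miss, "denominator"].sum())
            known_share = float(shares[~miss].sum())
            df.loc[g.index[miss], "denominator"] = known_total * shares[miss] / known_share
    return df


# ---------------------------------------------------------------------------
# effective sample size

def wilson_upper(p: float, n: float, z: float = Z95) -> float:
    """Upper bound of the Wilson score interval (no continuity correction)."""
    z2 = z * z
    center = p + z2 / (2.0 * n)
    half = z * math.sqrt(p * (1.0 - p) / n + z2 / (4.0 * n * n))
    return (center + half) / (1.0 + z2 / n)


def invert_wilson_upper(p: float, upper: float, n_hint: float, z: float = Z95) -> float:
    """Sample size whose Wilson 95% upper limit at prevalence ``p`` is ``upper``.

    Solved by bisection; the upper limit is strictly decreasing in n. Raises
    ``InversionError`` if ``upper <= p`` or no root lies in [1, 10 * n_hint].
    """
    if upper <= p:
        raise InversionError(f"reported upper limit {upper} <= prevalence {p}")
    lo, hi = 1.0, max(10.0 * n_hint, 10.0)
    f = lambda n: wilson_upper(p, n, z) - upper
    if f(lo) < 0 or f(hi) > 0:
        raise InversionError(
            f"Wilson inversion not bracketed in [1, {hi:.0f}] for p={p}, upper={upper}"
        )
    return brentq(f, lo, hi, xtol=1e-9, rtol=1e-12)


def effective_sample_size(row, design_effect: float = DEFAULT_DESIGN_EFFECT) -> float:
    """Effective denominator for one observation.

    Preference order: invert the Wilson upper limit of a design-adjusted CI;
    else use a reported standard error (N = p(1-p)/se^2); else divide the
    raw denominator by the default design effect.
    """
    p = float(row.prevalence)
    n = float(row.denominator)
    ci_upper = row.ci_upper if hasattr(row, "ci_upper") else None
    se = row.se if hasattr(row, "se") else None
    if ci_upper is not None and np.isfinite(ci_upper) and 0.0 < p < 1.0:
        try:
            return invert_wilson_upper(p, float(ci_upper), n)
        except InversionError as e:
            logger.warning("obs %s: %s; falling back to design effect",
                           getattr(row, "obs_id", "?"), e)
            return n / design_effect
    if se is not None and np.isfinite(se) and se > 0 and 0.0 < p < 1.0:
        return p * (1.0 - p) / (float(se) ** 2)
    return n / design_effect


# ---------------------------------------------------------------------------
# adjustment indicators and the full preparation pipeline

def adjustment_indicators(obs: pd.DataFrame) -> pd.DataFrame:
    """Binary adjustment-covariate indicators C for each observation.

    All-zero C means the observation uses the gold-standard instrument on
    every dimension.  Mixed sub-national strata carry no geographic
    indicator (only pure urban or rural strata are adjusted).
    """
    C = pd.DataFrame(index=obs.index)
    C["adj_severe_only"] = (obs.severity == "severe_only").astype(int)
    C["adj_physical_only"] = (obs.violence_type == "physical_only").astype(int)
    C["adj_sexual_only"] = (obs.violence_type == "sexual_only").astype(int)
    C["adj_all_women"] = (obs.population == "all_women").astype(int)
    C["adj_currently_partnered"] = (obs.population == "currently_partnered").astype(int)
    C["adj_partner_current"] = (obs.partner_ref == "current_or_most_recent").astype(int)
    C["adj_geo_urban"] = (obs.geo == "urban").astype(int)
    C["adj_geo_rural"] = (obs.geo == "rural").astype(int)
    return C


def prepare_observations(
    obs: pd.DataFrame,
    pop2010: PopulationWeights,
    hierarchy: GeoHierarchy | None = None,
    design_effect: float = DEFAULT_DESIGN_EFFECT,
    national_default: float = DEFAULT_NATIONAL_N,
    subnational_default: float = DEFAULT_SUBNATIONAL_N,
) -> pd.DataFrame:
    """Impute metadata and denominators, derive N_eff and binomial counts."""
    df = impute_metadata(obs)
    df = impute_denominators(df, pop2010, hierarchy,
                             national_default, subnational_default)
    df["n_effective"] = [effective_sample_size(r, design_effect)
                         for r in df.itertuples()]
    n_round = df.n_effective.round()
    df["y_adjusted"] = np.clip((df.prevalence * df.n_effective).round(), 0, n_round)
    df = pd.concat([df, adjustment_indicators(df)], axis=1)
    return df


# ---------------------------------------------------------------------------
# optimal-set selection and dataset construction

def _optimal_rank(df: pd.DataFrame) -> pd.Series:
    return list(zip(df.severity.map(_SEVERITY_RANK),
                    df.violence_type.map(_TYPE_RANK),
                    df.population.map(_POP_RANK),
                    df.partner_ref.map(_PARTNER_RANK)))


def optimal_distance(df: pd.DataFrame) -> pd.Series:
    """Number of instrument dimensions away from the gold standard."""
    return ((df.severity != REFERENCE_LEVELS["severity"]).astype(int)
            + (df.violence_type != REFERENCE_LEVELS["violence_type"]).astype(int)
            + (df.population != REFERENCE_LEVELS["population"]).astype(int)
            + (df.partner_ref != REFERENCE_LEVELS["partner_ref"]).astype(int))


def select_optimal_set(obs: pd.DataFrame) -> pd.DataFrame:
    """Keep one observation per (study, outcome, age stratum, geo stratum).

    Preference rules, applied in order: all-severity over severe-only;
    physical and/or sexual over physical-only over sexual-only;
    ever-partnered over all-women over currently-partnered; any partner
    over current/most recent.  ``in_optimal_set`` marks rows that sit at
    the reference level on all four dimensions.
    """
    if len(obs) == 0:
        raise ValidationError("select_optimal_set received an empty group")
    df = obs.copy()
    df["_rank"] = _optimal_rank(df)
    df = df.sort_values(["study_id", "outcome", "age_lower", "age_upper",
                         "geo", "_rank", "obs_id"])
    keep = df.drop_duplicates(
        ["study_id", "outcome", "age_lower", "age_upper", "geo"], keep="first"
    ).drop(columns="_rank")
    keep = keep.copy()
    keep["in_optimal_set"] = (optimal_distance(keep) == 0)
    return keep


def _band_width(df: pd.DataFrame) -> pd.Series:
    upper = df.age_upper.clip(upper=70)
    return upper - df.age_lower


def build_datasets(prepared: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split prepared observations into (adjustment, modeling) datasets."""
    df = prepared.copy()
    width = _band_width(df)
    df["_width"] = width

    # adjustment dataset: broadest age band within each study x instrument cell
    inst_cols = ["study_id", "outcome", "violence_type", "severity",
                 "population", "partner_ref", "geo"]
    adj = (df.sort_values(inst_cols + ["_width", "age_lower"],
                          ascending=[True] * len(inst_cols) + [False, True])
             .drop_duplicates(inst_cols, keep="first"))

    # modeling dataset: optimal instrument, national over urban/rural,
    # then the most granular non-overlapping age strata
    mod = select_optimal_set(df)
    has_national = mod.loc[mod.geo == "national", ["study_id", "outcome"]].drop_duplicates()
    key = pd.MultiIndex.from_frame(has_national)
    drop_mask = (mod.geo.isin(["urban", "rural"])
                 & pd.MultiIndex.from_frame(mod[["study_id", "outcome"]]).isin(key))
    mod = mod[~drop_mask]

    kept_rows = []
    for _, g in mod.groupby(["study_id", "outcome", "geo"], sort=False):
        g = g.sort_values(["_width", "age_lower", "obs_id"])
        kept: list[tuple[float, float, float, str]] = []
        for row in g.itertuples():
            lo, hi = row.age_lower, min(row.age_upper, 70)
            w = hi - lo
            clash = [k for k in kept if not (hi < k[0] or lo > k[1])]
            if not clash:
                kept.append((lo, hi, w, row.obs_id))
                kept_rows.append(row.Index)
            elif any(k[2] == w and not (k[0] <= lo and hi <= k[1]) for k in clash):
                ids = [row.obs_id] + [k[3] for k in clash if k[2] == w]
                raise ValidationError(
                    f"overlapping equal-width age strata cannot be disambiguated: obs {ids}"
                )
            # otherwise the wider (less granular) row is dropped
    mod = mod.loc[kept_rows]
    return (adj.drop(columns="_width").reset_index(drop=True),
            mod.drop(columns="_width").reset_index(drop=True))
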