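"""Domain types and file I/O for the violence-against-women survey database.

The package operates on three tabular inputs:

* a survey-observation table — one row per age-specific prevalence
  estimate, with study / country / instrument metadata;
* a geographic hierarchy mapping countries to regions and super-regions
  (the Global Burden of Disease grouping: 21 regions in 7 super-regions);
* female population-by-age weight tables used for age-standardization
  (reference year 2010) and for aggregation weighted by the proportion of
  women who have ever had sex (reference year 2018).

All tables travel as UTF-8 CSV with a header row; a column-mapping config
adapts external schemas to the internal column names used throughout.
Downstream modules consume only the validated containers defined here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

# sentinel for an open-ended upper age bound at the I/O boundary
OPEN_AGE = 999

# five-year age bands: lower bounds 15..60 plus an open-ended 65+ band
AGE_BAND_LOWER = np.arange(15, 70, 5)
# midpoints used to evaluate the age spline; the 65+ band is pinned at 65
AGE_MIDPOINTS = np.array([lb + 2 if lb < 65 else 65 for lb in AGE_BAND_LOWER], dtype=float)
N_AGE_BANDS = len(AGE_BAND_LOWER)

OUTCOMES = ("lifetime", "past_year")
VIOLENCE_TYPES = ("physical_and_or_sexual", "physical_only", "sexual_only")
SEVERITIES = ("all", "severe_only")
POPULATIONS = ("ever_partnered", "all_women", "currently_partnered")
PARTNER_REFS = ("any_partner", "current_or_most_recent")
GEO_LEVELS = ("national", "urban", "rural", "mixed_subnational")

#: reference (gold standard) level of each instrument dimension
REFERENCE_LEVELS = {
    "severity": "all",
    "violence_type": "physical_and_or_sexual",
    "population": "ever_partnered",
    "partner_ref": "any_partner",
    "geo": "national",
}

OBS_COLUMNS = [
    "obs_id", "study_id", "country_code", "year_start", "year_end",
    "outcome", "violence_type", "severity", "population", "partner_ref",
    "geo", "age_lower", "age_upper", "prevalence", "denominator",
    "se", "ci_lower", "ci_upper", "publication_year",
]

_CATEGORICAL = {
    "outcome": OUTCOMES,
    "violence_type": VIOLENCE_TYPES,
    "severity": SEVERITIES,
    "population": POPULATIONS,
    "partner_ref": PARTNER_REFS,
    "geo": GEO_LEVELS,
}


class SchemaError(ValueError):
    """A required column is absent from an input table."""


class ValidationError(ValueError):
    """One or more rows violate the observation invariants."""

    def __init__(self, message: str, bad_ids: list | None = None):
        super().__init__(message)
        self.bad_ids = bad_ids or []


class HierarchyError(ValueError):
    """The country/region/super-region mapping is not a tree."""


@dataclass(frozen=True)
class SurveyObservation:
    """One age-specific prevalence record. Mirrors a row of the table."""

    obs_id: str
    study_id: str
    country_code: str
    year_start: int
    year_end: int
    outcome: str
    violence_type: str
    severity: str
    population: str
    partner_ref: str
    geo: str
    age_lower: int
    age_upper: int          # OPEN_AGE marks an open-ended band
    prevalence: float
    denominator: float | None = None
    se: float | None = None
    ci_lower: float | None = None
    ci_upper: float | None = None
    publication_year: int | None = None

    @property
    def open_ended(self) -> bool:
        return self.age_upper == OPEN_AGE


@dataclass
class GeoHierarchy:
    """Country -> region -> super-region tree (GBD-style grouping)."""

    table: pd.DataFrame  # columns: country_code, region_id, super_region_id

    def __post_init__(self):
        t = self.table
        for col in ("country_code", "region_id", "super_region_id"):
            if col not in t.columns:
                raise SchemaError(f"hierarchy table missing column {col!r}")
        dup = t[t.duplicated("country_code", keep=False)]
        if len(dup):
            conflicting = (
                dup.groupby("country_code")[["region_id", "super_region_id"]]
                .nunique()
                .query("region_id > 1 or super_region_id > 1")
            )
            if len(conflicting):
                raise HierarchyError(
                    f"countries mapped to more than one region: "
                    f"{sorted(conflicting.index)}"
                )
            t = t.drop_duplicates("country_code")
        r2z = t.groupby("region_id")["super_region_id"].nunique()
        if (r2z > 1).any():
            raise HierarchyError(
                f"regions in more than one super-region: {sorted(r2z[r2z > 1].index)}"
            )
        self.table = t.reset_index(drop=True)
        self._region = dict(zip(t.country_code, t.region_id))
        self._super = dict(zip(t.country_code, t.super_region_id))
        self._region_super = dict(zip(t.region_id, t.super_region_id))

    @property
    def countries(self) -> list:
        return list(self.table.country_code)

    @property
    def regions(self) -> list:
        return sorted(self.table.region_id.unique())

    @property
    def super_regions(self) -> list:
        return sorted(self.table.super_region_id.unique())

    def region_of(self, country: str) -> str:
        return self._region[country]

    def super_region_of(self, country: str) -> str:
        return self._super[country]

    def super_region_of_region(self, region: str) -> str:
        return self._region_super[region]

    def countries_in_region(self, region: str) -> list:
        t = self.table
        return list(t.loc[t.region_id == region, "country_code"])


@dataclass
class PopulationWeights:
    """Female population counts by 5-year age band, per region or country.

    ``table`` columns: unit (region or country code), age_lower (band lower
    bound on the 15..65 grid), weight (female count), and optionally
    ever_sex_proportion for the 2018 aggregation table.
    """

    table: pd.DataFrame
    reference_year: int = 2010

    def __post_init__(self):
        t = self.table
        for col in ("unit", "age_lower", "weight"):
            if col not in t.columns:
                raise SchemaError(f"population table missing column {col!r}")
        if (t.weight < 0).any():
            bad = t.loc[t.weight < 0, "unit"].unique()
            raise ValidationError(f"negative population weights for units {sorted(bad)}")
        if "ever_sex_proportion" in t.columns:
            es = t.ever_sex_proportion.dropna()
            if ((es < 0) | (es > 1)).any():
                raise ValidationError("ever_sex_proportion outside [0, 1]")
        self._by_unit = {u: g.set_index("age_lower") for u, g in t.groupby("unit")}

    @property
    def units(self) -> list:
        return sorted(self._by_unit)

    def weights_for(self, unit: str, band_lowers=None, ever_sex: bool = False) -> np.ndarray:
        """Raw weights for a unit on the requested band grid (default: full grid)."""
        if unit not in self._by_unit:
            raise KeyError(f"no population weights for unit {unit!r}")
        g = self._by_unit[unit]
        lowers = AGE_BAND_LOWER if band_lowers is None else np.asarray(band_lowers)
        missing = [int(lb) for lb in lowers if lb not in g.index]
        if missing:
            raise ValidationError(f"unit {unit!r} missing weights for age bands {missing}")
        w = g.loc[lowers, "weight"].to_numpy(dtype=float)
        if ever_sex:
            if "ever_sex_proportion" not in g.columns:
                raise ValidationError("population table has no ever_sex_proportion column")
            w = w * g.loc[lowers, "ever_sex_proportion"].to_numpy(dtype=float)
        return w

    def shares_for(self, unit: str, band_lowers=None) -> np.ndarray:
        w = self.weights_for(unit, band_lowers)
        tot = w.sum()
        if tot <= 0:
            raise ValidationError(f"population weights for unit {unit!r} sum to zero")
        return w / tot


def bands_in_range(age_lower: int, age_upper: int) -> np.ndarray:
    """Indices of the 5-year bands covered by a closed age interval [l, h].

    ``age_upper == OPEN_AGE`` extends through the 65+ band; any upper bound
    above 65 is likewise truncated into the open top band.
    """
    lo = max(int(age_lower), 15)
    hi = 65 if age_upper >= 65 else int(age_upper)
    idx = np.where((AGE_BAND_LOWER >= (lo // 5) * 5) & (AGE_BAND_LOWER <= hi))[0]
    if len(idx) == 0:
        raise ValidationError(f"age range [{age_lower}, {age_upper}] covers no 5-year band")
    return idx


# ---------------------------------------------------------------------------
# readers / writers

def _load_mapping(schema) -> dict:
    if schema is None:
        return {}
    if isinstance(schema, dict):
        return dict(schema)
    path = Path(schema)
    text = path.read_text()
    if path.suffix in (".yml", ".yaml"):
        return yaml.safe_load(text) or {}
    return json.loads(text)


def read_observations(path, schema=None) -> pd.DataFrame:
    """Read an observation CSV into the internal schema and validate it.

    ``schema`` maps external column names to internal ones (dict, or path to
    a JSON/YAML file). Rows violating invariants raise ``ValidationError``
    listing the offending ``obs_id`` values — nothing is silently dropped.
    """
    mapping = _load_mapping(schema)
    df = pd.read_csv(path, dtype={"obs_id": str, "study_id": str, "country_code": str})
    if mapping:
        df = df.rename(columns=mapping)
    required = [c for c in OBS_COLUMNS if c not in
                ("denominator", "se", "ci_lower", "ci_upper", "publication_year",
                 "year_end", "age_upper")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"observation table missing required columns {missing}")
    for col in OBS_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[OBS_COLUMNS].copy()
    # a blank upper age means the band is open-ended
    df["age_upper"] = df["age_upper"].fillna(OPEN_AGE).astype(int)
    df["age_lower"] = df["age_lower"].astype(int)
    _validate_observations(df)
    return df


def _validate_observations(df: pd.DataFrame, hierarchy: GeoHierarchy | None = None):
    problems = []

    def flag(mask, why):
        if mask.any():
            problems.append((why, list(df.loc[mask, "obs_id"])))

    prev = pd.to_numeric(df.prevalence, errors="coerce")
    flag(prev.isna() | (prev < 0) | (prev > 1), "prevalence outside [0, 1]")
    flag(df.age_lower > df.age_upper, "age_lower > age_upper")
    year_end = pd.to_numeric(df.year_end, errors="coerce")
    known_end = year_end.notna()
    flag(known_end & (df.year_start > year_end), "year_start > year_end")
    for col, levels in _CATEGORICAL.items():
        flag(~df[col].isin(levels), f"invalid {col}")
    if hierarchy is not None:
        flag(~df.country_code.isin(hierarchy.countries), "unknown country_code")
    if problems:
        msgs = "; ".join(f"{why}: obs {ids}" for why, ids in problems)
        raise ValidationError(f"invalid observations — {msgs}",
                              bad_ids=sorted({i for _, ids in problems for i in ids}))


def write_observations(df: pd.DataFrame, path) -> None:
    df[OBS_COLUMNS].to_csv(path, index=False)


def read_hierarchy(path) -> GeoHierarchy:
    return GeoHierarchy(pd.read_csv(path, dtype=str))


def write_hierarchy(h: GeoHierarchy, path) -> None:
    h.table.to_csv(path, index=False)


def read_population(path, reference_year: int | None = None) -> PopulationWeights:
    df = pd.read_csv(path)
    if reference_year is None:
        reference_year = int(df["reference_year"].iloc[0]) if "reference_year" in df.columns else 2010
    return PopulationWeights(df, reference_year=reference_year)


def write_population(p: PopulationWeights, path) -> None:
    p.table.to_csv(path, index=False)
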