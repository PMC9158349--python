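"""Shared fixtures: synthetic databases and small fitted posteriors.

Everything is generated programmatically; the expensive fits are
session-scoped so multiple test modules can share them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from vawmeta.inference import McmcConfig
from vawmeta.pipeline import run_pipeline
from vawmeta.synthetic_data import make_fixture


@pytest.fixture(scope="session")
def tiny_bundle():
    return make_fixture("tiny", seed=2)


@pytest.fixture(scope="session")
def desk_bundle():
    return make_fixture("desk", seed=11)


@pytest.fixture(scope="session")
def tiny_cfg():
    return McmcConfig(chains=2, iterations=800, adaptation=400, warmup=200,
                      thin=2, seed=5)


@pytest.fixture(scope="session")
def tiny_result(tiny_bundle, tiny_cfg):
    """Full pipeline (both outcomes) on the tiny database, small chains."""
    return run_pipeline(tiny_bundle.observations, tiny_bundle.hierarchy,
                        tiny_bundle.pop2010, tiny_cfg)


LIFETIME_ONLY_COUNTRIES = ("C034", "C035", "C036", "C037", "C038", "C039")


@pytest.fixture(scope="session")
def desk_observations(desk_bundle):
    """Desk database with a handful of lifetime-only countries, mirroring
    real databases where some countries report a single recall period."""
    obs = desk_bundle.observations
    drop = (obs.outcome == "past_year") & obs.country_code.isin(LIFETIME_ONLY_COUNTRIES)
    return obs[~drop].reset_index(drop=True)


@pytest.fixture(scope="session")
def desk_result(desk_bundle, desk_observations):
    """Desk-profile joint fit used by the recovery and constraint checks."""
    cfg = McmcConfig.desk_profile(seed=4)
    return run_pipeline(desk_observations, desk_bundle.hierarchy,
                        desk_bundle.pop2010, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def make_obs_row(**kw) -> dict:
    """A fully-specified observation row; keyword overrides."""
    row = dict(
        obs_id="O1", study_id="S1", country_code="C000",
        year_start=2009, year_end=2010, outcome="lifetime",
        violence_type="physical_and_or_sexual", severity="all",
        population="ever_partnered", partner_ref="any_partner", geo="national",
        age_lower=15, age_upper=49, prevalence=0.25, denominator=1000.0,
        se=np.nan, ci_lower=np.nan, ci_upper=np.nan, publication_year=2012)
    row.update(kw)
    return row


def obs_frame(rows) -> pd.DataFrame:
    return pd.DataFrame([make_obs_row(**r) for r in rows])
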