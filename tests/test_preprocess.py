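"""Pre-processing: imputation, effective sample sizes, dataset split."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vawmeta.preprocess import (
    build_datasets,
    effective_sample_size,
    impute_denominators,
    impute_metadata,
    invert_wilson_upper,
    prepare_observations,
    select_optimal_set,
    wilson_upper,
    InversionError,
)
from vawmeta.vaw_data import OPEN_AGE, PopulationWeights, ValidationError

from conftest import obs_frame


def flat_population(weights_by_band, unit="R0"):
    rows = [dict(unit=unit, age_lower=lb, weight=w) for lb, w in weights_by_band]
    return PopulationWeights(pd.DataFrame(rows))


class TestDenominatorImputation:
    def test_equal_population_splits_equally(self):
        obs = obs_frame([
            dict(obs_id="A", age_lower=15, age_upper=19, denominator=np.nan,
                 country_code="R0", study_n=1000.0),
            dict(obs_id="B", age_lower=20, age_upper=24, denominator=np.nan,
                 country_code="R0", study_n=1000.0)])
        pop = flat_population([(15, 100.0), (20, 100.0)])
        out = impute_denominators(obs, pop)
        assert out.denominator.tolist() == [500.0, 500.0]

    def test_proportional_allocation(self):
        obs = obs_frame([
            dict(obs_id="A", age_lower=15, age_upper=19, denominator=np.nan,
                 country_code="R0", study_n=1000.0),
            dict(obs_id="B", age_lower=20, age_upper=24, denominator=np.nan,
                 country_code="R0", study_n=1000.0)])
        pop = flat_population([(15, 600.0), (20, 400.0)])
        out = impute_denominators(obs, pop)
        assert out.denominator.tolist() == [600.0, 400.0]

    def test_defaults_when_no_total_reported(self):
        pop = flat_population([(15, 1.0), (20, 1.0)])
        for geo, expected in (("national", 3000.0), ("urban", 1000.0)):
            obs = obs_frame([
                dict(obs_id="A", age_lower=15, age_upper=19, denominator=np.nan, geo=geo,
                     country_code="R0"),
                dict(obs_id="B", age_lower=20, age_upper=24, denominator=np.nan, geo=geo,
                     country_code="R0")])
            out = impute_denominators(obs, pop)
            assert out.denominator.sum() == pytest.approx(expected)
            assert out.imputed_total_n.all()

    def test_totals_preserved(self):
        obs = obs_frame([
            dict(obs_id=f"A{i}", age_lower=15 + 5 * i, age_upper=19 + 5 * i,
                 denominator=np.nan, country_code="R0", study_n=3333.0)
            for i in range(5)])
        pop = flat_population([(15 + 5 * i, float(100 - 7 * i)) for i in range(5)])
        out = impute_denominators(obs, pop)
        assert out.denominator.sum() == pytest.approx(3333.0)

    def test_age_range_outside_population_errors(self):
        obs = obs_frame([dict(obs_id="A", age_lower=60, age_upper=64,
                              denominator=np.nan, country_code="R0")])
        pop = flat_population([(15, 1.0)])
        with pytest.raises(ValidationError):
            impute_denominators(obs, pop)


class TestEffectiveSampleSize:
    def test_design_effect_fallback(self):
        row = obs_frame([dict(denominator=2500.0)]).iloc[0]
        assert effective_sample_size(row) == pytest.approx(1000.0)

    def test_reported_se_inverts_exactly(self):
        p, n = 0.3, 1600
        row = obs_frame([dict(prevalence=p, denominator=5000.0,
                              se=np.sqrt(p * (1 - p) / n))]).iloc[0]
        assert effective_sample_size(row) == pytest.approx(n, rel=1e-9)

    def test_wilson_inversion_bisection(self):
        p, upper = 0.30, 0.35
        n = invert_wilson_upper(p, upper, n_hint=1000)
        assert wilson_upper(p, n) == pytest.approx(upper, abs=1e-6)

    def test_upper_not_above_prevalence_errors(self):
        with pytest.raises(InversionError):
            invert_wilson_upper(0.3, 0.3, n_hint=100)

    def test_unbracketable_falls_back_to_design_effect(self, caplog):
        # upper limit wider than even n=1 allows -> fall back with a warning
        row = obs_frame([dict(prevalence=0.3, denominator=250.0,
                              ci_upper=0.9999)]).iloc[0]
        with caplog.at_level("WARNING"):
            out = effective_sample_size(row)
        assert out == pytest.approx(100.0)

    @given(st.floats(0.05, 0.95), st.integers(50, 20000))
    @settings(max_examples=60, deadline=None)
    def test_inversion_recovers_n(self, p, n):
        upper = wilson_upper(p, n)
        n_hat = invert_wilson_upper(p, upper, n_hint=n)
        assert abs(n_hat - n) / n < 1e-3

    def test_monotone_in_ci_width(self):
        p = 0.3
        uppers = [0.32, 0.34, 0.36, 0.38]
        ns = [invert_wilson_upper(p, u, n_hint=5000) for u in uppers]
        assert all(a > b for a, b in zip(ns, ns[1:]))


class TestMetadataImputation:
    def test_missing_end_year_from_publication(self):
        obs = obs_frame([dict(year_end=np.nan, publication_year=2014)])
        out = impute_metadata(obs)
        assert out.year_end.iloc[0] == 2014 and out.imputed_end_year.iloc[0]

    def test_nothing_missing_is_identity(self):
        obs = obs_frame([{}])
        out = impute_metadata(obs)
        assert out.year_end.iloc[0] == 2010
        assert not out.imputed_end_year.iloc[0]
        assert not out.imputed_upper_age.iloc[0]

    def test_missing_upper_age_flagged_open(self):
        obs = obs_frame([dict(age_upper=OPEN_AGE)])
        out = impute_metadata(obs)
        assert out.imputed_upper_age.iloc[0]

    def test_both_dates_missing_errors(self):
        obs = obs_frame([dict(year_end=np.nan, publication_year=np.nan)])
        with pytest.raises(ValidationError):
            impute_metadata(obs)


class TestOptimalSet:
    def test_all_severity_preferred_over_severe_only(self):
        obs = obs_frame([dict(obs_id="SEV", severity="severe_only"),
                         dict(obs_id="ALL", severity="all")])
        out = select_optimal_set(obs)
        assert list(out.obs_id) == ["ALL"] and out.in_optimal_set.iloc[0]

    def test_physical_preferred_over_sexual(self):
        obs = obs_frame([dict(obs_id="SX", violence_type="sexual_only"),
                         dict(obs_id="PH", violence_type="physical_only")])
        out = select_optimal_set(obs)
        assert list(out.obs_id) == ["PH"]
        assert not out.in_optimal_set.iloc[0]

    def test_single_observation_identity(self):
        obs = obs_frame([dict(obs_id="ONLY", population="all_women")])
        out = select_optimal_set(obs)
        assert list(out.obs_id) == ["ONLY"]

    def test_empty_group_errors(self):
        with pytest.raises(ValidationError):
            select_optimal_set(obs_frame([]).iloc[0:0])

    def test_rule_order_severity_dominates_type(self):
        obs = obs_frame([
            dict(obs_id="A", severity="severe_only",
                 violence_type="physical_and_or_sexual"),
            dict(obs_id="B", severity="all", violence_type="sexual_only")])
        assert list(select_optimal_set(obs).obs_id) == ["B"]


class TestBuildDatasets:
    def _prepared(self, rows, pop=None):
        df = obs_frame(rows)
        pop = pop or flat_population(
            [(lb, 100.0) for lb in range(15, 70, 5)], unit="R0")
        return prepare_observations(df, pop)

    def test_broad_band_to_adjustment_bands_to_modeling(self):
        rows = [dict(obs_id="BROAD", age_lower=15, age_upper=49)]
        rows += [dict(obs_id=f"B{lb}", age_lower=lb, age_upper=lb + 4)
                 for lb in range(15, 50, 5)]
        adj, mod = build_datasets(self._prepared(rows))
        assert list(adj.obs_id) == ["BROAD"]
        assert sorted(mod.obs_id) == sorted(f"B{lb}" for lb in range(15, 50, 5))

    def test_national_supersedes_urban_rural(self):
        rows = [dict(obs_id="NAT", geo="national"),
                dict(obs_id="URB", geo="urban"),
                dict(obs_id="RUR", geo="rural")]
        _, mod = build_datasets(self._prepared(rows))
        assert list(mod.obs_id) == ["NAT"]

    def test_lone_urban_stratum_kept(self):
        rows = [dict(obs_id="URB", geo="urban")]
        _, mod = build_datasets(self._prepared(rows))
        assert list(mod.obs_id) == ["URB"] and mod.geo.iloc[0] == "urban"

    def test_equal_width_partial_overlap_errors(self):
        rows = [dict(obs_id="A", age_lower=15, age_upper=30),
                dict(obs_id="B", age_lower=25, age_upper=40)]
        with pytest.raises(ValidationError, match="disambiguated"):
            build_datasets(self._prepared(rows))

    def test_modeling_age_strata_disjoint(self, tiny_bundle):
        prep = prepare_observations(tiny_bundle.observations, tiny_bundle.pop2010,
                                    tiny_bundle.hierarchy)
        _, mod = build_datasets(prep)
        for _, g in mod.groupby(["study_id", "outcome", "geo"]):
            bands = sorted(zip(g.age_lower, g.age_upper.clip(upper=70)))
            for (l1, h1), (l2, h2) in zip(bands, bands[1:]):
                assert h1 < l2, "overlapping bands survived"

    def test_count_identity_reproduces_prevalence(self, tiny_bundle):
        prep = prepare_observations(tiny_bundle.observations, tiny_bundle.pop2010,
                                    tiny_bundle.hierarchy)
        # y/N must reproduce prevalence to within half a count
        err = np.abs(prep.y_adjusted / prep.n_effective - prep.prevalence)
        assert (err <= 0.5 / prep.n_effective + 1e-12).all()
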