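"""Crosswalk: exact matching, paired ORs, pooling, geo factors, LHS draws."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from vawmeta.crosswalk import (
    BOUND_AT_NULL,
    MatchedSet,
    estimate_adjustment_factors,
    exact_match,
    fit_geo_strata_factors,
    matched_pair_table,
    meta_analyze,
    pair_odds_ratio,
    sample_adjustment_vectors,
)
from vawmeta.preprocess import prepare_observations
from vawmeta.vaw_data import GeoHierarchy, PopulationWeights

from conftest import obs_frame


def _prepared(rows):
    hier = GeoHierarchy(pd.DataFrame(dict(
        country_code=["C000", "C001"], region_id=["R0", "R0"],
        super_region_id=["Z0", "Z0"])))
    pop = PopulationWeights(pd.DataFrame(
        [dict(unit="R0", age_lower=lb, weight=100.0) for lb in range(15, 70, 5)]))
    return prepare_observations(obs_frame(rows), pop, hier), hier


def _mk_pair(p1, n1, p0, n0):
    mk = lambda p, n, oid: pd.Series(dict(
        obs_id=oid, y_adjusted=round(p * n), n_effective=float(n), outcome="lifetime"))
    return MatchedSet("S1", "physical_only", mk(p1, n1, "E"), mk(p0, n0, "R"), ())


class TestPairOddsRatio:
    def test_equal_prevalence_gives_null(self):
        log_or, se = pair_odds_ratio(_mk_pair(0.25, 400, 0.25, 400))
        assert log_or == pytest.approx(0.0)

    def test_two_by_two_arithmetic_oracle(self):
        log_or, se = pair_odds_ratio(_mk_pair(0.20, 100, 0.25, 100))
        assert math.exp(log_or) == pytest.approx(0.75, rel=1e-12)
        assert se == pytest.approx(math.sqrt(1 / 20 + 1 / 80 + 1 / 25 + 1 / 75))

    def test_zero_cell_continuity_corrected(self):
        log_or, se = pair_odds_ratio(_mk_pair(0.0, 50, 0.2, 50))
        assert np.isfinite(log_or) and np.isfinite(se)

    def test_missing_n_errors(self):
        m = _mk_pair(0.2, 100, 0.25, 100)
        m.exposed_obs["n_effective"] = np.nan
        with pytest.raises(ValueError):
            pair_odds_ratio(m)


class TestExactMatch:
    def test_direct_pair_on_violence_type(self):
        prep, _ = _prepared([
            dict(obs_id="REF"),
            dict(obs_id="EXP", violence_type="physical_only")])
        out = exact_match(prep, "physical_only")
        assert len(out) == 1
        assert out[0].exposed_obs.obs_id == "EXP"
        assert out[0].reference_obs.obs_id == "REF"

    def test_single_level_no_match(self):
        prep, _ = _prepared([dict(obs_id="ONLY", violence_type="physical_only")])
        assert exact_match(prep, "physical_only") == []

    def test_closest_to_optimal_reference_chosen(self):
        # two candidate references differ in partner_ref (not a matching key
        # for the population covariate): the any-partner one is closer to
        # the gold standard and must be retained
        prep, _ = _prepared([
            dict(obs_id="EXP", population="all_women"),
            dict(obs_id="REF_FAR", partner_ref="current_or_most_recent"),
            dict(obs_id="REF_OPT")])
        out = exact_match(prep, "all_women")
        assert len(out) == 1 and out[0].reference_obs.obs_id == "REF_OPT"

    def test_mismatched_age_bands_not_paired(self):
        prep, _ = _prepared([
            dict(obs_id="REF", age_lower=15, age_upper=49),
            dict(obs_id="EXP", violence_type="physical_only",
                 age_lower=15, age_upper=44)])
        assert exact_match(prep, "physical_only") == []

    def test_exposed_in_at_most_one_set_per_covariate(self, tiny_bundle):
        from vawmeta.preprocess import build_datasets
        prep = prepare_observations(tiny_bundle.observations, tiny_bundle.pop2010,
                                    tiny_bundle.hierarchy)
        adj, _ = build_datasets(prep)
        for cov in ("physical_only", "currently_partnered"):
            matches = exact_match(adj, cov)
            exposed = [m.exposed_obs.obs_id for m in matches]
            assert len(exposed) == len(set(exposed))


class TestMetaAnalyze:
    def _pairs(self, rows):
        return pd.DataFrame(rows)

    def test_single_pair_degenerate(self):
        pairs = self._pairs([dict(covariate="partner_current", outcome="lifetime",
                                  survey_id="S1", super_region="Z0",
                                  log_or=-0.2, se=0.1)])
        f = meta_analyze(pairs)
        row = f.entries[f.entries.stratum == "overall"].iloc[0]
        assert row.log_or == pytest.approx(-0.2) and row.se == pytest.approx(0.1)

    def test_two_identical_effects_closed_form(self):
        pairs = self._pairs([dict(covariate="partner_current", outcome="lifetime",
                                  survey_id=s, super_region="Z0",
                                  log_or=-0.3, se=0.2) for s in ("S1", "S2")])
        row = meta_analyze(pairs).entries.query("stratum == 'overall'").iloc[0]
        assert row.log_or == pytest.approx(-0.3)
        assert row.se == pytest.approx(0.2 / math.sqrt(2), rel=1e-6)

    def test_three_pairs_keep_overall_level(self):
        pairs = self._pairs([dict(covariate="partner_current", outcome="lifetime",
                                  survey_id=f"S{i}", super_region="Z0",
                                  log_or=-0.2, se=0.1) for i in range(3)])
        f = meta_analyze(pairs)
        z_row = f.entries.query("stratum == 'Z0'").iloc[0]
        assert z_row.used_level == "overall"
        assert f.lookup("partner_current", "lifetime", "Z0")[0] == pytest.approx(
            f.entries.query("stratum == 'overall'").log_or.iloc[0])

    def test_four_pairs_use_super_region_level(self):
        pairs = self._pairs([dict(covariate="partner_current", outcome="lifetime",
                                  survey_id=f"S{i}", super_region="Z0",
                                  log_or=-0.2 - 0.01 * i, se=0.1) for i in range(4)])
        f = meta_analyze(pairs)
        assert f.entries.query("stratum == 'Z0'").used_level.iloc[0] == "super_region"

    def test_bound_covariates_clamped_at_null(self):
        pairs = self._pairs([dict(covariate="severe_only", outcome="lifetime",
                                  survey_id="S1", super_region="Z0",
                                  log_or=0.4, se=0.1)])
        assert meta_analyze(pairs).entries.log_or.max() <= 0.0

    def test_all_women_past_year_reuses_lifetime(self):
        pairs = self._pairs([dict(covariate="all_women", outcome="lifetime",
                                  survey_id="S1", super_region="Z0",
                                  log_or=-0.24, se=0.05)])
        f = meta_analyze(pairs)
        assert f.lookup("all_women", "past_year", "Z0")[0] == pytest.approx(-0.24)

    def test_overall_within_hull_of_strata_when_homogeneous(self):
        pairs = self._pairs(
            [dict(covariate="partner_current", outcome="lifetime",
                  survey_id=f"A{i}", super_region="Z0", log_or=-0.30, se=0.1)
             for i in range(5)]
            + [dict(covariate="partner_current", outcome="lifetime",
                    survey_id=f"B{i}", super_region="Z1", log_or=-0.10, se=0.1)
               for i in range(5)])
        e = meta_analyze(pairs).entries
        overall = e.query("stratum == 'overall'").log_or.iloc[0]
        assert -0.30 - 1e-9 <= overall <= -0.10 + 1e-9


class TestGeoStrata:
    def _geo_rows(self, rng, n_surveys=8, or_urban=1.0, or_rural=1.0):
        rows = []
        for s in range(n_surveys):
            base = -1.0 + rng.normal(0, 0.2)
            for geo, lo in (("national", 0.0),
                            ("urban", math.log(or_urban)),
                            ("rural", math.log(or_rural))):
                n = 2000
                p = expit(base + lo)
                y = rng.binomial(n, p)
                rows.append(dict(obs_id=f"G{s}{geo}", study_id=f"GS{s}",
                                 country_code=["C000", "C001"][s % 2], geo=geo,
                                 prevalence=y / n, denominator=float(n)))
        return rows

    def test_null_recovery(self, rng):
        prep, hier = _prepared(self._geo_rows(rng))
        out = fit_geo_strata_factors(prep, hier)
        est = out.query("covariate == 'geo_rural' and stratum == 'overall'")
        assert abs(est.log_or.iloc[0]) < 0.1

    def test_injected_rural_effect_recovered(self, rng):
        prep, hier = _prepared(self._geo_rows(rng, n_surveys=10, or_rural=1.15))
        out = fit_geo_strata_factors(prep, hier)
        est = out.query("covariate == 'geo_rural' and stratum == 'overall'").iloc[0]
        assert abs(est.log_or - math.log(1.15)) < 2.5 * est.se + 0.05

    def test_survey_missing_a_stratum_excluded(self, rng):
        rows = self._geo_rows(rng, n_surveys=4)
        rows = [r for r in rows if not (r["study_id"] == "GS0" and r["geo"] == "urban")]
        prep, hier = _prepared(rows)
        out = fit_geo_strata_factors(prep, hier)
        assert out.query("stratum == 'overall'").n_matches.max() == 3

    def test_single_survey_falls_back_to_fixed_effect(self, rng, caplog):
        prep, hier = _prepared(self._geo_rows(rng, n_surveys=1))
        with caplog.at_level("WARNING"):
            out = fit_geo_strata_factors(prep, hier)
        assert (out.used_level == "overall").all() and len(out) > 0


class TestAdjustmentDraws:
    def _factors(self, se=0.1, cov="partner_current"):
        pairs = pd.DataFrame([dict(covariate=cov, outcome="lifetime",
                                   survey_id="S1", super_region="Z0",
                                   log_or=-0.2, se=se)])
        return meta_analyze(pairs)

    def test_zero_se_gives_constant_draws(self):
        ds = sample_adjustment_vectors(self._factors(se=0.0), ["lifetime"], ["Z0"],
                                       D=10, seed=1)
        assert np.allclose(ds.draws, -0.2)

    def test_lhs_mean_close_to_estimate(self):
        ds = sample_adjustment_vectors(self._factors(se=0.1), ["lifetime"], ["Z0"],
                                       D=10, seed=3)
        j = ds.meta.query("covariate == 'partner_current'").index[0]
        assert abs(ds.draws[:, j].mean() - (-0.2)) < 2 * 0.1 / math.sqrt(10)

    def test_bound_covariate_draws_truncated_at_null(self):
        ds = sample_adjustment_vectors(self._factors(se=0.5, cov="severe_only"),
                                       ["lifetime"], ["Z0"], D=50, seed=2)
        assert (ds.draws <= 0.0).all()
        assert ds.meta.covariate.isin(BOUND_AT_NULL).all()

    def test_reproducible_under_seed(self):
        a = sample_adjustment_vectors(self._factors(), ["lifetime"], ["Z0"], D=5, seed=7)
        b = sample_adjustment_vectors(self._factors(), ["lifetime"], ["Z0"], D=5, seed=7)
        assert np.array_equal(a.draws, b.draws)

    def test_invalid_draw_count_rejected(self):
        with pytest.raises(ValueError):
            sample_adjustment_vectors(self._factors(), ["lifetime"], ["Z0"], D=0)


class TestEndToEndRecovery:
    def test_injected_or_recovered_on_synthetic_database(self, tiny_bundle):
        """Matched-pair pooling over a generated database lands near the
        injected physical-only odds ratio."""
        from vawmeta.preprocess import build_datasets
        from vawmeta.synthetic_data import make_fixture

        b = make_fixture("paperlike", seed=7)
        prep = prepare_observations(b.observations, b.pop2010, b.hierarchy)
        adj, _ = build_datasets(prep)
        pairs = matched_pair_table(adj, b.hierarchy, "physical_only")
        f = meta_analyze(pairs)
        est, se = f.lookup("physical_only", "lifetime", "Z0")
        true = math.log(b.truth["settings"]["adjustment_or"]["physical_only"])
        assert abs(est - true) < 3 * se + 0.02
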