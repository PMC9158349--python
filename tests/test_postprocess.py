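"""Prediction, country imputation, and aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from vawmeta.postprocess import (
    aggregate,
    all_country_prevalence,
    broad_age_prevalence,
    estimate_table,
    impute_country,
    joint_country_predictions,
    predict_country,
    predict_country_logits,
)
from vawmeta.vaw_data import AGE_BAND_LOWER, PopulationWeights, bands_in_range


def _weights18(countries, rng=None, equal=True):
    rows = []
    for i, c in enumerate(countries):
        for lb in AGE_BAND_LOWER:
            w = 100.0 if equal else 100.0 * (i + 1)
            rows.append(dict(unit=c, age_lower=int(lb), weight=w,
                             ever_sex_proportion=min(0.4 + 0.05 * (lb - 15), 1.0)))
    return PopulationWeights(pd.DataFrame(rows), 2018)


class TestPredictCountry:
    def test_study_effects_excluded_from_predictions(self, tiny_result):
        post = tiny_result.post
        c = post.spec.units.countries[0]
        before = predict_country_logits(post, "lifetime", c, 2010.0)
        post.params["lifetime"]["u_s"] = post.params["lifetime"]["u_s"] + 99.0
        after = predict_country_logits(post, "lifetime", c, 2010.0)
        post.params["lifetime"]["u_s"] = post.params["lifetime"]["u_s"] - 99.0
        assert np.array_equal(before, after)

    def test_prediction_is_intercepts_plus_splines(self, tiny_result):
        post = tiny_result.post
        u = post.spec.units
        c = u.countries[0]
        zi, ri = int(u.country_super[0]), int(u.country_region[0])
        lg = predict_country_logits(post, "lifetime", c, 2010.0)
        p = post.params["lifetime"]
        flat = lambda k: post.flat("lifetime", k)
        icpt = (flat("u_g") + flat("u_z")[:, zi] + flat("u_r")[:, ri]
                + flat("u_c")[:, 0])
        lam = (flat("eta_g") + flat("eta_z")[:, zi] + flat("eta_r")[:, ri]
               + flat("eta_c")[:, 0])
        gamma = lam @ post.spec.age_basis.matrix.T
        phi = (flat("phi_g") + flat("phi_z")[:, zi] + flat("phi_r")[:, ri]
               + flat("phi_c")[:, 0])
        delta = phi @ post.spec.time_basis.evaluate(2010.0)[0]
        assert np.allclose(lg, icpt[:, None] + gamma + delta[:, None], atol=1e-12)

    def test_unknown_country_raises(self, tiny_result):
        with pytest.raises(KeyError):
            predict_country_logits(tiny_result.post, "lifetime", "NOPE", 2010.0)

    def test_prediction_inside_posterior_band_at_observed_cell(self, tiny_result):
        """At a surveyed cell the country prediction falls inside the fitted
        observation's posterior band (same linear predictor minus the modest
        study effect and instrument offset)."""
        post = tiny_result.post
        d = post.spec.outcome_data["lifetime"]
        # pick a gold-standard single-band national observation
        sel = [i for i in range(d.n_obs)
               if d.X[i] == 0.0 and (d.pair_obs == i).sum() == 1]
        i = sel[0]
        c = post.spec.units.countries[d.country_idx[i]]
        a = d.pair_age[d.pair_obs == i][0]
        pred = np.median(predict_country(post, "lifetime", c,
                                         float(d.year[i]))[:, a])
        p_fit = post.p_obs["lifetime"].reshape(-1, d.n_obs)[:, i]
        lo, hi = np.quantile(p_fit, [0.005, 0.995])
        assert lo - 0.05 <= pred <= hi + 0.05


class TestImputeCountry:
    def test_zero_sigma_c_matches_regional_mean_curve(self, tiny_result, rng):
        post = tiny_result.post
        u = post.spec.units
        region = u.regions[0]
        saved = post.params["lifetime"]["sig_c"]
        post.params["lifetime"]["sig_c"] = np.zeros_like(saved)
        try:
            imp = impute_country(post, "lifetime", region, 2010.0, rng)
            zi = int(u.region_super[0])
            flat = lambda k: post.flat("lifetime", k)
            icpt = flat("u_g") + flat("u_z")[:, zi] + flat("u_r")[:, 0]
            lam = flat("eta_g") + flat("eta_z")[:, zi] + flat("eta_r")[:, 0]
            phi = flat("phi_g") + flat("phi_z")[:, zi] + flat("phi_r")[:, 0]
            expected = expit(icpt[:, None] + lam @ post.spec.age_basis.matrix.T
                             + (phi @ post.spec.time_basis.evaluate(2010.0)[0])[:, None])
            assert np.allclose(imp, expected, atol=1e-12)
        finally:
            post.params["lifetime"]["sig_c"] = saved

    def test_imputed_intervals_wider_than_data_country(self, tiny_result, rng):
        post = tiny_result.post
        u = post.spec.units
        region = u.regions[0]
        sibling = u.countries[int(np.where(u.country_region == 0)[0][0])]
        imp = impute_country(post, "lifetime", region, 2010.0, rng)
        dat = predict_country(post, "lifetime", sibling, 2010.0)
        w_imp = np.diff(np.quantile(imp, [0.025, 0.975], axis=0), axis=0)
        w_dat = np.diff(np.quantile(dat, [0.025, 0.975], axis=0), axis=0)
        assert w_imp.mean() >= w_dat.mean()

    def test_full_mode_at_least_as_wide_as_intercept_mode(self, tiny_result):
        post = tiny_result.post
        region = post.spec.units.regions[0]
        a = impute_country(post, "lifetime", region, 2010.0,
                           np.random.default_rng(0), mode="intercept")
        b = impute_country(post, "lifetime", region, 2010.0,
                           np.random.default_rng(0), mode="full")
        assert b.std(axis=0).mean() >= a.std(axis=0).mean() - 1e-6

    def test_imputed_flagged_in_all_country_table(self, tiny_result, rng):
        post = tiny_result.post
        draws, imputed = all_country_prevalence(post, "lifetime", 2010.0, rng)
        fitted = set(post.spec.units.countries)
        for c, flag in imputed.items():
            assert flag == (c not in fitted)


class TestAggregate:
    def _draws(self, values, n_draws=200):
        return {c: np.full((n_draws, len(AGE_BAND_LOWER)), v)
                for c, v in values.items()}

    def test_single_country_region_equals_country(self):
        d = self._draws({"A": 0.25})
        w = _weights18(["A"])
        agg = aggregate(d, w, (15, 49), ["A"])
        assert np.allclose(agg, 0.25)

    def test_two_equal_weight_countries_average(self):
        d = self._draws({"A": 0.2, "B": 0.4})
        agg = aggregate(d, _weights18(["A", "B"]), (15, 49), ["A", "B"])
        assert np.allclose(agg, 0.3)

    def test_three_country_count_summation_oracle(self, rng):
        vals = {"A": 0.1, "B": 0.25, "C": 0.4}
        d = self._draws(vals)
        w = _weights18(list(vals), equal=False)
        cells = bands_in_range(15, 49)
        num = den = 0.0
        for c, v in vals.items():
            W = w.weights_for(c, AGE_BAND_LOWER[cells], ever_sex=True)
            num += v * W.sum()
            den += W.sum()
        agg = aggregate(d, w, (15, 49), list(vals))
        assert np.allclose(agg, num / den, atol=1e-12)

    def test_aggregate_within_member_range(self, rng):
        d = {c: rng.uniform(0.1, 0.5, size=(100, len(AGE_BAND_LOWER)))
             for c in "ABC"}
        agg = aggregate(d, _weights18(list("ABC")), (15, 49), list("ABC"))
        per_country = [broad_age_prevalence(d[c],
                                            _weights18(list("ABC")).weights_for(c, ever_sex=True),
                                            bands_in_range(15, 49)) for c in "ABC"]
        stacked = np.stack(per_country)
        assert (agg >= stacked.min(axis=0) - 1e-12).all()
        assert (agg <= stacked.max(axis=0) + 1e-12).all()

    def test_order_of_aggregation_invariant(self, rng):
        """Countries -> regions -> global equals countries -> global."""
        countries = ["A", "B", "C", "D"]
        d = {c: rng.uniform(0.1, 0.5, size=(50, len(AGE_BAND_LOWER)))
             for c in countries}
        w = _weights18(countries, equal=False)
        cells = bands_in_range(15, 49)
        direct = aggregate(d, w, (15, 49), countries)
        # two "regions" then weight-combine by summed member weights
        w1 = sum(w.weights_for(c, AGE_BAND_LOWER[cells], ever_sex=True).sum()
                 for c in ["A", "B"])
        w2 = sum(w.weights_for(c, AGE_BAND_LOWER[cells], ever_sex=True).sum()
                 for c in ["C", "D"])
        r1 = aggregate(d, w, (15, 49), ["A", "B"])
        r2 = aggregate(d, w, (15, 49), ["C", "D"])
        via_regions = (r1 * w1 + r2 * w2) / (w1 + w2)
        assert np.allclose(direct, via_regions, atol=1e-12)

    def test_missing_member_errors(self):
        d = self._draws({"A": 0.2})
        with pytest.raises(KeyError):
            aggregate(d, _weights18(["A", "B"]), (15, 49), ["A", "B"])


class TestEstimateTable:
    def test_tidy_output_invariants(self, tiny_result, tiny_bundle):
        table = estimate_table(tiny_result.post, tiny_bundle.pop2018,
                               year=2015.0, seed=3, constrain="none")
        assert set(table.level) >= {"country", "region", "global"}
        assert ((table.ci_lower <= table["median"] + 1e-12)
                & (table["median"] <= table.ci_upper + 1e-12)).all()
        assert table["median"].between(0, 1).all()
        world = table.query("level == 'global' and outcome == 'lifetime'")
        assert len(world) == 1 and 0.0 < world["median"].iloc[0] < 1.0
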