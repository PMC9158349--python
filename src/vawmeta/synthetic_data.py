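"""Fully synthetic survey databases with the model's generative structure.

The generator draws a country/region/super-region hierarchy, hierarchical
prevalence effects (intercepts, spline age patterns, spline time trends),
and simulates surveys the way the real database looks: heterogeneous age
reporting (5-year bands vs broad 15-49 groups), a mix of gold-standard
and non-reference instruments (with known injected adjustment odds
ratios), national and sub-national strata, design effects, and missing
denominators / confidence intervals at configurable rates.  Observed
counts are binomial draws at the design-deflated effective sample size:

    y ~ Binomial(N / design_effect, p * adjustment)

Because the generator and the likelihood share one model family, fitting
generated data with the true knots is a genuine parameter-recovery
experiment: credible intervals should cover the stored truth at their
nominal rate.

Default effect sizes echo the magnitudes reported for real IPV data
(lifetime prevalence near 27%, past-year near 13%, physical-only OR near
0.86, sexual-only near 0.26), so crosswalk and recovery tests exercise a
realistic regime.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .preprocess import wilson_upper
from .splines import build_age_spline_basis, build_time_spline_basis
from .vaw_data import (
    AGE_BAND_LOWER,
    AGE_MIDPOINTS,
    N_AGE_BANDS,
    GeoHierarchy,
    PopulationWeights,
)

# logit-scale target age pattern (offsets across the 11 grid cells),
# peaking in the mid-20s and declining after the mid-40s
_AGE_SHAPE = np.array([-0.30, -0.05, 0.08, 0.10, 0.05, -0.02,
                       -0.12, -0.22, -0.32, -0.40, -0.45])
# mild secular decline on the logit scale per year
_TIME_SLOPE = -0.012


@dataclass
class SyntheticTruth:
    """Generator settings plus the true effect sizes to recover."""

    n_super: int = 7
    n_regions: int = 21
    n_countries: int = 40
    studies_per_country: tuple = (1, 2)
    # hierarchy SDs on the logit scale
    sd_z: float = 0.25
    sd_r: float = 0.20
    sd_c: float = 0.25
    sd_n: float = 0.12          # national study SD
    tau: float = 0.12           # extra SD for sub-national studies
    # spline-coefficient deviation SDs (per level, all k)
    ups_z: float = 0.04
    ups_r: float = 0.03
    ups_c: float = 0.05
    om_z: float = 0.010
    om_r: float = 0.008
    om_c: float = 0.012
    age_knots: tuple = (25,)
    time_knot: float = 2011.0
    years: tuple = (2000, 2018)
    base_prevalence: dict = field(default_factory=lambda: {
        "lifetime": 0.27, "past_year": 0.13})
    outcome_correlation: float = 0.8
    #: injected adjustment odds ratios (per covariate; same for both outcomes)
    adjustment_or: dict = field(default_factory=lambda: {
        "severe_only": 0.38, "physical_only": 0.86, "sexual_only": 0.26,
        "all_women": 0.79, "currently_partnered": 0.91, "partner_current": 0.84,
        "geo_urban": 0.92, "geo_rural": 1.08})
    #: between-survey heterogeneity of the adjustment log-ORs
    adjustment_sd: float = 0.03
    #: probability a study uses each non-reference instrument level
    p_nonref: dict = field(default_factory=lambda: {
        "severe_only": 0.03, "physical_only": 0.20, "sexual_only": 0.05,
        "all_women": 0.06, "currently_partnered": 0.10, "partner_current": 0.30})
    p_bands: float = 0.70       # report 5-year bands (else broad group only)
    p_broad_total: float = 0.80  # banded studies also report a broad total
    p_dual: float = 0.40        # non-reference studies also report reference rows
    p_geo_trio: float = 0.10    # national studies also report urban+rural strata
    p_subnational: float = 0.12
    p_missing_denominator: float = 0.05
    p_report_ci: float = 0.30
    design_effect: float = 2.5
    national_n: tuple = (3000, 12000)
    subnational_n: tuple = (600, 3000)


@dataclass
class SyntheticBundle:
    """Everything generate_database emits, in memory."""

    observations: pd.DataFrame
    hierarchy: GeoHierarchy
    pop2010: PopulationWeights
    pop2018: PopulationWeights
    truth: dict


def _make_hierarchy(t: SyntheticTruth) -> GeoHierarchy:
    rows = []
    for c in range(t.n_countries):
        r = c % t.n_regions
        z = r % t.n_super
        rows.append((f"C{c:03d}", f"R{r:02d}", f"Z{z}"))
    return GeoHierarchy(pd.DataFrame(rows, columns=["country_code", "region_id",
                                                    "super_region_id"]))


def _make_populations(t: SyntheticTruth, h: GeoHierarchy, rng) -> tuple:
    """Smooth declining age pyramids (region-level 2010, country-level 2018)
    and an ever-had-sex proportion rising from ~0.4 at 15-19 to ~1 by 30."""
    ages = AGE_MIDPOINTS
    ever_sex = np.clip(0.4 + 0.05 * (ages - 17.0), 0.4, 0.995)
    rows10, rows18 = [], []
    for r in h.regions:
        decline = rng.uniform(0.015, 0.035)
        base = rng.uniform(0.8e6, 3e6)
        w = base * np.exp(-decline * (ages - 15.0))
        for lb, wi in zip(AGE_BAND_LOWER, w):
            rows10.append((r, int(lb), float(wi), 2010))
    for c in h.countries:
        decline = rng.uniform(0.015, 0.035)
        base = rng.uniform(2e5, 1.5e6)
        w = base * np.exp(-decline * (ages - 15.0))
        for lb, wi, es in zip(AGE_BAND_LOWER, w, ever_sex):
            rows18.append((c, int(lb), float(wi), 2018, float(es)))
    pop10 = PopulationWeights(pd.DataFrame(
        rows10, columns=["unit", "age_lower", "weight", "reference_year"]), 2010)
    pop18 = PopulationWeights(pd.DataFrame(
        rows18, columns=["unit", "age_lower", "weight", "reference_year",
                         "ever_sex_proportion"]), 2018)
    return pop10, pop18


def _project(target: np.ndarray, basis: np.ndarray) -> tuple[float, np.ndarray]:
    """Least-squares projection of a target curve on [1 | basis columns]."""
    Xd = np.column_stack([np.ones(len(target)), basis])
    coef, *_ = np.linalg.lstsq(Xd, target, rcond=None)
    return float(coef[0]), coef[1:]


def _draw_effects(t: SyntheticTruth, h: GeoHierarchy, rng) -> dict:
    """True hierarchical parameters for both outcomes, correlated across
    outcomes at the country/study-relevant levels."""
    age_basis = build_age_spline_basis(t.age_knots)
    years = np.arange(t.years[0], t.years[1] + 1)
    time_basis = build_time_spline_basis(years, knot=t.time_knot)
    K_a, K_t = age_basis.K, time_basis.K
    icpt_a, eta_g = _project(_AGE_SHAPE, age_basis.matrix)
    icpt_t, phi_g = _project(_TIME_SLOPE * (years - t.time_knot), time_basis.matrix)

    n_z, n_r, n_c = t.n_super, t.n_regions, t.n_countries
    rho = t.outcome_correlation

    def corr_pair(shape, sd):
        a = rng.normal(0, sd, size=shape)
        b = rho * a + np.sqrt(1 - rho ** 2) * rng.normal(0, sd, size=shape)
        return {"lifetime": a, "past_year": b}

    u_z = corr_pair(n_z, t.sd_z)
    u_r = corr_pair(n_r, t.sd_r)
    u_c = corr_pair(n_c, t.sd_c)
    eta_z = corr_pair((n_z, K_a), t.ups_z)
    eta_r = corr_pair((n_r, K_a), t.ups_r)
    eta_c = corr_pair((n_c, K_a), t.ups_c)
    phi_z = corr_pair((n_z, K_t), t.om_z)
    phi_r = corr_pair((n_r, K_t), t.om_r)
    phi_c = corr_pair((n_c, K_t), t.om_c)

    region_ix = {r: i for i, r in enumerate(h.regions)}
    super_ix = {z: i for i, z in enumerate(h.super_regions)}
    c_region = np.array([region_ix[h.region_of(c)] for c in h.countries])
    c_super = np.array([super_ix[h.super_region_of(c)] for c in h.countries])

    params = {}
    for o in ("lifetime", "past_year"):
        u_g = float(logit(t.base_prevalence[o]) + icpt_a + icpt_t)
        lam = (eta_g[None, :] + eta_z[o][c_super] + eta_r[o][c_region] + eta_c[o])
        phi = (phi_g[None, :] + phi_z[o][c_super] + phi_r[o][c_region] + phi_c[o])
        params[o] = dict(
            u_g=u_g, u_z=u_z[o], u_r=u_r[o], u_c=u_c[o],
            lam=lam, phi=phi, c_region=c_region, c_super=c_super)
    return dict(age_basis=age_basis, time_basis=time_basis, params=params,
                countries=h.countries)


def true_country_logits(truth: dict, outcome: str, country_index: int,
                        year: float) -> np.ndarray:
    """True logit prevalence on the age grid (reference instrument, no study)."""
    p = truth["params"][outcome]
    A = truth["age_basis"].matrix
    Tt = truth["time_basis"].evaluate(year)[0]
    c, r, z = country_index, p["c_region"][country_index], p["c_super"][country_index]
    return (p["u_g"] + p["u_z"][z] + p["u_r"][r] + p["u_c"][c]
            + A @ p["lam"][c] + float(Tt @ p["phi"][c]))


def generate_database(truth: SyntheticTruth, seed: int = 0,
                      outdir=None) -> SyntheticBundle:
    """Simulate the full observation database from the stated model.

    Identical ``(truth, seed)`` pairs produce identical outputs.
    """
    rng = np.random.default_rng(seed)
    h = _make_hierarchy(truth)
    pop10, pop18 = _make_populations(truth, h, rng)
    eff = _draw_effects(truth, h, rng)
    region_shares = {r: pop10.shares_for(r) for r in h.regions}

    log_or = {k: np.log(v) for k, v in truth.adjustment_or.items()}
    instrument_fields = dict(
        severe_only=("severity", "severe_only"),
        physical_only=("violence_type", "physical_only"),
        sexual_only=("violence_type", "sexual_only"),
        all_women=("population", "all_women"),
        currently_partnered=("population", "currently_partnered"),
        partner_current=("partner_ref", "current_or_most_recent"))
    reference_instr = dict(severity="all", violence_type="physical_and_or_sexual",
                           population="ever_partnered", partner_ref="any_partner")

    rows = []
    obs_counter = [0]

    def emit(study, country, year, outcome, instr, geo, l, hgt, N_row, base_logit,
             study_beta, report_ci, report_denom):
        """One observation row: standardize truth over the band, draw counts."""
        region = h.region_of(country)
        cells = np.where((AGE_BAND_LOWER >= l) & (AGE_BAND_LOWER <= min(hgt, 65)))[0]
        c_ix = h.countries.index(country)
        logits = true_country_logits_band(outcome, c_ix, year, cells)
        X = sum(study_beta.get(cov, 0.0)
                for cov, (fieldname, level) in instrument_fields.items()
                if instr[fieldname] == level)
        if geo in ("urban", "rural"):
            X += study_beta.get(f"geo_{geo}", log_or[f"geo_{geo}"])
        if len(cells) == 1:
            p_true = float(expit(base_logit + logits[0] + X))
        else:
            w = region_shares[region][cells]
            p_true = float(np.sum(expit(base_logit + logits + X) * w) / w.sum())
        if not (0.001 < p_true < 0.999):
            raise ValueError(
                f"true prevalence {p_true:.4f} outside (0.001, 0.999); "
                "adjust the generator settings")
        n_eff = max(int(round(N_row / truth.design_effect)), 5)
        y = rng.binomial(n_eff, p_true)
        prev = y / n_eff
        ci_lo = ci_hi = np.nan
        if report_ci and 0 < prev < 1:
            ci_hi = wilson_upper(prev, n_eff)
            ci_lo = max(2 * prev - ci_hi, 0.0)
        obs_counter[0] += 1
        rows.append(dict(
            obs_id=f"O{obs_counter[0]:05d}", study_id=study, country_code=country,
            year_start=year - 1, year_end=year, outcome=outcome,
            violence_type=instr["violence_type"], severity=instr["severity"],
            population=instr["population"], partner_ref=instr["partner_ref"],
            geo=geo, age_lower=int(l), age_upper=int(hgt), prevalence=prev,
            denominator=(N_row if report_denom else np.nan),
            se=np.nan, ci_lower=ci_lo, ci_upper=ci_hi, publication_year=year + 2))

    def true_country_logits_band(outcome, c_ix, year, cells):
        pr = eff["params"][outcome]
        A = eff["age_basis"].matrix[cells]
        Tt = eff["time_basis"].evaluate(year)[0]
        c, r, z = c_ix, pr["c_region"][c_ix], pr["c_super"][c_ix]
        return (pr["u_g"] + pr["u_z"][z] + pr["u_r"][r] + pr["u_c"][c]
                + A @ pr["lam"][c] + float(Tt @ pr["phi"][c]))

    study_counter = 0
    for c_ix, country in enumerate(h.countries):
        n_studies = rng.integers(truth.studies_per_country[0],
                                 truth.studies_per_country[1] + 1)
        for _ in range(n_studies):
            study_counter += 1
            study = f"S{study_counter:04d}"
            year = int(rng.integers(truth.years[0] + 1, truth.years[1] + 1))
            subnat = rng.uniform() < truth.p_subnational
            geo = (rng.choice(["urban", "rural", "mixed_subnational"])
                   if subnat else "national")
            lo_n, hi_n = (truth.subnational_n if subnat else truth.national_n)
            N_total = int(rng.integers(lo_n, hi_n))
            # study instrument: independent chances of each non-reference level
            instr = dict(reference_instr)
            active = []
            for cov, (fieldname, level) in instrument_fields.items():
                if rng.uniform() < truth.p_nonref[cov]:
                    if instr[fieldname] == reference_instr[fieldname]:
                        instr[fieldname] = level
                        active.append(cov)
            # per-study wiggle around the injected adjustment log-ORs
            study_beta = {cov: rng.normal(lo, truth.adjustment_sd)
                          for cov, lo in log_or.items()}
            banded = rng.uniform() < truth.p_bands
            report_denom = rng.uniform() >= truth.p_missing_denominator
            report_ci = rng.uniform() < truth.p_report_ci
            for outcome in ("lifetime", "past_year"):
                sd_s = truth.sd_n + (truth.tau if subnat else 0.0)
                base = rng.normal(0.0, sd_s)  # study effect
                region = h.region_of(country)
                band_cells = np.where((AGE_BAND_LOWER >= 15) & (AGE_BAND_LOWER <= 45))[0]
                shares = region_shares[region][band_cells]
                shares = shares / shares.sum()
                if banded:
                    for lb, sh in zip(AGE_BAND_LOWER[band_cells], shares):
                        emit(study, country, year, outcome, instr, geo,
                             lb, lb + 4, max(int(round(N_total * sh)), 30),
                             base, study_beta, report_ci, report_denom)
                    if rng.uniform() < truth.p_broad_total:
                        emit(study, country, year, outcome, instr, geo,
                             15, 49, N_total, base, study_beta,
                             report_ci, report_denom)
                else:
                    emit(study, country, year, outcome, instr, geo,
                         15, 49, N_total, base, study_beta, report_ci, report_denom)
                # reference-instrument duplicate rows enable exact matching
                if active and rng.uniform() < truth.p_dual:
                    emit(study, country, year, outcome, reference_instr, geo,
                         15, 49, N_total, base, study_beta, report_ci, report_denom)
                # a share of national studies also report urban/rural strata
                if geo == "national" and rng.uniform() < truth.p_geo_trio:
                    for stratum in ("urban", "rural"):
                        emit(study, country, year, outcome, instr, stratum,
                             15, 49, max(N_total // 2, 100), base, study_beta,
                             report_ci, report_denom)

    obs = pd.DataFrame(rows)
    truth_out = dict(settings=asdict(truth), seed=seed,
                     age_basis=eff["age_basis"], time_basis=eff["time_basis"],
                     params=eff["params"], countries=h.countries,
                     n_studies=study_counter)
    bundle = SyntheticBundle(obs, h, pop10, pop18, truth_out)
    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _write_bundle(b: SyntheticBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    b.observations.to_csv(outdir / "observations.csv", index=False)
    b.hierarchy.table.to_csv(outdir / "hierarchy.csv", index=False)
    b.pop2010.table.to_csv(outdir / "population_2010.csv", index=False)
    b.pop2018.table.to_csv(outdir / "population_2018.csv", index=False)
    ser = dict(settings=b.truth["settings"], seed=b.truth["seed"],
               n_studies=b.truth["n_studies"],
               countries=list(b.truth["countries"]),
               params={o: {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                           for k, v in p.items()}
                       for o, p in b.truth["params"].items()})
    (outdir / "truth.json").write_text(json.dumps(ser, indent=1))


def make_fixture(profile: str = "tiny", seed: int = 0, outdir=None,
                 **overrides) -> SyntheticBundle:
    """Canned generator settings: ``tiny`` (unit tests), ``desk``
    (integration-scale, 7 super-regions / 21 regions / 40 countries) and
    ``paperlike`` (real-database-scale marginals: ~300 studies, ~1,550
    age-specific rows per outcome, roughly half needing adjustment)."""
    if profile == "tiny":
        t = SyntheticTruth(n_super=2, n_regions=2, n_countries=6,
                           studies_per_country=(1, 3), **overrides)
    elif profile == "desk":
        t = SyntheticTruth(**overrides)
    elif profile == "paperlike":
        t = SyntheticTruth(n_countries=150, studies_per_country=(1, 3),
                           p_bands=0.75, **overrides)
    else:
        raise ValueError(f"unknown fixture profile {profile!r}")
    return generate_database(t, seed=seed, outdir=outdir)
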