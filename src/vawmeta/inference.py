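"""MCMC fitting of the multilevel binomial meta-regression.

The posterior is explored with an adaptive Metropolis-within-Gibbs
sampler written for this model's structure:

* every hierarchical-effect block (study, country, region, super-region,
  global, and the spline-coefficient analogues) is updated with
  random-walk proposals whose acceptance can be decided *per unit*,
  because units partition the observations;
* standard-deviation hyper-parameters are updated on the log scale
  against their half-Cauchy priors;
* dedicated "translation" moves shift mass between adjacent levels of the
  hierarchy (e.g. global intercept vs super-region effects) while leaving
  the likelihood invariant — these are essential for mixing, since the
  level sums are well identified but the individual levels are not.

Proposal scales adapt during the adaptation phase only, targeting
standard acceptance rates, so the retained chains are draws from a fixed
transition kernel.

Uncertainty in the crosswalk adjustment factors is propagated by
refitting the model once per sampled adjustment vector and pooling all
posterior draws with equal weight (a posterior mixture).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import arviz as az
import numpy as np

from .model_core import (
    GLOBAL_PRIOR_SD,
    HALF_CAUCHY_SCALE,
    ModelSpec,
    OutcomeData,
    UnitIndex,
    init_params,
    pointwise_log_likelihood,
    standardized_prevalence,
)

logger = logging.getLogger(__name__)


@dataclass
class McmcConfig:
    """Sampler settings.  The ``paper`` profile mirrors the full analysis
    (4 chains x 50,000 iterations after a 10,000-iteration adaptation
    phase, 5,000 warm-up, thinning 20); the ``desk`` profile is sized for
    synthetic fixtures on one CPU."""

    chains: int = 4
    iterations: int = 50_000
    adaptation: int = 10_000
    warmup: int = 5_000
    thin: int = 20
    seed: int = 0
    n_adjustment_draws: int = 10
    scale_factor: float = 1.0

    def __post_init__(self):
        if min(self.chains, self.iterations, self.thin) < 1 or self.warmup < 0:
            raise ValueError("all MCMC size settings must be positive")
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be smaller than iterations")

    @classmethod
    def paper_profile(cls, seed: int = 0) -> "McmcConfig":
        return cls(seed=seed)

    @classmethod
    def desk_profile(cls, seed: int = 0, **kw) -> "McmcConfig":
        return cls(chains=2, iterations=4000, adaptation=1000, warmup=1000,
                   thin=2, seed=seed, **kw)

    def scaled(self) -> "McmcConfig":
        if self.scale_factor == 1.0:
            return self
        f = self.scale_factor
        return replace(self, iterations=max(int(self.iterations * f), 10),
                       adaptation=max(int(self.adaptation * f), 10),
                       warmup=max(int(self.warmup * f), 1),
                       scale_factor=1.0)

    @property
    def draws_per_chain(self) -> int:
        return (self.iterations - self.warmup) // self.thin


@dataclass
class PosteriorDraws:
    """Thinned posterior draws for every outcome in the model.

    ``params[outcome][name]`` has shape (chains, draws, *param_shape);
    ``p_obs`` and ``log_lik`` hold the fitted standardized prevalence and
    pointwise binomial log-likelihood per observation.
    """

    spec: ModelSpec
    cfg: McmcConfig
    params: dict
    p_obs: dict
    log_lik: dict

    @property
    def outcomes(self) -> list:
        return sorted(self.params)

    def n_draws(self, outcome: str) -> int:
        return self.params[outcome]["u_g"].shape[0] * self.params[outcome]["u_g"].shape[1]

    def flat(self, outcome: str, name: str) -> np.ndarray:
        """(chains*draws, ...) view of one parameter."""
        a = self.params[outcome][name]
        return a.reshape(a.shape[0] * a.shape[1], *a.shape[2:])

    def stack_chains(self) -> "PosteriorDraws":
        """Collapse the chain axis (used when mixing adjustment-draw fits)."""
        def collapse(d):
            return {k: (v.reshape(1, -1, *v.shape[2:]) if isinstance(v, np.ndarray) else
                        {k2: v2.reshape(1, -1, *v2.shape[2:]) for k2, v2 in v.items()})
                    for k, v in d.items()}
        return PosteriorDraws(self.spec, self.cfg,
                              {o: collapse(p) for o, p in self.params.items()},
                              {o: v.reshape(1, -1, v.shape[-1]) for o, v in self.p_obs.items()},
                              {o: v.reshape(1, -1, v.shape[-1]) for o, v in self.log_lik.items()})


# ---------------------------------------------------------------------------
# the Gibbs-style sampler for one outcome

def _log_half_cauchy(x: float, scale: float = HALF_CAUCHY_SCALE) -> float:
    if x <= 0:
        return -np.inf
    return -np.log1p((x / scale) ** 2)


class _OutcomeSampler:
    """Adaptive MwG chain for a single outcome's parameter set."""

    TARGET_SCALAR = 0.44
    TARGET_VECTOR = 0.30
    ADAPT_EVERY = 25

    def __init__(self, units: UnitIndex, data: OutcomeData, K_a: int, K_t: int,
                 rng: np.random.Generator):
        self.units, self.d, self.rng = units, data, rng
        self.K_a, self.K_t = K_a, K_t
        self.params = init_params(units, data, K_a, K_t)
        d = data
        n_c = len(units.countries)
        # country of each study (a study sits in exactly one country)
        self.study_country = np.zeros(d.n_studies, dtype=int)
        self.study_country[d.study_idx] = d.country_idx
        # per-study/country/... observation maps for per-unit acceptance
        u = units
        self.blocks = [
            # key, obs->unit map, n_units, prior-sd getter, shape of unit param
            ("u_s", d.study_idx, d.n_studies, self._sd_us, 1),
            ("u_c", d.country_idx, n_c, lambda: self.params["sig_c"], 1),
            ("u_r", d.region_idx, len(u.regions), lambda: self.params["sig_r"], 1),
            ("u_z", d.super_idx, len(u.super_regions), lambda: self.params["sig_z"], 1),
            ("eta_c", d.country_idx, n_c, lambda: self.params["ups_c"], K_a),
            ("eta_r", d.region_idx, len(u.regions), lambda: self.params["ups_r"], K_a),
            ("eta_z", d.super_idx, len(u.super_regions), lambda: self.params["ups_z"], K_a),
            ("phi_c", d.country_idx, n_c, lambda: self.params["om_c"], K_t),
            ("phi_r", d.region_idx, len(u.regions), lambda: self.params["om_r"], K_t),
            ("phi_z", d.super_idx, len(u.super_regions), lambda: self.params["om_z"], K_t),
        ]
        self.scales = {key: np.full(n, 0.2) for key, _, n, _, _ in self.blocks}
        self.scales.update({"u_g": 0.1, "eta_g": 0.05, "phi_g": 0.05})
        self.sd_scales = {k: 0.5 for k in
                          ("sig_z", "sig_r", "sig_c", "sig_n", "tau",
                           "ups_z", "ups_r", "ups_c", "om_z", "om_r", "om_c")}
        self.acc = {k: np.zeros_like(v, dtype=float) for k, v in self.scales.items()
                    if isinstance(v, np.ndarray)}
        self.acc.update({k: 0.0 for k in ("u_g", "eta_g", "phi_g")})
        self.sd_acc = {k: 0.0 for k in self.sd_scales}
        # joint (sigma, effects) scaling moves to traverse the funnel
        self.scale_move_groups = [
            ("sig_z", ("u_z",)), ("sig_r", ("u_r",)), ("sig_c", ("u_c",)),
            ("sig_n", ("u_s",)), ("tau", ("u_s",)),
            ("ups_z", ("eta_z",)), ("ups_r", ("eta_r",)), ("ups_c", ("eta_c",)),
            ("om_z", ("phi_z",)), ("om_r", ("phi_r",)), ("om_c", ("phi_c",)),
        ]
        self.scale_move_scales = {k: 0.4 for k, _ in self.scale_move_groups}
        self.scale_move_acc = {k: 0.0 for k, _ in self.scale_move_groups}
        self.n_since_adapt = 0
        self._ll = pointwise_log_likelihood(self.params, units, data)

    # -- prior helpers -----------------------------------------------------
    def _sd_us(self) -> np.ndarray:
        p = self.params
        return np.where(self.d.study_subnational, p["sig_n"] + p["tau"], p["sig_n"])

    # -- likelihood blocks -------------------------------------------------
    def _update_block(self, key, unit_of_obs, n_units, sd_fn, width):
        p, rng = self.params, self.rng
        cur = p[key]
        sc = self.scales[key]
        if width == 1:
            prop = cur + rng.normal(size=n_units) * sc
        else:
            prop = cur + rng.normal(size=(n_units, width)) * sc[:, None]
        p[key] = prop
        ll_new = pointwise_log_likelihood(p, self.units, self.d)
        p[key] = cur
        ll0 = np.bincount(unit_of_obs, self._ll, minlength=n_units)
        ll1 = np.bincount(unit_of_obs, ll_new, minlength=n_units)
        sd = sd_fn()
        if width == 1:
            dprior = -0.5 * (prop ** 2 - cur ** 2) / np.asarray(sd) ** 2
        else:
            dprior = (-0.5 * (prop ** 2 - cur ** 2) / np.asarray(sd)[None, :] ** 2).sum(1)
        accept = np.log(rng.uniform(size=n_units)) < (ll1 - ll0) + dprior
        if width == 1:
            p[key] = np.where(accept, prop, cur)
        else:
            p[key] = np.where(accept[:, None], prop, cur)
        acc_obs = accept[unit_of_obs]
        self._ll = np.where(acc_obs, ll_new, self._ll)
        self.acc[key] += accept.astype(float)

    def _update_global(self, key, prior_sd):
        p, rng = self.params, self.rng
        cur = p[key]
        prop = cur + rng.normal(size=np.shape(cur)) * self.scales[key]
        p[key] = prop
        ll_new = pointwise_log_likelihood(p, self.units, self.d)
        dprior = -0.5 * float(np.sum(np.square(prop) - np.square(cur))) / prior_sd ** 2
        if np.log(rng.uniform()) < (ll_new.sum() - self._ll.sum()) + dprior:
            self._ll = ll_new
            self.acc[key] += 1.0
        else:
            p[key] = cur

    # -- hyper-parameter (SD) updates --------------------------------------
    def _sd_logpost_us(self, sig_n, tau):
        if sig_n <= 0 or tau <= 0:
            return -np.inf
        sd = np.where(self.d.study_subnational, sig_n + tau, sig_n)
        us = self.params["u_s"]
        return (-0.5 * np.sum((us / sd) ** 2) - np.sum(np.log(sd))
                + _log_half_cauchy(sig_n) + _log_half_cauchy(tau))

    def _update_sd_scalar(self, key, values_key):
        """MH on log sigma for one SD governing a vector of normal effects."""
        p, rng = self.params, self.rng
        if key in ("sig_n", "tau"):
            cur = p[key]
            prop = cur * np.exp(rng.normal() * self.sd_scales[key])
            args = dict(sig_n=p["sig_n"], tau=p["tau"])
            new_args = dict(args, **{key: prop})
            num = self._sd_logpost_us(**new_args) + np.log(prop)
            den = self._sd_logpost_us(**args) + np.log(cur)
            if np.log(rng.uniform()) < num - den:
                p[key] = prop
                self.sd_acc[key] += 1.0
            return
        vals = p[values_key]
        cur = p[key]
        prop = cur * np.exp(rng.normal() * self.sd_scales[key])
        n = vals.size
        num = (-0.5 * np.sum(vals ** 2) / prop ** 2 - n * np.log(prop)
               + _log_half_cauchy(prop) + np.log(prop))
        den = (-0.5 * np.sum(vals ** 2) / cur ** 2 - n * np.log(cur)
               + _log_half_cauchy(cur) + np.log(cur))
        if np.log(rng.uniform()) < num - den:
            p[key] = prop
            self.sd_acc[key] += 1.0

    def _update_sd_vector(self, key, values_key):
        """Per-component MH for the spline-coefficient SDs (one per k)."""
        p, rng = self.params, self.rng
        vals = p[values_key]           # (n_units, K)
        cur = p[key]                   # (K,)
        prop = cur * np.exp(rng.normal(size=cur.shape) * self.sd_scales[key])
        n = vals.shape[0]
        ss = (vals ** 2).sum(0)
        num = (-0.5 * ss / prop ** 2 - n * np.log(prop)
               + np.array([_log_half_cauchy(x) for x in prop]) + np.log(prop))
        den = (-0.5 * ss / cur ** 2 - n * np.log(cur)
               + np.array([_log_half_cauchy(x) for x in cur]) + np.log(cur))
        accept = np.log(rng.uniform(size=cur.shape)) < num - den
        p[key] = np.where(accept, prop, cur)
        self.sd_acc[key] += accept.mean()

    # -- joint scaling moves (funnel traversal) -----------------------------
    def _scale_move(self, sd_key, value_keys):
        """Rescale one SD (or SD vector) together with the effects it
        governs, so small-sigma states do not trap the chain.

        The effects are multiplied by the ratio of their new to old prior
        SDs; the prior-normalization and Jacobian terms then cancel, and
        the acceptance ratio is likelihood x half-Cauchy ratio x c^K.
        """
        p, rng = self.params, self.rng
        t = rng.normal() * self.scale_move_scales[sd_key]
        c = float(np.exp(t))
        old = {v: p[v].copy() for v in value_keys}
        old_sigma = p[sd_key]
        old_eff_sd = {v: np.asarray(self._effect_sd(v), dtype=float)
                      for v in value_keys}
        p[sd_key] = old_sigma * c
        sig_arr = np.atleast_1d(old_sigma)
        hc = float(sum(_log_half_cauchy(s * c) - _log_half_cauchy(s)
                       for s in sig_arr))
        n_sd = len(sig_arr)
        for v in value_keys:
            ratio = np.asarray(self._effect_sd(v), dtype=float) / old_eff_sd[v]
            if old[v].ndim == 2 and ratio.ndim == 1:
                ratio = ratio[None, :]    # per-k SDs scale basis columns
            p[v] = old[v] * ratio
        ll_new = pointwise_log_likelihood(p, self.units, self.d)
        logr = (ll_new.sum() - self._ll.sum()) + hc + n_sd * t
        if np.log(rng.uniform()) < logr:
            self._ll = ll_new
            self.scale_move_acc[sd_key] += 1.0
        else:
            p[sd_key] = old_sigma
            for v in value_keys:
                p[v] = old[v]

    def _effect_sd(self, value_key):
        """Current prior SD of one effect vector (per component as needed)."""
        p = self.params
        if value_key == "u_s":
            return self._sd_us()
        return p[{"u_z": "sig_z", "u_r": "sig_r", "u_c": "sig_c",
                  "eta_z": "ups_z", "eta_r": "ups_r", "eta_c": "ups_c",
                  "phi_z": "om_z", "phi_r": "om_r", "phi_c": "om_c"}[value_key]]

    # -- translation moves (likelihood-invariant recentering) --------------
    def _translate_scalar_vector(self, hi_key, lo_key, hi_sd, lo_sd_fn, scale=0.1):
        """Shift hi by delta, all lo components by -delta (per column for 2-D)."""
        p, rng = self.params, self.rng
        hi, lo = p[hi_key], p[lo_key]
        delta = rng.normal(size=np.shape(hi)) * scale
        hi_new, lo_new = hi + delta, lo - delta
        lo_sd = lo_sd_fn()
        dp = (-0.5 * np.sum(np.square(hi_new) - np.square(hi)) / hi_sd ** 2
              - 0.5 * np.sum((np.square(lo_new) - np.square(lo)) / np.square(lo_sd)))
        if np.log(rng.uniform()) < dp:
            p[hi_key], p[lo_key] = hi_new, lo_new

    def _translate_grouped(self, hi_key, lo_key, group_of_lo, n_hi, hi_sd_fn,
                           lo_sd_fn, scale=0.1):
        """Per-hi-unit shift between adjacent levels; accept per hi unit."""
        p, rng = self.params, self.rng
        hi, lo = p[hi_key], p[lo_key]
        width = 1 if hi.ndim == 1 else hi.shape[1]
        delta = rng.normal(size=hi.shape) * scale
        hi_sd = np.asarray(hi_sd_fn())
        lo_sd = np.asarray(lo_sd_fn())
        d_hi = -0.5 * (np.square(hi + delta) - np.square(hi)) / np.square(hi_sd)
        dlo_full = -0.5 * (np.square(lo - delta[group_of_lo]) - np.square(lo)) \
            / np.square(lo_sd)
        if width == 1:
            d_lo = np.bincount(group_of_lo, dlo_full, minlength=n_hi)
            logr = d_hi + d_lo
        else:
            d_lo = np.zeros((n_hi, width))
            for k in range(width):
                d_lo[:, k] = np.bincount(group_of_lo, dlo_full[:, k], minlength=n_hi)
            logr = (d_hi + d_lo).sum(1)
        accept = np.log(rng.uniform(size=n_hi)) < logr
        sel = accept if width == 1 else accept[:, None]
        p[hi_key] = np.where(sel, hi + delta, hi)
        lo_acc = accept[group_of_lo]
        sel_lo = lo_acc if width == 1 else lo_acc[:, None]
        p[lo_key] = np.where(sel_lo, lo - delta[group_of_lo], lo)

    def _translations(self):
        u, p = self.units, self.params
        n_z, n_r, n_c = len(u.super_regions), len(u.regions), len(u.countries)

        def s(*sds):
            # step size tracks the narrower of the two levels being traded
            return 0.6 * float(min(np.mean(x) for x in sds)) + 1e-4

        self._translate_scalar_vector("u_g", "u_z", GLOBAL_PRIOR_SD,
                                      lambda: p["sig_z"], scale=s(p["sig_z"]))
        self._translate_grouped("u_z", "u_r", u.region_super, n_z,
                                lambda: p["sig_z"], lambda: p["sig_r"],
                                scale=s(p["sig_z"], p["sig_r"]))
        self._translate_grouped("u_r", "u_c", u.country_region, n_r,
                                lambda: p["sig_r"], lambda: p["sig_c"],
                                scale=s(p["sig_r"], p["sig_c"]))
        self._translate_grouped("u_c", "u_s", self.study_country, n_c,
                                lambda: p["sig_c"], self._sd_us,
                                scale=s(p["sig_c"], self._sd_us()))
        for g, z, r, c, sdz, sdr, sdc in (
                ("eta_g", "eta_z", "eta_r", "eta_c", "ups_z", "ups_r", "ups_c"),
                ("phi_g", "phi_z", "phi_r", "phi_c", "om_z", "om_r", "om_c")):
            self._translate_scalar_vector(g, z, GLOBAL_PRIOR_SD,
                                          lambda sdz=sdz: p[sdz], scale=s(p[sdz]))
            self._translate_grouped(z, r, u.region_super, n_z,
                                    lambda sdz=sdz: p[sdz], lambda sdr=sdr: p[sdr],
                                    scale=s(p[sdz], p[sdr]))
            self._translate_grouped(r, c, u.country_region, n_r,
                                    lambda sdr=sdr: p[sdr], lambda sdc=sdc: p[sdc],
                                    scale=s(p[sdr], p[sdc]))

    # -- sweep and adaptation ----------------------------------------------
    def sweep(self):
        for key, unit_map, n_units, sd_fn, width in self.blocks:
            self._update_block(key, unit_map, n_units, sd_fn, width)
        self._update_global("u_g", GLOBAL_PRIOR_SD)
        self._update_global("eta_g", GLOBAL_PRIOR_SD)
        self._update_global("phi_g", GLOBAL_PRIOR_SD)
        # interweave centered (sigma | effects) and non-centered (joint
        # rescaling) hyper-parameter updates; repeat to speed funnel mixing
        for _ in range(2):
            for key, vals in (("sig_z", "u_z"), ("sig_r", "u_r"), ("sig_c", "u_c"),
                              ("sig_n", None), ("tau", None)):
                self._update_sd_scalar(key, vals)
            for key, vals in (("ups_z", "eta_z"), ("ups_r", "eta_r"),
                              ("ups_c", "eta_c"), ("om_z", "phi_z"),
                              ("om_r", "phi_r"), ("om_c", "phi_c")):
                self._update_sd_vector(key, vals)
            for sd_key, value_keys in self.scale_move_groups:
                self._scale_move(sd_key, value_keys)
            self._translations()
        self.n_since_adapt += 1

    def adapt(self):
        if self.n_since_adapt < self.ADAPT_EVERY:
            return
        n = self.n_since_adapt
        for key, sc in self.scales.items():
            rate = self.acc[key] / n
            target = self.TARGET_SCALAR if np.isscalar(sc) else self.TARGET_VECTOR
            adj = np.exp(np.clip(rate - target, -0.5, 0.5))
            self.scales[key] = np.clip(sc * adj, 1e-4, 10.0)
            self.acc[key] = np.zeros_like(self.acc[key]) if not np.isscalar(sc) else 0.0
        for key in self.sd_scales:
            rate = self.sd_acc[key] / n
            self.sd_scales[key] = float(np.clip(
                self.sd_scales[key] * np.exp(rate - self.TARGET_SCALAR), 1e-3, 5.0))
            self.sd_acc[key] = 0.0
        for key in self.scale_move_scales:
            rate = self.scale_move_acc[key] / n
            self.scale_move_scales[key] = float(np.clip(
                self.scale_move_scales[key] * np.exp(rate - self.TARGET_SCALAR),
                1e-3, 5.0))
            self.scale_move_acc[key] = 0.0
        self.n_since_adapt = 0

    def snapshot(self) -> dict:
        return {k: (v.copy() if isinstance(v, np.ndarray) else v)
                for k, v in self.params.items()}


def _run_chain(spec: ModelSpec, outcome: str, cfg: McmcConfig, seed: int):
    rng = np.random.default_rng(seed)
    d = spec.outcome_data[outcome]
    s = _OutcomeSampler(spec.units, d, spec.age_basis.K, spec.time_basis.K, rng)
    for _ in range(cfg.adaptation):
        s.sweep()
        s.adapt()
    draws, p_obs, ll = [], [], []
    for it in range(cfg.iterations):
        s.sweep()
        if it >= cfg.warmup and (it - cfg.warmup) % cfg.thin == cfg.thin - 1:
            draws.append(s.snapshot())
            p_obs.append(standardized_prevalence(s.params, spec.units, d))
            ll.append(s._ll.copy())
    stacked = {k: np.stack([dr[k] for dr in draws]) for k in draws[0]}
    return stacked, np.stack(p_obs), np.stack(ll)


def fit(spec: ModelSpec, cfg: McmcConfig, outcomes=None) -> PosteriorDraws:
    """Run the sampler for every outcome (or a subset) and collect draws."""
    cfg = cfg.scaled()
    outcomes = sorted(spec.outcome_data) if outcomes is None else list(outcomes)
    params, p_obs, log_lik = {}, {}, {}
    for oi, outcome in enumerate(outcomes):
        per_chain = [
            _run_chain(spec, outcome, cfg, seed=cfg.seed + 1000 * oi + ch)
            for ch in range(cfg.chains)]
        params[outcome] = {k: np.stack([c[0][k] for c in per_chain])
                           for k in per_chain[0][0]}
        p_obs[outcome] = np.stack([c[1] for c in per_chain])
        log_lik[outcome] = np.stack([c[2] for c in per_chain])
    return PosteriorDraws(spec, cfg, params, p_obs, log_lik)


# ---------------------------------------------------------------------------
# mixing over adjustment draws

class ConvergenceError(RuntimeError):
    pass


def fit_mixed_over_adjustments(spec_factory, draw_set, cfg: McmcConfig,
                               rhat_threshold: float = 1.5,
                               outcomes=None) -> PosteriorDraws:
    """Fit once per sampled adjustment vector and mix the posteriors.

    ``spec_factory(beta_vector, draw_id)`` must return the ModelSpec with
    the observation offsets X rebuilt from that adjustment vector.  Fits
    whose worst split-Rhat exceeds ``rhat_threshold`` are dropped with a
    warning (the default 1.5 is a coarse screen suited to desk-scale
    chains; tighten it for paper-profile runs); if fewer than half
    survive, the mixture is not trustworthy and an error is raised.
    Surviving fits contribute their chains with equal weight.
    """
    fits = []
    for d in range(draw_set.D):
        sub = fit(spec_factory(draw_set.vector(d), d),
                  replace(cfg, seed=cfg.seed + 7919 * d), outcomes=outcomes)
        rep = diagnostics(sub)
        if rep["max_rhat"] > rhat_threshold:
            logger.warning("adjustment draw %d: max Rhat %.3f > %.2f; excluded",
                           d, rep["max_rhat"], rhat_threshold)
            continue
        fits.append(sub)
    if len(fits) < max(draw_set.D // 2, 1):
        raise ConvergenceError(
            f"only {len(fits)}/{draw_set.D} adjustment-draw fits converged")
    first = fits[0]
    params = {o: {k: np.concatenate([f.params[o][k] for f in fits])
                  for k in first.params[o]} for o in first.outcomes}
    p_obs = {o: np.concatenate([f.p_obs[o] for f in fits]) for o in first.outcomes}
    log_lik = {o: np.concatenate([f.log_lik[o] for f in fits]) for o in first.outcomes}
    return PosteriorDraws(first.spec, cfg, params, p_obs, log_lik)


# ---------------------------------------------------------------------------
# diagnostics and model selection

def _to_inference_data(post: PosteriorDraws, outcome: str) -> az.InferenceData:
    """Monitored quantities: the *identified* combinations of the levels.

    Individual hierarchy levels (u_g vs u_z vs ...) trade off against each
    other under diffuse priors; what the model reports are their sums (the
    country-level intercepts), the fitted observation prevalences, and the
    variance hyper-parameters, so convergence is assessed on those.
    """
    p = post.params[outcome]
    u = post.spec.units
    country_icpt = (p["u_g"][..., None] + p["u_z"][..., u.country_super]
                    + p["u_r"][..., u.country_region] + p["u_c"])
    p_obs = post.p_obs[outcome]
    if p_obs.shape[-1] > 100:   # cap the monitored set for speed
        p_obs = p_obs[..., :: int(np.ceil(p_obs.shape[-1] / 100))]
    data = dict(country_intercept=country_icpt, p_obs=p_obs,
                sig_z=p["sig_z"], sig_r=p["sig_r"], sig_c=p["sig_c"],
                sig_n=p["sig_n"], tau=p["tau"])
    return az.from_dict(posterior=data)

def diagnostics(post: PosteriorDraws, ess_threshold: float = 1000.0,
                rhat_threshold: float = 1.05) -> dict:
    """Split-Rhat (PSRF) and effective sample size for reported quantities.

    The report passes when the worst PSRF is close to 1 (default threshold
    1.05) and the smallest ESS reaches the threshold (default 1,000).
    """
    worst_rhat, min_ess = 1.0, np.inf
    per_outcome = {}
    for outcome in post.outcomes:
        idata = _to_inference_data(post, outcome)
        rhat = az.rhat(idata)
        ess = az.ess(idata)
        # a single chain yields NaN split-Rhat; treat it as uninformative (1)
        o_rhat = float(max(np.nanmax(np.nan_to_num(np.atleast_1d(rhat[v].values),
                                                   nan=1.0))
                           for v in rhat.data_vars))
        o_ess = float(min(np.nanmin(np.atleast_1d(ess[v].values)) for v in ess.data_vars))
        per_outcome[outcome] = dict(max_rhat=o_rhat, min_ess=o_ess)
        worst_rhat = max(worst_rhat, o_rhat)
        min_ess = min(min_ess, o_ess)
    return dict(max_rhat=worst_rhat, min_ess=min_ess,
                passed=bool(worst_rhat <= rhat_threshold and min_ess >= ess_threshold),
                rhat_threshold=rhat_threshold, ess_threshold=ess_threshold,
                per_outcome=per_outcome)


def plot_traces(post: PosteriorDraws, outcome: str, path,
                var_names=("sig_c", "sig_n", "country_intercept")) -> None:
    """Traceplot export for visual convergence checks."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    idata = _to_inference_data(post, outcome)
    az.plot_trace(idata, var_names=list(var_names), compact=True)
    plt.gcf().savefig(path, dpi=90)
    plt.close("all")


def waic(post: PosteriorDraws, outcome: str) -> float:
    """Widely applicable information criterion on the deviance scale."""
    ll = post.log_lik[outcome]
    idata = az.from_dict(posterior={"u_g": post.params[outcome]["u_g"]},
                         log_likelihood={"y": ll})
    res = az.waic(idata, scale="deviance")
    return float(res.elpd_waic)


def dic(post: PosteriorDraws, outcome: str) -> float:
    """Deviance information criterion: Dbar + pD with pD = Dbar - D(mean)."""
    from .model_core import pointwise_log_likelihood as pll
    ll = post.log_lik[outcome]
    dbar = float(-2.0 * ll.sum(axis=-1).mean())
    mean_params = {k: v.mean(axis=(0, 1)) for k, v in post.params[outcome].items()}
    d_at_mean = float(-2.0 * pll(mean_params, post.spec.units,
                                 post.spec.outcome_data[outcome]).sum())
    return 2.0 * dbar - d_at_mean


def select_spline(spec_factory, candidate_knots, cfg: McmcConfig,
                  outcome: str = "lifetime"):
    """Fit every candidate age-knot set and pick the lowest-WAIC one.

    ``spec_factory(knots)`` returns the ModelSpec built with that age
    basis.  Ties (within 0.01) break toward fewer knots.  Returns the
    chosen knot set and a criterion table.
    """
    candidates = [tuple(np.atleast_1d(k)) for k in candidate_knots]
    if len(candidates) < 2:
        raise ValueError("need at least two candidate knot sets")
    rows = []
    for knots in candidates:
        post = fit(spec_factory(knots), cfg, outcomes=[outcome])
        rows.append(dict(knots=knots, waic=waic(post, outcome), dic=dic(post, outcome)))
    rows.sort(key=lambda r: (round(r["waic"], 2), len(r["knots"])))
    return rows[0]["knots"], rows
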