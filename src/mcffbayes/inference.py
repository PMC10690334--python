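"""Posterior inference for multi-component learning curves.

Three procedures are provided, differing in how they pool information across
subjects:

* :func:`fit_bip` — Bayesian inference procedure: each subject/test is fit
  independently under independent uniform priors on theta, with the
  psychometric slope ``beta`` fixed (default 2).
* :func:`fit_hbmv` — three-level hierarchical model (population -> subject
  -> test) with per-dimension *variance* hyperparameters: ``rho_ik ~
  N(mu_k, sigma_k)``, ``theta_ijk ~ N(rho_ik, eps_k)``; uniform priors on
  ``mu_k``, Gamma(15, 1) on ``1/sigma_k^2``, Gamma(20, 1) on ``1/eps_k^2``,
  ``beta ~ U(1, 4)`` shared by all subjects.
* :func:`fit_hbmc` — the same hierarchy with full *covariance*
  hyperparameters: ``rho_i ~ MVN(mu, Sigma)``, ``theta_ij ~ MVN(rho_i,
  phi)``, with Wishart priors on the precisions ``Omega = Sigma^-1`` and
  ``Lambda = phi^-1`` (``v = K+1`` degrees of freedom, scale chosen so the
  prior mean of the precision equals the inverse of a supplied covariance —
  typically the between-subject covariance of a previous variance-model
  run).

The sampler is Metropolis-within-Gibbs: every Gaussian/Gamma/Wishart
hyperparameter has a conjugate full conditional and is Gibbs-updated
exactly; the likelihood-coupled parameters (``theta``, ``beta``) use
componentwise random-walk Metropolis with proposal scales adapted during
warm-up only (Robbins-Monro on the acceptance rate, frozen before any draw
is kept, so the kept chain is a valid Markov chain).  With the likelihood
disabled every update is an exact conjugate draw, which is used by the
prior-predictive equivalence tests.

Convergence is monitored by the between/within-chain variance ratio
(:func:`convergence_ratio`); a run whose worst ratio exceeds the configured
threshold is returned flagged (``converged=False``), never raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import wishart

from .data import SubjectData, TrialDataset
from .model import (
    DEFAULT_PSYCHOMETRIC,
    PROB_CLIP,
    PriorBounds,
    PsychometricConfig,
)

__all__ = [
    "SamplerConfig",
    "PosteriorSamples",
    "convergence_ratio",
    "fit_bip",
    "fit_bip_all",
    "fit_hbmv",
    "fit_hbmc",
    "wishart_scales_from_hbmv",
]

_LN10 = math.log(10.0)
_EXP_MAX = 700.0
_TARGET_ACC = 0.44  # optimal acceptance rate for componentwise random walks

# hyperprior constants: shape/rate of the Gamma priors on the precisions
SIGMA_PREC_SHAPE, SIGMA_PREC_RATE = 15.0, 1.0
EPS_PREC_SHAPE, EPS_PREC_RATE = 20.0, 1.0
BETA_RANGE = (1.0, 4.0)


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC schedule.

    ``adaptation`` sweeps tune proposal scales, then ``burn_in`` sweeps are
    discarded, then ``kept * thin`` sweeps retain every ``thin``-th state.
    ``reference()`` gives the full-scale schedule (3 chains, 5000 kept,
    thinning 10, 5000 adaptation, 5000 burn-in — 500,000 for the
    covariance model); tests use reduced schedules.
    """

    n_chains: int = 3
    kept: int = 5000
    thin: int = 10
    burn_in: int = 5000
    adaptation: int = 5000
    rhat_threshold: float = 1.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chains, self.kept, self.thin) < 1 or min(self.burn_in, self.adaptation) < 0:
            raise ValueError("schedule values must be positive")
        if self.rhat_threshold <= 1.0:
            raise ValueError("rhat_threshold must exceed 1")

    @classmethod
    def reference(cls, model: str = "bip", seed: int = 0) -> "SamplerConfig":
        burn = 500_000 if model.lower() == "hbmc" else 5000
        return cls(burn_in=burn, seed=seed)

    @classmethod
    def reduced(cls, seed: int = 0, **overrides) -> "SamplerConfig":
        """A short schedule suitable for tests and small synthetic data."""
        defaults = dict(n_chains=2, kept=400, thin=2, burn_in=300, adaptation=500)
        defaults.update(overrides)
        return cls(seed=seed, **defaults)


def convergence_ratio(draws: np.ndarray) -> float:
    """Between/within-chain variance ratio for one scalar parameter.

    ``draws`` has shape (chains, samples).  Returns the variance of all
    samples pooled across chains divided by the mean within-chain variance;
    values near 1 indicate the chains are sampling the same distribution.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2 or draws.shape[1] < 2:
        raise ValueError("need >=2 chains with >=2 samples each")
    pooled = float(np.var(draws, ddof=1))
    within = float(np.mean(np.var(draws, axis=1, ddof=1)))
    if within == 0.0:
        return 1.0 if pooled == 0.0 else float("inf")
    return pooled / within


@dataclass(frozen=True)
class PosteriorSamples:
    """Labelled MCMC draws: ``draws[chain, sample, parameter]``."""

    model: str
    K: int
    names: tuple[str, ...]
    draws: np.ndarray
    pairs: tuple[tuple[int, int], ...]  # (subject, test) pairs in theta order
    rhat: np.ndarray
    converged: bool
    beta_fixed: float | None
    seed: int

    def __post_init__(self) -> None:
        if self.draws.ndim != 3 or self.draws.shape[2] != len(self.names):
            raise ValueError("draws must be (chains, samples, parameters)")

    @property
    def n_chains(self) -> int:
        return int(self.draws.shape[0])

    @property
    def n_kept(self) -> int:
        return int(self.draws.shape[1])

    def _index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"no parameter named {name!r}") from None

    def get(self, name: str) -> np.ndarray:
        """(chains, samples) draws of one scalar parameter."""
        return self.draws[:, :, self._index(name)]

    def flat(self, name: str) -> np.ndarray:
        return self.get(name).reshape(-1)

    def mean(self, name: str) -> float:
        return float(self.get(name).mean())

    def theta_draws(self, subject: int, test: int = 1) -> np.ndarray:
        """All kept draws of one subject/test's theta, shape (draws, K)."""
        cols = [self._index(f"theta[{subject},{test}][{k + 1}]") for k in range(self.K)]
        return self.draws[:, :, cols].reshape(-1, self.K)

    def theta_mean(self, subject: int, test: int = 1) -> np.ndarray:
        return self.theta_draws(subject, test).mean(axis=0)

    def beta_draws(self) -> np.ndarray:
        if self.beta_fixed is not None:
            return np.full(self.n_chains * self.n_kept, self.beta_fixed)
        return self.flat("beta")

    def vector_mean(self, prefix: str, K: int | None = None) -> np.ndarray:
        K = K or self.K
        return np.array([self.mean(f"{prefix}[{k + 1}]") for k in range(K)])

    def vector_sd(self, prefix: str, K: int | None = None) -> np.ndarray:
        K = K or self.K
        return np.array(
            [float(self.flat(f"{prefix}[{k + 1}]").std(ddof=1)) for k in range(K)]
        )

    def to_dataframe(self) -> pd.DataFrame:
        """One row per chain x sample, labelled columns."""
        nc, ns, npar = self.draws.shape
        df = pd.DataFrame(self.draws.reshape(nc * ns, npar), columns=list(self.names))
        df.insert(0, "draw", np.tile(np.arange(ns), nc))
        df.insert(0, "chain", np.repeat(np.arange(nc), ns))
        return df


# ---------------------------------------------------------------------------
# likelihood fast path


class _PairData:
    """Precomputed per-(subject, test) arrays for fast likelihood evaluation."""

    __slots__ = ("subject", "test", "log10_t", "s0", "tprime", "log10_c", "resp", "n")

    def __init__(self, sd: SubjectData):
        self.subject = sd.subject
        self.test = sd.test
        self.n = sd.n_trials
        self.log10_t = np.log10(sd.tglobal.astype(float))
        self.s0 = sd.session.astype(int) - 1
        self.tprime = sd.tprime.astype(float)
        self.log10_c = np.log10(sd.contrast.astype(float))
        self.resp = sd.response.astype(bool)


def _decode_arrays(theta: np.ndarray, n_sessions: int):
    """gamma, b, phi, tau scalars + per-session delta/d arrays from theta."""
    K = theta.size
    gamma = 10.0 ** theta[0]
    b = -(10.0 ** theta[1])
    delta = np.zeros(n_sessions)
    d = np.zeros(n_sessions)
    phi = tau = 0.0
    if K == 14:
        phi = 10.0 ** theta[2]
        delta[1:6] = 10.0 ** theta[3:8]
        tau = 10.0 ** theta[8]
        d[1:6] = 10.0 ** theta[9:14]
    elif K == 6:
        phi = 10.0 ** theta[2]
        delta[1:] = 10.0 ** theta[3]
        tau = 10.0 ** theta[4]
        d[1:] = 10.0 ** theta[5]
    return gamma, b, phi, delta, tau, d


def _loglik_kernel_py(
    theta, beta, log10_t, s0, tprime, resp_sign, log10_c, n_sessions, g, lapse, shift
) -> float:
    """Fused per-trial likelihood loop; JIT-compiled when numba is present."""
    K = theta.shape[0]
    gamma = 10.0 ** theta[0]
    b = -(10.0 ** theta[1])
    phi = 0.0
    tau = 0.0
    delta = np.zeros(n_sessions)
    d = np.zeros(n_sessions)
    if K == 14:
        phi = 10.0 ** theta[2]
        tau = 10.0 ** theta[8]
        for s in range(1, min(6, n_sessions)):
            delta[s] = 10.0 ** theta[2 + s]
            d[s] = 10.0 ** theta[8 + s]
    elif K == 6:
        phi = 10.0 ** theta[2]
        tau = 10.0 ** theta[4]
        for s in range(1, n_sessions):
            delta[s] = 10.0 ** theta[3]
            d[s] = 10.0 ** theta[5]
    total = 0.0
    for i in range(log10_t.shape[0]):
        s = s0[i]
        relearn = -tau * tprime[i]
        if relearn < -d[s]:
            relearn = -d[s]
        xi = b - gamma * log10_t[i] + delta[s] + relearn + phi * tprime[i]
        z = beta * _LN10 * (log10_c[i] - xi + shift)
        if z > _EXP_MAX:
            z = _EXP_MAX
        inner = g + (1.0 - g) * (-math.expm1(-math.exp(z)))
        p = g * lapse + (1.0 - lapse) * inner
        if p < PROB_CLIP:
            p = PROB_CLIP
        elif p > 1.0 - PROB_CLIP:
            p = 1.0 - PROB_CLIP
        if resp_sign[i]:
            total += math.log(p)
        else:
            total += math.log1p(-p)
    return total


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _loglik_kernel = njit(cache=False)(_loglik_kernel_py)
except ImportError:  # pragma: no cover
    _loglik_kernel = _loglik_kernel_py


def _pair_loglik(
    theta: np.ndarray,
    beta: float,
    pair: _PairData,
    n_sessions: int,
    config: PsychometricConfig,
) -> float:
    if pair.n == 0:
        return 0.0
    return _loglik_kernel(
        np.ascontiguousarray(theta),
        beta,
        pair.log10_t,
        pair.s0,
        pair.tprime,
        pair.resp,
        pair.log10_c,
        n_sessions,
        config.g,
        config.lapse,
        config.criterion_shift(beta),
    )


def _prepare_pairs(
    data: TrialDataset | SubjectData | list[SubjectData],
    subjects: list[tuple[int, int]] | None = None,
) -> list[_PairData]:
    if isinstance(data, SubjectData):
        return [_PairData(data)]
    if isinstance(data, TrialDataset):
        if subjects is None:
            subjects = [
                (int(s), int(j))
                for s, j in sorted(
                    set(zip(data.df["subject"], data.df["test"]))
                )
            ]
        return [_PairData(data.packed(s, j)) for s, j in subjects]
    return [_PairData(sd) for sd in data]


def _n_sessions_for(pairs: list[_PairData], K: int) -> int:
    observed = max((int(p.s0.max()) + 1 for p in pairs if p.n > 0), default=1)
    return max(observed, 6) if K > 2 else max(observed, 1)


# ---------------------------------------------------------------------------
# adaptive componentwise random walk bookkeeping


class _AdaptiveScales:
    """Per-coordinate proposal scales with Robbins-Monro adaptation."""

    def __init__(self, init: np.ndarray):
        self.log_s = np.log(np.asarray(init, dtype=float))
        self.t = 0

    def scale(self, idx) -> float:
        return math.exp(self.log_s[idx])

    def tick(self) -> None:
        self.t += 1

    def update(self, idx, acc_prob: float) -> None:
        gain = min(0.3, 2.0 / math.sqrt(1.0 + self.t))
        self.log_s[idx] += gain * (acc_prob - _TARGET_ACC)


class _RunningCov:
    """Running mean/covariance of a vector chain, for adaptive full-vector
    proposals along the posterior's correlation ridge (frozen after warmup)."""

    def __init__(self, K: int):
        self.n = 0
        self.mean = np.zeros(K)
        self.m2 = np.zeros((K, K))
        self._chol: np.ndarray | None = None

    def update(self, x: np.ndarray) -> None:
        self.n += 1
        delta = x - self.mean
        self.mean += delta / self.n
        self.m2 += np.outer(delta, x - self.mean)
        self._chol = None

    def proposal_chol(self) -> np.ndarray | None:
        if self.n < 10:
            return None
        if self._chol is None:
            K = self.mean.size
            cov = self.m2 / (self.n - 1) + 1e-10 * np.eye(K)
            # scaled optimal random-walk covariance, 2.38^2 / K
            self._chol = np.linalg.cholesky(cov * (2.38**2 / K))
        return self._chol


def _chain_rngs(seed: int, n_chains: int) -> list[np.random.Generator]:
    return [np.random.default_rng([seed, c]) for c in range(n_chains)]


def _truncnorm_rvs(lo, hi, loc, scale, rng: np.random.Generator):
    """Truncated-normal draw(s) by inverse-CDF (cheaper than scipy's rvs).

    ``lo``/``hi`` are the truncation bounds on the original scale.
    Degenerate tails (both CDF values rounding to the same number) fall
    back to clipping, which matters only when the mass inside the bounds
    is below double precision.
    """
    a = ndtr((np.asarray(lo) - loc) / scale)
    b = ndtr((np.asarray(hi) - loc) / scale)
    u = a + (b - a) * rng.random(np.shape(a)) if np.ndim(a) else a + (b - a) * rng.random()
    x = loc + scale * ndtri(np.clip(u, 1e-15, 1 - 1e-15))
    return np.clip(x, lo, hi)


def _empirical_theta_start(
    pair: _PairData, bounds: PriorBounds, rng: np.random.Generator
) -> np.ndarray:
    """Data-driven chain start for one subject's theta.

    The staircase keeps contrast near the threshold, so a least-squares line
    of log10 contrast on log10 trial gives rough starts for the learning
    rate and initial threshold; remaining dimensions start mid-bounds.
    Jitter disperses chains.  Initialisation only affects convergence speed,
    never the stationary distribution.
    """
    theta = bounds.midpoint.copy()
    if pair.n >= 10:
        slope, intercept = np.polyfit(pair.log10_t, pair.log10_c, 1)
        theta[0] = math.log10(min(max(-slope, 1e-3), 0.3))
        theta[1] = math.log10(min(max(-intercept, 1e-3), 0.3))
    theta += 0.05 * rng.standard_normal(theta.size)
    return np.clip(theta, bounds.lower, bounds.upper)


def _finish(
    model: str,
    K: int,
    names: list[str],
    chains: list[np.ndarray],
    pairs: list[_PairData],
    config: SamplerConfig,
    beta_fixed: float | None,
) -> PosteriorSamples:
    draws = np.stack(chains)  # (chains, kept, P)
    rhat = np.ones(len(names))
    if draws.shape[0] >= 2 and draws.shape[1] >= 2:
        pooled = np.var(draws.reshape(-1, draws.shape[2]), axis=0, ddof=1)
        within = np.mean(np.var(draws, axis=1, ddof=1), axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            rhat = np.where(
                within > 0, pooled / within, np.where(pooled > 0, np.inf, 1.0)
            )
    converged = bool(np.all(rhat < config.rhat_threshold))
    return PosteriorSamples(
        model=model,
        K=K,
        names=tuple(names),
        draws=draws,
        pairs=tuple((p.subject, p.test) for p in pairs),
        rhat=rhat,
        converged=converged,
        beta_fixed=beta_fixed,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# BIP


def fit_bip(
    trials: TrialDataset | SubjectData,
    bounds: PriorBounds,
    config: SamplerConfig,
    *,
    beta: float = 2.0,
    use_likelihood: bool = True,
    psychometric: PsychometricConfig = DEFAULT_PSYCHOMETRIC,
) -> PosteriorSamples:
    """Posterior over one subject/test's theta under uniform priors.

    ``beta`` is fixed (default 2).  With no trials (or ``use_likelihood=
    False``) the kept draws are exact prior samples.
    """
    pairs = _prepare_pairs(trials)
    if len(pairs) != 1:
        raise ValueError("fit_bip takes data from exactly one subject/test")
    pair = pairs[0]
    K = bounds.K
    n_sessions = _n_sessions_for(pairs, K)
    lo, hi = bounds.lower, bounds.upper
    names = [f"theta[{pair.subject},{pair.test}][{k + 1}]" for k in range(K)]
    warmup = config.adaptation + config.burn_in
    total = warmup + config.kept * config.thin
    likelihood_on = use_likelihood and pair.n > 0

    chains = []
    for rng in _chain_rngs(config.seed, config.n_chains):
        kept = np.empty((config.kept, K))
        if not likelihood_on:
            # posterior == prior: sample it exactly
            kept[:] = rng.uniform(lo, hi, size=(config.kept, K))
            chains.append(kept)
            continue
        theta = _empirical_theta_start(pair, bounds, rng)
        ll = _pair_loglik(theta, beta, pair, n_sessions, psychometric)
        scales = _AdaptiveScales((hi - lo) / 20.0)
        ridge = _RunningCov(K)
        n_kept = 0
        for sweep in range(total):
            adapting = sweep < config.adaptation
            for k in range(K):
                prop = theta[k] + scales.scale(k) * rng.standard_normal()
                if prop < lo[k] or prop > hi[k]:
                    acc = 0.0
                else:
                    old = theta[k]
                    theta[k] = prop
                    ll_new = _pair_loglik(theta, beta, pair, n_sessions, psychometric)
                    acc = min(1.0, math.exp(min(ll_new - ll, 0.0)))
                    if rng.random() < acc:
                        ll = ll_new
                    else:
                        theta[k] = old
                if adapting:
                    scales.update(k, acc)
            # full-vector move along the adapted covariance ridge
            L = ridge.proposal_chol()
            if L is not None:
                prop_vec = theta + L @ rng.standard_normal(K)
                if np.all(prop_vec >= lo) and np.all(prop_vec <= hi):
                    ll_new = _pair_loglik(prop_vec, beta, pair, n_sessions, psychometric)
                    if math.log(rng.random()) < ll_new - ll:
                        theta, ll = prop_vec, ll_new
            # long-range independence move on one coordinate, proposed from
            # its uniform prior (jumps between "component on/off" modes)
            k = int(rng.integers(K))
            old = theta[k]
            theta[k] = rng.uniform(lo[k], hi[k])
            ll_new = _pair_loglik(theta, beta, pair, n_sessions, psychometric)
            if math.log(rng.random()) < ll_new - ll:
                ll = ll_new
            else:
                theta[k] = old
            if adapting:
                scales.tick()
                ridge.update(theta.copy())
            if sweep >= warmup and (sweep - warmup + 1) % config.thin == 0:
                kept[n_kept] = theta
                n_kept += 1
        chains.append(kept)
    return _finish("bip", K, names, chains, pairs, config, beta)


def fit_bip_all(
    dataset: TrialDataset,
    bounds: PriorBounds,
    config: SamplerConfig,
    *,
    beta: float = 2.0,
    psychometric: PsychometricConfig = DEFAULT_PSYCHOMETRIC,
) -> dict[int, PosteriorSamples]:
    """Independent BIP fits for every subject in the dataset (test 1)."""
    out = {}
    for i, s in enumerate(dataset.subjects):
        cfg = replace(config, seed=config.seed + 1000 * (i + 1))
        out[s] = fit_bip(
            dataset.packed(s), bounds, cfg, beta=beta, psychometric=psychometric
        )
    return out


# ---------------------------------------------------------------------------
# HBMv


def fit_hbmv(
    dataset: TrialDataset | list[SubjectData],
    bounds: PriorBounds,
    config: SamplerConfig,
    *,
    beta: float | str = "sample",
    use_likelihood: bool = True,
    subjects: list[tuple[int, int]] | None = None,
    psychometric: PsychometricConfig = DEFAULT_PSYCHOMETRIC,
) -> PosteriorSamples:
    """Joint posterior of the variance-hyperparameter hierarchy.

    Samples ``theta_ij``, ``rho_ik``, ``mu_k``, ``sigma_k``, ``eps_k`` and
    (by default) a single ``beta`` shared across subjects.
    """
    pairs = _prepare_pairs(dataset, subjects)
    K = bounds.K
    n_sessions = _n_sessions_for(pairs, K)
    lo, hi = bounds.lower, bounds.upper
    subj_ids = sorted({p.subject for p in pairs})
    I = len(subj_ids)
    subj_index = {s: i for i, s in enumerate(subj_ids)}
    pair_subj = np.array([subj_index[p.subject] for p in pairs])
    n_pairs = len(pairs)
    tests_per_subject = np.bincount(pair_subj, minlength=I).astype(float)

    sample_beta = beta == "sample"
    beta_fixed = None if sample_beta else float(beta)

    names = (
        [f"theta[{p.subject},{p.test}][{k + 1}]" for p in pairs for k in range(K)]
        + [f"rho[{s}][{k + 1}]" for s in subj_ids for k in range(K)]
        + [f"mu[{k + 1}]" for k in range(K)]
        + [f"sigma[{k + 1}]" for k in range(K)]
        + [f"eps[{k + 1}]" for k in range(K)]
        + (["beta"] if sample_beta else [])
    )
    warmup = config.adaptation + config.burn_in
    total = warmup + config.kept * config.thin
    lik_on = [use_likelihood and p.n > 0 for p in pairs]

    def total_loglik(theta_mat, b):
        return sum(
            _pair_loglik(theta_mat[p], b, pairs[p], n_sessions, psychometric)
            for p in range(n_pairs)
            if lik_on[p]
        )

    chains = []
    for rng in _chain_rngs(config.seed, config.n_chains):
        # hyperparameters start from the priors (dispersed between chains);
        # theta starts at a data-driven guess to shorten burn-in
        mu = rng.uniform(lo, hi)
        sigma2 = 1.0 / rng.gamma(SIGMA_PREC_SHAPE, 1.0 / SIGMA_PREC_RATE, size=K)
        eps2 = 1.0 / rng.gamma(EPS_PREC_SHAPE, 1.0 / EPS_PREC_RATE, size=K)
        rho = mu + np.sqrt(sigma2) * rng.standard_normal((I, K))
        theta = rho[pair_subj] + np.sqrt(eps2) * rng.standard_normal((n_pairs, K))
        for p in range(n_pairs):
            if use_likelihood and pairs[p].n > 0:
                theta[p] = _empirical_theta_start(pairs[p], bounds, rng)
                rho[pair_subj[p]] = theta[p]
        b = rng.uniform(*BETA_RANGE) if sample_beta else beta_fixed
        lls = np.array(
            [
                _pair_loglik(theta[p], b, pairs[p], n_sessions, psychometric)
                if lik_on[p]
                else 0.0
                for p in range(n_pairs)
            ]
        )
        scales = _AdaptiveScales(np.full((n_pairs, K), 0.05).ravel())
        beta_scale = _AdaptiveScales(np.array([0.1]))
        ridges = [_RunningCov(K) for _ in range(n_pairs)]

        kept = np.empty((config.kept, len(names)))
        n_kept = 0
        for sweep in range(total):
            adapting = sweep < config.adaptation
            # -- theta | rho, eps, beta, data
            for p in range(n_pairs):
                i = pair_subj[p]
                if not lik_on[p]:
                    theta[p] = rho[i] + np.sqrt(eps2) * rng.standard_normal(K)
                    continue
                for k in range(K):
                    sidx = p * K + k
                    old = theta[p, k]
                    prop = old + scales.scale(sidx) * rng.standard_normal()
                    dprior = -0.5 * ((prop - rho[i, k]) ** 2 - (old - rho[i, k]) ** 2) / eps2[k]
                    theta[p, k] = prop
                    ll_new = _pair_loglik(theta[p], b, pairs[p], n_sessions, psychometric)
                    log_acc = ll_new - lls[p] + dprior
                    acc = min(1.0, math.exp(min(log_acc, 0.0)))
                    if rng.random() < acc:
                        lls[p] = ll_new
                    else:
                        theta[p, k] = old
                    if adapting:
                        scales.update(sidx, acc)
                L = ridges[p].proposal_chol()
                if L is not None:
                    prop_vec = theta[p] + L @ rng.standard_normal(K)
                    dprior = -0.5 * float(
                        np.sum(((prop_vec - rho[i]) ** 2 - (theta[p] - rho[i]) ** 2) / eps2)
                    )
                    ll_new = _pair_loglik(prop_vec, b, pairs[p], n_sessions, psychometric)
                    if math.log(rng.random()) < ll_new - lls[p] + dprior:
                        theta[p] = prop_vec
                        lls[p] = ll_new
                # independence move on one coordinate from its prior
                # conditional N(rho_ik, eps_k); MH ratio reduces to the
                # likelihood ratio (mode-jumping for on/off components)
                k = int(rng.integers(K))
                old = theta[p, k]
                theta[p, k] = rho[i, k] + math.sqrt(eps2[k]) * rng.standard_normal()
                ll_new = _pair_loglik(theta[p], b, pairs[p], n_sessions, psychometric)
                if math.log(rng.random()) < ll_new - lls[p]:
                    lls[p] = ll_new
                else:
                    theta[p, k] = old
                if adapting:
                    ridges[p].update(theta[p].copy())
            # -- (mu, rho) | theta, sigma, eps: blocked draw — mu from its
            #    rho-collapsed conditional (theta-bar_i ~ N(mu, sigma^2 +
            #    eps^2 / J_i)), then rho conjugate given the fresh mu
            theta_sums = np.zeros((I, K))
            np.add.at(theta_sums, pair_subj, theta)
            theta_bar = theta_sums / tests_per_subject[:, None]
            w = 1.0 / (sigma2 + eps2 / tests_per_subject[:, None])  # (I, K)
            wsum = w.sum(axis=0)
            loc = (w * theta_bar).sum(axis=0) / wsum
            sd = 1.0 / np.sqrt(wsum)
            mu = _truncnorm_rvs(lo, hi, loc, sd, rng)
            prec = 1.0 / sigma2 + tests_per_subject[:, None] / eps2
            mean = (mu / sigma2 + theta_sums / eps2) / prec
            rho = mean + rng.standard_normal((I, K)) / np.sqrt(prec)
            # -- precisions | rho, mu / theta, rho (conjugate gamma)
            ss_rho = np.sum((rho - mu) ** 2, axis=0)
            sigma2 = 1.0 / rng.gamma(
                SIGMA_PREC_SHAPE + 0.5 * I, 1.0 / (SIGMA_PREC_RATE + 0.5 * ss_rho)
            )
            ss_theta = np.sum((theta - rho[pair_subj]) ** 2, axis=0)
            eps2 = 1.0 / rng.gamma(
                EPS_PREC_SHAPE + 0.5 * n_pairs, 1.0 / (EPS_PREC_RATE + 0.5 * ss_theta)
            )
            # -- beta | theta, data
            if sample_beta:
                if use_likelihood and any(lik_on):
                    prop = b + beta_scale.scale(0) * rng.standard_normal()
                    if BETA_RANGE[0] <= prop <= BETA_RANGE[1]:
                        new_lls = np.array(
                            [
                                _pair_loglik(theta[p], prop, pairs[p], n_sessions, psychometric)
                                if lik_on[p]
                                else 0.0
                                for p in range(n_pairs)
                            ]
                        )
                        log_acc = float(new_lls.sum() - lls.sum())
                        acc = min(1.0, math.exp(min(log_acc, 0.0)))
                        if rng.random() < acc:
                            b, lls = prop, new_lls
                    else:
                        acc = 0.0
                    if adapting:
                        beta_scale.update(0, acc)
                        beta_scale.tick()
                else:
                    b = rng.uniform(*BETA_RANGE)
            if adapting:
                scales.tick()
            if sweep >= warmup and (sweep - warmup + 1) % config.thin == 0:
                row = [theta.ravel(), rho.ravel(), mu, np.sqrt(sigma2), np.sqrt(eps2)]
                if sample_beta:
                    row.append(np.array([b]))
                kept[n_kept] = np.concatenate(row)
                n_kept += 1
        chains.append(kept)
    return _finish("hbmv", K, names, chains, pairs, config, beta_fixed)


def wishart_scales_from_hbmv(
    post: PosteriorSamples, ridge: float = 1e-4
) -> tuple[np.ndarray, np.ndarray]:
    """Wishart scale matrices for the covariance model from a variance run.

    The between-subject scale is the sample covariance of the subject-level
    posterior means (plus a small ridge for positive definiteness); the
    within-subject scale is the diagonal of the posterior-mean test-level
    variances ``eps_k^2``.
    """
    if post.model != "hbmv":
        raise ValueError("expected an HBMv posterior")
    K = post.K
    subjects = sorted({s for s, _ in post.pairs})
    rho_means = np.array(
        [[post.mean(f"rho[{s}][{k + 1}]") for k in range(K)] for s in subjects]
    )
    scale_Sigma = np.cov(rho_means.T) + ridge * np.eye(K)
    eps2 = np.array([float(np.mean(post.flat(f"eps[{k + 1}]") ** 2)) for k in range(K)])
    scale_phi = np.diag(eps2)
    return scale_Sigma, scale_phi


# ---------------------------------------------------------------------------
# HBMc


def fit_hbmc(
    dataset: TrialDataset | list[SubjectData],
    bounds: PriorBounds,
    config: SamplerConfig,
    *,
    scale_Sigma: np.ndarray | None = None,
    scale_phi: np.ndarray | None = None,
    beta: float | str = "sample",
    use_likelihood: bool = True,
    subjects: list[tuple[int, int]] | None = None,
    psychometric: PsychometricConfig = DEFAULT_PSYCHOMETRIC,
) -> PosteriorSamples:
    """Joint posterior of the covariance-hyperparameter hierarchy.

    ``scale_Sigma`` / ``scale_phi`` are the covariance matrices anchoring
    the Wishart priors on the precisions (prior mean of ``Sigma^-1`` is
    ``scale_Sigma^-1``); pass the between-/within-subject covariances from a
    variance-model run (:func:`wishart_scales_from_hbmv`).  The cold-start
    default anchors at the dispersions the variance model's hyperpriors
    typify (``sigma^2 ~ 1/15``, ``eps^2 ~ 1/20`` per dimension) — an
    identity anchor would allow order-1 dispersion per log10 dimension,
    far outside the plausible range.
    """
    pairs = _prepare_pairs(dataset, subjects)
    K = bounds.K
    n_sessions = _n_sessions_for(pairs, K)
    lo, hi = bounds.lower, bounds.upper
    subj_ids = sorted({p.subject for p in pairs})
    I = len(subj_ids)
    subj_index = {s: i for i, s in enumerate(subj_ids)}
    pair_subj = np.array([subj_index[p.subject] for p in pairs])
    n_pairs = len(pairs)
    tests_per_subject = np.bincount(pair_subj, minlength=I).astype(float)

    v = K + 1  # Wishart degrees of freedom
    for name, m in (("scale_Sigma", scale_Sigma), ("scale_phi", scale_phi)):
        if m is not None:
            m = np.asarray(m, float)
            if m.shape != (K, K) or not np.allclose(m, m.T):
                raise ValueError(f"{name} must be a symmetric {K}x{K} matrix")
            try:
                np.linalg.cholesky(m)
            except np.linalg.LinAlgError:
                raise ValueError(f"{name} must be positive definite") from None
    S_Sigma = (
        np.eye(K) / SIGMA_PREC_SHAPE if scale_Sigma is None
        else np.asarray(scale_Sigma, float)
    )
    S_phi = (
        np.eye(K) / EPS_PREC_SHAPE if scale_phi is None
        else np.asarray(scale_phi, float)
    )
    # prior scale of the precision Wisharts: W(S^-1 / v, v), so E[Omega] = S^-1
    prior_scale_Omega = np.linalg.inv(S_Sigma) / v
    prior_scale_Lambda = np.linalg.inv(S_phi) / v
    inv_prior_scale_Omega = S_Sigma * v
    inv_prior_scale_Lambda = S_phi * v

    sample_beta = beta == "sample"
    beta_fixed = None if sample_beta else float(beta)

    cov_idx = [(k, l) for k in range(K) for l in range(k, K)]
    names = (
        [f"theta[{p.subject},{p.test}][{k + 1}]" for p in pairs for k in range(K)]
        + [f"rho[{s}][{k + 1}]" for s in subj_ids for k in range(K)]
        + [f"mu[{k + 1}]" for k in range(K)]
        + [f"Sigma[{k + 1},{l + 1}]" for k, l in cov_idx]
        + [f"phi[{k + 1},{l + 1}]" for k, l in cov_idx]
        + (["beta"] if sample_beta else [])
    )
    tri_r, tri_c = np.array([k for k, _ in cov_idx]), np.array([l for _, l in cov_idx])
    warmup = config.adaptation + config.burn_in
    total = warmup + config.kept * config.thin
    lik_on = [use_likelihood and p.n > 0 for p in pairs]

    chains = []
    for rng in _chain_rngs(config.seed, config.n_chains):
        # chains start at the prior-mean precisions (a random Wishart draw
        # with v = K+1 df can be nearly singular, stranding early sweeps)
        # and at uniform-random mu, giving dispersed but stable starts
        mu = rng.uniform(lo, hi)
        Omega = np.linalg.inv(S_Sigma)
        Lambda = np.linalg.inv(S_phi)
        Sigma = np.linalg.inv(Omega)
        phi_cov = np.linalg.inv(Lambda)
        rho = rng.multivariate_normal(mu, Sigma, size=I, method="cholesky")
        theta = np.array(
            [rng.multivariate_normal(rho[i], phi_cov, method="cholesky") for i in pair_subj]
        )
        for p in range(n_pairs):
            if use_likelihood and pairs[p].n > 0:
                theta[p] = _empirical_theta_start(pairs[p], bounds, rng)
                rho[pair_subj[p]] = theta[p]
        b = rng.uniform(*BETA_RANGE) if sample_beta else beta_fixed
        lls = np.array(
            [
                _pair_loglik(theta[p], b, pairs[p], n_sessions, psychometric)
                if lik_on[p]
                else 0.0
                for p in range(n_pairs)
            ]
        )
        scales = _AdaptiveScales(np.full((n_pairs, K), 0.05).ravel())
        beta_scale = _AdaptiveScales(np.array([0.1]))
        ridges = [_RunningCov(K) for _ in range(n_pairs)]

        kept = np.empty((config.kept, len(names)))
        n_kept = 0
        for sweep in range(total):
            adapting = sweep < config.adaptation
            # -- theta | rho, Lambda, beta, data
            chol_phi = None
            for p in range(n_pairs):
                i = pair_subj[p]
                if not lik_on[p]:
                    if chol_phi is None:
                        chol_phi = np.linalg.cholesky(np.linalg.inv(Lambda))
                    theta[p] = rho[i] + chol_phi @ rng.standard_normal(K)
                    continue
                r = theta[p] - rho[i]
                Lr = Lambda @ r
                for k in range(K):
                    sidx = p * K + k
                    old = theta[p, k]
                    dr = scales.scale(sidx) * rng.standard_normal()
                    # quadratic-form change of the MVN prior term
                    dq = 2.0 * dr * Lr[k] + dr * dr * Lambda[k, k]
                    theta[p, k] = old + dr
                    ll_new = _pair_loglik(theta[p], b, pairs[p], n_sessions, psychometric)
                    log_acc = ll_new - lls[p] - 0.5 * dq
                    acc = min(1.0, math.exp(min(log_acc, 0.0)))
                    if rng.random() < acc:
                        lls[p] = ll_new
                        Lr = Lr + dr * Lambda[:, k]
                        r[k] += dr
                    else:
                        theta[p, k] = old
                    if adapting:
                        scales.update(sidx, acc)
                L = ridges[p].proposal_chol()
                if L is not None:
                    prop_vec = theta[p] + L @ rng.standard_normal(K)
                    rp = prop_vec - rho[i]
                    r0 = theta[p] - rho[i]
                    dq = float(rp @ Lambda @ rp - r0 @ Lambda @ r0)
                    ll_new = _pair_loglik(prop_vec, b, pairs[p], n_sessions, psychometric)
                    if math.log(rng.random()) < ll_new - lls[p] - 0.5 * dq:
                        theta[p] = prop_vec
                        lls[p] = ll_new
                # independence move on one coordinate from its MVN prior
                # conditional; the MH ratio reduces to the likelihood ratio
                # (mode-jumping for on/off components)
                r = theta[p] - rho[i]
                k = int(rng.integers(K))
                cond_mean = rho[i, k] + r[k] - (Lambda[k] @ r) / Lambda[k, k]
                old = theta[p, k]
                theta[p, k] = cond_mean + rng.standard_normal() / math.sqrt(Lambda[k, k])
                ll_new = _pair_loglik(theta[p], b, pairs[p], n_sessions, psychometric)
                if math.log(rng.random()) < ll_new - lls[p]:
                    lls[p] = ll_new
                else:
                    theta[p, k] = old
                if adapting:
                    ridges[p].update(theta[p].copy())
            # -- (mu, rho) | theta, Omega, Lambda: blocked draw.  With rho
            #    integrated out, theta-bar_i ~ MVN(mu, Sigma + phi / J_i);
            #    mu is Gibbs-scanned componentwise under the box truncation,
            #    then rho is drawn conjugate given the fresh mu.
            theta_sums = np.zeros((I, K))
            np.add.at(theta_sums, pair_subj, theta)
            theta_bar = theta_sums / tests_per_subject[:, None]
            Sigma = np.linalg.inv(Omega)
            phi_cov = np.linalg.inv(Lambda)
            Jvals = np.unique(tests_per_subject)
            P = np.zeros((K, K))
            m_acc = np.zeros(K)
            for Jv in Jvals:
                Ci = np.linalg.inv(Sigma + phi_cov / Jv)
                sel = tests_per_subject == Jv
                P += Ci * sel.sum()
                m_acc += Ci @ theta_bar[sel].sum(axis=0)
            m = np.linalg.solve(P, m_acc)
            for k in range(K):
                resid = P[k] @ (mu - m) - P[k, k] * (mu[k] - m[k])
                loc = m[k] - resid / P[k, k]
                sd = 1.0 / math.sqrt(P[k, k])
                mu[k] = float(_truncnorm_rvs(lo[k], hi[k], loc, sd, rng))
            Om_mu = Omega @ mu
            for i in range(I):
                prec = Omega + tests_per_subject[i] * Lambda
                L = np.linalg.cholesky(prec)
                mean = np.linalg.solve(prec, Om_mu + Lambda @ theta_sums[i])
                z = rng.standard_normal(K)
                rho[i] = mean + np.linalg.solve(L.T, z)
            # -- Omega | rho, mu (conjugate Wishart)
            dev = rho - mu
            post_scale = np.linalg.inv(inv_prior_scale_Omega + dev.T @ dev)
            post_scale = 0.5 * (post_scale + post_scale.T)
            Omega = np.atleast_2d(
                wishart.rvs(df=v + I, scale=post_scale, random_state=rng)
            )
            # -- Lambda | theta, rho (conjugate Wishart)
            devt = theta - rho[pair_subj]
            post_scale = np.linalg.inv(inv_prior_scale_Lambda + devt.T @ devt)
            post_scale = 0.5 * (post_scale + post_scale.T)
            Lambda = np.atleast_2d(
                wishart.rvs(df=v + n_pairs, scale=post_scale, random_state=rng)
            )
            # -- beta | theta, data
            if sample_beta:
                if use_likelihood and any(lik_on):
                    prop = b + beta_scale.scale(0) * rng.standard_normal()
                    if BETA_RANGE[0] <= prop <= BETA_RANGE[1]:
                        new_lls = np.array(
                            [
                                _pair_loglik(theta[p], prop, pairs[p], n_sessions, psychometric)
                                if lik_on[p]
                                else 0.0
                                for p in range(n_pairs)
                            ]
                        )
                        acc = min(1.0, math.exp(min(float(new_lls.sum() - lls.sum()), 0.0)))
                        if rng.random() < acc:
                            b, lls = prop, new_lls
                    else:
                        acc = 0.0
                    if adapting:
                        beta_scale.update(0, acc)
                        beta_scale.tick()
                else:
                    b = rng.uniform(*BETA_RANGE)
            if adapting:
                scales.tick()
            if sweep >= warmup and (sweep - warmup + 1) % config.thin == 0:
                Sigma = np.linalg.inv(Omega)
                phi_cov = np.linalg.inv(Lambda)
                row = [
                    theta.ravel(),
                    rho.ravel(),
                    mu,
                    Sigma[tri_r, tri_c],
                    phi_cov[tri_r, tri_c],
                ]
                if sample_beta:
                    row.append(np.array([b]))
                kept[n_kept] = np.concatenate(row)
                n_kept += 1
        chains.append(kept)
    return _finish("hbmc", K, names, chains, pairs, config, beta_fixed)
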