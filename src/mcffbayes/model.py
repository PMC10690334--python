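"""Generative model of trial-by-trial performance in perceptual learning.

The observer's log10 contrast threshold on trial ``t`` is modelled as the sum
of four latent component processes (the multi-component functional form,
MCFF):

* **general learning** ``b - gamma * log10(t)`` — a log-linear improvement
  over the whole course of training (``b`` is the initial log10 threshold,
  ``gamma > 0`` the learning rate);
* **between-session forgetting** — a step ``delta_s`` at the start of each
  daily session ``s >= 2`` (no step in session 1);
* **within-session rapid relearning** — an elbow ``max(-d_s, -tau * t')``
  in the 0-based within-session trial index ``t'``: a fast linear recovery
  at rate ``tau`` that saturates at ``-d_s``;
* **within-session adaptation/deterioration** — a linear ramp ``phi * t'``
  that resets at every session start.

All components live in log10 threshold units.  The model order ``K`` selects
how many of these processes are free: ``K=14`` lets ``delta_s`` and ``d_s``
vary per session (sessions 2..6), ``K=6`` shares a single ``delta`` and
``d`` across sessions, and ``K=2`` keeps general learning only.  Parameters
are stored as a vector ``theta`` of log10 magnitudes, so every decoded
component magnitude is strictly positive by construction.

Performance on a trial is linked to the threshold through a Weibull
psychometric function for two-alternative forced choice (guessing rate
``g = 0.5``), with a lapse rate ``lambda = 0.04`` and a threshold criterion
fixed at the accuracy of an ideal observer at sensitivity d' = 1.5
(``p_ref = 0.856``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "MCFFParams",
    "MCFFComponents",
    "PriorBounds",
    "PsychometricConfig",
    "SessionStructure",
    "pc_2afc_dprime",
    "decode_params",
    "component_curves",
    "threshold_curve",
    "weibull_prob",
    "trial_loglik",
]

VALID_K = (2, 6, 14)

#: floor applied to per-trial probabilities before taking logs, so the
#: likelihood stays finite under extreme parameters proposed during sampling
PROB_CLIP = 1e-9

_LN10 = math.log(10.0)
_EXP_MAX = 700.0  # exp() overflow guard


def pc_2afc_dprime(dprime: float) -> float:
    """Percent correct of an unbiased 2AFC observer at sensitivity ``dprime``.

    Under the equal-variance Gaussian model the probability of a correct
    response is ``Phi(d' / sqrt(2))``.  ``pc_2afc_dprime(1.5)`` is the
    criterion accuracy that defines "threshold" throughout this package.
    """
    return float(norm.cdf(dprime / math.sqrt(2.0)))


@dataclass(frozen=True)
class PsychometricConfig:
    """Constants of the 2AFC Weibull psychometric function.

    Parameters
    ----------
    g : guessing rate (chance performance), default 0.5 for 2AFC.
    lapse : lapse rate ``lambda``; stimulus-independent error probability.
    p_ref : accuracy defining the threshold criterion (d' = 1.5 -> 0.856).
    """

    g: float = 0.5
    lapse: float = 0.04
    p_ref: float = 0.856

    def __post_init__(self) -> None:
        if not (0.0 < self.g < 1.0):
            raise ValueError(f"guessing rate g must be in (0,1), got {self.g}")
        if not (0.0 <= self.lapse < 1.0):
            raise ValueError(f"lapse rate must be in [0,1), got {self.lapse}")
        if not (self.g < self.p_ref < 1.0):
            raise ValueError(
                f"p_ref must be in (g, 1) = ({self.g}, 1), got {self.p_ref}"
            )

    @property
    def floor(self) -> float:
        """Probability correct as contrast -> 0."""
        return self.g * self.lapse + (1.0 - self.lapse) * self.g

    @property
    def ceiling(self) -> float:
        """Probability correct as contrast -> infinity."""
        return self.g * self.lapse + (1.0 - self.lapse)

    def criterion_shift(self, beta: float) -> float:
        """log10 offset between the threshold and the Weibull scale.

        ``log10(theta_scale) = xi - criterion_shift(beta)`` where
        ``criterion_shift = (1/beta) * log10(ln((1-g)/(1-p_ref)))``.
        """
        return math.log10(math.log((1.0 - self.g) / (1.0 - self.p_ref))) / beta


DEFAULT_PSYCHOMETRIC = PsychometricConfig()


@dataclass(frozen=True)
class SessionStructure:
    """Layout of trials into daily sessions, with optional pre-training.

    Global trial numbers are 1-based and cumulative over pre-training and all
    sessions.  Pre-training trials (at most 80) belong to session 1, so the
    within-session index ``t'`` of session 1 counts from the first
    pre-training trial.  ``t' = 0`` at the first trial of every session.
    """

    n_sessions: int = 6
    trials_per_session: int | Sequence[int] = 320
    pretrain_trials: int = 0

    def __post_init__(self) -> None:
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")
        if not (0 <= self.pretrain_trials <= 80):
            raise ValueError("pretrain_trials must be in [0, 80]")
        # normalise to a tuple so equality is canonical
        object.__setattr__(self, "trials_per_session", self._tps())
        tps = self._tps()
        if len(tps) != self.n_sessions or any(n < 1 for n in tps):
            raise ValueError("trials_per_session must give >=1 trial per session")

    def _tps(self) -> tuple[int, ...]:
        if isinstance(self.trials_per_session, int):
            return (self.trials_per_session,) * self.n_sessions
        return tuple(int(n) for n in self.trials_per_session)

    @property
    def session_lengths(self) -> tuple[int, ...]:
        """Trials in each session; session 1 includes pre-training."""
        tps = self._tps()
        return (tps[0] + self.pretrain_trials,) + tps[1:]

    @property
    def n_trials(self) -> int:
        return sum(self.session_lengths)

    def trial_layout(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Arrays ``(t_global 1-based, session 1-based, t_prime 0-based)``."""
        lengths = self.session_lengths
        session = np.repeat(np.arange(1, self.n_sessions + 1), lengths)
        tprime = np.concatenate([np.arange(n) for n in lengths])
        tglobal = np.arange(1, self.n_trials + 1)
        return tglobal, session, tprime

    def session_of(self, t: int) -> int:
        if not (1 <= t <= self.n_trials):
            raise ValueError(f"trial {t} outside 1..{self.n_trials}")
        return int(np.searchsorted(np.cumsum(self.session_lengths), t - 1, "right") + 1)

    def tprime_of(self, t: int) -> int:
        s = self.session_of(t)
        start = sum(self.session_lengths[: s - 1])
        return t - 1 - start


@dataclass(frozen=True)
class MCFFParams:
    """Parameter vector ``theta`` of a multi-component learning curve.

    Every entry is the log10 of a (positive) component magnitude; see
    :func:`decode_params` for the layout at each model order ``K``.
    """

    theta: np.ndarray
    K: int = field(init=False)

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        object.__setattr__(self, "theta", theta)
        if theta.ndim != 1 or theta.size not in VALID_K:
            raise ValueError(
                f"theta must be a vector of length 2, 6 or 14; got shape {theta.shape}"
            )
        if not np.all(np.isfinite(theta)):
            raise ValueError("theta must be finite")
        object.__setattr__(self, "K", int(theta.size))


@dataclass(frozen=True)
class MCFFComponents:
    """Named, decoded components of an MCFF parameter vector.

    ``delta`` and ``d`` are indexed by session (``delta[s-1]`` for session
    ``s``); session 1 has no forgetting step or relearning floor, so
    ``delta[0] == d[0] == 0`` always.
    """

    gamma: float
    b: float
    phi: float
    delta: np.ndarray
    tau: float
    d: np.ndarray


#: Default prior bounds on theta (log10 units), by dimension, for K=14:
#: gamma and -b in [-3, -0.5]; phi in [-6, -3]; delta_s in [-3, -1];
#: tau in [-4, -2]; d_s in [-3, -0.6].
_BOUNDS_14 = (
    [(-3.0, -0.5)] * 2
    + [(-6.0, -3.0)]
    + [(-3.0, -1.0)] * 5
    + [(-4.0, -2.0)]
    + [(-3.0, -0.6)] * 5
)
_BOUNDS_6 = (
    [(-3.0, -0.5)] * 2
    + [(-6.0, -3.0), (-3.0, -1.0), (-4.0, -2.0), (-3.0, -0.6)]
)
_BOUNDS_2 = [(-3.0, -0.5)] * 2


@dataclass(frozen=True)
class PriorBounds:
    """Box constraints ``(theta_k_min, theta_k_max)`` for the uniform priors."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.shape != upper.shape or lower.ndim != 1:
            raise ValueError("lower and upper must be vectors of equal length")
        if not np.all(lower < upper):
            raise ValueError("bounds must satisfy lower < upper elementwise")

    @property
    def K(self) -> int:
        return int(self.lower.size)

    @classmethod
    def default(cls, K: int) -> "PriorBounds":
        table = {2: _BOUNDS_2, 6: _BOUNDS_6, 14: _BOUNDS_14}
        if K not in table:
            raise ValueError(f"K must be one of {VALID_K}, got {K}")
        arr = np.array(table[K])
        return cls(lower=arr[:, 0], upper=arr[:, 1])

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.lower + self.upper)

    def contains(self, theta: np.ndarray) -> bool:
        theta = np.asarray(theta, dtype=float)
        return bool(np.all(theta >= self.lower) and np.all(theta <= self.upper))

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
        """Uniform draw(s) inside the box."""
        if size is None:
            return rng.uniform(self.lower, self.upper)
        return rng.uniform(self.lower, self.upper, size=(size, self.K))


def decode_params(params: MCFFParams | np.ndarray, n_sessions: int = 6) -> MCFFComponents:
    """Decode a theta vector into named component magnitudes.

    Layout: ``theta[0] = log10(gamma)``, ``theta[1] = log10(-b)``; for
    ``K=14``, ``theta[2] = log10(phi)``, ``theta[3:8] = log10(delta_s)`` for
    sessions 2..6, ``theta[8] = log10(tau)`` and ``theta[9:14] =
    log10(d_s)`` for sessions 2..6; ``K=6`` shares one ``delta`` and ``d``
    across sessions 2..S; ``K=2`` keeps general learning only.
    """
    if not isinstance(params, MCFFParams):
        params = MCFFParams(np.asarray(params, dtype=float))
    th = params.theta
    K = params.K
    gamma = 10.0 ** th[0]
    b = -(10.0 ** th[1])
    delta = np.zeros(n_sessions)
    d = np.zeros(n_sessions)
    phi = 0.0
    tau = 0.0
    if K == 14:
        if n_sessions != 6:
            raise ValueError("K=14 allocates per-session components for 6 sessions")
        phi = 10.0 ** th[2]
        delta[1:] = 10.0 ** th[3:8]
        tau = 10.0 ** th[8]
        d[1:] = 10.0 ** th[9:14]
    elif K == 6:
        phi = 10.0 ** th[2]
        delta[1:] = 10.0 ** th[3]
        tau = 10.0 ** th[4]
        d[1:] = 10.0 ** th[5]
    return MCFFComponents(gamma=gamma, b=b, phi=phi, delta=delta, tau=tau, d=d)


def _xi_from_layout(
    comp: MCFFComponents,
    tglobal: np.ndarray,
    session: np.ndarray,
    tprime: np.ndarray,
) -> np.ndarray:
    s0 = session - 1  # 0-based session index into delta/d
    general = comp.b - comp.gamma * np.log10(tglobal)
    forgetting = comp.delta[s0]
    relearning = np.maximum(-comp.d[s0], -comp.tau * tprime)
    adaptation = comp.phi * tprime
    return general + forgetting + relearning + adaptation


def component_curves(
    params: MCFFParams | np.ndarray, structure: SessionStructure
) -> dict[str, np.ndarray]:
    """Evaluate the four component processes on every trial of ``structure``.

    Returns a dict with keys ``general``, ``forgetting``, ``relearning`` and
    ``adaptation``, each an array of length ``structure.n_trials`` in log10
    threshold units.  Their elementwise sum is :func:`threshold_curve`.
    """
    comp = decode_params(params, structure.n_sessions)
    tglobal, session, tprime = structure.trial_layout()
    s0 = session - 1
    return {
        "general": comp.b - comp.gamma * np.log10(tglobal),
        "forgetting": comp.delta[s0],
        "relearning": np.maximum(-comp.d[s0], -comp.tau * tprime),
        "adaptation": comp.phi * tprime,
    }


def threshold_curve(
    params: MCFFParams | np.ndarray, structure: SessionStructure
) -> np.ndarray:
    """Per-trial log10 contrast threshold ``xi(t)``: the sum of all components."""
    comp = decode_params(params, structure.n_sessions)
    tglobal, session, tprime = structure.trial_layout()
    return _xi_from_layout(comp, tglobal, session, tprime)


def weibull_prob(
    xi: float | np.ndarray,
    contrast: float | np.ndarray,
    beta: float = 2.0,
    config: PsychometricConfig = DEFAULT_PSYCHOMETRIC,
) -> float | np.ndarray:
    """Probability of a correct 2AFC response at ``contrast``.

    ``xi`` is the log10 contrast threshold (the contrast at which accuracy is
    ``p_ref``).  The Weibull scale parameter is derived from ``xi`` so that
    the function passes through ``p_ref`` exactly at ``contrast = 10**xi``,
    then lapse-corrected:

    ``p = g*lapse + (1-lapse) * (g + (1-g) * (1 - exp(-(c/scale)**beta)))``
    """
    c = np.asarray(contrast, dtype=float)
    if np.any(c <= 0):
        raise ValueError("contrast must be strictly positive")
    if beta <= 0:
        raise ValueError("beta must be positive")
    xi = np.asarray(xi, dtype=float)
    log10_scale = xi - config.criterion_shift(beta)
    # (c/scale)**beta in log space to survive extreme proposals
    z = np.minimum(beta * _LN10 * (np.log10(c) - log10_scale), _EXP_MAX)
    inner = config.g + (1.0 - config.g) * (-np.expm1(-np.exp(z)))
    p = config.g * config.lapse + (1.0 - config.lapse) * inner
    if p.ndim == 0:
        return float(p)
    return p


def trial_loglik(
    params: MCFFParams | np.ndarray,
    beta: float,
    contrast: np.ndarray,
    response: np.ndarray,
    structure: SessionStructure | None = None,
    *,
    tglobal: np.ndarray | None = None,
    session: np.ndarray | None = None,
    tprime: np.ndarray | None = None,
    config: PsychometricConfig = DEFAULT_PSYCHOMETRIC,
) -> float:
    """Bernoulli log likelihood of one subject/test's responses.

    The trial layout can be given either as a :class:`SessionStructure`
    (covering all trials in order) or explicitly as aligned ``tglobal`` /
    ``session`` / ``tprime`` arrays (e.g. for a truncated dataset).
    Per-trial probabilities are clipped to ``[1e-9, 1 - 1e-9]`` before the
    log, so the result is always finite.  An empty collection gives 0.0.
    """
    contrast = np.asarray(contrast, dtype=float)
    response = np.asarray(response)
    if contrast.size == 0:
        return 0.0
    if structure is not None:
        tglobal, session, tprime = structure.trial_layout()
        if contrast.size != tglobal.size:
            raise ValueError(
                f"{contrast.size} trials but structure has {tglobal.size}"
            )
    elif tglobal is None or session is None or tprime is None:
        raise ValueError("pass either structure or tglobal/session/tprime arrays")
    n_sessions = int(np.max(session))
    comp = decode_params(params, max(n_sessions, 6))
    xi = _xi_from_layout(comp, np.asarray(tglobal), np.asarray(session), np.asarray(tprime))
    p = weibull_prob(xi, contrast, beta, config)
    p = np.clip(p, PROB_CLIP, 1.0 - PROB_CLIP)
    r = response.astype(bool)
    return float(np.sum(np.where(r, np.log(p), np.log1p(-p))))
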