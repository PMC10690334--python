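"""Synthetic staircase data from multi-component learning-curve observers.

Emulates a six-group perceptual-learning study design: each simulated
subject is a stochastic 2AFC observer whose log10 contrast threshold follows
a multi-component learning curve, trained for six daily sessions of 320
trials under an adaptive staircase that tracks a design accuracy of 65%
(low), 85% (high), or both interleaved (mixed).  Subject- and test-level
parameters are drawn from a three-level Gaussian hierarchy with full
covariance, so the generator doubles as ground truth for
parameter-recovery tests of the inference procedures.

The staircase is a Kesten-style accelerated stochastic approximation on
log10 contrast: the step size starts at ``initial_step / n`` for the first
two trials and thereafter shrinks with the number of response reversals,
``initial_step / (2 + reversals)``.  Any rule with this Robbins-Monro
convergence property would serve; convergence to the target accuracy is
checked by the test suite rather than assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import COLUMNS, TrialDataset
from .model import (
    DEFAULT_PSYCHOMETRIC,
    MCFFParams,
    PsychometricConfig,
    SessionStructure,
    threshold_curve,
    weibull_prob,
)

__all__ = [
    "StaircaseState",
    "staircase_step",
    "observer_response",
    "simulate_subject",
    "GroupDesign",
    "PopulationSpec",
    "TruthBundle",
    "default_population_spec",
    "simulate_population",
]

#: design accuracies of the low- and high-accuracy staircases
LOW_TARGET = 0.65
HIGH_TARGET = 0.85

_X_MIN = -10.0  # lower clip on log10 contrast; upper clip is 0 (contrast <= 1)


@dataclass(frozen=True)
class StaircaseState:
    """State of one accelerated stochastic approximation staircase."""

    target_accuracy: float
    log10_contrast: float = -0.5
    initial_step: float = 0.3
    trial_count: int = 0
    reversal_count: int = 0
    last_response: int | None = None

    def __post_init__(self) -> None:
        if not (0.5 < self.target_accuracy < 1.0):
            raise ValueError("target_accuracy must be in (0.5, 1)")
        if self.initial_step <= 0:
            raise ValueError("initial_step must be positive")

    @property
    def contrast(self) -> float:
        return 10.0 ** self.log10_contrast


def staircase_step(state: StaircaseState, response: int) -> StaircaseState:
    """Update the staircase with one response; returns the next state.

    ``x_{n+1} = x_n - (s / n) * (r_n - p_target)`` for the first two trials,
    then ``x_{n+1} = x_n - (s / (2 + m_n)) * (r_n - p_target)`` where ``m_n``
    counts response reversals.  log10 contrast is clipped so contrast <= 1.
    """
    n = state.trial_count + 1
    reversals = state.reversal_count
    if state.last_response is not None and response != state.last_response:
        reversals += 1
    if n <= 2:
        step = state.initial_step / n
    else:
        step = state.initial_step / (2.0 + reversals)
    x = state.log10_contrast - step * (response - state.target_accuracy)
    x = min(max(x, _X_MIN), 0.0)
    return replace(
        state,
        log10_contrast=x,
        trial_count=n,
        reversal_count=reversals,
        last_response=int(response),
    )


def observer_response(
    params: MCFFParams | np.ndarray,
    beta: float,
    structure: SessionStructure,
    t: int,
    contrast: float,
    rng: np.random.Generator,
    config: PsychometricConfig = DEFAULT_PSYCHOMETRIC,
) -> int:
    """One Bernoulli response of an MCFF observer at global trial ``t``."""
    xi = threshold_curve(params, structure)[t - 1]
    p = weibull_prob(xi, contrast, beta, config)
    return int(rng.random() < p)


def _staircases_for(condition: str, initial_contrast: float, initial_step: float):
    """(staircase_id, state) pairs for a training condition."""
    make = lambda target: StaircaseState(
        target_accuracy=target,
        log10_contrast=np.log10(initial_contrast),
        initial_step=initial_step,
    )
    if condition == "low":
        return [("s65", make(LOW_TARGET))]
    if condition == "high":
        return [("s85", make(HIGH_TARGET))]
    if condition == "mixed":
        return [("s65", make(LOW_TARGET)), ("s85", make(HIGH_TARGET))]
    raise ValueError(f"unknown condition {condition!r}; use low/high/mixed")


def simulate_subject(
    params: MCFFParams | np.ndarray,
    beta: float,
    condition: str,
    structure: SessionStructure,
    rng: np.random.Generator,
    *,
    subject: int = 1,
    test: int = 1,
    group: int = 1,
    config: PsychometricConfig = DEFAULT_PSYCHOMETRIC,
    initial_contrast: float = 10.0 ** -0.5,
    initial_step: float = 0.3,
    reset_between_sessions: bool = False,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate one subject's full staircase-controlled training run.

    In the mixed condition two staircases (65% and 85% targets) strictly
    alternate across trials, each updating only on its own trials.  Staircase
    state carries over between sessions unless ``reset_between_sessions``.
    Returns the trial table and the subject's true log10 threshold curve
    (one value per trial, for recovery tests).
    """
    xi = threshold_curve(params, structure)
    tglobal, session, _ = structure.trial_layout()
    stairs = _staircases_for(condition, initial_contrast, initial_step)
    fresh = [s for _, s in stairs]

    rows: dict[str, list] = {c: [] for c in COLUMNS}
    prev_session = 1
    for i in range(structure.n_trials):
        s = int(session[i])
        if reset_between_sessions and s != prev_session:
            stairs = [(sid, st) for (sid, _), st in zip(stairs, fresh)]
            prev_session = s
        idx = i % len(stairs)
        sid, state = stairs[idx]
        c = state.contrast
        p = weibull_prob(xi[i], c, beta, config)
        r = int(rng.random() < p)
        stairs[idx] = (sid, staircase_step(state, r))
        rows["subject"].append(subject)
        rows["test"].append(test)
        rows["group"].append(group)
        rows["session"].append(s)
        rows["global_trial"].append(int(tglobal[i]))
        rows["contrast"].append(c)
        rows["response"].append(r)
        rows["staircase_id"].append(sid)
    return pd.DataFrame(rows, columns=COLUMNS), xi


@dataclass(frozen=True)
class GroupDesign:
    """One training group: size, staircase condition, and mean offsets."""

    group: int
    n_subjects: int
    condition: str  # low / high / mixed
    feedback: bool = False
    #: additive offset applied to the population mean for this group's
    #: subjects (the generative model has no feedback term, so groups differ
    #: only through their true parameters)
    mu_shift: np.ndarray | None = None


def _default_mu(K: int) -> np.ndarray:
    """Population mean of theta (log10 units), inside the default prior
    bounds.  Component magnitudes are chosen so every process leaves a
    visible signature on the curve, as in the training data the design
    emulates: learning rate gamma ~ 0.045, initial threshold 10^-0.2,
    forgetting steps ~ 0.08 log units, rapid relearning of amplitude ~ 0.1
    recovered within ~30 trials (tau ~ 3e-3/trial), and an adaptation ramp
    of ~ 3e-4/trial (~0.1 log units over a 320-trial session)."""
    gamma, b = -1.35, -0.70
    if K == 2:
        return np.array([gamma, b])
    phi, delta, tau, d = -3.5, -1.1, -2.5, -1.0
    if K == 6:
        return np.array([gamma, b, phi, delta, tau, d])
    return np.array([gamma, b, phi] + [delta] * 5 + [tau] + [d] * 5)


def _default_sigma(K: int, sd: float = 0.15) -> np.ndarray:
    """Between-subject covariance with the correlation pattern such studies
    report: the relearning block (tau and the d_s) positively
    inter-correlated, the initial threshold negatively correlated with it,
    and the learning rate mildly coupled to tau."""
    corr = np.eye(K)

    def set_corr(i, j, r):
        corr[i, j] = corr[j, i] = r

    if K == 2:
        set_corr(0, 1, 0.1)
    elif K == 6:
        set_corr(4, 5, 0.45)   # tau with d
        set_corr(1, 5, -0.4)   # -b with d
        set_corr(0, 4, -0.3)   # gamma with tau
    else:
        d_block = list(range(9, 14))
        for a_i, i in enumerate(d_block):
            for j in d_block[a_i + 1 :]:
                set_corr(i, j, 0.5)
        for i in d_block:
            set_corr(8, i, 0.45)   # tau with each d_s
            set_corr(1, i, -0.35)  # -b with each d_s
        set_corr(0, 8, -0.3)
        set_corr(0, 1, 0.1)
    # validated PD by construction; guard anyway
    np.linalg.cholesky(corr)
    return (sd * np.eye(K)) @ corr @ (sd * np.eye(K))


@dataclass(frozen=True)
class PopulationSpec:
    """Design of a simulated study population.

    ``mu``/``Sigma`` are the population mean and between-subject covariance
    of the theta vectors; ``phi_cov`` is the within-subject (between-test)
    covariance.  Defaults reproduce the reference six-group design:
    (12, 12, 6, 6, 12, 12) subjects under low/low/mixed/mixed/high/high
    accuracy staircases, feedback alternating off/on, with the first
    (low-accuracy, no-feedback) group a slower learner.
    """

    K: int = 14
    mu: np.ndarray | None = None
    Sigma: np.ndarray | None = None
    phi_cov: np.ndarray | None = None
    beta: float = 2.0
    groups: tuple[GroupDesign, ...] | None = None
    n_sessions: int = 6
    trials_per_session: int = 320
    n_tests: int = 1
    pretrain_range: tuple[int, int] = (60, 80)
    initial_contrast: float = 10.0 ** -0.5
    initial_step: float = 0.3

    def resolved(self) -> "PopulationSpec":
        """Fill in defaults and validate covariance matrices."""
        mu = self.mu if self.mu is not None else _default_mu(self.K)
        mu = np.asarray(mu, dtype=float)
        if mu.size != self.K:
            raise ValueError(f"mu must have length K={self.K}")
        Sigma = self.Sigma if self.Sigma is not None else _default_sigma(self.K)
        phi_cov = self.phi_cov if self.phi_cov is not None else np.eye(self.K) * 0.05**2
        for name, m in (("Sigma", Sigma), ("phi_cov", phi_cov)):
            m = np.asarray(m, dtype=float)
            if m.shape != (self.K, self.K) or not np.allclose(m, m.T):
                raise ValueError(f"{name} must be a symmetric {self.K}x{self.K} matrix")
            try:
                np.linalg.cholesky(m)
            except np.linalg.LinAlgError:
                raise ValueError(f"{name} must be positive definite") from None
        groups = self.groups if self.groups is not None else _default_groups(self.K)
        return replace(
            self,
            mu=mu,
            Sigma=np.asarray(Sigma, float),
            phi_cov=np.asarray(phi_cov, float),
            groups=tuple(groups),
        )


def _default_groups(K: int) -> tuple[GroupDesign, ...]:
    slow = np.zeros(K)
    slow[0] = -0.24  # group 1 learns ~40% slower (lower gamma)
    return (
        GroupDesign(1, 12, "low", feedback=False, mu_shift=slow),
        GroupDesign(2, 12, "low", feedback=True),
        GroupDesign(3, 6, "mixed", feedback=False),
        GroupDesign(4, 6, "mixed", feedback=True),
        GroupDesign(5, 12, "high", feedback=False),
        GroupDesign(6, 12, "high", feedback=True),
    )


def default_population_spec(K: int = 14, **overrides) -> PopulationSpec:
    return PopulationSpec(K=K, **overrides).resolved()


@dataclass(frozen=True)
class TruthBundle:
    """Latent ground truth emitted alongside a simulated dataset."""

    spec: PopulationSpec
    rho: dict[int, np.ndarray]  # subject -> subject-level mean
    theta: dict[tuple[int, int], np.ndarray]  # (subject, test) -> test-level params
    curves: dict[tuple[int, int], np.ndarray]  # (subject, test) -> true xi(t)
    structures: dict[int, SessionStructure] = field(default_factory=dict)
    group_of: dict[int, int] = field(default_factory=dict)


def simulate_population(
    spec: PopulationSpec,
    seed: int | np.random.Generator,
    config: PsychometricConfig = DEFAULT_PSYCHOMETRIC,
) -> tuple[TrialDataset, TruthBundle]:
    """Simulate every subject of a study population.

    Subject-level means are drawn ``rho_i ~ MVN(mu + group shift, Sigma)``
    and test-level parameters ``theta_ij ~ MVN(rho_i, phi_cov)``; each test
    is then run through :func:`simulate_subject`.  Identical spec and seed
    give byte-identical trial tables.
    """
    spec = spec.resolved()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frames = []
    rho: dict[int, np.ndarray] = {}
    theta: dict[tuple[int, int], np.ndarray] = {}
    curves: dict[tuple[int, int], np.ndarray] = {}
    structures: dict[int, SessionStructure] = {}
    group_of: dict[int, int] = {}
    sid = 0
    lo, hi = spec.pretrain_range
    for gd in spec.groups:
        mu_g = spec.mu + (gd.mu_shift if gd.mu_shift is not None else 0.0)
        for _ in range(gd.n_subjects):
            sid += 1
            pretrain = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
            structure = SessionStructure(
                n_sessions=spec.n_sessions,
                trials_per_session=spec.trials_per_session,
                pretrain_trials=pretrain,
            )
            structures[sid] = structure
            group_of[sid] = gd.group
            rho_i = rng.multivariate_normal(mu_g, spec.Sigma)
            rho[sid] = rho_i
            for j in range(1, spec.n_tests + 1):
                th = rng.multivariate_normal(rho_i, spec.phi_cov)
                theta[(sid, j)] = th
                frame, xi = simulate_subject(
                    th,
                    spec.beta,
                    gd.condition,
                    structure,
                    rng,
                    subject=sid,
                    test=j,
                    group=gd.group,
                    config=config,
                    initial_contrast=spec.initial_contrast,
                    initial_step=spec.initial_step,
                )
                frames.append(frame)
                curves[(sid, j)] = xi
    dataset = TrialDataset(pd.concat(frames, ignore_index=True))
    truth = TruthBundle(
        spec=spec,
        rho=rho,
        theta=theta,
        curves=curves,
        structures=structures,
        group_of=group_of,
    )
    return dataset, truth
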