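"""Post-inference analytics for learning-curve posteriors.

Covers goodness of fit (Bayesian predictive information criterion),
trial-by-trial learning-curve posteriors summarised by their mean and the
half width of the central 68.2% credible interval (HWCI), group-level
posterior construction by across-subject sample averaging, MANOVA/LDA group
comparisons, and partial-data prediction of a subject's learning curve from
the hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .data import TrialDataset
from .inference import (
    PosteriorSamples,
    SamplerConfig,
    _n_sessions_for,
    _pair_loglik,
    _prepare_pairs,
    fit_hbmc,
)
from .model import (
    DEFAULT_PSYCHOMETRIC,
    PriorBounds,
    PsychometricConfig,
    SessionStructure,
    threshold_curve,
)

__all__ = [
    "LearningCurveEstimate",
    "GroupPosterior",
    "PredictionResult",
    "bpic",
    "curve_posterior",
    "group_posterior",
    "manova_groups",
    "lda_groups",
    "predict_curve",
]

#: central credible mass summarised by the HWCI (interval between the
#: 15.9th and 84.1st percentiles, i.e. +-1 SD for a Gaussian)
HWCI_MASS = 0.682
_Q_LO = 50.0 * (1.0 - HWCI_MASS)
_Q_HI = 100.0 - _Q_LO


@dataclass(frozen=True)
class LearningCurveEstimate:
    """Per-trial posterior mean and 68.2% HWCI of the log10 threshold curve."""

    mean: np.ndarray
    hwci: np.ndarray
    tglobal: np.ndarray
    session: np.ndarray

    def __post_init__(self) -> None:
        if not (self.mean.shape == self.hwci.shape == self.tglobal.shape):
            raise ValueError("mean, hwci and trial vectors must align")
        if np.any(self.hwci < 0):
            raise ValueError("HWCI must be non-negative")

    @property
    def n_trials(self) -> int:
        return int(self.mean.size)

    @property
    def average_hwci(self) -> float:
        return float(self.hwci.mean())


@dataclass(frozen=True)
class GroupPosterior:
    """Group-level parameter cloud: rows are across-subject means of
    independently resampled per-subject posterior draws."""

    group: int
    samples: np.ndarray  # (n_samples, K)

    @property
    def K(self) -> int:
        return int(self.samples.shape[1])

    @property
    def mean(self) -> np.ndarray:
        return self.samples.mean(axis=0)


def bpic(
    posterior: PosteriorSamples,
    dataset: TrialDataset,
    *,
    max_draws: int = 1000,
    psychometric: PsychometricConfig = DEFAULT_PSYCHOMETRIC,
) -> float:
    """Bayesian predictive information criterion; lower is better.

    ``BPIC = Dbar + 2 * p_D`` with ``Dbar`` the posterior mean of the
    deviance ``-2 log p(Y | theta, beta)`` and the effective number of
    parameters ``p_D = Dbar - D(theta-hat)``.  The plug-in ``theta-hat`` is
    the highest-likelihood kept draw rather than the coordinate-wise
    posterior mean: the parameters live on a log10 scale, where weakly
    constrained dimensions make the posterior banana-shaped and the mean
    plug-in can fall off the likelihood ridge (giving a negative penalty);
    the modal-draw plug-in keeps ``p_D >= 0`` and degenerates to ``p_D = 0``
    for a point-mass posterior.  The deviance sums over every subject/test
    in the posterior.  At most ``max_draws`` evenly spaced posterior draws
    are used for the average.
    """
    if posterior.n_kept == 0:
        raise ValueError("posterior has no kept draws")
    pairs = _prepare_pairs(dataset, subjects=list(posterior.pairs))
    n_sessions = _n_sessions_for(pairs, posterior.K)
    theta_all = [posterior.theta_draws(s, j) for s, j in posterior.pairs]
    betas = posterior.beta_draws()
    n = theta_all[0].shape[0]
    idx = np.unique(np.linspace(0, n - 1, min(max_draws, n)).astype(int))

    def deviance(thetas: list[np.ndarray], beta: float) -> float:
        return -2.0 * sum(
            _pair_loglik(th, beta, pair, n_sessions, psychometric)
            for th, pair in zip(thetas, pairs)
        )

    devs = np.array(
        [deviance([th[i] for th in theta_all], float(betas[i])) for i in idx]
    )
    dbar = float(devs.mean())
    d_hat = float(devs.min())
    p_d = dbar - d_hat
    return dbar + 2.0 * p_d


def curve_posterior(
    theta_draws: np.ndarray | PosteriorSamples,
    structure: SessionStructure,
    *,
    subject: int | None = None,
    test: int = 1,
) -> LearningCurveEstimate:
    """Push posterior theta draws through the learning curve.

    The per-trial mean is the pointwise sample mean; the HWCI is half the
    width of the central 68.2% interval (15.9th to 84.1st percentile).
    """
    if isinstance(theta_draws, PosteriorSamples):
        if subject is None:
            raise ValueError("pass subject= when giving a PosteriorSamples")
        theta_draws = theta_draws.theta_draws(subject, test)
    theta_draws = np.atleast_2d(np.asarray(theta_draws, dtype=float))
    curves = np.stack([threshold_curve(th, structure) for th in theta_draws])
    q_lo, q_hi = np.percentile(curves, [_Q_LO, _Q_HI], axis=0)
    tglobal, session, _ = structure.trial_layout()
    return LearningCurveEstimate(
        mean=curves.mean(axis=0),
        hwci=0.5 * (q_hi - q_lo),
        tglobal=tglobal,
        session=session,
    )


def group_posterior(
    subject_draws: dict[int, np.ndarray],
    group: int = 0,
    *,
    n_samples: int = 15_000,
    rng: np.random.Generator | int = 0,
) -> GroupPosterior:
    """Group-level posterior by across-subject sample averaging.

    Each of the ``n_samples`` group samples is the mean, across the group's
    subjects, of one per-subject posterior draw picked uniformly at random
    with replacement (draws are resampled independently per subject and
    repetition).
    """
    if not subject_draws:
        raise ValueError("need at least one subject")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    mats = [np.asarray(m, dtype=float) for m in subject_draws.values()]
    K = mats[0].shape[1]
    acc = np.zeros((n_samples, K))
    for m in mats:
        acc += m[rng.integers(0, m.shape[0], size=n_samples)]
    return GroupPosterior(group=group, samples=acc / len(mats))


def manova_groups(
    subject_means: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """One-way MANOVA (Pillai's trace) on per-subject mean parameter vectors.

    Returns ``(F statistic, p-value)`` for the group main effect.  Raises a
    ``ValueError`` when there are too few subjects for the within-group
    covariance to have full rank.
    """
    from statsmodels.multivariate.manova import MANOVA

    X = np.asarray(subject_means, dtype=float)
    labels = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("subject_means must be (n_subjects, K)")
    n, K = X.shape
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("need at least two groups")
    if n - groups.size < K:
        raise ValueError(
            f"rank-deficient design: {n} subjects, {groups.size} groups, "
            f"{K} dimensions — need n - G >= K"
        )
    df = pd.DataFrame(X, columns=[f"x{k}" for k in range(K)])
    df["group"] = pd.Categorical(labels)
    formula = " + ".join(df.columns[:-1]) + " ~ group"
    res = MANOVA.from_formula(formula, data=df).mv_test()
    stats = res.results["group"]["stat"]
    row = stats.loc["Pillai's trace"]
    return float(row["F Value"]), float(row["Pr > F"])


def lda_groups(
    group_posteriors: dict[int, GroupPosterior],
    *,
    train_frac: float = 0.9,
    repeats: int = 100,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Pairwise linear-discriminant separability of group posterior clouds.

    For each pair of groups and each repeat, each group's samples are split
    ``train_frac`` / ``1 - train_frac``, an LDA is fit on the pooled
    training samples (equal priors) and scored on the held-out samples.
    Returns a table with one row per pair: mean and SD of held-out accuracy
    over ``repeats`` repeats.  A singular within-class covariance triggers a
    shrinkage-regularised fallback.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    gids = sorted(group_posteriors)
    rows = []
    for a_i, ga in enumerate(gids):
        for gb in gids[a_i + 1 :]:
            Xa = group_posteriors[ga].samples
            Xb = group_posteriors[gb].samples
            accs = np.empty(repeats)
            for r in range(repeats):
                train_X, train_y, test_X, test_y = [], [], [], []
                for X, label in ((Xa, 0), (Xb, 1)):
                    perm = rng.permutation(X.shape[0])
                    cut = int(round(train_frac * X.shape[0]))
                    train_X.append(X[perm[:cut]])
                    test_X.append(X[perm[cut:]])
                    train_y.append(np.full(cut, label))
                    test_y.append(np.full(X.shape[0] - cut, label))
                Xtr, ytr = np.vstack(train_X), np.concatenate(train_y)
                Xte, yte = np.vstack(test_X), np.concatenate(test_y)
                try:
                    clf = LinearDiscriminantAnalysis(priors=[0.5, 0.5])
                    clf.fit(Xtr, ytr)
                except np.linalg.LinAlgError:
                    clf = LinearDiscriminantAnalysis(
                        solver="lsqr", shrinkage="auto", priors=[0.5, 0.5]
                    )
                    clf.fit(Xtr, ytr)
                accs[r] = clf.score(Xte, yte)
            rows.append(
                {
                    "group_a": ga,
                    "group_b": gb,
                    "accuracy_mean": float(accs.mean()),
                    "accuracy_sd": float(accs.std(ddof=1)) if repeats > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PredictionResult:
    """A predicted learning curve and its agreement with the full-data fit."""

    subject: int
    sessions_provided: int
    estimate: LearningCurveEstimate
    reference: LearningCurveEstimate
    correlation: float
    hwci_ratio: float  # average predicted HWCI / average reference HWCI


def predict_curve(
    dataset: TrialDataset,
    subject: int,
    sessions_provided: int,
    bounds: PriorBounds,
    config: SamplerConfig,
    *,
    structure: SessionStructure | None = None,
    reference: LearningCurveEstimate | None = None,
    test: int = 1,
    psychometric: PsychometricConfig = DEFAULT_PSYCHOMETRIC,
    **fit_kwargs,
) -> PredictionResult:
    """Predict one subject's full learning curve from truncated data.

    The target subject's trials beyond the first ``sessions_provided``
    sessions are removed (0 removes all of them); every other subject keeps
    its full data.  The covariance-hierarchy model is refit on this
    truncated dataset and the target's curve posterior over the *full*
    session structure is the prediction.  Reported metrics: Pearson
    correlation between the predicted and reference mean curves, and the
    ratio of their average HWCIs.  ``reference`` defaults to a fresh
    full-data fit.
    """
    structure = structure or dataset.structure_for(subject, test)
    all_pairs = [
        (int(s), int(j)) for s, j in sorted(set(zip(dataset.df["subject"], dataset.df["test"])))
    ]
    truncated = dataset.truncate_subject(subject, sessions_provided, test)
    post = fit_hbmc(
        truncated, bounds, config, subjects=all_pairs, psychometric=psychometric, **fit_kwargs
    )
    estimate = curve_posterior(post, structure, subject=subject, test=test)
    if reference is None:
        full_post = fit_hbmc(
            dataset, bounds, config, subjects=all_pairs, psychometric=psychometric, **fit_kwargs
        )
        reference = curve_posterior(full_post, structure, subject=subject, test=test)
    corr = float(pearsonr(estimate.mean, reference.mean).statistic)
    ratio = estimate.average_hwci / reference.average_hwci
    return PredictionResult(
        subject=subject,
        sessions_provided=sessions_provided,
        estimate=estimate,
        reference=reference,
        correlation=corr,
        hwci_ratio=ratio,
    )
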