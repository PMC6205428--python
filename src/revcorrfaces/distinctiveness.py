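"""Distinctiveness analyses: split-half Bayesian classification of fitted
expression models, d-prime analysis of validation responses, and the 2x2
chi-square helper.

The classifier is a Bernoulli naive Bayes over the 1 x 42 binary AU
vectors with Laplace smoothing; distinctiveness is summarized as the mean
posterior probability that a held-out model of each affect is classified
as each affect, aggregated over random split-half repetitions.
Perceptual discriminability of individual models is quantified with
d' = Phi^-1(hit rate) - Phi^-1(false-alarm rate) after a log-linear
correction, and each model lands in one of four quadrants by its hit and
false-alarm rates relative to 0.5.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_observer import ValidationTrial

QUADRANTS = ("discriminated", "ambiguous", "confused", "missed")


@dataclass(frozen=True)
class NBParams:
    """Trained Bernoulli naive-Bayes parameters.

    ``theta[c, j]`` is P(AU_j = 1 | class c) with Laplace smoothing
    (count + alpha) / (n_class + 2 alpha); priors are proportional to
    class sizes.
    """

    classes: tuple[str, ...]
    theta: np.ndarray
    priors: np.ndarray
    alpha: float


@dataclass
class ClassificationResult:
    """Split-half classification summary.

    ``posterior_matrix[i, j]`` is the mean posterior that a held-out
    model of true class i is classified as class j; ``posterior_sd`` is
    the standard deviation of the per-repetition means across the
    ``n_splits`` random splits, and ``posterior_sd_models`` the SD across
    held-out models (both reported because either convention is found in
    the literature).
    """

    classes: tuple[str, ...]
    posterior_matrix: np.ndarray
    posterior_sd: np.ndarray
    posterior_sd_models: np.ndarray
    n_splits: int

    def __post_init__(self) -> None:
        if not np.allclose(self.posterior_matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("posterior matrix rows must sum to 1")


@dataclass(frozen=True)
class DiscriminationOutcome:
    """Signal-detection summary for one displayed model."""

    model_id: str
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int
    hit_rate: float
    fa_rate: float
    dprime: float
    quadrant: str


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    """2x2 contingency table with labeled margins."""

    counts: np.ndarray
    row_labels: tuple[str, str]
    col_labels: tuple[str, str]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (2, 2) or (counts < 0).any():
            raise ValueError("counts must be a 2x2 non-negative table")
        if counts.sum() == 0:
            raise ValueError("table total must be positive")


def train_bernoulli_nb(
    X: np.ndarray,
    labels: Sequence[str],
    alpha: float = 1.0,
    classes: Sequence[str] | None = None,
) -> NBParams:
    """Train Bernoulli naive Bayes on binary model vectors.

    With ``alpha = 0`` an AU absent from a class gets probability 0,
    permitting -inf log-likelihoods; this is allowed but flagged.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = tuple(classes) if classes else tuple(sorted(set(labels.tolist())))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes (one or more is empty)")
    if alpha < 0:
        raise ValueError("smoothing alpha must be non-negative")
    theta = np.empty((len(classes), X.shape[1]))
    priors = np.empty(len(classes))
    for c, name in enumerate(classes):
        rows = X[labels == name]
        if len(rows) == 0:
            raise ValueError(f"empty class {name!r}")
        theta[c] = (rows.sum(axis=0) + alpha) / (len(rows) + 2.0 * alpha)
        priors[c] = len(rows)
    priors /= priors.sum()
    return NBParams(classes, theta, priors, alpha)


def posterior(nb: NBParams, vector: np.ndarray) -> np.ndarray:
    """Posterior class probabilities for one binary AU vector.

    Bayes rule over independent Bernoulli likelihoods across AUs,
    computed in log space; the returned pair sums to 1.
    """
    x = np.asarray(vector, dtype=float)
    with np.errstate(divide="ignore"):
        log_t = np.log(nb.theta)
        log_1mt = np.log1p(-nb.theta)
        # select per feature instead of multiplying, so 0 * -inf never occurs
        loglik = np.where(x[None, :] > 0, log_t, log_1mt).sum(axis=1)
        logpost = loglik + np.log(nb.priors)
    if np.all(np.isinf(logpost)):  # alpha=0 boundary in every class
        return np.full(len(nb.classes), 1.0 / len(nb.classes))
    logpost -= logpost.max()
    post = np.exp(logpost)
    return post / post.sum()


def split_half_classify(
    X: np.ndarray,
    labels: Sequence[str],
    n_splits: int = 1000,
    rng: np.random.Generator | None = None,
    alpha: float = 1.0,
) -> ClassificationResult:
    """Split-half naive-Bayes classification of binary model vectors.

    On each repetition every class is split into random halves; the
    classifier is trained on one half per class and the mean posterior is
    evaluated on the held-out halves.  The posterior matrix and its SDs
    aggregate over ``n_splits`` repetitions.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    rng = rng or np.random.default_rng()
    classes = tuple(sorted(set(labels.tolist())))
    idx_by_class = {c: np.flatnonzero(labels == c) for c in classes}
    for c, idx in idx_by_class.items():
        if len(idx) < 2:
            raise ValueError(f"class {c!r} needs at least 2 models to split")
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")

    k = len(classes)
    rep_means = np.empty((n_splits, k, k))
    sum_post = np.zeros((k, k))
    sumsq_post = np.zeros((k, k))
    n_held = np.zeros(k)
    for s in range(n_splits):
        train_idx, test_idx = [], []
        for c in classes:
            perm = rng.permutation(idx_by_class[c])
            half = len(perm) // 2
            train_idx.append(perm[:half])
            test_idx.append(perm[half:])
        nb = train_bernoulli_nb(
            X[np.concatenate(train_idx)],
            labels[np.concatenate(train_idx)],
            alpha,
        )
        for i, c in enumerate(classes):
            posts = np.vstack([posterior(nb, X[t]) for t in test_idx[i]])
            rep_means[s, i] = posts.mean(axis=0)
            sum_post[i] += posts.sum(axis=0)
            sumsq_post[i] += (posts**2).sum(axis=0)
            n_held[i] += len(posts)
    mean = rep_means.mean(axis=0)
    sd_splits = rep_means.std(axis=0)
    var_models = sumsq_post / n_held[:, None] - (sum_post / n_held[:, None]) ** 2
    sd_models = np.sqrt(np.maximum(var_models, 0.0))
    # renormalize rows against accumulated floating-point drift
    mean = mean / mean.sum(axis=1, keepdims=True)
    return ClassificationResult(classes, mean, sd_splits, sd_models, n_splits)


def _corrected_rates(
    hits: int, misses: int, false_alarms: int, correct_rejections: int
) -> tuple[float, float]:
    if hits + misses <= 0 or false_alarms + correct_rejections <= 0:
        raise ValueError("both signal and noise trial counts must be positive")
    h = (hits + 0.5) / (hits + misses + 1.0)
    f = (false_alarms + 0.5) / (false_alarms + correct_rejections + 1.0)
    return h, f


def _quadrant(hit_rate: float, fa_rate: float) -> str:
    """Quadrant by hit/false-alarm rates versus 0.5 (ties leave the
    discriminated quadrant)."""
    high_h = hit_rate > 0.5
    low_f = fa_rate < 0.5
    if high_h and low_f:
        return "discriminated"
    if high_h:
        return "ambiguous"
    if low_f:
        return "missed"
    return "confused"


def dprime(
    hits: int, misses: int, false_alarms: int, correct_rejections: int
) -> tuple[float, str]:
    """d' from response counts, with the log-linear correction.

    0.5 is added to every cell and 1 to each denominator before the
    inverse-normal transform (applied always, to avoid conditional
    bias); the quadrant uses the corrected rates against 0.5.
    """
    h, f = _corrected_rates(hits, misses, false_alarms, correct_rejections)
    return dprime_from_rates(h, f), _quadrant(h, f)


def dprime_from_rates(hit_rate: float, fa_rate: float) -> float:
    """d' directly from (already corrected or interior) rates."""
    if not (0.0 < hit_rate < 1.0 and 0.0 < fa_rate < 1.0):
        raise ValueError("rates must lie strictly inside (0, 1)")
    return float(stats.norm.ppf(hit_rate) - stats.norm.ppf(fa_rate))


def discrimination_outcome(
    model_id: str, hits: int, misses: int, false_alarms: int, correct_rejections: int
) -> DiscriminationOutcome:
    h, f = _corrected_rates(hits, misses, false_alarms, correct_rejections)
    d, quad = dprime(hits, misses, false_alarms, correct_rejections)
    return DiscriminationOutcome(
        model_id, hits, misses, false_alarms, correct_rejections, h, f, d, quad
    )


def discrimination_from_validation(
    sessions: Iterable[Sequence[ValidationTrial]],
) -> list[DiscriminationOutcome]:
    """Pool validation responses across observers into per-model d'.

    A hit is a yes on a matched trial; a false alarm a yes on a
    mismatched trial.
    """
    tallies: dict[str, np.ndarray] = defaultdict(lambda: np.zeros(4, dtype=int))
    for session in sessions:
        for t in session:
            cell = (0 if t.answer else 1) if t.matched else (2 if t.answer else 3)
            tallies[t.model_id][cell] += 1
    return [
        discrimination_outcome(model_id, *counts)
        for model_id, counts in sorted(tallies.items())
    ]


def outcomes_to_frame(outcomes: Sequence[DiscriminationOutcome]) -> pd.DataFrame:
    """Tabular export of per-model discrimination outcomes, ranked by d'."""
    df = pd.DataFrame([o.__dict__ for o in outcomes])
    return df.sort_values("dprime", ascending=False).reset_index(drop=True)


def chi_square_2x2(confusion: ConfusionMatrix2x2) -> tuple[float, int, float]:
    """Uncorrected Pearson chi-square for a 2x2 table.

    statistic = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), df = 1; no Yates
    correction.
    """
    (a, b), (c, d) = confusion.counts.astype(float)
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("all margins of the 2x2 table must be positive")
    n = a + b + c + d
    statistic = n * (a * d - b * c) ** 2 / np.prod(margins)
    p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), 1, p
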