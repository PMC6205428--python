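"""Frequent-AU detection and mutual-information analyses with Monte Carlo
permutation nulls.

Two screening steps operate on stacks of binary AU model vectors.  First,
*highly frequent* AUs are those appearing across individual observer
models more often than a Monte Carlo null in which each model's AU
positions are permuted (preserving its AU count); the observed count must
exceed the 95th percentile of the per-iteration maxima (one-tailed
p < .05, familywise).  Second, the association between AU presence and a
binary label (affect, or culture) is measured with the plug-in mutual
information in bits and tested with a maximum-statistic permutation
scheme: labels are shuffled 1,000 times, the maximum MI across tested AUs
is recorded each time, and observed values above the 95th percentile of
that maximum distribution are significant — controlling the familywise
error across the tested AUs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .stimgen import DEFAULT_CATALOG, ActionUnitCatalog


@dataclass
class MIResult:
    """Outcome of a max-statistic mutual-information permutation test."""

    tested_aus: list[int]
    mi_bits: dict[int, float]
    null_max_distribution: np.ndarray
    threshold_95: float
    significant_aus: set[int]
    class_names: tuple[str, str]
    #: per-AU presence rate within each class, ``{au: (rate_0, rate_1)}``
    rates: dict[int, tuple[float, float]]
    partition: dict[int, str] = field(default_factory=dict)


def au_frequencies(models: np.ndarray) -> np.ndarray:
    """Count of models containing each AU (column sums)."""
    X = np.asarray(models)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("need a non-empty (n_models, n_aus) matrix")
    return X.sum(axis=0).astype(int)


def _percentile_nearest_rank(values: np.ndarray, q: float) -> float:
    """Nearest-rank percentile (the ceil(q m)-th order statistic)."""
    v = np.sort(np.asarray(values, dtype=float))
    idx = int(np.ceil(q * len(v))) - 1
    return float(v[max(idx, 0)])


def _null_max_counts(
    X: np.ndarray,
    n_iter: int,
    rng: np.random.Generator,
    method: str,
) -> np.ndarray:
    """Per-iteration maximum AU count under the frequent-AU null.

    ``within_model`` permutes each model's AU positions uniformly
    (preserving per-model AU counts); ``pooled`` draws each model's AUs
    without replacement with probabilities proportional to the pooled
    observed AU frequencies.
    """
    n_models, n_aus = X.shape
    k = X.sum(axis=1).astype(int)
    maxima = np.empty(n_iter)
    if method == "within_model":
        rand = rng.random((n_iter, n_models, n_aus))
        counts = np.zeros((n_iter, n_aus))
        for kk in np.unique(k):
            if kk == 0:
                continue
            rows = np.flatnonzero(k == kk)
            sub = rand[:, rows, :]
            kth = np.partition(sub, kk - 1, axis=2)[:, :, kk - 1 : kk]
            counts += (sub <= kth).sum(axis=1)
        maxima = counts.max(axis=1)
    elif method == "pooled":
        freq = X.sum(axis=0).astype(float)
        if freq.sum() == 0:
            raise ValueError("all-empty models")
        # Gumbel-max trick for weighted sampling without replacement
        with np.errstate(divide="ignore"):
            logw = np.log(freq)
        for it in range(n_iter):
            counts = np.zeros(n_aus)
            g = logw + rng.gumbel(size=(n_models, n_aus))
            for m in range(n_models):
                if k[m] == 0:
                    continue
                top = np.argpartition(-g[m], k[m] - 1)[: k[m]]
                counts[top] += 1
            maxima[it] = counts.max()
    else:
        raise ValueError("method must be 'within_model' or 'pooled'")
    return maxima


def highly_frequent(
    models: np.ndarray,
    n_iter: int = 1000,
    rng: np.random.Generator | None = None,
    catalog: ActionUnitCatalog | None = None,
    method: str = "within_model",
    return_details: bool = False,
):
    """AUs that are highly frequent across models (one-tailed p < .05).

    Returns the set of AU ids whose observed count strictly exceeds the
    nearest-rank 95th percentile of the null per-iteration maxima.  With
    ``return_details`` a ``(flagged, counts, threshold)`` triple is
    returned instead.
    """
    X = np.asarray(models, dtype=np.uint8)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("need at least 2 models")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    catalog = catalog or DEFAULT_CATALOG
    if X.shape[1] != catalog.size:
        raise ValueError("model vectors do not match the catalog size")
    rng = rng or np.random.default_rng()
    counts = au_frequencies(X)
    maxima = _null_max_counts(X, n_iter, rng, method)
    threshold = _percentile_nearest_rank(maxima, 0.95)
    flagged = {int(catalog.ids[j]) for j in np.flatnonzero(counts > threshold)}
    if return_details:
        return flagged, counts, threshold
    return flagged


def _mi_from_counts(n11, n10, n01, n00) -> np.ndarray:
    """Plug-in MI in bits from 2x2 joint counts (broadcasting).

    Empty cells contribute zero.
    """
    n11, n10, n01, n00 = (np.asarray(v, dtype=float) for v in (n11, n10, n01, n00))
    n = n11 + n10 + n01 + n00
    mi = np.zeros(np.broadcast(n11, n10, n01, n00).shape)
    for nxy, nx, ny in (
        (n11, n11 + n10, n11 + n01),
        (n10, n11 + n10, n10 + n00),
        (n01, n01 + n00, n11 + n01),
        (n00, n01 + n00, n10 + n00),
    ):
        with np.errstate(divide="ignore", invalid="ignore"):
            term = nxy / n * np.log2(nxy * n / (nx * ny))
        mi += np.where(nxy > 0, term, 0.0)
    return np.maximum(mi, 0.0)


def mi_binary(presence, labels) -> float:
    """Plug-in mutual information (bits) between two binary vectors.

    Constant vectors are allowed and give MI = 0.
    """
    x = np.asarray(presence).astype(bool)
    y = np.asarray(labels).astype(bool)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    n11 = int(np.sum(x & y))
    n10 = int(np.sum(x & ~y))
    n01 = int(np.sum(~x & y))
    n00 = int(np.sum(~x & ~y))
    return float(_mi_from_counts(n11, n10, n01, n00))


def maxT_mi_test(
    models: np.ndarray,
    labels: Sequence,
    restrict_to: Iterable[int] | None = None,
    n_iter: int = 1000,
    rng: np.random.Generator | None = None,
    catalog: ActionUnitCatalog | None = None,
) -> MIResult:
    """Max-statistic MI permutation test over the restricted AU set.

    The binary ``labels`` are shuffled ``n_iter`` times; each iteration
    records the maximum MI across all tested AUs.  The observed MI is
    included in the null distribution before taking the nearest-rank
    95th percentile (guaranteeing validity); observed values strictly
    above the threshold are significant.
    """
    X = np.asarray(models, dtype=float)
    labels = np.asarray(labels)
    catalog = catalog or DEFAULT_CATALOG
    rng = rng or np.random.default_rng()
    if X.ndim != 2 or X.shape[0] != len(labels):
        raise ValueError("models and labels must align")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    names = tuple(sorted(set(labels.tolist())))
    if len(names) != 2:
        raise ValueError("labels must contain exactly 2 classes")
    y = (labels == names[1]).astype(float)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least 2 models per class")
    if restrict_to is None:
        tested = [int(a) for a in catalog.ids if X[:, catalog.index(a)].sum() > 0]
    else:
        tested = sorted(int(a) for a in restrict_to)
    if not tested:
        raise ValueError("restricted AU set must not be empty")
    cols = np.array([catalog.index(a) for a in tested])
    Xr = X[:, cols]

    n = len(y)
    ny = y.sum()
    colsum = Xr.sum(axis=0)
    observed = _mi_from_counts(
        y @ Xr, (1 - y) @ Xr, ny - y @ Xr, (n - ny) - (1 - y) @ Xr
    )

    perms = np.empty((n_iter, n))
    for i in range(n_iter):
        perms[i] = rng.permutation(y)
    n11 = perms @ Xr  # (n_iter, k): presence=1 & label=1
    null_mi = _mi_from_counts(n11, colsum[None, :] - n11, ny - n11,
                              (n - ny) - (colsum[None, :] - n11))
    null_max = np.append(null_mi.max(axis=1), observed.max())
    threshold = _percentile_nearest_rank(null_max, 0.95)
    significant = {a for a, mi in zip(tested, observed) if mi > threshold}

    rate1 = (y @ Xr) / ny
    rate0 = ((1 - y) @ Xr) / (n - ny)
    return MIResult(
        tested_aus=tested,
        mi_bits={a: float(mi) for a, mi in zip(tested, observed)},
        null_max_distribution=null_max,
        threshold_95=threshold,
        significant_aus=significant,
        class_names=(str(names[0]), str(names[1])),
        rates={a: (float(r0), float(r1)) for a, r0, r1 in zip(tested, rate0, rate1)},
    )


def specific_common_partition(
    mi: MIResult,
    freq_A: Iterable[int],
    freq_B: Iterable[int],
) -> dict[int, str]:
    """Partition tested AUs into specific / common / unclassified.

    Significant AUs frequent in exactly one class are *specific* to the
    class with the higher presence rate; non-significant AUs frequent in
    both classes are *common*; everything else is reported as
    unclassified rather than forced into a category.  The result is also
    stored on ``mi.partition``.
    """
    fa, fb = set(freq_A), set(freq_B)
    name_a, name_b = mi.class_names
    partition: dict[int, str] = {}
    for au in mi.tested_aus:
        in_a, in_b = au in fa, au in fb
        sig = au in mi.significant_aus
        if sig and (in_a != in_b):
            r0, r1 = mi.rates[au]
            partition[au] = f"specific_{name_a}" if r0 > r1 else f"specific_{name_b}"
        elif not sig and in_a and in_b:
            partition[au] = "common"
        else:
            partition[au] = "unclassified"
    mi.partition = partition
    return partition


def cross_culture_test(
    models_culture1: np.ndarray,
    models_culture2: np.ndarray,
    culture_names: tuple[str, str] = ("western", "east_asian"),
    restrict_to: Iterable[int] | None = None,
    n_iter: int = 1000,
    rng: np.random.Generator | None = None,
    catalog: ActionUnitCatalog | None = None,
    freq_n_iter: int = 1000,
) -> MIResult:
    """Cross-cultural MI test for one affect's models.

    Identical machinery to :func:`maxT_mi_test` with culture as the
    label.  When ``restrict_to`` is not given it defaults to the union
    of each culture's highly frequent AUs, and the specific/common
    partition over that union is filled in.
    """
    X1 = np.asarray(models_culture1, dtype=np.uint8)
    X2 = np.asarray(models_culture2, dtype=np.uint8)
    if len(X1) == 0 or len(X2) == 0:
        raise ValueError("both cultures must be represented")
    rng = rng or np.random.default_rng()
    freq1 = freq2 = None
    if restrict_to is None:
        freq1 = highly_frequent(X1, freq_n_iter, rng, catalog)
        freq2 = highly_frequent(X2, freq_n_iter, rng, catalog)
        restrict_to = freq1 | freq2
        if not restrict_to:
            # tiny cohorts may flag nothing; fall back to every AU present
            restrict_to = None
    X = np.vstack([X1, X2])
    labels = np.array([culture_names[0]] * len(X1) + [culture_names[1]] * len(X2))
    result = maxT_mi_test(X, labels, restrict_to, n_iter, rng, catalog)
    if freq1 is not None:
        specific_common_partition(result, freq1, freq2)
    return result
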