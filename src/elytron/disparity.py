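"""Disparity metrics per time-bin and resampling inference.

Disparity of a set of taxa is measured on their ordination scores over a
fixed set of retained axes (for PCoA, the shortest prefix of axes
reaching 90% of total variance; for NMDS, all k axes):

* ``sov`` — sum over axes of the sample variance (n-1 denominator);
* ``pov`` — nth root of the product of per-axis variances, n = number
  of retained axes (the geometric mean of the variances).

Uncertainty is bootstrapped by resampling taxa with replacement.  Two
tests compare an older against a younger bin, with the test statistic
T = disparity(older) - disparity(younger):

* a plain two-tailed permutation test: taxa are pooled and repartitioned
  into groups of the original sizes; the reported proportion is the
  fraction of null statistics strictly greater than the observed T, and
  the decision uses the 0.025 / 0.975 thresholds;
* a subsampling-corrected variant for unequal sizes: per replicate the
  larger group is subsampled without replacement to the smaller size,
  an observed T is computed on the equal-size pair, then one permutation
  of the pooled equal-size groups yields one null T.  Each observed T is
  ranked against the pooled null distribution and the median of these
  proportions is reported (thresholds <= 0.025 / >= 0.975).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from elytron.ordination import OrdinationResult
from elytron.timebins import TimeBin

logger = logging.getLogger(__name__)

DECISION_OLDER = "older_larger"
DECISION_YOUNGER = "younger_larger"
DECISION_NONE = "not_significant"


@dataclass
class AxisSelection:
    indices: np.ndarray  # retained axis indices (0-based, prefix)
    cumulative_variance: float
    rule: str

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)


@dataclass
class DisparityEstimate:
    bin: TimeBin | str
    metric: str
    n_taxa: int
    value: float
    bootstrap_distribution: np.ndarray | None = None
    ci_low: float | None = None
    ci_high: float | None = None


@dataclass
class PermutationResult:
    older_bin: TimeBin | str
    younger_bin: TimeBin | str
    metric: str
    observed_T: float
    proportion: float
    replications: int
    decision: str
    seed: int
    test: str = "plain"  # "plain" | "subsampled"


def select_axes(o: OrdinationResult, rule: str = "cumulative_90") -> AxisSelection:
    """Retained-axis prefix for disparity.

    ``cumulative_90`` (PCoA only): shortest prefix of axes whose
    cumulative variance fraction reaches 0.90.  ``all_axes``: every axis
    (the only legal rule for NMDS).
    """
    if rule == "all_axes":
        return AxisSelection(
            indices=np.arange(o.n_axes), cumulative_variance=1.0, rule=rule
        )
    if rule == "cumulative_90":
        if o.method != "PCoA" or o.axis_variance is None:
            raise ValueError("cumulative_90 requires a PCoA result with axis variances")
        cum = np.cumsum(o.axis_variance)
        stop = int(np.searchsorted(cum, 0.90 - 1e-12)) + 1
        stop = min(stop, o.n_axes)
        return AxisSelection(
            indices=np.arange(stop),
            cumulative_variance=float(cum[stop - 1]),
            rule=rule,
        )
    raise ValueError(f"unknown axis rule {rule!r}")


def _variances(scores: np.ndarray) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("scores must be a 2-D taxa x axes grid")
    if scores.shape[0] < 2:
        raise ValueError("disparity needs at least 2 taxa")
    return scores.var(axis=0, ddof=1)


def sum_of_variances(scores: np.ndarray) -> float:
    """Sum over retained axes of the sample variance of scores."""
    return float(_variances(scores).sum())


def product_of_variances(scores: np.ndarray) -> float:
    """nth-root-normalized product of per-axis sample variances."""
    v = _variances(scores)
    if (v <= 0).any():
        return 0.0
    return float(np.exp(np.mean(np.log(v))))


_METRICS = {"sov": sum_of_variances, "pov": product_of_variances}


def _batch_metric(samples: np.ndarray, metric: str) -> np.ndarray:
    """Metric over axis 1 of a (reps, n, k) stack, vectorized."""
    v = samples.var(axis=1, ddof=1)  # (reps, k)
    if metric == "sov":
        return v.sum(axis=1)
    if metric == "pov":
        out = np.zeros(v.shape[0])
        ok = (v > 0).all(axis=1)
        out[ok] = np.exp(np.log(v[ok]).mean(axis=1))
        return out
    raise ValueError(f"unknown metric {metric!r}")


def bootstrap_disparity(
    scores: np.ndarray,
    metric: str = "sov",
    reps: int = 500,
    seed: int = 0,
) -> DisparityEstimate:
    """Bootstrap distribution and 95% CI of a disparity metric.

    Taxa (rows) are resampled with replacement at the original sample
    size; the 2.5% and 97.5% empirical quantiles bound the CI.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    scores = np.asarray(scores, dtype=float)
    point = _METRICS[metric](scores)
    rng = np.random.default_rng(seed)
    n = scores.shape[0]
    idx = rng.integers(0, n, size=(reps, n))
    dist = _batch_metric(scores[idx], metric)
    return DisparityEstimate(
        bin="",
        metric=metric,
        n_taxa=n,
        value=point,
        bootstrap_distribution=dist,
        ci_low=float(np.quantile(dist, 0.025)),
        ci_high=float(np.quantile(dist, 0.975)),
    )


def _decide(proportion: float, strict: bool) -> str:
    if strict:
        if proportion < 0.025:
            return DECISION_OLDER
        if proportion > 0.975:
            return DECISION_YOUNGER
    else:
        if proportion <= 0.025:
            return DECISION_OLDER
        if proportion >= 0.975:
            return DECISION_YOUNGER
    return DECISION_NONE


def _permutation_indices(rng, reps: int, n: int) -> np.ndarray:
    """(reps, n) independent permutations of range(n)."""
    return np.argsort(rng.random((reps, n)), axis=1)


# replicate batches are sized so intermediate (reps, n, k) stacks stay
# within a fixed element budget; results are exact regardless of chunking
_CHUNK_ELEMENTS = 20_000_000


def _chunk_sizes(reps: int, n: int, k: int) -> list[int]:
    per = max(1, _CHUNK_ELEMENTS // max(1, n * k))
    sizes = [per] * (reps // per)
    if reps % per:
        sizes.append(reps % per)
    return sizes


def permutation_test(
    scores_old: np.ndarray,
    scores_young: np.ndarray,
    metric: str = "sov",
    reps: int = 5000,
    seed: int = 0,
    older_bin: TimeBin | str = "older",
    younger_bin: TimeBin | str = "younger",
) -> PermutationResult:
    """Two-tailed permutation test of equal disparity between two bins.

    Null replicates pool all taxa and repartition them at random into
    groups of the original sizes.  ``proportion`` is the fraction of
    null statistics strictly greater than the observed one; ties count
    as not greater.
    """
    scores_old = np.asarray(scores_old, dtype=float)
    scores_young = np.asarray(scores_young, dtype=float)
    if scores_old.shape[0] < 2 or scores_young.shape[0] < 2:
        raise ValueError("each group needs at least 2 taxa")
    if scores_old.shape[1] != scores_young.shape[1]:
        raise ValueError("groups must share the same retained axes")
    fn = _METRICS[metric]
    observed = fn(scores_old) - fn(scores_young)
    pooled = np.vstack([scores_old, scores_young])
    n1 = scores_old.shape[0]
    rng = np.random.default_rng(seed)
    null_parts = []
    for chunk in _chunk_sizes(reps, pooled.shape[0], pooled.shape[1]):
        perm = _permutation_indices(rng, chunk, pooled.shape[0])
        null_parts.append(
            _batch_metric(pooled[perm[:, :n1]], metric)
            - _batch_metric(pooled[perm[:, n1:]], metric)
        )
    null = np.concatenate(null_parts)
    proportion = float((null > observed).sum() / reps)
    return PermutationResult(
        older_bin=older_bin,
        younger_bin=younger_bin,
        metric=metric,
        observed_T=float(observed),
        proportion=proportion,
        replications=reps,
        decision=_decide(proportion, strict=True),
        seed=seed,
        test="plain",
    )


def subsampled_permutation_test(
    scores_old: np.ndarray,
    scores_young: np.ndarray,
    metric: str = "sov",
    reps: int = 10000,
    seed: int = 0,
    older_bin: TimeBin | str = "older",
    younger_bin: TimeBin | str = "younger",
) -> PermutationResult:
    """Sample-size-corrected permutation test for unequal group sizes.

    Each replicate subsamples the larger group to the smaller size,
    records an observed statistic on the equal-size pair, then permutes
    the pooled equal-size groups once for one null statistic.  All null
    statistics are pooled into a single null distribution; each observed
    statistic's exceedance proportion is computed against it, and the
    median proportion drives the decision (older larger if <= 0.025,
    younger larger if >= 0.975).

    Equal-size inputs fall back to the plain permutation test.
    """
    scores_old = np.asarray(scores_old, dtype=float)
    scores_young = np.asarray(scores_young, dtype=float)
    if scores_old.shape[0] < 2 or scores_young.shape[0] < 2:
        raise ValueError("each group needs at least 2 taxa")
    if scores_old.shape[1] != scores_young.shape[1]:
        raise ValueError("groups must share the same retained axes")
    n_old, n_young = scores_old.shape[0], scores_young.shape[0]
    if n_old == n_young:
        logger.info("equal group sizes: falling back to plain permutation test")
        result = permutation_test(
            scores_old, scores_young, metric=metric, reps=reps, seed=seed,
            older_bin=older_bin, younger_bin=younger_bin,
        )
        result.test = "subsampled(fallback=plain)"
        return result

    rng = np.random.default_rng(seed)
    m = min(n_old, n_young)
    old_is_larger = n_old > n_young
    larger = scores_old if old_is_larger else scores_young
    smaller = scores_young if old_is_larger else scores_old

    small_metric = _METRICS[metric](smaller)
    k = smaller.shape[1]
    observed_parts, null_parts = [], []
    for chunk in _chunk_sizes(reps, 2 * m, k):
        sub_idx = _permutation_indices(rng, chunk, larger.shape[0])[:, :m]
        sub = larger[sub_idx]  # (chunk, m, k)
        if old_is_larger:
            observed_parts.append(_batch_metric(sub, metric) - small_metric)
        else:
            observed_parts.append(small_metric - _batch_metric(sub, metric))
        small = np.broadcast_to(smaller, (chunk, m, k))
        pooled = np.concatenate([sub, small], axis=1)  # (chunk, 2m, k)
        perm = _permutation_indices(rng, chunk, 2 * m)
        g1 = np.take_along_axis(pooled, perm[:, :m, None], axis=1)
        g2 = np.take_along_axis(pooled, perm[:, m:, None], axis=1)
        null_parts.append(_batch_metric(g1, metric) - _batch_metric(g2, metric))
    observed = np.concatenate(observed_parts)
    null = np.concatenate(null_parts)

    null_sorted = np.sort(null)
    # fraction of pooled null strictly greater than each observed value
    greater = reps - np.searchsorted(null_sorted, observed, side="right")
    proportions = greater / reps
    median_p = float(np.median(proportions))
    return PermutationResult(
        older_bin=older_bin,
        younger_bin=younger_bin,
        metric=metric,
        observed_T=float(np.median(observed)),
        proportion=median_p,
        replications=reps,
        decision=_decide(median_p, strict=False),
        seed=seed,
        test="subsampled",
    )
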