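"""Morphospace ordination: principal coordinates and non-metric MDS.

PCoA eigendecomposes the double-centered matrix of squared distances.
Discrete-character distances are generally non-Euclidean, producing
negative eigenvalues; the Cailliez correction adds the smallest constant
to every off-diagonal distance that makes the matrix Euclidean-
embeddable.

NMDS minimizes Kruskal's stress-1,

    stress = sqrt( sum (d_ij - dhat_ij)^2 / sum d_ij^2 ),

where d_ij are configuration distances and dhat_ij the monotone
(isotonic) regression of d_ij on the rank order of the input
dissimilarities.  Minimization alternates isotonic fits with Guttman
transform updates, from one PCoA-derived start plus a number of random
starts, keeping the lowest-stress solution.  Ties in the input
dissimilarities use Kruskal's primary treatment: tied dissimilarities
may receive unequal fitted values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from elytron.distances import DistanceMatrix

logger = logging.getLogger(__name__)

EIG_REL_TOL = 1e-8


class ConvergenceError(RuntimeError):
    def __init__(self, best_stress: float):
        self.best_stress = best_stress
        super().__init__(f"NMDS failed to converge; best stress {best_stress:.4f}")


@dataclass
class OrdinationResult:
    """Taxon scores on ordered axes plus method diagnostics."""

    labels: list[str]
    scores: np.ndarray  # taxa x axes
    method: str  # "PCoA" | "NMDS"
    eigenvalues: np.ndarray | None = None  # PCoA
    axis_variance: np.ndarray | None = None  # PCoA: fraction per axis
    correction_constant: float | None = None  # PCoA + cailliez
    stress: float | None = None  # NMDS
    nonmetric_fit: float | None = None  # NMDS: 1 - stress^2
    linear_fit: float | None = None  # NMDS
    seed: int | None = None  # NMDS
    dropped_taxa: list[str] = field(default_factory=list)

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]

    def scores_for(self, taxa: list[str]) -> np.ndarray:
        idx = [self.labels.index(t) for t in taxa]
        return self.scores[idx]

    def write_tsv(self, path) -> None:
        cols = [f"axis_{k + 1}" for k in range(self.n_axes)]
        pd.DataFrame(self.scores, index=self.labels, columns=cols).rename_axis(
            "taxon"
        ).to_csv(path, sep="\t")


def _check_square(d: DistanceMatrix) -> np.ndarray:
    D = np.asarray(d.d, dtype=float)
    if np.isnan(D).any():
        raise ValueError(
            "distance matrix has missing pairs; trim taxa first "
            "(see trim_missing_pairs)"
        )
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    return D


def trim_missing_pairs(d: DistanceMatrix) -> tuple[DistanceMatrix, list[str]]:
    """Greedily remove the taxa responsible for NaN pairs.

    Repeatedly drops the taxon involved in the most missing pairs until
    none remain; returns the trimmed matrix and the dropped labels.
    """
    D = np.array(d.d, dtype=float)
    keep = list(range(d.n))
    dropped: list[str] = []
    while True:
        sub = D[np.ix_(keep, keep)]
        counts = np.isnan(sub).sum(axis=0)
        if counts.sum() == 0:
            break
        worst = keep[int(np.argmax(counts))]
        dropped.append(d.labels[worst])
        keep.remove(worst)
    if dropped:
        logger.warning("trimmed %d taxa with missing distances: %s",
                       len(dropped), dropped)
    return d.subset([d.labels[i] for i in keep]), dropped


def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D**2
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def cailliez_constant(d: DistanceMatrix) -> float:
    """Smallest c >= 0 with D + c (off-diagonal) Euclidean-embeddable.

    Computed as the largest real eigenvalue of the 2n x 2n companion
    problem of Cailliez (block matrix of the centered -D^2/2 and -D/2
    forms); clipped to 0 when the input is already Euclidean.
    """
    D = _check_square(d)
    B = _gower_center(D)
    ev = np.linalg.eigvalsh(B)
    if ev.min() >= -EIG_REL_TOL * max(ev.max(), 1.0):
        return 0.0
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    delta1 = B
    delta2 = J @ (-0.5 * D) @ J
    upper = np.hstack([np.zeros((n, n)), 2 * delta1])
    lower = np.hstack([-np.eye(n), -4 * delta2])
    special = np.vstack([upper, lower])
    eigs = np.linalg.eigvals(special)
    c = float(np.max(eigs.real))
    return max(c, 0.0)


def _apply_cailliez(D: np.ndarray, c: float) -> np.ndarray:
    out = D + c
    np.fill_diagonal(out, 0.0)
    return out


def pcoa(d: DistanceMatrix, correction: str = "cailliez") -> OrdinationResult:
    """Principal coordinates of a distance matrix.

    With ``correction="cailliez"`` the Cailliez constant is added to all
    off-diagonal distances first.  Axes with eigenvalue below the
    relative tolerance are dropped; per-axis variance fractions are
    eigenvalue / sum of positive eigenvalues.  Each axis is oriented so
    its largest-magnitude loading is positive.
    """
    D = _check_square(d)
    if d.n < 3:
        raise ValueError("PCoA needs at least 3 taxa")
    if correction == "cailliez":
        c = cailliez_constant(d)
        D = _apply_cailliez(D, c)
    elif correction == "none":
        c = None
    else:
        raise ValueError(f"unknown correction {correction!r}")
    B = _gower_center(D)
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = EIG_REL_TOL * max(eigvals.max(), 1.0)
    keep = eigvals > tol
    lam = eigvals[keep]
    scores = eigvecs[:, keep] * np.sqrt(lam)
    # reproducible sign convention: dominant loading positive
    for k in range(scores.shape[1]):
        if scores[np.argmax(np.abs(scores[:, k])), k] < 0:
            scores[:, k] = -scores[:, k]
    total = lam.sum()
    return OrdinationResult(
        labels=list(d.labels),
        scores=scores,
        method="PCoA",
        eigenvalues=lam,
        axis_variance=lam / total if total > 0 else np.zeros_like(lam),
        correction_constant=c,
    )


def _stress1(dist: np.ndarray, fitted: np.ndarray) -> float:
    denom = (dist**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dist - fitted) ** 2).sum() / denom))


def _monotone_fit(dist: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Isotonic regression of configuration distances on rank order."""
    fitted = np.empty_like(dist)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    fitted[order] = iso.fit_transform(np.arange(order.size), dist[order])
    return fitted


def _kruskal_descent(
    delta_order: np.ndarray,
    X0: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, float, list[float]]:
    """Minimize stress-1 from one start; returns (config, stress, trace)."""
    X = X0 - X0.mean(axis=0)
    n = X.shape[0]
    dist = pdist(X)
    fitted = _monotone_fit(dist, delta_order)
    stress = _stress1(dist, fitted)
    trace = [stress]
    best_X, best_stress = X.copy(), stress
    stall = 0
    for _ in range(max_iter):
        # Guttman transform with the monotone-fitted values as disparities
        ratio = np.where(dist > 0, fitted / dist, 0.0)
        R = squareform(ratio)
        Bmat = -R
        np.fill_diagonal(Bmat, R.sum(axis=1))
        X = Bmat @ X / n
        X -= X.mean(axis=0)
        dist = pdist(X)
        fitted = _monotone_fit(dist, delta_order)
        stress = _stress1(dist, fitted)
        # the trace records accepted (improving) configurations only,
        # so it is non-increasing; transient wobbles are discarded
        if stress < best_stress - tol:
            best_X, best_stress = X.copy(), stress
            trace.append(stress)
            stall = 0
        else:
            if stress < best_stress:
                best_X, best_stress = X.copy(), stress
                trace.append(stress)
            stall += 1
            if stall >= 10:
                break
    return best_X, best_stress, trace


def nmds(
    d: DistanceMatrix,
    k: int = 3,
    restarts: int = 20,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
    stress_ceiling: float = 0.999,
) -> OrdinationResult:
    """Non-metric MDS in ``k`` dimensions by stress-1 minimization.

    Runs one PCoA-seeded start plus ``restarts`` random starts and keeps
    the lowest-stress configuration.  Deterministic given ``seed``.
    Raises :class:`ConvergenceError` (carrying the best stress found) if
    every start ends essentially unordered (stress >= ``stress_ceiling``).
    """
    D = _check_square(d)
    if k < 2:
        raise ValueError("k must be >= 2")
    if d.n < k + 1:
        raise ValueError(f"need more than {k} taxa for a {k}-dimensional NMDS")
    rng = np.random.default_rng(seed)
    delta = squareform(D, checks=False)
    # primary tie treatment: within tied dissimilarities the fit is free,
    # so sorting is by dissimilarity only (stable), leaving ties adjacent
    delta_order = np.argsort(delta, kind="stable")

    starts: list[np.ndarray] = []
    try:
        metric_start = pcoa(d, correction="cailliez").scores
        if metric_start.shape[1] >= k:
            starts.append(metric_start[:, :k])
        else:
            pad = np.zeros((d.n, k - metric_start.shape[1]))
            starts.append(np.hstack([metric_start, pad]))
    except ValueError:
        pass
    scale = max(delta.max(), 1.0)
    for _ in range(restarts):
        starts.append(rng.normal(scale=scale, size=(d.n, k)))

    best: tuple[np.ndarray, float] | None = None
    for X0 in starts:
        X, stress, _ = _kruskal_descent(delta_order, X0, max_iter, tol)
        if best is None or stress < best[1]:
            best = (X, stress)
    assert best is not None
    X, stress = best
    if stress >= stress_ceiling:
        raise ConvergenceError(stress)

    # orientation convention as for PCoA: align to principal axes first
    X = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    X = X @ Vt.T
    for kk in range(X.shape[1]):
        if X[np.argmax(np.abs(X[:, kk])), kk] < 0:
            X[:, kk] = -X[:, kk]

    result = OrdinationResult(
        labels=list(d.labels),
        scores=X,
        method="NMDS",
        stress=stress,
        nonmetric_fit=1.0 - stress**2,
        seed=seed,
    )
    nonmetric, linear = goodness_of_fit(result, d)
    result.nonmetric_fit = nonmetric
    result.linear_fit = linear
    return result


def goodness_of_fit(o: OrdinationResult, d: DistanceMatrix) -> tuple[float, float]:
    """(non-metric R^2, linear R^2) of an NMDS solution against ``d``.

    Non-metric R^2 is 1 - stress^2; linear R^2 is the squared Pearson
    correlation between configuration distances and the monotone-fitted
    values (the Shepard-diagram fit).
    """
    if o.method != "NMDS":
        raise ValueError("goodness_of_fit applies to NMDS results")
    D = _check_square(d)
    delta = squareform(D, checks=False)
    dist = pdist(o.scores)
    fitted = _monotone_fit(dist, np.argsort(delta, kind="stable"))
    stress = _stress1(dist, fitted)
    nonmetric = 1.0 - stress**2
    if np.std(dist) == 0 or np.std(fitted) == 0:
        linear = 1.0
    else:
        linear = float(np.corrcoef(dist, fitted)[0, 1] ** 2)
    return nonmetric, linear
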