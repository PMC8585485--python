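"""Inter-taxon distances from discrete characters: MORD and GED.

Both metrics start from per-character differences: for a character that
is scored (neither missing nor inapplicable) in both taxa, the
difference is a 0/1 mismatch indicator for unordered characters and
|a - b| for ordered ones; polymorphic cells take the minimum difference
over the cross-product of their state sets.  Characters unscored in
either taxon are incomparable.

MORD (maximum observable rescaled distance) rescales each comparable
difference by the character's maximum possible difference and averages
over comparable characters, giving a Gower-type coefficient in [0, 1]
that ignores incomparable characters entirely.

GED (generalized Euclidean distance) instead imputes each incomparable
character with the mean of that pair's observed raw differences and
takes the Euclidean norm over all characters.  Under heavy missing data
this imputation inflates distances, which is why MORD is preferred for
fossil matrices.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from elytron.charmatrix import (
    INAPPLICABLE,
    MISSING,
    CharacterMatrix,
    _cell_states,
)

logger = logging.getLogger(__name__)


class IncomparablePairError(ValueError):
    """A taxon pair shares no scored character."""


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances plus per-pair comparable counts.

    ``d`` may contain NaN for MORD pairs with no comparable characters
    (reported by :func:`mord_distance`); such taxa are trimmed before
    ordination.
    """

    labels: list[str]
    d: np.ndarray
    comparable: np.ndarray
    metric_tag: str

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.comparable = np.asarray(self.comparable, dtype=int)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError(f"distance grid {self.d.shape} for {n} labels")
        if not np.allclose(np.nan_to_num(self.d), np.nan_to_num(self.d.T)):
            raise ValueError("distance matrix must be symmetric")
        if np.nanmax(np.abs(np.diag(self.d)), initial=0) > 1e-12:
            raise ValueError("distance matrix must have a zero diagonal")

    @property
    def n(self) -> int:
        return len(self.labels)

    def missing_pairs(self) -> list[tuple[str, str]]:
        i, j = np.where(np.isnan(np.triu(self.d, 1)))
        return [(self.labels[a], self.labels[b]) for a, b in zip(i, j)]

    def subset(self, keep: list[str]) -> "DistanceMatrix":
        idx = np.array([self.labels.index(t) for t in keep])
        return DistanceMatrix(
            labels=list(keep),
            d=self.d[np.ix_(idx, idx)],
            comparable=self.comparable[np.ix_(idx, idx)],
            metric_tag=self.metric_tag,
        )

    def write_tsv(self, path, sidecar: dict | None = None) -> None:
        df = pd.DataFrame(self.d, index=self.labels, columns=self.labels)
        df.to_csv(path, sep="\t")
        meta = {"metric": self.metric_tag, "n_taxa": self.n}
        if sidecar:
            meta.update(sidecar)
        with open(str(path) + ".json", "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _cell_diff(a, b, ordered: bool) -> float | None:
    """Minimum difference between two cells; None if incomparable."""
    if a in (MISSING, INAPPLICABLE) or b in (MISSING, INAPPLICABLE):
        return None
    sa, sb = _cell_states(a), _cell_states(b)
    if ordered:
        return float(min(abs(x - y) for x in sa for y in sb))
    return 0.0 if set(sa) & set(sb) else 1.0


def pairwise_differences(
    m: CharacterMatrix, i: str | int, j: str | int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-character raw differences and comparability mask for one pair.

    Returns (diffs, mask): ``diffs`` has one entry per comparable
    character in matrix order; ``mask`` is a boolean vector over all
    characters, True where the pair is comparable.
    """
    ri = m.states[m.taxa.index(i) if isinstance(i, str) else i]
    rj = m.states[m.taxa.index(j) if isinstance(j, str) else j]
    diffs, mask = [], np.zeros(m.n_characters, dtype=bool)
    for k, char in enumerate(m.characters):
        delta = _cell_diff(ri[k], rj[k], char.ordered)
        if delta is not None:
            mask[k] = True
            diffs.append(delta)
    return np.array(diffs, dtype=float), mask


def _difference_tensors(m: CharacterMatrix) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs raw differences (n,n,c) and comparability mask (n,n,c).

    Single-state cells take a fast vectorized path; polymorphic cells
    fall back to the per-cell minimum-difference rule.
    """
    n, c = m.n_taxa, m.n_characters
    grid = np.full((n, c), np.nan)
    poly: list[tuple[int, int]] = []
    for a, row in enumerate(m.states):
        for k, cell in enumerate(row):
            st = _cell_states(cell)
            if len(st) == 1:
                grid[a, k] = st[0]
            elif len(st) > 1:
                poly.append((a, k))
    mask = ~np.isnan(grid[:, None, :]) & ~np.isnan(grid[None, :, :])
    raw = np.abs(grid[:, None, :] - grid[None, :, :])
    unordered = np.array([not ch.ordered for ch in m.characters])
    raw[..., unordered] = (raw[..., unordered] > 0).astype(float)
    raw[~mask] = 0.0
    for a, k in poly:  # exact rule for polymorphic cells
        ordered = m.characters[k].ordered
        for b in range(n):
            delta = _cell_diff(m.states[a][k], m.states[b][k], ordered)
            if delta is None:
                mask[a, b, k] = mask[b, a, k] = False
                raw[a, b, k] = raw[b, a, k] = 0.0
            else:
                mask[a, b, k] = mask[b, a, k] = True
                raw[a, b, k] = raw[b, a, k] = delta
    return raw, mask


def mord_distance(m: CharacterMatrix) -> DistanceMatrix:
    """Maximum observable rescaled distance over all taxon pairs.

    Each comparable difference is divided by its character's maximum
    possible difference (the declared max_state for ordered characters,
    1 for unordered) and the mean over comparable characters is taken.
    Pairs with no comparable character get NaN and are reported; if no
    pair at all is comparable the matrix is useless and an error is
    raised.
    """
    if m.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    raw, mask = _difference_tensors(m)
    ranges = np.array(
        [ch.max_state if ch.ordered else 1 for ch in m.characters], dtype=float
    )
    rescaled = raw / ranges
    comparable = mask.sum(axis=2)
    with np.errstate(invalid="ignore"):
        d = np.where(comparable > 0, (rescaled * mask).sum(axis=2), np.nan) / np.where(
            comparable > 0, comparable, 1
        )
    d[comparable == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    off = ~np.eye(m.n_taxa, dtype=bool)
    if np.isnan(d[off]).all():
        raise IncomparablePairError("no taxon pair shares a scored character")
    dm = DistanceMatrix(labels=list(m.taxa), d=d, comparable=comparable, metric_tag="MORD")
    bad = dm.missing_pairs()
    if bad:
        logger.warning("%d taxon pair(s) with no comparable characters: %s",
                       len(bad), bad[:10])
    return dm


def ged_distance(m: CharacterMatrix) -> DistanceMatrix:
    """Generalized Euclidean distance with pair-mean imputation.

    For each pair, every incomparable character is assigned the mean of
    that pair's observed raw differences, then the Euclidean norm is
    taken over all characters.  Every pair must share at least one
    scored character.
    """
    if m.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    raw, mask = _difference_tensors(m)
    comparable = mask.sum(axis=2)
    off = ~np.eye(m.n_taxa, dtype=bool)
    if (comparable[off] == 0).any():
        i, j = np.argwhere((comparable == 0) & off)[0]
        raise IncomparablePairError(
            f"taxa {m.taxa[i]!r} and {m.taxa[j]!r} share no scored character"
        )
    pair_mean = (raw * mask).sum(axis=2) / comparable
    n_sub = m.n_characters - comparable
    sq = (raw**2 * mask).sum(axis=2) + n_sub * pair_mean**2
    d = np.sqrt(sq)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=list(m.taxa), d=d, comparable=comparable, metric_tag="GED")
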