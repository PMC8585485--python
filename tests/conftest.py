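"""Shared fixtures: time-bin scheme, tiny hand-built matrices, and the
session-scoped synthetic fixture suite."""

from __future__ import annotations

import numpy as np
import pytest

from elytron import (
    CharacterDefinition,
    CharacterMatrix,
    MISSING,
    build_default_bins,
    make_fixture_suite,
)


@pytest.fixture(scope="session")
def scheme():
    return build_default_bins()


@pytest.fixture
def tiny_matrix():
    """3 taxa x 4 binary characters with one missing cell."""
    chars = [CharacterDefinition(index=k, ordered=False, max_state=1) for k in range(4)]
    return CharacterMatrix(
        taxa=["alpha", "beta", "gamma"],
        characters=chars,
        states=[
            [0, 1, 0, 1],
            [1, 1, MISSING, 0],
            [0, 0, 1, 1],
        ],
    )


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    files = make_fixture_suite(out, seed=2021)
    return files


def random_binary_matrix(seed, n_taxa=8, n_char=10, missing_rate=0.2, max_state=1,
                         ordered_fraction=0.0):
    """Small random matrix for oracle comparisons (no polymorphism)."""
    rng = np.random.default_rng(seed)
    ordered = rng.random(n_char) < ordered_fraction
    chars = [
        CharacterDefinition(index=k, ordered=bool(ordered[k]), max_state=max_state)
        for k in range(n_char)
    ]
    states = []
    for _ in range(n_taxa):
        row = [int(s) for s in rng.integers(0, max_state + 1, size=n_char)]
        for k in np.flatnonzero(rng.random(n_char) < missing_rate):
            row[k] = MISSING
        states.append(row)
    return CharacterMatrix(
        taxa=[f"t{i}" for i in range(n_taxa)], characters=chars, states=states
    )


def brute_force_mord(m: CharacterMatrix) -> np.ndarray:
    """Independent per-pair loop over the MORD definition."""
    n = m.n_taxa
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = den = 0.0
            for k, ch in enumerate(m.characters):
                a, b = m.states[i][k], m.states[j][k]
                if a == MISSING or b == MISSING or a == "-" or b == "-":
                    continue
                den += 1
                diff = abs(a - b) if ch.ordered else float(a != b)
                rng_k = ch.max_state if ch.ordered else 1
                num += diff / rng_k
            out[i, j] = num / den if den else np.nan
    np.fill_diagonal(out, 0.0)
    return out


def brute_force_ged(m: CharacterMatrix) -> np.ndarray:
    """Independent per-pair loop over the GED pair-mean substitution rule."""
    n, c = m.n_taxa, m.n_characters
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            observed = []
            for k, ch in enumerate(m.characters):
                a, b = m.states[i][k], m.states[j][k]
                if a == MISSING or b == MISSING or a == "-" or b == "-":
                    observed.append(None)
                else:
                    observed.append(abs(a - b) if ch.ordered else float(a != b))
            seen = [d for d in observed if d is not None]
            mean = sum(seen) / len(seen)
            total = sum((d if d is not None else mean) ** 2 for d in observed)
            out[i, j] = total**0.5
    np.fill_diagonal(out, 0.0)
    return out
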