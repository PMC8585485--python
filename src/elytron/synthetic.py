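"""Seeded synthetic character matrices and occurrence databases.

The generator stands in for the study's fossil database so that every
pipeline stage can be exercised against known ground truth.  A
character matrix is simulated as a set of taxon groups (the five
epoch-level assemblages P1, P2, P3, T1, T2 by default): each group
draws a modal state vector and each member taxon deviates from it
independently per character with a group-specific dispersion
probability, so expected within-group disparity increases with
dispersion.  Cells are then blanked completely at random to emulate the
heavy missing data of fossil matrices (default 30%).

Occurrence databases draw a true stratigraphic range per taxon and thin
it bin-wise with a preservation probability, so the recovered
range-through curve is a lower bound on the true one (equal when
preservation is perfect).

Defaults mirror the study design: 346 species-level taxa in five epoch
groups scored for 35 binary characters, with a low-high-high-low-medium
dispersion profile across P1..T2 mimicking the observed disparity
trajectory (Middle/Late Permian peak, Early Triassic plunge, partial
Middle Triassic recovery), and 31 "Voltzia" taxa of controversial age
inside T2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from elytron.charmatrix import (
    MISSING,
    CharacterDefinition,
    CharacterMatrix,
    write_character_matrix,
)
from elytron.occurrences import DiversityCurve
from elytron.timebins import TimeBinScheme, build_default_bins

EPOCHS = ("P1", "P2", "P3", "T1", "T2")
# representative bin index per epoch for single-bin taxon labels
EPOCH_BIN = {"P1": 2, "P2": 5, "P3": 7, "T1": 9, "T2": 10}
# dispersion trajectory: low - high - high - low - medium
DEFAULT_DISPERSION = (0.08, 0.35, 0.35, 0.08, 0.20)
DEFAULT_GROUP_SIZES = (40, 90, 90, 36, 90)  # sums to 346 taxa
N_VOLTZIA = 31


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a group-structured discrete character matrix."""

    group_sizes: tuple[int, ...] = DEFAULT_GROUP_SIZES
    group_names: tuple[str, ...] = EPOCHS
    dispersion: tuple[float, ...] = DEFAULT_DISPERSION
    n_characters: int = 35
    max_state: int = 1  # binary characters keep Hamming oracles exact
    missing_rate: float = 0.30
    level: str = "species"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.group_sizes) != len(self.dispersion) or len(
            self.group_sizes
        ) != len(self.group_names):
            raise ValueError("group_sizes, group_names and dispersion must align")
        if any(s < 2 for s in self.group_sizes):
            raise ValueError("every group needs at least 2 taxa")
        if not all(0.0 <= d <= 1.0 for d in self.dispersion):
            raise ValueError("dispersion must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass(frozen=True)
class SyntheticOccurrenceSpec:
    """Parameters of a synthetic occurrence database."""

    n_taxa: int = 300
    scheme: TimeBinScheme = field(default_factory=build_default_bins)
    preservation_p: float = 0.7
    formal_fraction: float = 0.26  # share of form taxa (isolated elytra)
    mean_duration: float = 2.0  # mean true range length in bins (geometric)
    taxa_per_genus: float = 2.4
    genera_per_family: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.preservation_p <= 1.0:
            raise ValueError("preservation_p must lie in (0, 1]")


def simulate_character_matrix(
    spec: SyntheticSpec,
) -> tuple[CharacterMatrix, dict[str, str]]:
    """Simulate a matrix; returns it plus taxon -> group ground truth."""
    rng = np.random.default_rng(spec.seed)
    n_states = spec.max_state + 1
    taxa: list[str] = []
    rows: list[list[object]] = []
    groups: dict[str, str] = {}
    bin_label: dict[str, int] = {}
    for g, (size, name, disp) in enumerate(
        zip(spec.group_sizes, spec.group_names, spec.dispersion)
    ):
        modal = rng.integers(0, n_states, size=spec.n_characters)
        for t in range(size):
            taxon = f"{name}_taxon_{t + 1:03d}"
            states = modal.copy()
            flip = rng.random(spec.n_characters) < disp
            # deviate to a uniformly chosen *different* state
            shift = rng.integers(1, n_states, size=spec.n_characters)
            states[flip] = (states[flip] + shift[flip]) % n_states
            cells: list[object] = [int(s) for s in states]
            blank = rng.random(spec.n_characters) < spec.missing_rate
            for k in np.flatnonzero(blank):
                cells[k] = MISSING
            taxa.append(taxon)
            rows.append(cells)
            groups[taxon] = name
            bin_label[taxon] = EPOCH_BIN.get(name, g)
    characters = [
        CharacterDefinition(index=k, ordered=False, max_state=spec.max_state)
        for k in range(spec.n_characters)
    ]
    matrix = CharacterMatrix(
        taxa=taxa,
        characters=characters,
        states=rows,
        bin_label=bin_label,
        group_label=dict(groups),
        level=spec.level,
    )
    return matrix, groups


def _draw_ranges(rng, spec: SyntheticOccurrenceSpec) -> np.ndarray:
    """(n_taxa, 2) true (first_bin, last_bin), geometric durations."""
    n_bins = len(spec.scheme)
    first = rng.integers(0, n_bins, size=spec.n_taxa)
    duration = rng.geometric(1.0 / spec.mean_duration, size=spec.n_taxa) - 1
    last = np.minimum(first + duration, n_bins - 1)
    return np.column_stack([first, last])


def simulate_occurrences(
    spec: SyntheticOccurrenceSpec, path: str | Path | None = None
) -> tuple[pd.DataFrame, DiversityCurve]:
    """Simulate an occurrence table and its true species curve.

    True ranges are thinned bin-wise with ``preservation_p``; taxa with
    no preserved bin are lost entirely.  The returned table is in the
    loader's CSV format (written to ``path`` when given); the returned
    curve is the range-through curve of the *true* ranges.
    """
    rng = np.random.default_rng(spec.seed)
    scheme = spec.scheme
    n_bins = len(scheme)
    ranges = _draw_ranges(rng, spec)

    true_counts = np.zeros(n_bins, dtype=int)
    for first, last in ranges:
        true_counts[first : last + 1] += 1
    true_curve = DiversityCurve(rank="species", taxon_set="mixed", counts=true_counts)

    n_genera = max(1, round(spec.n_taxa / spec.taxa_per_genus))
    n_families = max(1, round(n_genera / spec.genera_per_family))
    genus_of = rng.integers(0, n_genera, size=spec.n_taxa)
    family_of_genus = rng.integers(0, n_families, size=n_genera)
    formal = rng.random(spec.n_taxa) < spec.formal_fraction

    rows = []
    for i in range(spec.n_taxa):
        first, last = ranges[i]
        preserved = np.flatnonzero(
            rng.random(last - first + 1) < spec.preservation_p
        )
        if preserved.size == 0:
            continue
        obs_first = scheme.bins[first + preserved.min()]
        obs_last = scheme.bins[first + preserved.max()]
        genus = f"Genus_{genus_of[i] + 1:03d}"
        rows.append(
            {
                "taxon_name": f"{genus} species_{i + 1:03d}",
                "rank": "species",
                "status": "formal" if formal[i] else "natural",
                "family": f"Family_{family_of_genus[genus_of[i]] + 1:02d}",
                "genus": genus,
                "first_stage": obs_first.name,
                "last_stage": obs_last.name,
                "flags": "",
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "taxon_name",
            "rank",
            "status",
            "family",
            "genus",
            "first_stage",
            "last_stage",
            "flags",
        ],
    )
    if path is not None:
        df.to_csv(path, index=False, lineterminator="\n")
    return df, true_curve


def _write_sidecar(
    matrix: CharacterMatrix, path: Path, scheme: TimeBinScheme, voltzia: set[str]
) -> None:
    rows = [
        {
            "taxon_name": t,
            "bin_name": scheme.bins[matrix.bin_label[t]].name,
            "group": matrix.group_label[t],
            "voltzia": int(t in voltzia),
        }
        for t in matrix.taxa
    ]
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")


def make_fixture_suite(out_dir: str | Path, seed: int = 2021) -> dict[str, str]:
    """Write the canonical synthetic fixtures used by the test suite.

    Emits a species-level (346 taxa) and genus-level (197 taxa) mock
    character matrix in NEXUS plus taxon-metadata sidecars, a synthetic
    occurrence CSV, and a manifest recording every seed and spec.  The
    last 31 T2 taxa of the species mock are marked as the
    Voltzia-Formation analogue for the age-sensitivity switch.
    Deterministic: rerunning with the same seed rewrites identical
    files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = build_default_bins()
    manifest: dict[str, object] = {"seed": seed, "files": {}}

    species_spec = SyntheticSpec(seed=seed)
    sp_matrix, _ = simulate_character_matrix(species_spec)
    voltzia = {t for t in sp_matrix.taxa if sp_matrix.group_label[t] == "T2"}
    voltzia = set(sorted(voltzia)[-N_VOLTZIA:])
    write_character_matrix(sp_matrix, out / "species_matrix.nex", dialect="nexus")
    _write_sidecar(sp_matrix, out / "species_metadata.csv", scheme, voltzia)

    genus_sizes = (22, 52, 52, 20, 51)  # sums to 197
    genus_spec = SyntheticSpec(
        group_sizes=genus_sizes, level="genus", seed=seed + 1
    )
    ge_matrix, _ = simulate_character_matrix(genus_spec)
    write_character_matrix(ge_matrix, out / "genus_matrix.nex", dialect="nexus")
    _write_sidecar(ge_matrix, out / "genus_metadata.csv", scheme, set())

    occ_spec = SyntheticOccurrenceSpec(seed=seed + 2)
    simulate_occurrences(occ_spec, out / "occurrences.csv")

    manifest["files"] = {
        "species_matrix.nex": {"spec": _spec_dict(species_spec)},
        "species_metadata.csv": {"voltzia_taxa": sorted(voltzia)},
        "genus_matrix.nex": {"spec": _spec_dict(genus_spec)},
        "genus_metadata.csv": {},
        "occurrences.csv": {
            "n_taxa": occ_spec.n_taxa,
            "preservation_p": occ_spec.preservation_p,
            "seed": occ_spec.seed,
        },
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {name: str(out / name) for name in list(manifest["files"]) + ["manifest.json"]}


def _spec_dict(spec: SyntheticSpec) -> dict:
    return {
        "group_sizes": list(spec.group_sizes),
        "group_names": list(spec.group_names),
        "dispersion": list(spec.dispersion),
        "n_characters": spec.n_characters,
        "max_state": spec.max_state,
        "missing_rate": spec.missing_rate,
        "level": spec.level,
        "seed": spec.seed,
    }
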