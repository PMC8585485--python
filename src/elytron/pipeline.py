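"""End-to-end orchestration: diversity curves and the disparity grid.

One :class:`RunConfig` drives both pipelines.  The disparity pipeline
executes the requested metric x ordination grid (MORD/GED x PCoA/NMDS),
computes per-epoch disparity with bootstrap CIs, runs the pairwise
permutation tests between every older/younger epoch pair, and writes
TSV tables plus a JSON manifest echoing every tunable and derived seed.
Reruns of an identical config reproduce identical outputs: all stage
seeds are split deterministically from the one master seed.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from elytron._version import __version__
from elytron.charmatrix import read_character_matrix, load_taxon_metadata
from elytron.disparity import (
    bootstrap_disparity,
    permutation_test,
    select_axes,
    subsampled_permutation_test,
)
from elytron.distances import ged_distance, mord_distance
from elytron.occurrences import (
    RANKS,
    TAXON_SETS,
    apply_curation_filter,
    diversity_table,
    load_occurrences,
    range_through_counts,
)
from elytron.ordination import nmds, pcoa, trim_missing_pairs
from elytron.synthetic import EPOCHS
from elytron.timebins import build_default_bins

logger = logging.getLogger(__name__)

_METRIC_FN = {"MORD": mord_distance, "GED": ged_distance}


@dataclass
class RunConfig:
    """Every tunable of a pipeline run; serializable to/from JSON."""

    matrix_path: str = ""
    sidecar_path: str = ""
    occurrences_path: str = ""
    dialect: str = "nexus"
    level: str = "species"
    metrics: tuple[str, ...] = ("MORD", "GED")
    ordinations: tuple[str, ...] = ("PCoA", "NMDS")
    disparity_metrics: tuple[str, ...] = ("sov", "pov")
    axis_rule: str = "cumulative_90"  # PCoA; NMDS always uses all k axes
    test_type: str = "both"  # plain | subsampled | both
    bootstrap_reps: int = 500
    permutation_reps: int = 5000
    subsampled_reps: int = 10000
    nmds_dimensions: int = 3
    nmds_restarts: int = 20
    bin_membership: str = "range"  # range | first (occurrence-driven grouping)
    voltzia_age: str = "T2"  # T2 (default) | T1 (age-sensitivity rerun)
    seed: int = 0

    def __post_init__(self) -> None:
        self.metrics = tuple(self.metrics)
        self.ordinations = tuple(self.ordinations)
        self.disparity_metrics = tuple(self.disparity_metrics)
        for reps in (self.bootstrap_reps, self.permutation_reps, self.subsampled_reps):
            if reps < 100:
                raise ValueError("replication counts below 100 are not meaningful")
        if self.voltzia_age not in ("T1", "T2"):
            raise ValueError("voltzia_age must be 'T1' or 'T2'")
        if self.test_type not in ("plain", "subsampled", "both"):
            raise ValueError("test_type must be plain, subsampled or both")
        unknown = set(self.metrics) - set(_METRIC_FN)
        if unknown:
            raise ValueError(f"unknown distance metric(s): {sorted(unknown)}")
        for p in (self.matrix_path, self.sidecar_path, self.occurrences_path):
            if p and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))

    def to_dict(self) -> dict:
        return asdict(self)


def _stage_seed(master: int, label: str) -> int:
    """Deterministic per-stage 31-bit seed split from the master seed."""
    h = np.random.SeedSequence([master, zlib.crc32(label.encode())])
    return int(h.generate_state(1)[0] % 2**31)


def _epoch_order(groups: list[str]) -> list[str]:
    known = [e for e in EPOCHS if e in groups]
    extra = sorted(set(groups) - set(EPOCHS))
    return known + extra


def _apply_voltzia_switch(matrix, cfg: RunConfig, sidecar_path: str):
    """Reassign the Voltzia-marked taxa to T1 when requested."""
    if cfg.voltzia_age == "T2" or not sidecar_path:
        return matrix
    df = pd.read_csv(sidecar_path, dtype=str, keep_default_na=False)
    if "voltzia" not in df.columns:
        return matrix
    scheme = build_default_bins()
    t1_bin = scheme.bin_by_name("Induan+Olenekian").index
    marked = set(df.loc[df["voltzia"] == "1", "taxon_name"])
    if not marked:
        return matrix
    logger.info("age switch: moving %d Voltzia taxa to T1", len(marked))
    for t in matrix.taxa:
        if t in marked:
            matrix.group_label[t] = "T1"
            matrix.bin_label[t] = t1_bin
    return matrix


def run_disparity_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Run the metric x ordination grid; write tables and a manifest.

    Returns a bundle with, per grid cell, the disparity table (epoch,
    metric, estimate, CI, n) and the pairwise test matrix.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix = read_character_matrix(cfg.matrix_path, dialect=cfg.dialect)
    scheme = build_default_bins()
    if cfg.sidecar_path:
        matrix = load_taxon_metadata(matrix, cfg.sidecar_path, scheme)
    matrix = _apply_voltzia_switch(matrix, cfg, cfg.sidecar_path)
    unlabeled = [t for t in matrix.taxa if t not in matrix.group_label]
    if unlabeled:
        raise ValueError(f"taxa without group labels: {unlabeled[:10]}")

    bundle: dict[str, dict] = {}
    manifest: dict = {
        "config": cfg.to_dict(),
        "package_version": __version__,
        "stages": {},
    }
    for metric in cfg.metrics:
        dmat = _METRIC_FN[metric](matrix)
        dmat, dropped = trim_missing_pairs(dmat)
        dmat.write_tsv(out / f"distances_{metric.lower()}.tsv")
        for method in cfg.ordinations:
            cell = f"{metric}_{method}"
            stage_meta: dict = {"dropped_taxa": dropped}
            if method == "PCoA":
                ordination = pcoa(dmat, correction="cailliez")
                selection = select_axes(ordination, cfg.axis_rule)
                stage_meta["correction_constant"] = ordination.correction_constant
            elif method == "NMDS":
                nmds_seed = _stage_seed(cfg.seed, f"nmds_{cell}")
                ordination = nmds(
                    dmat,
                    k=cfg.nmds_dimensions,
                    restarts=cfg.nmds_restarts,
                    seed=nmds_seed,
                )
                selection = select_axes(ordination, "all_axes")
                stage_meta.update(
                    stress=ordination.stress,
                    nonmetric_fit=ordination.nonmetric_fit,
                    linear_fit=ordination.linear_fit,
                    seed=nmds_seed,
                    restarts=cfg.nmds_restarts,
                )
            else:
                raise ValueError(f"unknown ordination {method!r}")
            ordination.write_tsv(out / f"scores_{cell.lower()}.tsv")
            stage_meta["retained_axes"] = int(selection.indices.size)
            stage_meta["cumulative_variance"] = selection.cumulative_variance

            groups = [matrix.group_label[t] for t in ordination.labels]
            order = _epoch_order(groups)
            scores_by_group = {
                g: ordination.scores[
                    [i for i, gg in enumerate(groups) if gg == g]
                ][:, selection.indices]
                for g in order
            }

            disparity_rows = []
            for g in order:
                for dm in cfg.disparity_metrics:
                    if scores_by_group[g].shape[0] < 2:
                        logger.warning("epoch %s has <2 taxa; skipped", g)
                        continue
                    boot_seed = _stage_seed(cfg.seed, f"boot_{cell}_{g}_{dm}")
                    est = bootstrap_disparity(
                        scores_by_group[g], metric=dm,
                        reps=cfg.bootstrap_reps, seed=boot_seed,
                    )
                    disparity_rows.append(
                        {
                            "bin": g,
                            "metric": dm,
                            "estimate": est.value,
                            "ci_low": est.ci_low,
                            "ci_high": est.ci_high,
                            "n_taxa": est.n_taxa,
                        }
                    )
            disparity_df = pd.DataFrame(disparity_rows)
            disparity_df.to_csv(
                out / f"disparity_{cell.lower()}.tsv", sep="\t", index=False
            )

            test_rows = []
            for a, older in enumerate(order):
                for younger in order[a + 1 :]:
                    so, sy = scores_by_group[older], scores_by_group[younger]
                    if so.shape[0] < 2 or sy.shape[0] < 2:
                        continue
                    for dm in cfg.disparity_metrics:
                        runs = []
                        if cfg.test_type in ("plain", "both"):
                            seed_p = _stage_seed(
                                cfg.seed, f"perm_{cell}_{older}_{younger}_{dm}"
                            )
                            runs.append(
                                permutation_test(
                                    so, sy, metric=dm, reps=cfg.permutation_reps,
                                    seed=seed_p, older_bin=older, younger_bin=younger,
                                )
                            )
                        if cfg.test_type in ("subsampled", "both"):
                            seed_s = _stage_seed(
                                cfg.seed, f"subperm_{cell}_{older}_{younger}_{dm}"
                            )
                            runs.append(
                                subsampled_permutation_test(
                                    so, sy, metric=dm, reps=cfg.subsampled_reps,
                                    seed=seed_s, older_bin=older, younger_bin=younger,
                                )
                            )
                        for r in runs:
                            test_rows.append(
                                {
                                    "older_bin": r.older_bin,
                                    "younger_bin": r.younger_bin,
                                    "metric": r.metric,
                                    "test": r.test,
                                    "observed_T": r.observed_T,
                                    "proportion": r.proportion,
                                    "decision": r.decision,
                                    "reps": r.replications,
                                    "seed": r.seed,
                                }
                            )
            tests_df = pd.DataFrame(test_rows)
            tests_df.to_csv(out / f"tests_{cell.lower()}.tsv", sep="\t", index=False)

            manifest["stages"][cell] = stage_meta
            bundle[cell] = {
                "disparity": disparity_df,
                "tests": tests_df,
                "ordination": ordination,
                "selection": selection,
            }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    bundle["manifest"] = manifest
    return bundle


def run_diversity_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Nine range-through curves (3 ranks x natural/formal/mixed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = build_default_bins()
    records = load_occurrences(cfg.occurrences_path, scheme)
    records, curation_report = apply_curation_filter(records)
    curves = [
        range_through_counts(records, rank, taxon_set, scheme)
        for rank in RANKS
        for taxon_set in TAXON_SETS
    ]
    table = diversity_table(curves, scheme)
    table.to_csv(out / "diversity.tsv", sep="\t", index=False)
    manifest = {
        "config": cfg.to_dict(),
        "package_version": __version__,
        "n_records": len(records),
        "curation_exclusions": curation_report,
    }
    with open(out / "diversity_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"curves": curves, "table": table, "manifest": manifest}
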