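# elytron

Range-through taxonomic diversity and discrete-character morphological
disparity for the beetle fossil record across the end-Permian mass
extinction (EPME, ~252 Ma).

## The scientific problem

Permian and Triassic beetles are known mostly from isolated elytra
(hardened forewings), scored as discrete morphological characters.  Two
questions drive the analysis this package implements:

1. **Diversity** — how many families, genera and species existed in each
   stage-level time-bin from the Asselian to the Ladinian (298–237 Ma)?
   Counting uses the *range-through* convention: a taxon is present in
   every bin between (and including) its first and last appearance.
   Because many fossils are form taxa erected on isolated elytra
   ("formal" taxa) that cannot be placed in a natural group, curves are
   computed separately for natural, formal and mixed (pooled) taxon sets.
2. **Disparity** — how much morphological variety did those beetles span,
   and how did it change across the EPME?  Taxa are embedded in a
   morphospace built from pairwise distances on a taxa × characters
   matrix with heavy missing data, and per-bin disparity is measured on
   the ordination scores.

## Methods at the core

* **Distances.** For taxa *i, j* and characters *k* comparable in both
  (neither missing nor inapplicable), with per-character difference
  δ_k (0/1 mismatch for unordered, |a−b| for ordered characters):
  - **MORD** (maximum observable rescaled distance):
    `MORD(i,j) = Σ_k (δ_k / r_k) / N_ij`, where r_k is the character's
    maximum possible difference and N_ij the number of comparable
    characters; bounded in [0, 1].
  - **GED** (generalized Euclidean distance): incomparable characters
    are imputed with the pair's mean observed difference, then
    `GED(i,j) = sqrt(Σ_k δ_k²)` over all characters.  GED inflates under
    heavy missing data, which is why MORD is preferred.
* **Ordination.** Principal coordinates (PCoA) of the double-centered
  squared-distance matrix, with the **Cailliez correction** (smallest
  constant added to all off-diagonal distances making the matrix
  Euclidean-embeddable) to eliminate negative eigenvalues; and 3-D
  non-metric multidimensional scaling (**NMDS**) minimizing Kruskal
  stress-1, `stress = sqrt(Σ(d−d̂)² / Σd²)`, by isotonic regression plus
  Guttman updates over one metric start and 20 random restarts.
* **Disparity.** Over the retained axes (shortest PCoA prefix reaching
  90% of variance; all k axes for NMDS): **sov** = Σ per-axis sample
  variances, **pov** = (Π variances)^(1/n).  Uncertainty from 500 taxon
  bootstraps.
* **Inference.** For an older bin O and younger bin Y, the statistic is
  T = disparity(O) − disparity(Y).  A plain permutation test (5000
  replicates) repartitions the pooled taxa at the original sizes and
  reports the fraction of null T strictly above the observed one
  (older-larger if < 0.025, younger-larger if > 0.975).  A
  subsampling-corrected variant (10,000 replicates) equalizes group
  sizes by subsampling before each permutation and ranks each
  replicate's observed T against the pooled null, deciding on the
  median proportion (≤ 0.025 / ≥ 0.975).

A seeded synthetic-data module generates character matrices with known
group structure (five epoch assemblages P1, P2, P3, T1, T2) and
occurrence databases with known true ranges, so every stage of the
pipeline is testable against ground truth without any download.

## Worked example

```python
from elytron import (SyntheticSpec, simulate_character_matrix,
                     mord_distance, pcoa, sum_of_variances,
                     permutation_test)
from elytron.disparity import select_axes
from elytron.ordination import trim_missing_pairs

spec = SyntheticSpec(group_sizes=(30, 30), group_names=("P2", "T1"),
                     dispersion=(0.35, 0.08), seed=4)
matrix, groups = simulate_character_matrix(spec)
dm, _ = trim_missing_pairs(mord_distance(matrix))
ordination = pcoa(dm)                      # Cailliez-corrected
axes = select_axes(ordination, "cumulative_90")
scores = {g: ordination.scores_for([t for t in ordination.labels
                                    if groups[t] == g])[:, axes.indices]
          for g in ("P2", "T1")}
print(round(sum_of_variances(scores["P2"]), 3),
      round(sum_of_variances(scores["T1"]), 3))
res = permutation_test(scores["P2"], scores["T1"], metric="sov",
                       reps=5000, seed=1)
print(round(res.observed_T, 3), res.proportion, res.decision)
```

prints

```
1.433 0.936
0.497 0.0 older_larger
```

— the Middle Permian mock assemblage (dispersion 0.35) spans half again
as much morphospace as the Early Triassic mock (dispersion 0.08); none
of the 5000 permuted repartitions of the pooled taxa produced a larger
difference than the observed 0.497, so the older bin's disparity is
significantly larger.

The command-line interface exposes the same pipelines:

```
elytron fixtures --seed 2021 --out fx/
elytron diversity --occurrences fx/occurrences.csv --out out/
elytron disparity --matrix fx/species_matrix.nex --sidecar fx/species_metadata.csv \
                  --seed 1 --voltzia-age T2 --out out/
```

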