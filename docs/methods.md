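# Methods

This note documents the models, conventions and numerical choices of
the package, what the synthetic generator does and does not emulate,
and the known limitations.

## Time-binning and range-through diversity

The study interval (Asselian–Ladinian, 298–237 Ma) is divided into 12
stage-level bins; the short Induan and Olenekian are merged into one
Early Triassic bin, so 13 ICS stage names resolve to 12 bins.  Internal
boundaries follow ICS chart ages; the outer bounds are pinned at 298
and 237 Ma.  Bins group into five epochs: P1 (Asselian–Kungurian), P2
(Roadian–Capitanian), P3 (Wuchiapingian–Changhsingian), T1
(Induan+Olenekian), T2 (Anisian–Ladinian).

The loader accepts only global chronostratigraphic stage names.
Converting local stratigraphic units to global stages is a curation
judgment that belongs upstream of this package; rows that do not
resolve are reported (with row numbers) and the load fails rather than
silently dropping them.

Range-through counting is closed on both ends: a taxon contributes to
every bin from `first_bin` to `last_bin` inclusive.  Genus and family
ranges are the union of directly recorded ranges at that rank and the
ranges of contained lower-rank records, whichever is wider — the
aggregation rule is a package convention, stated here because published
databases rarely spell one out.  Mixed (natural + formal) curves
deduplicate taxa by exact name, taking the union of ranges for a name
present in both sets.  Records flagged `illegitimate`, `questionable`
or `synonym` are excluded before counting, with per-flag counts
reported.

## Character matrices

Cells hold one integer state, a polymorphic state set, `?` (unknown) or
`-` (inapplicable).  The two non-data markers are preserved through I/O
but treated identically (incomparable) by both distance metrics; the
matrices this field produces do not document a usable distinction for
distance purposes.  `max_state` per character is inferred from the
observed maximum unless declared.  Characters default to unordered;
ordering flags are read from a NEXUS ASSUMPTIONS `TYPESET` line when
present.  Duplicate taxon labels are made unique by suffixing a counter
(and logged), since undetermined specimens legitimately repeat names.

## Distances

Per-character differences: 0/1 mismatch for unordered characters,
|a−b| for ordered; polymorphic cells take the minimum difference over
the cross-product of state sets (the least-assumption convention).

* **MORD** rescales each comparable difference by the character's
  theoretical maximum (declared `max_state` for ordered, 1 for
  unordered) — not the observed range, so subsetting taxa never changes
  the distances among the remainder — and averages over comparable
  characters.  Pairs with no comparable character get a missing
  distance and are reported; ordination trims the involved taxa
  greedily (most-missing first) with a logged list.
* **GED** imputes each incomparable character with the **pair's own
  mean** observed raw difference (the pair-mean variant, recorded in
  the output metadata; a matrix-wide-mean variant exists in the
  literature and the choice matters under heavy missingness), then
  takes the Euclidean norm over all characters.

## Ordination

**PCoA** eigendecomposes the double-centered −½D² matrix.  Axes with
eigenvalues below 1e-8 × the largest eigenvalue are dropped; per-axis
variance fractions are normalized over the positive spectrum.  The
**Cailliez constant** is the largest real eigenvalue of the standard
2n × 2n companion problem, clipped at zero for already-Euclidean input;
the implementation agrees with R's `ape::pcoa` Cailliez note to 1e-12
on seeded inputs.  Each axis is oriented so its largest-magnitude score
is positive, making score signs reproducible across platforms.

**NMDS** minimizes Kruskal stress-1 with monotone (isotonic) regression
of configuration distances on the dissimilarity rank order — Kruskal's
primary tie treatment: tied dissimilarities are left adjacent in a
stable sort, so the isotonic fit may assign them unequal values —
alternating with Guttman-transform updates.  Defaults: k = 3, one
PCoA-seeded start plus 20 random starts, up to 300 iterations per
start, convergence when the best stress improves by < 1e-6 (with a
10-iteration stall window, since Guttman steps guarantee descent of raw
stress, not of stress-1; only improving configurations are accepted, so
the recorded stress trace is non-increasing).  Reported diagnostics:
stress-1, non-metric R² = 1 − stress², and linear R² (squared Pearson
correlation of configuration distances with the monotone-fitted
values).  Runs record their seed; identical seeds reproduce identical
scores.

## Disparity and inference

Disparity is computed on one joint ordination of all taxa, then subset
by epoch — bins must be compared within a common subspace, and the
90%-cumulative-variance axis prefix is likewise selected once on the
joint PCoA and shared by every bin (NMDS uses all k axes).  Sample
variances use the n−1 denominator.  `pov` is the nth root of the
product of per-axis variances (geometric mean), which makes the AM–GM
bound `pov ≤ sov/n` an invariant asserted in the tests.  Bootstrap CIs
resample taxa with replacement (500 replicates, 2.5/97.5 percentiles).

The plain permutation test pools both groups and repartitions at the
original sizes (5000 replicates); the reported proportion counts null
statistics **strictly** greater than the observed one (ties contribute
nothing), and decisions use strict thresholds (< 0.025 / > 0.975).  The
subsampling-corrected test (10,000 replicates) subsamples the larger
group to the smaller size, records an observed statistic per replicate,
permutes the pooled equal-size groups once per replicate for one null
value, pools all null values into a single distribution, ranks every
observed value against it, and decides on the **median** proportion
with inclusive thresholds (≤ 0.025 / ≥ 0.975).  Pooling the nulls (as
opposed to ranking each observed value against its own replicate's
null) is the package's reading of the procedure; it yields one
10,000-value null distribution and one set of 10,000 proportions.
Equal-size inputs fall back to the plain test with a log notice.

Permutation internals are vectorized and processed in replicate chunks
bounded by a fixed element budget, so results are exact and independent
of chunking while memory stays flat even with hundreds of retained
axes (a Cailliez-corrected PCoA of a 346-taxon matrix retains ~250
axes under the 90% rule — the correction flattens the spectrum).

Taxa whose range spans several bins contribute to every bin in their
range, consistent with range-through counting; the sidecar metadata
used by the pipeline assigns one epoch per taxon, and the
Voltzia-Formation age switch (`voltzia_age="T1"`) reassigns the marked
taxa from T2 to T1 to propagate their controversial age through every
downstream table.

## Synthetic data

A simulated matrix draws, per group, a modal state vector; each taxon
copies it and deviates per character with probability equal to the
group's dispersion, moving to a uniformly chosen different state; cells
are then blanked completely at random (default 30%, matching the
missing-data load typical of fossil matrices).  Defaults mirror the
study design: 346 species-level taxa (and a 197-taxon genus-level
counterpart) in five epoch groups, 35 binary characters, dispersion
profile 0.08/0.35/0.35/0.08/0.20 across P1/P2/P3/T1/T2 — low Early
Permian disparity, a Middle Permian rise, an Early Triassic plunge and
partial Middle Triassic recovery — plus 31 taxa inside T2 marked as the
Grès-à-Voltzia analogue.  Binary characters keep the Hamming-based
distance oracles exact; expected within-group disparity is provably
monotone in dispersion, which is the generator's key testable contract.

Occurrence simulation draws true ranges (uniform first bin, geometric
duration, mean 2 bins), thins them bin-wise with a preservation
probability (default 0.7), and writes the loader's CSV format; the true
range-through curve is returned for comparison, giving exact oracles
(recovered = true at p = 1, recovered ≤ true below).

**What the generator does not emulate.**  Missingness is MCAR, whereas
fossil missingness is structured by preservation; characters are
independent given the group mode, whereas real elytral characters are
correlated.  The practical consequence is that synthetic matrices are
*harder* to embed in 3-D than the real published matrix: across seeds
and settings the synthetic NMDS stress sits at ~0.21–0.26 with linear
fit 0.4–0.6, where the real species-level matrix embeds below 0.2 with
fits above 0.9.  This is a property of the data, not the optimizer —
R's `vegan::metaMDS` and scikit-learn's non-metric MDS reach the same
or slightly worse stress on identical synthetic input.  Passing tests
therefore demonstrate correct diagnostics, calibrated inference and
recovered group structure, not that MCAR synthetic data meets the
embedding-quality rules of thumb of real matrices; the real-data
embedding checks live in the tests that load the published matrices
from `data/`.

## Numerical choices and degenerate inputs

* Eigenvalue tolerance: 1e-8 relative to the largest eigenvalue,
  both for dropping PCoA axes and for the "Euclidean-embeddable" test.
* All-zero distance input: PCoA returns zero axes (an empty score
  grid); NMDS reports stress 0 on perfectly embeddable input.
* `pov` returns 0 whenever any retained axis has zero variance.
* Disparity requires ≥ 2 taxa per group; ordination requires ≥ 3 taxa
  (PCoA) and more than k taxa (NMDS).
* Every stochastic stage takes an explicit seed; the pipeline splits
  per-stage seeds deterministically from one master seed via hashed
  stage labels, so one integer reproduces a full run byte-for-byte.

## Problem sizes in the shipped suites

The test suite and the acceptance script size their simulations for a
single CPU: distance oracles run on hundreds of small random matrices;
type-I calibration uses 2000 null trials at 1000 permutations each
(the decision thresholds are identical at any replication count, so
calibration transfers to the 5000-replicate default); power runs 40
trials at the dispersion-ratio-4 / n=30 design point; the acceptance
script runs the full 346-taxon grid at full replication counts (5000 /
10,000 / 500).

## Known limitations

* No Lingoes correction, character weighting, or alternative distance
  coefficients; no rarefaction or partial-disparity decompositions.
* The loader does not resolve nomenclature or detect synonymy; curation
  flags are taken as given.
* Phylogenetically correlated character simulation (Mk-on-tree) is out
  of scope for the generator.
* The subsampled test's pooled-null reading (above) is one of two
  defensible interpretations of the procedure it implements.
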