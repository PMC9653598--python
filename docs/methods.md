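# Methods

## The analysis model

The pipeline treats a gene's regulatory context as the set of genes that are
repeatedly differentially expressed in the same studies where an *anchor*
gene is itself differentially expressed. Its stages are deliberately simple
and auditable:

**Differential expression and the anchor gate.** Each dataset is a
genes × samples matrix of log2 expression with a two-level group factor
(control/case). Every gene is tested with Welch's unequal-variance *t*
(Satterthwaite degrees of freedom, two-sided p). A dataset contributes a DE
list only when the anchor's p ≤ α *and* the sign of its log2 fold change
(case − control) matches the cohort direction. When the gate passes, the DE
list contains every gene at p ≤ α regardless of its own direction — the
extraction is of "all significantly altered genes", not direction-matched
ones. Many public-repository screens of this kind use a moderated
(empirical-Bayes shrunken) *t*; this package deliberately uses the plain
Welch test instead. With ≥ 10 samples per group, the shrinkage target and
the per-gene variance estimate are close and the gate behaves near
identically; the substitution keeps the statistical machinery fully
transparent and exactly matched by the noncentral-*t* power oracle used in
the tests. No multiple-testing correction is applied to the gate or the DE
cut by default (the gate threshold is a raw-p convention); a
Benjamini–Hochberg variant of the gene cut is available via the `bh` flag.

**Commonality.** The gated DE lists are assembled into a boolean
gene × dataset matrix. Genes are ranked by the number of datasets containing
them, ties broken by symbol order so the ranking is a pure function of the
input sets. The ranked list is truncated to `top_n` (default 1000) *after*
ranking. The "common to ≥ k" slices are computed from the full matrix, not
the truncated list, so slice contents do not depend on `top_n`; the
alternative reading is available (`slice_from_ranked`). Level thresholds are
read as *at least* k datasets; the two cohorts get their own level sets
(defaults {3,4,5,6} of 7 and {5,6,7,8} of 9).

**Over-representation and consensus.** Each slice is tested against a GMT
collection with the upper-tail hypergeometric probability
P[X ≥ k], X ~ Hypergeom(N, K, n). Significance additionally requires an
overlap of at least `min_overlap` genes (default 2) — a one-gene overlap is
never called, however small its p. The universe defaults to the union of all
genes tested in the contributing datasets; it can be overridden by file.
Collection members absent from the universe are trimmed from K (the test is
conditioned on what could have been observed). BH q-values are always
computed across the records of a run; `adjust` only switches which value the
significance flag uses. A pathway reaches *consensus* when significant in at
least `min_levels` (default 3) of the levels tested. The functional grouping
used to compare the up- and down-cohort consensus sets is user-supplied
curation, consumed as a mapping file and never computed.

**Reference-set overlap.** The ranked cohort is intersected with a reference
gene set. The null model draws `n_perm` random sets of the reference's size
(within the universe, without replacement within a draw, independent across
draws) and records their overlap with the cohort. Reported are the null
mean, the SEM (sample n−1 SD over √n_perm, matching the mean ± SEM
presentation convention), a z-score, and the add-one empirical p
(1 + #{null ≥ obs})/(1 + n_perm), which is never zero. The historical
default of n_perm = 10 is kept for continuity, but ≥ 999 draws are
recommended and used everywhere it matters; at n_perm = 10 the smallest
attainable p is 1/11.

**Minimum-order subnetwork.** Connecting all seed proteins with as few added
nodes as possible is a node-weighted Steiner problem (NP-hard). Per
connected component containing ≥ 2 seeds: if the component has at most 14
candidate connector nodes the exact minimum is found by enumerating
connector subsets in increasing size (≤ 2^14 subsets, with early exit — a
few milliseconds); larger components use the Takahashi–Matsuyama
shortest-path heuristic (grow from a seed, repeatedly attach the nearest
unconnected seed via its shortest path) run from every seed, keeping the
smallest result, followed by removal of redundant connectors. All tie-breaks
are lexicographic on symbols, so the output is deterministic. The final
subnetwork is the *induced* subgraph on the selected nodes (every graph edge
among them is kept). Seeds absent from the graph are reported dropped; seeds
alone in their component are reported isolated rather than failing the run.
Edge confidence scores, when present in input files, are ignored — the graph
is unweighted.

**Clustering.** Server-side PPI clustering tools operate on undisclosed
feature spaces; the local stand-in defined here is: pairwise shortest-path
distances among the proteins (unreachable pairs receive the finite penalty
*graph diameter + 1*), classical Torgerson MDS of that distance matrix
(eigendecomposition of the double-centered squared distances, keeping
positive modes), then Lloyd k-means with 10 restarts from a seeded RNG.
k defaults to 4. Labels are canonicalized so the cluster containing the
alphabetically smallest protein is cluster 0, making assignments comparable
across runs. `k = |proteins|` returns singletons directly.

## The synthetic-data generator

The generator emulates the *statistical* structure of a multi-dataset
two-group co-expression study, not its technical artifacts:

- Expression is log2-scale Gaussian: per-gene baseline ~ N(8, 1.5²), i.i.d.
  observation noise of SD `noise_sd` (default 1.0 log2 units, a typical
  residual SD for array data).
- The anchor always carries the planted shift `effect_size` (default ±2.0,
  a strong but realistic fold change of 4×); each module gene carries it
  with per-dataset probability `module_penetrance` (default 1.0; lowering it
  is the designed knob for populating the intermediate "common to ≥ k"
  strata).
- A fraction `background_de_fraction` (default 0.05) of the remaining genes
  receives an independent shift of magnitude 1–2 log2 units with random
  sign, **resampled per dataset** — so cross-dataset commonality of
  non-module genes is governed by chance alone, which is what makes the
  commonality ranking informative.
- Gene symbols are zero-padded tokens plus the named anchor and module;
  symbol identity is normalized by stripping and uppercasing everywhere, and
  no alias/probe resolution is attempted.
- Defaults: 5,000 genes, 10 samples per group, 7 datasets. Sample sizes and
  platform sizes of real repository series vary widely; these are stated
  choices, not estimates.

Not emulated: microarray normalization, batch and platform effects,
probe-set summarization, correlated noise between genes, missing values.
Consequently, passing tests demonstrate that the pipeline's inferential
machinery is correct and calibrated under its stated assumptions — they do
not certify robustness to the technical artifacts of real repository data.

All generators, and every stochastic stage, draw from a single root seed
through named substreams (seed words combined with CRC32-hashed tags), so
any artifact is reproducible from one integer.

## Numerical choices

- **Zero-variance genes** (possible in noiseless fixtures): identical group
  means → t = 0, p = 1; unequal means → t = ±∞, p = 0, with df falling back
  to n₁+n₂−2.
- **Hypergeometric tail** is accumulated in log space (log-binomials via
  `gammaln`, combined with `logsumexp`); results are clipped into (0, 1] and
  deep tails (p ~ 1e-300) do not underflow to zero.
- **Determinism**: ranking ties, Steiner tie-breaks and cluster labels are
  all resolved by symbol order; run reports contain no timestamps and are
  serialized with sorted keys, so identical config + seed reproduces
  byte-identical report files.
- **Degenerate pipeline inputs**: empty DE lists are skipped (a run needs at
  least one); slice levels exceeding the number of gated datasets are
  skipped with a machine-readable warning rather than failing the run.

## Validation strategy and problem sizes

The test suite checks each stage against an independent oracle: exact
rational enumeration for the hypergeometric tail (all feasible arguments up
to N = 25), the noncentral-*t* power function for planted-module stratum
occupancy (Binomial prediction over 200 simulations at 5 datasets × 200
genes), exact label-permutation p-values for the Welch test, closed-form
hypergeometric moments and a 500-replicate uniformity check for the overlap
null, brute-force Steiner search on 500 random ≤ 10-node graphs, and
planted-partition recovery (ARI = 1 over 20 seeds) for clustering.
End-to-end consensus recovery uses 100 runs of 7 datasets × 1,000 genes with
a 50-gene module. The empirical-p calibration check is run in a
wide-overlap regime (universe 10,000, target and draw size 3,000) because
the add-one estimator is conservative in the presence of heavy ties; with a
null SD of ~21 overlap counts, ties are rare relative to the p-grid.
The acceptance study in `scripts/acceptance.py` uses 10,000 genes per
cohort so the 1,000-gene ranked cohorts remain a modest fraction of the
universe, as in real repository data.

## Known limitations

- Welch *t* rather than a moderated *t* is the one deliberate
  methodological substitution (see above); at very small group sizes
  (n ≤ 3) the moderated test would behave materially better.
- The Steiner heuristic beyond the exact-search threshold guarantees
  connectivity and irredundancy, not global node-minimality.
- The clustering stand-in uses only graph distances; clusterings produced
  by services that mix interaction evidence with text mining will differ.
- The permutation null treats the universe as exchangeable; structured
  universes (e.g. GC- or expression-level-matched draws) are out of scope.
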