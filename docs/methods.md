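# Methods

This note documents the models and procedures implemented in `amp2bgc`, the
parameter choices that matter, and what the synthetic benchmarks do and do
not demonstrate.

## Reference atlas

The atlas maps each unique 16S rRNA sequence to the BGC contents of the
genomes that carry exactly that sequence.

* **Genome quality filter**: CheckM completeness ≥ 90 % and contamination
  ≤ 5 %, both bounds inclusive. Records with malformed percentages are
  rejected individually (logged), never crash the build.
* **Marker selection**: among a genome's candidate 16S sequences, those with
  non-ACGT characters or lengths outside 250–2000 nt are discarded; the
  longest survivor is kept. A genome with no survivor leaves the atlas.
* **Class mapping**: each antiSMASH region is assigned to exactly one of the
  eight BiG-SCAPE classes. The shipped product→class table follows
  BiG-SCAPE v1 conventions and is replaceable by a two-column TSV. Decision
  rule per region: products spanning a PKS class *and* NRPS →
  `PKS-NRPS_Hybrids`; all products in one class → that class; any other
  multi-class combination or any unknown token → `Others`. Tokens are
  compared case-insensitively after trimming. Consequently the profile
  total always equals the region count. Genomes with zero regions are kept
  as all-zero profiles — they are informative negatives.
* **Dereplication**: exact string equality of the full marker sequence;
  multiplicities are preserved, so the sum of entry multiplicities equals
  the number of genomes passing all filters.
* **Aggregation strategies**: per class, mean or median over member
  profiles; the `*_int` variants round to the nearest integer with ties
  away from zero (3.5 → 4). All four are the identity on single-member
  entries. Duplicate genome ids in the metadata are a hard error because a
  silent overwrite would corrupt multiplicities.

## Identity-search engine

Local pairwise alignment with match +1, mismatch −2, and affine gaps costing
5 + 2L for a gap of length L (the BLASTn default open/extend pair; note
"open 5, extend 2" in the BLAST convention charges open *plus* extend per
position). Percent identity is identical columns over alignment length
(BLAST `pident`). The aligner is exact; a k-mer prefilter (k = 11) only
limits *which* references get aligned: candidates are ranked by shared
distinct k-mer count and capped at 50 per query. The best hit maximises
score, with ties broken by higher identity, then lexicographically smallest
reference id — fully deterministic across runs and platforms. Queries whose
best identity falls below the threshold (default 80 %, the lowest identity
tier the accuracy protocol distinguishes) are reported as failures.
Precomputed BLAST outfmt-6 tables are accepted as an external engine;
malformed lines are rejected per line with line numbers.

Caveat: for truly non-homologous inputs a short perfect local block can
carry a high `pident` at a low score; the engine ranks by score, so this
only matters if a query shares no real homology with any reference. The
intended input domain (16S sequences, which are globally homologous) avoids
the issue.

## Phylogenetic engine

The full placement stack of phylogenetic marker-gene predictors is replaced
by documented nearest-reference grafting: the query attaches at the midpoint
of its best hit's terminal branch, on a pendant of Jukes–Cantor length
d = −(3/4)·ln(1 − (4/3)p), p = 1 − identity/100, capped at 1.0
substitutions/site (the cap applies directly at and beyond p = 0.74, near
JC saturation). This preserves the decision-relevant quantity — which
neighbourhood informs the inferred state — without an external placement
dependency. A query identical to a reference (p = 0) inherits that
reference's state directly rather than passing through the HSP machinery:
with midpoint attachment, squared-change parsimony at the attachment node
is a weighted blend of all tips and would not return the neighbour's exact
profile even at pendant 0.

Hidden-state prediction methods, each applied per class independently:

* `subtree_average`: ascend from the attachment until the subtree contains
  at least one observed tip; return the arithmetic mean of observed tip
  states in it.
* `scp` (squared-change parsimony): minimise Σ_edges (Δstate)²/length with
  observed tips fixed. Solved exactly by the standard two-pass
  weighted-average algorithm (downpass conditional values with effective
  branch lengths, uppass complements); this coincides with the
  maximum-likelihood ancestral states under Brownian motion. Zero branch
  lengths are replaced by ε = 1e−6 for this method only. Verified in the
  test suite against direct numerical minimisation of the objective.
* `mp` (Sankoff maximum parsimony): integer states 0..max_state
  (default max observed + 5), linear edge cost |i − j|, branch lengths
  ignored, backtrace ties resolved toward the smallest state. Verified
  against exhaustive enumeration on small trees. Note that with the
  smallest-state tie rule a genuinely tied topology resolves downward; this
  is deliberate and deterministic.

`pic` and `emp_prob` variants are not implemented. When no reference tree
is supplied, a neighbor-joining helper builds one from pairwise JC distances
over the atlas (quadratic; intended for modest atlas sizes).

## Per-sample aggregation

A[s, c] = Σ_f T[f, s]·P[f, c] over successfully predicted features, using
absolute feature counts (a `--relative` switch row-normalises the output).
Failed or unmatched features are excluded, not imputed; the excluded
fraction of total table abundance is reported. Per-sequence CSV totals are
recomputed at write time as the sum of the eight class columns so the file
is self-consistent under integer rounding strategies. All CSVs are UTF-8,
comma-separated, LF, floats at 6 significant digits.

## Validation statistics

* **Profile similarity**: (1/8)·Σ 1/(|a_i − b_i| + 1); equals 1 iff equal,
  symmetric, strictly decreasing in any single coordinate gap.
* **Intra-cluster statistics**: mean, median, population standard deviation
  (divide by the number of pairs), minimum and maximum over all C(n,2)
  pairs; singleton clusters are excluded.
* **Greedy clustering**: sequences sorted longest-first (ties by id); each
  joins the first centroid, in creation order, at ≥ threshold identity by
  the engine's aligner, else seeds a new cluster. Only the greedy semantics
  of CD-HIT are reproduced, not its word filters; a conservative shared-k-mer
  screen — skip a centroid when the shared distinct 11-mer count is below
  (L_min − k + 1) − 2k(1 − t)L_max — merely skips alignments that cannot
  reach the threshold (the 2× factor absorbs gap effects and repeats; the
  tests confirm equality with an unscreened reimplementation).
* **Outliers**: Tukey fences Q1 − 1.5·IQR, Q3 + 1.5·IQR with
  linear-interpolation quartiles; groups of fewer than 4 values are skipped;
  the rate is pooled over groups.
* **Accuracy protocol**: deviations |predicted − true| of total BGC counts
  binned into [0,1], (1,5], (5,∞); proportions are over successful
  predictions with failures counted separately. Identity tiers are
  left-open right-closed — (0,80], (80,90], (90,95], (95,100], with 0
  assigned to the first tier. Per-class evaluation applies the same bins to
  each class column.
* **V3–V4 extraction**: in-silico PCR with 341F (`CCTACGGGNGGCWGCAG`) and
  805R (`GACTACHVGGGTATCTAATCC`), IUPAC matching, up to 2 mismatches per
  primer, best (fewest-mismatch, leftmost) sites, primers excluded from the
  returned span.

## Synthetic data

The generator emulates the paired 16S–genome test design:

* **Tree**: Yule pure-birth (unit rate), branch lengths rescaled so the
  mean root-to-tip depth is 0.1 substitutions/site — the scale at which tip
  pairs span roughly 80–100 % sequence identity, matching the identity range
  the evaluation stratifies.
* **Sequences**: Jukes–Cantor evolution, default length 1200 nt,
  substitution-only (no indels), so simulated homologs are positionally
  alignable.
* **Traits**: per class, a reflected ±1 random walk along branches with
  Poisson(step_rate·length) steps, keeping all counts integer and
  non-negative at every node. Default step_rate = 5 steps/class/unit
  branch: tip pairs at ~97 % identity (path ≈ 0.06) then expect ≈ 0.3 steps
  per class, i.e. near-identical profiles among close relatives — the
  regime the marker-gene approach presumes. Default root profile
  (1,0,2,0,2,0,1,1), a modest 7-BGC bacterium.
* **Benchmark**: tips split into references (atlas + sheared reference
  tree) and holdout queries; each query's best identity to the reference
  set is logged. An optional identity band re-mutates queries into the band
  by positional edits toward/away from their best reference (truth traits
  are never altered). `tune_pendant_steps=s` calibrates the step rate so
  the expected number of trait steps summed over the 8 classes along a mean
  query pendant equals s.
* **Amplicon fixture**: half reference-identical, half lightly mutated
  features; negative-binomial counts (mean 50, dispersion 2), the standard
  overdispersed model for amplicon abundances; emitted as FASTA + TSV +
  BIOM v1 JSON.

What the synthetic benchmarks do **not** show: robustness to chimeras,
sequencing error, intragenomic 16S copy variation, horizontal gene transfer
(which decouples traits from phylogeny), or assembly artefacts in reference
annotations. Passing them demonstrates the correctness of the machinery and
the qualitative identity–accuracy relationship, not field performance on
real microbiomes.

## Problem sizes and numerics

The acceptance computations use 250 tips (200 references / 50 queries) for
the identity-engine accuracy check and 300 tips for the clustering-trend
check — sizes chosen so the full suite completes in minutes on one CPU
while leaving dozens of non-singleton clusters and a 50-query test set.
Randomness flows through `numpy.random.Generator` seeded per step from the
run seed; reruns are byte-identical. Alignment correctness is pinned by a
brute-force Gotoh oracle (200 random pairs up to 300 nt, exact score and
identity equality); SCP by numerical minimisation (1e−5); Sankoff by
exhaustive enumeration on ≤ 6-tip trees.

## Known limitations

* The product→class table is a reconstruction of BiG-SCAPE v1 conventions;
  users with their own mapping should pass `--mapping`.
* The phylogenetic engine's grafting is nearest-neighbour, not
  likelihood-based placement; for queries equidistant from several clades
  the inferred neighbourhood may differ from a full placement stack.
* BIOM v2 (HDF5) tables are not read; export v1 JSON or TSV.
* The NJ helper scales quadratically and is not meant for atlases beyond a
  few hundred entries.
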