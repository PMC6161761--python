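# Methods

This note documents the models, conventions, parameter defaults and
numerical choices behind `cnepairs`, and what the synthetic benchmark does
and does not demonstrate.

## Coordinates and formats

All intervals are 0-based, half-open `[start, end)` (BED convention); the
length of `[s, e)` is `e − s` everywhere. GTF input (1-based, closed) is
converted on read. The midpoint of `[s, e)` is `⌊(s+e)/2⌋`, which makes
midpoint-derived quantities deterministic for odd lengths. Signal tracks
follow the sparse bedGraph convention: positions outside every listed bin
have value 0, and fold-enrichment 1.0 is the control (background) level —
an all-background region must therefore be listed explicitly. Strand is
ignored except for TSS extraction, where the gene strand selects the 5'
end; every other quantity in the pipeline is strand-free.

Two distinct inter-CNE conventions coexist deliberately. Distance-type
quantities (`d_h`, `d_r`, transposon lengths `T_h`, `T_r`, density regions)
use the **midpoint-to-midpoint span**; epigenetic summaries use the
**inner-edge interval** `[left.end, right.start)`. Both are kept because
they serve different definitions and neither can substitute for the other.

## Pair construction

Conserved elements closer than 100 bp are merged transitively left-to-right
on the sorted set; merged elements shorter than 100 bp are removed (the
merge runs before the length filter, so short fragments that coalesce into
a long element survive). Elements are classified by descending precedence
exon > UTR > intron > intergenic against protein-coding genes only;
anything not exonic is a CNE. Adjacency is computed over *all* conserved
elements, coding included — a coding element between two CNEs breaks their
adjacency — and a pair is emitted only when both members are noncoding and
neither exceeds 1,000 bp (long elements likely aggregate several conserved
features).

Orthology is reciprocal-best-hit: the top-scoring forward hit is accepted
iff the top-scoring reverse hit of that target overlaps the original query
by at least 1 bp. Score ties break deterministically (higher score, then
smaller target start, then lexicographic chromosome) and are logged. A pair
is "conserved in species S" iff both CNEs have orthologs in S on the same
chromosome with midpoint distance ≤ 250,000 bp; a larger ortholog distance
in *any* species discards the pair (suspected misassignment or
rearrangement). The distance cap is applied to midpoint distances for
consistency with `d_h`. "Mammalian conserved" requires conservation in
platypus; "deeply conserved" requires ≥ 2 of lizard, turtle, chicken,
zebra finch, frog, fugu, zebrafish. Ortholog adjacency in the second
species is required only for the two-genome (AO) pair analysis, where both
orthologs must additionally form a pair in the other genome.

## Ancestral reconstruction

A continuous trait evolving by Brownian motion on a dated tree has a
Gaussian tip distribution whose ML state at an internal node `r` is the GLS
mean `x̂ = (1ᵀC⁻¹x)/(1ᵀC⁻¹1)`, with `C_ij` the shared path length from `r`
to the divergence of tips `i` and `j` (the covariance of the tree rerooted
at `r`). The diffusion rate σ² multiplies `C` uniformly and cancels, so it
is never estimated. The estimate is a convex combination of tip values and
an exact match to brute-force maximization of the joint likelihood over all
internal states (asserted in the tests against an independent quadratic
solver on random trees).

Practical choices: species without an observation are pruned per pair
(pairwise deletion, mirroring per-pair ortholog availability); polytomies
are resolved with zero-length internal branches (a seeded, arbitrary
resolution — zero-length branches leave the BM likelihood unchanged);
traits are reconstructed on the raw bp scale, matching the direct use of
`d_r` in nRDD. The common mammalian ancestor is the MRCA of the mammalian
tips; without a platypus observation that node is not identifiable (the
MRCA of the remaining mammals is a more recent node), so such pairs are
flagged `no_platypus` and skipped. Ancestral transposon traits use
*lengths* (covered bp within the midpoint span) rather than densities, as
the length is what enters the nRTD formula; negative GLS outputs are floored
at 0 and flagged. GLS weights are cached per observed-species subset.

## nRDD, nRTD and groups

nRDD = (d_h/G_h − d_r/G_r) / ((d_h/G_h + d_r/G_r)/2) with default
`G_r = 3,270,000,000 bp`. As a relative difference of positive quantities it
is strictly inside (−2, 2); ±2 are the complete-loss/appearance limits. nRTD
applies the same form to transposon-covered lengths; `T_h = T_r = 0`
(transposon-free in both genomes) is reported as undefined (NaN) and
excluded from summaries rather than coerced to 0, because transposon-free
regions form a biologically distinct category. Decile groups sort by
(value, pair id) — the id breaks ties deterministically — and split into 10
contiguous blocks whose sizes differ by at most 1, the first `n mod 10`
groups absorbing the remainder.

## Transposon densities and the randomization test

Densities are covered fractions computed on class-wise merged intervals;
the total uses the union of all classes, so total ≤ sum of class densities
and ≥ their maximum. The depletion test matches each real region with one
random region of the same length (uniform start, fully inside a
chromosome; an optional mask supports gap exclusion on real assemblies),
compares the paired density vectors with a two-sided Wilcoxon signed-rank
test, and repeats this 1,000 times. Two summaries are reported per class:
`prop_significant`, the fraction of replicates with p ≤ 0.05, and its
complement `empirical_p` — the headline column, small when the effect is
strong. The direction is the sign of the median paired difference across
replicates.

A separate calibration routine measures the per-replicate test size under
the null by drawing *both* the "real" surrogate set and its random
counterpart fresh in every replicate. This is the configuration in which
the real regions are statistically identical to random regions; holding one
fixed real draw across all replicates instead measures a quantity
conditional on that single draw, which has the correct 5% mean over draws
but large draw-to-draw spread, and is therefore not a usable check of the
test's size.

Gain/loss calls compare present-day and ancestral lengths with a tolerance
ε = 1 bp absorbing the continuous ancestral estimates: loss = ancestral
presence only, gain = present-day only, stable = both, absent = neither
(boundary values `≤ ε` count as absent). A pair is transposon-free iff all
eight per-class values (4 present-day + 4 ancestral) are ≤ ε.

## Epigenetic summaries

Per pair, tissue and mark: 300-bp windows centered on each CNE midpoint,
the inner-edge inter-CNE interval, and the best 200-bp window inside it.
The window scan strides at the track bin size (default 25 bp, matching
consortium-style binned tracks) with a flush-right final window. The best200
value is floored at the whole-region mean: a max over overlapping windows
can undershoot the region average when signal concentrates at both region
edges, and best200 is defined to dominate the region mean (regions shorter
than 200 bp fall back to the whole-region mean and are flagged). The two
CNEs are relabelled CNE_h/CNE_l by their mean H3K27ac window level across
tissues (ties go left), making the feature matrix invariant to left/right
orientation. Feature columns are ordered tissue-major, then region (CNE_h,
CNE_l, interCNE, best200), then mark alphabetically; the column count is
enforced to `n_tissues × 4 × 5`. "Above background" means fold-enrichment
strictly greater than 1.0, since 1.0 *is* the control level. The tissue
panel is taken from the input directory rather than hard-coded, as
different screens legitimately use different panels.

## Self-organizing map

12 units on a 4 × 3 hexagonal grid (offset rows, unit spacing 1), codebooks
initialized to distinct random input rows, 1,000 online iterations: draw a
row uniformly, find the best-matching unit by Euclidean distance (ties to
the lowest unit id), update all units within the bubble toward the sample.
The learning rate falls linearly 0.05 → 0.01. The bubble radius falls
linearly from the 2/3 quantile of the grid distance distribution to 0, so
the later part of training updates the BMU alone and codebooks settle on
their members' centroids — the schedule the classic SOM packages default
to. (A radius floor of 1.0 was tried first and rejected: with unit grid
spacing it keeps immediate neighbors coupled until the last step, which
visibly prevents convergence and can leave the trained quantization error
above that of the random initialization.) Features enter unscaled — fold
enrichments share a scale — with an optional z-scoring flag. Unit
fingerprints (mean enrichment per region × mark across tissues and member
pairs) feed complete-linkage hierarchical clustering cut at k = 4, and
cross-map comparisons use reciprocally-nearest unit pairs, with unmatched
units inheriting the cluster of their nearest matched unit. Specific
unit-to-cluster assignments are data outcomes, not constants.

## Enrichment statistics

Odds ratio (N11/N10)/(N01/N00) with explicit conventions: zero numerator
cell → 0, zero `N01` with positive `N11` → +∞, 0/0 branches → undefined
(flagged). Significance is the one-sided ("greater") Fisher exact test —
the screen reports overrepresentation only — computed as the hypergeometric
upper tail; the tests verify it against exhaustive integer enumeration of
every table with total ≤ 60. The FDR family is all group × unit tests of
one analysis run (10 groups × 12 units), adjusted by Benjamini–Hochberg.
Wilcoxon tests use exact null distributions for small tie-free samples
(n ≤ 25 signed-rank, both sizes ≤ 12 rank-sum) and a continuity-corrected
normal approximation otherwise; zero differences are dropped (Wilcoxon's
original treatment) and ties take midranks.

## Synthetic data: what it emulates

The generator plants a complete study: 23 vertebrate species (16 mammals,
7 outgroup vertebrates) on an ultrametric tree with approximate divergence
times in My (root 430 My, mammalian ancestor 180 My); per-pair ancestral
distances log-uniform on [1,000, 50,000] bp evolving by BM (default
σ² = 10 bp²/My — the low-drift regime in which per-branch displacement is
small relative to the distances, so recovery tests measure estimator
correctness rather than irreducible noise) outward from the mammalian
ancestor; class fractions 0.3/0.4/0.3 for contracted/conserved/expanded
matching the decile-bin structure (groups 1–3/4–7/8–10), with deterministic
focal-branch shifts of −0.5·d_r (contraction) and +1.0·d_r (expansion);
distances clipped at 200 bp (with the default distance range the clip never
binds, so no clipping bias is incurred; at higher σ² the clip would bias
reconstructions upward). CNEs of 100–1,000 bp are placed on one synthetic
chromosome per species (auto-sized to 3× the span) so that midpoint
distances match the simulated values *exactly*; a 2-kb coding element
between consecutive focal pairs prevents spurious cross-pair adjacency;
inter-CNE gaps stay ≥ 100 bp so the merge rule cannot swallow a planted
pair. Hit tables contain the true ortholog as best hit plus optional decoys
at 0.5–0.95× the best score and an optional fraction of
reciprocal-best-violating entries to exercise RBH rejection.

Transposons: ancestral per-class densities 0.05/0.05/0.03/0.02
(SINE/LINE/LTR/DNA) of the midpoint span — depleted relative to the
genome-wide background of 0.46 total (0.13/0.21/0.08/0.04), the covered
fraction at which background intervals are laid down outside planted pair
regions. 15% of pairs are transposon-free. Contracted pairs lose all focal
transposons; expanded pairs gain SINEs/LINEs proportional to the added
span. Epigenetic tracks plant four archetypes — inactive (baseline 1.0),
CNE-active (H3K27ac/H3K4me1/H3K4me3 high across the pair), CNE-poised
(H3K27me3+H3K4me1 at the CNE windows), inter-CNE-poised (one 200-bp
H3K4me1/H3K27me3/H3K9me3 hotspot) — at amplitude 5 over baseline with
Gaussian bin noise (sd 0.25), on a 25-bp grid aligned with the window
stride. The archetype mixture depends on the contraction class (conserved
pairs carry most poised/active CNE signal; expansions favor isolated
inter-CNE hotspots), which plants the group-in-unit enrichment the
enrichment screen must detect.

What the synthetic data does **not** emulate: nucleotide sequence (no
FASTA anywhere), assembly gaps and alignability structure, realistic
transposon subfamily phylogenies or age structure, inter-chromosomal
rearrangements, correlated noise across tissues, or cell-type-specific
archetype switching. Passing recovery tests therefore demonstrates that the
estimators and tests are correct and calibrated under their stated models,
not that real genomes satisfy those models.

## Problem sizes and determinism

The standing benchmark uses 500 pairs × 3 tissues for parameter recovery,
1,000 replicates for null calibration, 10,000 tuples for the nRDD bound,
100 random trees for the BM oracle, and every contingency table with total
≤ 60 for the Fisher oracle — sizes chosen so the complete suite runs on a
single CPU in minutes while keeping Monte-Carlo error well inside the
asserted tolerances. All randomness flows through seeded numpy generators;
identical config + seed reproduces every output file byte for byte.

## Known limitations

- The midpoint-span transposon convention counts half of each CNE; heavily
  transposon-overlapping CNEs (rare after conservation filtering) blur the
  inter-CNE signal slightly.
- GLS caching assumes the per-pair species subsets repeat; pathological
  inputs where every pair has a distinct subset forfeit the speedup (not
  the correctness).
- The AO-pair module requires both genomes' pair sets and ortholog maps in
  memory; it has not been profiled beyond tens of thousands of pairs.
- `empirical_p = 1 − prop_significant` is a replicate-vote summary, not a
  p-value with uniform null distribution; the calibration routine exists
  precisely to check the per-replicate size instead.
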