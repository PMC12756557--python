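# Methods

## Problem and model

The package targets cohorts — here modelled on *Populus*, where related
species form syngameons connected by frequent hybridization — in which
pairwise relatedness must be estimated from whole-genome variant calls of
samples that may be pure species members or inter-species hybrids. The
unit of information is the per-sample **variant allele frequency** at a
site, `v = AO / DP`: for a diploid it concentrates near 0, 0.5 or 1 by
genotype, so an F1 hybrid of two taxa fixed for alternative alleles sits at
0.5 — intermediate between its parents in VAF space. Distances on VAF
vectors therefore place hybrids between their parental clusters, which a
presence/absence genotype distance would blur.

## Record inclusion

Records enter the analysis only if their Phred quality is *strictly*
greater than 25, and they satisfy the caller minima: alternate
observations ≥ 4, total depth ≥ 5, VAF ≥ 0.2 (boundary values pass —
these are minimums). Multi-allelic records are collapsed to a single
alternate with summed observation counts and are keyed by
(chrom, pos, ref, alt) without normalization or decomposition. `DP`/`AO`
INFO fields are the primary source (per-sample caller output semantics);
per-sample `AD`/`DP` FORMAT fields are the fallback when `AO` is absent.
Optionally the site union is restricted to CDS intervals given as 0-based
half-open BED; a 1-based site *p* is inside [start, end) iff
start < p ≤ end, and this conversion lives in a single function.

A site with adequate coverage but no surviving record is assigned VAF 0.0
(reference-homozygous) by default. The usable-position mask excludes only
low-coverage positions, which implies covered-but-uncalled positions
contribute as reference; because the alternative reading (treat them as
missing) is defensible, `build_vaf_matrix(..., uncalled="missing")`
exposes it, and both behaviours are tested.

## Distance

For samples *i*, *j*: `P_ij = { p : depth_i(p) ≥ t and depth_j(p) ≥ t }`
with t = 8 reads by default, depths taken from an explicit per-sample ×
per-site depth table (variant records alone do not carry coverage at sites
where a sample has no call; the table makes the pair mask computable and
is agnostic about whether coverage came from the caller's DP or a separate
track). Then

d_ij = sqrt( |P_ij|⁻¹ · Σ_{p∈P_ij} (v_i(p) − v_j(p))² ),

the normalization inside the square root. Properties relied on downstream:
0 ≤ d ≤ 1 (VAF range), invariance to |P_ij|, exact symmetry and zero
diagonal. Pairs with fewer than a configurable floor of usable sites
(default 1) are flagged undefined; clustering refuses flagged matrices
rather than imputing, since there is no principled fill-in value. The
implementation is three matrix products over the 0/1 coverage mask; tests
compare it to a naive double loop at 1e-12. Exports round distances to 6
decimals with a `%.17g` full-precision sidecar, read back with round-trip
float parsing.

## Clustering

Ward.D2 agglomeration via the Lance–Williams recurrence on squared
distances,

d²(k, i∪j) = ((n_i+n_k)·d²(k,i) + (n_j+n_k)·d²(k,j) − n_k·d²(i,j)) / (n_i+n_j+n_k),

heights reported on the distance scale (two singletons merge at their
distance), matching R's `hclust(method = "ward.D2")` and scipy's `ward`.
The implementation is authored here rather than delegated because a
deterministic tie-break is wanted: among minimum-cost merges the
lexicographically smallest (low-id, high-id) cluster pair wins, making
output platform-independent where library nearest-neighbour-chain orders
are unspecified. Two independent cross-checks cover it: a naive oracle
that recomputes every cluster-pair cost from the *original* squared
distances at every step via the stored-data identity
D²(A,B) = 2·(W(A∪B) − W(A) − W(B)), W(C) = |C|⁻¹ Σ_{pairs in C} d², and
scipy's `linkage(..., "ward")` on the condensed matrix. The O(n³) global
minimum search is ample for cohort sizes here (≤ ~100 leaves).

Newick export is ultrametric: branch length = parent merge height − child
merge height, leaves at height 0; labels containing Newick
metacharacters are single-quoted with internal quotes doubled. Tree
cutting uses scipy's `cut_tree` on the linkage matrix; partition agreement
is scored with the adjusted Rand index (chance-corrected; 1 = identical).

## Bootstrap clade support

Replicates resample site columns with replacement (same count), carrying
the depth mask with each resampled column, then recompute masked distances
and the tree. Resampling precedes the per-pair mask re-application — the
replication unit is the character (position) underlying the distance, the
only unit available to a position-wise analysis; this ordering is an
assumption, documented here. Support of a reference-tree clade is the
fraction of replicate trees containing an identical leaf set (trivial
clades excluded). Replicate r draws from a stream keyed by (seed, r), so
results are reproducible and order-independent. A replicate with an
undefined pair is dropped and counted; more than 10% dropped aborts with a
diagnostic, since supports over a heavily censored replicate set would be
biased. The default is 1000 replicates; validation experiments use 200,
where clade support estimates have a standard error below 0.04.

## Synthetic cohorts

The generator emulates: K populations diverged from a shared ancestor
(ancestral frequency p ~ Uniform over (0.05, 0.95) by default; population
frequency q ~ Beta(p(1−F)/F, (1−p)(1−F)/F), the Balding–Nichols drift
model, F the divergence parameter), diploid genotypes g ~ Binomial(2, q),
F1 hybrids with one allele from each parent's frequency, depth
D ~ Poisson(mean 30), and alternate reads A ~ Binomial(D, (g/2)(1−e) +
(1−g/2)e) with error rate e = 0.005. A record is emitted iff A ≥ 4, D ≥ 5
and A/D ≥ 0.2, with a fixed placeholder quality of 60 (the strict Q > 25
path is exercised by a separate low-quality fixture). Sites sit at
positions 1..m on one synthetic contig; the depth table carries D for
*every* sample at the union of emitted sites, which is what makes the
pair mask computable. Default cohort scale for validation: 3–5 species ×
4 samples, 1–2 F1 pairs, 2000 sites, F ∈ [0.3, 0.5] — divergence deep
enough that species are well-separated but frequencies are not fixed,
i.e. a strong- but not degenerate-signal regime.

One RNG seeded once drives all draws in a fixed vectorised order;
identical config + seed reproduces the cohort byte-for-byte, but draw
stability under config edits (e.g. adding a sample) is deliberately not
guaranteed. What the simulator does *not* model: linkage/coalescent
genealogy (sites are independent), indels and multi-allelic variation,
mapping error, duplicate reads, or depth heterogeneity beyond Poisson.
Passing recovery tests therefore demonstrates correctness of the
distance/clustering machinery under the stated sampling model, not
robustness to alignment artifacts or LD structure in real data.

## Validation instrumentation

`cut_and_score` (tree cut + ARI against truth labels, optionally restricted
to pure samples) and `hybrid_intermediacy` (mean inter-group distances:
each F1 group must be closer to both parent groups than the parents are to
each other) quantify recovery on simulated cohorts. The packaged
23-sample manifest transcribes the study collection this pipeline is
designed around (23 samples, 11 taxa, sections Tacamahaca / Aigeiros /
intersectional hybrids); the packaged 97-sample joint manifest extends it
with 74 synthetic SRA-style entries so that cohort-scale runs (97-leaf
dendrograms) are exercised without archive downloads.

## Numerical and degenerate-input choices

- Squared-difference sums are clipped at 0 before the square root
  (matrix-product rounding can produce −1e-17 for identical rows).
- The distance matrix is symmetrized as (d + dᵀ)/2 to remove
  last-ulp matmul asymmetry; the diagonal is set to exactly 0.
- Zero samples/sites, F outside (0,1), hybrid parents out of range,
  error rate outside [0, 0.05]: explicit `ValueError`s, never empty files.
- `N_ii` (diagonal of the usable-site counts) is the sample's own
  covered-site count — the pair-mask definition applied at i = j.
- Empty manifests and duplicate sample ids are rejected by name.

## Problem sizes used in tests and acceptance

Validation cohorts use 2000 sites and ≤ 24 samples with 200 bootstrap
replicates over 5 seeds; oracle comparisons use ≥ 100 random instances of
3–11 samples. These sizes give stable, separated statistics for the model
above while keeping the suite fast; they are the package's validation
conditions, not limits of the implementation.
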