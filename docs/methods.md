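# Methods

## The inference

Two cell populations are called distinct memory compartments when they
share significantly fewer TCR clonotypes than expected under random
assortment. The statistic is the count of *distinct* clonotypes present in
both populations; the null model is cell-label exchangeability: all cells
of the two populations are pooled, each keeping its clonotype, and
compartment labels are reassigned uniformly at random with the two group
sizes held fixed. Shuffling whole cells (rather than clonotype identities)
preserves the pooled clone-size distribution exactly, which is the only
null compatible with holding subset sizes constant in cells. The test is
one-sided toward *low* overlap, because the scientific alternative is
repertoire segregation; a two-sided variant is exposed.

The Monte-Carlo p-value uses the add-one estimator
`p = (1 + #{null ≤ observed}) / (1 + n_permutations)`, which is never zero
(floor `1/(n_permutations+1)`, i.e. 1/1001 at the default 1000
permutations) and is valid (super-uniform) under the null.

### Tie handling and calibration

The overlap statistic is integer-valued, and with realistic group sizes a
substantial fraction of null draws ties the observed value. Counting ties
fully (the reported default) makes the p-value conservative: its null
distribution is stochastically *larger* than uniform, so rejection rates
run below nominal (a property verified by the DKW-banded calibration test
in the suite). For calibration diagnostics the test also offers `ties="mid"`
(half-weight to ties) and `ties="randomized"` (uniform-weight to ties,
exactly uniform under exchangeability). These affect only the p-value, not
the null histogram, and are off by default: reported results should err
conservative.

### Reproducibility of a test battery

Each (donor, lineage, scope, pair) stratum derives its own RNG seed as
`(master_seed · 2654435761 + crc32(stratum_id)) mod 2³¹`, so adding or
removing one stratum never perturbs another's stream. Inside one test the
pooled clonotype multiset is sorted and the smaller group size taken as the
first permutation block; the statistic is symmetric in the two blocks, so
swapping the compartments with the same seed reproduces the null
distribution exactly.

## Clonotype calling

A clonotype is the exact pair of alpha- and beta-chain CDR3 amino-acid
sequences; V/J gene segments and nucleotide sequences are deliberately
ignored, and cross-donor key collisions are tolerated because every
analysis stratifies by donor. Contigs flagged as non-cell, low-confidence
or non-productive, and CDR3s containing stop codons or non-standard
residues, are removed first. When one locus has several surviving contigs,
the highest-UMI contig wins, with ties broken by lexicographically smallest
CDR3 — deterministic and order-independent. Barcodes lacking either locus
after filtering are excluded (counted and logged, never raised).

## Gating

Gating thresholds act on log1p-transformed antibody counts. Defaults are
2.3 (≈ raw count 9) for all three markers; like any "manual" gate they are
dataset-specific configuration, not code. Lineage assignment requires
exactly one of CD4/CD8 above threshold; double-positive barcodes are
rejected as putative doublets and double-negatives as non-T events, since
the assay sorts the two lineages separately upstream. Blood cells are not
split on surface CD69 by default — circulating memory T cells are the
surface-CD69-negative reference — but a `split_blood_cd69` option exists.

The opt-in `auto-valley` mode places each cutoff at the kernel-density
minimum between the two dominant modes of the log1p counts. Raw antibody
counts are integers, so the KDE shows one spike per count value at the low
end; local maxima closer than 1.0 log-units are merged, maxima below 2 % of
the peak are ignored, and the valley is only accepted if it dips below 0.7×
the smaller mode — otherwise the distribution is treated as unimodal and
the configured fallback is returned with a flag.

## Diversity

Per stratum the package reports the plug-in Gini–Simpson index
`1 − Σ (nᵢ/N)²` — the probability that two cells drawn with replacement
carry different clonotypes, matching the two-cell-disagreement reading —
with the unbiased without-replacement form
`1 − Σ nᵢ(nᵢ−1)/(N(N−1))` as an option. Shannon entropy is in nats by
default (configurable base), with no evenness normalization. Strata with
fewer than `min_cells` cells (default 20) are flagged `insufficient` rather
than dropped, mirroring the practice of excluding very small clusters from
repertoire statistics; the same gate skips overlap tests on undersized
groups.

## The synthetic generator

The generator emulates a multi-donor paired blood/bone-marrow CITE-seq +
V(D)J experiment. Defaults: 3 donors, both lineages, 1000 cells in each of
the three compartments (Blood, BM CD69⁻, BM CD69⁺) per donor and lineage —
in the range of cells per compartment such experiments yield — 10
transcriptional clusters with geometrically decaying frequencies (the
CD69⁺ compartment tilted toward cluster 2, echoing the dominance of one
resident cluster in tissue data), 100 clonotypes per (donor, lineage,
cluster, compartment) pool, and a sharing fraction of 0.2, reflecting the
partial clonal connectivity between blood and tissue that motivates the
test.

Clone frequencies follow the configured law *as a fixed probability vector
over clone ranks* (geometric with p = 0.10 by default, i.e. the largest
clone holds ~10 % of the pool; a discrete power law is the alternative),
randomly permuted across clonotype identities. Cells are then sampled
i.i.d. from that vector. This makes the realized clone-size frequencies
match the law up to multinomial noise (testable by goodness of fit) and —
because a `sharing_fraction` of 1 gives every compartment the identical
pool *and* identical frequency vector — makes compartment labels exactly
exchangeable, the regime in which the permutation test's calibration is
provable. Shared clonotypes occupy the same frequency rank in every
compartment; at sharing 0 the pools are pairwise disjoint.

CITE counts are two-component negative-binomial mixtures on the raw scale
(negative mode mean 1, positive mode mean 60, dispersion 8), giving the
clean bimodality on the log1p scale that marker gating requires. CD4 and
CD8 positive modes are mutually exclusive by lineage; CD69 is positive only
in the surface-CD69⁺ bone-marrow compartment. Optional noise — secondary
alpha chains at lower UMI count and non-productive contigs — is off by
default and exists to exercise the ingest resolution rules.

What the generator does *not* emulate: transcriptome-driven cluster
structure (cluster labels are drawn, not inferred), ambient-antibody
background and isotype effects in CITE counts, barcode collisions or
doublets, PCR/UMI errors in CDR3 sequences, and convergent recombination
across donors. Passing tests therefore demonstrate the correctness and
calibration of the statistics on data with the stated sampling structure,
not robustness to those artifacts in real data.

## Numerical and engineering choices

- Permutations are vectorized in chunks of 256 shuffles; each chunk is
  checked against the pooled clonotype multiset before use.
- All randomness flows through `numpy.random.default_rng` seeded
  explicitly; derived seeds stay below 2³¹.
- Output tables are written with `%.10g` float formatting so identical runs
  are byte-identical; re-execution equality is part of the test suite.
- Degenerate inputs: empty strata yield missing diversity values; a test
  with every cell sharing one clonotype returns p = 1; groups below
  `min_cells` are flagged skipped rather than tested.
- No multiple-testing correction is applied by default (per-test p-values
  are reported, with 0.05 as the conventional reporting line); a
  Benjamini–Hochberg pass over the suite output is left to the caller.

## Problem sizes in the test battery

The operating-characteristic simulations use 500 calibration tests (300
cells/group, 100-clonotype geometric pools, 200 permutations), 100 power
replicates (same geometry, 1000 permutations), 50 selectivity replicates
(two clusters of ~250 cells per side, one fully shared, one fully private),
and a 3-donor, 10-cluster, 6-subset end-to-end determinism run — sizes
chosen to keep each battery in the seconds-to-minutes range on one CPU
while leaving Monte-Carlo error well inside the asserted margins.

## Known limitations

- The conservative tie-inclusive p-value under-rejects at nominal levels on
  heavily tied overlap statistics (see *Tie handling*); use the randomized
  variant when studying calibration itself.
- Clonotype identity by exact CDR3-aa pairs cannot distinguish convergent
  clonotypes and ignores cells with two genuine alpha chains (the
  higher-UMI chain is taken).
- Auto-valley gating assumes well-separated bimodal markers; markers with a
  continuum of expression need manually chosen gates.
- The cluster × compartment frequency matrix pools donors; per-donor
  composition is recoverable from the per-cell table.
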