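# tcrcompart

Compartmentalization analysis of paired-chain single-cell T-cell receptor
(TCR) repertoires, for immunologists comparing memory T cells between blood
and a tissue such as bone marrow (BM).

Memory T cells persist both in circulation and as tissue residents. Whether
the blood and tissue populations are one exchanging pool or distinct
compartments can be read off their TCR repertoires: if two populations were
seeded and maintained independently, they should share fewer clonotypes
than random assortment of the same cells would produce. `tcrcompart`
implements that inference end to end:

1. **Clonotype calling** — each cell barcode in a 10x-style
   `filtered_contig_annotations.csv` is resolved to one paired clonotype,
   defined by the exact alpha- and beta-chain CDR3 amino-acid sequences
   (`TRA:<cdr3>|TRB:<cdr3>`). Cells lacking a complete productive
   annotation for both chains are excluded; multiple contigs per locus
   resolve to the highest-UMI call.
2. **CITE-seq gating** — log1p-transformed antibody counts for CD4, CD8 and
   CD69 assign each cell to one of six subsets: Blood CD4⁺, BM CD4⁺CD69⁺,
   BM CD4⁺CD69⁻, Blood CD8⁺, BM CD8⁺CD69⁺, BM CD8⁺CD69⁻ (surface CD69
   marking putative tissue residents).
3. **Diversity** — per (donor, lineage, cluster, compartment) stratum the
   Gini–Simpson index `1 − Σᵢ (nᵢ/N)²` and Shannon entropy
   `−Σᵢ pᵢ ln pᵢ` summarize clonal expansion.
4. **Overlap test** — the number of distinct clonotypes shared between two
   compartments is compared with its permutation null: cells of both
   compartments are pooled and labels reshuffled (sizes held fixed, 1000
   permutations by default), and the one-sided lower-tail Monte-Carlo
   p-value `p = (1 + #{null ≤ observed}) / (1 + n_perm)` is reported —
   globally and cluster by cluster, per donor and lineage.

A synthetic paired-tissue generator with known ground truth (skewed
geometric/power-law clone sizes, tunable clonotype sharing between
compartments, bimodal negative-binomial CITE counts) makes every stage
testable without any data download.

## Worked example

Simulate three donors with 1000 cells in each of the six subsets, ten
transcriptional clusters, and 20 % of each clonotype pool shared between
compartments, then run the full pipeline:

```yaml
# config.yaml
seed: 7
n_permutations: 1000
min_cells: 20
simulate:
  n_donors: 3
  n_cells_per_compartment: 1000
  clusters: 10
  sharing_fraction: 0.2
  seed: 7
```

```sh
tcrcompart -v run --config config.yaml --out out/
```

The log reports per-stage retention:

```
tcrcompart.ingest: call_clonotypes: 18000 barcodes in, 0 contigs filtered,
  0 cells excluded for incomplete alpha/beta pairing, 18000 cells retained
tcrcompart.report: build_cell_table: 18000 paired cells, 17998 gated
  barcodes (2 rejected), 17998 cells in final table
```

`out/diversity.tsv` holds one row per stratum — here cluster 0 of donor 1's
CD4 cells is polyclonal in all three compartments (Simpson ≈ 0.94, i.e. two
random cells almost always carry different TCRs):

```
donor   lineage cluster compartment n_cells n_clonotypes simpson      shannon    flag
donor1  CD4     0       BM_CD69neg  249     37           0.9445008951 3.14457045 ok
donor1  CD4     0       BM_CD69pos  212     36           0.9381452474 3.089461459 ok
donor1  CD4     0       Blood       291     36           0.9477450668 3.187538031 ok
```

`out/overlap.tsv` holds the permutation tests. With only 20 % of the pools
shared, the observed global overlap (39 clonotypes) falls far below the
shuffled expectation (227.7 ± 5.9), so the test reports the smallest
attainable p-value, 1/1001 — evidence that blood and bone marrow hold
distinct repertoires in this simulation:

```
donor   lineage scope  compartment_a compartment_b n_cells_a n_cells_b observed_overlap null_mean null_sd     p_value
donor1  CD4     global Blood         BM_CD69neg    1000      1000      39               227.659   5.893786474 0.000999000999
donor1  CD4     global BM_CD69pos    BM_CD69neg    1000      1000      37               211.005   5.495359406 0.000999000999
```

`out/null_histograms.json` keeps each test's full null distribution;
`tcrcompart plot --overlap-json out/null_histograms.json --test-id
'donor1|CD4|global|Blood|BM_CD69neg' --out hist.png` renders the histogram
with the observed overlap marked. `out/cluster_frequencies.tsv` gives the
cluster × compartment composition matrix (normalized within each
compartment), and `out/provenance.json` records config, seed and version so
any run can be reproduced exactly.

The same stages are available individually (`simulate`, `ingest`, `gate`,
`diversity`, `overlap`) and as library functions
(`tcrcompart.permutation_overlap_test`, `tcrcompart.simpson_index`, …).

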