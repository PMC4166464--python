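# crypticdelim

Integrative delimitation of cryptic species from multilocus sequence
data. The package is aimed at taxonomists working on morphologically
uninformative groups (meiofauna, and similar), where species boundaries
must be discovered and diagnosed from DNA alone, typically from a few
ribosomal and protein-coding markers sequenced for tens to hundreds of
specimens.

## What it computes

Given per-locus alignments (FASTA), gene trees with node support
(Newick), and a specimen table (TSV), the pipeline combines four lines
of evidence per putative species:

1. **Distance discovery (relative threshold).** Uncorrected p-distances
   under pairwise deletion: for sequences *x*, *y* the distance is
   mismatches / comparable sites, excluding columns where either has a
   gap or missing state. A group *g* passes when

   min over h≠g of  d̄(g, h)  ≥  2 · d̄(g, g)

   i.e. its smallest mean between-group distance is at least twice its
   mean within-group distance (inclusive). De-novo groups are found by
   scanning all cut heights of an average-linkage dendrogram and
   selecting the cut with the strongest 2× gap.

2. **Statistical-parsimony haplotype networks.** Identical sequences
   collapse to haplotypes; haplotypes within j_max mutational steps
   (gaps counted as a fifth state) join one network. j_max is the
   largest j whose probability of a fully parsimonious j-step
   connection, P_j = [λe^(−λ)/(1−e^(−λ))]^j with λ = −ln(1 − j/L),
   still meets the connection limit (98% for slow loci, 90% for the
   fast one). A species should occupy networks exclusively.

3. **Gene-tree concordance.** A clade counts as recovered at a locus
   when it is monophyletic (bipartition test, restricted to the
   specimens present) with support ≥ 70 bootstrap / 0.95 posterior in
   the ML or Bayesian tree; at least two of three loci must concur.

4. **External validation.** Multilocus coalescent posteriors (BP&P
   style) are consumed from a TSV, never recomputed.

Clades with ≥ 3 specimens meeting all criteria become
`described_candidate`; clades with ≤ 2 specimens stay `candidate`;
conflicting evidence yields `unresolved`. Described species get
nucleotide diagnoses: alignment columns fixed in the focal species and
absent from all compared species (plus contiguous insert blocks), in
both alignment and type-specimen coordinates (1-based).

Support modules provide Tajima's D (with the full 1989 constant set
retained for audit) and a substitution-saturation diagnostic (p-distance
vs patristic distance, slope through the origin), plus a seeded
multilocus simulator with ground truth for testing every stage.

## Worked example

```python
from crypticdelim import SimConfig, simulate_dataset, run_pipeline
from crypticdelim.pipeline import PipelineConfig

dataset, truth = simulate_dataset(SimConfig(seed=42))
result = run_pipeline(dataset, PipelineConfig(
    use_a_priori_partition=False,          # discover groups de novo
    connection_limits={"h3_like": 0.90}))  # relaxed limit, fast locus

cols = ["clade", "n_specimens", "dist_lsu_like", "net_lsu_like",
        "net_h3_like", "trees_lsu_like", "status"]
print(result.evidence[cols].to_string(index=False))
```

prints

```
      clade  n_specimens dist_lsu_like net_lsu_like net_h3_like trees_lsu_like              status
grp_sp01_01            8       3.1/0.1          yes       yes*2            100 described_candidate
grp_sp02_01            8       3.1/0.1          yes         yes            100 described_candidate
grp_sp03_01            8       3.4/0.1          yes       yes*2            100 described_candidate
grp_sp04_02            7       3.7/0.2          yes         yes            100 described_candidate
grp_sp05_01            7       3.2/0.0          yes         yes            100 described_candidate
grp_sp06_01            8       3.2/0.2          yes       yes*2            100 described_candidate
```

Reading a row: `3.1/0.1` is the smallest mean between-group distance
versus the mean within-group distance in percent (a 31× ratio, passing
the 2× rule); `yes` means the clade occupies haplotype networks
exclusively at that locus, `yes*2` that it does so split over two
networks; `100` is the bootstrap support of the clade in the gene tree;
all six simulated species are recovered and describable. Two clades
show 7 of 8 specimens because one partial sequence each fell below the
50% coverage filter at the discovery locus. On the same run,

```python
print("Tajima's D (fast locus): %.3f" % result.tajima["h3_like"].D)
print({k: round(v.slope, 3) for k, v in result.saturation.items()})
```

prints `Tajima's D (fast locus): 3.760` (strongly positive, as expected
when distinct species are pooled into one sample) and saturation slopes
`{'lsu_like': 1.113, 'ssu_like': 0.937, 'h3_like': 0.591}` — the fast
locus's observed distances grow only half as fast as its true tree
distances, the signature of saturation.

The same analysis runs from the shell:

```bash
crypticdelim simulate --out data/ --seed 42
crypticdelim all --data-dir data/ --out results/ --discover
```

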