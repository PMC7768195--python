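# bafdomains

Analytics for *broad* chromatin domains: the unusually wide ChIP-seq
occupancy regions formed by the BAF (SWI/SNF) chromatin-remodeling complex
in SS18-SSX–driven synovial sarcoma, and the statistics that link domain
breadth to chromatin state and tumor-specific gene expression.

The package is aimed at computational epigenomics groups who already have
per-sample peak calls (BED) and depth-normalized signal tracks (bedGraph)
and want a reproducible, fully tested implementation of the downstream
domain analytics:

- **Consensus peaks** — regions whose per-base support reaches a minimum
  number of samples (e.g. 3 of 4 replicates), merged within a fixed gap
  (2 kb for BAF ATPase domains, 5 kb for H3K27me3 polycomb domains), after
  within-sample 200-bp merging and ENCODE-style blacklist exclusion.
  Fusion-protein sites additionally require a ≥ 2-fold ChIP signal excess
  over control.
- **Width quartiles** — peaks ranked by width and partitioned into Q1
  (narrowest) … Q4 (broadest); Q4 is the operational "broad domain". The
  partition is balanced, width-monotone, and deterministic under ties.
- **Annotation** — promoter (overlap with the closed ±1 kb TSS window, or
  mean H3K4me3 signal > 8 on the per-10-million-fragment scale), distal
  intragenic (gene-body overlap), distal intergenic (the rest); CpG-island
  overlap flags.
- **Chromatin states** — six states (active promoter, active enhancer,
  primed enhancer, bivalent, polycomb-only, no signal) assigned from
  per-site mean histone-mark signal by ordered rules, with Ward
  hierarchical clustering for exploration; state-change summaries (mean
  log₂ fold change per mark per state) and a reversibility score (fraction
  of sites whose state returns to the control label after the perturbation
  is removed).
- **Expression association** — TPM transform, a Welch-on-log₂(TPM+1)
  stand-in for count-model differential expression (4-fold, BH-adjusted
  P < 0.05), fold-change signatures (5×/20×), peak-to-gene mapping
  (all overlapping genes for promoter/intragenic peaks, nearest gene for
  intergenic peaks), Welch comparison of per-gene domain widths between
  gene sets, Q4/Q1 binding percentages with Fisher's exact test, and the
  up- vs down-regulated binding-enrichment ratio.
- **Synthetic data** — a seeded generator producing a complete dataset
  (genome, genes, CpG islands, blacklist, replicated tumor/control peak
  sets with planted broad domains, state-archetype mark tracks for
  control/induced/reverted conditions, negative-binomial counts with
  planted folds and binding probabilities) plus a ground-truth manifest,
  so every stage is testable offline.

## The statistics at the core

For a peak set of *n* peaks ranked by width, the peak of rank *r* receives
quantile label Q⌈*kr*/*n*⌉ (*k* = 4 by default). Domain breadth is compared
between gene sets A and B with the Welch two-sample *t* test on per-gene
widths *w*:

    t = (w̄_A − w̄_B) / √(s²_A/n_A + s²_B/n_B)

with Welch–Satterthwaite degrees of freedom and a 95 % CI; each gene's
width is the maximum width among its mapped peaks. Binding enrichment of
induced genes is prop(up genes bound) / prop(down genes bound). Adjusted
p-values use Benjamini–Hochberg: q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ (n/j)·p₍ⱼ₎.

## Worked example

Simulate a small two-chromosome dataset and run the whole pipeline:

```bash
bafdomains simulate --seed 7 --config small.yaml --out demo/
bafdomains run-all --dir demo/ --out demo_out/
```

(`small.yaml` here sets `n_chroms: 2`, `chrom_length: 5000000`,
`n_genes: 800`, `n_tumor_high_genes: 60`, `n_control_high_genes: 20`.)
`demo_out/quartile_summary.tsv` then contains:

```
quantile   n  median     q1      q3  min   max
      Q1  44   377.5  291.0  434.25  140   477
      Q2  45   630.0  556.0  686.00  485   774
      Q3  45  1023.0  869.0 1620.00  795  3825
      Q4  45  6006.0 4975.0 7250.00 3912 15898
 overall 179   795.0  489.0 3868.50  140 15898
```

i.e. the consensus of the four simulated tumor replicates contains 179
domains whose broadest quartile (median 6.0 kb) is an order of magnitude
wider than the narrowest (377 bp) — the planted broad-domain regime.
`demo_out/association.json` reports the breadth–expression link:

```json
"breadth_vs_signature": {
  "median_width_a": 5306.5,
  "median_width_b": 575.0,
  "welch_t": 11.27,
  "welch_p": 1.04e-17,
  "n_a": 56, "n_b": 20
}
```

genes high in the simulated tumor group sit under domains with median
width 5.3 kb versus 575 bp for genes high in the control group
(Welch p ≈ 1e-17), and `"reversibility": 1.0` records that every site
returned to its control chromatin state after the simulated perturbation
was removed.

The same stages are available as library functions
(`consensus_peaks`, `assign_width_quantiles`, `classify_location`,
`assign_states`, `two_group_de`, `breadth_vs_signature`, …) operating on
plain dataclasses, pandas frames and numpy arrays.

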