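# drugseq

A Python implementation of a plate-based 3′ digital gene expression
pipeline for high-throughput compound screening, together with a
truth-controlled simulator that generates every input the pipeline
consumes.

In this assay class, each well of a 384- or 1536-well plate is lysed in
place and reverse-transcribed with a primer carrying a **well-specific
10-base barcode** and a **random 10-base unique molecular index (UMI)**.
All wells are pooled after first-strand synthesis and sequenced as a pair:
read 1 holds the barcode + UMI, read 2 holds the 3′ cDNA fragment. The
computational problem is to turn those read pairs into a UMI-deduplicated
wells × genes count matrix and then into compound-level biology: quality
control (cross-well contamination, well reproducibility, saturation),
differential expression against DMSO controls, and clustering of compound
signatures by mechanism of action (MoA).

The package is aimed at computational biologists building or validating
such pipelines: because real screens are expensive, every stage here can be
exercised against simulated data with exact per-read ground truth.

## What it computes

- **Demultiplexing** (`drugseq.demux`) — extract barcode and UMI from
  read 1, correct barcodes up to a configurable Hamming distance against a
  whitelist with pairwise distance ≥ 3 (single-error correction is then
  unambiguous), and rewrite read 2 identifiers as `<id>_<barcode>_<umi>`.
- **Counting** (`drugseq.count`) — collapse transcript hits to genes, keep
  reads that map uniquely at gene level, and count distinct
  (well, gene, UMI) triples: `count[w, g] = |{umi : (w, g, umi) observed}|`,
  which removes PCR duplicates exactly. A directional 1-mismatch UMI
  collapse is available for error-containing data.
- **QC** (`drugseq.qc`) — barnyard species purity
  (`purity_w = max_s UMI_{w,s} / Σ_s UMI_{w,s}` on a mixed human/mouse
  plate, with the fraction of wells above a strict 0.96 threshold),
  Pearson well–well correlation on log1p CPM, binomial downsampling and
  gene-detection saturation, ROC of DE scores against a reference platform
  (positives: reference |log2FC| > 2; AUC equals the normalized
  Mann–Whitney U), and CRISPR indel frame binning (net length 0 → wild
  type, ≡0 mod 3 → in-frame, else frameshift).
- **Compound profiling** (`drugseq.profiling`) — potent-compound filtering
  (> 50 genes with padj < 0.05 and |log2FC| > 1 at the top dose), per-compound
  candidate lists (up to 200 genes, ranked by padj then |log2FC|), classic
  quantile normalization of the log2FC matrix across compounds, Euclidean
  hierarchical clustering and tSNE of the feature matrix. A lightweight
  internal DE routine (median-of-ratios size factors, Welch test on log1p
  normalized counts, Benjamini–Hochberg) supports simulations; externally
  computed DE tables are first-class input.
- **Meta-clustering** (`drugseq.metaclust`) — to compare platforms, sample
  correlations r are Fisher-transformed (z = atanh r, variance 1/(n−3)),
  combined per sample pair across datasets with a DerSimonian–Laird
  random-effects summary (τ² from the Q statistic), and clustered by
  average linkage performed in similarity space; dendrogram heights are
  tanh of the linkage scores, i.e. correlations again.
- **Simulation** (`drugseq.simulate`) — synthetic transcriptomes,
  negative-binomial expression, Hill dose–response compound effects,
  geometric PCR re-emission, i.i.d. substitution errors, cross-well
  contamination, and a per-read truth table enabling exact oracle tests.

## Worked example

`examples/demux_and_count.py` simulates a 4-well plate (25 molecules of
each of 30 genes per well, 40% PCR duplication), demultiplexes, and counts:

```
simulated molecules: 3000
sequenced reads:     4956 (PCR duplicates included)
assigned reads:      4956
matrix UMI total:    3000
```

The matrix total equals the number of simulated molecules, not reads —
UMI deduplication removed the 1,956 PCR copies exactly. The barnyard QC
example (`examples/barnyard_qc.py`, 96 wells, 0.5% cross-contamination)
prints:

```
wells evaluated:        96
median well purity:     0.9975
fraction purity > 0.96: 1.0000
```

i.e. every well keeps > 96% of its UMIs on its own species at this
contamination level. See also `examples/compound_clustering.py` (MoA
recovery from DE signatures) and `examples/meta_clustering.py`
(two-platform random-effects dendrogram). Shell users can run the same
stages via the `drugseq` CLI (`drugseq demux|count|qc|de|cluster`).

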