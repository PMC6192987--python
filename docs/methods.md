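# Methods

This note documents the models, conventions and design choices behind each
stage of the package. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Read structure and barcodes

Read 1 is modeled as a well barcode at offset 0 followed immediately by a
UMI (defaults 10 + 10 bases) and a poly-T remainder; both offsets and
lengths are configurable through `ReadStructure`. The original assay fixes
the barcode and UMI on the RT primer but the published material does not
ship the primer sequences, so the whitelist is generated: greedy rejection
sampling places `n` codes at pairwise Hamming distance ≥ 3 (default),
which makes single-mismatch correction unambiguous — for any observed
sequence at distance ≤ 1 from a codeword, that codeword is unique, since
two codewords within distance 2·1 of one observation would violate the
distance-3 guarantee. The generator is deterministic per seed and raises a
feasibility error after a bounded number of restarts rather than looping
forever; the whitelist is ordinary TSV input, so a real primer list can be
substituted verbatim.

Plate geometry defaults to 384 wells (16×24, labels `A01`–`P24`); 1536
(32×48, three-digit columns) is supported. Plate maps are CSV
(`well,treatment,dose_um,replicate,species,cell_line`) with an empty dose
for controls. Partial plates are accepted; full coverage is an opt-in
validation.

## Simulator

The simulator exists to give every pipeline stage an exact oracle, not to
be a realistic sequencer model. Its components:

- **Expression**: per-gene molecule counts are negative binomial in the
  mean/dispersion parameterization (variance μ + αμ², gamma-Poisson
  sampling; α → 0 is Poisson). Default profiles draw lognormal relative
  abundances (σ = 1) scaled to a per-well molecule budget.
- **Compound effects**: a Hill curve on the log2 fold change,
  `lfc(d) = lfc_max · d^h / (d^h + EC50^h)`, applied multiplicatively to
  target-gene means (2^lfc). The assay literature shows dose-dependent
  dysregulation without prescribing a functional form; Hill is the
  standard pharmacological choice and is used only to generate test data.
- **UMIs**: uniform over 4^10 per molecule. No saturation or collision
  correction is applied anywhere in the pipeline (counting is distinct
  UMIs, matching the assay's published processing); the birthday bound
  m²/(2·4^10) keeps collisions negligible at the simulated depths
  (m = 2000/well → expected collisions < 0.002).
- **PCR duplication**: each molecule is emitted Geometric(1 − p) times
  (support ≥ 1), so p = 0 means single copies and the expected read
  inflation is 1/(1 − p). Duplicates re-emit the same barcode, UMI and
  fragment.
- **Cross-well contamination**: with probability c a molecule is emitted
  under a uniformly random *other* well's barcode and flagged; the truth
  table records both the source well and the barcode well.
- **Sequencing error**: i.i.d. substitutions at a per-base rate on both
  mates (number of errors drawn binomially, positions uniform; two errors
  can coincide with negligible probability). No indels, no
  quality-dependent profile — enough to exercise barcode/UMI error paths,
  not a platform error model.
- **Alignments**: read 2 "alignment" is emitted directly from the truth as
  SAM v1 text (@HD/@SQ headers, MAPQ 255 for unique hits), replacing an
  external spliced aligner at desk scale. With probability m a read gets a
  low-MAPQ primary plus a secondary record to a different transcript,
  exercising the unique-read filter. When a demultiplexed FASTQ is
  supplied, the SAM carries the demultiplexer's query names verbatim, so
  barcode-correction and UMI-error effects flow through counting honestly.

Per-read truth rows match FASTQ records 1:1, and all outputs are
byte-deterministic given seed and parameters.

The simulated barnyard (two species interleaved in a checkerboard) is the
package's contamination benchmark. What the passing checks show: the
demultiplexer, the dedup logic and the purity arithmetic are exact, and at
the simulated rates (0.5% contamination, 0.1% base error, 30% PCR) the
purity pass fraction is at ceiling. What they do not show: real plates add
effects the simulator deliberately omits — index hopping, ambient RNA
gradients, barcode synthesis errors, homopolymer and quality-dependent
errors — so a real purity distribution must be measured, not assumed.

## Demultiplexing

Exact whitelist hits always win. With tolerance 1 (the default), all
single-mismatch neighbors over A/C/G/T/N are precomputed into a hash map
(an N in the observation mismatches every base); larger tolerances fall
back to a linear scan. An observation within tolerance of two codewords is
*ambiguous* and counted separately from unassigned; with distance-3 codes
and tolerance 1 this cannot happen for true-codeword errors. Unassigned
and ambiguous reads are dropped from the tagged output (optionally written
with reason codes), and the accounting identity
`assigned + unassigned + ambiguous = total` is asserted on every run. The
tag format `<id>_<barcode>_<umi>` is an underscore-delimited suffix on the
query name — safe for SAM QNAME, parsed by `rsplit('_', 2)` so the
original id may itself contain underscores.

Whether the original assay's script tolerated barcode mismatches is not
documented; both exact-only and 1-mismatch modes are provided, with
1-mismatch as the default because the generated whitelist guarantees its
correctness.

## Counting

Uniqueness is decided *after* collapsing transcripts to genes: a read
hitting two isoforms of one gene is unique, a read touching two genes is
discarded. Transcript-level uniqueness would throw away most 3′ reads of
multi-isoform genes, which is why gene level is the default; MAPQ is not
used for uniqueness on simulated input (an optional `min_mapq` exists for
real aligner output where MAPQ 255 marks unique hits).

Default UMI collapse is **exact**: the count is the number of distinct
(well, gene, UMI) triples, which removes PCR duplicates exactly and adds
no error correction — matching the documented processing of the original
assay. The **directional** mode additionally merges UMI pairs at Hamming
distance 1 when `count(a) ≥ 2·count(b) − 1` (the standard network
criterion), absorbing sequencing-error UMIs at the cost of rare true-UMI
merges. UMIs containing N are discarded. Matrices are CSR sparse with well
and gene metadata, serialized as MatrixMarket + TSV sidecars (ERCC columns
summarized separately); `to_anndata()` bridges to the single-cell
ecosystem.

## QC conventions

- **Purity**: ERCC columns are excluded; wells with zero UMIs are excluded
  from the pass-fraction denominator (the underlying report keeps them as
  NaN); the threshold comparison is strict (`>`).
- **Correlation**: counts-per-million on endogenous genes, then log(1+x),
  then Pearson. The original description does not state its transform;
  log1p-CPM is the field's default. Zero-variance wells propagate NaN
  rather than an arbitrary value.
- **Downsampling**: binomial thinning per matrix entry (UMI space), or
  uniform read subsampling before dedup (read space). Thinning UMIs is not
  identical to thinning reads before dedup, but at exact-mode counting the
  two coincide in expectation for unsaturated UMIs.
- **ROC**: truth labels use the *absolute* reference log2FC by default so
  down-regulated genes count as positives; a signed mode matches the
  literal "log2FC > 2" reading. AUC is the trapezoid area, which equals
  the normalized Mann–Whitney U — asserted against scipy as an
  independent oracle.
- **Gene detection**: counts strictly above a threshold, per well. The
  original expression-level breakdown is defined on FPKM from bulk
  RNA-seq; the count-threshold analogue here is an adaptation, not a
  reproduction.
- **Indels**: net indel length 0 / ≡0 (mod 3) / otherwise → wild type /
  in-frame / frameshift, weighted by read count. Upstream amplicon
  alignment and genotype calling are out of scope; the input is a tally
  table.

## Differential expression stand-in

`internal_de` is intentionally simple and is **not** a negative-binomial
GLM: median-of-ratios size factors (genes with nonzero geometric mean),
log2 fold change of normalized group means with pseudocount 1, two-sided
Welch t on log1p-normalized counts, BH adjustment over tested genes.
All-zero genes are reported untested (NaN padj). Its role is to close the
loop on simulations; real screens should import externally computed DE
tables through `read_de_table`, which the profiling stage treats
identically. A Welch test at n = 3 per group has limited power at moderate
biological dispersion — the planted-recovery checks therefore use the
technical-replicate regime they are meant to model (NB dispersion 0.005,
~7% extra CV, means of a few hundred counts), where sensitivity for
4-fold changes is high; at dispersion ≥ 0.02 the same test drops to ~50–60%
sensitivity, a limitation users should expect on noisy data.

## Profiling conventions

- Significance cutoffs are strict on both sides (padj < 0.05, |log2FC| > 1),
  and "potent" means strictly more than `min_genes` (default 50)
  significant genes.
- The "up to 200" candidate ranking is not specified in the source
  description; here it is padj ascending, ties by |log2FC| descending,
  then gene id — fixed and documented rather than implementation-defined.
  The pairwise-compound analysis uses the same machinery with a 1000-gene
  cap.
- Genes absent from a compound's DE table are imputed as log2FC = 0
  *before* quantile normalization.
- Quantile normalization is column-wise over compounds (each compound's
  log2FC distribution is mapped to the cross-compound mean of order
  statistics; ties receive the mean of their rank range). Whether the
  original normalization ran over compounds or genes is ambiguous;
  compound-wise makes compounds directly comparable and is the
  implemented choice.
- Hierarchical clustering of the feature matrix is scipy agglomerative on
  Euclidean distance; default linkage is `complete` (configurable), since
  the source does not state one. tSNE delegates to scikit-learn with a
  fixed seed and PCA initialization; only the feature matrix it consumes
  is this package's contribution.

## Meta-clustering

Fisher z = atanh(r) with |r| clamped to 1 − 10⁻⁶ before the transform;
the diagonal carries a +inf sentinel that is excluded from all
combination and linkage arithmetic. Per-pair combination across k
datasets uses DerSimonian–Laird: w_i = n_i − 3,
Q = Σ w_i (z_i − z̄_FE)², τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)),
weights 1/(1/w_i + τ²). The cited clustering tool's exact random-effects
estimator is not published; DL with 1/(n−3) Fisher variance is the
standard interpretation and is cross-checked against statsmodels'
meta-analysis routine in the tests. Agglomeration maximizes similarity
(not minimizes distance), cluster–cluster similarity is the unweighted
mean of member-pair z values, ties break on the lexicographically
smallest label pair, and display heights are tanh(linkage z) —
correlations, as the method describes. Row ordering for display is
computed once on the column-pooled matrix and applied unchanged to each
per-dataset panel.

## Problem sizes and determinism

The acceptance pipeline runs a full 384-well plate at ~2000 molecules/well
(~1.1 M read pairs at 30% PCR duplication), which completes in about a
minute on one CPU; unit and property tests run the same code paths on 24-
well plates with a few hundred molecules per well, chosen so the whole
suite stays interactive. Every stochastic component takes an explicit seed
and is reproducible to the byte; property tests are seeded or
derandomized.

## Known limitations

- The simulator omits indel errors, quality-score structure, index
  hopping, ambient contamination gradients and fragment-length modeling.
- The internal DE routine is a t-test stand-in, underpowered at n = 3 for
  dispersed data (see above).
- Exact UMI counting applies no saturation correction; at depths where
  UMI collisions matter the counts are biased low.
- tSNE and scipy linkage internals are consumed as-is; their tie-breaking
  and convergence behavior is theirs.
- 1536-well support is geometric only; it has not been exercised against
  a full-scale 1536 simulation in the default suite.
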