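# Methods

## The model

An allopolyploid genome carries two (or three) homoeologous subgenomes.
For every homoeologue group (one gene per subgenome) in a balanced
accession, the member copies each contribute roughly equal transcript
abundance. A homoeologous exchange (HE) substitutes a chromosomal segment
of one subgenome with a duplicate of the corresponding segment of the
other, so within the affected span one member drops to copy number 0 and
its partner rises to 2. Because transcript abundance tracks gene dosage at
this coarse level, HEs appear in mRNA-seq as reciprocal shifts of
homoeologue expression, and in low-pass DNA coverage as the same shifts of
read redundancy. The pipeline treats both assays identically apart from
default filter thresholds; concordance of the two is the standard control
that distinguishes structural exchange from expression dominance.

All positional reasoning is done in *gene-order space*: each gene has a
0-based ordinal rank along its chromosome, and one designated subgenome
(the "ordering genome", e.g. *Brassica* C for A/C panels) indexes
tile-plot columns, block coordinates and BED exports. Base-pair
coordinates are optional pass-through; block boundaries are therefore
gene-resolution, not breakpoint-resolution.

## Homoeologue pairing

Reciprocal best hits over two-way alignment tables. Hits with E-value
above the threshold (default 1e-30) are discarded; multiple HSPs per
(query, subject) collapse to the strongest; the best hit per query is the
highest bitscore, with ties broken by lower E-value and then
lexicographically smallest subject id, making the pair set deterministic.
Bitscore (not E-value) is the primary ranking key because it is
length-normalized and the robust community standard for RBH. Triplets
require all three pairwise RBH edges (a consistent triangle) — the most
conservative rule; genes in incomplete triangles are dropped and counted.
No synteny-aware disambiguation of paralogs is attempted.

## Quantification and filtering

RPKM: `counts / (length_bp/1000) / (aligned_total/1e6)`. Aligned totals
are caller-supplied (they are a mapping statistic, not a property of the
count matrix); a sum-of-counts fallback exists behind an explicit flag.
The low-abundance filter removes a group when **any** member's panel-wide
mean RPKM (all non-control samples, replicates included) falls below the
threshold — 0.4 for mRNA-seq, 0.01 for DNA coverage. Dropping the whole
group rather than the single gene avoids one-sided pairs that would
masquerade as exchanges. Missing values are a hard error by default
(silent imputation hides quantification failures); a config flag imputes
zero. No TPM/variance-stabilizing normalizations are offered: the
classification operates on the RPKM scale by design.

## Dosage classification

Per (group, accession, genome): a two-sided one-sample t-test of the
accession's replicate RPKM values against the scalar panel mean of that
gene, significant at raw p < alpha (default 0.01, no multiple-testing
correction; BH-FDR is available but off by default). Significant calls
take direction from the sign of the mean difference; the per-genome
direction vector maps onto the nine dosage categories
(high/low pair → "Exchange loser → gainer"; pure highs → duplication;
pure lows → deletion; all null → "No difference"). The same rule extends
to triplets, emitting one exchange label per (loser, gainer) pair.

Choices where the design was genuinely open:

* **Panel mean includes the tested accession's own samples.** The
  alternative (exclude-self) is available as a flag. Including self
  slightly shrinks the test statistic (the panel mean is correlated with
  the accession mean); on balanced simulated panels the realized per-test
  rejection rate is ~0.0095 at alpha 0.01, i.e. mildly conservative and
  within three binomial standard errors of nominal at 80,000 tests.
* **Untransformed RPKM.** A log2(x+1) option exists but is off: the
  dosage signal is multiplicative (0×/1×/2×) and the replicate noise at
  the panel scales tested is modest, so the untransformed test is both
  simpler and directly interpretable.
* **Zero-variance replicates are never dropped.** Deleted copies commonly
  yield identical (all-zero) replicate RPKM. If the replicate mean equals
  the panel mean the call is null with p = 1; otherwise the case is
  flagged `degenerate`, p is recorded as 0 and the direction comes from
  the sign of the mean difference. Mean equality is assessed to relative
  1e-9 because means reduced along different code paths differ by float
  rounding; this also makes fully noiseless (synthetic limiting-case)
  panels classify exactly.
* **Statistical power at four replicates.** With df = 3, alpha 0.01 and
  ~10% replicate CV, the one-sample test detects a doubled copy (against a
  carrier-inflated panel mean) in ~95% of genes; the lost copy is
  detected essentially always via the degenerate zero path. Per-gene
  direction recall on planted events is therefore ~97%, while demanding
  both genomes of a pair simultaneously significant yields ~94–95%.
  Block-level smoothing absorbs the residual per-gene misses.

## Tile plots

Each member gene is scaled across the plotted population of samples by
division by its maximum (an outlier-resistant percentile-cap variant is
available). Max-scaling preserves zeros — a deleted copy stays white —
and makes colour a purely relative quantity within each homoeologue set,
which is why replicates and even assays (mRNA vs DNA) render nearly
identically. Values tied with the maximum up to 1e-12 relative are
snapped to exactly 1 so that full saturation is exact. Channels: one
genome per CMYK channel (default alphabetical → cyan, magenta, yellow; K
unused), naive conversion `r=(1−c)(1−k)` etc. Rendering is deterministic:
PNG via an explicit uint8 pixel array, SVG as hand-written rects;
chromosome boundaries are white gap columns (default 2 px), annotated
genes 1-px black marker lines; replicates are adjacent rows with an
optional collapse-to-accession-mean layout for large panels.

## Block calling and frequency

Run-length smoothing over categorical calls, chosen over an HMM because
it is auditable and parameter-transparent: a block is a maximal run of
≥ `min_run` (default 10) genes with the same single-direction exchange
category, tolerating ≤ `max_gap` (default 2) non-concordant genes between
consecutive concordant ones; blocks never span chromosomes; `support` is
the concordant fraction over the ordinal span. Per-position frequency
counts covering accessions by direction; a position is flagged telomeric
when a covering block touches either ordinal extreme of its chromosome
(the gene-order proxy for chromosome ends). The direction-bias summary
totals block-genes per direction. The aneuploidy screen flags a
chromosome when ≥ 80% of its groups carry the same single-genome
duplication or deletion category.

## The synthetic generator

`simulate_panel` draws one baseline expression level per group (shared by
all members: balanced 1:1) from a lognormal, and per-sample counts as
`Poisson(copy × baseline_RPKM × length_kb × library_millions × noise)`
with multiplicative lognormal replicate noise. Defaults model a
well-replicated crop variety panel: 27 accessions × 4 replicates,
baseline median 30 RPKM (σ_log 0.7) — the well-quantified regime of
transcripts that survive the 0.4-RPKM filter — median 1.5 kb gene models,
2×10⁷ aligned reads per library, 10% replicate CV. Planted events set
copy numbers (exchange: loser 0× / gainer 2×; duplication 2×; deletion
0×; whole-chromosome variants likewise), never overlapping on a span.
`count_noise="none"` yields exact expected counts for limiting-case
checks. `simulate_alignment_tables` emits reciprocal hit tables whose RBH
solution is the true pairing, with optional sub-best decoys and
deliberate reciprocity breaks. Presets bundle the study layouts
(27-accession A/C panel, A/B panel with small internal exchanges,
three-genome triplet panel, high-HE doubled-haploid panel).

What the generator does **not** model: genome dominance and other
expression-level confounders, mapping bias between subgenomes,
between-accession baseline variation (heritable expression differences),
negative-binomial overdispersion beyond the lognormal×Poisson mixture,
and sequence-level read simulation. Passing recovery tests therefore
demonstrates the statistical machinery under dosage-only signal, not
robustness to those real-data effects — the DNA-coverage concordance path
is the designed control for the most important of them.

## Problem sizes in the checks

The calibration check uses 2,000 balanced groups × 20 accessions × 4
replicates (80,000 tests); recovery uses 360 groups × 27 accessions with
ten planted events (411 affected member genes, six exchange blocks of
20–40 genes); oracle comparisons use toy tables small enough for
exhaustive search. These sizes give sub-percent Monte-Carlo error on every
reported rate while keeping the full suite in a few seconds.

## Known limitations

* Breakpoints are gene-ordinal, not base-pair, resolution.
* The t-test treats the panel mean as a constant; carrier accessions
  shift it at their planted columns, inflating false calls for other
  accessions there (visible as scattered opposite-direction calls around
  strong HEs in small panels). Larger panels shrink the effect as 1/n.
* Raw p-values, by design; panel-wide scans at other alpha levels should
  enable the optional FDR correction.
* Run-length block calling has no probabilistic boundary uncertainty.
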