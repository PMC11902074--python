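# Methods

This note documents the models, numerical choices and limitations behind
`homeodyn`, in the order the pipeline runs.

## Coordinates and containers

Internal coordinates are 0-based half-open; GFF3 I/O converts to/from the
1-based inclusive convention, and a round trip preserves the external
coordinates exactly.  Strand is stored but all interval arithmetic is
positional.  "Sequence" throughout means the annotated transcript/CDS
sequence supplied in FASTA; extraction from genomic sequence is out of
scope.  Which GFF3 feature level carries the gene models is configurable
(`feature_type`, default `"gene"`).  Count matrices are genes × samples
integer DataFrames bound to a design of ordered stages (default 0M, 5M,
12M, EC, BC) with a fixed replicate count (default 3).

## Synthetic allopolyploid genomes

The generator emulates the evolutionary structure the pipeline is meant to
detect, not banana biology in detail.

* An ancestral array of `genes_per_chrom` genes per chromosome is laid out
  with gene lengths uniform on [⅔·`mean_gene_len`, 4⁄3·`mean_gene_len`]
  (default mean 900 bp, a typical plant CDS) and intergenic spacers uniform
  on [100, 500] bp.  Spacers are deliberately compact: the geometry must
  satisfy L_min > (ratio_min − 1)·(s_max + pseudo) ≈ 300 bp so that an
  inserted gene detectably enlarges its flanking interval.
* Each subgenome copy of every gene is mutated independently at
  `substitution_rate` per site (substitutions to a uniformly chosen
  different base).  The rate is per *copy*, so pairwise divergence between
  homoeologs is roughly twice the rate.
* **Insertions** place a novel random-sequence gene inside the spacer
  following a chosen ancestral gene, splitting it, so the carrier's
  flanking interval grows by exactly the inserted length.  Random sequence
  guarantees the gene has no homology anywhere, making specificity
  confirmation unambiguous.
* **Losses** remove a gene from one subgenome's annotation (and sequence
  set) while retaining its genomic span, the way pseudogenized relic DNA
  keeps locus lengths comparable.  Flanking intervals therefore stay
  (nearly) equal between subgenomes while the homolog is absent — the
  signature that separates loss from insertion.
* Structural events occupy ancestral loci at least two genes apart, so each
  event's local anchor context is unambiguous.  Without this, an insertion
  adjacent to a loss would mix both signatures and the origin call would be
  undecidable from interval geometry alone.

Counts are negative binomial (dispersion 0.1 by default, the usual order
for bulk RNA-seq biological replicates) with gene-wise baseline means drawn
log-uniformly from [5, 500].  Homoeolog pairs share a baseline; planted DE
(default 10% of genes per stage transition, |log2FC| uniform on [1, 3],
applied to both alleles) accumulates along the stage order as a random
walk; planted bias multiplies one allele's mean by 2² at every stage
(defaults: 10% A-dominant, 2% B-dominant pairs, mirroring the A-biased
composition reported for ABB banana).  Per-sample library-size factors are
uniform on [0.85, 1.15].  Both count matrices are indexed by the union of
A and B gene ids; a gene absent from a subgenome has an all-zero row there,
the analogue of quantifying each library against one reference at a time.

One global seed drives everything; operations derive independent
substreams, so structure and counts are separately reproducible and two
identically seeded end-to-end runs are byte-identical.

What the generator does **not** model: intron/exon structure, read-level
sampling, tandem duplication and paralogy, cross-mapping ambiguity between
near-identical subgenome copies (counts are emitted subgenome-resolved, as
if read assignment were already correct), GC/length biases, and dosage
differences from triploidy (one A vs two B copies).  Passing tests
therefore demonstrate correctness of the *computation*, not robustness to
mapping artefacts of real ABB data.

## Homoeolog identification

Local alignment uses Bio.Align.PairwiseAligner with match +2, mismatch −3,
gap open −5, gap extend −2 ("open" is the score of the first gap column).
Identity is matches / alignment columns (gaps included); coverage is the
query span of the alignment / query length — the query-side convention
common in BLAST-based protocols.  Pairing thresholds are identity ≥ 0.6 and
coverage ≥ 0.2; both applied at the nucleotide level.

The all-vs-all step prefilters candidate pairs by shared distinct 12-mers
(≥ 3 shared; genes shorter than 2k bypass the filter).  At the divergence
regimes the generator produces (≤ 10% per copy, i.e. pairwise identity
≳ 0.8) a true pair shares dozens of 12-mers, so the prefilter is lossless
there; a hypothetical pair at exactly 0.6 identity spread uniformly across
the sequence could evade any k-mer filter, which is the standard trade-off
of seeded search.

Synteny chains maximize (#anchors − gap penalties) over anchor sets
strictly monotone in both gene-order ranks, same and inverted orientation
scored separately; the penalty for skipping ranks is 0.5 + 0.1 per skipped
rank, with gaps capped at 25 ranks and blocks requiring ≥ 3 anchors.  These
defaults are sized for compact synthetic genomes and are exposed in the
configuration.  Blocks are extracted best-first; anchors sharing a gene
with an extracted block are retired, so each gene joins at most one block.
The DP is verified against exhaustive chain enumeration on instances of
≤ 12 anchors.

Reciprocal best hits break score ties by higher identity, then
lexicographic subject id (logged).  The homology supplement admits the best
remaining above-threshold hit per still-unpaired gene, greedily by
descending score.  Specificity confirmation uses stricter presence
thresholds (identity 0.8, coverage 0.5) than pairing, so "specific" is
conservative: a gene is only confirmed when no cross-subgenome alignment
reaches both.  Because confirmation aligns against the other subgenome's
*transcript* set, a relic of a lost gene (absent from the annotation) does
not count as presence; a genome-level check would be stricter still.

## Structural origin calls

For each confirmed specific gene the nearest paired genes left and right
(scanning up to `max_scan` = 10 genes per side) whose partners share a
chromosome serve as anchors.  The interval is the inner-boundary distance
(left anchor end → right anchor start) on each subgenome.  With pseudo-count
100 bp (guarding zero-spacer adjacencies), ratio ≥ 1.5 ⇒ insertion;
ratio < 1.5 *and* homolog confirmed absent ⇒ loss; otherwise ambiguous.
The 1.5/100 bp quantification is this package's own; the underlying
qualitative signature (enlarged carrier interval vs equal intervals with a
missing homolog) is what the generator plants by construction.
Unanchorable genes (chromosome ends, no consistent anchors) are reported
and excluded rather than guessed.

## Normalization and differential expression

TMM follows the published formula: M and A values against a reference
sample (the one whose upper-quartile of library-scaled counts is closest to
the mean), double trimming (30% on M, 5% on A, average ranks), weights
from the delta-method asymptotic variance of M, factors rescaled to
multiply to 1.  The implementation agrees with edgeR's
`calcNormFactors(method="TMM")` to ~1e-6 (tested) and with a direct-formula
oracle to machine precision.  A median-of-ratios variant is provided behind
the same interface because the upstream literature names both conventions;
TMM is the default.

The DE test is a negative-binomial Wald test:

* normalized counts q = count / (effective library size in millions);
* per-gene method-of-moments dispersion from the pooled within-group
  variance, α̂ = (s² − μ̄·c̄⁻¹)/μ̄², clipped to [0, 10];
* a mean–dispersion trend α(μ) = a₀ + a₁/μ fitted to *binned* moments
  (ratios of bin-averaged variances and means, with a small-sample
  correction for E[μ̂²] > μ²), which is far less attenuated than averaging
  per-gene ratios;
* final dispersion = 0.5·α̂ + 0.5·α(μ̄), floored at 1e-8;
* log2FC from group means with pseudo-count 0.5 per group; its asymptotic
  SE from var(ln μ̂) ≈ (1/μ + α)/n per group; p from the normal tail;
  BH adjustment per comparison; DE ⇔ |log2FC| > 1 and padj < 0.05.

Genes with < 5 raw counts summed over the two groups are not tested
(method-of-moments dispersion is unstable there) and are returned flagged
with NaN p-values; all-zero genes get p = 1 and log2FC = 0.  At n = 3 vs 3
the Wald test with estimated dispersions is measurably anti-conservative:
with the true dispersion plugged in the null rejection at p < 0.05 is
~0.05, while the 50/50-shrunk estimate yields ~0.06 (the acceptance script
recomputes this fraction).  This is the familiar small-sample behaviour of
NB Wald pipelines and the reason the calibration check uses a band rather
than a point.

Exact concordance with DESeq2 is a non-goal; the test is a documented,
self-contained procedure, not a wrapper.

## Allele bias and pathway summaries

Bias is called per pair and stage on stage-mean expression with
pseudo-count 0.5 per side; |log2 ratio| ≤ 1 is balanced (mirroring the DE
fold-change convention — the upstream literature never quantifies
"balanced"), and pairs with both alleles below `min_expr` are excluded as
not expressed.  `min_expr` defaults to 1.0 in FPKM units; on synthetic
fixtures with small total library sizes the floor should be rescaled to the
fixture's depth (the tests use the expression value corresponding to ~10
normalized counts).  With NB dispersion 0.1 and 3 replicates, a balanced
pair's log2-ratio noise has sd ≈ 0.3–0.5 depending on expression, so a few
percent of weakly expressed balanced pairs inevitably cross the threshold;
planted-bias recovery is assessed against that noise floor.  Whether allele
dominance is reported as a count of genes or an expression-level statement
is ambiguous in the source material; the per-stage fractions reported here
are gene counts, and the underlying per-pair ratios are emitted alongside.

Enrichment is the upper-tail hypergeometric test P(X ≥ k) with BH
adjustment, universe defaulting to all genes in the count matrices (not the
pathway table).  Pathway membership retrieval is out of scope; memberships
are inputs.

## qPCR

ΔΔCt with amplification efficiency fixed at 2 and replicate aggregation on
the ΔCt scale (mean and SD, then exponentiation), so reported spreads are
symmetric in cycles.  Concordance with RNA-seq is computed per gene across
stages on the log2 scale; stages with non-positive FPKM are dropped for
that gene (log undefined), and at least 3 shared stages are required.

## Problem sizes

The default simulation (2 chromosomes × 200 genes per subgenome, 20
insertions and 10 losses per subgenome) is sized so the full classification
runs in well under a minute while leaving every gene class populated;
calibration studies use 2000 genes at 3 vs 3 replicates, enumeration
oracles use ≤ 12 anchors and N ≤ 20 universes, where exhaustive search is
exact and fast.
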