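# Methods

This note documents the models, parameter choices and numerical conventions
behind each module, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the problem was genuinely open.

## Coordinate and rounding conventions

All internal coordinates are 0-based half-open; VCF output is 1-based per
the standard, and BED output matches the internal convention. Percentages
are rounded half-up to 2 decimal places and p-values to 4, using decimal
arithmetic (`cohortstats.round_half_up`) so that display rounding is
platform-independent.

## Low-pass CNV calling (`cnv_lowpass`)

**Model.** Read counts per 20 kb bin are treated as Poisson with a
multiplicative mean: sequencing depth × bin share of the genome × bin bias ×
sample scale × copies/2. Copy-number signal therefore lives in the *ratio*
of a sample's scaled counts to a batch reference.

**Batch normalization.** Every sample in a batch (minimum 8) is scaled to a
common total; the per-bin reference is the across-batch **median** of scaled
counts — robust to the occasional CNV carrier in the batch, which a mean
reference would absorb. Bins with reference below `min_ref` (default 10
scaled counts) are masked and excluded from all downstream arithmetic.
Because bin bias is shared within a batch, ratioing to the batch median
cancels it; this is why no explicit GC correction is performed — bin-level
bias of any origin is absorbed by the reference.

**Breakpoint statistic.** The log2-ratio series is smoothed with a centered
local linear regression (window `W` = 15 bins; edge windows are truncated;
computed in closed form with sliding sums) and differenced. A copy step of
height *h* smoothed over *W* bins yields a per-bin difference of ≈ *h/W*, so
the raw difference shrinks with the window and cannot be compared against a
fixed log2-unit threshold. The statistic is therefore scaled back:
`D_j = W·(s_j − s_{j−1})`, an estimate of the *step height* in log2 units
(for `W` = 1 it is the plain first difference). The threshold is
`τ = max(k·1.4826·MAD(D), 0.1)` with `k` = 5; the absolute floor of 0.1
log2 units keeps zero-noise toy inputs from thresholding at τ = 0.

**Breakpoint localization.** A smoothed step produces a same-sign
over-threshold plateau of width ≈ `W` in `D`, not a sharp peak. Each such
run is collapsed to its |D|-weighted centroid, which coincides with the true
step under a symmetric smoother, and then refined on the *unsmoothed* series
by choosing, within ±`W`/2 bins, the split maximizing the absolute difference
of 4-bin flanking means (ties keep the provisional position). The refinement
matters for events shorter than the smoothing window, where the two edge
plateaus overlap and the centroid alone is biased by several bins; with it,
simulated events of ≥ 10 bins at ≥ 1000 expected reads/bin localize to
within ±2 bins in ≥ 99% of replicates.

**Call assembly.** Breakpoints are paired per chromosome: a loss needs a
down-breakpoint entering and an up-breakpoint leaving (gains the reverse).
Chromosome ends and masked-bin gaps (> 2 masked bins) act as implicit
wildcard breakpoints so terminal and flanking events stay callable. A
candidate becomes a call when it spans ≥ `min_bins` = 3 bins (60 kb) and
its mean linear ratio leaves [0.75, 1.25] — midpoints between integer copy
ratios with margin. Copy number is `round(2·ratio)` clipped to [0, 6].
Everything is deterministic for fixed inputs.

## Exonic CNV calling (`cnv_exonic`)

Exome read depth is dominated by capture efficiency and batch structure, so
the caller first filters extreme exons (mean depth outside [10, 2000]) and
samples (outside [25, 500]), mean-centers exon columns, and removes every
principal component whose variance exceeds 0.7 × the mean component
variance — the convention used by exome-HMM CNV callers for separating
cohort-wide structure from single-sample dosage signal. Residual rows are
z-scored (flat rows map to all-zero z).

Each sample × chromosome z series is decoded with a 3-state HMM: emissions
N(−M, 1) (deletion), N(0, 1) (diploid), N(+M, 1) (duplication) with
`M` = 3; transitions allow entering an event from diploid with
`p_event` = 10⁻⁴ and extending with `p_stay` = 0.9; DEL↔DUP jumps are
forbidden. This is a deliberate simplification of the published exome-HMM
design (fixed emission means, no distance-scaled transitions, no genotyping
quality scores). Viterbi decoding is exact and is verified in the tests
against exhaustive enumeration of all 3ⁿ state paths up to n = 12 exons.
Only runs of ≥ 3 contiguous non-diploid exons become calls — one- and
two-exon excursions are suppressed as noise — and calls never span
chromosome boundaries.

## Variant quality screen (`wes_filter`)

A member's record passes iff GQ ≥ 15 and DP ≥ 3 and the fraction of
low-quality bases at the site is **< 0.4**. The third criterion is stated in
the source pipeline as "≥ 0.4" inside a list of keep-criteria, which read
literally would keep only sites *dominated* by low-quality bases; it is
implemented here as an exclusion (the boundary 0.4 fails), since that is the
only reading under which the screen is a quality screen. The definition of a
"low-quality base" is upstream; the fraction arrives as a per-sample VCF
FORMAT field (`LQF`). Missing quality fields fail closed with reason
`missing_field`. The filter partitions its input exactly, is monotone in
each threshold, and is idempotent on its own pass set (property-tested).

## Trio integration (`trio`)

Candidates are fetal variants (with parental genotypes from the same
record) and fetal CNV calls; a parent carries a CNV when it has a same-state
call with ≥ 50% reciprocal overlap. Inheritance rules apply in order:
de novo (no parent carries) → X-linked maternal (male fetus hemizygous,
mother het, father non-carrier) → biparental homozygous (fetus 1/1, both
parents het) → paternal/maternal (exactly one carrier parent) →
unclassified. Male X genotypes are hemizygous (`0`/`1`) on input;
pseudoautosomal regions are not modeled.

Compound-het pairing is gene-wise over heterozygous-carrier candidates
(a called CNV counts as one structural allele). Opposite parental origins
give `certain` phase; a de novo allele with one inherited partner gives
`possible` (trio genotypes alone cannot phase a de novo event — such pairs
are retained rather than dropped because de novo and inherited findings do
co-occur in real reports); same-origin pairs are rejected as cis. Only
rare (AF ≤ 0.01), non-silent alleles are eligible: without this gate,
common polymorphisms carried in trans would pair in essentially every gene
and would override de novo labels. A Mendelian-error-rate helper logs a
contamination warning above 5% of sites but never filters.

A trio's diagnosis is the set of reported (P/LP) findings; *double
diagnosis* means at least one reported CNV and one reported sequence
variant.

## Prioritization (`prioritizer`)

The phenotype score is gene-centric information content: with *n(t)* = genes
whose annotation closure contains *t* and *n_pa(t)* = genes whose closure
contains all parents of *t* (the full annotated gene set for the root),
Φ(t) = −log₂(n(t)/n_pa(t)) and the score is ΣΦ over the intersection of the
profile's and the gene's ancestor closures. Φ ≥ 0 always, the root carries 0
bits, and along any root-to-leaf chain ΣΦ telescopes to
−log₂(n(leaf)/N) — an identity the tests check exactly.

Allele-frequency filters default to 0.001 (dominant/de novo context) and
0.01 (recessive context); both configurable, chosen as standard diagnostic
practice. Ranking is (score desc, consequence severity desc with
truncating > splice region > missense > other, genomic position asc) — a
deterministic total order. The tier table is deliberately labelled
**ACMG-lite**: P for de novo loss-of-function with phenotype match or a CNV
hitting a configured known-microdeletion/duplication-syndrome region; LP for
any two of {de novo, LoF, phenotype match} or a recessive genotype
(compound het, biparental homozygous, X-linked hemizygous) in a
phenotype-matched gene; VUS otherwise. `phenotype_match` means positive
score within the top 3 ranks. Genes on a configured secondary-findings list
are withheld from the default report. "Literature" and in-silico evidence
are reduced to the consequence field supplied on input; no external
databases are consulted.

## Cohort statistics (`cohortstats`)

The per-class table columns are cases, double-diagnosis, CNV-only and
variant-only fetuses (each fetus counted once; the CNV and variant columns
count single diagnoses). Yield = 100 × (double + cnv_only + variant_only) /
cases. The bundled `fixtures/cohort_classes.tsv` satisfies exact row/column
consistency: class cases sum to 959, diagnosed fetuses to 227, doubles to
10, CNV-only to 99 and variant-only to 118.

The two-tailed Fisher test sums hypergeometric point probabilities of all
same-margin tables whose probability is ≤ the observed one, with a 10⁻⁷
relative tolerance for floating-point ties — the standard exact two-sided
definition. It is verified against exhaustive enumeration for every 2×2
table with total ≤ 30 (agreement to 10⁻¹⁰) and cross-checked against an
independent library implementation.

The de novo fraction is computed over diagnosed trios whose *single*
diagnosis is de novo, as a percent of all diagnosed trios; recurrence tables
key findings by gene symbol (CNVs fall back to their interval label) and
report carrier percent of the whole cohort.

## Synthetic data (`synthdata`)

**What it emulates.** (i) Shallow-WGS bin counts: ~5 million reads per
sample dropped into 20 kb bins, Poisson-distributed around a mean with
log-normal per-bin bias (σ = 0.1, shared within a batch — standing in for
mappability/GC structure) and log-normal per-sample scale (σ = 0.05);
planted CNVs rescale means by copies/2 and their truth coordinates snap to
bin boundaries. (ii) Exon depths: a rank-1 sample × exon expectation
(library size σ = 0.2 around 100×, capture efficiency σ = 0.3) times
dosage, plus 2 low-rank latent factors (PCA-removable batch structure) and
log-normal noise (σ = 0.1); planted events span 3–8 whole exons of a gene,
i.e. genomic sizes from a few to tens of kb. (iii) Trio genotypes: a shared
background site panel (2 sites per gene, allele frequencies uniform in
[0.05, 0.3]) with Hardy–Weinberg parents and Mendelian transmission;
background de novo injection at 5×10⁻⁴ per site; designated causal
mechanisms per trio. The default mechanism mix follows a 959-trio prenatal
cohort's diagnostic spectrum: ~22% of trios causal, of which ~90% autosomal
dominant de novo (split ~52:48 CNV:SNV), ~4.7% X-linked maternal, ~3.8%
recessive homozygous, ~0.9% each SNV+SNV and CNV+SNV compound het. Fetal sex
is Bernoulli(0.58 male), matching the cohort ratio. Causal sites carry clean
quality fields — reported findings have, by definition, survived upstream
QC — while background sites have noisy GQ/DP/low-quality fractions.
(iv) Phenotypes: the causal gene's ontology terms with 0.2 per-term dropout
plus 2 decoy terms (3 decoys for non-causal trios), over a generated
ontology tree (default 3 levels, branching 3) in which every leaf is
annotated to at least one gene.

**What it does not emulate.** Read-level artifacts (FASTQ, alignment,
duplicates, sequencing error), GC waves beyond static bin bias, mosaicism,
maternal-cell contamination, segmental duplications/low-copy repeats,
linkage structure between sites, and population stratification. Passing
recovery tests therefore demonstrate algorithmic correctness under the
stated noise model, not clinical performance on real sequencing data.

**Quality-field round-tripping.** Low-quality fractions and allele
frequencies are generated at 4-decimal precision so that writing to VCF
(single-precision FORMAT floats) and reading back is lossless; the test
suite asserts exact object equality across a full write/read cycle.

## Problem sizes used in tests and the acceptance script

The default simulated genome is two 10 Mb autosomes plus a 5 Mb X (1250 ×
20 kb bins), 8 genes per chromosome with 8 exons each. Recovery sweeps use
200 replicates (low-pass; events of 10–79 bins, copies 1 or 3, 2000 expected
reads/bin, batches of 10), 50 replicates (exonic, cohorts of 50), and
100-trio cohorts (inheritance and ranking). The Fisher implementation is
swept exhaustively over all 2×2 tables with total ≤ 30. These sizes keep the
full suite in the tens of seconds while leaving every statistical check
well-powered.

## Known limitations

* The low-pass smoothing family, window, threshold constant and batch
  scaling are reasonable reconstructions, not published values; they are
  exposed as parameters.
* The exome HMM omits distance-scaled transitions and per-call quality
  scores; breakpoints are exon-resolution only.
* The tier table is a simplification and must not be mistaken for a full
  ACMG implementation.
* CNV trans-phase relies on parental-origin inference via 50% reciprocal
  overlap, not read-backed phasing.
* Aneuploidy reporting, mosaic fraction estimation, uniparental disomy and
  germline mosaicism are out of scope.
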