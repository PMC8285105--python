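# Methods

## Problem and model

`hetnuc` analyzes the establishment of H3K9me3-marked constitutive
heterochromatin across early embryonic stages from staged single-embryo
ChIP-seq. The working model is nucleation-and-spreading: the mark first
appears on isolated, roughly single-nucleosome loci (nucleation sites) at or
before embryonic stage 3, predominantly at specific positions of recently
active transposable-element (TE) families, and is then deposited on
neighboring nucleosomes stage by stage until broad, stable heterochromatin
domains have formed. The package implements the quantitative machinery this
model requires: comparable enrichment tracks across samples with very
different pull-down efficiencies, a taxonomy of peaks by developmental
behavior, projection of enrichment into TE consensus coordinates, structural
classification of LTR-retrotransposon copies, and association of nucleation
with maternal piRNA abundance and zygotic expression.

Developmental stages are labeled `s3, e4, l4, s5, s7` (stage 3, early and
late stage 4, stage 5, stage 7) throughout.

## Enrichment and normalization

Coverage tracks are per-base, per-chromosome arrays. Each library is scaled
by its median autosomal coverage, computed over a non-overlapping 1 kb window
tiling (final partial windows are kept; dropping them biases medians on short
chromosomes). Per-site enrichment of a ChIP/input pair is

    enrichment = (chip_norm + 0.01) / (input_norm + 0.01)

stored as log2. The pseudocount (default 0.01, configurable) keeps every
value finite; a site with zero coverage in both libraries is exactly 0.
Ties between the sample and spike-in genome in the combined mapping carry
mapping quality 0 and are discarded during read partitioning.

**Spike-in correction.** Equal exogenous chromatin in every sample means
between-sample differences in the spike-in enrichment *distribution* reflect
pull-down efficiency. The correction is quantile-bin matching: spike-in
window (1 kb) log2 enrichments and a reference (the mean spike-in enrichment
over all samples) are each cut into 1000 rank bins of width 0.1 percentile;
the bin shift is (mean reference in bin) − (mean spike-in in bin). Shifts
are fitted at window level and applied per base through a value-keyed lookup:
a value falls into the spike-in bin whose recorded upper boundary first
reaches it, values beyond the extreme boundaries clamp to the first/last bin,
and bins left empty by short inputs inherit the nearest non-empty bin's
shift, keeping the function total and piecewise constant.

A purely additive log2 distortion is identical to a library-size factor and
is already removed by median normalization — it can never be observed in
median-normalized enrichment. The distortion the quantile correction
actually repairs is a change of enrichment *dynamic range* (gain), so the
synthetic spike-in model distorts samples with a multiplicative gain on the
log2 surface (drawn once per sample from U(0.75, 1.25)); constant-offset
behavior of the fitter itself is exercised directly on constructed value
distributions, where the fitted shifts recover the negated offset exactly.

## Peak taxonomy

Peak calling is external (MACS2 in production; a documented naive
threshold-and-merge caller stands in for it on synthetic tracks:
25 bp boxcar smoothing, runs above log2 0.5, sub-100 bp gaps merged,
minimum width 60 bp, summit at the smoothed maximum). Post-processing:

- **Replicate merging** — peaks from different replicates with an
  end-to-start gap strictly below 100 bp are the same peak; the merged
  interval is the union span and the merged summit is the summit of the
  most-enriched member (a real summit, not an invented midpoint).
- **Peak enrichment** — mean log2 enrichment over the half-open 200 bp
  window `[summit−100, summit+100)`, truncated at chromosome ends.
  The enrichment rule is strict: enriched iff log2 > 0.5. A 1.5-fold variant
  (log2 ≈ 0.585) is exposed as a configurable threshold for the
  pre-enrichment fractions.
- **Representative tracks** — per-base mean over replicates; on Y/neo-Y
  chromosomes only male replicates contribute (females carry no Y, so their
  reads there are cross-mapping noise).
- **Phantom filtering** — a peak enriched in ≥ 1 alternative-antibody
  preparation (H3, H3K4me3, H4K16ac) at the same rule is an artifact
  ("phantom") and removed.
- **Persistence** — a stage-3 peak still enriched at the final stage (s7)
  is persistent, otherwise temporary. Judging at s7 alone (not s5 ∧ s7) is
  the simplest rule consistent with depletion "over time".
- **Novelty** — an early-stage-4 peak already enriched on the stage-3
  representative track is old (nucleation was underway below the
  peak-calling detection limit); otherwise new.

Profiles (±1 kb around summits, rows sorted by descending mean, NaN outside
chromosome bounds excluded from column medians) and per-stage trajectories
report medians with 95% percentile-bootstrap bands (1000 resamples over
peaks, seeded; bootstrap resampling is chunked to bound memory).
Annotation categories follow the precedence TE > microsatellite > gene >
other; the pericentric fraction counts summits inside annotated pericentric
regions.

## TE consensus projection and LTR structure

RepeatMasker-style GFF (1-based closed, `Target` attribute carrying the
consensus span) is converted to 0-based half-open on read; `(motif)n`
entries are microsatellites, not TEs. Each insertion's genomic enrichment is
resampled onto its consensus span by linear position scaling (indels inside
insertions are not realigned), with reverse-strand insertions flipped so
matrix columns always follow consensus orientation. Each GFF record is one
matrix row; multi-fragment copies are not reassembled.

LTR retrotransposons are annotated as separate LTR and internal entries.
For each internal sequence, each genomic flank is searched for a same-strand
LTR entry of the family: present within ≤ 10 bp (inclusive) → intact;
absent or > 5 kb away (strict) → lost. Both flanks intact is full length; a
lost 5′ flank (strand-aware) with an intact 3′ flank is 5′-truncated, and
symmetrically for 3′; anything else — strand mismatches, intermediate gaps —
is `other`. One LTR may serve as 3′ flank of one copy and 5′ flank of the
next, so head-to-tail tandems classify as two full-length copies.

The truncation contrast averages log2 enrichment over the terminal 1 kb of
the *internal* sequence (LTRs excluded): the last 1 kb for the 5′ contrast,
the first 1 kb for the 3′ contrast, truncated to the internal length when
shorter so short fragments stay comparable. Groups are compared per stage by
the ratio of group mean linear enrichments (2^x of per-insertion means) and
a two-sided rank-sum test.

## piRNA and expression association

piRNA reads are size-filtered to 23–29 nt inclusive and split by strand.
Window RPM uses a non-overlapping 5 kb tiling; a read counts in the window
containing its start, and RPM = count / (total filtered mapped reads / 10⁶).
Windows overlapping classified peaks are grouped by the peak's label;
windows without peaks split into pericentric/euchromatic by window midpoint.
Per-TE piRNA coverage is mean per-position read coverage on the consensus,
per strand.

Copy-scaled TE expression is (RNA count / median autosomal gene count) /
(DNA count / median autosomal coverage); it is reported missing when the
normalized DNA count is zero, and stage-to-stage folds add the same 0.01
pseudocount convention on both sides. Sex is inferred from the
autosome:X median window-coverage ratio (male iff strictly > 1.5, the
midpoint of the expected 1 for females and 2 for males). ATAC enrichment is
log2((ATAC + 0.01)/(DNA + 0.01)) on median-normalized fragment tracks with a
sex-match guard, since dividing by sex-matched DNA controls both copy number
and the halved male sex-chromosome coverage.

## Shared statistics

The rank-sum test switches to exact enumeration when min(n, m) ≤ 8 and the
pooled sample is tie-free, otherwise a tie-corrected normal approximation
(implemented over `scipy.stats.mannwhitneyu`; the test suite checks the
exact branch against an independent enumeration over all rank assignments).
If every pooled observation is tied, p = 1. Pearson correlation uses the
t-distributed p-value and rejects zero-variance input; multiple testing uses
Benjamini–Hochberg step-up.

## Synthetic data generator

The generator is first-class, tested code; it defines the study conditions
for every recovery test. Defaults: a 2.0 Mb sample genome (two 600 kb
autosomes, a 400 kb X, a 400 kb neo-Y; pericentric = leading 120 kb of the
non-Y chromosomes, the neo-Y wholly heterochromatic), a 240 kb spike-in
genome, 30× depth, 3 replicates per stage (two male, one female), 5 stages.
A full pipeline run takes about one minute on one CPU.

- **TE annotation** — an LTR family (372 bp LTR + 4628 bp internal) with 40
  full-length copies (flank gaps ≤ 10 bp, one pair at exactly 10 bp, one
  head-to-tail tandem), 5 five-prime-truncated (5′ LTR absent or 5001 bp
  away) and 5 three-prime-truncated copies, isolated by > 5 kb so lost
  flanks stay lost; three non-LTR families (one early-nucleating with
  full-length copies and fragments missing the nucleation region, two late);
  microsatellites and genes.
- **Nucleation sites** — stage-3-onset persistent sites at one fixed
  consensus position of the early non-LTR family and at the 5′ LTR of every
  intact LTR copy; early-stage-4-onset sites at late families and inside
  pericentric regions; temporary sites at microsatellites with amplitude
  decay (1, 0.55, 0.25, 0.08, 0) reaching zero by s7; phantom sites that add
  signal to every antibody's surface. Sites are kept ≥ 2.5 kb apart so
  peak-to-truth matching is unambiguous.
- **Signal model** — log2 surface per site: flat-top plateau of the
  stage-specific half-width with Gaussian shoulders (σ = 50 bp), amplitude
  2.5 log2 units, combined by maximum. Spreading half-widths by stages since
  onset are 70 / 150 / 450 / 1500 / 5000 bp: 70 bp emulates single-nucleosome
  stage-3 peaks, 150 bp keeps early-stage-4 domains narrow enough that a
  summit-±100 bp rule resolves old vs new, and 5000 bp lets stage-7 domains
  span an entire LTR element so truncated copies (which lack the 5′ source)
  are measurably less enriched at their homologous terminal window.
  Coverage is Poisson: input ~ Poisson(depth), ChIP ~ Poisson(depth·2^E),
  with male X/Y at half depth and trace female Y coverage (0.02×).
- **piRNA** — reads multinomial over families at rates ∝ rate × consensus
  length (early families ~10× the late rate), 90% of lengths in 23–29 nt,
  70% sense, placed inside insertions of the family plus a 20% uniform
  background; consensus-space reads emitted in parallel.
- **Expression** — per-copy Poisson RNA rates with planted induction folds
  (early families 1.4× between the s2 and s4 RNA samples, late families
  1.6× between s4 and s5), DNA counts ∝ copy number.

What the generator does **not** emulate — and therefore what passing tests do
not establish about real data: read-level sequences, mappability and
cross-mapping between repeat copies (the dominant real-world confounder for
truncation contrasts), fragment-length effects, nucleosome positioning,
biological replicate variability beyond Poisson counting noise, and MACS2's
statistical peak model. Recovery accuracies near 1.0 reflect the planted
margins (amplitude 2.5 vs threshold 0.5 at 30×), not expected performance on
real libraries.

## Numerical choices

Quantile bins: `numpy.array_split` of the sorted values into 1000 rank
chunks; bin boundaries are the spike-in chunk maxima; value-to-bin lookup is
`searchsorted(..., side="left")` with clamping. Bootstrap CIs: percentile
method, 1000 resamples, seeded. Row sorting of matrices uses stable argsort
on (nan-aware) row means. Summit-to-consensus mapping is the linear
fractional position, strand-flipped for reverse insertions. Windows, peaks
and insertions all use 0-based half-open coordinates internally; GFF is
converted at the boundary.

## Known limitations

Per-base tracks are dense arrays (memory ∝ genome length; fine for desk-
scale and single Drosophila-sized chromosome arms, not for mammalian
genomes). The naive caller is a stand-in, not a MACS2 replacement. The
quantile correction assumes the spike-in and sample share pull-down
chemistry; it cannot correct distortions that differ between the two
genomes. Exactly-tied enrichment values can land in a neighboring quantile
bin. LTR structure classification trusts the annotation's strand and family
assignments and does not attempt to reassemble fragmented internal entries.
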