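# hetnuc

Analysis toolkit for mapping the **establishment of H3K9me3 heterochromatin
across early embryonic stages** from staged, spike-in ChIP-seq — built for
chromatin biologists studying how repressive domains nucleate at
transposable elements (TEs) and spread to neighboring nucleosomes, and for
anyone who needs reproducible spike-in-normalized enrichment tracks and a
developmental peak taxonomy at desk scale.

## What it computes

Per-site enrichment of a ChIP/input pair on median-autosomal-normalized
coverage, with a pseudocount guarding zero coverage:

```
E(x) = log2( (chip(x)/chip_median + 0.01) / (input(x)/input_median + 0.01) )
```

Samples with different pull-down efficiencies are made comparable through
exogenous spike-in chromatin: spike-in enrichment distributions are matched
to a cross-sample reference by **quantile bins of width 0.1 percentile**
(1000 bins); the per-bin shift fitted on the spike-in is applied to the
sample's own values. On top of the corrected tracks the package builds:

- a **peak taxonomy** — phantom vs specific (artifact peaks reproduced
  across unrelated antibody preparations), persistent vs temporary (still
  enriched, log2 > 0.5 over summit ± 100 bp, at the final stage), and old vs
  new early-stage-4 peaks (already enriched at stage 3 or not), with
  replicate peaks < 100 bp apart merged;
- **TE consensus metaprofiles** — per-insertion enrichment projected onto
  family consensus coordinates (insertions × positions matrices);
- **LTR structure** — full-length vs 5′/3′-truncated copies (same-strand
  LTR within 10 bp = intact flank, missing or > 5 kb = lost) and the
  terminal-1 kb enrichment contrast between full-length and truncated
  copies;
- **piRNA association** — 23–29 nt reads, strand-split, RPM in 5 kb
  windows, grouped by peak overlap and pericentric location with rank-sum
  tests; and **copy-number-scaled TE expression**
  `(RNA/median gene count) / (DNA/median coverage)` with stage folds.

A first-class synthetic-data module generates a ~2 Mb genome with planted
nucleation sites, spreading schedules, phantom peaks, LTR truncations,
spike-in distortions, piRNA rates and expression folds, so the entire
pipeline is testable against known ground truth with no downloads.

## Worked example

```python
from hetnuc.pipeline import run_pipeline

r = run_pipeline("out/", seed=1)
print(r["n_s3_peaks"], r["n_s3_specific"], r["n_s3_phantom"])
print(r["ltr_structure_counts"])
print(round(r["truncation_fold_s7"], 2), r["truncation_p_s7"] < 0.01)
print({k: round(v) for k, v in r["pirna_group_medians"].items()})
```

prints

```
91 81 10
{'full_length': 40, 'five_prime_truncated': 5, 'three_prime_truncated': 5, 'other': 0}
6.16 True
{'peri': 1238, 'persistent': 4906, 'eu': 522, 'temporary': 489}
```

Reading: of 91 stage-3 peaks called on the synthetic genome, 10 are flagged
phantom (all 10 planted artifacts; the 81 specific peaks match the planted
real sites). The LTR family's planted structural classes (40 full-length,
5 five-prime-, 5 three-prime-truncated) are recovered exactly. At stage 7,
full-length copies are 6.2-fold more enriched than 5′-truncated copies over
the shared terminal 1 kb (rank-sum p < 0.01) — truncated copies lost the 5′
nucleation source. And 5 kb windows holding persistent stage-3 peaks carry
an order of magnitude more piRNA (median RPM 4906) than euchromatic
background windows (522), the planted piRNA–nucleation association.

The same run writes bedGraph enrichment tracks, narrowPeak and taxonomy
tables, consensus matrices, contrast and expression TSVs into `out/`.
A thin CLI wraps the library: `hetnuc simulate`, `hetnuc coverage`,
`hetnuc enrich`, `hetnuc pipeline` (see `--help`).

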