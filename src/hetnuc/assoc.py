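"""piRNA window association, copy-scaled TE expression, sex inference, ATAC.

piRNAs (23-29 nt in Drosophila) are size-filtered, split by strand, and
counted in 5 kb genomic windows as RPM (reads per million 23-29 nt mapped
reads). Window RPM distributions are then compared between windows that do or
do not overlap classified peaks, and inside versus outside the pericentromere.
TE expression is scaled by copy number: RNA counts (normalized by the median
autosomal gene count) divided by DNA counts (normalized by median autosomal
coverage), so highly repetitive families are not mistaken for highly
expressed ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .genome import GenomeModel
from .normalization import (
    DEFAULT_PSEUDOCOUNT,
    EnrichmentTrack,
    log2_enrichment_values,
)
from .tracks import CoverageTrack, Window, window_mean_array

PIRNA_MIN_NT = 23
PIRNA_MAX_NT = 29
PIRNA_WINDOW = 5000
SEX_RATIO_THRESHOLD = 1.5  # autosome:X median coverage; male iff strictly above
EXACT_RANKSUM_MAX = 8  # exact p-value when min(n, m) <= this and no ties


@dataclass(frozen=True)
class SmallRNARead:
    target: str  # chromosome or TE consensus name
    start: int  # 0-based
    length: int  # nt
    strand: str  # + | -

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("read length must be positive")


# -- piRNA processing -------------------------------------------------------

def filter_pirna(
    reads: Iterable[SmallRNARead],
    min_nt: int = PIRNA_MIN_NT,
    max_nt: int = PIRNA_MAX_NT,
) -> list[SmallRNARead]:
    """Keep reads in the piRNA size range, bounds inclusive."""
    return [r for r in reads if min_nt <= r.length <= max_nt]


def split_by_strand(
    reads: Iterable[SmallRNARead],
) -> tuple[list[SmallRNARead], list[SmallRNARead]]:
    """(sense/forward, antisense/reverse) partition; counts conserved."""
    fwd = [r for r in reads if r.strand == "+"]
    rev = [r for r in reads if r.strand != "+"]
    return fwd, rev


def window_rpm(
    reads: Sequence[SmallRNARead],
    genome: GenomeModel,
    width: int = PIRNA_WINDOW,
) -> list[Window]:
    """RPM per non-overlapping window; a read counts where it starts.

    RPM = window count / (total mapped filtered reads / 1e6), with the total
    taken over the reads passed in (i.e. after the 23-29 nt filter).
    """
    total = len(reads)
    if total == 0:
        raise ValueError("zero mapped reads; RPM undefined")
    counts: dict[str, np.ndarray] = {}
    for c in genome.chromosomes:
        n_windows = -(-c.length // width)
        counts[c.name] = np.zeros(n_windows)
    for r in reads:
        if r.target in counts:
            counts[r.target][r.start // width] += 1
    scale = total / 1e6
    out = []
    for c in genome.chromosomes:
        for i, n in enumerate(counts[c.name]):
            start = i * width
            out.append(
                Window(c.name, start, min(start + width, c.length), float(n / scale))
            )
    return out


def associate_windows_peaks(
    windows: Sequence[Window],
    peaks: Sequence,
    genome: GenomeModel,
    label_attr: str = "persistence",
) -> tuple[dict[str, np.ndarray], dict[str, float], dict[tuple[str, str], float]]:
    """Group window RPM by peak overlap/label and pericentric location.

    Windows overlapping a peak are grouped by the peak's taxonomy label (e.g.
    persistence -> 'persistent'/'temporary'); windows without peaks split into
    'peri'/'eu' by window midpoint. Returns (group values, group medians,
    pairwise two-sided rank-sum p-values). Pairs with an empty group are
    skipped.
    """
    peaks_by_chrom: dict[str, list] = {}
    for p in peaks:
        peaks_by_chrom.setdefault(p.chrom, []).append(p)
    groups: dict[str, list[float]] = {}
    for w in windows:
        label = None
        for p in peaks_by_chrom.get(w.chrom, []):
            if p.start < w.end and w.start < p.end:
                label = getattr(p, label_attr, "NA")
                break
        if label is None:
            mid = (w.start + w.end) // 2
            label = "peri" if genome.in_pericentric(w.chrom, mid) else "eu"
        groups.setdefault(label, []).append(w.value)
    arrays = {k: np.asarray(v) for k, v in groups.items()}
    medians = {k: float(np.median(v)) for k, v in arrays.items()}
    pvals: dict[tuple[str, str], float] = {}
    names = sorted(arrays)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if len(arrays[a]) and len(arrays[b]):
                _, p = rank_sum(arrays[a], arrays[b])
                pvals[(a, b)] = p
    return arrays, medians, pvals


def te_pirna_coverage(
    reads: Sequence[SmallRNARead], library
) -> dict[str, dict[str, float]]:
    """Per family, per strand: mean per-position read coverage on the consensus.

    A 25 nt read on a 100 nt consensus contributes 25/100 mean coverage.
    Reads targeting unknown consensus names are skipped with a warning.
    """
    import warnings

    cover: dict[str, dict[str, float]] = {}
    for r in reads:
        if r.target not in library:
            warnings.warn(f"read targets unknown consensus {r.target!r}, skipped")
            continue
        L = library[r.target].length
        strand = "sense" if r.strand == "+" else "antisense"
        fam = cover.setdefault(r.target, {"sense": 0.0, "antisense": 0.0})
        covered = min(r.length, L - r.start) if r.start < L else 0
        fam[strand] += covered / L
    return cover


# -- expression -------------------------------------------------------------

def scaled_te_expression(
    rna_count: float,
    dna_count: float,
    rna_normalizer: float,
    dna_normalizer: float,
) -> float:
    """Copy-number-scaled expression: (RNA/norm) / (DNA/norm).

    Returns NaN when the normalized DNA count is 0 (no copies detected).
    """
    if rna_normalizer <= 0 or dna_normalizer <= 0:
        raise ValueError("normalizers must be positive")
    dna = dna_count / dna_normalizer
    if dna == 0:
        return float("nan")
    return (rna_count / rna_normalizer) / dna


def stage_fold_change(
    expr_a: dict[str, float],
    expr_b: dict[str, float],
    pseudo: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[dict[str, float], float]:
    """Per-family expression fold of stage b relative to stage a.

    A pseudocount on both sides guards zero expression. Returns the per-family
    folds and their mean over families present at both stages (NaN scaled
    values excluded).
    """
    folds = {}
    for fam in expr_a.keys() & expr_b.keys():
        a, b = expr_a[fam], expr_b[fam]
        if np.isnan(a) or np.isnan(b):
            continue
        folds[fam] = (b + pseudo) / (a + pseudo)
    mean = float(np.mean(list(folds.values()))) if folds else float("nan")
    return folds, mean


# -- sex inference and ATAC -------------------------------------------------

def infer_sex(
    track: CoverageTrack,
    genome: GenomeModel,
    width: int = 1000,
    threshold: float = SEX_RATIO_THRESHOLD,
) -> tuple[str, float]:
    """Infer embryo sex from the autosome:X median window-coverage ratio.

    Males carry one X, so the ratio sits near 2; females near 1. The call is
    male iff ratio is strictly above ``threshold``.
    """
    auto = [
        window_mean_array(track.data[c.name], width)
        for c in genome.autosomes()
        if c.name in track.data
    ]
    x = [
        window_mean_array(track.data[c.name], width)
        for c in genome.chroms_of_class("X")
        if c.name in track.data
    ]
    if not x:
        raise ValueError("genome/track has no X windows")
    if not auto:
        raise ValueError("genome/track has no autosomal windows")
    x_med = float(np.median(np.concatenate(x)))
    if x_med <= 0:
        raise ValueError("zero median X coverage")
    ratio = float(np.median(np.concatenate(auto))) / x_med
    return ("male" if ratio > threshold else "female"), ratio


def atac_enrichment(
    atac: CoverageTrack,
    dna: CoverageTrack,
    pseudo: float = DEFAULT_PSEUDOCOUNT,
) -> EnrichmentTrack:
    """log2((ATAC + pseudo)/(DNA + pseudo)) on median-normalized fragment tracks.

    Dividing by sex-matched DNA coverage controls for copy number and for the
    halved sex-chromosome coverage of males, hence the sex-match guard.
    """
    if atac.sex != dna.sex:
        raise ValueError(f"sex mismatch: atac={atac.sex!r}, dna={dna.sex!r}")
    if not (atac.normalized and dna.normalized):
        raise ValueError("both tracks must be median-normalized first")
    data = {
        c: log2_enrichment_values(atac.data[c], dna.data[c], pseudo)
        for c in atac.data
    }
    return EnrichmentTrack(
        data,
        chip_id=atac.sample_id,
        input_id=dna.sample_id,
        pseudocount=pseudo,
        sex=atac.sex,
        mark="atac",
    )


# -- shared statistics ------------------------------------------------------

def rank_sum(x, y, sides: str = "two") -> tuple[float, float]:
    """Wilcoxon-Mann-Whitney rank-sum test.

    Exact enumeration when min(n, m) <= 8 and the pooled sample has no ties;
    normal approximation with tie correction otherwise. Returns (U statistic
    of x, p-value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):  # degenerate: every observation tied
        return float(len(x) * len(y) / 2), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = min(len(x), len(y)) <= EXACT_RANKSUM_MAX and not has_ties
    alternative = {"two": "two-sided", "less": "less", "greater": "greater"}[sides]
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with its t-distributed p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need n >= 3 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance sample")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# -- small-RNA I/O ----------------------------------------------------------

def read_smallrna_tsv(path: str | Path) -> list[SmallRNARead]:
    """BED-like TSV: target, start, length, strand."""
    reads = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        target, start, length, strand = line.split("\t")[:4]
        reads.append(SmallRNARead(target, int(start), int(length), strand))
    return reads


def write_smallrna_tsv(reads: Iterable[SmallRNARead], path: str | Path) -> None:
    lines = [f"{r.target}\t{r.start}\t{r.length}\t{r.strand}" for r in reads]
    Path(path).write_text("\n".join(lines) + "\n")
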