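"""Developmental taxonomy of H3K9me3 peaks and enrichment profiles.

Peak *calling* happens upstream (MACS2); this module post-processes called
peaks. Peaks first appearing at embryonic stage 3 sit on single nucleosomes
and either nucleate stable heterochromatin (persistent) or lose the mark by
stage 7 (temporary). Peaks reproduced across unrelated antibody preparations
are artifacts (phantom) and are removed. Early-stage-4 peaks are split into
those already enriched at stage 3 (old) and genuinely new nucleation events
(new).

The operative enrichment rule throughout is mean log2 enrichment over a
±100 bp window around the summit strictly greater than 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genome import GenomeModel, MALE_LIMITED_CLASSES
from .normalization import EnrichmentTrack
from .tracks import STAGES

ENRICHMENT_THRESHOLD = 0.5  # log2 units, strict inequality
MERGE_GAP = 100  # bp; replicate peaks closer than this are the same peak


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    summit: int
    stage: str | None = None
    name: str = ""
    score: float = 0.0
    specificity: str = "NA"  # specific | phantom | NA
    persistence: str = "NA"  # persistent | temporary | NA
    novelty: str = "NA"  # old | new | NA
    stage_enrichment: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"peak {self.name or self.chrom}: summit {self.summit} outside "
                f"[{self.start},{self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class StageSet:
    """Representative enrichment track per ordered developmental stage."""

    representative: dict[str, EnrichmentTrack]
    stages: tuple[str, ...] = STAGES

    def track(self, stage: str) -> EnrichmentTrack:
        if stage not in self.representative:
            raise ValueError(f"no representative track for stage {stage!r}")
        return self.representative[stage]

    def stages_before(self, stage: str) -> tuple[str, ...]:
        return tuple(self.stages[: self.stages.index(stage)])


# -- representative enrichment ---------------------------------------------

def representative_enrichment(
    replicates: Sequence[EnrichmentTrack], genome: GenomeModel
) -> EnrichmentTrack:
    """Per-base mean across replicates; Y/neo-Y from male replicates only.

    The Y-linked chromosomes are absent in females, so female replicates
    contribute only noise there and are excluded.
    """
    if not replicates:
        raise ValueError("at least one replicate required")
    males = [r for r in replicates if r.sex == "male"]
    data = {}
    for chrom in replicates[0].data:
        if genome.chrom_class(chrom) in MALE_LIMITED_CLASSES:
            if not males:
                raise ValueError(
                    f"{chrom} is male-limited but no male replicates present"
                )
            use = males
        else:
            use = replicates
        data[chrom] = np.mean([r.data[chrom] for r in use], axis=0)
    first = replicates[0]
    return EnrichmentTrack(
        data,
        chip_id="representative",
        pseudocount=first.pseudocount,
        spikein_normalized=first.spikein_normalized,
        stage=first.stage,
        mark=first.mark,
    )


# -- replicate merging ------------------------------------------------------

def merge_replicate_peaks(
    peak_lists: Sequence[Sequence[Peak]], gap: int = MERGE_GAP
) -> list[Peak]:
    """Unify peaks from replicates whose gap is < ``gap`` bp (0 if overlapping).

    The merged interval is the union span; the merged summit is the summit of
    the member with the highest score (mean enrichment), so the reported
    summit is always a real one.
    """
    peaks = sorted(
        (p for lst in peak_lists for p in lst), key=lambda p: (p.chrom, p.start)
    )
    merged: list[Peak] = []
    cluster: list[Peak] = []

    def _flush() -> None:
        if not cluster:
            return
        best = max(cluster, key=lambda p: p.score)
        merged.append(
            Peak(
                chrom=best.chrom,
                start=min(p.start for p in cluster),
                end=max(p.end for p in cluster),
                summit=best.summit,
                stage=best.stage,
                name=best.name,
                score=best.score,
            )
        )

    for p in peaks:
        if cluster and p.chrom == cluster[-1].chrom:
            span_end = max(q.end for q in cluster)
            if p.start - span_end < gap:  # strict: gap of exactly 100 stays split
                cluster.append(p)
                continue
        _flush()
        cluster = [p]
    _flush()
    return merged


# -- enrichment around summits ---------------------------------------------

def peak_enrichment(
    peak: Peak, track: EnrichmentTrack, halfwidth: int = 100
) -> float:
    """Mean log2 enrichment over [summit-halfwidth, summit+halfwidth).

    The window is truncated at chromosome boundaries; the mean runs over the
    bases actually available.
    """
    arr = track.data[peak.chrom]
    lo = max(0, peak.summit - halfwidth)
    hi = min(len(arr), peak.summit + halfwidth)
    return float(arr[lo:hi].mean())


def is_enriched(value: float, threshold: float = ENRICHMENT_THRESHOLD) -> bool:
    """Strictly greater than the log2 threshold (0.5 by default)."""
    return value > threshold


# -- taxonomy ---------------------------------------------------------------

def filter_phantom(
    peaks: Sequence[Peak],
    alt_tracks: Sequence[EnrichmentTrack],
    threshold: float = ENRICHMENT_THRESHOLD,
) -> tuple[list[Peak], list[Peak]]:
    """Partition into (specific, phantom).

    A peak is phantom iff it is enriched in at least one alternative-mark
    preparation; with no alternative tracks all peaks are specific.
    """
    specific, phantom = [], []
    for p in peaks:
        is_phantom = any(
            is_enriched(peak_enrichment(p, t), threshold) for t in alt_tracks
        )
        p.specificity = "phantom" if is_phantom else "specific"
        (phantom if is_phantom else specific).append(p)
    return specific, phantom


def classify_persistence(
    peaks: Sequence[Peak],
    stages: StageSet,
    final_stage: str = "s7",
    threshold: float = ENRICHMENT_THRESHOLD,
) -> list[Peak]:
    """Label peaks temporary iff not enriched at the final stage."""
    track = stages.track(final_stage)
    for p in peaks:
        e = peak_enrichment(p, track)
        p.stage_enrichment[final_stage] = e
        p.persistence = "persistent" if is_enriched(e, threshold) else "temporary"
    return list(peaks)


def classify_novelty(
    peaks: Sequence[Peak],
    earlier_track: EnrichmentTrack,
    threshold: float = ENRICHMENT_THRESHOLD,
) -> list[Peak]:
    """Label stage-4 peaks old iff already enriched in the earlier-stage track."""
    for p in peaks:
        e = peak_enrichment(p, earlier_track)
        p.novelty = "old" if is_enriched(e, threshold) else "new"
    return list(peaks)


def fraction_pre_enriched(
    peaks: Sequence[Peak],
    stages: StageSet,
    stage: str,
    threshold: float = ENRICHMENT_THRESHOLD,
) -> dict[str, float]:
    """Fraction of this stage's peaks already enriched at each earlier stage.

    ``threshold`` defaults to the operative log2 > 0.5 rule; pass
    ``np.log2(1.5)`` for the 1.5-fold variant.
    """
    if not peaks:
        return {s: float("nan") for s in stages.stages_before(stage)}
    out = {}
    for earlier in stages.stages_before(stage):
        if earlier not in stages.representative:
            continue
        track = stages.track(earlier)
        hits = sum(
            is_enriched(peak_enrichment(p, track), threshold) for p in peaks
        )
        out[earlier] = hits / len(peaks)
    return out


# -- profiles and trajectories ---------------------------------------------

def profile_around(
    peaks: Sequence[Peak],
    track: EnrichmentTrack,
    flank: int = 1000,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-peak enrichment matrix around summits plus a median profile.

    Returns ``(matrix, median, ci)`` where matrix rows are peaks sorted by
    descending mean enrichment and columns are offsets -flank..+flank;
    boundary-truncated positions are NaN and excluded from column medians.
    ``ci`` is a (2, width) percentile-bootstrap 95% band over peaks.
    """
    if not peaks:
        raise ValueError("empty peak list")
    width = 2 * flank + 1
    mat = np.full((len(peaks), width), np.nan)
    for i, p in enumerate(peaks):
        arr = track.data[p.chrom]
        lo = max(0, p.summit - flank)
        hi = min(len(arr), p.summit + flank + 1)
        mat[i, lo - (p.summit - flank) : hi - (p.summit - flank)] = arr[lo:hi]
    order = np.argsort(-np.nanmean(mat, axis=1), kind="stable")
    mat = mat[order]
    median = np.nanmedian(mat, axis=0)
    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, width))
    chunk = max(1, int(2e7 // (len(peaks) * width)))  # bound resample memory
    for b0 in range(0, n_boot, chunk):
        b1 = min(b0 + chunk, n_boot)
        idx = rng.integers(0, len(peaks), size=(b1 - b0, len(peaks)))
        boot[b0:b1] = np.nanmedian(mat[idx], axis=1)
    ci = np.nanpercentile(boot, [2.5, 97.5], axis=0)
    return mat, median, ci


def trajectory(
    peaks: Sequence[Peak],
    stages: StageSet,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[str, tuple[float, float, float]]:
    """Median ±100 bp peak enrichment per stage with bootstrap 95% CI."""
    if not peaks:
        raise ValueError("empty peak list")
    rng = np.random.default_rng(seed)
    out = {}
    for stage in stages.stages:
        if stage not in stages.representative:
            continue
        track = stages.track(stage)
        vals = np.array([peak_enrichment(p, track) for p in peaks])
        idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
        boot = np.median(vals[idx], axis=1)
        lo, hi = np.percentile(boot, [2.5, 97.5])
        out[stage] = (float(np.median(vals)), float(lo), float(hi))
    return out


# -- annotation -------------------------------------------------------------

ANNOTATION_PRECEDENCE = ("TE", "microsatellite", "gene")


def annotate_peaks(
    peaks: Sequence[Peak], genome: GenomeModel
) -> tuple[dict[str, str], float]:
    """Assign each peak an annotation category and the pericentric fraction.

    Category by interval overlap with precedence TE > microsatellite > gene >
    other. Returns ``({peak name or index: category}, pericentric_fraction)``
    where a peak is pericentric if its summit lies inside a pericentric region.
    """
    by_chrom: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for iv in genome.annotations:
        by_chrom.setdefault(iv.chrom, {}).setdefault(iv.category, []).append(
            (iv.start, iv.end)
        )
    categories: dict[str, str] = {}
    n_peri = 0
    for i, p in enumerate(peaks):
        key = p.name or str(i)
        cat = "other"
        chrom_cats = by_chrom.get(p.chrom, {})
        for candidate in ANNOTATION_PRECEDENCE:
            if any(
                s < p.end and p.start < e for s, e in chrom_cats.get(candidate, [])
            ):
                cat = candidate
                break
        categories[key] = cat
        if genome.in_pericentric(p.chrom, p.summit):
            n_peri += 1
    fraction = n_peri / len(peaks) if peaks else float("nan")
    return categories, fraction


# -- narrowPeak / BED I/O ---------------------------------------------------

def read_narrowpeak(path: str | Path, stage: str | None = None) -> list[Peak]:
    """Read MACS2 narrowPeak; summit = start + 10th-column offset."""
    peaks = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        start, end = int(f[1]), int(f[2])
        offset = int(f[9]) if len(f) > 9 and int(f[9]) >= 0 else (end - start) // 2
        peaks.append(
            Peak(
                chrom=f[0],
                start=start,
                end=end,
                summit=start + offset,
                stage=stage,
                name=f[3] if len(f) > 3 else "",
                score=float(f[6]) if len(f) > 6 else 0.0,
            )
        )
    return peaks


def write_narrowpeak(peaks: Iterable[Peak], path: str | Path) -> None:
    lines = []
    for i, p in enumerate(peaks):
        lines.append(
            "\t".join(
                [
                    p.chrom,
                    str(p.start),
                    str(p.end),
                    p.name or f"peak_{i}",
                    "0",
                    ".",
                    f"{p.score:g}",
                    "-1",
                    "-1",
                    str(p.summit - p.start),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_taxonomy_tsv(peaks: Iterable[Peak], path: str | Path) -> None:
    """BED-like TSV with summit and taxonomy label columns."""
    header = "chrom\tstart\tend\tsummit\tname\tstage\tspecificity\tpersistence\tnovelty"
    lines = [header]
    for i, p in enumerate(peaks):
        lines.append(
            f"{p.chrom}\t{p.start}\t{p.end}\t{p.summit}\t{p.name or f'peak_{i}'}"
            f"\t{p.stage or 'NA'}\t{p.specificity}\t{p.persistence}\t{p.novelty}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
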