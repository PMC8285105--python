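"""Library-size normalization, log2 enrichment, and spike-in correction.

The enrichment of a ChIP/input pair is computed on median-autosomal-normalized
coverage with a small pseudocount guarding zero coverage::

    enrichment = (chip/chip_median + 0.01) / (input/input_median + 0.01)

stored per base as log2(enrichment). Because equal amounts of exogenous
(spike-in) chromatin are added to every sample, differences between samples in
their spike-in enrichment distributions reflect pull-down efficiency rather
than biology. The correction matches each sample's spike-in enrichment
distribution to a reference (the mean spike-in enrichment across samples) by
quantile bins of width 0.1 percentile: if the bin holding log2 enrichment 3.2
sits at 4.0 in the reference, every sample value in that bin is raised by 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome import GenomeModel
from .tracks import CoverageTrack, median_autosomal, window_mean_array

DEFAULT_PSEUDOCOUNT = 0.01
N_QUANTILE_BINS = 1000  # bins of width 0.1 percentile


@dataclass
class EnrichmentTrack:
    """Per-base log2 ChIP/input enrichment with provenance."""

    data: dict[str, np.ndarray]
    chip_id: str = ""
    input_id: str = ""
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    spikein_normalized: bool = False
    stage: str | None = None
    mark: str = ""
    sex: str = "unknown"

    def __post_init__(self) -> None:
        for chrom, arr in self.data.items():
            arr = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{chrom}: enrichment must be finite")
            self.data[chrom] = arr

    def values(self) -> np.ndarray:
        return np.concatenate([self.data[c] for c in self.data])

    def copy_with(self, **changes) -> "EnrichmentTrack":
        data = {c: a.copy() for c, a in self.data.items()}
        return replace(self, data=data, **changes)


@dataclass
class ReferenceProfile:
    """Per-1kb-window mean log2 enrichment across all spike-in pairs."""

    window_values: dict[str, np.ndarray]
    window_width: int = 1000
    n_pairs: int = 0

    def values(self) -> np.ndarray:
        return np.concatenate([self.window_values[c] for c in self.window_values])


@dataclass
class ShiftFunction:
    """Piecewise-constant additive log2 correction keyed by value.

    ``boundaries[k]`` is the upper edge of quantile bin k in the spike-in
    distribution the function was fitted from; values beyond the extreme
    boundaries clamp to the first/last bin.
    """

    boundaries: np.ndarray  # non-decreasing, one upper bound per bin
    shifts: np.ndarray
    bin_counts: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        self.shifts = np.asarray(self.shifts, dtype=float)
        if len(self.boundaries) != len(self.shifts):
            raise ValueError("one shift per bin required")
        if np.any(np.diff(self.boundaries) < 0):
            raise ValueError("bin boundaries must be non-decreasing")

    def bin_of(self, values: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.boundaries, values, side="left")
        return np.clip(idx, 0, len(self.shifts) - 1)

    def __call__(self, values) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        return values + self.shifts[self.bin_of(values)]

    def to_tsv(self, path: str | Path) -> None:
        lines = [
            f"{b:.10g}\t{s:.10g}" for b, s in zip(self.boundaries, self.shifts)
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ShiftFunction":
        rows = [
            line.split("\t")
            for line in Path(path).read_text().splitlines()
            if line.strip()
        ]
        b = np.array([float(r[0]) for r in rows])
        s = np.array([float(r[1]) for r in rows])
        return cls(b, s)


# -- median normalization and enrichment -----------------------------------

def normalize_by_median(
    track: CoverageTrack, genome: GenomeModel, width: int = 1000
) -> CoverageTrack:
    """Divide per-base coverage by the median autosomal window coverage."""
    med = median_autosomal(track, genome, width)
    if med <= 0:
        raise ValueError(
            f"sample {track.sample_id!r}: zero median autosomal coverage "
            "(degenerate library)"
        )
    out = track.copy_with(normalized=True)
    for chrom in out.data:
        out.data[chrom] = out.data[chrom] / med
    return out


def log2_enrichment_values(
    chip: np.ndarray, inp: np.ndarray, pseudo: float = DEFAULT_PSEUDOCOUNT
) -> np.ndarray:
    """log2((chip + pseudo) / (input + pseudo)) on already-normalized values."""
    return np.log2((chip + pseudo) / (inp + pseudo))


def enrichment(
    chip: CoverageTrack,
    inp: CoverageTrack,
    genome: GenomeModel,
    pseudo: float = DEFAULT_PSEUDOCOUNT,
    width: int = 1000,
) -> EnrichmentTrack:
    """Per-base log2 enrichment of a ChIP/input pair.

    Both tracks are median-autosomal normalized first (skipped for tracks
    already flagged normalized). Pseudocount keeps every value finite; a site
    with zero coverage in both samples has enrichment exactly 0.
    """
    if set(chip.data) != set(inp.data):
        raise ValueError("chip and input tracks cover different chromosomes")
    chip_n = chip if chip.normalized else normalize_by_median(chip, genome, width)
    inp_n = inp if inp.normalized else normalize_by_median(inp, genome, width)
    data = {
        c: log2_enrichment_values(chip_n.data[c], inp_n.data[c], pseudo)
        for c in chip_n.data
    }
    return EnrichmentTrack(
        data,
        chip_id=chip.sample_id,
        input_id=inp.sample_id,
        pseudocount=pseudo,
        stage=chip.stage,
        mark=chip.mark,
        sex=chip.sex,
    )


# -- spike-in reference and quantile-bin shift ------------------------------

def window_log2_enrichment(
    chip: CoverageTrack,
    inp: CoverageTrack,
    genome: GenomeModel,
    pseudo: float = DEFAULT_PSEUDOCOUNT,
    width: int = 1000,
) -> dict[str, np.ndarray]:
    """Window-mean coverages fed through the enrichment formula."""
    chip_n = chip if chip.normalized else normalize_by_median(chip, genome, width)
    inp_n = inp if inp.normalized else normalize_by_median(inp, genome, width)
    out = {}
    for chrom in chip_n.data:
        cw = window_mean_array(chip_n.data[chrom], width)
        iw = window_mean_array(inp_n.data[chrom], width)
        out[chrom] = log2_enrichment_values(cw, iw, pseudo)
    return out


def build_spikein_reference(
    spikein_pairs: Sequence[tuple[CoverageTrack, CoverageTrack]],
    genome: GenomeModel,
    pseudo: float = DEFAULT_PSEUDOCOUNT,
    width: int = 1000,
) -> ReferenceProfile:
    """Mean window-level log2 enrichment across all spike-in ChIP/input pairs."""
    if not spikein_pairs:
        raise ValueError("at least one spike-in pair required")
    per_pair = [
        window_log2_enrichment(c, i, genome, pseudo, width) for c, i in spikein_pairs
    ]
    chrom_sets = {frozenset(p) for p in per_pair}
    if len(chrom_sets) != 1:
        raise ValueError("spike-in pairs cover different genomes")
    mean = {
        chrom: np.mean([p[chrom] for p in per_pair], axis=0) for chrom in per_pair[0]
    }
    return ReferenceProfile(mean, width, len(spikein_pairs))


def fit_quantile_shift(
    spikein_values,
    reference: ReferenceProfile | np.ndarray,
    n_bins: int = N_QUANTILE_BINS,
) -> ShiftFunction:
    """Per-quantile-bin additive shift mapping spike-in onto the reference.

    Both distributions are cut into ``n_bins`` rank bins (0.1 percentile each
    by default); the shift of bin k is (mean reference in bin k) - (mean
    spike-in in bin k). Bin boundaries are recorded from the spike-in
    distribution. Bins left empty by short inputs inherit the nearest
    non-empty bin's shift, keeping the function total.
    """
    spike = np.sort(np.asarray(spikein_values, dtype=float).ravel())
    ref = reference.values() if isinstance(reference, ReferenceProfile) else reference
    ref = np.sort(np.asarray(ref, dtype=float).ravel())
    if len(spike) < 2 or len(ref) < 2:
        raise ValueError("need at least 2 windows to fit quantile shifts")

    spike_chunks = np.array_split(spike, n_bins)
    ref_chunks = np.array_split(ref, n_bins)
    shifts = np.full(n_bins, np.nan)
    boundaries = np.empty(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    last_boundary = spike[0]
    for k, (sc, rc) in enumerate(zip(spike_chunks, ref_chunks)):
        if len(sc) and len(rc):
            shifts[k] = rc.mean() - sc.mean()
        if len(sc):
            last_boundary = sc[-1]
        boundaries[k] = last_boundary
        counts[k] = len(sc)

    # nearest-non-empty fill for bins with no data
    filled = np.flatnonzero(~np.isnan(shifts))
    if len(filled) == 0:
        raise ValueError("no populated quantile bins")
    empty = np.flatnonzero(np.isnan(shifts))
    if len(empty):
        nearest = filled[np.argmin(np.abs(empty[:, None] - filled[None, :]), axis=1)]
        shifts[empty] = shifts[nearest]
    return ShiftFunction(boundaries, shifts, counts)


def apply_shift(sample: EnrichmentTrack, fn: ShiftFunction) -> EnrichmentTrack:
    """Shift every per-base log2 value by its spike-in quantile bin's shift."""
    if sample.spikein_normalized:
        raise ValueError("track is already spike-in normalized")
    out = sample.copy_with(spikein_normalized=True)
    for chrom in out.data:
        out.data[chrom] = fn(out.data[chrom])
    return out
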