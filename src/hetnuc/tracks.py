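"""Per-base coverage tracks, windowed summaries, and alignment partitioning.

A :class:`CoverageTrack` holds one non-negative per-base array per chromosome
for a single sample (ChIP, input, ATAC, DNA or RNA). Reads from a combined
sample+spike-in mapping are split by target genome with
:func:`partition_spikein`; ambiguous alignments (mapping quality 0, i.e. ties
between the two genomes) are discarded, following the dual-genome spike-in
design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genome import GenomeModel

STAGES = ("s3", "e4", "l4", "s5", "s7")
ASSAYS = ("chip", "input", "atac", "dna", "rna")


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    target_name: str
    position: int  # 0-based leftmost aligned base
    aligned_length: int
    strand: str = "+"
    mapping_quality: int = 60
    pair_role: str = "single"  # single | mate1 | mate2

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"record {self.read_id}: negative position")
        if self.aligned_length <= 0:
            raise ValueError(f"record {self.read_id}: aligned_length must be > 0")

    @property
    def end(self) -> int:
        return self.position + self.aligned_length


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int
    end: int
    value: float


@dataclass
class CoverageTrack:
    """Per-base signal per chromosome with sample metadata."""

    data: dict[str, np.ndarray]
    sample_id: str = ""
    stage: str | None = None
    assay: str = "chip"
    mark: str = ""
    replicate: str = ""
    sex: str = "unknown"
    normalized: bool = field(default=False)

    def __post_init__(self) -> None:
        for chrom, arr in self.data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"{chrom}: coverage must be 1-D")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"{chrom}: coverage must be finite and >= 0")
            self.data[chrom] = arr

    def validate_against(self, genome: GenomeModel) -> None:
        for chrom, arr in self.data.items():
            if not genome.has_chrom(chrom):
                raise ValueError(f"track chromosome {chrom!r} not in genome")
            if len(arr) != genome.chrom_length(chrom):
                raise ValueError(
                    f"{chrom}: array length {len(arr)} != chromosome length "
                    f"{genome.chrom_length(chrom)}"
                )

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))

    def copy_with(self, **changes) -> "CoverageTrack":
        data = {c: a.copy() for c, a in self.data.items()}
        return replace(self, data=data, **changes)


# -- spike-in partition ----------------------------------------------------

def partition_spikein(
    records: Iterable[AlignmentRecord],
    sample_chroms: set[str],
    spikein_chroms: set[str],
) -> tuple[list[AlignmentRecord], list[AlignmentRecord], int]:
    """Split records by target genome; drop ambiguous (mapq 0) alignments.

    Returns ``(sample_records, spikein_records, discarded_count)``; the three
    partitions always sum to the input count.
    """
    overlap = sample_chroms & spikein_chroms
    if overlap:
        raise ValueError(f"chromosome name sets overlap: {sorted(overlap)}")
    sample, spikein, discarded = [], [], 0
    for rec in records:
        if rec.target_name in sample_chroms:
            bucket = sample
        elif rec.target_name in spikein_chroms:
            bucket = spikein
        else:
            raise ValueError(
                f"record {rec.read_id}: target {rec.target_name!r} in neither genome"
            )
        if rec.mapping_quality == 0:
            discarded += 1
        else:
            bucket.append(rec)
    return sample, spikein, discarded


# -- coverage --------------------------------------------------------------

def coverage_from_alignments(
    records: Sequence[AlignmentRecord],
    genome: GenomeModel,
    mode: str = "read",
    **metadata,
) -> CoverageTrack:
    """Accumulate per-base coverage in ``read`` or ``fragment`` mode.

    Read mode adds 1 to every base covered by each record. Fragment mode pairs
    mate1/mate2 records by read_id and adds 1 once per pair over the full
    fragment span (leftmost start to rightmost end), the ``-pc`` convention
    used for ATAC fragment coverage.
    """
    if mode not in ("read", "fragment"):
        raise ValueError(f"unknown mode {mode!r}")
    data = {c.name: np.zeros(c.length) for c in genome.chromosomes}

    def _add(chrom: str, start: int, end: int, read_id: str) -> None:
        if chrom not in data:
            raise ValueError(f"record {read_id}: unknown chromosome {chrom!r}")
        if end > len(data[chrom]):
            raise ValueError(
                f"record {read_id} extends past end of {chrom} ({end} > {len(data[chrom])})"
            )
        data[chrom][start:end] += 1

    if mode == "read":
        for rec in records:
            _add(rec.target_name, rec.position, rec.end, rec.read_id)
    else:
        pairs: dict[str, list[AlignmentRecord]] = {}
        for rec in records:
            pairs.setdefault(rec.read_id, []).append(rec)
        unpaired = [rid for rid, rs in pairs.items() if len(rs) != 2]
        if unpaired:
            raise ValueError(f"fragment mode requires mate pairs; unpaired: {unpaired}")
        for rid, (a, b) in pairs.items():
            if a.target_name != b.target_name:
                raise ValueError(f"pair {rid}: mates on different chromosomes")
            _add(a.target_name, min(a.position, b.position), max(a.end, b.end), rid)
    return CoverageTrack(data, **metadata)


def records_from_sam(path: str | Path, min_length: int = 1) -> list[AlignmentRecord]:
    """Load mapped records from a SAM/BAM file via pysam."""
    import pysam

    records = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped or aln.reference_length is None:
                continue
            if aln.reference_length < min_length:
                continue
            if aln.is_paired:
                role = "mate1" if aln.is_read1 else "mate2"
            else:
                role = "single"
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    target_name=aln.reference_name,
                    position=aln.reference_start,
                    aligned_length=aln.reference_length,
                    strand="-" if aln.is_reverse else "+",
                    mapping_quality=aln.mapping_quality,
                    pair_role=role,
                )
            )
    return records


# -- windows ---------------------------------------------------------------

def window_mean_array(values: np.ndarray, width: int) -> np.ndarray:
    """Means over a non-overlapping tiling from 0; final partial window kept."""
    if width < 1:
        raise ValueError("width must be >= 1")
    n = len(values)
    if n == 0:
        return np.zeros(0)
    edges = np.arange(0, n, width)
    sums = np.add.reduceat(values, edges)
    lengths = np.minimum(edges + width, n) - edges
    return sums / lengths


def window_means(track: CoverageTrack, width: int = 1000) -> list[Window]:
    """Mean coverage over a non-overlapping window tiling of every chromosome."""
    out: list[Window] = []
    for chrom in track.data:
        vals = window_mean_array(track.data[chrom], width)
        n = len(track.data[chrom])
        for i, v in enumerate(vals):
            start = i * width
            out.append(Window(chrom, start, min(start + width, n), float(v)))
    return out


def median_autosomal(
    track: CoverageTrack, genome: GenomeModel, width: int = 1000
) -> float:
    """Median of window means restricted to autosomal windows."""
    vals = []
    for chrom in genome.autosomes():
        if chrom.name in track.data:
            vals.append(window_mean_array(track.data[chrom.name], width))
    if not vals:
        raise ValueError("no autosomal windows in track")
    return float(np.median(np.concatenate(vals)))


# -- bedGraph I/O ----------------------------------------------------------

def write_bedgraph(track_data: dict[str, np.ndarray], path: str | Path) -> None:
    """Write per-base arrays as run-length-collapsed 4-column bedGraph."""
    with open(path, "w") as fh:
        for chrom, arr in track_data.items():
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]:g}\n")


def read_bedgraph(
    path: str | Path, genome: GenomeModel, fill: float = 0.0
) -> dict[str, np.ndarray]:
    """Read 4-column bedGraph into per-base arrays sized from the genome."""
    data = {c.name: np.full(c.length, fill) for c in genome.chromosomes}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        chrom, start, end, value = line.split("\t")[:4]
        if chrom not in data:
            raise ValueError(f"bedGraph chromosome {chrom!r} not in genome")
        data[chrom][int(start) : int(end)] = float(value)
    return data
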