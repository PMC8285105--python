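"""Transposable-element consensus projection and LTR structure analysis.

Each genomic TE insertion carries the interval it occupies plus the interval
of the family consensus it matches, so per-base enrichment can be projected
into consensus coordinates and stacked across insertions (rows = insertions,
columns = consensus positions). For LTR retrotransposons the LTRs and the
internal sequence are separate annotation entries; a full-length copy is an
internal sequence flanked on both sides by same-strand LTRs within 10 bp,
while a copy whose 5' (or 3') LTR is missing or more than 5 kb away is 5'
(3') truncated. Because the 5' LTR carries the promoter and the early
nucleation sites, contrasting terminal-1 kb enrichment between full-length
and 5'-truncated copies tests whether losing the nucleation region impairs
downstream heterochromatin establishment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genome import GenomeModel, Interval
from .normalization import EnrichmentTrack
from .peaks import Peak
from .assoc import rank_sum

LTR_FLANK_GAP = 10  # bp, inclusive: max gap between LTR and internal sequence
LTR_FAR = 5000  # bp, strict: beyond this an LTR no longer counts as present
TERMINAL_WINDOW = 1000  # bp averaged at the element terminus for contrasts

STRUCTURAL_CLASSES = (
    "full_length",
    "five_prime_truncated",
    "three_prime_truncated",
    "other",
)


@dataclass(frozen=True)
class TEConsensus:
    family: str
    length: int
    element_kind: str = "non_ltr"  # ltr_internal | ltr_terminal | non_ltr | other
    partner: str | None = None  # links internal <-> LTR entries of one family

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.family}: consensus length must be positive")


@dataclass
class TELibrary:
    entries: dict[str, TEConsensus]

    def __post_init__(self) -> None:
        for name, entry in self.entries.items():
            if entry.partner is not None:
                other = self.entries.get(entry.partner)
                if other is None or other.partner != name:
                    raise ValueError(f"{name}: partner link not symmetric")

    def __contains__(self, family: str) -> bool:
        return family in self.entries

    def __getitem__(self, family: str) -> TEConsensus:
        return self.entries[family]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TELibrary":
        """4-column TSV: family, consensus length, kind, partner ('.' if none)."""
        entries = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            fam, length, kind, partner = line.split("\t")[:4]
            entries[fam] = TEConsensus(
                fam, int(length), kind, None if partner == "." else partner
            )
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        lines = [
            f"{e.family}\t{e.length}\t{e.element_kind}\t{e.partner or '.'}"
            for e in self.entries.values()
        ]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class TEInsertion:
    chrom: str
    start: int
    end: int
    strand: str
    family: str
    consensus_start: int
    consensus_end: int
    structural_class: str = "NA"
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.consensus_start < self.consensus_end):
            raise ValueError(
                f"{self.family} insertion: bad consensus span "
                f"[{self.consensus_start},{self.consensus_end})"
            )
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.family} insertion: bad genomic span")

    @property
    def genomic_length(self) -> int:
        return self.end - self.start

    @property
    def consensus_length(self) -> int:
        return self.consensus_end - self.consensus_start


@dataclass
class ConsensusMatrix:
    """Insertion x consensus-position enrichment matrix (NaN = not aligned)."""

    family: str
    matrix: np.ndarray  # rows sorted by descending row mean
    insertions: list[TEInsertion]  # matching row order

    def to_tsv(self, path: str | Path) -> None:
        header = "insertion\t" + "\t".join(
            str(i) for i in range(self.matrix.shape[1])
        )
        lines = [header]
        for ins, row in zip(self.insertions, self.matrix):
            name = ins.name or f"{ins.chrom}:{ins.start}-{ins.end}"
            lines.append(
                name + "\t" + "\t".join("" if np.isnan(v) else f"{v:.4g}" for v in row)
            )
        Path(path).write_text("\n".join(lines) + "\n")


# -- RepeatMasker GFF -------------------------------------------------------

def _parse_target(attributes: str) -> tuple[str, int, int] | None:
    """Extract (family, consensus_start_1based, consensus_end) from GFF attrs.

    Handles both `Target "Motif:FAM" 12 372` and `Target=FAM 12 372`.
    """
    attributes = attributes.strip()
    if "Target" not in attributes:
        return None
    rest = attributes.split("Target", 1)[1].lstrip("= ")
    rest = rest.replace('"', " ").replace("Motif:", " ")
    parts = [p for p in rest.replace(";", " ").split() if p]
    if len(parts) < 3:
        return None
    return parts[0], int(parts[1]), int(parts[2])


def parse_repeatmasker_gff(
    path: str | Path, library: TELibrary
) -> tuple[list[TEInsertion], list[Interval], int]:
    """Parse RepeatMasker-style GFF into TE insertions and microsatellites.

    GFF is 1-based closed; both genomic and consensus spans are converted to
    0-based half-open. ``(motif)n`` entries become microsatellite intervals.
    Records with unknown families or consensus spans beyond the library length
    are skipped with a warning; the skip count is returned.
    """
    insertions: list[TEInsertion] = []
    microsats: list[Interval] = []
    skipped = 0
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 9:
            continue
        chrom, start1, end1, strand, attrs = f[0], int(f[3]), int(f[4]), f[6], f[8]
        target = _parse_target(attrs)
        if target is None:
            continue
        family, cs1, ce1 = target
        if family.endswith(")n"):
            microsats.append(
                Interval(chrom, start1 - 1, end1, "microsatellite", family)
            )
            continue
        if family not in library:
            warnings.warn(f"line {ln}: unknown family {family!r}, skipped")
            skipped += 1
            continue
        if ce1 > library[family].length or cs1 < 1:
            warnings.warn(
                f"line {ln}: consensus span {cs1}..{ce1} outside {family} "
                f"consensus (length {library[family].length}), skipped"
            )
            skipped += 1
            continue
        insertions.append(
            TEInsertion(
                chrom=chrom,
                start=start1 - 1,
                end=end1,
                strand=strand if strand in "+-" else "+",
                family=family,
                consensus_start=cs1 - 1,
                consensus_end=ce1,
            )
        )
    return insertions, microsats, skipped


def write_repeatmasker_gff(
    insertions: Iterable[TEInsertion],
    microsats: Iterable[Interval],
    path: str | Path,
) -> None:
    """Write insertions back out in RepeatMasker GFF convention (1-based)."""
    lines = ["##gff-version 2"]
    for ins in insertions:
        lines.append(
            "\t".join(
                [
                    ins.chrom,
                    "RepeatMasker",
                    "similarity",
                    str(ins.start + 1),
                    str(ins.end),
                    ".",
                    ins.strand,
                    ".",
                    f'Target "Motif:{ins.family}" {ins.consensus_start + 1} {ins.consensus_end}',
                ]
            )
        )
    for ms in microsats:
        lines.append(
            "\t".join(
                [
                    ms.chrom,
                    "RepeatMasker",
                    "similarity",
                    str(ms.start + 1),
                    str(ms.end),
                    ".",
                    "+",
                    f'Target "Motif:{ms.name}" 1 {ms.end - ms.start}',
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# -- consensus projection ---------------------------------------------------

def project_insertion(insertion: TEInsertion, track: EnrichmentTrack) -> np.ndarray:
    """Genomic enrichment of one insertion resampled onto its consensus span.

    Reverse-strand insertions are flipped so returned values always follow
    consensus orientation. Length mismatches between genomic and consensus
    spans (internal indels) are resolved by linear position scaling.
    """
    g = track.data[insertion.chrom][insertion.start : insertion.end]
    if insertion.strand == "-":
        g = g[::-1]
    clen = insertion.consensus_length
    idx = np.minimum((np.arange(clen) * len(g)) // clen, len(g) - 1)
    return g[idx]


def project_to_consensus(
    insertions: Sequence[TEInsertion],
    track: EnrichmentTrack,
    library: TELibrary,
) -> ConsensusMatrix:
    """Stack insertions of one family into a consensus-coordinate matrix."""
    if not insertions:
        raise ValueError("empty insertion list")
    families = {i.family for i in insertions}
    if len(families) != 1:
        raise ValueError(f"insertions span multiple families: {sorted(families)}")
    family = families.pop()
    L = library[family].length
    mat = np.full((len(insertions), L), np.nan)
    for i, ins in enumerate(insertions):
        mat[i, ins.consensus_start : ins.consensus_end] = project_insertion(ins, track)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        order = np.argsort(-np.nanmean(mat, axis=1), kind="stable")
    return ConsensusMatrix(family, mat[order], [insertions[i] for i in order])


def consensus_profile(matrix: ConsensusMatrix) -> np.ndarray:
    """Column means over defined cells; NaN where no insertion aligns."""
    if matrix.matrix.shape[0] < 1:
        raise ValueError("matrix has no rows")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(matrix.matrix, axis=0)


# -- LTR structure ----------------------------------------------------------

def classify_ltr_structure(
    entries: Sequence[TEInsertion],
    library: TELibrary,
    flank_gap: int = LTR_FLANK_GAP,
    far: int = LTR_FAR,
) -> list[TEInsertion]:
    """Assign structural classes to the internal sequences of one LTR family.

    For each internal entry, each flank is checked for a same-strand LTR
    entry: present within ``flank_gap`` bp (inclusive) -> intact flank;
    absent or more than ``far`` bp away -> lost flank. Both flanks intact is
    full length; a lost 5' (strand-aware) flank with an intact 3' flank is 5'
    truncated, and vice versa; anything else (including strand mismatches and
    intermediate gaps) is 'other'. One LTR may flank two internal sequences,
    so head-to-tail tandems classify correctly.
    """
    internals = [
        e for e in entries if library[e.family].element_kind == "ltr_internal"
    ]
    ltrs = [e for e in entries if library[e.family].element_kind == "ltr_terminal"]
    ltrs_by_chrom: dict[str, list[TEInsertion]] = {}
    for l in ltrs:
        ltrs_by_chrom.setdefault(l.chrom, []).append(l)

    def flank_status(internal: TEInsertion, side: str) -> str:
        """side is 'left' or 'right' in genomic orientation."""
        candidates = [
            l
            for l in ltrs_by_chrom.get(internal.chrom, [])
            if l.strand == internal.strand
        ]
        gaps = []
        for l in candidates:
            gap = internal.start - l.end if side == "left" else l.start - internal.end
            if gap >= 0:
                gaps.append(gap)
        if not gaps or min(gaps) > far:
            return "lost"
        if min(gaps) <= flank_gap:
            return "intact"
        return "intermediate"

    for internal in internals:
        left = flank_status(internal, "left")
        right = flank_status(internal, "right")
        five, three = (left, right) if internal.strand == "+" else (right, left)
        if five == "intact" and three == "intact":
            internal.structural_class = "full_length"
        elif five == "lost" and three == "intact":
            internal.structural_class = "five_prime_truncated"
        elif three == "lost" and five == "intact":
            internal.structural_class = "three_prime_truncated"
        else:
            internal.structural_class = "other"
    return internals


# -- truncation contrast ----------------------------------------------------

@dataclass
class TruncationContrast:
    stage: str
    full_means: np.ndarray  # per-insertion mean log2 over the terminal window
    truncated_means: np.ndarray
    fold: float  # ratio of group mean linear enrichments, full / truncated
    p_value: float


def _terminal_window_mean(
    insertion: TEInsertion, track: EnrichmentTrack, end_of_element: str, width: int
) -> float:
    """Mean log2 enrichment over the first/last ``width`` bp of the internal
    sequence in element orientation, truncated to the element if shorter."""
    w = min(width, insertion.genomic_length)
    # element 5' end sits at genomic start for + strand, genomic end for -
    at_genomic_start = (end_of_element == "first") == (insertion.strand == "+")
    if at_genomic_start:
        lo, hi = insertion.start, insertion.start + w
    else:
        lo, hi = insertion.end - w, insertion.end
    return float(track.data[insertion.chrom][lo:hi].mean())


def truncation_contrast(
    full: Sequence[TEInsertion],
    truncated: Sequence[TEInsertion],
    stage_tracks: dict[str, EnrichmentTrack],
    side: str = "five_prime",
    terminal: int = TERMINAL_WINDOW,
) -> dict[str, TruncationContrast]:
    """Contrast terminal-1 kb enrichment between full-length and truncated copies.

    For the 5'-truncation contrast the *last* 1 kb of the internal sequence is
    averaged (the region both groups retain; LTRs excluded since the entries
    are internal sequences); for the 3' contrast, the *first* 1 kb.
    """
    if side not in ("five_prime", "three_prime"):
        raise ValueError(f"unknown side {side!r}")
    if not full or not truncated:
        raise ValueError("both insertion groups must be non-empty")
    which = "last" if side == "five_prime" else "first"
    out = {}
    for stage, track in stage_tracks.items():
        fm = np.array(
            [_terminal_window_mean(i, track, which, terminal) for i in full]
        )
        tm = np.array(
            [_terminal_window_mean(i, track, which, terminal) for i in truncated]
        )
        fold = float(np.mean(2.0**fm) / np.mean(2.0**tm))
        _, p = rank_sum(fm, tm)
        out[stage] = TruncationContrast(stage, fm, tm, fold, p)
    return out


# -- copy counts and peak overlap -------------------------------------------

def family_copy_counts(
    insertions: Sequence[TEInsertion],
    genome: GenomeModel,
    neo_y_classes: tuple[str, ...] = ("neoY", "Y"),
) -> dict[str, tuple[int, int]]:
    """Per family: (total insertion count, neo-Y insertion count)."""
    counts: dict[str, list[int]] = {}
    for ins in insertions:
        total_neo = counts.setdefault(ins.family, [0, 0])
        total_neo[0] += 1
        if genome.chrom_class(ins.chrom) in neo_y_classes:
            total_neo[1] += 1
    return {fam: (t, n) for fam, (t, n) in counts.items()}


def compare_group_counts(
    counts: dict[str, tuple[int, int]],
    group_a: set[str],
    group_b: set[str],
    neo_y_only: bool = False,
) -> tuple[float, float, float]:
    """Rank-sum comparison of per-family copy counts between two family sets.

    Returns (mean_a / mean_b fold, statistic, p).
    """
    idx = 1 if neo_y_only else 0
    a = np.array([counts[f][idx] for f in group_a if f in counts], dtype=float)
    b = np.array([counts[f][idx] for f in group_b if f in counts], dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty family group")
    stat, p = rank_sum(a, b)
    fold = float(a.mean() / b.mean()) if b.mean() > 0 else float("inf")
    return fold, stat, p


def summit_to_consensus(peak: Peak, insertion: TEInsertion) -> float:
    """Map a peak summit inside an insertion to a consensus position."""
    frac = (peak.summit - insertion.start) / insertion.genomic_length
    if insertion.strand == "-":
        frac = 1.0 - frac
    return insertion.consensus_start + frac * insertion.consensus_length


def te_peak_overlap(
    peaks: Sequence[Peak],
    insertions: Sequence[TEInsertion],
) -> dict[str, list[tuple[Peak, float]]]:
    """Per family: peaks whose summit falls inside one of its insertions,
    with the summit mapped to consensus coordinates."""
    by_chrom: dict[str, list[TEInsertion]] = {}
    for ins in insertions:
        by_chrom.setdefault(ins.chrom, []).append(ins)
    out: dict[str, list[tuple[Peak, float]]] = {}
    for p in peaks:
        for ins in by_chrom.get(p.chrom, []):
            if ins.start <= p.summit < ins.end:
                out.setdefault(ins.family, []).append(
                    (p, summit_to_consensus(p, ins))
                )
                break
    return out
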