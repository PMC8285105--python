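"""Genome model: chromosomes, pericentric regions, and interval annotations.

All coordinates are 0-based, half-open. GFF input (1-based, closed) is
converted at the parsing boundary; BED/bedGraph are native.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

CHROM_CLASSES = ("autosome", "X", "Y", "neoY")
#: chromosome classes averaged from male embryos only
MALE_LIMITED_CLASSES = ("Y", "neoY")


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    chrom_class: str = "autosome"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name}: length must be positive")
        if self.chrom_class not in CHROM_CLASSES:
            raise ValueError(
                f"chromosome {self.name}: unknown class {self.chrom_class!r}"
            )


@dataclass(frozen=True)
class Interval:
    """A genomic interval with an optional category and name.

    Categories used by peak annotation are ``TE``, ``microsatellite`` and
    ``gene``; anything else falls through to ``other``.
    """

    chrom: str
    start: int
    end: int
    category: str = ""
    name: str = ""
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end}: require 0 <= start < end"
            )

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class GenomeModel:
    """Chromosome table plus pericentric regions and interval annotations."""

    chromosomes: list[Chromosome]
    pericentric: list[Interval] = field(default_factory=list)
    annotations: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        self._by_name = {c.name: c for c in self.chromosomes}
        for iv in list(self.pericentric) + list(self.annotations):
            self._check_interval(iv)

    def _check_interval(self, iv: Interval) -> None:
        chrom = self._by_name.get(iv.chrom)
        if chrom is None:
            raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
        if iv.end > chrom.length:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {chrom.length}"
            )

    # -- lookups -----------------------------------------------------------
    def chrom_names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def chrom_length(self, name: str) -> int:
        return self._by_name[name].length

    def chrom_class(self, name: str) -> str:
        return self._by_name[name].chrom_class

    def has_chrom(self, name: str) -> bool:
        return name in self._by_name

    def autosomes(self) -> list[Chromosome]:
        return [c for c in self.chromosomes if c.chrom_class == "autosome"]

    def chroms_of_class(self, chrom_class: str) -> list[Chromosome]:
        return [c for c in self.chromosomes if c.chrom_class == chrom_class]

    def add_annotations(self, intervals: Iterable[Interval]) -> None:
        for iv in intervals:
            self._check_interval(iv)
            self.annotations.append(iv)

    def in_pericentric(self, chrom: str, position: int) -> bool:
        return any(
            p.chrom == chrom and p.start <= position < p.end for p in self.pericentric
        )


# -- plain-text I/O --------------------------------------------------------

def read_chrom_table(path: str | Path) -> list[Chromosome]:
    """Read a 3-column TSV: name, length, class."""
    chroms = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, length, cls = line.split("\t")[:3]
        chroms.append(Chromosome(name, int(length), cls))
    return chroms


def write_chrom_table(chroms: Iterable[Chromosome], path: str | Path) -> None:
    lines = [f"{c.name}\t{c.length}\t{c.chrom_class}" for c in chroms]
    Path(path).write_text("\n".join(lines) + "\n")


def read_bed_intervals(path: str | Path, category: str = "") -> list[Interval]:
    """Read BED3+ intervals (0-based half-open, native)."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        name = fields[3] if len(fields) > 3 else ""
        out.append(Interval(fields[0], int(fields[1]), int(fields[2]), category, name))
    return out


def write_bed_intervals(intervals: Iterable[Interval], path: str | Path) -> None:
    lines = [
        f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or iv.category or '.'}"
        for iv in intervals
    ]
    Path(path).write_text("\n".join(lines) + "\n")
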