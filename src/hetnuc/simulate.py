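"""Synthetic genome, coverage, reads and annotations with known ground truth.

The generator emulates the qualitative biology the pipeline is built to
detect: narrow (single-nucleosome scale) H3K9me3 nucleation sites planted at
specific positions of TE insertions that switch on at embryonic stage 3 or
early stage 4 and spread outward with each stage; temporary sites that decay;
phantom sites that show up in every antibody preparation; an LTR family with
full-length, 5'-truncated and 3'-truncated copies (truncated copies lack the
5'-LTR nucleation source); spike-in samples with a known monotone distortion
of enrichment; piRNA reads concentrated on early-nucleating families; and a
maternal + zygotic TE expression model.

Coverage is Poisson: input ~ Poisson(depth), ChIP ~ Poisson(depth * 2**E(x))
where E(x) is the planted log2 enrichment surface (flat-top plateau of the
site's stage-specific half-width with Gaussian shoulders, sigma = 50 bp).
Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome import Chromosome, GenomeModel, Interval
from .normalization import EnrichmentTrack
from .peaks import Peak
from .te import TEConsensus, TEInsertion, TELibrary
from .assoc import SmallRNARead
from .tracks import STAGES, CoverageTrack

#: spreading half-widths (bp) by stages elapsed since onset, persistent sites
SPREAD_HALFWIDTHS = (70, 150, 450, 1500, 5000)
#: amplitude decay of temporary sites by stage index (onset is always s3)
TEMPORARY_DECAY = (1.0, 0.55, 0.25, 0.08, 0.0)
SHOULDER_SIGMA = 50.0  # bp, Gaussian edge of the enrichment plateau

TRAM_LTR_LEN = 372
TRAM_INTERNAL_LEN = 4628


@dataclass
class SimConfig:
    """Default desk-scale study conditions (~2 Mb genome, 30x, 3 reps/stage)."""

    chromosomes: tuple = (
        ("chr2L", 600_000, "autosome"),
        ("chr2R", 600_000, "autosome"),
        ("chrX", 400_000, "X"),
        ("chrY", 400_000, "neoY"),
    )
    pericentric_bp: int = 120_000  # leading bp of each non-Y chromosome
    spikein_chrom: tuple = ("spk_2L", 240_000)
    depth: float = 30.0
    n_replicates: int = 3
    replicate_sexes: tuple = ("male", "male", "female")
    # planted TRAM structural counts
    n_tram_full: int = 40  # includes the head-to-tail tandem pair
    n_tram_five_prime: int = 5
    n_tram_three_prime: int = 5
    site_amplitude: float = 2.5  # log2 units
    n_phantom: int = 10
    n_temporary: int = 12
    n_pericentric_e4: int = 30
    # piRNA model: reads/kb weight per consensus entry; early families high
    pirna_rates: dict = field(
        default_factory=lambda: {
            "R1": 8.0,
            "TRAM_I": 5.0,
            "TRAM_LTR": 5.0,
            "CR1": 0.8,
            "Gypsy18": 0.8,
        }
    )
    pirna_background: float = 0.2  # fraction of genomic reads placed uniformly
    pirna_sense_fraction: float = 0.7
    pirna_total_reads: int = 200_000
    # expression model (stage labels follow the RNA time course: s2, s4, s5)
    early_families: tuple = ("R1", "TRAM")
    late_families: tuple = ("CR1", "Gypsy18")
    per_copy_rna: dict = field(default_factory=lambda: {"early": 8.0, "late": 25.0})
    fold_s2_s4: dict = field(default_factory=lambda: {"early": 1.4, "late": 1.0})
    fold_s4_s5: dict = field(default_factory=lambda: {"early": 1.2, "late": 1.6})
    dna_per_copy: float = 50.0
    # median autosomal gene RNA count / median autosomal DNA coverage of the
    # toy libraries; chosen so scaled expression is O(1) per copy
    rna_normalizer: float = 10.0
    dna_normalizer: float = 50.0


@dataclass
class NucleationSite:
    chrom: str
    pos: int
    onset: str  # s3 | e4
    kind: str  # persistent | temporary | phantom
    amplitude: float
    family: str = ""


@dataclass
class SyntheticTruth:
    config: SimConfig
    seed: int
    genome: GenomeModel
    spike_genome: GenomeModel
    library: TELibrary
    insertions: list[TEInsertion]
    microsatellites: list[Interval]
    sites: list[NucleationSite]
    spike_surface: dict[str, np.ndarray]
    spikein_gains: dict[str, float]

    def sites_of(self, kind: str | None = None, onset: str | None = None):
        return [
            s
            for s in self.sites
            if (kind is None or s.kind == kind)
            and (onset is None or s.onset == onset)
        ]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "chromosomes": [
                [c.name, c.length, c.chrom_class] for c in self.genome.chromosomes
            ],
            "sites": [
                [s.chrom, s.pos, s.onset, s.kind, s.amplitude, s.family]
                for s in self.sites
            ],
            "n_insertions": len(self.insertions),
            "structural_counts": {
                cls: sum(1 for i in self.insertions if i.structural_class == cls)
                for cls in ("full_length", "five_prime_truncated", "three_prime_truncated")
            },
            "spikein_gains": self.spikein_gains,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def default_library() -> TELibrary:
    return TELibrary(
        {
            "TRAM_LTR": TEConsensus(
                "TRAM_LTR", TRAM_LTR_LEN, "ltr_terminal", "TRAM_I"
            ),
            "TRAM_I": TEConsensus(
                "TRAM_I", TRAM_INTERNAL_LEN, "ltr_internal", "TRAM_LTR"
            ),
            "R1": TEConsensus("R1", 5000, "non_ltr"),
            "CR1": TEConsensus("CR1", 4500, "non_ltr"),
            "Gypsy18": TEConsensus("Gypsy18", 3000, "non_ltr"),
        }
    )


# -- genome construction ----------------------------------------------------

class _Placer:
    """Sequential feature placement along one chromosome with jittered gaps."""

    def __init__(self, chrom: str, length: int, rng: np.random.Generator):
        self.chrom = chrom
        self.length = length
        self.rng = rng
        self.cursor = 10_000

    def take(self, width: int, gap_lo: int = 300, gap_hi: int = 900) -> int:
        start = self.cursor
        if start + width > self.length - 5_000:
            raise ValueError(
                f"{self.chrom}: genome too small to place feature of {width} bp"
            )
        self.cursor = start + width + int(self.rng.integers(gap_lo, gap_hi))
        return start


def _tram_unit(
    placer: _Placer,
    strand: str,
    counter: list[int],
    kind: str,
    gaps: tuple[int, int] | None = None,
    far_gap: int | None = None,
    tandem: bool = False,
) -> tuple[list[TEInsertion], list[int]]:
    """Lay out one TRAM insertion unit; returns (entries, 5'-LTR site positions).

    ``kind`` in {full, five, three}. Layout is left-to-right in genomic
    coordinates; for '-' strand entries the 5' end is on the right, which the
    structural classifier resolves strand-aware.
    """
    rng = placer.rng
    g1, g2 = gaps if gaps else (int(rng.integers(0, 6)), int(rng.integers(0, 6)))
    entries: list[TEInsertion] = []
    site_pos: list[int] = []

    def ltr(start: int) -> TEInsertion:
        counter[0] += 1
        return TEInsertion(
            placer.chrom, start, start + TRAM_LTR_LEN, strand, "TRAM_LTR",
            0, TRAM_LTR_LEN, name=f"TRAM_LTR_{counter[0]}",
        )

    def internal(start: int) -> TEInsertion:
        counter[0] += 1
        return TEInsertion(
            placer.chrom, start, start + TRAM_INTERNAL_LEN, strand, "TRAM_I",
            0, TRAM_INTERNAL_LEN, name=f"TRAM_I_{counter[0]}",
        )

    # maintain TRAM-to-TRAM isolation > LTR_FAR so lost flanks stay lost
    gap_lo, gap_hi = 5_300, 6_100
    if kind == "full" and tandem:
        # LTR I LTR I LTR: the middle LTR flanks both internal sequences
        width = 3 * TRAM_LTR_LEN + 2 * TRAM_INTERNAL_LEN + 4 * g1
        s = placer.take(width, gap_lo, gap_hi)
        l1 = ltr(s)
        i1 = internal(l1.end + g1)
        l2 = ltr(i1.end + g1)
        i2 = internal(l2.end + g1)
        l3 = ltr(i2.end + g1)
        entries += [l1, i1, l2, i2, l3]
        if strand == "+":
            site_pos += [(l1.start + l1.end) // 2, (l2.start + l2.end) // 2]
        else:
            site_pos += [(l3.start + l3.end) // 2, (l2.start + l2.end) // 2]
    elif kind == "full":
        width = 2 * TRAM_LTR_LEN + TRAM_INTERNAL_LEN + g1 + g2
        s = placer.take(width, gap_lo, gap_hi)
        l1 = ltr(s)
        i1 = internal(l1.end + g1)
        l2 = ltr(i1.end + g2)
        entries += [l1, i1, l2]
        five_ltr = l1 if strand == "+" else l2
        site_pos.append((five_ltr.start + five_ltr.end) // 2)
    elif kind == "five":
        # 5' LTR lost (absent, or 'far_gap' away); 3' LTR intact
        lead = (TRAM_LTR_LEN + far_gap) if far_gap else 0
        width = lead + TRAM_INTERNAL_LEN + g2 + TRAM_LTR_LEN
        s = placer.take(width, gap_lo, gap_hi)
        if strand == "+":
            if far_gap:
                entries.append(ltr(s))
            i1 = internal(s + lead)
            entries += [i1, ltr(i1.end + g2)]
        else:
            i1 = internal(s + TRAM_LTR_LEN + g2)
            entries += [ltr(s), i1]  # intact 3' LTR on the left for '-' strand
            if far_gap:
                entries.append(ltr(i1.end + far_gap))
    elif kind == "three":
        width = TRAM_LTR_LEN + g1 + TRAM_INTERNAL_LEN
        s = placer.take(width, gap_lo, gap_hi)
        if strand == "+":
            l1 = ltr(s)
            entries += [l1, internal(l1.end + g1)]
            site_pos.append((l1.start + l1.end) // 2)
        else:
            i1 = internal(s)
            l1 = ltr(i1.end + g1)
            entries += [i1, l1]
            site_pos.append((l1.start + l1.end) // 2)
    else:  # pragma: no cover - guarded by callers
        raise ValueError(kind)
    return entries, site_pos


def _nonltr_insertion(
    placer: _Placer,
    family: str,
    library: TELibrary,
    counter: list[int],
    consensus_span: tuple[int, int] | None = None,
    strand: str = "+",
) -> TEInsertion:
    L = library[family].length
    cs, ce = consensus_span or (0, L)
    s = placer.take(ce - cs)
    counter[0] += 1
    return TEInsertion(
        placer.chrom, s, s + (ce - cs), strand, family, cs, ce,
        name=f"{family}_{counter[0]}",
    )


R1_NUCLEATION_CONSENSUS = 3750  # site position on the R1 consensus


def generate_genome(
    config: SimConfig | None = None, seed: int = 0
) -> SyntheticTruth:
    """Build the toy genome, TE annotations and planted nucleation sites."""
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    library = default_library()

    chroms = [Chromosome(n, l, c) for n, l, c in config.chromosomes]
    peri = []
    for c in chroms:
        if c.chrom_class in ("autosome", "X"):
            peri.append(Interval(c.name, 0, min(config.pericentric_bp, c.length)))
        else:
            peri.append(Interval(c.name, 0, c.length))  # Y arm fully heterochromatic

    placers = {c.name: _Placer(c.name, c.length, rng) for c in chroms}
    insertions: list[TEInsertion] = []
    microsats: list[Interval] = []
    genes: list[Interval] = []
    sites: list[NucleationSite] = []
    counter = [0]
    amp = config.site_amplitude

    def add_site(chrom, pos, onset, kind, family=""):
        for s in sites:  # keep planted sites separable for truth matching
            if s.chrom == chrom and abs(s.pos - pos) < 2_500:
                return
        sites.append(NucleationSite(chrom, int(pos), onset, kind, amp, family))

    # --- TRAM units: planted structural classes ---------------------------
    n_plain_full = config.n_tram_full - 2  # tandem contributes two copies
    full_plan = [("chr2L", 13), ("chr2R", 15), ("chrY", n_plain_full - 28)]
    five_plan = [("chr2R", 3), ("chrY", config.n_tram_five_prime - 3)]
    three_plan = [("chr2L", 3), ("chrY", config.n_tram_three_prime - 3)]

    def do_unit(chrom, kind, **kw):
        strand = "+" if rng.random() < 0.5 else "-"
        entries, ltr_sites = _tram_unit(placers[chrom], strand, counter, kind, **kw)
        insertions.extend(entries)
        for p in ltr_sites:
            add_site(chrom, p, "s3", "persistent", "TRAM")

    do_unit("chr2L", "full", tandem=True, gaps=(3, 3))
    first_full = True
    for chrom, n in full_plan:
        for _ in range(n):
            kw = {"gaps": (10, 10)} if first_full else {}
            first_full = False
            do_unit(chrom, "full", **kw)
    first_five = True
    for chrom, n in five_plan:
        for _ in range(n):
            kw = {"far_gap": 5_001} if first_five else {}
            first_five = False
            do_unit(chrom, "five", **kw)
    for chrom, n in three_plan:
        for _ in range(n):
            do_unit(chrom, "three")

    # --- non-LTR families --------------------------------------------------
    r1_full_plan = [("chr2L", 5), ("chr2R", 5), ("chrX", 3), ("chrY", 12)]
    r1_frag_plan = [("chr2L", 3), ("chr2R", 3), ("chrX", 2), ("chrY", 4)]
    cr1_plan = [("chr2L", 7), ("chr2R", 7), ("chrX", 5), ("chrY", 4)]
    gy_plan = [("chr2L", 5), ("chr2R", 5), ("chrX", 4), ("chrY", 3)]

    for chrom, n in r1_full_plan:
        for _ in range(n):
            strand = "+" if rng.random() < 0.5 else "-"
            ins = _nonltr_insertion(placers[chrom], "R1", library, counter, strand=strand)
            insertions.append(ins)
            # early nucleation is restricted to one consensus region of R1
            if strand == "+":
                pos = ins.start + R1_NUCLEATION_CONSENSUS
            else:
                pos = ins.end - R1_NUCLEATION_CONSENSUS
            add_site(chrom, pos, "s3", "persistent", "R1")
    for chrom, n in r1_frag_plan:
        for _ in range(n):  # fragments miss the nucleation region: no site
            insertions.append(
                _nonltr_insertion(placers[chrom], "R1", library, counter, (1000, 3000))
            )
    for chrom, n in cr1_plan:
        for _ in range(n):  # late nucleators: e4 onset near consensus mid
            ins = _nonltr_insertion(placers[chrom], "CR1", library, counter)
            insertions.append(ins)
            add_site(chrom, (ins.start + ins.end) // 2, "e4", "persistent", "CR1")
    for chrom, n in gy_plan:
        for _ in range(n):
            ins = _nonltr_insertion(placers[chrom], "Gypsy18", library, counter)
            insertions.append(ins)
            add_site(chrom, (ins.start + ins.end) // 2, "e4", "persistent", "Gypsy18")

    # --- microsatellites, genes, free-standing sites ------------------------
    motifs = ("(AGAT)n", "(AATAT)n", "(CA)n", "(GATA)n")
    ms_plan = [("chr2L", 15), ("chr2R", 15), ("chrX", 8), ("chrY", 5)]
    ms_all: list[Interval] = []
    for chrom, n in ms_plan:
        for i in range(n):
            w = int(rng.integers(100, 220))
            # wide spacing keeps decaying sites clear of neighboring
            # stage-7 spreading domains
            s = placers[chrom].take(w, 2_000, 2_700)
            ms_all.append(
                Interval(chrom, s, s + w, "microsatellite", motifs[i % len(motifs)])
            )
    microsats.extend(ms_all)
    gene_plan = [("chr2L", 10), ("chr2R", 10), ("chrX", 8)]
    for chrom, n in gene_plan:
        for i in range(n):
            s = placers[chrom].take(2_000)
            genes.append(Interval(chrom, s, s + 2_000, "gene", f"gene_{chrom}_{i}"))

    # temporary sites sit at microsatellites (decaying nucleation)
    for ms in ms_all[::2][: config.n_temporary]:
        add_site(ms.chrom, ms.midpoint, "s3", "temporary")
    # phantom sites: artifact signal shared by every antibody preparation
    for _ in range(config.n_phantom):
        chrom = ("chr2L", "chr2R", "chrX")[int(rng.integers(0, 3))]
        pos = placers[chrom].take(1, 2_600, 3_400)
        add_site(chrom, pos, "s3", "phantom")
    # extra early-stage-4 nucleation inside pericentric regions
    for k in range(config.n_pericentric_e4):
        chrom = ("chr2L", "chr2R", "chrX")[k % 3]
        pos = int(rng.integers(3_000, config.pericentric_bp - 3_000))
        add_site(chrom, pos, "e4", "persistent")

    genome = GenomeModel(chroms, pericentric=peri)
    genome.add_annotations(
        [Interval(i.chrom, i.start, i.end, "TE", i.name, i.strand) for i in insertions]
    )
    genome.add_annotations(microsats)
    genome.add_annotations(genes)

    # spike-in genome: block-constant enrichment surface shared by all samples
    spk_name, spk_len = config.spikein_chrom
    spike_genome = GenomeModel([Chromosome(spk_name, spk_len, "autosome")])
    srng = np.random.default_rng(seed + 104729)
    blocks = np.clip(srng.normal(0.8, 1.2, size=-(-spk_len // 1000)), -1.5, 4.5)
    spike_surface = {spk_name: np.repeat(blocks, 1000)[:spk_len]}

    gains = {}
    for stage in STAGES:
        for r in range(config.n_replicates):
            gains[f"{stage}_r{r}"] = float(np.round(srng.uniform(0.75, 1.25), 3))

    return SyntheticTruth(
        config=config,
        seed=seed,
        genome=genome,
        spike_genome=spike_genome,
        library=library,
        insertions=insertions,
        microsatellites=microsats,
        sites=sites,
        spike_surface=spike_surface,
        spikein_gains=gains,
    )


# -- enrichment surfaces and Poisson sampling --------------------------------

def _add_kernel(E: np.ndarray, pos: int, amp: float, half: int) -> None:
    lo = max(0, pos - half - int(4 * SHOULDER_SIGMA))
    hi = min(len(E), pos + half + int(4 * SHOULDER_SIGMA))
    if hi <= lo:
        return
    d = np.abs(np.arange(lo, hi) - pos).astype(float)
    k = np.where(
        d <= half, 1.0, np.exp(-0.5 * ((d - half) / SHOULDER_SIGMA) ** 2)
    )
    np.maximum(E[lo:hi], amp * k, out=E[lo:hi])


def enrichment_surface(
    truth: SyntheticTruth, stage: str, mark: str = "H3K9me3"
) -> dict[str, np.ndarray]:
    """Planted log2 enrichment surface for one stage and antibody."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    si = STAGES.index(stage)
    E = {c.name: np.zeros(c.length) for c in truth.genome.chromosomes}
    for site in truth.sites:
        if site.kind == "phantom":
            _add_kernel(E[site.chrom], site.pos, site.amplitude, SPREAD_HALFWIDTHS[0])
            continue
        if mark != "H3K9me3":
            continue
        onset_i = STAGES.index(site.onset)
        if si < onset_i:
            continue
        if site.kind == "temporary":
            a = site.amplitude * TEMPORARY_DECAY[si]
            if a > 0:
                _add_kernel(E[site.chrom], site.pos, a, SPREAD_HALFWIDTHS[0])
        else:
            _add_kernel(
                E[site.chrom], site.pos, site.amplitude, SPREAD_HALFWIDTHS[si - onset_i]
            )
    return E


def _sex_scale(chrom_class: str, sex: str) -> float:
    if sex == "male":
        return 0.5 if chrom_class in ("X", "Y", "neoY") else 1.0
    # females carry no Y; residual cross-mapping leaves trace coverage
    return 0.02 if chrom_class in ("Y", "neoY") else 1.0


def simulate_stage_tracks(
    truth: SyntheticTruth,
    stage: str,
    replicate: int = 0,
    sex: str = "male",
    seed: int = 0,
    mark: str = "H3K9me3",
    gain: float | None = None,
) -> tuple[CoverageTrack, CoverageTrack]:
    """(chip, input) Poisson coverage for one replicate of one stage.

    ``gain`` multiplies the log2 enrichment surface and models the sample's
    pull-down efficiency; by default it is looked up from the per-sample
    spike-in gains so the spike-in correction has a real distortion to undo.
    """
    sample_id = f"{stage}_r{replicate}"
    if gain is None:
        gain = truth.spikein_gains.get(sample_id, 1.0)
    E = enrichment_surface(truth, stage, mark)
    rng = np.random.default_rng(seed)
    depth = truth.config.depth
    chip_data, input_data = {}, {}
    for c in truth.genome.chromosomes:
        scale = _sex_scale(c.chrom_class, sex)
        lam_in = np.full(c.length, depth * scale)
        lam_chip = depth * scale * 2.0 ** (gain * E[c.name])
        input_data[c.name] = rng.poisson(lam_in).astype(float)
        chip_data[c.name] = rng.poisson(lam_chip).astype(float)
    meta = dict(stage=stage, mark=mark, replicate=str(replicate), sex=sex)
    chip = CoverageTrack(chip_data, sample_id=f"{sample_id}_chip", assay="chip", **meta)
    inp = CoverageTrack(input_data, sample_id=f"{sample_id}_input", assay="input", **meta)
    return chip, inp


def simulate_spikein_pair(
    truth: SyntheticTruth, sample_id: str, seed: int = 0
) -> tuple[CoverageTrack, CoverageTrack]:
    """Spike-in (chip, input) for one sample: shared surface, sample's gain."""
    gain = truth.spikein_gains.get(sample_id, 1.0)
    rng = np.random.default_rng(seed)
    depth = truth.config.depth
    chip_data, input_data = {}, {}
    for c in truth.spike_genome.chromosomes:
        E = truth.spike_surface[c.name]
        input_data[c.name] = rng.poisson(np.full(c.length, depth)).astype(float)
        chip_data[c.name] = rng.poisson(depth * 2.0 ** (gain * E)).astype(float)
    chip = CoverageTrack(
        chip_data, sample_id=f"{sample_id}_spk_chip", assay="chip", mark="spikein"
    )
    inp = CoverageTrack(
        input_data, sample_id=f"{sample_id}_spk_input", assay="input", mark="spikein"
    )
    return chip, inp


def simulate_atac_pair(
    truth: SyntheticTruth, stage: str, sex: str = "male", seed: int = 0
) -> tuple[CoverageTrack, CoverageTrack]:
    """(ATAC fragment, DNA) coverage; accessibility drops where H3K9me3 rises."""
    E = enrichment_surface(truth, stage)
    rng = np.random.default_rng(seed)
    depth = truth.config.depth
    atac_data, dna_data = {}, {}
    for c in truth.genome.chromosomes:
        scale = _sex_scale(c.chrom_class, sex)
        atac_data[c.name] = rng.poisson(
            depth * scale * 2.0 ** (-0.5 * E[c.name])
        ).astype(float)
        dna_data[c.name] = rng.poisson(np.full(c.length, depth * scale)).astype(float)
    atac = CoverageTrack(
        atac_data, sample_id=f"{stage}_atac", stage=stage, assay="atac", sex=sex
    )
    dna = CoverageTrack(
        dna_data, sample_id=f"{stage}_dna", stage=stage, assay="dna", sex=sex
    )
    return atac, dna


# -- small RNA ---------------------------------------------------------------

def _sample_lengths(rng: np.random.Generator, n: int) -> np.ndarray:
    """90% of reads in the 23-29 nt piRNA range, the rest just outside."""
    lengths = rng.integers(23, 30, size=n)
    off = rng.random(n) >= 0.9
    lengths[off] = rng.choice([21, 22, 30, 31], size=int(off.sum()))
    return lengths


def simulate_family_reads(
    rates: dict[str, float],
    library: TELibrary,
    total_reads: int,
    seed: int = 0,
    sense_fraction: float = 0.7,
) -> list[SmallRNARead]:
    """Consensus-space piRNA reads, multinomial across families by rate*length."""
    rng = np.random.default_rng(seed)
    fams = sorted(rates)
    weights = np.array([rates[f] * library[f].length for f in fams], dtype=float)
    if weights.sum() == 0:
        return []
    n_per = rng.multinomial(total_reads, weights / weights.sum())
    reads: list[SmallRNARead] = []
    for fam, n in zip(fams, n_per):
        if n == 0:
            continue
        L = library[fam].length
        lengths = _sample_lengths(rng, n)
        starts = rng.integers(0, np.maximum(1, L - lengths))
        sense = rng.random(n) < sense_fraction
        for s, l, sn in zip(starts, lengths, sense):
            reads.append(SmallRNARead(fam, int(s), int(l), "+" if sn else "-"))
    return reads


def simulate_pirna(
    truth: SyntheticTruth, total_reads: int | None = None, seed: int = 0
) -> tuple[list[SmallRNARead], list[SmallRNARead]]:
    """(genomic reads, consensus-mapped reads) from the planted family rates.

    Genomic reads fall inside annotated insertions of their family (plus a
    uniform background fraction); consensus reads target library entries.
    """
    config = truth.config
    total = total_reads or config.pirna_total_reads
    if total <= 0:
        raise ValueError("total_reads must be positive")
    rng = np.random.default_rng(seed)
    consensus = simulate_family_reads(
        config.pirna_rates, truth.library, total, seed + 1, config.pirna_sense_fraction
    )
    by_family: dict[str, list[TEInsertion]] = {}
    for ins in truth.insertions:
        by_family.setdefault(ins.family, []).append(ins)

    fams = sorted(f for f in config.pirna_rates if f in by_family)
    weights = np.array(
        [config.pirna_rates[f] * truth.library[f].length for f in fams]
    )
    n_bg = int(total * config.pirna_background)
    n_fam = rng.multinomial(total - n_bg, weights / weights.sum())
    genomic: list[SmallRNARead] = []
    for fam, n in zip(fams, n_fam):
        copies = by_family[fam]
        pick = rng.integers(0, len(copies), size=n)
        lengths = _sample_lengths(rng, n)
        sense = rng.random(n) < config.pirna_sense_fraction
        for ci, l, sn in zip(pick, lengths, sense):
            ins = copies[ci]
            hi = max(ins.start + 1, ins.end - int(l))
            pos = int(rng.integers(ins.start, hi))
            strand = ins.strand if sn else ("-" if ins.strand == "+" else "+")
            genomic.append(SmallRNARead(ins.chrom, pos, int(l), strand))
    chrom_lens = np.array([c.length for c in truth.genome.chromosomes], dtype=float)
    pick = rng.choice(len(chrom_lens), size=n_bg, p=chrom_lens / chrom_lens.sum())
    lengths = _sample_lengths(rng, n_bg)
    for ci, l in zip(pick, lengths):
        c = truth.genome.chromosomes[ci]
        genomic.append(
            SmallRNARead(
                c.name,
                int(rng.integers(0, c.length - int(l))),
                int(l),
                "+" if rng.random() < 0.5 else "-",
            )
        )
    return genomic, consensus


# -- expression ---------------------------------------------------------------

@dataclass
class ExpressionSim:
    rna: dict[str, dict[str, int]]  # stage -> family -> read count
    dna: dict[str, int]  # family -> read count
    copies: dict[str, int]
    rna_normalizer: float
    dna_normalizer: float

    def scaled(self, stage: str) -> dict[str, float]:
        from .assoc import scaled_te_expression

        return {
            fam: scaled_te_expression(
                self.rna[stage][fam],
                self.dna[fam],
                self.rna_normalizer,
                self.dna_normalizer,
            )
            for fam in self.dna
        }


def _base_family(entry_name: str) -> str:
    return entry_name.split("_")[0]


def simulate_expression(
    truth: SyntheticTruth, seed: int = 0, stages: Sequence[str] = ("s2", "s4", "s5")
) -> ExpressionSim:
    """Maternal baseline plus planted zygotic induction, scaled by copy number.

    Early-nucleating families induce between the s2 and s4 RNA samples; late
    families between s4 and s5. DNA counts track copy number with Poisson
    noise, so copy-scaled expression isolates the per-copy rate.
    """
    config = truth.config
    rng = np.random.default_rng(seed)
    copies: dict[str, int] = {}
    for ins in truth.insertions:
        fam = _base_family(ins.family)
        copies[fam] = copies.get(fam, 0) + 1
    rna: dict[str, dict[str, int]] = {s: {} for s in stages}
    dna: dict[str, int] = {}
    for fam, n_copies in sorted(copies.items()):
        group = "early" if fam in config.early_families else "late"
        per_copy = config.per_copy_rna[group]
        folds = {
            stages[0]: 1.0,
            stages[1]: config.fold_s2_s4[group],
            stages[2]: config.fold_s2_s4[group] * config.fold_s4_s5[group],
        }
        for stage in stages:
            lam = per_copy * n_copies * folds[stage]
            rna[stage][fam] = int(rng.poisson(lam))
        dna[fam] = int(rng.poisson(config.dna_per_copy * n_copies))
    return ExpressionSim(
        rna, dna, copies, config.rna_normalizer, config.dna_normalizer
    )


# -- naive peak caller (stand-in for MACS2 in the test loop) -----------------

def call_peaks(
    track: EnrichmentTrack,
    stage: str | None = None,
    threshold: float = 0.5,
    min_width: int = 60,
    merge_gap: int = 100,
    smooth: int = 25,
) -> list[Peak]:
    """Threshold-and-merge peak caller on a log2 enrichment track.

    A deliberately simple stand-in for MACS2 used on synthetic tracks: boxcar
    smoothing, runs above threshold, merging of runs separated by less than
    ``merge_gap`` bp, minimum width filter. Summit = maximum of the smoothed
    signal; score = mean raw enrichment over the peak.
    """
    peaks: list[Peak] = []
    for chrom, arr in track.data.items():
        if len(arr) < smooth:
            continue
        sm = np.convolve(arr, np.ones(smooth) / smooth, mode="same") if smooth > 1 else arr
        mask = sm > threshold
        if not mask.any():
            continue
        d = np.diff(mask.astype(np.int8))
        starts = np.flatnonzero(d == 1) + 1
        ends = np.flatnonzero(d == -1) + 1
        if mask[0]:
            starts = np.concatenate(([0], starts))
        if mask[-1]:
            ends = np.concatenate((ends, [len(mask)]))
        merged: list[list[int]] = []
        for s, e in zip(starts, ends):
            if merged and s - merged[-1][1] < merge_gap:
                merged[-1][1] = e
            else:
                merged.append([int(s), int(e)])
        for s, e in merged:
            if e - s < min_width:
                continue
            summit = s + int(np.argmax(sm[s:e]))
            peaks.append(
                Peak(
                    chrom, s, e, summit, stage=stage,
                    name=f"{stage or 'peak'}_{chrom}_{s}",
                    score=float(arr[s:e].mean()),
                )
            )
    return peaks
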