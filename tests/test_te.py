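"""TE consensus projection, LTR structure rules, truncation contrasts."""

import numpy as np
import pytest

from hetnuc.genome import GenomeModel, Chromosome
from hetnuc.normalization import EnrichmentTrack
from hetnuc.peaks import Peak
from hetnuc.te import (
    TEConsensus,
    TEInsertion,
    TELibrary,
    classify_ltr_structure,
    consensus_profile,
    family_copy_counts,
    parse_repeatmasker_gff,
    project_insertion,
    project_to_consensus,
    summit_to_consensus,
    te_peak_overlap,
    truncation_contrast,
    write_repeatmasker_gff,
)


@pytest.fixture
def library():
    return TELibrary(
        {
            "TRAM_LTR": TEConsensus("TRAM_LTR", 372, "ltr_terminal", "TRAM_I"),
            "TRAM_I": TEConsensus("TRAM_I", 4628, "ltr_internal", "TRAM_LTR"),
            "R1": TEConsensus("R1", 5000, "non_ltr"),
        }
    )


def track(length=60_000, value=0.0):
    return EnrichmentTrack({"c": np.full(length, value)})


def ltr(start, strand="+", chrom="c"):
    return TEInsertion(chrom, start, start + 372, strand, "TRAM_LTR", 0, 372)


def internal(start, strand="+", chrom="c", length=4628):
    return TEInsertion(chrom, start, start + length, strand, "TRAM_I", 0, 4628)


class TestGFF:
    def test_round_trip_preserves_coordinates(self, tmp_path, library):
        ins = [
            TEInsertion("c", 999, 1371, "+", "TRAM_LTR", 0, 372),
            TEInsertion("c", 5000, 9628, "-", "TRAM_I", 0, 4628),
            TEInsertion("c", 20_000, 22_000, "+", "R1", 1000, 3000),
        ]
        path = tmp_path / "rm.gff"
        write_repeatmasker_gff(ins, [], path)
        back, ms, skipped = parse_repeatmasker_gff(path, library)
        assert skipped == 0 and not ms
        assert [(i.start, i.end, i.strand, i.consensus_start, i.consensus_end)
                for i in back] == [(999, 1371, "+", 0, 372),
                                   (5000, 9628, "-", 0, 4628),
                                   (20_000, 22_000, "+", 1000, 3000)]

    def test_motif_entries_become_microsatellites(self, tmp_path, library):
        path = tmp_path / "rm.gff"
        path.write_text(
            'c\tRepeatMasker\tsimilarity\t101\t200\t.\t+\t.\tTarget "Motif:(AGAT)n" 1 100\n'
        )
        ins, ms, skipped = parse_repeatmasker_gff(path, library)
        assert not ins and skipped == 0
        assert ms[0].category == "microsatellite"
        assert (ms[0].start, ms[0].end) == (100, 200)

    def test_unknown_family_and_bad_span_skipped_with_warning(self, tmp_path, library):
        path = tmp_path / "rm.gff"
        path.write_text(
            'c\tRM\tsimilarity\t1\t100\t.\t+\t.\tTarget "Motif:Unseen" 1 100\n'
            'c\tRM\tsimilarity\t1\t100\t.\t+\t.\tTarget "Motif:TRAM_LTR" 1 999\n'
        )
        with pytest.warns(UserWarning):
            ins, ms, skipped = parse_repeatmasker_gff(path, library)
        assert skipped == 2 and not ins


class TestProjection:
    def test_identity_round_trip(self, library, rng):
        vals = rng.normal(size=60_000)
        t = EnrichmentTrack({"c": vals})
        ins = TEInsertion("c", 1000, 6000, "+", "R1", 0, 5000)
        mat = project_to_consensus([ins], t, library)
        assert np.array_equal(mat.matrix[0], vals[1000:6000])
        assert np.array_equal(consensus_profile(mat), vals[1000:6000])

    def test_reverse_strand_follows_consensus_orientation(self, library):
        vals = np.zeros(60_000)
        vals[1000:6000] = np.arange(5000)  # ascending left to right
        t = EnrichmentTrack({"c": vals})
        ins = TEInsertion("c", 1000, 6000, "-", "R1", 0, 5000)
        row = project_insertion(ins, t)
        assert row[0] == 4999 and row[-1] == 0

    def test_strand_reversal_equivariance(self, library, rng):
        vals = rng.normal(size=60_000)
        fwd = project_insertion(
            TEInsertion("c", 1000, 6000, "+", "R1", 0, 5000),
            EnrichmentTrack({"c": vals}),
        )
        flipped = vals.copy()
        flipped[1000:6000] = vals[1000:6000][::-1]
        rev = project_insertion(
            TEInsertion("c", 1000, 6000, "-", "R1", 0, 5000),
            EnrichmentTrack({"c": flipped}),
        )
        assert np.array_equal(fwd, rev)

    def test_disjoint_consensus_spans(self, library):
        t = track(value=2.0)
        a = TEInsertion("c", 1000, 1050, "+", "R1", 0, 50)
        b = TEInsertion("c", 3000, 3050, "+", "R1", 50, 100)
        mat = project_to_consensus([a, b], t, library)
        defined = ~np.isnan(mat.matrix)
        assert defined[:, :50].sum(axis=0).tolist() == [1] * 50
        assert defined.sum() == 100

    def test_length_mismatch_linear_scaling(self, library):
        vals = np.zeros(60_000)
        vals[1000:1100] = np.repeat([1.0, 2.0], 50)  # 100 bp genomic span
        ins = TEInsertion("c", 1000, 1100, "+", "R1", 0, 200)  # 200 consensus cols
        row = project_insertion(ins, EnrichmentTrack({"c": vals}))
        assert len(row) == 200
        assert np.all(row[:100] == 1.0) and np.all(row[100:] == 2.0)

    def test_mixed_families_rejected(self, library):
        a = TEInsertion("c", 0, 50, "+", "R1", 0, 50)
        b = TEInsertion("c", 100, 150, "+", "TRAM_LTR", 0, 50)
        with pytest.raises(ValueError, match="families"):
            project_to_consensus([a, b], track(), library)


class TestLTRStructure:
    def classify(self, entries, library):
        return {
            i.name or i.start: i.structural_class
            for i in classify_ltr_structure(entries, library)
        }

    def test_small_gaps_full_length(self, library):
        # gaps of 3 and 2 bp
        entries = [ltr(1000), internal(1375), ltr(6005)]
        out = classify_ltr_structure(entries, library)
        assert out[0].structural_class == "full_length"

    def test_gap_exactly_10_is_full_length(self, library):
        entries = [ltr(1000), internal(1382), ltr(6020)]
        assert classify_ltr_structure(entries, library)[0].structural_class == "full_length"

    def test_gap_11_is_not_full_length(self, library):
        entries = [ltr(1000), internal(1383), ltr(6013)]
        assert classify_ltr_structure(entries, library)[0].structural_class == "other"

    def test_far_upstream_ltr_is_five_prime_truncated(self, library):
        # upstream LTR 6000 bp away, downstream adjacent
        entries = [ltr(1000), internal(1372 + 6000), ltr(1372 + 6000 + 4628 + 2)]
        assert (
            classify_ltr_structure(entries, library)[0].structural_class
            == "five_prime_truncated"
        )

    def test_gap_5001_counts_as_lost_5000_does_not(self, library):
        for gap, expected in [(5001, "five_prime_truncated"), (5000, "other")]:
            entries = [ltr(1000), internal(1372 + gap),
                       ltr(1372 + gap + 4628 + 2)]
            got = classify_ltr_structure(entries, library)[0].structural_class
            assert got == expected, gap

    def test_missing_downstream_ltr_is_three_prime_truncated(self, library):
        entries = [ltr(1000), internal(1375)]
        assert (
            classify_ltr_structure(entries, library)[0].structural_class
            == "three_prime_truncated"
        )

    def test_opposite_strand_flanks_are_not_full_length(self, library):
        entries = [ltr(1000, "-"), internal(1375, "+"), ltr(6005, "-")]
        assert classify_ltr_structure(entries, library)[0].structural_class == "other"

    def test_minus_strand_five_prime_is_genomic_right(self, library):
        # '-' strand: intact 3' LTR on the left, 5' side (right) empty
        entries = [ltr(1000, "-"), internal(1375, "-")]
        assert (
            classify_ltr_structure(entries, library)[0].structural_class
            == "five_prime_truncated"
        )

    def test_head_to_tail_tandem_shares_middle_ltr(self, library):
        l1 = ltr(1000)
        i1 = internal(l1.end + 3)
        l2 = ltr(i1.end + 3)
        i2 = internal(l2.end + 3)
        l3 = ltr(i2.end + 3)
        out = classify_ltr_structure([l1, i1, l2, i2, l3], library)
        assert [i.structural_class for i in out] == ["full_length", "full_length"]

    def test_classes_exhaustive_and_exclusive(self, library):
        entries = [ltr(1000), internal(1375), ltr(6005), internal(20_000)]
        out = classify_ltr_structure(entries, library)
        assert len(out) == 2
        assert all(
            i.structural_class in (
                "full_length", "five_prime_truncated",
                "three_prime_truncated", "other",
            )
            for i in out
        )


class TestTruncationContrast:
    def test_identical_groups_fold_one(self, rng):
        vals = rng.normal(1.0, 0.05, size=60_000)
        t = EnrichmentTrack({"c": vals})
        full = [internal(i * 6000) for i in range(1, 5)]
        trunc = [internal(i * 6000) for i in range(5, 9)]
        out = truncation_contrast(full, trunc, {"s7": t})
        assert out["s7"].fold == pytest.approx(1.0, abs=0.05)
        assert out["s7"].p_value > 0.05

    def test_planted_difference_detected(self):
        vals = np.zeros(120_000)
        full = [internal(i * 6000) for i in range(1, 10)]
        trunc = [internal(i * 6000) for i in range(10, 19)]
        for ins in full:
            vals[ins.start : ins.end] = 2.0  # spreading covered the element
        t = EnrichmentTrack({"c": np.resize(vals, 120_000)})
        out = truncation_contrast(full, trunc, {"s7": t})
        assert out["s7"].fold == pytest.approx(4.0, rel=0.01)
        assert out["s7"].p_value < 0.01

    def test_terminal_window_strand_aware(self):
        vals = np.zeros(60_000)
        ins_plus = internal(1000, "+")
        ins_minus = internal(7000, "-")
        vals[ins_plus.end - 1000 : ins_plus.end] = 3.0  # element 3' end, + strand
        vals[ins_minus.start : ins_minus.start + 1000] = 3.0  # 3' end, - strand
        t = EnrichmentTrack({"c": vals})
        out = truncation_contrast([ins_plus], [ins_minus], {"s": t}, side="five_prime")
        assert out["s"].full_means[0] == pytest.approx(3.0)
        assert out["s"].truncated_means[0] == pytest.approx(3.0)

    def test_short_internal_averaged_over_full_length(self):
        vals = np.full(60_000, 1.0)
        short = internal(1000, length=400)
        out = truncation_contrast([short], [short], {"s": EnrichmentTrack({"c": vals})})
        assert out["s"].full_means[0] == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            truncation_contrast([], [internal(0)], {})


class TestCountsAndOverlap:
    def test_family_copy_counts(self):
        genome = GenomeModel(
            [Chromosome("c", 60_000, "autosome"), Chromosome("y", 60_000, "neoY")]
        )
        ins = [
            TEInsertion("c", 0, 50, "+", "R1", 0, 50),
            TEInsertion("y", 0, 50, "+", "R1", 0, 50),
            TEInsertion("y", 100, 150, "+", "R1", 0, 50),
        ]
        assert family_copy_counts(ins, genome) == {"R1": (3, 2)}

    def test_summit_maps_linearly_to_consensus(self):
        ins = TEInsertion("c", 1000, 1100, "+", "R1", 0, 100)
        peak = Peak("c", 1040, 1060, 1050)
        assert summit_to_consensus(peak, ins) == pytest.approx(50.0)
        ins_rev = TEInsertion("c", 1000, 1100, "-", "R1", 0, 100)
        assert summit_to_consensus(peak, ins_rev) == pytest.approx(50.0)

    def test_peak_outside_insertions_unassigned(self):
        ins = [TEInsertion("c", 1000, 1100, "+", "R1", 0, 100)]
        out = te_peak_overlap([Peak("c", 5000, 5100, 5050)], ins)
        assert out == {}
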