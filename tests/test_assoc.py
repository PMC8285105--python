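"""piRNA processing, expression scaling, sex inference, shared statistics."""

import itertools
import math

import numpy as np
import pytest

from hetnuc.assoc import (
    SmallRNARead,
    associate_windows_peaks,
    atac_enrichment,
    bh_fdr,
    filter_pirna,
    infer_sex,
    pearson_r,
    rank_sum,
    scaled_te_expression,
    split_by_strand,
    stage_fold_change,
    te_pirna_coverage,
    window_rpm,
)
from hetnuc.genome import Chromosome, GenomeModel, Interval
from hetnuc.peaks import Peak
from hetnuc.te import TEConsensus, TELibrary
from hetnuc.tracks import CoverageTrack


def read(target="c", start=0, length=25, strand="+"):
    return SmallRNARead(target, start, length, strand)


class TestPirnaFiltering:
    def test_bounds_inclusive(self):
        kept = filter_pirna([read(length=23), read(length=29), read(length=22),
                             read(length=30)])
        assert [r.length for r in kept] == [23, 29]

    def test_mixed_list(self):
        kept = filter_pirna([read(length=l) for l in (21, 23, 29, 31)])
        assert [r.length for r in kept] == [23, 29]

    def test_strand_split_conserves_counts(self):
        reads = [read(strand=s) for s in "+--"]
        fwd, rev = split_by_strand(reads)
        assert (len(fwd), len(rev)) == (1, 2)
        assert split_by_strand([]) == ([], [])


class TestWindowRPM:
    @pytest.fixture
    def genome(self):
        return GenomeModel([Chromosome("c", 20_000, "autosome")])

    def test_rpm_arithmetic_and_conservation(self, genome):
        reads = [read(start=i) for i in range(10)] + [
            read(start=5000 + i) for i in range(20)
        ]
        windows = window_rpm(reads, genome)
        total = len(reads)
        counts = [w.value * total / 1e6 for w in windows]
        assert sum(counts) == pytest.approx(total)
        assert windows[0].value == pytest.approx(10 / (total / 1e6))
        # doubling a window's count doubles its RPM exactly
        assert windows[1].value == 2 * windows[0].value
        assert windows[2].value == 0.0

    def test_all_reads_in_one_window_closed_form(self, genome):
        reads = [read(start=i) for i in range(50)]
        windows = window_rpm(reads, genome)
        assert windows[0].value == 1e6

    def test_zero_reads_rejected(self, genome):
        with pytest.raises(ValueError):
            window_rpm([], genome)


class TestAssociation:
    def test_grouping_and_pericentric_midpoint(self):
        genome = GenomeModel(
            [Chromosome("c", 20_000, "autosome")],
            pericentric=[Interval("c", 0, 7_600)],
        )
        peaks = [Peak("c", 100, 300, 200, persistence="persistent")]
        reads = (
            [read(start=i * 3) for i in range(100)]  # window 0: overlaps peak
            + [read(start=5_000 + i) for i in range(10)]  # window 1: peri (mid 7500)
            + [read(start=10_000 + i) for i in range(5)]  # window 2: eu
        )
        windows = window_rpm(filter_pirna(reads), genome)
        groups, medians, pvals = associate_windows_peaks(windows, peaks, genome)
        assert set(groups) == {"persistent", "peri", "eu"}
        assert medians["persistent"] > medians["peri"] > 0
        assert len(groups["peri"]) == 1  # straddling window assigned by midpoint

    def test_identical_windows_give_p_near_one(self):
        genome = GenomeModel([Chromosome("c", 40_000, "autosome")])
        peaks = [Peak("c", 100, 300, 200, persistence="persistent")]
        reads = [read(start=s + i) for s in range(0, 40_000, 5_000) for i in range(7)]
        windows = window_rpm(reads, genome)
        _, medians, pvals = associate_windows_peaks(windows, peaks, genome)
        assert medians["persistent"] == medians["eu"]
        assert pvals[("eu", "persistent")] == 1.0


class TestTEPirnaCoverage:
    @pytest.fixture
    def library(self):
        return TELibrary({"fam": TEConsensus("fam", 100, "non_ltr")})

    def test_single_read_mean_coverage(self, library):
        cov = te_pirna_coverage([read("fam", 0, 25, "+")], library)
        assert cov["fam"]["sense"] == pytest.approx(0.25)
        assert cov["fam"]["antisense"] == 0.0

    def test_additivity_and_unknown_target(self, library):
        with pytest.warns(UserWarning):
            cov = te_pirna_coverage(
                [read("fam", 0, 25, "-"), read("fam", 0, 25, "-"),
                 read("nope", 0, 25, "+")],
                library,
            )
        assert cov["fam"]["antisense"] == pytest.approx(0.5)
        assert "nope" not in cov


class TestExpression:
    def test_scaled_expression_arithmetic(self):
        assert scaled_te_expression(100, 200, 50, 100) == pytest.approx(1.0)
        assert scaled_te_expression(0, 200, 50, 100) == 0.0
        assert math.isnan(scaled_te_expression(10, 0, 50, 100))
        with pytest.raises(ValueError):
            scaled_te_expression(1, 1, 0, 1)

    def test_scaled_expression_rna_rescaling_invariance(self):
        base = scaled_te_expression(100, 200, 50, 100)
        assert scaled_te_expression(700, 200, 350, 100) == pytest.approx(base)

    def test_stage_fold_change(self):
        folds, mean = stage_fold_change({"a": 2.0, "b": 1.0}, {"a": 2.0, "b": 2.0})
        assert folds["a"] == pytest.approx(1.0)
        assert folds["b"] == pytest.approx(2.01 / 1.01)
        assert mean == pytest.approx((folds["a"] + folds["b"]) / 2)


class TestSexAndATAC:
    @pytest.fixture
    def genome(self):
        return GenomeModel(
            [Chromosome("a1", 10_000, "autosome"), Chromosome("x", 10_000, "X")]
        )

    @pytest.mark.parametrize(
        "x_cov,expected_sex,expected_ratio",
        [(50.0, "male", 2.0), (100.0, "female", 1.0)],
    )
    def test_ratio_calls(self, genome, x_cov, expected_sex, expected_ratio):
        track = CoverageTrack(
            {"a1": np.full(10_000, 100.0), "x": np.full(10_000, x_cov)}, assay="dna"
        )
        sex, ratio = infer_sex(track, genome)
        assert sex == expected_sex
        assert ratio == pytest.approx(expected_ratio)

    def test_exact_threshold_is_female(self, genome):
        track = CoverageTrack(
            {"a1": np.full(10_000, 150.0), "x": np.full(10_000, 100.0)}
        )
        sex, ratio = infer_sex(track, genome)
        assert ratio == pytest.approx(1.5) and sex == "female"

    def test_atac_identity_and_two_fold(self):
        dna = CoverageTrack({"c": np.full(1000, 1.0)}, sex="male", normalized=True)
        atac = CoverageTrack({"c": np.full(1000, 1.0)}, sex="male", normalized=True)
        assert np.all(atac_enrichment(atac, dna).data["c"] == 0.0)
        atac2 = CoverageTrack({"c": np.full(1000, 2.0)}, sex="male", normalized=True)
        assert atac_enrichment(atac2, dna).data["c"][0] == pytest.approx(1.0, abs=0.02)

    def test_atac_sex_mismatch_rejected(self):
        dna = CoverageTrack({"c": np.ones(10)}, sex="female", normalized=True)
        atac = CoverageTrack({"c": np.ones(10)}, sex="male", normalized=True)
        with pytest.raises(ValueError, match="sex"):
            atac_enrichment(atac, dna)


def ranksum_oracle(x, y):
    """Two-sided exact p by enumerating every assignment of pooled ranks."""
    n, m = len(x), len(y)
    pooled = sorted(x + y)
    ranks_x = [pooled.index(v) + 1 for v in x]
    u_obs = sum(ranks_x) - n * (n + 1) / 2
    u_min = min(u_obs, n * m - u_obs)
    hits = total = 0
    for combo in itertools.combinations(range(1, n + m + 1), n):
        u = sum(combo) - n * (n + 1) / 2
        total += 1
        if min(u, n * m - u) <= u_min:
            hits += 1
    return hits / total


class TestRankSum:
    def test_textbook_separation_example(self):
        _, p = rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_exact_branch_matches_enumeration(self, rng):
        for n, m in [(1, 2), (2, 2), (3, 3), (2, 5), (4, 6), (5, 5), (3, 7)]:
            vals = rng.permutation(np.arange(1.0, n + m + 1))
            x, y = list(vals[:n]), list(vals[n:])
            _, p = rank_sum(x, y)
            assert p == pytest.approx(ranksum_oracle(x, y)), (n, m)

    def test_identical_samples_p_one(self):
        _, p = rank_sum([1.0, 2.0, 5.0], [1.5, 2.5, 4.0])
        assert p >= 0.6  # balanced ranks: no evidence of shift

    def test_large_shift_tiny_p(self, rng):
        x = rng.normal(0, 1, 300)
        y = rng.normal(3, 1, 300)
        _, p = rank_sum(x, y)
        assert p < 1e-6

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum([], [1.0])

    def test_planted_family_association_detected(self, rng):
        """lambda ratio >= 5 between groups of >= 20 families: p < 0.01 in
        at least 95% of seeded replicates."""
        detections = 0
        n_rep = 60
        for k in range(n_rep):
            r = np.random.default_rng(k)
            high = r.poisson(50, size=20)
            low = r.poisson(10, size=20)
            _, p = rank_sum(high.astype(float), low.astype(float))
            detections += p < 0.01
        assert detections / n_rep >= 0.95


class TestPearsonAndFDR:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, _ = pearson_r(x, [2 * v + 1 for v in x])
        assert r == pytest.approx(1.0)
        r, _ = pearson_r(x, [-v for v in x])
        assert r == pytest.approx(-1.0)

    def test_independent_samples_near_zero(self):
        r_gen = np.random.default_rng(7)
        r, p = pearson_r(r_gen.normal(size=1000), r_gen.normal(size=1000))
        assert abs(r) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_bh_adjustment(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        assert bh_fdr([0.2]) == pytest.approx([0.2])
        assert np.all(bh_fdr([1.0, 1.0, 1.0]) == 1.0)

    def test_bh_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])
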