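"""End-to-end run on the synthetic genome: simulate, normalize, classify.

``run_pipeline`` exercises every stage of the analysis on the default
synthetic configuration — spike-in normalized enrichment tracks, replicate
peak merging, phantom filtering, the developmental taxonomy, TE consensus
projection, the LTR truncation contrast, piRNA window association, and
copy-scaled expression — writes all documented output formats, and returns
the headline numbers together with recovery accuracies against the planted
truth.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import assoc, normalization, peaks, simulate, te, tracks
from .genome import write_bed_intervals, write_chrom_table
from .simulate import SimConfig, SyntheticTruth

ALT_MARKS = ("H3", "H3K4me3", "H4K16ac")


def _subseed(seed: int, k: int) -> int:
    return (seed * 9973 + k) % (2**31 - 1)


def match_peaks_to_sites(
    peak_list, sites, max_dist: int = 400
) -> list[tuple[peaks.Peak, simulate.NucleationSite | None]]:
    """Pair each peak with the nearest planted site within ``max_dist`` bp."""
    out = []
    for p in peak_list:
        best, best_d = None, max_dist + 1
        for s in sites:
            if s.chrom != p.chrom:
                continue
            d = abs(s.pos - p.summit)
            if d < best_d:
                best, best_d = s, d
        out.append((p, best))
    return out


def label_accuracy(pairs, truth_fn, label_fn) -> float:
    """Fraction of truth-matched peaks whose label agrees with the planted one."""
    matched = [(p, s) for p, s in pairs if s is not None]
    if not matched:
        return float("nan")
    hits = sum(1 for p, s in matched if truth_fn(s) == label_fn(p))
    return hits / len(matched)


def _write_window_bedgraph(track, genome, path, width=1000) -> None:
    lines = []
    for chrom in track.data:
        vals = tracks.window_mean_array(track.data[chrom], width)
        n = len(track.data[chrom])
        for i, v in enumerate(vals):
            lines.append(f"{chrom}\t{i * width}\t{min((i + 1) * width, n)}\t{v:.4g}")
    Path(path).write_text("\n".join(lines) + "\n")


def run_pipeline(
    outdir: str | Path,
    seed: int = 0,
    config: SimConfig | None = None,
    spikein_normalize: bool = True,
) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or SimConfig()
    truth = simulate.generate_genome(config, seed)
    genome = truth.genome
    results: dict = {"seed": seed}

    # --- static annotation outputs ---------------------------------------
    write_chrom_table(genome.chromosomes, outdir / "chromosomes.tsv")
    write_bed_intervals(genome.pericentric, outdir / "pericentric.bed")
    te.write_repeatmasker_gff(
        truth.insertions, truth.microsatellites, outdir / "repeats.gff"
    )
    truth.library.to_tsv(outdir / "te_library.tsv")
    truth.to_json(outdir / "truth.json")

    # --- spike-in reference and per-sample shifts -------------------------
    sample_ids = [
        f"{stage}_r{r}" for stage in tracks.STAGES for r in range(config.n_replicates)
    ]
    spike_pairs = {
        sid: simulate.simulate_spikein_pair(truth, sid, _subseed(seed, 100 + i))
        for i, sid in enumerate(sample_ids)
    }
    reference = normalization.build_spikein_reference(
        list(spike_pairs.values()), truth.spike_genome
    )
    shift_fns = {}
    if spikein_normalize:
        for sid, (sc, si) in spike_pairs.items():
            wl = normalization.window_log2_enrichment(sc, si, truth.spike_genome)
            vals = np.concatenate(list(wl.values()))
            shift_fns[sid] = normalization.fit_quantile_shift(vals, reference)
        shift_fns[sample_ids[0]].to_tsv(outdir / "shift_function_example.tsv")

    # --- per-replicate enrichment and stage representatives ---------------
    stage_replicates: dict[str, list[normalization.EnrichmentTrack]] = {}
    sex_by_sample = {}
    for stage in tracks.STAGES:
        reps = []
        for r in range(config.n_replicates):
            sid = f"{stage}_r{r}"
            sex = config.replicate_sexes[r % len(config.replicate_sexes)]
            chip, inp = simulate.simulate_stage_tracks(
                truth, stage, r, sex, _subseed(seed, 200 + len(sex_by_sample))
            )
            sex_by_sample[sid] = sex
            enr = normalization.enrichment(chip, inp, genome)
            if spikein_normalize:
                enr = normalization.apply_shift(enr, shift_fns[sid])
            enr.sex = sex
            reps.append(enr)
            if stage == "s3" and r == 0:
                inferred, ratio = assoc.infer_sex(inp, genome)
                results["sex_inference"] = {
                    "sample": sid, "true": sex, "inferred": inferred, "ratio": ratio
                }
        stage_replicates[stage] = reps
    stage_set = peaks.StageSet(
        {
            stage: peaks.representative_enrichment(reps, genome)
            for stage, reps in stage_replicates.items()
        }
    )
    for stage in ("s3", "e4", "s7"):
        _write_window_bedgraph(
            stage_set.track(stage), genome, outdir / f"enrichment_{stage}.1kb.bedgraph"
        )

    # --- stage 3 peaks: replicate merge, phantom filter, persistence ------
    male_reps_s3 = [t for t in stage_replicates["s3"] if t.sex == "male"]
    rep_peak_lists = [simulate.call_peaks(t, "s3") for t in male_reps_s3]
    s3_peaks = peaks.merge_replicate_peaks(rep_peak_lists)
    peaks.write_narrowpeak(s3_peaks, outdir / "peaks_s3.narrowPeak")
    s3_peaks = peaks.read_narrowpeak(outdir / "peaks_s3.narrowPeak", stage="s3")

    alt_tracks = []
    for k, mark in enumerate(ALT_MARKS):
        chip, inp = simulate.simulate_stage_tracks(
            truth, "s3", 0, "male", _subseed(seed, 300 + k), mark=mark
        )
        alt_tracks.append(normalization.enrichment(chip, inp, genome))
    specific, phantom = peaks.filter_phantom(s3_peaks, alt_tracks)
    peaks.classify_persistence(specific, stage_set)
    peaks.write_taxonomy_tsv(specific + phantom, outdir / "taxonomy_s3.tsv")

    pairs_s3 = match_peaks_to_sites(s3_peaks, truth.sites)
    results["n_s3_peaks"] = len(s3_peaks)
    results["n_s3_specific"] = len(specific)
    results["n_s3_phantom"] = len(phantom)
    results["phantom_accuracy"] = label_accuracy(
        pairs_s3,
        lambda s: "phantom" if s.kind == "phantom" else "specific",
        lambda p: p.specificity,
    )
    spec_pairs = [(p, s) for p, s in pairs_s3 if p.specificity == "specific"]
    results["persistence_accuracy"] = label_accuracy(
        spec_pairs,
        lambda s: "temporary" if s.kind == "temporary" else "persistent",
        lambda p: p.persistence,
    )
    persistent = [p for p in specific if p.persistence == "persistent"]
    temporary = [p for p in specific if p.persistence == "temporary"]
    results["n_persistent"] = len(persistent)
    results["n_temporary"] = len(temporary)

    # --- stage 4 peaks: old/new ------------------------------------------
    e4_peaks = simulate.call_peaks(stage_set.track("e4"), "e4")
    peaks.classify_novelty(e4_peaks, stage_set.track("s3"))
    peaks.write_taxonomy_tsv(e4_peaks, outdir / "taxonomy_e4.tsv")
    pairs_e4 = match_peaks_to_sites(e4_peaks, truth.sites)
    results["n_e4_peaks"] = len(e4_peaks)
    results["novelty_accuracy"] = label_accuracy(
        pairs_e4,
        lambda s: "new" if s.onset == "e4" else "old",
        lambda p: p.novelty,
    )
    results["n_e4_old"] = sum(1 for p in e4_peaks if p.novelty == "old")
    results["n_e4_new"] = sum(1 for p in e4_peaks if p.novelty == "new")
    old_w = [p.width for p in e4_peaks if p.novelty == "old"]
    new_w = [p.width for p in e4_peaks if p.novelty == "new"]
    if old_w and new_w:
        results["mean_width_old"] = float(np.mean(old_w))
        results["mean_width_new"] = float(np.mean(new_w))

    # --- trajectories, profiles, annotation -------------------------------
    traj = peaks.trajectory(persistent, stage_set, seed=_subseed(seed, 7))
    with open(outdir / "trajectory_persistent.tsv", "w") as fh:
        fh.write("stage\tmedian\tci_lo\tci_hi\n")
        for stage, (med, lo, hi) in traj.items():
            fh.write(f"{stage}\t{med:.4f}\t{lo:.4f}\t{hi:.4f}\n")
    results["trajectory_persistent"] = {k: v[0] for k, v in traj.items()}
    _, median_prof, _ = peaks.profile_around(
        specific, stage_set.track("s7"), seed=_subseed(seed, 8)
    )
    np.savetxt(outdir / "profile_s3peaks_at_s7.tsv", median_prof, fmt="%.4f")
    categories, peri_frac = peaks.annotate_peaks(specific, genome)
    results["s3_peak_categories"] = {
        c: sum(1 for v in categories.values() if v == c)
        for c in ("TE", "microsatellite", "gene", "other")
    }
    results["s3_pericentric_fraction"] = peri_frac
    results["fraction_pre_enriched_s7"] = peaks.fraction_pre_enriched(
        simulate.call_peaks(stage_set.track("s7"), "s7"), stage_set, "s7"
    )

    # --- TE structure and truncation contrast -----------------------------
    insertions, microsats, _ = te.parse_repeatmasker_gff(
        outdir / "repeats.gff", truth.library
    )
    tram = [i for i in insertions if i.family.startswith("TRAM")]
    internals = te.classify_ltr_structure(tram, truth.library)
    counts = {
        cls: sum(1 for i in internals if i.structural_class == cls)
        for cls in te.STRUCTURAL_CLASSES
    }
    results["ltr_structure_counts"] = counts
    with open(outdir / "tram_structure.bed", "w") as fh:
        for i in internals:
            fh.write(f"{i.chrom}\t{i.start}\t{i.end}\t{i.structural_class}\n")

    full = [i for i in internals if i.structural_class == "full_length"]
    five = [i for i in internals if i.structural_class == "five_prime_truncated"]
    contrast = te.truncation_contrast(
        full, five, stage_set.representative, side="five_prime"
    )
    with open(outdir / "tram_truncation_contrast.tsv", "w") as fh:
        fh.write("stage\tfold\tp\n")
        for stage, c in contrast.items():
            fh.write(f"{stage}\t{c.fold:.4f}\t{c.p_value:.3g}\n")
    results["truncation_fold_s7"] = contrast["s7"].fold
    results["truncation_p_s7"] = contrast["s7"].p_value

    r1 = [i for i in insertions if i.family == "R1"]
    matrix = te.project_to_consensus(r1, stage_set.track("s3"), truth.library)
    matrix.to_tsv(outdir / "r1_consensus_matrix_s3.tsv")
    profile = te.consensus_profile(matrix)
    results["r1_profile_argmax_s3"] = int(np.nanargmax(profile))

    copy_counts = te.family_copy_counts(insertions, genome)
    results["copy_counts"] = copy_counts
    early = {"R1"}
    others = set(copy_counts) - early - {"TRAM_LTR", "TRAM_I"}
    # overlap of classified peaks with TE families in consensus coordinates
    overlap = te.te_peak_overlap(specific, insertions)
    results["te_peak_overlap_counts"] = {f: len(v) for f, v in overlap.items()}

    # --- piRNA windows and association ------------------------------------
    genomic_reads, consensus_reads = simulate.simulate_pirna(
        truth, seed=_subseed(seed, 9)
    )
    filtered = assoc.filter_pirna(genomic_reads)
    results["pirna_filter_fraction"] = len(filtered) / len(genomic_reads)
    windows = assoc.window_rpm(filtered, genome)
    with open(outdir / "pirna_windows.bedgraph", "w") as fh:
        for w in windows:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.value:.4g}\n")
    groups, medians, pvals = assoc.associate_windows_peaks(
        windows, persistent + temporary, genome
    )
    results["pirna_group_medians"] = medians
    results["pirna_group_p"] = {f"{a}|{b}": p for (a, b), p in pvals.items()}
    cons_filtered = assoc.filter_pirna(consensus_reads)
    cov = assoc.te_pirna_coverage(cons_filtered, truth.library)
    with open(outdir / "te_pirna_coverage.tsv", "w") as fh:
        fh.write("family\tsense\tantisense\n")
        for fam, c in cov.items():
            fh.write(f"{fam}\t{c['sense']:.3f}\t{c['antisense']:.3f}\n")

    # --- expression --------------------------------------------------------
    expr = simulate.simulate_expression(truth, _subseed(seed, 10))
    scaled = {stage: expr.scaled(stage) for stage in ("s2", "s4", "s5")}
    with open(outdir / "te_expression_scaled.tsv", "w") as fh:
        fh.write("family\ts2\ts4\ts5\n")
        for fam in sorted(expr.dna):
            fh.write(
                f"{fam}\t{scaled['s2'][fam]:.4f}\t{scaled['s4'][fam]:.4f}"
                f"\t{scaled['s5'][fam]:.4f}\n"
            )
    folds_24, _ = assoc.stage_fold_change(scaled["s2"], scaled["s4"])
    early_fams = [f for f in folds_24 if f in config.early_families]
    late_fams = [f for f in folds_24 if f in config.late_families]
    results["expression_fold_s2_s4_early"] = float(
        np.mean([folds_24[f] for f in early_fams])
    )
    results["expression_fold_s2_s4_late"] = float(
        np.mean([folds_24[f] for f in late_fams])
    )
    return results
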