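"""Synthetic-data generator: determinism, planted truth, read chemistry,
count matrices and structure masks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam
import pytest
from scipy import stats as sps

from bsm5c.config import ConfigError, SimConfig
from bsm5c import simulate
from bsm5c.simulate import GenerationError


def _cfg(**kw) -> SimConfig:
    base = dict(seed=3, n_transcripts=10, n_true_sites=5)
    base.update(kw)
    return SimConfig(**base)


class TestTranscriptome:
    def test_empty_request_gives_empty_outputs(self, tmp_path):
        cfg = _cfg(n_transcripts=0, n_true_sites=0)
        ts = simulate.generate_transcriptome(cfg)
        assert ts == []
        simulate.write_fasta(ts, tmp_path / "empty.fa")
        simulate.write_annotation_bed(ts, tmp_path / "empty.bed")
        assert (tmp_path / "empty.fa").read_text() == ""
        assert (tmp_path / "empty.bed").read_text() == ""

    def test_same_seed_identical_fasta_bytes(self, tmp_path):
        for name in ("a.fa", "b.fa"):
            ts = simulate.generate_transcriptome(_cfg(seed=7))
            simulate.write_fasta(ts, tmp_path / name)
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_mrna_feature_lengths_sum_to_sequence_length(self):
        ts = simulate.generate_transcriptome(_cfg(n_transcripts=50))
        mrnas = [t for t in ts if t.biotype == "mRNA"]
        assert mrnas
        for t in mrnas:
            assert t.utr5_len + t.cds_len + t.utr3_len == t.length
            assert set(t.sequence) <= set("ACGT")

    def test_spike_in_present_and_flagged(self):
        ts = simulate.generate_transcriptome(_cfg())
        spikes = [t for t in ts if t.is_spike]
        assert len(spikes) == 1
        assert spikes[0].transcript_id.startswith("SPIKE_")
        assert spikes[0].length == 1850

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigError, match="conversion_rate"):
            _cfg(conversion_rate=1.5).validate()
        with pytest.raises(ConfigError, match="read_length"):
            _cfg(read_length=30).validate()


class TestPlantTruthSites:
    def test_zero_sites_requested(self):
        ts = simulate.generate_transcriptome(_cfg())
        out, sites = simulate.plant_truth_sites(ts, _cfg(n_true_sites=0))
        assert sites == []

    def test_sites_sit_on_reference_cytosines_with_spacing(self):
        cfg = _cfg(n_transcripts=50, n_true_sites=40)
        ts = simulate.generate_transcriptome(cfg)
        ts, sites = simulate.plant_truth_sites(ts, cfg)
        seqs = {t.transcript_id: t.sequence for t in ts}
        assert len(sites) == 40
        by_tid: dict[str, list[int]] = {}
        for s in sites:
            assert seqs[s.transcript_id][s.position] == "C"
            assert 0 < s.true_level <= 1
            by_tid.setdefault(s.transcript_id, []).append(s.position)
        for positions in by_tid.values():
            positions.sort()
            assert all(b - a >= cfg.read_length
                       for a, b in zip(positions, positions[1:]))

    def test_level_median_matches_beta(self):
        cfg = _cfg(n_transcripts=2500, n_true_sites=10_000, seed=11)
        ts = simulate.generate_transcriptome(cfg)
        _, sites = simulate.plant_truth_sites(ts, cfg)
        levels = np.array([s.true_level for s in sites])
        expected = sps.beta(2.0, 8.2).median()
        assert abs(np.median(levels) - expected) < 0.03

    def test_forced_motif_rewrites_downstream_context(self):
        cfg = _cfg(n_transcripts=40, n_true_sites=25, motif_fraction=1.0)
        ts = simulate.generate_transcriptome(cfg)
        ts, sites = simulate.plant_truth_sites(ts, cfg)
        seqs = {t.transcript_id: t.sequence for t in ts}
        for s in sites:
            seq = seqs[s.transcript_id]
            assert seq[s.position + 1] in "AG"
            assert seq[s.position + 2: s.position + 5] == "GGG"

    def test_impossible_request_raises(self):
        cfg = _cfg(n_transcripts=1, n_true_sites=500)
        ts = simulate.generate_transcriptome(cfg)
        with pytest.raises(GenerationError):
            simulate.plant_truth_sites(ts, cfg)


def _read_sam_records(path):
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        return list(fh)


class TestBsLibrary:
    def test_perfect_conversion_leaves_no_unconverted_cs(self, tmp_path):
        cfg = _cfg(conversion_rate=1.0, incomplete_read_fraction=0.0,
                   n_true_sites=0, n_transcripts=5, mean_coverage=5.0)
        ts = simulate.generate_transcriptome(cfg)
        sam = tmp_path / "perfect.sam"
        simulate.simulate_bs_library(ts, [], cfg, 1, "LF", sam)
        refs = {t.transcript_id: t.sequence for t in ts}
        for read in _read_sam_records(sam):
            ref = refs[read.reference_name]
            for off, base in enumerate(read.query_sequence):
                if ref[read.reference_start + off] == "C":
                    assert base == "T"

    def test_fully_methylated_site_always_unconverted(self, tmp_path):
        cfg = _cfg(n_transcripts=3, n_true_sites=2, incomplete_read_fraction=0.0)
        ts = simulate.generate_transcriptome(cfg)
        ts, sites = simulate.plant_truth_sites(ts, cfg)
        target = sites[0]
        overrides = {(target.transcript_id, target.position): 1.0}
        sam = tmp_path / "meth.sam"
        simulate.simulate_bs_library(ts, sites, cfg, 1, "LF", sam,
                                     level_overrides=overrides)
        n_cover = 0
        for read in _read_sam_records(sam):
            if read.reference_name != target.transcript_id:
                continue
            off = target.position - read.reference_start
            if 0 <= off < len(read.query_sequence):
                n_cover += 1
                assert read.query_sequence[off] == "C"
        assert n_cover >= 10

    def test_spike_fraction_and_conversion_rate(self, tmp_path):
        cfg = _cfg(n_transcripts=40, n_true_sites=0, mean_coverage=20.0,
                   conversion_rate=0.999, incomplete_read_fraction=0.0)
        ts = simulate.generate_transcriptome(cfg)
        sam = tmp_path / "spike.sam"
        simulate.simulate_bs_library(ts, [], cfg, 1, "LF", sam)
        records = _read_sam_records(sam)
        spike = [r for r in records if r.reference_name.startswith("SPIKE_")]
        frac = len(spike) / len(records)
        se = np.sqrt(0.005 * 0.995 / len(records))
        assert abs(frac - 0.005) <= max(3 * se, 1 / len(records))
        # unconverted fraction on spike cytosines ~ Binomial(n, 0.001)
        refs = {t.transcript_id: t.sequence for t in ts}
        n_c = n_unconv = 0
        for read in spike:
            ref = refs[read.reference_name]
            for off, base in enumerate(read.query_sequence):
                if ref[read.reference_start + off] == "C":
                    n_c += 1
                    n_unconv += base == "C"
        assert n_c > 1000
        se_c = np.sqrt(0.001 * 0.999 / n_c)
        assert abs(n_unconv / n_c - 0.001) <= 3 * se_c + 1e-9

    def test_same_seed_identical_sam_bytes(self, tmp_path):
        cfg = _cfg(n_transcripts=5)
        ts = simulate.generate_transcriptome(cfg)
        ts, sites = simulate.plant_truth_sites(ts, cfg)
        for name in ("x.sam", "y.sam"):
            simulate.simulate_bs_library(ts, sites, cfg, 1, "LF", tmp_path / name)
        assert (tmp_path / "x.sam").read_bytes() == (tmp_path / "y.sam").read_bytes()

    def test_truth_on_unknown_transcript_rejected(self, tmp_path):
        cfg = _cfg(n_transcripts=2, n_true_sites=0)
        ts = simulate.generate_transcriptome(cfg)
        bogus = [simulate.GroundTruthSite("NOPE", 10, 0.5, "")]
        with pytest.raises(GenerationError):
            simulate.simulate_bs_library(ts, bogus, cfg, 1, "LF", tmp_path / "z.sam")


class TestStructureMask:
    def test_no_masks_requested(self):
        ts = simulate.generate_transcriptome(_cfg(n_transcripts=3))
        bed, brackets = simulate.generate_structure_mask(ts, n_per_transcript=0)
        assert bed.empty and brackets == {}

    def test_hairpin_pairs_inside_interval(self):
        ts = simulate.generate_transcriptome(_cfg(n_transcripts=5))
        bed, brackets = simulate.generate_structure_mask(ts, n_per_transcript=1,
                                                         seed=4)
        from bsm5c.sites import paired_positions
        for tid, (offset, structure) in brackets.items():
            row = bed[bed.transcript_id == tid].iloc[0]
            paired = paired_positions(structure, offset)
            assert all(row.start <= p < row.end for p in paired)

    def test_oversized_mask_rejected(self):
        t = simulate.TranscriptModel("tiny", "ACGT" * 3, 0, 0, 0, "ncRNA")
        with pytest.raises(GenerationError):
            simulate.generate_structure_mask([t], stem_len=10, loop_len=10)


class TestCountMatrices:
    def test_zero_dispersion_deterministic_limit(self):
        truth = simulate.generate_count_truth(20, conditions=("A",), seed=5,
                                              frac_te_affected=0.0,
                                              frac_expr_affected=0.0)
        truth["dispersion"] = 0.0
        counts, samples = simulate.simulate_count_matrices(
            truth, ("A",), 2, seed=5, library_size_spread=0.0,
        )
        total = counts[[s for s in counts.columns if "total" in s]]
        poly = counts[[s for s in counts.columns if "polysome" in s]]
        assert (total.to_numpy() == poly.to_numpy()).all()
        expected = np.round(truth["base_mean"].to_numpy())
        assert (total.to_numpy() == expected[:, None]).all()

    def test_planted_te_effect_scales_polysome_ratio(self):
        truth = simulate.generate_count_truth(50, conditions=("A",), seed=6,
                                              frac_te_affected=0.0,
                                              frac_expr_affected=0.0)
        truth["base_mean"] = 1e5
        truth["dispersion"] = 1e-4  # near-Poisson so the mean dominates
        truth.iloc[0, truth.columns.get_loc("te_log2fc_A")] = 2.0
        counts, samples = simulate.simulate_count_matrices(
            truth, ("A",), 2, seed=6, library_size_spread=0.0,
        )
        total = counts[[s for s in counts.columns if "total" in s]].mean(axis=1)
        poly = counts[[s for s in counts.columns if "polysome" in s]].mean(axis=1)
        ratio = poly / total
        baseline = ratio.iloc[1:].median()
        assert ratio.iloc[0] / baseline == pytest.approx(4.0, rel=0.05)

    def test_seed_reproducibility(self):
        truth = simulate.generate_count_truth(30, seed=9)
        c1, _ = simulate.simulate_count_matrices(truth, ("LF", "MF", "HF"), 2, 9)
        c2, _ = simulate.simulate_count_matrices(truth, ("LF", "MF", "HF"), 2, 9)
        pd.testing.assert_frame_equal(c1, c2)

    def test_single_replicate_rejected(self):
        truth = simulate.generate_count_truth(5, seed=1)
        with pytest.raises(ConfigError):
            simulate.simulate_count_matrices(truth, ("LF",), 1, 1)
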