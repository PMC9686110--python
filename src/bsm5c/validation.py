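"""Seeded simulation experiments measuring the pipeline's operating
characteristics on data with known ground truth.

Each function runs one self-contained experiment — generate synthetic
inputs, execute the relevant pipeline stages, score the result against the
planted truth — and returns a dict of plain numbers. They power both the
test suite and ``scripts/acceptance.py``.

Problem sizes are chosen so each experiment finishes in seconds to a few
minutes on one core while keeping the statistical checks meaningful
(binomial/Wilcoxon tail probabilities at the tested effect sizes are far
from the decision boundaries).
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .config import SimConfig, FilterThresholds
from . import annotate as ann
from . import diffmeth, reads, simulate, sites, translation
from .stats import paired_signed_rank


def _count_cytosines(transcripts) -> int:
    return sum(t.sequence.count("C") for t in transcripts if not t.is_spike)


def _simulate_and_call(
    cfg: SimConfig,
    truth,
    transcripts,
    condition: str,
    workdir: Path,
    thresholds: FilterThresholds | None = None,
) -> tuple[pd.DataFrame, list[pd.DataFrame], list[float]]:
    """Simulate all replicates of one condition, process and call sites."""
    refs = {t.transcript_id: t.sequence for t in transcripts}
    pileups, p0s = [], []
    for rep in range(1, cfg.n_replicates + 1):
        sam = workdir / f"{condition}_R{rep}.sam"
        simulate.simulate_bs_library(transcripts, truth, cfg, rep, condition, sam)
        pileup, est, _ = reads.process_library(
            sam, refs, default_conversion_rate=cfg.conversion_rate
        )
        sam.unlink()  # keep the scratch footprint small
        pileups.append(pileup)
        p0s.append(est.p0)
    high, _ = sites.call_condition_sites(pileups, p0s, thresholds)
    return high, pileups, p0s


def null_specificity(seed: int, n_cytosines: int = 100_000) -> dict:
    """High-confidence site count on libraries with no methylation.

    Three conditions x two replicates at 50x coverage and conversion rate
    0.999, with zero planted sites: every called site is a false positive.
    """
    # ~25% of random bases are C, so total nt ~= 4 * n_cytosines
    n_transcripts = max(1, int(round(n_cytosines * 4 / 1500)))
    cfg = SimConfig(
        seed=seed, n_transcripts=n_transcripts, n_true_sites=0,
        mean_coverage=50.0, conversion_rate=0.999, n_replicates=2,
        conditions=("LF", "MF", "HF"),
    )
    transcripts = simulate.generate_transcriptome(cfg)
    transcripts, truth = ([*transcripts], [])
    total_sites = 0
    with tempfile.TemporaryDirectory() as tmp:
        for cond in cfg.conditions:
            high, _, _ = _simulate_and_call(
                cfg, truth, transcripts, cond, Path(tmp)
            )
            total_sites += len(high)
    return {
        "n_high_confidence_sites": total_sites,
        "n_cytosines": _count_cytosines(transcripts),
        "n_libraries": len(cfg.conditions) * cfg.n_replicates,
    }


def site_recovery(seed: int, n_sites: int = 200, coverage: float = 50.0) -> dict:
    """Recall/precision/level accuracy on planted m5C sites.

    Levels are Beta(2, 8.2); recall is reported for sites with true level
    >= 0.15 (sites below that are largely invisible at the published
    methylated-depth threshold of 6 at ~50x).
    """
    cfg = SimConfig(
        seed=seed, n_transcripts=max(60, int(n_sites * 1.5)),
        n_true_sites=n_sites, mean_coverage=coverage, n_replicates=2,
        conditions=("LF",),
    )
    transcripts = simulate.generate_transcriptome(cfg)
    transcripts, truth = simulate.plant_truth_sites(transcripts, cfg)
    with tempfile.TemporaryDirectory() as tmp:
        high, _, _ = _simulate_and_call(cfg, truth, transcripts, "LF", Path(tmp))
    truth_map = {(s.transcript_id, s.position): s.true_level for s in truth}
    called = set(zip(high["transcript_id"], high["position"]))
    true_keys = set(truth_map)
    tp = called & true_keys
    strong = {k for k, v in truth_map.items() if v >= 0.15}
    levels = high.set_index(["transcript_id", "position"])["pooled_level"]
    errors = [abs(levels.loc[k] - truth_map[k]) for k in tp]
    return {
        "n_called": len(called),
        "n_true": len(true_keys),
        "recall_level_ge_0.15": len(tp & strong) / len(strong) if strong else float("nan"),
        "precision": len(tp) / len(called) if called else float("nan"),
        "pooled_level_mae": float(np.mean(errors)) if errors else float("nan"),
        "median_called_level": (
            float(high["pooled_level"].median()) if len(high) else float("nan")
        ),
    }


def three_c_filter_efficacy(seed: int, n_transcripts: int = 60) -> dict:
    """Removal rate of incomplete-conversion reads and residual site calls.

    5% of reads are incomplete conversions (per-C conversion 0.5) on an
    otherwise unmethylated library; incomplete reads are identified by the
    simulator's ground-truth read-name tag. The removal rate is reported
    over incomplete reads covering >= 10 cytosines.
    """
    cfg = SimConfig(
        seed=seed, n_transcripts=n_transcripts, n_true_sites=0,
        mean_coverage=50.0, incomplete_read_fraction=0.05,
        incomplete_read_conversion=0.5, n_replicates=2, conditions=("LF",),
    )
    transcripts = simulate.generate_transcriptome(cfg)
    refs = {t.transcript_id: t.sequence for t in transcripts}
    n_incomplete = n_removed = 0
    with tempfile.TemporaryDirectory() as tmp:
        sam = Path(tmp) / "lib.sam"
        simulate.simulate_bs_library(transcripts, [], cfg, 1, "LF", sam)
        with pysam.AlignmentFile(str(sam), "r", check_sq=False) as fh:
            for read in fh:
                if not read.query_name.endswith(":INC"):
                    continue
                profile = reads.profile_read_conversions(
                    read.query_sequence, read.reference_start,
                    refs[read.reference_name],
                )
                if len(profile.cytosine_positions) < 10:
                    continue
                n_incomplete += 1
                if profile.n_unconverted > 3:
                    n_removed += 1
        high, _, _ = _simulate_and_call(cfg, [], transcripts, "LF", Path(tmp))
    return {
        "n_incomplete_reads": n_incomplete,
        "removal_rate": n_removed / n_incomplete if n_incomplete else float("nan"),
        "n_false_positive_sites": len(high),
    }


def _observed_levels(
    rng: np.random.Generator, true_levels: np.ndarray, coverage: int
) -> np.ndarray:
    return rng.binomial(coverage, true_levels) / coverage


def signed_rank_shift_detection(
    seed: int, n_sites: int = 100, shift: float = 0.05,
    coverage: int = 50, n_runs: int = 100, n_null_runs: int = 400,
) -> dict:
    """Power and size of the paired polysome-vs-total signed-rank test.

    Each run draws true site levels from Beta(2, 8.2), observes them with
    binomial noise at the given coverage in both methylomes, and adds the
    planted shift to the polysome levels (shifted runs) or nothing (null
    runs). One-sided p-values (polysome > total) are used throughout.
    """
    rng = np.random.default_rng([seed, 51])
    reject_shift = reject_null = 0
    for _ in range(n_runs):
        levels = rng.beta(2.0, 8.2, n_sites)
        total = _observed_levels(rng, levels, coverage)
        poly = _observed_levels(rng, np.clip(levels + shift, 0, 1), coverage)
        if paired_signed_rank(total, poly)["p_greater"] < 0.01:
            reject_shift += 1
    # the size of the test is estimated on more runs than the power: its
    # acceptance band is much tighter relative to the binomial noise
    for _ in range(n_null_runs):
        levels = rng.beta(2.0, 8.2, n_sites)
        total0 = _observed_levels(rng, levels, coverage)
        poly0 = _observed_levels(rng, levels, coverage)
        if paired_signed_rank(total0, poly0)["p_greater"] < 0.05:
            reject_null += 1
    return {
        "power_at_0.01": reject_shift / n_runs,
        "null_rejection_at_0.05": reject_null / n_null_runs,
        "n_runs": n_runs,
        "n_null_runs": n_null_runs,
    }


def _binomial_pileup(
    rng: np.random.Generator, keys, levels: np.ndarray, coverage: int
) -> pd.DataFrame:
    k = rng.binomial(coverage, levels)
    return pd.DataFrame({
        "transcript_id": [t for t, _ in keys],
        "position": [p for _, p in keys],
        "coverage_all": coverage,
        "coverage_pass": coverage,
        "k": k,
    })


def dms_calibration(
    seed: int, n_sites: int = 50, coverage: int = 50, n_runs: int = 100,
) -> dict:
    """Specificity and power of Fisher + BH differential methylation.

    Null runs draw both conditions (two replicates each) from identical
    truth; the planted run adds one site at level 0.30 vs 0.10 (pooled
    n = 100 per condition). Counts are simulated at the pileup layer.
    """
    rng = np.random.default_rng([seed, 62])
    keys = [(f"T{i:04d}", 100) for i in range(n_sites)]
    hc = pd.DataFrame(
        {"transcript_id": [t for t, _ in keys],
         "position": [p for _, p in keys]}
    )
    dms_counts = []
    planted_hits = 0
    planted_key = [("PLANT", 100)]
    hc_p = pd.DataFrame({"transcript_id": ["PLANT"], "position": [100]})
    for _ in range(n_runs):
        levels = rng.beta(2.0, 8.2, n_sites)
        pa = [_binomial_pileup(rng, keys, levels, coverage) for _ in range(2)]
        pb = [_binomial_pileup(rng, keys, levels, coverage) for _ in range(2)]
        dms = diffmeth.call_dms(pa, pb, hc, hc)
        dms_counts.append(int(dms["significant"].sum()))

        # power: a targeted comparison of the one differential site
        lv_a, lv_b = np.array([0.30]), np.array([0.10])
        pa2 = [_binomial_pileup(rng, planted_key, lv_a, coverage) for _ in range(2)]
        pb2 = [_binomial_pileup(rng, planted_key, lv_b, coverage) for _ in range(2)]
        dms2 = diffmeth.call_dms(pa2, pb2, hc_p, hc_p)
        if len(dms2) and bool(dms2["significant"].iloc[0]):
            planted_hits += 1
    return {
        "median_null_dms": float(np.median(dms_counts)),
        "max_null_dms": int(np.max(dms_counts)),
        "planted_detection_rate": planted_hits / n_runs,
        "n_runs": n_runs,
    }


def te_recovery(seed: int, n_genes: int = 2000, n_runs: int = 5) -> dict:
    """DTG recall and false-positive rate on NB count simulations.

    Recall is aggregated over genes with planted |te_log2fc| >= 1 and
    base mean >= 100 (flagged DTG with the correct sign); the false-
    positive rate is over genes with no planted TE effect.
    """
    n_strong = n_recovered = n_null = n_false = 0
    for r in range(n_runs):
        truth = simulate.generate_count_truth(
            n_genes, conditions=("C", "T"), seed=seed * 1000 + r,
        )
        counts, samples = simulate.simulate_count_matrices(
            truth, ("C", "T"), 2, seed=seed * 1000 + r,
        )
        res = translation.call_dtgs(counts, samples, "T", "C")
        te = truth["te_log2fc_T"]
        strong = (te.abs() >= 1.0) & (truth["base_mean"] >= 100)
        correct = res["dtg"] & (np.sign(res["te_log2fc"]) == np.sign(te))
        n_strong += int(strong.sum())
        n_recovered += int(correct[strong].sum())
        null = te == 0
        n_null += int(null.sum())
        n_false += int(res.loc[null, "dtg"].sum())
    return {
        "dtg_recall": n_recovered / n_strong if n_strong else float("nan"),
        "null_dtg_rate": n_false / n_null if n_null else float("nan"),
        "n_strong_genes": n_strong,
        "n_null_genes": n_null,
        "n_runs": n_runs,
    }


def metagene_flatness(seed: int, n_sites: int = 100_000) -> dict:
    """Deviation of the metagene profile from the uniform expectation.

    Sites are placed uniformly on transcripts with identical 150/900/450
    feature lengths, so the expected percentage of each bin is the
    feature's length share divided by its bin count.
    """
    rng = np.random.default_rng([seed, 93])
    u5, cds, u3 = 150, 900, 450
    total = u5 + cds + u3
    t = simulate.TranscriptModel("T0", "A" * total, u5, cds, u3, "mRNA")
    positions = rng.integers(0, total, n_sites)
    df = pd.DataFrame({"transcript_id": "T0", "position": positions})
    annotated = ann.annotate_sites(df, {"T0": t})
    profile = ann.metagene_profile(annotated)
    expected = np.concatenate([
        np.full(5, u5 / total / 5), np.full(18, cds / total / 18),
        np.full(22, u3 / total / 22),
    ]) * 100.0
    dev = np.abs(profile["pct"].to_numpy() - expected)
    return {
        "max_abs_deviation_pp": float(dev.max()),
        "pct_sum": float(profile["pct"].sum()),
        "n_sites": n_sites,
    }
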