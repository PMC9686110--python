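"""Shared fixtures: one small simulated bisulfite study reused across
module tests (session-scoped; everything is generated in-memory/tmp)."""

from __future__ import annotations

from pathlib import Path

import pytest
from hypothesis import settings

from bsm5c.config import SimConfig
from bsm5c import reads, simulate, sites

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A 60-transcript, 40-site study with two replicates at 50x.

    Returns a dict with the transcripts, truth sites, per-replicate
    pileups/p0s, per-replicate surviving candidates and the
    high-confidence intersection.
    """
    cfg = SimConfig(
        seed=7, n_transcripts=60, n_true_sites=40, mean_coverage=50.0,
        n_replicates=2, conditions=("LF",),
    )
    transcripts = simulate.generate_transcriptome(cfg)
    transcripts, truth = simulate.plant_truth_sites(transcripts, cfg)
    refs = {t.transcript_id: t.sequence for t in transcripts}
    workdir = tmp_path_factory.mktemp("small_study")
    pileups, p0s = [], []
    for rep in (1, 2):
        sam = workdir / f"rep{rep}.sam"
        simulate.simulate_bs_library(transcripts, truth, cfg, rep, "LF", sam)
        pileup, est, stats = reads.process_library(sam, refs)
        pileups.append(pileup)
        p0s.append(est.p0)
    high, survivors = sites.call_condition_sites(pileups, p0s)
    return {
        "config": cfg,
        "transcripts": transcripts,
        "refs": refs,
        "truth": truth,
        "pileups": pileups,
        "p0s": p0s,
        "survivors": survivors,
        "high_confidence": high,
        "workdir": Path(workdir),
    }
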