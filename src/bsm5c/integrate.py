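"""Joining differential methylation with translation classes.

For each condition, every transcript bearing a significant polysome-vs-
total differentially methylated site (DMS) is paired with its translation
class (polysome-vs-total differential expression) and assigned one of
three correlation categories:

* positive — hypermethylated and highly translated, or hypomethylated and
  lowly translated;
* negative — hypermethylated and lowly translated, or hypomethylated and
  highly translated;
* neutral — any methylation direction with median (unchanged) translation.

Transcripts carrying DMS of opposite directions are reported once per
direction and flagged ambiguous rather than silently collapsed.

:func:`run_pipeline` wires the whole analysis end to end on simulated
inputs (simulate -> process reads -> call sites -> annotate -> diffmeth ->
TE -> integrate) and writes a JSON run manifest; identical configs
reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import FilterThresholds, SimConfig
from . import annotate as ann
from . import diffmeth, reads, simulate, sites, translation

POSITIVE, NEGATIVE, NEUTRAL = "positive", "negative", "neutral"

_CATEGORY = {
    ("hyper", "high"): POSITIVE,
    ("hypo", "low"): POSITIVE,
    ("hyper", "low"): NEGATIVE,
    ("hypo", "high"): NEGATIVE,
    ("hyper", "median"): NEUTRAL,
    ("hypo", "median"): NEUTRAL,
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def classify_correlation(dms_direction: str, translation_class: str) -> str:
    """Map (methylation direction, translation class) to a category."""
    try:
        return _CATEGORY[(dms_direction, translation_class)]
    except KeyError:
        raise ValueError(
            f"invalid combination ({dms_direction!r}, {translation_class!r}); "
            f"direction must be hyper|hypo, class high|low|median"
        ) from None


def build_correlation_records(
    dms: pd.DataFrame,
    translation_classes: pd.DataFrame,
    condition: str,
) -> pd.DataFrame:
    """One record per (transcript, DMS direction) for a condition.

    ``dms`` is a polysome-vs-total differential methylation table (A =
    polysome, so "hyper" means hypermethylated on polysomes); only
    significant sites contribute. ``translation_classes`` indexes gene ==
    transcript ids with a ``translation_class`` column; transcripts absent
    from it default to the median class.
    """
    sig = dms.loc[dms["significant"]]
    rows = []
    for tid, grp in sig.groupby("transcript_id"):
        directions = sorted(set(grp["direction"]))
        ambiguous = len(directions) > 1
        if tid in translation_classes.index:
            tclass = str(translation_classes.loc[tid, "translation_class"])
        else:
            tclass = "median"
        for direction in directions:
            rows.append({
                "transcript_id": tid,
                "condition": condition,
                "dms_direction": direction,
                "n_sites": int((grp["direction"] == direction).sum()),
                "translation_class": tclass,
                "category": classify_correlation(direction, tclass),
                "ambiguous_direction": ambiguous,
            })
    return pd.DataFrame(rows, columns=[
        "transcript_id", "condition", "dms_direction", "n_sites",
        "translation_class", "category", "ambiguous_direction",
    ])


def summarize_categories(records: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per category per condition.

    Tallies both transcripts (one per transcript-direction record) and
    DMS sites (summing ``n_sites``); percentages per condition sum to 100.
    """
    rows = []
    for condition, grp in records.groupby("condition"):
        n_records = len(grp)
        n_sites = int(grp["n_sites"].sum()) if "n_sites" in grp else n_records
        for category in (POSITIVE, NEGATIVE, NEUTRAL):
            sub = grp.loc[grp["category"] == category]
            count = len(sub)
            site_count = int(sub["n_sites"].sum()) if "n_sites" in sub else count
            rows.append({
                "condition": condition,
                "category": category,
                "n_transcripts": count,
                "pct_transcripts": 100.0 * count / n_records if n_records else 0.0,
                "n_sites": site_count,
                "pct_sites": 100.0 * site_count / n_sites if n_sites else 0.0,
            })
    return pd.DataFrame(rows)


def consistent_transcripts(records: pd.DataFrame) -> dict[str, list[str]]:
    """Transcripts with the same category in every condition.

    A transcript qualifies only if it has at least one record in each
    condition and every one of its records (all conditions, all
    directions) carries the same category.
    """
    conditions = set(records["condition"])
    if len(conditions) < 2:
        raise ValueError("need records from >= 2 conditions")
    out: dict[str, list[str]] = {POSITIVE: [], NEGATIVE: [], NEUTRAL: []}
    for tid, grp in records.groupby("transcript_id"):
        if set(grp["condition"]) != conditions:
            continue
        cats = set(grp["category"])
        if len(cats) == 1:
            out[cats.pop()].append(tid)
    return {k: sorted(v) for k, v in out.items()}


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class PipelineConfig:
    """Configuration of a full simulated run."""

    sim: SimConfig = field(default_factory=lambda: SimConfig(
        n_transcripts=12, n_true_sites=8, mean_coverage=30.0,
    ))
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    polysome_level_shift: float = 0.10  # added to planted levels on polysomes
    count_n_replicates: int = 2

    def validate(self) -> "PipelineConfig":
        self.sim.validate()
        self.thresholds.validate()
        if not 0 <= self.polysome_level_shift <= 1:
            raise ValueError("polysome_level_shift must be in [0, 1]")
        return self


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _log(msg: str) -> None:
    print(f"[bsm5c] {msg}", file=sys.stderr)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full simulated analysis and write the output tree.

    Stages: simulate, process_reads, call_sites, annotate,
    differential_methylation, translation, integration. Returns the run
    manifest (also written to ``manifest.json``).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.sim
    manifest: dict = {
        "package": "bsm5c",
        "version": __version__,
        "seed": sim.seed,
        "thresholds": asdict(config.thresholds),
        "stages": [],
        "outputs": {},
    }
    stage_t0 = time.time()

    def finish_stage(name: str, **info) -> None:
        nonlocal stage_t0
        manifest["stages"].append(
            {"name": name, "seconds": round(time.time() - stage_t0, 3), **info}
        )
        _log(f"stage {name} done ({manifest['stages'][-1]['seconds']}s)")
        stage_t0 = time.time()

    def run_stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise PipelineError(f"stage {name} failed: {exc}") from exc

    # -- simulate ----------------------------------------------------------
    def _simulate():
        transcripts = simulate.generate_transcriptome(sim)
        transcripts, truth = simulate.plant_truth_sites(transcripts, sim)
        simulate.write_fasta(transcripts, outdir / "transcripts.fa")
        simulate.write_annotation_bed(transcripts, outdir / "annotation.bed")
        simulate.write_truth_bed(truth, outdir / "truth_sites.bed")
        sim.to_yaml(outdir / "sim_config.yaml")
        shifted = {
            (s.transcript_id, s.position):
                min(1.0, s.true_level + config.polysome_level_shift)
            for s in truth
        }
        sams: dict[tuple[str, str, int], Path] = {}
        for cond in sim.conditions:
            for fraction in ("total", "polysome"):
                overrides = shifted if fraction == "polysome" else None
                for rep in range(1, sim.n_replicates + 1):
                    path = outdir / f"reads_{cond}_{fraction}_R{rep}.sam"
                    rep_key = rep if fraction == "total" else rep + 100
                    simulate.simulate_bs_library(
                        transcripts, truth, sim, rep_key, cond, path,
                        level_overrides=overrides,
                    )
                    sams[(cond, fraction, rep)] = path
        gene_ids = [t.transcript_id for t in transcripts if not t.is_spike]
        truth_counts = simulate.generate_count_truth(
            len(gene_ids), conditions=sim.conditions, seed=sim.seed,
        )
        truth_counts.index = pd.Index(gene_ids, name="gene_id")
        counts, samples = simulate.simulate_count_matrices(
            truth_counts, sim.conditions, config.count_n_replicates, sim.seed,
        )
        counts.to_csv(outdir / "counts.tsv", sep="\t")
        samples.to_csv(outdir / "samples.tsv", sep="\t")
        truth_counts.to_csv(outdir / "count_truth.tsv", sep="\t")
        return transcripts, truth, sams, counts, samples

    transcripts, truth, sams, counts, samples = run_stage("simulate", _simulate)
    finish_stage("simulate", n_transcripts=len(transcripts),
                 n_truth_sites=len(truth), n_libraries=len(sams))

    # -- process reads -----------------------------------------------------
    refs = {t.transcript_id: t.sequence for t in transcripts}

    def _process():
        pileups: dict[tuple[str, str, int], pd.DataFrame] = {}
        p0s: dict[tuple[str, str, int], float] = {}
        for key, path in sams.items():
            pileup, est, stats = reads.process_library(
                path, refs,
                max_unconverted=config.thresholds.max_unconverted_per_read,
                default_conversion_rate=sim.conversion_rate,
            )
            pileups[key] = pileup
            p0s[key] = est.p0
        return pileups, p0s

    pileups, p0s = run_stage("process_reads", _process)
    finish_stage("process_reads", n_libraries=len(pileups))

    # -- call sites --------------------------------------------------------
    def _call():
        hc: dict[tuple[str, str], pd.DataFrame] = {}
        for cond in sim.conditions:
            for fraction in ("total", "polysome"):
                keys = [(cond, fraction, r) for r in range(1, sim.n_replicates + 1)]
                high, _ = sites.call_condition_sites(
                    [pileups[k] for k in keys], [p0s[k] for k in keys],
                    config.thresholds,
                )
                hc[(cond, fraction)] = high
                sites.write_sites_tsv(
                    high, outdir / f"m5c_sites_{cond}_{fraction}.tsv"
                )
        return hc

    hc = run_stage("call_sites", _call)
    finish_stage("call_sites",
                 n_sites={f"{c}_{f}": len(v) for (c, f), v in hc.items()})

    # -- annotate ----------------------------------------------------------
    def _annotate():
        tmap = {t.transcript_id: t for t in transcripts}
        summaries = {}
        for (cond, fraction), high in hc.items():
            if high.empty:
                continue
            annotated = ann.annotate_sites(high, tmap)
            profile = ann.metagene_profile(annotated)
            profile.to_csv(
                outdir / f"metagene_{cond}_{fraction}.tsv", sep="\t", index=False
            )
            matrix = ann.motif_matrix(high, refs)
            matrix.to_csv(outdir / f"motif_{cond}_{fraction}.tsv", sep="\t")
            summaries[f"{cond}_{fraction}"] = ann.level_summary(
                high["pooled_level"]
            )
        (outdir / "level_summaries.json").write_text(
            json.dumps(summaries, indent=2)
        )
        return summaries

    run_stage("annotate", _annotate)
    finish_stage("annotate")

    # -- differential methylation -----------------------------------------
    def _diffmeth():
        dms_by_cond = {}
        signed_rank = {}
        for cond in sim.conditions:
            pt = [pileups[(cond, "total", r)] for r in range(1, sim.n_replicates + 1)]
            pp = [pileups[(cond, "polysome", r)] for r in range(1, sim.n_replicates + 1)]
            dms = diffmeth.call_dms(
                pp, pt, hc[(cond, "polysome")], hc[(cond, "total")],
                diffmeth.ComparisonSpec("polysome", "total",
                                        config.thresholds.min_coverage),
            )
            dms.to_csv(outdir / f"dms_polysome_vs_total_{cond}.tsv",
                       sep="\t", index=False)
            dms_by_cond[cond] = dms
            signed_rank[cond] = diffmeth.compare_total_polysome(
                pt, pp, hc[(cond, "total")], hc[(cond, "polysome")],
                config.thresholds.min_coverage,
            )
        (outdir / "polysome_hypermethylation.json").write_text(
            json.dumps(signed_rank, indent=2)
        )
        return dms_by_cond, signed_rank

    dms_by_cond, signed_rank = run_stage("differential_methylation", _diffmeth)
    finish_stage("differential_methylation",
                 n_dms={c: int(d["significant"].sum()) for c, d in dms_by_cond.items()})

    # -- translation -------------------------------------------------------
    def _translation():
        classes = {}
        for cond in sim.conditions:
            cls = translation.classify_translation(counts, samples, cond)
            cls.to_csv(outdir / f"translation_class_{cond}.tsv", sep="\t")
            classes[cond] = cls
        dtgs = {}
        ref_cond = sim.conditions[0]
        for cond in sim.conditions[1:]:
            res = translation.call_dtgs(counts, samples, cond, ref_cond)
            res.to_csv(outdir / f"dtg_{cond}_vs_{ref_cond}.tsv", sep="\t")
            dtgs[cond] = res
        return classes, dtgs

    classes, dtgs = run_stage("translation", _translation)
    finish_stage("translation",
                 n_dtg={c: int(d["dtg"].sum()) for c, d in dtgs.items()})

    # -- integration -------------------------------------------------------
    def _integrate():
        all_records = []
        for cond in sim.conditions:
            rec = build_correlation_records(
                dms_by_cond[cond], classes[cond], cond
            )
            all_records.append(rec)
        records = pd.concat(all_records, ignore_index=True)
        records.to_csv(outdir / "correlation_records.tsv", sep="\t", index=False)
        summary = summarize_categories(records)
        summary.to_csv(outdir / "correlation_summary.tsv", sep="\t", index=False)
        if len(sim.conditions) >= 2 and len(records):
            consistent = consistent_transcripts(records)
        else:
            consistent = {POSITIVE: [], NEGATIVE: [], NEUTRAL: []}
        (outdir / "consistent_transcripts.json").write_text(
            json.dumps(consistent, indent=2)
        )
        return records, summary, consistent

    records, summary, consistent = run_stage("integration", _integrate)
    finish_stage("integration", n_records=len(records))

    for path in sorted(outdir.iterdir()):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][path.name] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
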