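"""Synthetic bisulfite-seq and polysome-profiling data with known truth.

Generates everything the pipeline consumes, fully seeded:

* a transcriptome (5'UTR/CDS/3'UTR-segmented mRNAs plus a few noncoding
  RNAs and pseudogenes, and one unmethylated spike-in control transcript);
* planted m5C sites with Beta-distributed methylation levels and an
  optional downstream (A/G)GGG context;
* aligned, sense-strand bisulfite-converted reads written as SAM in
  transcript coordinate space, including spike-in reads and a configurable
  fraction of incomplete-conversion reads;
* secondary-structure masks (BED intervals and hairpin dot-brackets);
* negative-binomial total/polysome count matrices with planted expression
  and translation-efficiency effects.

Reads are emitted pre-aligned: every record has FLAG 0, a full-length match
CIGAR and a 1-based POS on its transcript. Genome alignment is outside the
scope of the pipeline, whose computation starts from aligned reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import ConfigError, SimConfig

SPIKE_PREFIX = "SPIKE_"
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_C, _T = ord("C"), ord("T")

# per-stage salts so each operation has an independent, reproducible stream
_SALT_TRANSCRIPTOME = 1
_SALT_SITES = 2
_SALT_READS = 3
_SALT_COUNTS = 4
_SALT_MASKS = 5


class GenerationError(RuntimeError):
    """Raised when the requested synthetic dataset cannot be constructed."""


@dataclass
class TranscriptModel:
    transcript_id: str
    sequence: str
    utr5_len: int
    cds_len: int
    utr3_len: int
    biotype: str  # mRNA | ncRNA | pseudogene | spike

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_spike(self) -> bool:
        return self.transcript_id.startswith(SPIKE_PREFIX)


@dataclass
class GroundTruthSite:
    transcript_id: str
    position: int  # 0-based offset on the transcript
    true_level: float
    context: str  # +/-5 nt flanking sequence, site at the centre


def _rng(seed: int, *salt: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), *map(int, salt)])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(rng.choice(_BASES, size=length)).decode()


def generate_transcriptome(config: SimConfig) -> list[TranscriptModel]:
    """Generate the transcript set, spike-in control last.

    mRNA lengths are drawn uniformly within ``length_jitter`` of the three
    configured region means, so feature lengths vary across transcripts but
    always sum to the sequence length.
    """
    config.validate()
    rng = _rng(config.seed, _SALT_TRANSCRIPTOME)
    transcripts: list[TranscriptModel] = []
    if config.n_transcripts == 0:
        return transcripts
    for i in range(config.n_transcripts):
        u = rng.random()
        if u < config.ncrna_fraction:
            biotype = "ncRNA"
        elif u < config.ncrna_fraction + config.pseudogene_fraction:
            biotype = "pseudogene"
        else:
            biotype = "mRNA"
        lens = []
        for mean in (config.utr5_mean, config.cds_mean, config.utr3_mean):
            jitter = config.length_jitter
            lens.append(max(1, int(round(mean * rng.uniform(1 - jitter, 1 + jitter)))))
        total = sum(lens)
        seq = _random_seq(rng, total)
        if biotype == "mRNA":
            u5, cds, u3 = lens
        else:
            u5 = cds = u3 = 0
        transcripts.append(
            TranscriptModel(f"T{i:05d}", seq, u5, cds, u3, biotype)
        )
    spike = TranscriptModel(
        SPIKE_PREFIX + "XEF1A",
        _random_seq(rng, config.spike_in_length),
        0, 0, 0, "spike",
    )
    transcripts.append(spike)
    return transcripts


def write_fasta(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.transcript_id, description=t.biotype)
        for t in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_annotation_bed(
    transcripts: Iterable[TranscriptModel], path: str | Path
) -> None:
    """BED6-style feature annotation (0-based half-open) per transcript."""
    with open(path, "w") as fh:
        for t in transcripts:
            if t.biotype == "mRNA":
                bounds = [
                    ("5UTR", 0, t.utr5_len),
                    ("CDS", t.utr5_len, t.utr5_len + t.cds_len),
                    ("3UTR", t.utr5_len + t.cds_len, t.length),
                ]
            else:
                bounds = [(t.biotype, 0, t.length)]
            for name, start, end in bounds:
                if end > start:
                    fh.write(f"{t.transcript_id}\t{start}\t{end}\t{name}\t0\t+\n")


def read_annotation_bed(path: str | Path) -> list[TranscriptModel]:
    """Rebuild transcript segmentation models from a feature BED.

    Sequences are not stored in BED; models carry empty sequences and are
    suitable for feature annotation only.
    """
    feats: dict[str, dict[str, tuple[int, int]]] = {}
    other_biotype: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        tid, start, end, name = line.split("\t")[:4]
        if name in ("5UTR", "CDS", "3UTR"):
            feats.setdefault(tid, {})[name] = (int(start), int(end))
        else:
            other_biotype[tid] = name
            feats.setdefault(tid, {})[name] = (int(start), int(end))
    models = []
    for tid, d in feats.items():
        if tid in other_biotype:
            length = d[other_biotype[tid]][1]
            models.append(TranscriptModel(tid, "", 0, 0, 0, other_biotype[tid]))
            models[-1].sequence = "N" * length
        else:
            u5 = d.get("5UTR", (0, 0))
            cds = d.get("CDS", (u5[1], u5[1]))
            u3 = d.get("3UTR", (cds[1], cds[1]))
            m = TranscriptModel(tid, "", u5[1] - u5[0], cds[1] - cds[0],
                                u3[1] - u3[0], "mRNA")
            m.sequence = "N" * u3[1]
            models.append(m)
    return models


def plant_truth_sites(
    transcripts: Sequence[TranscriptModel], config: SimConfig
) -> tuple[list[TranscriptModel], list[GroundTruthSite]]:
    """Choose cytosines to methylate and (optionally) rewrite their context.

    Sites are restricted to the transcript interior (at least one read
    length from either end) and spaced at least one read length apart, so
    no read can span two planted sites and every site has full flanking
    context and even coverage. A ``motif_fraction`` of sites has its
    downstream context rewritten to A/G at +1 and GGG at +2..+4, emulating
    the G-rich context observed downstream of m5C sites.

    Returns a new transcript list (sequences possibly rewritten) plus the
    ground-truth site records; the input list is not modified.
    """
    config.validate()
    if not transcripts:
        raise GenerationError("no transcripts to plant sites on")
    rng = _rng(config.seed, _SALT_SITES)
    seqs = {t.transcript_id: bytearray(t.sequence, "ascii") for t in transcripts}
    if config.n_true_sites == 0:
        return list(transcripts), []

    rl = config.read_length
    candidates: list[tuple[str, int]] = []
    for t in transcripts:
        if t.is_spike:
            continue
        lo, hi = rl, t.length - rl
        if hi <= lo:
            continue
        seq = t.sequence
        candidates.extend(
            (t.transcript_id, p) for p in range(lo, hi) if seq[p] == "C"
        )
    if not candidates:
        raise GenerationError("no eligible cytosines available for planting")
    order = rng.permutation(len(candidates))
    chosen: list[tuple[str, int]] = []
    taken: dict[str, list[int]] = {}
    for idx in order:
        tid, pos = candidates[idx]
        if any(abs(pos - q) < rl for q in taken.get(tid, ())):
            continue
        chosen.append((tid, pos))
        taken.setdefault(tid, []).append(pos)
        if len(chosen) == config.n_true_sites:
            break
    if len(chosen) < config.n_true_sites:
        raise GenerationError(
            f"only {len(chosen)} spaced cytosines available for "
            f"{config.n_true_sites} requested sites"
        )

    levels = rng.beta(config.level_alpha, config.level_beta, size=len(chosen))
    levels = np.clip(levels, 1e-6, 1.0)
    has_motif = rng.random(len(chosen)) < config.motif_fraction
    sites: list[GroundTruthSite] = []
    for (tid, pos), level, motif in zip(chosen, levels, has_motif):
        seq = seqs[tid]
        if motif:
            seq[pos + 1] = ord(rng.choice(["A", "G"]))
            seq[pos + 2 : pos + 5] = b"GGG"
        context = seq[pos - 5 : pos + 6].decode()
        sites.append(GroundTruthSite(tid, pos, float(level), context))
    sites.sort(key=lambda s: (s.transcript_id, s.position))
    out = [
        TranscriptModel(t.transcript_id, seqs[t.transcript_id].decode(),
                        t.utr5_len, t.cds_len, t.utr3_len, t.biotype)
        for t in transcripts
    ]
    return out, sites


def write_truth_bed(sites: Iterable[GroundTruthSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.transcript_id}\t{s.position}\t{s.position + 1}\t"
                f"m5C\t{int(round(s.true_level * 1000))}\t+\n"
            )


def _sam_header(transcripts: Sequence[TranscriptModel], rg_id: str) -> str:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    lines += [f"@SQ\tSN:{t.transcript_id}\tLN:{t.length}" for t in transcripts]
    lines.append(f"@RG\tID:{rg_id}\tSM:{rg_id}")
    return "\n".join(lines) + "\n"


def _emit_reads(
    t: TranscriptModel,
    n_reads: int,
    level_by_pos: Mapping[int, float],
    config: SimConfig,
    rng: np.random.Generator,
    rg_id: str,
    fh,
) -> None:
    """Vectorised bisulfite read simulation for one transcript."""
    if n_reads <= 0:
        return
    rl = min(config.read_length, t.length)
    seq_arr = np.frombuffer(t.sequence.encode(), dtype=np.uint8)
    # probability of observing C at each reference position for a
    # complete-conversion read
    p_c = np.full(t.length, 1.0 - config.conversion_rate)
    for pos, level in level_by_pos.items():
        p_c[pos] = level
    starts = rng.integers(0, t.length - rl + 1, size=n_reads)
    idx = starts[:, None] + np.arange(rl)[None, :]
    base = seq_arr[idx]
    is_c = base == _C
    pmat = p_c[idx]
    incomplete = np.zeros(n_reads, dtype=bool)
    if config.incomplete_read_fraction > 0:
        incomplete = rng.random(n_reads) < config.incomplete_read_fraction
        pmat = np.where(
            incomplete[:, None], 1.0 - config.incomplete_read_conversion, pmat
        )
    draw = rng.random(idx.shape)
    out = base.copy()
    out[is_c] = _T
    out[is_c & (draw < pmat)] = _C
    if config.substitution_error_rate > 0:
        err = rng.random(idx.shape) < config.substitution_error_rate
        out[err] = _BASES[rng.integers(0, 4, size=int(err.sum()))]
    qual = "I" * rl
    cigar = f"{rl}M"
    tid = t.transcript_id
    for i in range(n_reads):
        # ground-truth label: incomplete-conversion reads get an :INC suffix
        tag = ":INC" if incomplete[i] else ""
        fh.write(
            f"{rg_id}:{tid}:{i}{tag}\t0\t{tid}\t{starts[i] + 1}\t255\t{cigar}\t"
            f"*\t0\t0\t{bytes(out[i]).decode()}\t{qual}\tRG:Z:{rg_id}\n"
        )


def simulate_bs_library(
    transcripts: Sequence[TranscriptModel],
    truth_sites: Sequence[GroundTruthSite],
    config: SimConfig,
    replicate_id: int,
    condition: str,
    out_sam: str | Path,
    level_overrides: Mapping[tuple[str, int], float] | None = None,
) -> Path:
    """Simulate one aligned bisulfite library and write it as SAM.

    Each reference cytosine under a read is emitted as C with probability
    ``true_level`` at a planted site and ``1 - conversion_rate`` elsewhere;
    incomplete-conversion reads emit every C with probability
    ``1 - incomplete_read_conversion``. Spike-in reads come from the
    unmethylated control transcript at a ``spike_in_fraction`` share of the
    library. ``level_overrides`` replaces planted levels per (transcript,
    position), e.g. to shift levels in one condition.
    """
    config.validate()
    if config.mean_coverage <= 0:
        raise ConfigError("mean_coverage: must be > 0")
    tids = {t.transcript_id for t in transcripts}
    for s in truth_sites:
        if s.transcript_id not in tids:
            raise GenerationError(f"truth site on unknown transcript {s.transcript_id}")
    try:
        cond_index = list(config.conditions).index(condition)
    except ValueError:
        cond_index = len(config.conditions) + (hash(condition) % 1000)
    rng = _rng(config.seed, _SALT_READS, cond_index, replicate_id)
    rg_id = f"{condition}_R{replicate_id}"

    levels: dict[str, dict[int, float]] = {}
    for s in truth_sites:
        level = s.true_level
        if level_overrides is not None:
            level = level_overrides.get((s.transcript_id, s.position), level)
        levels.setdefault(s.transcript_id, {})[s.position] = level

    main = [t for t in transcripts if not t.is_spike]
    spike = [t for t in transcripts if t.is_spike]
    out_sam = Path(out_sam)
    with open(out_sam, "w") as fh:
        fh.write(_sam_header(transcripts, rg_id))
        n_main_total = 0
        for t in main:
            rl = min(config.read_length, t.length)
            n_reads = int(round(t.length * config.mean_coverage / rl))
            n_main_total += n_reads
            _emit_reads(t, n_reads, levels.get(t.transcript_id, {}),
                        config, rng, rg_id, fh)
        if spike and config.spike_in_fraction > 0:
            f = config.spike_in_fraction
            n_spike = int(round(n_main_total * f / (1.0 - f)))
            for t in spike:
                _emit_reads(t, n_spike, {}, config, rng, rg_id, fh)
    return out_sam


# ---------------------------------------------------------------------------
# structure masks


def generate_structure_mask(
    transcripts: Sequence[TranscriptModel],
    n_per_transcript: int = 1,
    stem_len: int = 5,
    loop_len: int = 4,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, tuple[int, str]]]:
    """Place non-overlapping hairpin regions on each transcript.

    Returns a BED-style frame (transcript, start, end; 0-based half-open)
    and, per masked transcript, the (offset, dot-bracket) of the first
    hairpin. Each hairpin is ``stem_len`` paired bases on each side of a
    ``loop_len`` loop; all paired positions fall inside the BED interval.
    """
    if not transcripts:
        raise GenerationError("no transcripts to mask")
    span = 2 * stem_len + loop_len
    rng = _rng(seed, _SALT_MASKS)
    rows = []
    brackets: dict[str, tuple[int, str]] = {}
    structure = "(" * stem_len + "." * loop_len + ")" * stem_len
    for t in transcripts:
        if t.is_spike or n_per_transcript <= 0:
            continue
        if span > t.length:
            raise GenerationError(
                f"mask span {span} exceeds transcript {t.transcript_id} "
                f"length {t.length}"
            )
        placed: list[int] = []
        for _ in range(n_per_transcript):
            for _attempt in range(50):
                start = int(rng.integers(0, t.length - span + 1))
                if all(abs(start - p) >= span for p in placed):
                    placed.append(start)
                    break
        for start in sorted(placed):
            rows.append((t.transcript_id, start, start + span))
        if placed:
            brackets[t.transcript_id] = (min(placed), structure)
    bed = pd.DataFrame(rows, columns=["transcript_id", "start", "end"])
    return bed, brackets


def write_mask_bed(bed: pd.DataFrame, path: str | Path) -> None:
    bed.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# count matrices


def generate_count_truth(
    n_genes: int,
    conditions: Sequence[str] = ("LF", "MF", "HF"),
    seed: int = 0,
    frac_expr_affected: float = 0.1,
    frac_te_affected: float = 0.1,
    base_mean_log_mu: float = np.log(300.0),
    base_mean_log_sigma: float = 1.2,
    dispersion_log_mu: float = np.log(0.02),
    dispersion_log_sigma: float = 0.3,
    expr_lfc_range: tuple[float, float] = (0.5, 2.0),
    te_lfc_range: tuple[float, float] = (1.0, 2.0),
) -> pd.DataFrame:
    """Draw per-gene simulation truth for the count matrices.

    The first condition is the reference (all fold changes zero). Affected
    genes receive signed log2 fold changes drawn uniformly from the given
    magnitude ranges, independently per non-reference condition.
    """
    rng = _rng(seed, _SALT_COUNTS, 1)
    base_mean = rng.lognormal(base_mean_log_mu, base_mean_log_sigma, n_genes)
    dispersion = rng.lognormal(dispersion_log_mu, dispersion_log_sigma, n_genes)
    data = {
        "gene_id": [f"G{i:05d}" for i in range(n_genes)],
        "base_mean": base_mean,
        "dispersion": dispersion,
    }
    for j, cond in enumerate(conditions):
        if j == 0:
            data[f"expr_log2fc_{cond}"] = np.zeros(n_genes)
            data[f"te_log2fc_{cond}"] = np.zeros(n_genes)
            continue
        expr = np.zeros(n_genes)
        sel = rng.random(n_genes) < frac_expr_affected
        mag = rng.uniform(*expr_lfc_range, size=int(sel.sum()))
        expr[sel] = mag * rng.choice([-1.0, 1.0], size=int(sel.sum()))
        te = np.zeros(n_genes)
        sel_te = rng.random(n_genes) < frac_te_affected
        mag_te = rng.uniform(*te_lfc_range, size=int(sel_te.sum()))
        te[sel_te] = mag_te * rng.choice([-1.0, 1.0], size=int(sel_te.sum()))
        data[f"expr_log2fc_{cond}"] = expr
        data[f"te_log2fc_{cond}"] = te
    return pd.DataFrame(data).set_index("gene_id")


def simulate_count_matrices(
    truth: pd.DataFrame,
    conditions: Sequence[str],
    n_replicates: int = 2,
    seed: int = 0,
    library_size_spread: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate total and polysome count matrices from a truth table.

    Counts are NB(mean, dispersion) with per-sample library-size factors
    drawn log-normally around 1; polysome means are total means scaled by
    2**te_log2fc and condition means by 2**expr_log2fc. Dispersion 0 is the
    deterministic limit: counts equal the rounded means exactly.

    Returns (counts, samples): a genes x samples integer frame and a sample
    sheet with columns sample, condition, fraction, replicate.
    """
    if n_replicates < 2:
        raise ConfigError("n_replicates: need >= 2 replicates per condition")
    if (truth["base_mean"] < 0).any():
        raise ConfigError("base_mean: must be >= 0")
    rng = _rng(seed, _SALT_COUNTS, 2)
    genes = truth.index.to_numpy()
    base = truth["base_mean"].to_numpy(float)
    disp = truth["dispersion"].to_numpy(float)
    counts: dict[str, np.ndarray] = {}
    meta = []
    for cond in conditions:
        expr = 2.0 ** truth[f"expr_log2fc_{cond}"].to_numpy(float)
        te = 2.0 ** truth[f"te_log2fc_{cond}"].to_numpy(float)
        for fraction in ("total", "polysome"):
            for rep in range(1, n_replicates + 1):
                sf = float(rng.lognormal(0.0, library_size_spread)) \
                    if library_size_spread > 0 else 1.0
                mu = base * expr * sf
                if fraction == "polysome":
                    mu = mu * te
                sample = f"{cond}_{fraction}_R{rep}"
                zero_d = disp <= 0
                c = np.empty(len(genes), dtype=np.int64)
                c[zero_d] = np.round(mu[zero_d]).astype(np.int64)
                if (~zero_d).any():
                    size = 1.0 / disp[~zero_d]
                    p = size / (size + mu[~zero_d])
                    c[~zero_d] = rng.negative_binomial(size, p)
                counts[sample] = c
                meta.append((sample, cond, fraction, rep))
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"))
    samples = pd.DataFrame(
        meta, columns=["sample", "condition", "fraction", "replicate"]
    ).set_index("sample")
    return counts_df, samples
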