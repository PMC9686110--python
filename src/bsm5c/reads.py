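"""Bisulfite read processing: per-read conversion profiles, the 3C filter,
spike-in conversion-rate estimation, and strand-aware pileups.

The library is stranded, so only sense-strand cytosines are profiled: a
reference C read as T is a converted (unmethylated) cytosine, read as C it
is unconverted (methylated or conversion failure), and any other base is a
mismatch counted in neither tally. Reads carrying more than
``max_unconverted_per_read`` unconverted Cs are treated as incomplete
bisulfite conversions and removed (the 3C filter) before pileup counting,
but still contribute to the per-site "all reads" denominator used by the
signal/noise filter downstream.

Coordinates are 0-based half-open internally; SAM input is 1-based per the
standard and converted at the I/O boundary (pysam already yields 0-based
``reference_start``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .simulate import SPIKE_PREFIX

_C, _T = ord("C"), ord("T")

CONVERTED = "converted"
UNCONVERTED = "unconverted"
OTHER = "other"


class AlignmentConsistencyError(ValueError):
    """A read is inconsistent with its reference (e.g. extends past its end)."""


class EstimationError(RuntimeError):
    """Conversion rate cannot be estimated (no spike-in observations);
    fall back to the configured default rate."""


@dataclass
class ReadConversionProfile:
    read_id: str
    transcript_id: str
    start: int  # 0-based
    cytosine_positions: list[int]  # reference offsets of covered Cs
    statuses: list[str]  # converted | unconverted | other, per position

    @property
    def n_unconverted(self) -> int:
        return sum(s == UNCONVERTED for s in self.statuses)


@dataclass
class ConversionRateEstimate:
    library_id: str
    total_c_observations: int
    converted_c_observations: int
    rate_override: float | None = None  # set when falling back to a default

    @property
    def rate(self) -> float:
        if self.rate_override is not None:
            return self.rate_override
        return self.converted_c_observations / self.total_c_observations

    @property
    def p0(self) -> float:
        return 1.0 - self.rate


@dataclass
class LibraryStats:
    """Read-accounting tallies for one processed library."""

    n_records: int = 0
    n_antisense_skipped: int = 0
    n_nonunique_skipped: int = 0
    n_profiled: int = 0
    n_failed_3c: int = 0
    n_spike_reads: int = 0


def profile_read_conversions(
    read_seq: str,
    start: int,
    reference: str,
    read_id: str = "",
    transcript_id: str = "",
) -> ReadConversionProfile:
    """Classify every reference cytosine under an ungapped read.

    ``start`` is the 0-based leftmost reference position of the read.
    """
    if start < 0 or start + len(read_seq) > len(reference):
        raise AlignmentConsistencyError(
            f"read {read_id!r} [{start}, {start + len(read_seq)}) extends "
            f"outside reference of length {len(reference)}"
        )
    positions: list[int] = []
    statuses: list[str] = []
    for offset, ref_base in enumerate(reference[start : start + len(read_seq)]):
        if ref_base != "C":
            continue
        positions.append(start + offset)
        base = read_seq[offset]
        if base == "T":
            statuses.append(CONVERTED)
        elif base == "C":
            statuses.append(UNCONVERTED)
        else:
            statuses.append(OTHER)
    return ReadConversionProfile(read_id, transcript_id, start, positions, statuses)


def apply_3c_filter(
    profiles: Iterable[ReadConversionProfile], max_unconverted: int = 3
) -> tuple[list[ReadConversionProfile], list[ReadConversionProfile]]:
    """Partition reads into (passing, failing) by the 3C rule.

    A read fails iff it carries more than ``max_unconverted`` unconverted
    cytosines; the partition is exhaustive and disjoint, and the filter is
    idempotent.
    """
    passing: list[ReadConversionProfile] = []
    failing: list[ReadConversionProfile] = []
    for p in profiles:
        (failing if p.n_unconverted > max_unconverted else passing).append(p)
    return passing, failing


def estimate_conversion_rate(
    spike_profiles: Iterable[ReadConversionProfile], library_id: str = ""
) -> ConversionRateEstimate:
    """Estimate the bisulfite conversion rate from unmethylated spike-in reads.

    Every cytosine observation on the spike-in control counts (the 3C
    filter is *not* applied here): rate = converted / (converted +
    unconverted). Mismatch ("other") bases are excluded.
    """
    converted = unconverted = 0
    for p in spike_profiles:
        for s in p.statuses:
            if s == CONVERTED:
                converted += 1
            elif s == UNCONVERTED:
                unconverted += 1
    total = converted + unconverted
    if total == 0:
        raise EstimationError(
            "no spike-in cytosine observations; use the configured default "
            "conversion rate"
        )
    return ConversionRateEstimate(library_id, total, converted)


def build_pileup(
    passing: Sequence[ReadConversionProfile],
    failing: Sequence[ReadConversionProfile] = (),
) -> pd.DataFrame:
    """Per-cytosine pileup from profiled reads.

    ``coverage_pass`` and the methylated depth ``k`` count 3C-passing reads
    only (mismatch bases excluded from both); ``coverage_all`` counts every
    profiled read covering the site, passing or failing. Returns a frame
    with columns transcript_id, position, coverage_all, coverage_pass, k.
    """
    cov_all: dict[tuple[str, int], int] = {}
    cov_pass: dict[tuple[str, int], int] = {}
    meth: dict[tuple[str, int], int] = {}
    for group, is_pass in ((passing, True), (failing, False)):
        for p in group:
            for pos, status in zip(p.cytosine_positions, p.statuses):
                key = (p.transcript_id, pos)
                cov_all[key] = cov_all.get(key, 0) + 1
                if is_pass and status != OTHER:
                    cov_pass[key] = cov_pass.get(key, 0) + 1
                    if status == UNCONVERTED:
                        meth[key] = meth.get(key, 0) + 1
    rows = [
        (tid, pos, cov_all[(tid, pos)], cov_pass.get((tid, pos), 0),
         meth.get((tid, pos), 0))
        for tid, pos in sorted(cov_all)
    ]
    return pd.DataFrame(
        rows, columns=["transcript_id", "position", "coverage_all",
                       "coverage_pass", "k"]
    )


def process_library(
    sam_path: str | Path,
    references: Mapping[str, str],
    max_unconverted: int = 3,
    library_id: str | None = None,
    default_conversion_rate: float | None = None,
) -> tuple[pd.DataFrame, ConversionRateEstimate, LibraryStats]:
    """Stream one SAM/BAM library into a pileup and a conversion estimate.

    Antisense alignments (FLAG 0x10) and non-uniquely aligned reads (MAPQ 0
    or secondary/supplementary flags) are skipped and tallied. Reads on
    spike-in references (ID prefix ``SPIKE_``) feed the conversion-rate
    estimate and are excluded from the pileup. If the library has no
    spike-in observations and ``default_conversion_rate`` is given, a
    degenerate estimate at that rate is returned instead of raising.

    This is the fast vectorised equivalent of profiling each read with
    :func:`profile_read_conversions`, applying :func:`apply_3c_filter` and
    :func:`build_pileup`; equality of the two routes is asserted in the
    test suite on small libraries.
    """
    sam_path = Path(sam_path)
    if library_id is None:
        library_id = sam_path.stem
    ref_arrays = {
        tid: np.frombuffer(seq.encode(), dtype=np.uint8)
        for tid, seq in references.items()
    }
    c_positions = {tid: np.nonzero(arr == _C)[0] for tid, arr in ref_arrays.items()}
    # per-transcript accumulators over cytosine positions
    acc: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    stats = LibraryStats()
    spike_conv = spike_unconv = 0

    mode = "rb" if sam_path.suffix == ".bam" else "r"
    with pysam.AlignmentFile(str(sam_path), mode, check_sq=False) as fh:
        for read in fh:
            stats.n_records += 1
            if read.is_unmapped:
                continue
            if read.is_secondary or read.is_supplementary or read.mapping_quality == 0:
                stats.n_nonunique_skipped += 1
                continue
            if read.is_reverse:
                stats.n_antisense_skipped += 1
                continue
            tid = read.reference_name
            if tid not in ref_arrays:
                raise AlignmentConsistencyError(f"read aligned to unknown reference {tid}")
            seq = read.query_sequence
            start = read.reference_start
            ref_arr = ref_arrays[tid]
            if start + len(seq) > ref_arr.size:
                raise AlignmentConsistencyError(
                    f"read {read.query_name} extends past end of {tid}"
                )
            cpos = c_positions[tid]
            lo = np.searchsorted(cpos, start)
            hi = np.searchsorted(cpos, start + len(seq))
            window = cpos[lo:hi]
            bases = np.frombuffer(seq.encode(), dtype=np.uint8)[window - start]
            unconv = bases == _C
            conv = bases == _T
            if tid.startswith(SPIKE_PREFIX):
                stats.n_spike_reads += 1
                spike_conv += int(conv.sum())
                spike_unconv += int(unconv.sum())
                continue
            stats.n_profiled += 1
            if tid not in acc:
                size = c_positions[tid].size
                acc[tid] = (
                    np.zeros(size, dtype=np.int64),  # coverage_all
                    np.zeros(size, dtype=np.int64),  # coverage_pass
                    np.zeros(size, dtype=np.int64),  # k
                )
            cov_all, cov_pass, meth = acc[tid]
            idx = np.arange(lo, hi)
            cov_all[idx] += 1
            if int(unconv.sum()) > max_unconverted:
                stats.n_failed_3c += 1
                continue
            informative = conv | unconv
            cov_pass[idx[informative]] += 1
            meth[idx[unconv]] += 1

    if spike_conv + spike_unconv == 0:
        if default_conversion_rate is None:
            raise EstimationError(
                "no spike-in cytosine observations; pass "
                "default_conversion_rate to proceed"
            )
        est = ConversionRateEstimate(
            library_id, 0, 0, rate_override=default_conversion_rate
        )
    else:
        est = ConversionRateEstimate(
            library_id, spike_conv + spike_unconv, spike_conv
        )

    frames = []
    for tid in sorted(acc):
        cov_all, cov_pass, meth = acc[tid]
        covered = cov_all > 0
        if not covered.any():
            continue
        frames.append(pd.DataFrame({
            "transcript_id": tid,
            "position": c_positions[tid][covered],
            "coverage_all": cov_all[covered],
            "coverage_pass": cov_pass[covered],
            "k": meth[covered],
        }))
    if frames:
        pileup = pd.concat(frames, ignore_index=True)
    else:
        pileup = pd.DataFrame(columns=["transcript_id", "position",
                                       "coverage_all", "coverage_pass", "k"])
    return pileup, est, stats


def write_pileup_tsv(pileup: pd.DataFrame, path: str | Path) -> None:
    pileup.to_csv(path, sep="\t", index=False)


def read_pileup_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
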