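"""Feature annotation, metagene profiling, sequence context, level summary.

mRNA sites are assigned to 5'UTR / CDS / 3'UTR by position against the
transcript's segmentation (half-open boundaries: position == utr5_len is
the first CDS base); sites on any other biotype are ncRNA. The metagene
profile divides the three mRNA features into 5, 18 and 22 bins
respectively — bin widths reflecting transcriptome-average feature
lengths — and reports per-bin site percentages with a centred moving
average. The sequence-context matrix tallies base composition at offsets
-5..+5 around each site, where the published sites show a downstream
(A/G)GGG-rich context.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import TranscriptModel

FEATURES = ("5UTR", "CDS", "3UTR")
METAGENE_BINS = {"5UTR": 5, "CDS": 18, "3UTR": 22}
N_BINS = sum(METAGENE_BINS.values())  # 45
_FEATURE_OFFSET = {"5UTR": 0, "CDS": 5, "3UTR": 23}


class AnnotationError(ValueError):
    pass


def annotate_site(
    transcript: TranscriptModel, position: int
) -> tuple[str, float]:
    """(feature, relative position in [0, 1)) for one site."""
    if not 0 <= position < transcript.length:
        raise AnnotationError(
            f"position {position} outside {transcript.transcript_id} "
            f"(length {transcript.length})"
        )
    if transcript.biotype != "mRNA":
        return "ncRNA", position / transcript.length
    u5, cds = transcript.utr5_len, transcript.cds_len
    if position < u5:
        return "5UTR", position / u5
    if position < u5 + cds:
        return "CDS", (position - u5) / cds
    return "3UTR", (position - u5 - cds) / transcript.utr3_len


def annotate_sites(
    sites: pd.DataFrame, transcripts: Mapping[str, TranscriptModel] | Sequence[TranscriptModel]
) -> pd.DataFrame:
    """Add ``feature`` and ``relative_position`` columns to a site table."""
    if not isinstance(transcripts, Mapping):
        transcripts = {t.transcript_id: t for t in transcripts}
    feats, rels = [], []
    for row in sites.itertuples(index=False):
        t = transcripts.get(row.transcript_id)
        if t is None:
            raise AnnotationError(f"unknown transcript {row.transcript_id}")
        feature, rel = annotate_site(t, int(row.position))
        feats.append(feature)
        rels.append(rel)
    out = sites.copy()
    out["feature"] = feats
    out["relative_position"] = rels
    return out


def metagene_bin(feature: str, relative_position: float) -> int:
    """45-bin index (5'UTR 0-4, CDS 5-22, 3'UTR 23-44), clamped per feature."""
    if feature not in METAGENE_BINS:
        raise AnnotationError(f"not an mRNA feature: {feature}")
    n = METAGENE_BINS[feature]
    local = min(int(np.floor(relative_position * n)), n - 1)
    return _FEATURE_OFFSET[feature] + local


def metagene_profile(
    annotated: pd.DataFrame, smoothing_window: int = 3
) -> pd.DataFrame:
    """Per-bin site counts, percentages and a moving average.

    Only mRNA sites (feature in 5UTR/CDS/3UTR) enter the profile. Returns
    a 45-row frame with columns bin, feature, count, pct, smoothed_pct;
    percentages sum to 100 over the profile, and the smoothed track is a
    centred moving average of width ``smoothing_window`` with truncated
    edges.
    """
    mask = annotated["feature"].isin(FEATURES)
    counts = np.zeros(N_BINS, dtype=np.int64)
    for row in annotated.loc[mask].itertuples(index=False):
        counts[metagene_bin(row.feature, float(row.relative_position))] += 1
    total = counts.sum()
    pct = counts / total * 100.0 if total else np.zeros(N_BINS)
    half = smoothing_window // 2
    smoothed = np.array([
        pct[max(0, i - half): i + half + 1].mean() for i in range(N_BINS)
    ])
    feature_col = (
        ["5UTR"] * METAGENE_BINS["5UTR"]
        + ["CDS"] * METAGENE_BINS["CDS"]
        + ["3UTR"] * METAGENE_BINS["3UTR"]
    )
    return pd.DataFrame({
        "bin": np.arange(N_BINS),
        "feature": feature_col,
        "count": counts,
        "pct": pct,
        "smoothed_pct": smoothed,
    })


def motif_matrix(
    sites: pd.DataFrame,
    sequences: Mapping[str, str],
    flank: int = 5,
) -> pd.DataFrame:
    """Base-count matrix at offsets -flank..+flank around each site.

    Sites without a full flank on both sides are dropped (the dropped
    count is stored in ``df.attrs['n_dropped']``). Offset 0 is the
    methylated cytosine, so its column is all C by construction.
    """
    offsets = np.arange(-flank, flank + 1)
    counts = {b: np.zeros(offsets.size, dtype=np.int64) for b in "ACGT"}
    n_used = n_dropped = 0
    for row in sites.itertuples(index=False):
        seq = sequences[row.transcript_id]
        pos = int(row.position)
        if pos - flank < 0 or pos + flank >= len(seq):
            n_dropped += 1
            continue
        n_used += 1
        window = seq[pos - flank: pos + flank + 1]
        for j, base in enumerate(window):
            if base in counts:
                counts[base][j] += 1
    df = pd.DataFrame(counts, index=pd.Index(offsets, name="offset"))
    df.attrs["n_used"] = n_used
    df.attrs["n_dropped"] = n_dropped
    return df


def motif_frequencies(matrix: pd.DataFrame) -> pd.DataFrame:
    totals = matrix.sum(axis=1)
    return matrix.div(totals.replace(0, np.nan), axis=0)


def level_summary(levels: Sequence[float]) -> dict:
    """Median, tail fractions and a decile histogram of site levels."""
    arr = np.asarray(list(levels), dtype=float)
    if arr.size == 0:
        raise AnnotationError("no sites to summarise")
    hist, _ = np.histogram(arr, bins=np.linspace(0.0, 1.0, 11))
    return {
        "n_sites": int(arr.size),
        "median_level": float(np.median(arr)),
        "fraction_below_0.3": float(np.mean(arr < 0.3)),
        "fraction_above_0.5": float(np.mean(arr > 0.5)),
        "histogram": (hist / arr.size).tolist(),
    }
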