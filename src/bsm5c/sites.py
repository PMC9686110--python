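"""Candidate m5C scoring and the sequential filter cascade.

A candidate site is a covered cytosine with coverage n (3C-passing reads),
methylated depth k, level m = k/n, a one-sided binomial p-value against the
conversion-failure rate p0, a BH-adjusted q-value, and a signal/noise ratio
S = coverage_pass / coverage_all. The cascade retains a site iff

    n >= 20  and  m >= 0.1  and  k >= 6      (standard filter)
    and S > 0.9                              (signal/noise filter)
    and q < 0.05                             (FDR filter)

optionally followed by removal of sites inside predicted
conversion-resistant secondary-structure regions, and finally intersection
across biological replicates: only sites passing every filter in every
replicate of a condition are high-confidence, with a pooled level
sum(k)/sum(n) across replicates.

The binomial test is one-sided (upper tail): methylation can only inflate
the unconverted count. The BH family is the per-library candidates with
k >= 1; structural zeros (k = 0) are kept as candidates with p = q = 1 but
excluded from the multiple-testing family.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import ConfigError, FilterThresholds
from .stats import adjust_bh, binom_upper_tail_vec

CANDIDATE_COLUMNS = [
    "transcript_id", "position", "n", "k", "level", "signal_noise",
    "p_value", "q_value",
]


class DotBracketError(ValueError):
    """Unbalanced or malformed dot-bracket string."""


def score_candidates(pileup: pd.DataFrame, p0: float) -> pd.DataFrame:
    """Score every covered cytosine as a candidate site.

    ``pileup`` needs columns transcript_id, position, coverage_all,
    coverage_pass, k. Sites with no passing coverage are dropped; sites
    with k = 0 are retained with p = q = 1.
    """
    if not 0 <= p0 < 0.5:
        raise ConfigError(f"p0: must be in [0, 0.5), got {p0}")
    df = pileup.loc[pileup["coverage_pass"] >= 1].copy()
    df = df.rename(columns={"coverage_pass": "n"})
    df["level"] = df["k"] / df["n"]
    df["signal_noise"] = df["n"] / df["coverage_all"]
    df["p_value"] = binom_upper_tail_vec(
        df["k"].to_numpy(), df["n"].to_numpy(), p0
    )
    df["q_value"] = 1.0
    tested = df["k"].to_numpy() >= 1
    if tested.any():
        df.loc[tested, "q_value"] = adjust_bh(df.loc[tested, "p_value"])
    return df.reset_index(drop=True)[
        ["transcript_id", "position", "coverage_all"] + CANDIDATE_COLUMNS[2:]
    ]


def filter_cascade(
    candidates: pd.DataFrame, thresholds: FilterThresholds | None = None
) -> pd.DataFrame:
    """Apply the standard, signal/noise and FDR filters.

    Adds a ``passed`` flag and a ``fail_stage`` column naming the first
    failing stage in reporting order (standard -> signal_noise -> fdr);
    survival itself is order-independent.
    """
    th = (thresholds or FilterThresholds()).validate()
    df = candidates.copy()
    standard = (
        (df["n"] >= th.min_coverage)
        & (df["level"] >= th.min_level)
        & (df["k"] >= th.min_meth_depth)
    )
    signal = df["signal_noise"] > th.min_signal_noise
    fdr = df["q_value"] < th.max_fdr
    df["pass_standard"] = standard
    df["pass_signal_noise"] = signal
    df["pass_fdr"] = fdr
    df["passed"] = standard & signal & fdr
    stage = np.full(len(df), "", dtype=object)
    stage[~fdr.to_numpy()] = "fdr"
    stage[~signal.to_numpy()] = "signal_noise"
    stage[~standard.to_numpy()] = "standard"
    df["fail_stage"] = stage
    return df


def parse_dot_bracket(structure: str) -> list[tuple[int, int]]:
    """Base-pair list (i, j), 0-based, from a dot-bracket string."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise DotBracketError(f"unbalanced ')' at position {i}")
            pairs.append((stack.pop(), i))
        elif ch != ".":
            raise DotBracketError(f"unexpected character {ch!r} at position {i}")
    if stack:
        raise DotBracketError(f"unclosed '(' at position {stack[-1]}")
    return sorted(pairs)


def paired_positions(structure: str, offset: int = 0) -> set[int]:
    """All base-paired positions of a dot-bracket, shifted by ``offset``."""
    out: set[int] = set()
    for i, j in parse_dot_bracket(structure):
        out.add(offset + i)
        out.add(offset + j)
    return out


def structure_filter(
    sites: pd.DataFrame,
    mask_bed: pd.DataFrame | None = None,
    dot_brackets: Mapping[str, tuple[int, str]] | None = None,
) -> pd.DataFrame:
    """Remove sites inside conversion-resistant regions.

    ``mask_bed`` holds 0-based half-open intervals (transcript_id, start,
    end); ``dot_brackets`` maps transcript_id -> (offset, structure), in
    which case a site is removed iff its cytosine is base-paired.
    """
    if sites.empty:
        return sites.copy()
    remove = np.zeros(len(sites), dtype=bool)
    if mask_bed is not None and len(mask_bed):
        for tid, grp in mask_bed.groupby("transcript_id"):
            sel = sites["transcript_id"] == tid
            if not sel.any():
                continue
            pos = sites.loc[sel, "position"].to_numpy()
            hit = np.zeros(pos.size, dtype=bool)
            for start, end in grp[["start", "end"]].itertuples(index=False):
                hit |= (pos >= start) & (pos < end)
            remove[sel.to_numpy()] |= hit
    if dot_brackets:
        for tid, (offset, structure) in dot_brackets.items():
            sel = sites["transcript_id"] == tid
            if not sel.any():
                continue
            masked = paired_positions(structure, offset)
            pos = sites.loc[sel, "position"].to_numpy()
            remove[sel.to_numpy()] |= np.isin(pos, list(masked))
    return sites.loc[~remove].reset_index(drop=True)


def intersect_replicates(replicates: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """High-confidence sites: present (and passing) in every replicate.

    Input frames are per-replicate *surviving* candidates (after the
    cascade and any structure filter). Returns one row per shared site
    with per-replicate counts pooled: pooled_level = sum(k) / sum(n).
    """
    if len(replicates) < 2:
        raise ValueError("need at least 2 replicates to intersect")
    keyed = []
    for df in replicates:
        if df.empty:
            sub = pd.DataFrame(
                columns=["transcript_id", "position", "n", "k", "level"]
            )
        else:
            sub = df[["transcript_id", "position", "n", "k", "level"]].copy()
        keyed.append(sub.set_index(["transcript_id", "position"]))
    shared = keyed[0].index
    for other in keyed[1:]:
        shared = shared.intersection(other.index)
    if len(shared) == 0:
        return pd.DataFrame(columns=["transcript_id", "position", "pooled_n",
                                     "pooled_k", "pooled_level"])
    rows = []
    for tid, pos in sorted(shared):
        n = sum(int(df.loc[(tid, pos), "n"]) for df in keyed)
        k = sum(int(df.loc[(tid, pos), "k"]) for df in keyed)
        row = {"transcript_id": tid, "position": pos, "pooled_n": n,
               "pooled_k": k, "pooled_level": k / n}
        for i, df in enumerate(keyed, start=1):
            row[f"level_R{i}"] = float(df.loc[(tid, pos), "level"])
        rows.append(row)
    return pd.DataFrame(rows)


def replicate_concordance(
    rep_a: pd.DataFrame, rep_b: pd.DataFrame
) -> dict[str, float]:
    """Between-replicate overlap and level agreement.

    Reports set sizes, overlap fractions relative to each replicate,
    Pearson correlation of levels on shared sites (NaN when fewer than two
    shared sites), and mean levels of shared vs replicate-specific sites.
    """
    a = rep_a.set_index(["transcript_id", "position"])
    b = rep_b.set_index(["transcript_id", "position"])
    shared = a.index.intersection(b.index)
    n_a, n_b, n_shared = len(a), len(b), len(shared)
    result = {
        "n_a": n_a,
        "n_b": n_b,
        "n_shared": n_shared,
        "frac_of_a": n_shared / n_a if n_a else float("nan"),
        "frac_of_b": n_shared / n_b if n_b else float("nan"),
    }
    if n_shared >= 2:
        la = a.loc[shared, "level"].to_numpy(float)
        lb = b.loc[shared, "level"].to_numpy(float)
        if np.std(la) > 0 and np.std(lb) > 0:
            result["pearson_r"] = float(sps.pearsonr(la, lb)[0])
        else:
            result["pearson_r"] = float("nan")
    else:
        result["pearson_r"] = float("nan")
    shared_levels = []
    specific_levels = []
    for df, other_index in ((a, b.index), (b, a.index)):
        in_other = df.index.isin(other_index)
        shared_levels.append(df.loc[in_other, "level"].to_numpy(float))
        specific_levels.append(df.loc[~in_other, "level"].to_numpy(float))
    shared_all = np.concatenate(shared_levels) if shared_levels else np.array([])
    spec_all = np.concatenate(specific_levels) if specific_levels else np.array([])
    result["mean_level_shared"] = (
        float(shared_all.mean()) if shared_all.size else float("nan")
    )
    result["mean_level_specific"] = (
        float(spec_all.mean()) if spec_all.size else float("nan")
    )
    return result


def call_condition_sites(
    pileups: Sequence[pd.DataFrame],
    p0s: Sequence[float] | float,
    thresholds: FilterThresholds | None = None,
    mask_bed: pd.DataFrame | None = None,
    dot_brackets: Mapping[str, tuple[int, str]] | None = None,
) -> tuple[pd.DataFrame, list[pd.DataFrame]]:
    """Full per-condition calling: score, cascade, structure filter and
    replicate intersection.

    ``p0s`` is the per-replicate conversion-failure rate (or one value for
    all). Returns (high_confidence, per_replicate_survivors).
    """
    if isinstance(p0s, float):
        p0s = [p0s] * len(pileups)
    if len(p0s) != len(pileups):
        raise ValueError("need one p0 per replicate pileup")
    survivors = []
    for pileup, p0 in zip(pileups, p0s):
        cand = score_candidates(pileup, p0)
        filt = filter_cascade(cand, thresholds)
        surv = filt.loc[filt["passed"]].reset_index(drop=True)
        surv = structure_filter(surv, mask_bed, dot_brackets)
        survivors.append(surv)
    high_conf = intersect_replicates(survivors)
    return high_conf, survivors


def write_sites_tsv(sites: pd.DataFrame, path) -> None:
    sites.to_csv(path, sep="\t", index=False)


def write_sites_bed(high_conf: pd.DataFrame, path) -> None:
    """BED6 of high-confidence sites, score = pooled level x 1000."""
    with open(path, "w") as fh:
        for row in high_conf.itertuples(index=False):
            score = int(round(row.pooled_level * 1000))
            fh.write(
                f"{row.transcript_id}\t{row.position}\t{row.position + 1}\t"
                f"m5C\t{score}\t+\n"
            )
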