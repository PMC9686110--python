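"""Differential m5C methylation between conditions.

Per-site 2x2 Fisher's exact tests on pooled (methylated, unmethylated)
counts, with the published eligibility rules: a site is tested only if it
has coverage >= 20 in every library involved in the comparison and is
methylated (a high-confidence site) in at least one of the two conditions.
BH correction runs across the eligible sites; adjusted p < 0.05 defines a
differentially methylated site (DMS). Replicate counts are pooled within
condition before testing.

The module also implements the paired total-vs-polysome comparison: on
sites that are high-confidence in either methylome and covered >= 20 in
both, a Wilcoxon signed-rank test asks whether polysome-associated mRNAs
are hypermethylated relative to total mRNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .stats import adjust_bh, fisher_exact_2x2, paired_signed_rank

__all__ = [
    "ComparisonSpec",
    "pool_pileups",
    "call_dms",
    "compare_total_polysome",
]


@dataclass
class ComparisonSpec:
    condition_a: str = "A"
    condition_b: str = "B"
    min_coverage: int = 20
    max_fdr: float = 0.05


def pool_pileups(pileups: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Sum passing coverage and methylated depth across replicate pileups."""
    frames = [
        p[["transcript_id", "position", "coverage_pass", "k"]] for p in pileups
    ]
    cat = pd.concat(frames, ignore_index=True)
    pooled = cat.groupby(["transcript_id", "position"]).sum()
    return pooled.rename(columns={"coverage_pass": "n"})


def _per_library_coverage(pileups: Sequence[pd.DataFrame]) -> list[pd.Series]:
    return [
        p.set_index(["transcript_id", "position"])["coverage_pass"]
        for p in pileups
    ]


def call_dms(
    pileups_a: Sequence[pd.DataFrame],
    pileups_b: Sequence[pd.DataFrame],
    high_conf_a: pd.DataFrame,
    high_conf_b: pd.DataFrame,
    spec: ComparisonSpec | None = None,
) -> pd.DataFrame:
    """Fisher + BH differential methylation between two conditions.

    Returns one row per eligible site with pooled counts, levels,
    ``fisher_p``, ``q_value``, ``direction`` (hyper iff the level in
    condition A exceeds B) and a ``significant`` flag (q < max_fdr).
    An empty frame (with columns) is returned when no site is eligible.
    """
    spec = spec or ComparisonSpec()
    columns = [
        "transcript_id", "position", "k_a", "n_a", "k_b", "n_b",
        "level_a", "level_b", "fisher_p", "q_value", "direction",
        "significant",
    ]

    def hc_index(df: pd.DataFrame) -> pd.MultiIndex:
        if df.empty:
            return pd.MultiIndex.from_tuples([], names=["transcript_id", "position"])
        return pd.MultiIndex.from_frame(df[["transcript_id", "position"]])

    universe = hc_index(high_conf_a).union(hc_index(high_conf_b))
    if len(universe) == 0:
        return pd.DataFrame(columns=columns)

    pooled_a = pool_pileups(pileups_a)
    pooled_b = pool_pileups(pileups_b)
    cov_libs = _per_library_coverage(pileups_a) + _per_library_coverage(pileups_b)

    rows = []
    for key in sorted(universe):
        if key not in pooled_a.index or key not in pooled_b.index:
            continue
        if any(
            key not in cov.index or cov.loc[key] < spec.min_coverage
            for cov in cov_libs
        ):
            continue
        n_a, k_a = int(pooled_a.loc[key, "n"]), int(pooled_a.loc[key, "k"])
        n_b, k_b = int(pooled_b.loc[key, "n"]), int(pooled_b.loc[key, "k"])
        level_a = k_a / n_a if n_a else 0.0
        level_b = k_b / n_b if n_b else 0.0
        p = fisher_exact_2x2([[k_a, n_a - k_a], [k_b, n_b - k_b]])
        rows.append({
            "transcript_id": key[0], "position": key[1],
            "k_a": k_a, "n_a": n_a, "k_b": k_b, "n_b": n_b,
            "level_a": level_a, "level_b": level_b, "fisher_p": p,
            "direction": "hyper" if level_a > level_b else "hypo",
        })
    if not rows:
        return pd.DataFrame(columns=columns)
    df = pd.DataFrame(rows)
    df["q_value"] = adjust_bh(df["fisher_p"])
    df["significant"] = df["q_value"] < spec.max_fdr
    return df[columns]


def replicate_level_matrix(
    pileups_a: Sequence[pd.DataFrame],
    pileups_b: Sequence[pd.DataFrame],
    dms: pd.DataFrame,
    labels: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Heatmap-ready per-replicate levels at DMS sites (rows = sites,
    columns = <condition>_R<i>)."""
    out = dms[["transcript_id", "position"]].copy()
    for label, pileups in zip(labels, (pileups_a, pileups_b)):
        for i, p in enumerate(pileups, start=1):
            idx = p.set_index(["transcript_id", "position"])
            levels = []
            for key in zip(out["transcript_id"], out["position"]):
                if key in idx.index and idx.loc[key, "coverage_pass"] > 0:
                    levels.append(
                        float(idx.loc[key, "k"] / idx.loc[key, "coverage_pass"])
                    )
                else:
                    levels.append(float("nan"))
            out[f"{label}_R{i}"] = levels
    return out


def compare_total_polysome(
    pileups_total: Sequence[pd.DataFrame],
    pileups_polysome: Sequence[pd.DataFrame],
    high_conf_total: pd.DataFrame,
    high_conf_polysome: pd.DataFrame,
    min_coverage: int = 20,
) -> dict:
    """Paired signed-rank comparison of methylation in polysome vs total.

    Site universe: high-confidence in either methylome, with pooled
    coverage >= ``min_coverage`` in both. Levels are pooled within each
    methylome; a positive median difference means polysome
    hypermethylation. Returns the signed-rank result dict plus the number
    of eligible sites.
    """
    def hc_index(df: pd.DataFrame) -> pd.MultiIndex:
        if df.empty:
            return pd.MultiIndex.from_tuples([], names=["transcript_id", "position"])
        return pd.MultiIndex.from_frame(df[["transcript_id", "position"]])

    universe = hc_index(high_conf_total).union(hc_index(high_conf_polysome))
    pooled_t = pool_pileups(pileups_total)
    pooled_p = pool_pileups(pileups_polysome)
    lv_t, lv_p = [], []
    for key in sorted(universe):
        if key not in pooled_t.index or key not in pooled_p.index:
            continue
        n_t = int(pooled_t.loc[key, "n"])
        n_p = int(pooled_p.loc[key, "n"])
        if n_t < min_coverage or n_p < min_coverage:
            continue
        lv_t.append(pooled_t.loc[key, "k"] / n_t)
        lv_p.append(pooled_p.loc[key, "k"] / n_p)
    result = paired_signed_rank(lv_t, lv_p)
    result["n_sites"] = len(lv_t)
    return result
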