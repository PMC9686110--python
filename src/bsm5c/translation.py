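"""Translation efficiency from total/polysome count matrices.

TE for a gene is the ratio of its normalized polysome-fraction abundance
to its normalized total-mRNA abundance (TE = polysome/total), and TE fold
changes between conditions are ratios of these ratios. Significance comes
from a self-contained negative-binomial Wald engine:

* median-of-ratios size factors absorb library size;
* per-gene NB dispersion by within-group method of moments, shrunk toward
  a fitted mean-dispersion trend a0 + a1/mu;
* per-group NB mean MLE by Newton iteration with size-factor offsets;
* Wald tests on log-mean contrasts — a two-group contrast for
  differential expression (and polysome-vs-total translation classes), a
  fraction x condition interaction contrast for differential TE.

Decision rules follow the published thresholds: a differentially
expressed/translated gene needs fold change > 1.2 and BH-adjusted
p < 0.05; TE testing requires a mean count >= 1 (minMeanCount). Fold
changes are reported from normalized means with a half-count pseudocount
(reporting only — tests use the raw MLE contrast), so zero counts never
produce infinite log2 fold changes.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import ConfigError
from .stats import adjust_bh

_MIN_Q = 1e-12
_PRIOR_DF = 6.0
_MAX_ALPHA = 10.0


class NormalizationError(RuntimeError):
    pass


def size_factors(matrix: pd.DataFrame, pseudocount: float = 0.0) -> pd.Series:
    """Median-of-ratios size factors (one per sample/column).

    Uses genes with all-positive counts as the reference set; if none
    exist, raises unless a ``pseudocount`` > 0 is supplied.
    """
    counts = matrix.to_numpy(dtype=float) + pseudocount
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise NormalizationError(
            "no gene has positive counts in every sample; retry with a "
            "pseudocount (size_factors(matrix, pseudocount=0.5))"
        )
    ref = counts[all_positive]
    geo_mean = np.exp(np.log(ref).mean(axis=1))
    factors = np.median(ref / geo_mean[:, None], axis=0)
    return pd.Series(factors, index=matrix.columns, name="size_factor")


def expressed_genes(
    matrix: pd.DataFrame, sample_columns: Sequence[str] | None = None,
    min_count: int = 1,
) -> pd.Index:
    """Union of genes detected (count >= min_count) in any listed sample.

    Mirrors compiling the expressed-gene list as the union of genes seen
    in the replicates.
    """
    cols = list(sample_columns) if sample_columns is not None else list(matrix.columns)
    detected = (matrix[cols] >= min_count).any(axis=1)
    return matrix.index[detected]


def _group_mom_dispersion(
    norm: np.ndarray, groups: list[np.ndarray]
) -> np.ndarray:
    """Per-gene method-of-moments dispersion pooled over replicate groups.

    For each group with >= 2 samples: alpha_g = (var - mean) / mean^2 on
    normalized counts; groups are combined by degrees of freedom. Genes
    where the estimate is undefined get NaN.
    """
    n_genes = norm.shape[0]
    num = np.zeros(n_genes)
    den = np.zeros(n_genes)
    for cols in groups:
        if cols.size < 2:
            continue
        sub = norm[:, cols]
        mean = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        df = cols.size - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (var - mean) / mean**2
        ok = np.isfinite(a)
        num[ok] += df * a[ok]
        den[ok] += df
    out = np.full(n_genes, np.nan)
    pos = den > 0
    out[pos] = num[pos] / den[pos]
    return out


def _dispersion_trend(mean: np.ndarray, alpha_mom: np.ndarray) -> np.ndarray:
    """Fit alpha ~ a0 + a1/mu on informative genes; return per-gene trend."""
    use = np.isfinite(alpha_mom) & (alpha_mom > 0) & (mean > 5)
    if use.sum() < 20:
        base = np.nanmedian(np.clip(alpha_mom, 1e-6, _MAX_ALPHA))
        if not np.isfinite(base):
            base = 0.01
        return np.full(mean.shape, max(base, 1e-4))
    x = 1.0 / mean[use]
    y = alpha_mom[use]
    for _ in range(2):  # one trimming pass against outliers
        A = np.stack([np.ones_like(x), x], axis=1)
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        keep = np.abs(resid) <= 3 * np.std(resid)
        if keep.all():
            break
        x, y = x[keep], y[keep]
    a0 = max(float(coef[0]), 1e-4)
    a1 = max(float(coef[1]), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        trend = a0 + a1 / mean
    trend[~np.isfinite(trend)] = a0
    return np.clip(trend, 1e-4, _MAX_ALPHA)


def estimate_dispersions(
    matrix: pd.DataFrame,
    factors: pd.Series,
    groups: list[list[str]],
) -> pd.Series:
    """Trend-shrunk per-gene NB dispersions.

    The raw method-of-moments value (replicate-level degrees of freedom,
    so very noisy) is shrunk toward the fitted trend with a prior weight
    of ``_PRIOR_DF`` pseudo-degrees of freedom.
    """
    norm = matrix.to_numpy(float) / factors.loc[matrix.columns].to_numpy()
    col_index = {c: i for i, c in enumerate(matrix.columns)}
    group_cols = [np.array([col_index[s] for s in g]) for g in groups]
    alpha_mom = _group_mom_dispersion(norm, group_cols)
    mean = norm.mean(axis=1)
    trend = _dispersion_trend(mean, alpha_mom)
    df = sum(max(0, g.size - 1) for g in group_cols)
    mom = np.clip(np.nan_to_num(alpha_mom, nan=0.0), 0.0, _MAX_ALPHA)
    has_mom = np.isfinite(alpha_mom)
    shrunk = np.where(
        has_mom,
        (df * mom + _PRIOR_DF * trend) / (df + _PRIOR_DF),
        trend,
    )
    return pd.Series(np.clip(shrunk, 1e-8, _MAX_ALPHA), index=matrix.index,
                     name="dispersion")


def _fit_group(
    counts: np.ndarray, sf: np.ndarray, alpha: np.ndarray, n_iter: int = 30
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised NB mean MLE per gene for one sample group.

    Model: K_j ~ NB(s_j * q, alpha). Returns (q, fisher_info) where the
    information is for beta = ln q. Genes with all-zero counts get q = 0
    and info 0.
    """
    q = counts.sum(axis=1) / sf.sum()
    positive = q > 0
    q = np.where(positive, q, _MIN_Q)
    a = alpha[:, None]
    s = sf[None, :]
    for _ in range(n_iter):
        mu = s * q[:, None]
        denom = 1.0 + a * mu
        f = ((counts - mu) / denom).sum(axis=1)
        fprime = ((-s * denom - (counts - mu) * a * s) / denom**2).sum(axis=1)
        step = np.where(fprime != 0, f / fprime, 0.0)
        q_new = q - step
        q = np.where((q_new > 0) & np.isfinite(q_new), q_new, q / 2.0)
    mu = s * q[:, None]
    info = (mu / (1.0 + a * mu)).sum(axis=1)
    q = np.where(positive, q, 0.0)
    info = np.where(positive, info, 0.0)
    return q, info


def nb_wald_de(
    matrix: pd.DataFrame,
    samples_a: list[str],
    samples_b: list[str],
    expressed: pd.Index | Sequence | None = None,
    fc_threshold: float = 1.2,
    max_fdr: float = 0.05,
    apply_fc_threshold: bool = True,
) -> pd.DataFrame:
    """Two-group NB Wald differential expression (A vs B).

    Returns per-gene base_mean (mean normalized count), log2_fold_change
    (pseudocounted, A over B), p, q, ``tested`` and ``significant``
    (|FC| > fc_threshold if ``apply_fc_threshold`` and q < max_fdr).
    Genes outside ``expressed`` are excluded entirely; genes with all-zero
    counts in either group are reported but not tested.
    """
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ConfigError("samples: need >= 2 samples per group")
    if expressed is not None:
        matrix = matrix.loc[matrix.index.intersection(pd.Index(expressed))]
    sub = matrix[list(samples_a) + list(samples_b)]
    factors = size_factors(sub)
    disp = estimate_dispersions(sub, factors, [list(samples_a), list(samples_b)])

    counts_a = sub[samples_a].to_numpy(float)
    counts_b = sub[samples_b].to_numpy(float)
    sf_a = factors.loc[samples_a].to_numpy()
    sf_b = factors.loc[samples_b].to_numpy()
    alpha = disp.to_numpy()
    q_a, info_a = _fit_group(counts_a, sf_a, alpha)
    q_b, info_b = _fit_group(counts_b, sf_b, alpha)

    norm_mean = (sub.to_numpy(float) / factors.to_numpy()[None, :]).mean(axis=1)
    log2fc = np.log2((q_a + 0.5) / (q_b + 0.5))
    tested = (q_a > 0) & (q_b > 0)
    p = np.full(len(sub), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(1.0 / np.where(info_a > 0, info_a, np.nan)
                     + 1.0 / np.where(info_b > 0, info_b, np.nan))
        z = (np.log(np.where(q_a > 0, q_a, np.nan))
             - np.log(np.where(q_b > 0, q_b, np.nan))) / se
    p[tested] = 2.0 * sps.norm.sf(np.abs(z[tested]))
    q_adj = np.full(len(sub), np.nan)
    if tested.any():
        q_adj[tested] = adjust_bh(p[tested])
    fc_ok = np.abs(log2fc) > np.log2(fc_threshold) if apply_fc_threshold else True
    significant = tested & (q_adj < max_fdr) & fc_ok
    return pd.DataFrame({
        "base_mean": norm_mean,
        "log2_fold_change": log2fc,
        "p": p,
        "q": q_adj,
        "tested": tested,
        "significant": significant,
    }, index=sub.index)


def _fraction_samples(samples: pd.DataFrame, condition: str, fraction: str) -> list[str]:
    sel = (samples["condition"] == condition) & (samples["fraction"] == fraction)
    return list(samples.index[sel])


def compute_te(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    condition: str,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene TE = mean normalized polysome / mean normalized total.

    Size factors are median-of-ratios over the condition's samples unless
    precomputed ``factors`` are given (joint normalization, so TE is
    relative to the median gene's polysome association). Genes with zero
    total signal get TE = NaN (flagged ``te_defined`` = False) and are
    excluded downstream.
    """
    total = _fraction_samples(samples, condition, "total")
    poly = _fraction_samples(samples, condition, "polysome")
    if not total or not poly:
        raise ConfigError(
            f"fraction: condition {condition} needs total and polysome samples"
        )
    cols = total + poly
    if factors is None:
        factors = size_factors(matrix[cols])
    factors = factors.loc[cols]
    norm = matrix[cols].to_numpy(float) / factors.to_numpy()[None, :]
    mean_total = norm[:, : len(total)].mean(axis=1)
    mean_poly = norm[:, len(total):].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        te = np.where(mean_total > 0, mean_poly / mean_total, np.nan)
    return pd.DataFrame({
        "mean_total": mean_total,
        "mean_polysome": mean_poly,
        "te": te,
        "te_defined": mean_total > 0,
    }, index=matrix.index)


def call_dtgs(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    treatment: str,
    control: str,
    min_mean_count: float = 1.0,
    fc_threshold: float = 1.2,
    max_fdr: float = 0.05,
) -> pd.DataFrame:
    """Differential translation between two conditions.

    te_log2fc is the ratio of TE ratios, log2(TE_treatment / TE_control),
    computed from pseudocounted normalized group means (the authoritative
    value for the 1.2-fold rule). Significance is a Wald test on the
    fraction x condition interaction of the NB model. A gene is a DTG iff
    its mean count >= ``min_mean_count``, |TE fold change| > fc_threshold
    in either direction and q < max_fdr.
    """
    group_names = [
        (treatment, "polysome"), (treatment, "total"),
        (control, "polysome"), (control, "total"),
    ]
    groups = [_fraction_samples(samples, c, f) for c, f in group_names]
    for (c, f), g in zip(group_names, groups):
        if not g:
            raise ConfigError(f"fraction: no {f} samples for condition {c}")
    cols = [s for g in groups for s in g]
    sub = matrix[cols]
    factors = size_factors(sub)
    disp = estimate_dispersions(sub, factors, groups)
    alpha = disp.to_numpy()

    fits = []
    for g in groups:
        qg, ig = _fit_group(
            sub[g].to_numpy(float), factors.loc[g].to_numpy(), alpha
        )
        fits.append((qg, ig))
    (q_tp, i_tp), (q_tt, i_tt), (q_cp, i_cp), (q_ct, i_ct) = fits

    norm_mean = (sub.to_numpy(float) / factors.to_numpy()[None, :]).mean(axis=1)
    te_treat = (q_tp + 0.5) / (q_tt + 0.5)
    te_ctrl = (q_cp + 0.5) / (q_ct + 0.5)
    te_log2fc = np.log2(te_treat / te_ctrl)

    all_pos = (q_tp > 0) & (q_tt > 0) & (q_cp > 0) & (q_ct > 0)
    tested = all_pos & (norm_mean >= min_mean_count)
    with np.errstate(divide="ignore", invalid="ignore"):
        interaction = (
            np.log(q_tp) - np.log(q_tt) - np.log(q_cp) + np.log(q_ct)
        )
        se = np.sqrt(sum(
            1.0 / np.where(i > 0, i, np.nan) for i in (i_tp, i_tt, i_cp, i_ct)
        ))
        z = interaction / se
    p = np.full(len(sub), np.nan)
    p[tested] = 2.0 * sps.norm.sf(np.abs(z[tested]))
    q_adj = np.full(len(sub), np.nan)
    if tested.any():
        q_adj[tested] = adjust_bh(p[tested])
    fc_ok = np.abs(te_log2fc) > np.log2(fc_threshold)
    dtg = tested & (q_adj < max_fdr) & fc_ok
    return pd.DataFrame({
        "base_mean": norm_mean,
        "te_log2fc": te_log2fc,
        "interaction_log2fc": interaction / np.log(2.0),
        "p": p,
        "q": q_adj,
        "tested": tested,
        "dtg": dtg,
        "direction": np.where(te_log2fc > 0, "up", "down"),
    }, index=sub.index)


def classify_translation(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    condition: str,
    expressed: pd.Index | Sequence | None = None,
    fc_threshold: float = 1.2,
    max_fdr: float = 0.05,
    apply_fc_threshold: bool = True,
) -> pd.DataFrame:
    """Per-gene translation class within one condition.

    Differential expression of polysome vs total samples: up-regulated in
    the polysome fraction = high translation efficiency, down-regulated =
    low, otherwise (including untested genes, by convention) = median.
    """
    poly = _fraction_samples(samples, condition, "polysome")
    total = _fraction_samples(samples, condition, "total")
    de = nb_wald_de(
        matrix, poly, total, expressed=expressed, fc_threshold=fc_threshold,
        max_fdr=max_fdr, apply_fc_threshold=apply_fc_threshold,
    )
    cls = np.where(
        de["significant"] & (de["log2_fold_change"] > 0), "high",
        np.where(de["significant"] & (de["log2_fold_change"] < 0), "low",
                 "median"),
    )
    out = de.copy()
    out["translation_class"] = cls
    return out
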