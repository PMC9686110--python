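"""Size factors, the NB Wald engine, TE computation and DTG calling."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from bsm5c.config import ConfigError
from bsm5c import simulate, translation as tr
from bsm5c.translation import (
    NormalizationError,
    call_dtgs,
    classify_translation,
    compute_te,
    expressed_genes,
    nb_wald_de,
    size_factors,
)


def _samples(conditions=("C", "T"), n_rep=2):
    rows = []
    for c in conditions:
        for f in ("total", "polysome"):
            for r in range(1, n_rep + 1):
                rows.append((f"{c}_{f}_R{r}", c, f, r))
    return pd.DataFrame(
        rows, columns=["sample", "condition", "fraction", "replicate"]
    ).set_index("sample")


class TestSizeFactors:
    def test_doubled_library_doubles_factor(self):
        a = np.array([10, 100, 50, 400])
        m = pd.DataFrame({"A": a, "B": 2 * a})
        f = size_factors(m)
        assert f["B"] / f["A"] == pytest.approx(2.0)

    def test_identical_samples_equal_factors(self):
        m = pd.DataFrame({"A": [5, 10, 20], "B": [5, 10, 20]})
        f = size_factors(m)
        assert f["A"] == pytest.approx(f["B"])

    def test_matches_naive_median_of_ratios(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.negative_binomial(10, 0.1, size=(200, 4)),
                         columns=list("ABCD"))
        f = size_factors(m)
        counts = m.to_numpy(float)
        ref_rows = counts[(counts > 0).all(axis=1)]
        geo = np.exp(np.mean(np.log(ref_rows), axis=1))
        for j, col in enumerate(m.columns):
            assert f[col] == pytest.approx(
                float(np.median(ref_rows[:, j] / geo))
            )

    def test_no_reference_gene_raises_then_pseudocount_recovers(self):
        m = pd.DataFrame({"A": [0, 5], "B": [5, 0]})
        with pytest.raises(NormalizationError):
            size_factors(m)
        f = size_factors(m, pseudocount=0.5)
        assert np.isfinite(f).all()


class TestNbWaldDe:
    def test_all_zero_gene_not_tested(self):
        m = pd.DataFrame({
            "A1": [0, 10], "A2": [0, 12], "B1": [0, 9], "B2": [0, 11],
        }, index=["dead", "alive"])
        de = nb_wald_de(m, ["A1", "A2"], ["B1", "B2"])
        assert not de.loc["dead", "tested"]
        assert de.loc["alive", "tested"]

    def test_excluded_gene_absent_from_output(self):
        m = pd.DataFrame({
            "A1": [5, 10], "A2": [6, 12], "B1": [5, 9], "B2": [6, 11],
        }, index=["g0", "g1"])
        de = nb_wald_de(m, ["A1", "A2"], ["B1", "B2"], expressed=["g1"])
        assert list(de.index) == ["g1"]

    def test_null_calibration(self):
        truth = simulate.generate_count_truth(
            2000, conditions=("C", "T"), seed=21,
            frac_expr_affected=0.0, frac_te_affected=0.0,
        )
        counts, samples = simulate.simulate_count_matrices(
            truth, ("C", "T"), 2, seed=21
        )
        a = [s for s in counts.columns if s.startswith("C_total")]
        b = [s for s in counts.columns if s.startswith("T_total")]
        de = nb_wald_de(counts, a, b)
        frac = float((de.loc[de["tested"], "p"] < 0.05).mean())
        assert 0.02 <= frac <= 0.08

    def test_planted_fold_change_power(self):
        hits = 0
        runs = 20
        for r in range(runs):
            truth = simulate.generate_count_truth(
                500, conditions=("C", "T"), seed=400 + r,
                frac_expr_affected=0.0, frac_te_affected=0.0,
            )
            truth.iloc[0, truth.columns.get_loc("base_mean")] = 500.0
            truth.iloc[0, truth.columns.get_loc("dispersion")] = 0.05
            truth.iloc[0, truth.columns.get_loc("expr_log2fc_T")] = 2.0
            counts, _ = simulate.simulate_count_matrices(
                truth, ("C", "T"), 2, seed=400 + r
            )
            a = [s for s in counts.columns if s.startswith("T_total")]
            b = [s for s in counts.columns if s.startswith("C_total")]
            de = nb_wald_de(counts, a, b)
            hits += bool(de["significant"].iloc[0]
                         and de["log2_fold_change"].iloc[0] > 0)
        assert hits / runs >= 0.95


class TestComputeTe:
    def test_ratio_with_unit_factors(self):
        m = pd.DataFrame({
            "C_total_R1": [50], "C_total_R2": [50],
            "C_polysome_R1": [100], "C_polysome_R2": [100],
        }, index=["g"])
        unit = pd.Series(1.0, index=m.columns)
        te = compute_te(m, _samples(("C",)), "C", factors=unit)
        assert te.loc["g", "te"] == pytest.approx(2.0)

    def test_zero_polysome_gives_zero(self):
        m = pd.DataFrame({
            "C_total_R1": [50, 10], "C_total_R2": [50, 10],
            "C_polysome_R1": [0, 10], "C_polysome_R2": [0, 10],
        }, index=["g", "ref"])
        te = compute_te(m, _samples(("C",)), "C")
        assert te.loc["g", "te"] == 0.0

    def test_zero_total_flagged_undefined(self):
        m = pd.DataFrame({
            "C_total_R1": [0, 10], "C_total_R2": [0, 10],
            "C_polysome_R1": [50, 10], "C_polysome_R2": [50, 10],
        }, index=["g", "ref"])
        te = compute_te(m, _samples(("C",)), "C")
        assert not te.loc["g", "te_defined"]
        assert np.isnan(te.loc["g", "te"])

    def test_invariant_to_sample_rescaling(self):
        truth = simulate.generate_count_truth(300, conditions=("C",), seed=31)
        counts, samples = simulate.simulate_count_matrices(
            truth, ("C",), 2, seed=31, library_size_spread=0.0
        )
        te1 = compute_te(counts, samples, "C")["te"]
        scaled = counts.copy()
        scaled["C_total_R1"] = (scaled["C_total_R1"] * 7)
        te2 = compute_te(scaled, samples, "C")["te"]
        good = te1.notna()
        assert np.allclose(te1[good], te2[good], rtol=1e-6)


class TestCallDtgs:
    def test_low_mean_count_excluded(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(
            rng.poisson(200, size=(50, 8)),
            columns=list(_samples().index),
        )
        m.iloc[0] = [0, 1, 0, 1, 1, 0, 1, 0]  # mean 0.5 < minMeanCount
        res = call_dtgs(m, _samples(), "T", "C")
        assert not res["tested"].iloc[0]

    def test_te_log2fc_antisymmetric(self):
        truth = simulate.generate_count_truth(200, conditions=("C", "T"),
                                              seed=41)
        counts, samples = simulate.simulate_count_matrices(
            truth, ("C", "T"), 2, seed=41
        )
        fwd = call_dtgs(counts, samples, "T", "C")
        rev = call_dtgs(counts, samples, "C", "T")
        assert np.allclose(fwd["te_log2fc"], -rev["te_log2fc"])

    def test_missing_fraction_rejected(self):
        m = pd.DataFrame({"C_total_R1": [5], "C_total_R2": [5]})
        sheet = _samples(("C",)).loc[["C_total_R1", "C_total_R2"]]
        with pytest.raises(ConfigError):
            call_dtgs(m, sheet, "C", "T")


class TestClassifyTranslation:
    def test_identical_fractions_all_median(self):
        truth = simulate.generate_count_truth(
            100, conditions=("C",), seed=51,
            frac_te_affected=0.0, frac_expr_affected=0.0,
        )
        truth["dispersion"] = 0.0  # deterministic: polysome == total
        counts, samples = simulate.simulate_count_matrices(
            truth, ("C",), 2, seed=51, library_size_spread=0.0
        )
        cls = classify_translation(counts, samples, "C")
        assert (cls["translation_class"] == "median").all()

    def test_strong_polysome_enrichment_is_high(self):
        truth = simulate.generate_count_truth(
            300, conditions=("C",), seed=61,
            frac_te_affected=0.0, frac_expr_affected=0.0,
        )
        truth.iloc[0, truth.columns.get_loc("base_mean")] = 1000.0
        truth.iloc[0, truth.columns.get_loc("te_log2fc_C")] = np.log2(10)
        counts, samples = simulate.simulate_count_matrices(
            truth, ("C",), 2, seed=61
        )
        cls = classify_translation(counts, samples, "C")
        assert cls["translation_class"].iloc[0] == "high"

    def test_untested_gene_is_median(self):
        truth = simulate.generate_count_truth(50, conditions=("C",), seed=71)
        counts, samples = simulate.simulate_count_matrices(
            truth, ("C",), 2, seed=71
        )
        counts.iloc[0] = 0
        cls = classify_translation(counts, samples, "C")
        assert not cls["tested"].iloc[0]
        assert cls["translation_class"].iloc[0] == "median"


def test_expressed_genes_union():
    m = pd.DataFrame({"R1": [0, 3, 0], "R2": [0, 0, 2]},
                     index=["off", "a", "b"])
    assert list(expressed_genes(m)) == ["a", "b"]
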