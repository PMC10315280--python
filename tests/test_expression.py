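"""Factorial NB-GLM testing, stage contrasts and divergence classification."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from divergescan.config import SimulationConfig, expression_design
from divergescan.errors import DivergescanError
from divergescan import simulate as sim
from divergescan.expression import (
    categorize_effects,
    classify_predominance,
    cpm_filter,
    define_deg_set,
    design_matrices,
    estimate_size_factors,
    fit_and_test,
    fit_nb_glm,
    nb_loglik,
    stage_contrasts,
    vst_like_normalize,
)
from divergescan.stats import bh_adjust


class TestCpmFilter:
    def _counts(self, values):
        return pd.DataFrame(values, index=[f"g{i}" for i in range(len(values))])

    def test_all_zero_gene_removed(self):
        counts = pd.DataFrame({"s1": [0, 100], "s2": [0, 100], "s3": [0, 100]}, index=["a", "b"])
        assert cpm_filter(counts).index.tolist() == ["b"]

    def test_cpm_boundary_counts(self):
        # library 10M reads: count 10 = CPM 1 (> 0.5) in exactly 3 samples -> kept
        base = np.zeros((2, 4), dtype=int)
        base[1] = 10_000_000
        counts = pd.DataFrame(base, index=["g", "filler"], columns=list("abcd"))
        counts.loc["g", ["a", "b", "c"]] = 10
        assert "g" in cpm_filter(counts).index
        counts.loc["g", "c"] = 0
        assert "g" not in cpm_filter(counts).index

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"s1": [0, 0]}, index=["a", "b"])
        with pytest.raises(DivergescanError):
            cpm_filter(counts)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5], "c": [10, 20, 5]})
        assert np.allclose(estimate_size_factors(counts), 1.0)

    def test_doubled_column_has_doubled_factor(self):
        rng = np.random.default_rng(0)
        base = rng.integers(10, 1000, size=200)
        counts = pd.DataFrame({"a": base, "b": base, "c": 2 * base})
        sf = estimate_size_factors(counts)
        assert sf["c"] / sf["a"] == pytest.approx(2.0, rel=1e-6)

    def test_single_sample_factor_one(self):
        counts = pd.DataFrame({"a": [5, 6, 7]})
        assert estimate_size_factors(counts).tolist() == [1.0]

    def test_no_universally_expressed_gene_rejected(self):
        counts = pd.DataFrame({"a": [1, 0], "b": [0, 1]})
        with pytest.raises(DivergescanError):
            estimate_size_factors(counts)


class TestNbGlmAgainstStatsmodels:
    def test_fit_matches_statsmodels_glm(self):
        """IRLS coefficients and log-likelihood agree with the reference GLM."""
        rng = np.random.default_rng(4)
        design = expression_design(SimulationConfig(n_genes=1, seed=0))
        X = design_matrices(design)["additive"]
        offset = rng.normal(0, 0.1, len(design))
        mu = np.exp(5 + 0.7 * X[:, 1] + offset)
        alpha = 0.08
        y = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu)).astype(float)
        beta, mu_hat, ll, cov, conv = fit_nb_glm(y, X, offset, alpha)
        ref = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
        ).fit()
        assert conv
        assert np.allclose(beta, ref.params, atol=1e-6)
        assert ll == pytest.approx(ref.llf, abs=1e-6)
        assert np.allclose(np.sqrt(np.diag(cov)), ref.bse, rtol=1e-4)

    def test_loglik_matches_scipy_pmf(self):
        from scipy.stats import nbinom

        y = np.array([0.0, 3.0, 10.0])
        mu = np.array([2.0, 2.0, 8.0])
        alpha = 0.5
        r = 1 / alpha
        expected = nbinom.logpmf(y, r, r / (r + mu)).sum()
        assert nb_loglik(y, mu, alpha) == pytest.approx(expected, abs=1e-10)


class TestCategories:
    def test_category_assignment_logic(self):
        q = dict(
            q_geno=[0.001, 0.5, 0.001, 0.5, 0.001],
            q_devo=[0.5, 0.001, 0.001, 0.5, 0.5],
            q_int=[0.5, 0.5, 0.5, 0.5, 0.001],
        )
        cats = categorize_effects(**q)
        assert cats.tolist() == [
            "genotype_only", "development_only", "both_additive", "none", "interaction",
        ]

    def test_nan_qvalues_stay_none(self):
        assert categorize_effects([np.nan], [np.nan], [np.nan]).tolist() == ["none"]


@pytest.fixture(scope="module")
def planted_fit():
    """Factorial fit on a small simulation with all three planted effects."""
    cfg = SimulationConfig(n_genes=250, seed=31, frac_deg=(0.12, 0.12, 0.12), deg_log2fc=2.0)
    genomes = sim.generate_gene_models(cfg)
    counts, design, truth = sim.simulate_counts(genomes, cfg)
    counts = cpm_filter(counts)
    fit = fit_and_test(counts, design, estimate_size_factors(counts))
    return fit, truth, design, counts


class TestFactorial:
    def test_categories_partition_tested_genes(self, planted_fit):
        fit, truth, _, _ = planted_fit
        counts = fit.results["category"].value_counts()
        assert counts.sum() == len(fit.results)
        assert set(counts.index) <= {
            "interaction", "genotype_only", "development_only", "both_additive", "none"
        }

    def test_planted_effects_recovered(self, planted_fit):
        fit, truth, _, _ = planted_fit
        tr = truth.set_index("gene_id")
        ints = tr.index[tr["effect"] == "interaction"].intersection(fit.results.index)
        genos = tr.index[tr["effect"] == "genotype"].intersection(fit.results.index)
        assert (fit.results.loc[ints, "category"] == "interaction").mean() >= 0.8
        geno_cats = fit.results.loc[genos, "category"]
        assert geno_cats.isin(["genotype_only", "both_additive"]).mean() >= 0.8

    def test_swapping_genotype_labels_negates_log2fc(self, planted_fit):
        fit, truth, design, counts = planted_fit
        flipped = design.copy()
        flipped["genotype"] = flipped["genotype"].map({"HAL2": "FIL2", "FIL2": "HAL2"})
        fit2 = fit_and_test(counts, flipped, fit.size_factors)
        genes = fit.results.index[fit.results["divergent"]].tolist()[:40]
        c1 = stage_contrasts(fit, genes).set_index(["gene_id", "stage"])
        c2 = stage_contrasts(fit2, genes).set_index(["gene_id", "stage"])
        assert np.allclose(c1["log2fc"], -c2["log2fc"], atol=1e-6)
        assert np.allclose(c1["p"].fillna(-1), c2["p"].fillna(-1), atol=1e-8)


class TestStageContrasts:
    def test_planted_fourfold_at_single_stage(self):
        """A 4x FIL2/HAL2 difference at stage D2 only shows log2fc ~ 2 there."""
        rng = np.random.default_rng(6)
        cfg = SimulationConfig(n_genes=1, seed=0)
        design = expression_design(cfg)
        n_target = 30
        genes, rows = [], []
        for i in range(60):
            base = 300.0
            lfc = 2.0 if i < n_target else 0.0
            mu = np.array(
                [
                    base * (2.0 ** lfc if (g == "FIL2" and s == "D2") else 1.0)
                    for g, s in zip(design["genotype"], design["stage"])
                ]
            )
            alpha = 0.05
            rows.append(rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu)))
            genes.append(f"g{i:03d}")
        counts = pd.DataFrame(rows, index=genes, columns=design["sample"])
        # unit size factors: libraries are constructed balanced, and the
        # planted fraction is far too high for median-of-ratios to hold
        unit_sf = pd.Series(1.0, index=counts.columns)
        fit = fit_and_test(counts, design, unit_sf)
        con = stage_contrasts(fit, genes[:n_target]).set_index(["gene_id", "stage"])
        d2 = con.xs("D2", level="stage")["log2fc"]
        others = con.drop("D2", level="stage")["log2fc"]
        assert d2.mean() == pytest.approx(2.0, abs=0.15)
        assert abs(others.mean()) < 0.15

    def test_bh_with_equal_pvalues_is_identity(self):
        assert np.allclose(bh_adjust([0.01] * 7), 0.01)


def _contrast_frame(stage_data):
    rows = []
    for gene, per_stage in stage_data.items():
        for stage, (lfc, padj) in per_stage.items():
            rows.append({"gene_id": gene, "stage": stage, "log2fc": lfc, "p": padj, "padj": padj})
    return pd.DataFrame(rows)


class TestPredominance:
    def test_all_positive_significant_stages_is_fil2_predominant(self):
        con = _contrast_frame({"g": {"D1": (0.2, 0.5), "D2": (1.0, 0.001), "D4": (0.8, 0.004)}})
        assert classify_predominance(con)["g"] == "FIL2_predominant"

    def test_all_negative_significant_stages_is_hal2_predominant(self):
        con = _contrast_frame({"g": {"D1": (-1.2, 0.002), "D3": (-0.4, 0.0005)}})
        assert classify_predominance(con)["g"] == "HAL2_predominant"

    def test_sign_flip_is_rank_changing(self):
        con = _contrast_frame({"g": {"D1": (1.0, 0.001), "D4": (-1.5, 0.003)}})
        assert classify_predominance(con)["g"] == "rank_changing"

    def test_no_significant_stage_is_none(self):
        con = _contrast_frame({"g": {"D1": (2.0, 0.5), "D4": (-1.0, 0.2)}})
        assert classify_predominance(con)["g"] == "none"


class TestDegSet:
    @pytest.mark.parametrize(
        "padj, lfc, included",
        [(0.005, 0.5, False), (0.005, 1.0, True), (0.02, 3.0, False)],
    )
    def test_stringent_thresholds(self, padj, lfc, included):
        con = pd.DataFrame(
            [{"gene_id": "g", "stage": "D1", "log2fc": lfc, "p": padj, "padj": padj}]
        )
        assert (len(define_deg_set(con)) == 1) is included


class TestVst:
    def test_zero_count_maps_to_zero(self):
        counts = pd.DataFrame({"a": [0, 8], "b": [0, 8]}, index=["g1", "g2"])
        out = vst_like_normalize(counts)
        assert out.loc["g1"].tolist() == [0.0, 0.0]

    def test_monotone_within_sample(self):
        counts = pd.DataFrame({"a": [1, 5, 25, 125]}, index=list("wxyz"))
        out = vst_like_normalize(counts, pd.Series({"a": 1.0}))
        assert (np.diff(out["a"]) > 0).all()

    def test_library_scaling_cancels(self):
        rng = np.random.default_rng(2)
        base = rng.integers(20, 2000, 100)
        counts = pd.DataFrame({"a": base, "b": base * 2})
        out = vst_like_normalize(counts)
        assert np.allclose(out["a"], out["b"], atol=0.1)
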