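"""Differential methylation calling: t-tests, q-values, thresholds, joins."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from divergescan.dmr import call_dmgs, contrast_feature, contrast_groups, is_degenerate
from divergescan.errors import DivergescanError
from divergescan.simulate import simulate_feature_table
from divergescan.stats import storey_qvalues


def _pooled_t(a, b):
    """Hand-computed equal-variance two-sample t (b vs a)."""
    na, nb = len(a), len(b)
    va = sum((x - sum(a) / na) ** 2 for x in a) / (na - 1)
    vb = sum((x - sum(b) / nb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    return (sum(b) / nb - sum(a) / na) / math.sqrt(sp2 * (1 / na + 1 / nb))


class TestContrastFeature:
    def test_matches_hand_computed_pooled_t(self):
        a, b = (0.2, 0.25, 0.22), (0.5, 0.55, 0.52)
        t, p, delta = contrast_feature(a, b)
        assert delta == pytest.approx(0.30)
        assert t == pytest.approx(_pooled_t(a, b), abs=1e-12)
        # df = 4 two-sided p from the t distribution
        from scipy.stats import t as tdist

        assert p == pytest.approx(2 * tdist.sf(abs(t), 4), abs=1e-12)

    def test_identical_constant_groups(self):
        t, p, delta = contrast_feature((0.3, 0.3, 0.3), (0.3, 0.3, 0.3))
        assert (t, p, delta) == (0.0, 1.0, 0.0)

    def test_zero_variance_different_means_is_certain(self):
        t, p, delta = contrast_feature((0.1, 0.1, 0.1), (0.4, 0.4, 0.4))
        assert p == 0.0 and delta == pytest.approx(0.3)

    def test_single_replicate_untestable(self):
        t, p, _ = contrast_feature((0.2,), (0.3, 0.4))
        assert np.isnan(t) and np.isnan(p)

    def test_degenerate_detection(self):
        assert is_degenerate((0, 0, 0), (0.15, 0.12, 0.18))
        assert not is_degenerate((0, 0, 0), (0, 0, 0))
        assert not is_degenerate((0.1, 0, 0), (0.2, 0.1, 0.1))


class TestStoreyQvalues:
    def test_all_ones_stay_ones(self):
        assert storey_qvalues([1.0] * 10).tolist() == [1.0] * 10

    def test_small_input_equals_benjamini_hochberg(self):
        """With pi0 forced to 1 (< 100 tests) q-values are exactly BH."""
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        q = storey_qvalues(p)
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, bh, atol=1e-12)

    def test_pi0_shrinks_qvalues_with_signal(self):
        rng = np.random.default_rng(1)
        p = np.concatenate([rng.uniform(size=500) * 1e-4, rng.uniform(size=500)])
        q = storey_qvalues(p)
        bh = multipletests(p, method="fdr_bh")[1]
        assert (q <= bh + 1e-12).all()

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=200))
    def test_monotone_in_p(self, pvals):
        q = storey_qvalues(np.array(pvals))
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues([0.5, 1.5])


def _contrast_row(q=np.nan, delta=0.0, degenerate=False, p=np.nan, pair="og1", kind="promoter", ctx="CG"):
    return {
        "pair_id": pair, "feature_kind": kind, "context": ctx,
        "mean_a": 0.2, "mean_b": 0.2 + delta, "delta": delta,
        "t": np.nan, "p": p, "degenerate": degenerate, "n_a": 3, "n_b": 3,
    }


class TestCallDmgs:
    def test_threshold_rule(self):
        """q and |delta| must both pass; the delta bound is strict."""
        rows = [
            _contrast_row(p=1e-6, delta=0.15, pair="a"),
            _contrast_row(p=1e-6, delta=0.08, pair="b"),
            _contrast_row(p=0.9, delta=0.5, pair="c"),
        ]
        out, dmg, _ = call_dmgs(pd.DataFrame(rows))
        sig = out.set_index("pair_id")["significant"]
        assert sig["a"] and not sig["b"] and not sig["c"]
        assert dmg.set_index("pair_id")["is_dmg"].tolist() == [True, False, False]

    def test_degenerate_significant_by_delta_alone(self):
        rows = [
            _contrast_row(degenerate=True, delta=0.15, pair="a"),
            _contrast_row(degenerate=True, delta=0.05, pair="b"),
        ]
        out, _, _ = call_dmgs(pd.DataFrame(rows))
        assert out.set_index("pair_id")["significant"].tolist() == [True, False]
        assert out["q"].isna().all()

    def test_direction_counts_follow_delta_sign(self):
        rows = [
            _contrast_row(p=1e-9, delta=0.3, pair="a"),
            _contrast_row(p=1e-9, delta=-0.3, pair="b"),
        ]
        _, _, direction = call_dmgs(pd.DataFrame(rows))
        d = direction.set_index("direction")["n"]
        assert d["hyper_b"] == 1 and d["hypo_b"] == 1


def _design():
    rows = []
    for g in ("HAL2", "FIL2"):
        for s in ("D1", "D4"):
            for r in (1, 2, 3):
                rows.append({"sample": f"{g}_{s}_r{r}", "genotype": g, "stage": s})
    return pd.DataFrame(rows)


def _table(gene_levels: dict, stage="D1"):
    """gene_levels: gene_id -> {genotype: [r1, r2, r3]} for one feature."""
    rows = []
    for gid, per_geno in gene_levels.items():
        for g, levels in per_geno.items():
            for r, lv in enumerate(levels):
                rows.append(
                    {
                        "gene_id": f"{g}_{gid[2:]}" if gid.startswith("og") else gid,
                        "feature_kind": "promoter",
                        "context": "CG",
                        "sample": f"{g}_{stage}_r{r + 1}",
                        "mean_level": lv,
                        "n_sites": 10,
                    }
                )
    return pd.DataFrame(rows)


OMAP = pd.DataFrame(
    {"pair_id": ["og0001", "og0002"], "HAL2": ["HAL2_0001", "HAL2_0002"], "FIL2": ["FIL2_0001", "FIL2_0002"]}
)


class TestContrastGroups:
    def test_ortholog_join_produces_pair_contrast(self):
        table = _table({"og0001": {"HAL2": [0.2, 0.25, 0.22], "FIL2": [0.5, 0.55, 0.52]}})
        out = contrast_groups(
            table, _design(), {"genotype": "HAL2", "stage": "D1"},
            {"genotype": "FIL2", "stage": "D1"}, ortholog_map=OMAP,
        )
        assert out["pair_id"].tolist() == ["og0001"]
        assert out["delta"].iloc[0] == pytest.approx(0.30)

    def test_pair_in_one_genotype_only_emits_nothing(self):
        table = _table({"og0001": {"HAL2": [0.2, 0.25, 0.22]}})
        out = contrast_groups(
            table, _design(), {"genotype": "HAL2", "stage": "D1"},
            {"genotype": "FIL2", "stage": "D1"}, ortholog_map=OMAP,
        )
        assert out.empty

    def test_stage_contrast_needs_no_map(self):
        rows = []
        for stage, levels in (("D1", [0.2, 0.3, 0.25]), ("D4", [0.6, 0.7, 0.65])):
            for r, lv in enumerate(levels):
                rows.append(
                    {"gene_id": "HAL2_0001", "feature_kind": "cds", "context": "CHH",
                     "sample": f"HAL2_{stage}_r{r + 1}", "mean_level": lv, "n_sites": 4}
                )
        out = contrast_groups(
            pd.DataFrame(rows), _design(), {"genotype": "HAL2", "stage": "D1"},
            {"genotype": "HAL2", "stage": "D4"},
        )
        assert len(out) == 1 and out["delta"].iloc[0] == pytest.approx(0.4)

    def test_full_feature_context_grid_counts(self):
        rows = []
        for kind in ("promoter", "cds", "utr3"):
            for ctx in ("CG", "CHG", "CHH"):
                for g in ("HAL2", "FIL2"):
                    for r in (1, 2, 3):
                        rows.append(
                            {"gene_id": f"{g}_0001", "feature_kind": kind, "context": ctx,
                             "sample": f"{g}_D1_r{r}", "mean_level": 0.5, "n_sites": 5}
                        )
        out = contrast_groups(
            pd.DataFrame(rows), _design(), {"genotype": "HAL2", "stage": "D1"},
            {"genotype": "FIL2", "stage": "D1"}, ortholog_map=OMAP,
        )
        assert len(out) == 9

    def test_non_bijective_map_rejected(self):
        bad = pd.DataFrame({"pair_id": ["p1", "p2"], "HAL2": ["h1", "h1"], "FIL2": ["f1", "f2"]})
        table = _table({"og0001": {"HAL2": [0.1, 0.2, 0.3], "FIL2": [0.1, 0.2, 0.3]}})
        with pytest.raises(DivergescanError, match="bijection"):
            contrast_groups(
                table, _design(), {"genotype": "HAL2", "stage": "D1"},
                {"genotype": "FIL2", "stage": "D1"}, ortholog_map=bad,
            )

    def test_swapping_groups_negates_delta_keeps_p(self):
        table, _ = simulate_feature_table(40, frac_planted=0.2, seed=8)
        design = table[["sample", "group"]].drop_duplicates().rename(columns={"group": "genotype"})
        design["stage"] = "D1"
        ab = contrast_groups(table, design, {"genotype": "HAL2"}, {"genotype": "FIL2"})
        ba = contrast_groups(table, design, {"genotype": "FIL2"}, {"genotype": "HAL2"})
        merged = ab.merge(ba, on=["pair_id", "feature_kind", "context"], suffixes=("_ab", "_ba"))
        assert np.allclose(merged["delta_ab"], -merged["delta_ba"])
        both = merged.dropna(subset=["p_ab", "p_ba"])
        assert np.allclose(both["p_ab"], both["p_ba"])


class TestRecoverySignConvention:
    def test_planted_hypermethylation_in_fil2_gives_positive_delta(self):
        table, truth = simulate_feature_table(300, frac_planted=0.3, delta=0.3, seed=13)
        design = table[["sample", "group"]].drop_duplicates().rename(columns={"group": "genotype"})
        design["stage"] = "D1"
        con = contrast_groups(table, design, {"genotype": "HAL2"}, {"genotype": "FIL2"})
        out, _, _ = call_dmgs(con)
        recovered = out[out["significant"] & out["pair_id"].isin(set(truth["gene_id"]))]
        assert len(recovered) > 0
        assert (recovered["delta"] > 0).all()
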