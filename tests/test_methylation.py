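"""Cytosine-report parsing and methylation summaries."""

import numpy as np
import pandas as pd
import pytest

from divergescan.errors import MissingDataError, ParseError
from divergescan.features import GeneModel
from divergescan.methylation import (
    CX_COLUMNS,
    conversion_rate,
    expression_rank_groups,
    feature_levels,
    filter_min_coverage,
    global_levels,
    level_histogram,
    metagene_profile,
    parse_cx_report,
    read_cx_report,
    window_profiles,
)

from oracles import oracle_feature_level


def _report(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=CX_COLUMNS)
    df["coverage"] = df["count_methylated"] + df["count_unmethylated"]
    return df


class TestParsing:
    def test_single_row_level_derivable(self, tmp_path):
        path = tmp_path / "r.txt"
        path.write_text("chr1\t100\t+\t3\t7\tCG\tCGA\n")
        (rec,) = parse_cx_report(path)
        assert rec.level == pytest.approx(0.3)
        assert rec.coverage == 10

    def test_empty_file_yields_empty_stream(self, tmp_path):
        path = tmp_path / "e.txt"
        path.write_text("")
        assert list(parse_cx_report(path)) == []

    @pytest.mark.parametrize(
        "line, match",
        [
            ("chr1\t100\t+\t3\t7\tCG", "columns"),
            ("chr1\t100\t+\tx\t7\tCG\tCGA", "non-integer"),
            ("chr1\t100\t*\t3\t7\tCG\tCGA", "strand"),
        ],
    )
    def test_malformed_rows_name_the_line(self, tmp_path, line, match):
        path = tmp_path / "bad.txt"
        path.write_text("chr1\t1\t+\t0\t5\tCG\tCGA\n" + line + "\n")
        with pytest.raises(ParseError, match=match) as err:
            list(parse_cx_report(path))
        assert "line 2" in str(err.value)

    def test_dataframe_reader_agrees_with_stream(self, small_simulation):
        _, _, manifest = small_simulation
        path = manifest["cx_HAL2_D1_r1"]
        df = read_cx_report(path)
        stream = list(parse_cx_report(path))
        assert len(df) == len(stream)
        k = len(df) // 2
        assert (df.iloc[k]["chrom"], int(df.iloc[k]["pos"]), int(df.iloc[k]["count_methylated"])) == (
            stream[k].chrom, stream[k].pos, stream[k].n_meth
        )


class TestCoverageFilter:
    @pytest.mark.parametrize("meth,unmeth,kept", [(2, 2, False), (2, 3, True), (5, 0, True)])
    def test_boundary_is_inclusive(self, meth, unmeth, kept):
        df = _report([("chr1", 1, "+", meth, unmeth, "CG", "CGA")])
        assert (len(filter_min_coverage(df, 5)) == 1) is kept

    def test_min_cov_one_keeps_all_covered(self):
        df = _report([("chr1", 1, "+", 0, 1, "CG", "CGA"), ("chr1", 5, "+", 1, 0, "CHH", "CAA")])
        assert len(filter_min_coverage(df, 1)) == 2


ASSIGN = pd.DataFrame(
    {"chrom": ["chr1"] * 3, "pos": [0, 4, 9], "gene_id": "g1", "feature_kind": "cds"}
)


class TestFeatureLevels:
    def test_unweighted_mean_of_site_proportions(self):
        df = _report(
            [
                ("chr1", 1, "+", 2, 8, "CG", "CGA"),
                ("chr1", 5, "+", 4, 6, "CG", "CGA"),
                ("chr1", 10, "+", 9, 1, "CG", "CGA"),
            ]
        )
        out = feature_levels(df, ASSIGN, sample="s1")
        assert out["mean_level"].iloc[0] == pytest.approx(0.5)
        assert out["n_sites"].iloc[0] == 3

    def test_mixed_coverage_not_pooled(self):
        """(3/10 + 30/40)/2 = 0.525, not the pooled 33/50 = 0.66."""
        df = _report(
            [("chr1", 1, "+", 3, 7, "CG", "CGA"), ("chr1", 5, "+", 30, 10, "CG", "CGA")]
        )
        out = feature_levels(df, ASSIGN, sample="s1")
        assert out["mean_level"].iloc[0] == pytest.approx(0.525)
        pooled = feature_levels(df, ASSIGN, sample="s1", pooled=True)
        assert pooled["mean_level"].iloc[0] == pytest.approx(33 / 50)

    def test_matches_brute_force_oracle_on_random_fixture(self):
        rng = np.random.default_rng(12)
        meth = rng.integers(0, 20, 30)
        unmeth = rng.integers(1, 20, 30)
        df = _report(
            [("chr1", i + 1, "+", int(m), int(u), "CG", "CGA") for i, (m, u) in enumerate(zip(meth, unmeth))]
        )
        assign = pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(30), "gene_id": "g1", "feature_kind": "cds"}
        )
        out = feature_levels(df, assign, sample="s1")
        assert out["mean_level"].iloc[0] == pytest.approx(
            oracle_feature_level(meth, unmeth), abs=1e-12
        )

    def test_permuting_record_order_changes_nothing(self):
        rng = np.random.default_rng(5)
        df = _report(
            [("chr1", i + 1, "+", int(m), 5, "CG", "CGA") for i, m in enumerate(rng.integers(0, 10, 20))]
        )
        assign = pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(20), "gene_id": "g1", "feature_kind": "cds"}
        )
        a = feature_levels(df, assign, sample="s")
        b = feature_levels(df.sample(frac=1, random_state=1), assign, sample="s")
        pd.testing.assert_frame_equal(a, b)

    def test_min_sites_filters_sparse_features(self):
        df = _report([("chr1", 1, "+", 1, 1, "CG", "CGA")])
        assert len(feature_levels(df, ASSIGN, "s", min_sites=2)) == 0


class TestGlobalSummaries:
    def test_all_unmethylated(self):
        df = _report([("chr1", 1, "+", 0, 9, "CG", "CGA"), ("chr1", 4, "+", 0, 5, "CG", "CGA")])
        out = global_levels(df)
        assert out["mean_level"].iloc[0] == 0 and out["frac_methylated"].iloc[0] == 0

    def test_single_site_level(self):
        out = global_levels(_report([("chr1", 1, "+", 5, 5, "CHG", "CAG")]))
        assert out["mean_level"].iloc[0] == pytest.approx(0.5)

    def test_empty_input_raises(self):
        with pytest.raises(MissingDataError):
            global_levels(_report([]))

    def test_histogram_boundaries_and_normalization(self):
        rows = [("chr1", i + 1, "+", m, 10 - m, "CG", "CGA") for i, m in enumerate([0, 2, 5, 9, 10])]
        out = level_histogram(_report(rows))
        # levels 0.0, 0.2, 0.5, 0.9, 1.0 -> low=1, mid=2 (0.2 inclusive), high=2
        assert out[["low", "mid", "high"]].iloc[0].tolist() == pytest.approx([0.2, 0.4, 0.4])
        assert out[["low", "mid", "high"]].sum(axis=1).iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_conversion_rate_arithmetic(self):
        df = _report([("chrC", 1, "+", 25, 975, "CHH", "CAA")])
        assert conversion_rate(df) == pytest.approx(0.975)
        assert conversion_rate(_report([("chrC", 1, "+", 0, 1000, "CG", "CGA")])) == 1.0
        assert conversion_rate(_report([("chrC", 1, "+", 1000, 0, "CG", "CGA")])) == 0.0


class TestWindows:
    def test_zero_variance_correlation_missing(self):
        df = _report([("chr1", i * 100 + 1, "+", 5, 5, "CG", "CGA") for i in range(10)])
        spans = pd.DataFrame({"chrom": "chr1", "start": [0], "end": [100]})
        _, corr = window_profiles(df, spans, {"chr1": 1000}, 100)
        assert np.isnan(corr.loc[corr["context"] == "CG", "pearson_r"]).all()

    def test_single_window_correlation_missing(self):
        df = _report([("chr1", 1, "+", 5, 5, "CG", "CGA")])
        spans = pd.DataFrame({"chrom": "chr1", "start": [0], "end": [10]})
        _, corr = window_profiles(df, spans, {"chr1": 100}, 1000)
        assert np.isnan(corr.loc[corr["context"] == "CG", "pearson_r"]).all()

    def test_planted_negative_correlation_recovered(self):
        rng = np.random.default_rng(3)
        rows, genes = [], []
        for w in range(20):
            gene_rich = w % 2 == 0
            level = 0.2 if gene_rich else 0.8
            for k in range(20):
                pos = w * 1000 + k * 40 + 1
                m = rng.binomial(20, level)
                rows.append(("chr1", pos, "+", m, 20 - m, "CG", "CGA"))
            for g in range(5 if gene_rich else 0):
                genes.append({"chrom": "chr1", "start": w * 1000 + g, "end": w * 1000 + g + 100})
        _, corr = window_profiles(_report(rows), pd.DataFrame(genes), {"chr1": 20000}, 1000)
        assert corr.loc[corr["context"] == "CG", "pearson_r"].iloc[0] < -0.9


class TestMetagene:
    def _uniform_report(self, positions, level=0.4, context="CG"):
        rows = [("chr1", p + 1, "+", int(level * 10), int((1 - level) * 10), context, "CGA") for p in positions]
        return _report(rows)

    def test_uniform_gene_gives_flat_profile(self):
        m = GeneModel("g1", "chr1", "+", 3000, 5000, exons=[(3000, 5000)])
        df = self._uniform_report(range(1000, 7000, 13))
        out = metagene_profile(df, [m], {"g1": "rank1"})
        assert out["mean_level"].to_numpy() == pytest.approx(np.full(len(out), 0.4))
        assert out["bin"].nunique() == 60

    def test_minus_strand_downstream_signal_appears_in_5prime_flank(self):
        """High methylation genomically downstream of a minus-strand gene
        must show up in the upstream (5') flank bins of the profile."""
        m = GeneModel("g1", "chr1", "-", 3000, 5000, exons=[(3000, 5000)])
        rows = []
        for p in range(5000, 7000, 10):  # genomic downstream = transcript upstream
            rows.append(("chr1", p + 1, "+", 9, 1, "CG", "CGA"))
        for p in range(3000, 5000, 10):
            rows.append(("chr1", p + 1, "+", 1, 9, "CG", "CGA"))
        out = metagene_profile(_report(rows), [m], {"g1": "r"})
        first_flank = out[out["bin"] < 20]["mean_level"]
        body = out[(out["bin"] >= 20) & (out["bin"] < 40)]["mean_level"]
        assert np.allclose(first_flank, 0.9)
        assert np.allclose(body, 0.1)

    def test_group_mean_averages_over_genes(self):
        m1 = GeneModel("g1", "chr1", "+", 1000, 2000, exons=[(1000, 2000)])
        m2 = GeneModel("g2", "chr1", "+", 10000, 11000, exons=[(10000, 11000)])
        df = pd.concat(
            [
                self._uniform_report(range(1000, 2000, 10), 0.2),
                self._uniform_report(range(10000, 11000, 10), 0.6),
            ],
            ignore_index=True,
        )
        out = metagene_profile(df, [m1, m2], {"g1": "r", "g2": "r"})
        body = out[(out["bin"] >= 20) & (out["bin"] < 40)]
        assert body["mean_level"].to_numpy() == pytest.approx(np.full(len(body), 0.4))


class TestRankGroups:
    COUNTS = pd.DataFrame(
        {"s1": [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10], "s2": [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10]},
        index=[f"g{i:02d}" for i in range(11)],
    )

    def test_zero_count_genes_are_rank1(self):
        ranks = expression_rank_groups(self.COUNTS, ["s1", "s2"], n_groups=6)
        assert ranks["g00"] == 1

    def test_equal_size_quantile_groups(self):
        ranks = expression_rank_groups(self.COUNTS, ["s1", "s2"], n_groups=6)
        sizes = ranks[ranks > 1].value_counts()
        assert sorted(sizes) == [2, 2, 2, 2, 2]
        assert ranks["g01"] == 2 and ranks["g10"] == 6

    def test_ties_broken_by_gene_id_deterministically(self):
        counts = pd.DataFrame({"s1": [1, 1, 1, 1]}, index=["gd", "gc", "gb", "ga"])
        r1 = expression_rank_groups(counts, ["s1"], n_groups=3)
        r2 = expression_rank_groups(counts.iloc[::-1], ["s1"], n_groups=3)
        assert r1.sort_index().equals(r2.sort_index())
        assert r1["ga"] == 2 and r1["gd"] == 3
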