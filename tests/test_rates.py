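"""Calibration, AC/FC metrics, rate categories and the rate table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import lineage_rates as lr
from lineage_rates.rates import (
    CalibrationParams,
    ExpressionMatrix,
    CATEGORY_ORDER,
    cluster_rate_profiles,
    pseudobulk_median,
)

PARAMS = CalibrationParams()


class TestCalibration:
    def test_maternal_threshold_identity(self):
        # 12.5 TPM in the whole-volume zygote = 100 molecules
        assert lr.tpm_to_count(12.5, 1.0) == pytest.approx(100.0)

    def test_zero_and_direct_arithmetic(self):
        assert lr.tpm_to_count(0.0, 0.5) == 0.0
        assert lr.tpm_to_count(250.0, 0.25) == pytest.approx(500.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        tpm=st.floats(0, 1e5),
        v1=st.floats(0.01, 1.0),
        scale=st.floats(0.1, 5.0),
    )
    def test_linearity_in_tpm_and_volume(self, tpm, v1, scale):
        base = lr.tpm_to_count(tpm, v1)
        assert lr.tpm_to_count(tpm * scale, v1) == pytest.approx(base * scale, rel=1e-12)
        if v1 * scale <= 1.0:
            assert lr.tpm_to_count(tpm, v1 * scale) == pytest.approx(
                base * scale, rel=1e-12
            )

    def test_maternal_filter_strict_inequality(self):
        assert lr.is_maternal(12.6)
        assert not lr.is_maternal(12.5)
        assert not lr.is_maternal(0.0)

    def test_absolute_change_consistency_with_calibration(self):
        # AC(a, b, v) == count(b, v) − count(a, v) exactly
        for a, b, v in [(0, 12.5, 1.0), (10, 110, 0.125), (40, 30, 0.5)]:
            assert lr.absolute_change(a, b, v) == pytest.approx(
                lr.tpm_to_count(b, v) - lr.tpm_to_count(a, v), abs=1e-12
            )
        assert lr.absolute_change(10, 110, 0.125) == pytest.approx(100.0)
        assert lr.absolute_change(7, 7, 0.3) == 0.0


class TestFoldChange:
    def test_pseudocount_examples(self):
        assert lr.fold_change(0, 90) == pytest.approx(10.0)
        assert lr.fold_change(40, 240) == pytest.approx(5.0)
        assert lr.fold_change(123, 123) == 1.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(a=st.floats(0, 1e6), b=st.floats(0, 1e6), d=st.floats(0.1, 100))
    def test_monotone_in_both_arguments(self, a, b, d):
        assert lr.fold_change(a, b + d) > lr.fold_change(a, b)
        assert lr.fold_change(a + d, b) < lr.fold_change(a, b)


class TestClassifyRate:
    @pytest.mark.parametrize(
        "ac,fc,expected",
        [
            (300, 15, "high"),
            (300, 8, "medium"),  # one metric high, other medium
            (300, 3, "low"),  # FC in (1,5] overrides to low
            (0, 20, "none"),
            (100, 8, "medium"),
            (100, 15, "medium"),
            (30, 3, "low"),
            (30, 8, "low"),
            (500, 0.5, "none"),
            (1.0, 5.0, "none"),  # boundaries are strict
            (1.1, 1.1, "low"),
        ],
    )
    def test_category_table(self, ac, fc, expected):
        assert lr.classify_rate(ac, fc) == expected

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        ac=st.floats(0, 500),
        fc=st.floats(0, 20),
        dac=st.floats(0, 100),
        dfc=st.floats(0, 5),
    )
    def test_monotone_in_ac_and_fc(self, ac, fc, dac, dfc):
        rank = {c: i for i, c in enumerate(CATEGORY_ORDER)}
        base = rank[lr.classify_rate(ac, fc)]
        assert rank[lr.classify_rate(ac + dac, fc)] >= base
        assert rank[lr.classify_rate(ac, fc + dfc)] >= base


def test_rate_per_minute():
    # ~300 transcripts over the 16-min MS cycle -> ~19/min
    assert lr.rate_per_minute(300, 16) == pytest.approx(18.75)
    assert round(lr.rate_per_minute(300, 16)) == 19
    assert lr.rate_per_minute(0, 16) == 0.0
    assert lr.rate_per_minute(450, 15) == pytest.approx(30.0)
    with pytest.raises(ValueError):
        lr.rate_per_minute(300, 0)


class TestPseudobulk:
    def test_median_over_replicates(self):
        m = pseudobulk_median({"MS": [[10.0, 20.0, 30.0]]}, genes=["g"])
        assert m.values.loc["g", "MS"] == 20.0

    def test_tossed_replicates_excluded(self):
        m = pseudobulk_median(
            {"MS": [[10.0, 20.0, 1000.0]]},
            tossed_flags={"MS": [False, False, True]},
            genes=["g"],
        )
        assert m.values.loc["g", "MS"] == 15.0

    def test_single_replicate_identity(self):
        m = pseudobulk_median({"E": [[7.0]]}, genes=["g"])
        assert m.values.loc["g", "E"] == 7.0

    def test_all_tossed_raises_with_cell_name(self):
        with pytest.raises(ValueError, match="MS"):
            pseudobulk_median({"MS": [[5.0]]}, tossed_flags={"MS": [True]})


def brute_force_rate_table(tpm: pd.DataFrame, tree, params=PARAMS):
    """Independent per-gene, per-edge recomputation from the raw formulas."""
    rows = []
    for gene in tpm.index:
        if tpm.loc[gene, "P0"] > params.maternal_tpm_threshold:
            continue
        for parent, daughter in tree.edges():
            if parent not in tpm.columns or daughter not in tpm.columns:
                continue
            v = tree.volume_fraction(daughter)
            ac = (tpm.loc[gene, daughter] - tpm.loc[gene, parent]) / 1e6 * v * params.embryo_total
            cp = tpm.loc[gene, parent] / 1e6 * v * params.embryo_total
            cd = tpm.loc[gene, daughter] / 1e6 * v * params.embryo_total
            fc = (cd + params.fc_pseudocount) / (cp + params.fc_pseudocount)
            rows.append((gene, parent, daughter, ac, fc))
    return sorted(rows, key=lambda r: (r[0], r[2]))


class TestRateTable:
    def toy_matrix(self, tree):
        cells = list(tree.nodes)
        rng = np.random.default_rng(42)
        tpm = pd.DataFrame(
            rng.uniform(0, 50, size=(3, len(cells))), index=["g1", "g2", "g3"],
            columns=cells,
        )
        tpm.loc["g1", "P0"] = 0.0  # zygotic
        tpm.loc["g2", "P0"] = 20.0  # maternal
        tpm.loc["g3", "P0"] = 12.5  # boundary: not maternal (strict >)
        return tpm

    def test_matches_brute_force_oracle_exactly(self, tree):
        tpm = self.toy_matrix(tree)
        records = lr.build_rate_table(ExpressionMatrix(tpm), tree)
        oracle = brute_force_rate_table(tpm, tree)
        assert len(records) == len(oracle)
        for rec, (gene, parent, daughter, ac, fc) in zip(records, oracle):
            assert (rec.gene, rec.parent_cell, rec.daughter_cell) == (gene, parent, daughter)
            assert rec.ac == pytest.approx(ac, abs=1e-9)
            assert rec.fc == pytest.approx(fc, abs=1e-12)

    def test_maternal_genes_are_excluded(self, tree):
        records = lr.build_rate_table(ExpressionMatrix(self.toy_matrix(tree)), tree)
        assert not any(r.gene == "g2" for r in records)
        assert any(r.gene == "g3" for r in records)

    def test_single_zygotic_gene_edges(self, tree):
        cells = list(tree.nodes)
        tpm = pd.DataFrame(0.0, index=["z"], columns=cells)
        tpm.loc["z", "MS"] = 100.0
        records = lr.build_rate_table(ExpressionMatrix(tpm), tree)
        ms = [r for r in records if r.daughter_cell == "MS"]
        assert len(ms) == 1 and ms[0].gene == "z"
        assert ms[0].ac > 0
        # one record per edge for the gene, all cells present
        assert len(records) == len(tree.edges())

    def test_missing_parent_edge_skipped(self, tree):
        cells = [c for c in tree.nodes if c != "EMS"]
        tpm = pd.DataFrame(1.0, index=["z"], columns=cells)
        records = lr.build_rate_table(ExpressionMatrix(tpm), tree)
        assert not any(r.daughter_cell in ("MS", "E") for r in records)


class TestStrictCategories:
    def rec(self, gene, cell, cat):
        return lr.RateRecord(gene, "X", cell, "8-cell", 0, 1, 0, cat)

    def test_high_never_low(self):
        records = [self.rec("a", "MS", "high"), self.rec("a", "E", "none")]
        assert "a" in lr.strict_category_genes(records)["high"]

    def test_high_somewhere_low_elsewhere_excluded(self):
        records = [self.rec("a", "MS", "high"), self.rec("a", "ABa", "low")]
        strict = lr.strict_category_genes(records)
        assert "a" not in strict["high"]
        assert "a" in strict["low"]

    def test_medium_only(self):
        records = [self.rec("a", "E", "medium"), self.rec("a", "C", "medium")]
        assert "a" in lr.strict_category_genes(records)["medium"]


def brute_force_average_linkage(dist):
    """O(n^3) agglomerative average linkage over a dense distance matrix."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    nxt = n
    while len(clusters) > 1:
        (i, j), h = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        merged = clusters[i] + clusters[j]
        del clusters[i], clusters[j]
        d = {k: v for k, v in d.items() if i not in k and j not in k}
        for k, members in clusters.items():
            val = np.mean([dist[a, b] for a in merged for b in members])
            d[(min(k, nxt), max(k, nxt))] = val
        clusters[nxt] = merged
        merges.append((h, sorted(merged)))
        nxt += 1
    return merges


class TestClustering:
    def test_identical_rows_merge_first_at_zero(self):
        df = pd.DataFrame(
            [[1, 2, 3, 4], [2, 4, 6, 8], [4, 1, 1, 0], [0, 5, 1, 9]],
            index=list("abcd"),
        )
        Z, order, _ = cluster_rate_profiles(df)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert sorted(Z[0, :2]) == [0, 1]  # rows a and b (perfectly correlated)

    def test_anticorrelated_distance_two(self):
        df = pd.DataFrame([[1, 2, 3], [3, 2, 1], [1, 3, 1]], index=list("abc"))
        Z, _, _ = cluster_rate_profiles(df)
        heights = Z[:, 2]
        assert heights.max() <= 2.0 + 1e-12
        # a vs b are perfectly anticorrelated: they only meet at distance 2
        # after c joins one of them; the direct a-b distance is 2
        X = df.to_numpy(dtype=float)
        c = np.corrcoef(X)[0, 1]
        assert 1 - c == pytest.approx(2.0)

    def test_merge_heights_match_brute_force(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(5, 6)))
        X = df.to_numpy()
        dist = 1 - np.corrcoef(X)
        np.fill_diagonal(dist, 0)
        Z, _, _ = cluster_rate_profiles(df)
        expected = brute_force_average_linkage(dist)
        for (h, _), zh in zip(expected, Z[:, 2]):
            assert zh == pytest.approx(h, abs=1e-10)

    def test_zero_variance_row_handled(self):
        df = pd.DataFrame([[1, 1, 1], [1, 2, 3], [3, 1, 2]], index=list("abc"))
        Z, order, _ = cluster_rate_profiles(df)
        assert len(order) == 3  # degenerate row assigned distance 1, no crash


def test_calibration_params_from_yaml(tmp_path):
    cfg = tmp_path / "cal.yaml"
    cfg.write_text("embryo_total: 4.0e6\nmaternal_tpm_threshold: 10\n")
    p = CalibrationParams.from_yaml(cfg)
    assert p.embryo_total == 4e6
    assert p.maternal_tpm_threshold == 10.0
    assert p.fc_pseudocount == 10.0
    cfg.write_text("bogus_key: 1\n")
    with pytest.raises(ValueError, match="unknown"):
        CalibrationParams.from_yaml(cfg)
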