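"""Gene mapping, fold changes, and the two concordance classifiers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from concordx import concordance as cc
from concordx import synthetic_data as sd
from concordx.panel_io import ExpressionMatrix, Platform, SampleTable, Scale

PANEL = sd.default_panel(sd.SimulationConfig(n_genes=6, n_discordant=0))


def array_matrix(columns: dict, index) -> ExpressionMatrix:
    return ExpressionMatrix(values=pd.DataFrame(columns, index=index, dtype=float),
                            platform=Platform.ARRAY, scale=Scale.NORMALIZED)


def fc_frame(count, array):
    fc = pd.DataFrame({"log2fc_count": count, "log2fc_array": array},
                      index=[f"g{i}" for i in range(len(count))])
    fc["mean_expr_stratum"] = "medium"
    return fc


class TestGeneMap:
    def test_collapse_rules(self):
        ann = pd.DataFrame({"gene_symbol": ["GENE001", "GENE001", "GENE002"],
                            "probeset_id": ["GENE001_at", "GENE001_x_at", "GENE002_at"]})
        m = array_matrix({"s1": [120.0, 80.0, 10.0], "s2": [120.0, 80.0, 10.0]},
                         index=["GENE001_at", "GENE001_x_at", "GENE002_at"])
        gmap = cc.build_gene_map(PANEL, ann, m)
        assert gmap.resolved["GENE001"] == "GENE001_at"      # higher mean wins
        assert gmap.resolved["GENE002"] == "GENE002_at"      # single probe set

    def test_controls_excluded_and_unmapped_reported(self):
        ann = pd.DataFrame({"gene_symbol": ["GENE001", "POS_A", "NEG_A"],
                            "probeset_id": ["GENE001_at", "POS_A_at", "NEG_A_at"]})
        m = array_matrix({"s": [1.0, 1.0, 1.0]}, index=["GENE001_at", "POS_A_at", "NEG_A_at"])
        gmap = cc.build_gene_map(PANEL, ann, m)
        assert "POS_A" not in gmap.resolved and "NEG_A" not in gmap.resolved
        assert set(gmap.unmapped) == set(PANEL.endogenous[1:]) | set(PANEL.housekeeping)

    def test_default_fixture_maps_all_genes(self, gene_map):
        assert len(gene_map.genes) == 332
        assert gene_map.unmapped == []


class TestCrossPlatformSampleR:
    def test_affine_transform_gives_unit_between_r(self, dataset, gene_map, normalized,
                                                   qc_passed):
        from concordx.nanostring import log2_transform
        norm, _ = normalized
        m = log2_transform(norm).subset_samples(qc_passed[:6])
        fake_array = ExpressionMatrix(
            values=(2.0 * m.values.loc[[g for g in gene_map.genes]] + 3.0).rename(
                index={g: gene_map.resolved[g] for g in gene_map.genes}),
            platform=Platform.ARRAY, scale=Scale.LOG2)
        out = cc.cross_platform_sample_r(m, fake_array, gene_map)
        assert out["between_r_median"] == pytest.approx(1.0)

    def test_between_platform_r_below_within(self, dataset, gene_map, normalized, qc_passed):
        """Independent per-gene affinities: absolute levels correlate poorly
        across platforms while within-platform correlation stays high."""
        from concordx.nanostring import log2_transform
        norm, _ = normalized
        out = cc.cross_platform_sample_r(
            log2_transform(norm).subset_samples(qc_passed),
            log2_transform(dataset.array_norm).subset_samples(qc_passed),
            gene_map)
        assert out["between_r_median"] < out["within_count_r_median"]
        assert out["between_r_median"] < out["within_array_r_median"]

    def test_too_few_genes_rejected(self, gene_map):
        small = cc.GeneMap(resolved={"GENE001": "GENE001_at"}, unmapped=[], collapse_rule="max_mean")
        m = ExpressionMatrix(values=pd.DataFrame({"s1": [1.0], "s2": [2.0]},
                                                 index=["GENE001"]),
                             platform=Platform.COUNT, scale=Scale.LOG2)
        a = ExpressionMatrix(values=pd.DataFrame({"s1": [1.0], "s2": [2.0]},
                                                 index=["GENE001_at"]),
                             platform=Platform.ARRAY, scale=Scale.LOG2)
        with pytest.raises(ValueError, match=">= 3 mapped genes"):
            cc.cross_platform_sample_r(m, a, small)


class TestFoldChangeTable:
    def _toy(self, n_genes=12, mean_a=200.0, mean_b=100.0):
        genes = [f"GENE{i + 1:03d}" for i in range(n_genes)]
        rows = []
        for case, subtype in (("ER1", "ERpos"), ("TNB1", "TNB")):
            for d in (1, 2):
                rows.append((f"{case}-Lab1-D{d}", case, subtype, "Lab1", d, "op", 100.0, True))
        meta = SampleTable(pd.DataFrame(
            rows, columns=["sample_id", "case_id", "subtype", "lab", "day",
                           "operator", "rna_mass_ng", "qc_pass"]))
        level = np.array([mean_a, mean_a, mean_b, mean_b])
        scale = np.exp2(np.arange(n_genes) / 2)[:, None]   # spread across strata
        values = pd.DataFrame(np.tile(level, (n_genes, 1)) * scale,
                              index=genes, columns=meta.sample_ids)
        m_count = ExpressionMatrix(values=values, platform=Platform.COUNT,
                                   scale=Scale.NORMALIZED)
        m_array = ExpressionMatrix(values=values.rename(index=lambda g: f"{g}_at"),
                                   platform=Platform.ARRAY, scale=Scale.NORMALIZED)
        gmap = cc.GeneMap(resolved={g: f"{g}_at" for g in genes}, unmapped=[],
                          collapse_rule="max_mean")
        return m_count, m_array, meta, gmap

    def test_pseudocount_ratio_of_means(self):
        m_count, m_array, meta, gmap = self._toy(n_genes=1)
        fc = cc.fold_change_table(m_count, m_array, meta, gmap)
        expected = np.log2(200.5 / 100.5)
        assert fc["log2fc_count"].iloc[0] == pytest.approx(expected, abs=1e-10)
        assert fc["log2fc_count"].iloc[0] == pytest.approx(0.9964, abs=1e-4)

    def test_equal_means_zero_fc(self):
        m_count, m_array, meta, gmap = self._toy(n_genes=3, mean_a=100.0, mean_b=100.0)
        fc = cc.fold_change_table(m_count, m_array, meta, gmap)
        assert np.allclose(fc["log2fc_count"], 0.0)

    def test_tertile_partition_sizes(self):
        m_count, m_array, meta, gmap = self._toy(n_genes=12)
        fc = cc.fold_change_table(m_count, m_array, meta, gmap)
        assert fc["mean_expr_stratum"].value_counts().to_dict() == {
            "low": 4, "medium": 4, "high": 4}

    def test_empty_group_rejected(self):
        m_count, m_array, meta, gmap = self._toy()
        with pytest.raises(ValueError, match="no samples"):
            cc.fold_change_table(m_count, m_array, meta, gmap,
                                 samples_a=["missing-sample"])


class TestStratifiedCorrelation:
    def test_identical_vectors_unit_r(self):
        fc = fc_frame([1.0, -1.0, 2.0], [1.0, -1.0, 2.0])
        out = cc.stratified_fc_correlation(fc)
        assert out["overall"] == pytest.approx(1.0)
        assert out["medium"] == pytest.approx(1.0)

    def test_small_stratum_undefined(self):
        fc = fc_frame([1.0, -1.0, 2.0, 0.5], [1.0, -1.0, 2.0, 0.4])
        fc.loc["g3", "mean_expr_stratum"] = "low"
        out = cc.stratified_fc_correlation(fc)
        assert np.isnan(out["low"])
        assert np.isnan(out["high"])


class TestClassifyTwofold:
    @pytest.mark.parametrize("count,array,tier", [
        (0.5, 0.9, "within2fold"),
        (1.5, 2.0, "concordant_change"),
        (1.5, -1.2, "discordant"),
        (0.0, 0.0, "within2fold"),
        (1.5, -0.5, "within2fold"),    # opposite signs, one below threshold
        (1.5, 0.5, "concordant_change"),
    ])
    def test_tier_examples(self, count, array, tier):
        tiers, _ = cc.classify_twofold(fc_frame([count], [array]))
        assert tiers.iloc[0] == tier

    def test_summary_partition(self):
        tiers, summary = cc.classify_twofold(fc_frame([0.5, 1.5, 1.5], [0.9, 2.0, -1.2]))
        assert summary["n_within2fold"] + summary["n_concordant_change"] \
            + summary["n_discordant"] == summary["n_genes"]
        assert summary["concordant_fraction"] == pytest.approx(2 / 3)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-5, 5), st.floats(-5, 5)),
                    min_size=3, max_size=20))
    def test_swap_and_negation_symmetry(self, pairs):
        """The discordant set ignores which platform is which; negating both
        fold changes (relabeling the groups) preserves every tier."""
        count = [p[0] for p in pairs]
        array = [p[1] for p in pairs]
        tiers, _ = cc.classify_twofold(fc_frame(count, array))
        swapped, _ = cc.classify_twofold(fc_frame(array, count))
        assert ((tiers == "discordant") == (swapped == "discordant")).all()
        negated, _ = cc.classify_twofold(fc_frame([-c for c in count],
                                                  [-a for a in array]))
        assert (tiers == negated).all()


class TestRegressionBand:
    def test_perfect_fit_all_in_band(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        fit, tiers, summary = cc.classify_regression_band(fc_frame(x, x))
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-12)
        assert (tiers == "in_band").all()
        assert summary["concordant_fraction"] == 1.0

    def test_planted_opposite_outlier_found(self):
        """Ten-point toy set: nine near y = x, one opposite-sign point far
        off the line is the only out_band_opposite gene."""
        rng = np.random.default_rng(42)
        x = np.linspace(-3, 3, 9)
        y = x + rng.normal(0, 0.05, 9)
        x_all = np.append(x, 2.0)
        y_all = np.append(y, -2.0)
        fit, tiers, _ = cc.classify_regression_band(fc_frame(y_all, x_all))
        assert tiers.iloc[-1] == "out_band_opposite"
        assert (tiers.iloc[:-1] == "in_band").all()
        # the planted point sits well outside the band
        resid = y_all[-1] - (fit.slope * x_all[-1] + fit.intercept)
        assert abs(resid) > fit.band_halfwidth

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1.5, 20)
        y = x + rng.normal(0, 0.3, 20)
        fc = fc_frame(y, x)
        _, tiers, _ = cc.classify_regression_band(fc)
        perm = rng.permutation(20)
        _, tiers_perm, _ = cc.classify_regression_band(fc.iloc[perm])
        assert (tiers_perm.sort_index() == tiers.sort_index()).all()

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValueError, match="zero predictor variance"):
            cc.classify_regression_band(fc_frame([1.0, 2.0, 3.0], [1.0, 1.0, 1.0]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_normal_equations(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 2, 20)
        y = 1.3 * x + rng.normal(0, 0.5, 20)
        fit, tiers, _ = cc.classify_regression_band(fc_frame(y, x))
        # explicit normal equations
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        intercept = y.mean() - slope * x.mean()
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)
        resid = np.array([y[i] - (slope * x[i] + intercept) for i in range(20)])
        assert fit.residual_sd == pytest.approx(np.sqrt((resid ** 2).sum() / 18), abs=1e-10)
        in_band = np.abs(resid) <= 1.96 * fit.residual_sd
        assert ((tiers == "in_band").to_numpy() == in_band).all()

    def test_band_never_less_concordant_than_twofold_beyond_one_gene(self, fold_changes):
        """On pooled data the two classifiers agree to within one gene; the
        band rule is never materially stricter."""
        _, s2 = cc.classify_twofold(fold_changes)
        _, _, sb = cc.classify_regression_band(fold_changes)
        assert sb["concordant_fraction"] >= s2["concordant_fraction"] - 1.0 / s2["n_genes"]


class TestPooling:
    def test_full_pool_reproduces_overall_r(self, dataset, normalized, qc_passed, gene_map,
                                            fold_changes):
        norm, _ = normalized
        meta = dataset.design.subset(qc_passed)
        n_full = min(
            len(meta.samples_where(subtype="ERpos")),
            len(meta.samples_where(subtype="TNB")))
        curve = cc.pooling_curve(norm.subset_samples(qc_passed),
                                 dataset.array_norm.subset_samples(qc_passed),
                                 meta, gene_map, pool_sizes=[n_full])
        # full pool uses every sample of the smaller group; compare against a
        # fold-change table built on those same deterministic subsets
        samples_a = sorted(meta.samples_where(subtype="ERpos"))[:n_full]
        samples_b = sorted(meta.samples_where(subtype="TNB"))[:n_full]
        fc = cc.fold_change_table(norm.subset_samples(qc_passed),
                                  dataset.array_norm.subset_samples(qc_passed),
                                  meta, gene_map, samples_a=samples_a, samples_b=samples_b)
        expected = cc.stratified_fc_correlation(fc)["overall"]
        assert curve["r"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_single_sample_pool_is_finite(self, dataset, normalized, qc_passed, gene_map):
        norm, _ = normalized
        meta = dataset.design.subset(qc_passed)
        curve = cc.pooling_curve(norm.subset_samples(qc_passed),
                                 dataset.array_norm.subset_samples(qc_passed),
                                 meta, gene_map, pool_sizes=[1])
        assert np.isfinite(curve["r"].iloc[0])

    def test_oversized_pool_rejected(self, dataset, normalized, qc_passed, gene_map):
        norm, _ = normalized
        meta = dataset.design.subset(qc_passed)
        with pytest.raises(ValueError, match="exceeds group size"):
            cc.pooling_curve(norm.subset_samples(qc_passed),
                             dataset.array_norm.subset_samples(qc_passed),
                             meta, gene_map, pool_sizes=[40])
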