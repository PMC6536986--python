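"""Lane QC metrics and the three-step normalization chain."""

import numpy as np
import pandas as pd
import pytest

from concordx import nanostring as ns
from concordx import synthetic_data as sd
from concordx.panel_io import ExpressionMatrix, LaneCounts, Platform, Scale

PANEL = sd.default_panel()


def make_lane(pos=None, neg=None, endo_value=100, fov=(276, 280), bd=0.5):
    counts = pd.Series(endo_value, index=PANEL.probe_ids, dtype=np.int64)
    ladder = PANEL.positive_ladder()
    if pos is not None:
        counts[ladder.index] = pos
    if neg is not None:
        counts[PANEL.negative] = neg
    return LaneCounts(sample_id="L", counts=counts, fov_requested=fov[1],
                      fov_counted=fov[0], binding_density=bd)


def make_matrix(columns: dict, scale=Scale.NORMALIZED):
    values = pd.DataFrame(columns, index=PANEL.probe_ids, dtype=float)
    return ExpressionMatrix(values=values, platform=Platform.COUNT, scale=scale)


@pytest.fixture(scope="module")
def clean_dataset():
    """No degraded lanes: every positive-control count is nonzero, so the
    chain's multiplicative algebra is exact (no +0.5 offsets involved)."""
    return sd.simulate_dataset(sd.SimulationConfig(outliers=()), seed=1)


class TestLaneQC:
    def test_perfectly_linear_positives_have_r2_one(self):
        ladder = PANEL.positive_ladder()
        lane = make_lane(pos=(100 * ladder).round().astype(int), neg=3)
        report = ns.qc_lane(lane, PANEL)
        assert report.pos_control_r2 == pytest.approx(1.0, abs=1e-4)
        assert report.passed

    def test_fov_ratio_boundary_passes_at_threshold(self):
        lane = make_lane(pos=(100 * PANEL.positive_ladder()).round().astype(int),
                         neg=3, fov=(210, 280))
        report = ns.qc_lane(lane, PANEL)
        assert report.fov_ratio == pytest.approx(0.75)
        assert "fov_ratio" not in report.flags        # threshold is >=

    def test_lod_fails_on_zero_variance_background(self):
        # negatives all 10 (sd 0): threshold 10; low positive 9 -> fail
        pos = (100 * PANEL.positive_ladder()).round().astype(int)
        pos.iloc[-2] = 9                               # the 0.5 fM LOD probe
        lane = make_lane(pos=pos, neg=10)
        report = ns.qc_lane(lane, PANEL)
        assert not report.lod_pass
        assert "lod" in report.flags and not report.passed

    def test_binding_density_range_flagged(self):
        lane = make_lane(pos=(100 * PANEL.positive_ladder()).round().astype(int),
                         neg=3, bd=3.0)
        assert "binding_density" in ns.qc_lane(lane, PANEL).flags

    def test_too_few_positives_rejected(self):
        two_pos = PANEL.table[PANEL.table["code_class"].map(lambda c: c.value) != "Positive"]
        extra = PANEL.table[PANEL.table["code_class"].map(lambda c: c.value) == "Positive"].head(2)
        from concordx.panel_io import PanelAnnotation
        small = PanelAnnotation(pd.concat([two_pos, extra]).reset_index(drop=True).assign(
            code_class=lambda d: d["code_class"].map(lambda c: c.value)))
        counts = pd.Series(10, index=small.probe_ids, dtype=np.int64)
        lane = LaneCounts(sample_id="L", counts=counts, fov_requested=280,
                          fov_counted=276, binding_density=0.5)
        with pytest.raises(ValueError, match="fewer than 3"):
            ns.qc_lane(lane, small)


class TestNormalizePositive:
    def test_hand_computed_factors(self):
        m = make_matrix({"s1": 100.0, "s2": 400.0}, scale=Scale.RAW)
        out, factors = ns.normalize_positive(m, PANEL)
        assert factors.pos_factor["s1"] == pytest.approx(2.0)
        assert factors.pos_factor["s2"] == pytest.approx(0.5)
        assert out.scale == Scale.NORMALIZED

    def test_identical_samples_unchanged(self):
        m = make_matrix({"s1": 100.0, "s2": 100.0}, scale=Scale.RAW)
        out, factors = ns.normalize_positive(m, PANEL)
        assert np.allclose(factors.pos_factor, 1.0)
        assert np.allclose(out.values, m.values)

    def test_second_pass_factors_are_unity(self, clean_dataset):
        once, _ = ns.normalize_positive(clean_dataset.count_raw, clean_dataset.panel)
        relabeled = ExpressionMatrix(values=once.values, platform=once.platform,
                                     scale=Scale.RAW)
        _, factors = ns.normalize_positive(relabeled, clean_dataset.panel)
        assert np.allclose(factors.pos_factor, 1.0, atol=1e-12)

    def test_zero_positive_count_warns(self):
        m = make_matrix({"s1": 100.0, "s2": 100.0}, scale=Scale.RAW)
        m.values.loc[PANEL.positive[0], "s1"] = 0.0
        with pytest.warns(UserWarning, match="positive-control"):
            ns.normalize_positive(m, PANEL)

    def test_wrong_scale_refused(self):
        m = make_matrix({"s1": 1.0})
        with pytest.raises(ValueError, match="scale"):
            ns.normalize_positive(m, PANEL)


class TestSubtractBackground:
    def test_zero_variance_background(self):
        m = make_matrix({"s1": 15.0})
        m.values.loc[PANEL.negative, "s1"] = 10.0
        out, b = ns.subtract_background(m, PANEL)
        assert b["s1"] == pytest.approx(10.0)
        assert out.values.loc[PANEL.endogenous[0], "s1"] == pytest.approx(5.0)

    def test_floor_applied(self):
        m = make_matrix({"s1": 3.0})
        m.values.loc[PANEL.negative, "s1"] = 10.0
        out, _ = ns.subtract_background(m, PANEL)
        assert out.values.loc[PANEL.endogenous[0], "s1"] == 1.0

    def test_sample_sd_background(self):
        # negatives alternate 8/12: mean 10, sd(n-1) 2.1381, threshold 14.2762
        m = make_matrix({"s1": 20.0})
        m.values.loc[PANEL.negative, "s1"] = [8, 12, 8, 12, 8, 12, 8, 12]
        out, b = ns.subtract_background(m, PANEL)
        assert b["s1"] == pytest.approx(10 + 2 * np.std([8, 12] * 4, ddof=1))
        assert b["s1"] == pytest.approx(14.2762, abs=1e-4)
        assert out.values.loc[PANEL.endogenous[0], "s1"] == pytest.approx(5.7238, abs=1e-4)

    def test_controls_left_untouched(self):
        m = make_matrix({"s1": 50.0})
        m.values.loc[PANEL.negative, "s1"] = 10.0
        out, _ = ns.subtract_background(m, PANEL)
        assert (out.values.loc[PANEL.positive, "s1"] == 50.0).all()
        assert (out.values.loc[PANEL.negative, "s1"] == 10.0).all()


class TestNormalizeHousekeeping:
    def test_hand_computed_factors_and_equal_geomeans(self):
        m = make_matrix({"s1": 50.0, "s2": 50.0})
        m.values.loc[PANEL.housekeeping, "s1"] = 100.0
        m.values.loc[PANEL.housekeeping, "s2"] = 400.0
        out, factors = ns.normalize_housekeeping(m, PANEL)
        assert factors.hk_factor["s1"] == pytest.approx(2.0)
        assert factors.hk_factor["s2"] == pytest.approx(0.5)
        geo = np.exp(np.log(out.values.loc[PANEL.housekeeping]).mean(axis=0))
        assert np.allclose(geo / geo.iloc[0], 1.0, rtol=1e-12)

    def test_single_sample_factor_one(self):
        m = make_matrix({"only": 123.0})
        _, factors = ns.normalize_housekeeping(m, PANEL)
        assert factors.hk_factor["only"] == pytest.approx(1.0)

    def test_equal_housekeeping_identity(self):
        m = make_matrix({"s1": 10.0, "s2": 20.0})
        m.values.loc[PANEL.housekeeping] = 150.0
        _, factors = ns.normalize_housekeeping(m, PANEL)
        assert np.allclose(factors.hk_factor, 1.0)


class TestLog2Transform:
    @pytest.mark.parametrize("value,expected", [
        (0.0, 0.0),
        (1023.0, 10.0),
        (5.724, np.log2(6.724)),
    ])
    def test_values(self, value, expected):
        m = make_matrix({"s1": value})
        out = ns.log2_transform(m)
        assert out.values.iloc[0, 0] == pytest.approx(expected, abs=1e-4)
        assert out.scale == Scale.LOG2

    def test_nonpositive_offset_rejected(self):
        with pytest.raises(ValueError, match="offset"):
            ns.log2_transform(make_matrix({"s1": 1.0}), offset=0.0)


class TestChainInvariants:
    def test_factor_geometric_means_are_one(self, normalized):
        _, factors = normalized
        for col in ("pos_factor", "hk_factor"):
            f = getattr(factors, col)
            assert np.exp(np.log(f).mean()) == pytest.approx(1.0, abs=1e-12)

    def test_housekeeping_geomeans_equal_after_chain(self, dataset, normalized):
        norm, _ = normalized
        geo = np.exp(np.log(norm.values.loc[dataset.panel.housekeeping]).mean(axis=0))
        assert np.allclose(geo / geo.iloc[0], 1.0, rtol=1e-9)

    def test_scale_invariance_geomean_one_scalings(self, clean_dataset):
        """Per-sample rescaling with geometric mean 1 leaves the chain output
        exactly unchanged (the ensemble reference is unmoved)."""
        rng = np.random.default_rng(0)
        scales = np.exp(rng.normal(0.0, 0.5, len(clean_dataset.count_raw.sample_ids)))
        scales /= np.exp(np.log(scales).mean())
        scaled = ExpressionMatrix(values=clean_dataset.count_raw.values * scales,
                                  platform=Platform.COUNT, scale=Scale.RAW)
        base, _ = ns.normalize_chain(clean_dataset.count_raw, clean_dataset.panel)
        out, _ = ns.normalize_chain(scaled, clean_dataset.panel)
        genes = clean_dataset.panel.endogenous + clean_dataset.panel.housekeeping
        assert np.allclose(out.values.loc[genes], base.values.loc[genes], rtol=1e-9)

    def test_arbitrary_scaling_shifts_only_global_constant(self, clean_dataset):
        """An arbitrary per-sample rescaling moves every un-floored value by
        the single constant geomean(scales); relative structure is intact."""
        dataset = clean_dataset
        rng = np.random.default_rng(1)
        scales = np.exp(rng.normal(0.0, 0.5, len(dataset.count_raw.sample_ids)))
        t = np.exp(np.log(scales).mean())
        scaled = ExpressionMatrix(values=dataset.count_raw.values * scales,
                                  platform=Platform.COUNT, scale=Scale.RAW)
        base, _ = ns.normalize_chain(dataset.count_raw, dataset.panel)
        out, _ = ns.normalize_chain(scaled, dataset.panel)
        genes = dataset.panel.endogenous + dataset.panel.housekeeping
        b = base.values.loc[genes].to_numpy()
        o = out.values.loc[genes].to_numpy()
        free = (b > 1.5) & (o > 1.5 * t)        # cells not pinned by the floor
        assert free.mean() > 0.5
        assert np.allclose(o[free], b[free] * t, rtol=1e-9)

    def test_chain_tightens_technical_replicates(self, dataset, normalized, qc_passed):
        """Median pairwise distance between technical replicates shrinks
        versus raw counts after normalization."""
        norm, _ = normalized
        genes = dataset.panel.endogenous + dataset.panel.housekeeping

        def median_replicate_distance(matrix):
            log_m = np.log2(matrix.values.loc[genes, qc_passed] + 1.0)
            dists = []
            for _, grp in dataset.design.subset(qc_passed).table.groupby("case_id"):
                ids = grp["sample_id"].tolist()
                for i in range(len(ids)):
                    for j in range(i + 1, len(ids)):
                        dists.append(np.linalg.norm(log_m[ids[i]] - log_m[ids[j]]))
            return np.median(dists)

        assert median_replicate_distance(norm) < median_replicate_distance(dataset.count_raw)
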