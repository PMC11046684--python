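import numpy as np
import pandas as pd
import pytest

from conftest import make_cohort, noiseless_cohort

from stereoshape.analysis import (
    GroupStats,
    bh_fdr,
    cochran_q,
    drawing_shape_ratio,
    mcnemar_pair,
    paired_cohen_d,
    per_participant_correlation,
    prediction_fit_metrics,
    rm_anova_2x2,
)
from stereoshape.observers import (
    simulate_shape_adjustment,
    simulate_slant_adjustment,
)


def response_table(task, data):
    """data: {pid: [(axis, eye, mag, rep, response), ...]}"""
    rows = []
    for pid, trials in data.items():
        for axis, eye, mag, rep, resp in trials:
            rows.append((pid, task, axis, eye, mag, rep, resp))
    return pd.DataFrame(rows, columns=[
        "participant_id", "task", "axis", "eye",
        "magnification_pct", "repetition", "response",
    ])


def linear_table(slopes, mags=(-4, -2, 0, 2, 4), task="slant", axis="horizontal"):
    data = {}
    for pid, slope in slopes.items():
        data[pid] = [(axis, "right" if m >= 0 else "left", float(m), 0,
                      slope * m) for m in mags]
    return response_table(task, data)


class TestDrawingShapeRatio:
    def test_basic_values(self):
        assert drawing_shape_ratio(10, 10) == 1.0
        assert drawing_shape_ratio(10, 10.5) == pytest.approx(1.05)

    def test_reciprocal_inputs(self):
        assert drawing_shape_ratio(8, 10) == pytest.approx(
            1 / drawing_shape_ratio(10, 8))

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            drawing_shape_ratio(0, 10)


class TestPerParticipantCorrelation:
    @pytest.mark.filterwarnings("ignore:Precision loss")
    def test_perfectly_linear_gives_unit_r(self):
        table = linear_table({"P0": 2.0, "P1": 0.5})
        per, grp = per_participant_correlation(table, "slant", "horizontal")
        assert per["r"].tolist() == pytest.approx([1.0, 1.0])
        assert grp.mean == pytest.approx(1.0)

    @pytest.mark.filterwarnings("ignore:Precision loss")
    def test_sign_flip_gives_minus_one(self):
        table = linear_table({"P0": -2.0, "P1": -0.7})
        per, _ = per_participant_correlation(table, "slant", "horizontal")
        assert per["r"].tolist() == pytest.approx([-1.0, -1.0])

    def test_zero_variance_raises(self):
        table = linear_table({"P0": 0.0})
        with pytest.raises(ValueError, match="zero variance"):
            per_participant_correlation(table, "slant", "horizontal")

    def test_group_stats_match_scipy_convention(self):
        table = linear_table({"P0": 1.0, "P1": 2.0, "P2": -0.5, "P3": 0.1})
        _, grp = per_participant_correlation(table, "slant", "horizontal")
        assert grp.df == 3
        assert grp.cohen_d == pytest.approx(grp.mean / grp.sd)

    def test_default_cohort_horizontal_slant_strongly_negative(self, geom):
        cfg = make_cohort(n=8, reps=2, seed=0,
                          sds={"gain_h": 0.05}, slant_noise_sd=1.0)
        table = simulate_slant_adjustment(cfg, geom)
        _, grp = per_participant_correlation(table, "slant", "horizontal")
        assert grp.mean < -0.9


class TestPredictionFitMetrics:
    def _tables(self, geom, screen_obj, shift=0.0):
        cfg = noiseless_cohort(n=2, gain_h=1.0, gain_v=0.85, coupling=1.0)
        slant = simulate_slant_adjustment(cfg, geom)
        shape = simulate_shape_adjustment(cfg, geom, screen_obj)
        shape = shape.assign(response=shape["response"] + shift)
        return shape, slant

    @pytest.mark.filterwarnings("ignore:Precision loss")
    def test_noiseless_cohort_near_perfect_fit(self, geom, screen_obj):
        shape, slant = self._tables(geom, screen_obj)
        per, group = prediction_fit_metrics(shape, slant, screen_obj)
        # residual is pure cubic lack-of-fit of the smooth generative
        # curve: tiny but not zero
        assert (per["r2"] > 0.99).all()
        assert (per["rmse"] < 0.005).all()

    @pytest.mark.filterwarnings("ignore:Precision loss")
    def test_constant_offset_keeps_r2_but_not_rmse(self, geom, screen_obj):
        shape, slant = self._tables(geom, screen_obj, shift=0.02)
        per, _ = prediction_fit_metrics(shape, slant, screen_obj)
        base, _ = prediction_fit_metrics(*self._tables(geom, screen_obj),
                                         screen_obj)
        np.testing.assert_allclose(per["r2"], base["r2"], atol=1e-9)
        # RMSE is dominated by the 0.02 offset (base lack-of-fit < 0.004)
        np.testing.assert_allclose(per["rmse"], 0.02, atol=1.5e-3)
        assert (per["rmse"] > base["rmse"]).all()

    def test_r2_affine_invariant_rmse_not(self):
        pred = np.array([1.0, 1.01, 1.02, 1.03, 1.05])
        obs = pred + np.random.default_rng(0).normal(0, 0.002, 5)
        from scipy.stats import pearsonr
        r2 = pearsonr(pred, obs)[0] ** 2
        r2_scaled = pearsonr(0.5 * pred + 3, obs)[0] ** 2
        assert r2 == pytest.approx(r2_scaled, abs=1e-12)
        rmse = np.sqrt(np.mean((obs - pred) ** 2))
        rmse_scaled = np.sqrt(np.mean((obs - (0.5 * pred + 3)) ** 2))
        assert rmse != pytest.approx(rmse_scaled, abs=1e-6)

    def test_missing_slant_data_reported(self, geom, screen_obj):
        shape, slant = self._tables(geom, screen_obj)
        slant = slant[slant["participant_id"] != "P01"]
        with pytest.raises(ValueError, match="P01"):
            prediction_fit_metrics(shape, slant, screen_obj)


def drawings_frame(cells):
    """cells: (n, 4) array ordered control-phone, control-square,
    experimental-phone, experimental-square."""
    rows = []
    for i, vals in enumerate(np.atleast_2d(cells)):
        for (s, o), v in zip(
            [("control", "phone"), ("control", "square"),
             ("experimental", "phone"), ("experimental", "square")], vals):
            rows.append((f"P{i}", s, o, 10.0, 10.0 * v))
    return pd.DataFrame(rows, columns=[
        "participant_id", "spectacles", "object", "left_cm", "right_cm"])


class TestRmAnova:
    def test_identical_cells_give_zero_f(self):
        cells = np.ones((5, 4))
        res = rm_anova_2x2(drawings_frame(cells), n_permutations=50, seed=0)
        assert (res["F"] == 0).all()

    def test_pure_spectacles_shift_gives_infinite_f(self):
        cells = np.ones((5, 4))
        cells[:, 2:] += 0.05  # experimental cells only, zero noise
        res = rm_anova_2x2(drawings_frame(cells), n_permutations=50, seed=0)
        f = res.set_index("effect")["F"]
        assert np.isinf(f["spectacles"])
        assert f["object"] == 0
        assert f["interaction"] == 0

    def test_four_participant_dataset_matches_manual_decomposition(self):
        # manual within-subject sums of squares, computed independently
        cells = np.array([
            [1.00, 1.02, 1.06, 1.05],
            [0.98, 1.00, 1.07, 1.09],
            [1.01, 0.99, 1.04, 1.06],
            [1.00, 1.01, 1.08, 1.07],
        ])
        res = rm_anova_2x2(drawings_frame(cells), n_permutations=10, seed=0)
        f = res.set_index("effect")["F"]

        y = cells.reshape(4, 2, 2)  # participant x spectacles x object
        m = y.mean()
        m_s = y.mean(axis=(0, 2))
        m_o = y.mean(axis=(0, 1))
        m_i = y.mean(axis=(1, 2))
        m_is = y.mean(axis=2)
        m_io = y.mean(axis=1)
        m_so = y.mean(axis=0)
        n = 4
        ss_s = 2 * n * np.sum((m_s - m) ** 2)
        ss_sxp = 2 * np.sum((m_is - m_s[None, :] - m_i[:, None] + m) ** 2)
        ss_o = 2 * n * np.sum((m_o - m) ** 2)
        ss_oxp = 2 * np.sum((m_io - m_o[None, :] - m_i[:, None] + m) ** 2)
        ss_so = n * np.sum((m_so - m_s[:, None] - m_o[None, :] + m) ** 2)
        resid = (y - m_is[:, :, None] - m_io[:, None, :] - m_so[None, :, :]
                 + m_s[None, :, None] + m_o[None, None, :] + m_i[:, None, None]
                 - m)
        ss_soxp = np.sum(resid ** 2)
        assert f["spectacles"] == pytest.approx(ss_s / (ss_sxp / (n - 1)))
        assert f["object"] == pytest.approx(ss_o / (ss_oxp / (n - 1)))
        assert f["interaction"] == pytest.approx(ss_so / (ss_soxp / (n - 1)))

    def test_matches_pingouin_on_noisy_data(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        cells = 1 + rng.normal(0, 0.03, (12, 4))
        cells[:, 2:] += 0.04
        df = drawings_frame(cells)
        res = rm_anova_2x2(df, n_permutations=10, seed=0).set_index("effect")
        df["ratio"] = df["right_cm"] / df["left_cm"]
        ref = pg.rm_anova(data=df, dv="ratio", within=["spectacles", "object"],
                          subject="participant_id")
        for ours, theirs in [("spectacles", "spectacles"), ("object", "object"),
                             ("interaction", "spectacles * object")]:
            row = ref[ref["Source"] == theirs].iloc[0]
            assert res.loc[ours, "F"] == pytest.approx(row["F"], rel=1e-9)
            assert res.loc[ours, "p_param"] == pytest.approx(row["p_unc"],
                                                             rel=1e-9)

    def test_permutation_p_is_seeded_and_reproducible(self):
        rng = np.random.default_rng(3)
        cells = 1 + rng.normal(0, 0.02, (8, 4))
        df = drawings_frame(cells)
        a = rm_anova_2x2(df, n_permutations=200, seed=11)
        b = rm_anova_2x2(df, n_permutations=200, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_incomplete_design_raises(self):
        df = drawings_frame(np.ones((3, 4)))
        df = df[~((df["participant_id"] == "P1")
                  & (df["spectacles"] == "control"))]
        with pytest.raises(ValueError, match="incomplete"):
            rm_anova_2x2(df, n_permutations=10, seed=0)


class TestCochranQ:
    def test_equal_column_totals_give_zero(self):
        mat = np.array([[1, 0], [0, 1], [1, 1], [0, 0]])
        q, df, p = cochran_q(mat)
        assert q == 0 and df == 1 and p == 1.0

    def test_toy_matrix_matches_hand_computation(self):
        # G = (3,1,1,2), L = (2,2,2,1): Q = 4*3*2.75 / (28-13) = 2.2
        mat = np.array([
            [1, 0, 0, 1],
            [1, 1, 0, 0],
            [1, 0, 1, 0],
            [0, 0, 0, 1],
        ])
        q, df, p = cochran_q(mat)
        assert q == pytest.approx(2.2)
        assert df == 3

    def test_k2_equals_uncorrected_mcnemar(self):
        rng = np.random.default_rng(0)
        mat = (rng.random((30, 2)) < [0.3, 0.6]).astype(int)
        q, _, _ = cochran_q(mat)
        b = np.sum((mat[:, 0] == 1) & (mat[:, 1] == 0))
        c = np.sum((mat[:, 0] == 0) & (mat[:, 1] == 1))
        assert q == pytest.approx((b - c) ** 2 / (b + c), abs=1e-9)

    def test_degenerate_rows_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            cochran_q(np.array([[1, 1], [0, 0]]))


class TestMcNemar:
    def test_equal_discordants_give_zero(self):
        x = np.array([1, 0, 1, 0])
        y = np.array([0, 1, 0, 1])
        chi2, p, _ = mcnemar_pair(x, y)
        assert chi2 == 0.0  # continuity correction clamps at zero
        assert p > 0.9

    def test_b1_c5_gives_1_5(self):
        # (|1-5| - 1)^2 / 6 = 9/6
        x = np.array([1] + [0] * 5 + [0] * 4)
        y = np.array([0] + [1] * 5 + [0] * 4)
        chi2, p, _ = mcnemar_pair(x, y)
        assert chi2 == pytest.approx(1.5)

    def test_all_zero_column_gets_haldane_correction(self):
        control = np.zeros(10, dtype=int)
        experimental = np.array([1] * 6 + [0] * 4)
        _, _, orat = mcnemar_pair(control, experimental)
        expected = (0.5 / 10.5) / (6 / 4)
        assert orat == pytest.approx(expected)
        assert np.isfinite(orat)

    def test_no_discordance(self):
        x = np.array([1, 1, 0])
        chi2, p, _ = mcnemar_pair(x, x)
        assert (chi2, p) == (0.0, 1.0)

    def test_exact_binomial_option(self):
        x = np.array([1] * 2 + [0] * 8)
        y = np.array([0] * 2 + [1] * 6 + [0] * 2)
        _, p, _ = mcnemar_pair(x, y, exact=True)
        from scipy.stats import binomtest
        assert p == pytest.approx(binomtest(2, 8, 0.5).pvalue)


class TestBhFdr:
    def test_single_p_unchanged(self):
        p_adj, rej = bh_fdr([0.03])
        assert p_adj[0] == pytest.approx(0.03)
        assert rej[0]

    def test_all_equal_ps_unchanged(self):
        p_adj, _ = bh_fdr([0.02, 0.02, 0.02])
        np.testing.assert_allclose(p_adj, 0.02)

    def test_step_up_example(self):
        p_adj, _ = bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(p_adj, 0.04)

    def test_monotone_after_sorting(self):
        rng = np.random.default_rng(1)
        p = rng.random(20)
        p_adj, _ = bh_fdr(p)
        assert np.all(np.diff(p_adj[np.argsort(p)]) >= -1e-12)


class TestEffectSizes:
    def test_paired_cohen_d(self):
        x = np.array([1.05, 1.08, 1.02, 1.06])
        y = np.array([1.00, 1.01, 0.99, 1.02])
        d = paired_cohen_d(x, y)
        diff = x - y
        assert d == pytest.approx(diff.mean() / diff.std(ddof=1))

    def test_group_stats_one_sample(self):
        vals = np.array([0.8, 0.9, 0.85, 0.95, 0.7])
        g = GroupStats.from_values(vals)
        from scipy.stats import ttest_1samp
        t, p = ttest_1samp(vals, 0.0)
        assert g.t == pytest.approx(t)
        assert g.p == pytest.approx(p)
        assert g.df == 4
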