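import itertools
import math
import warnings

import numpy as np
import pytest
from scipy import stats as sps

import synaptoglu as sg


class TestOriginRegression:
    def test_exact_double_slope(self):
        x = np.array([1.0, 2.0, 3.0])
        res = sg.regress_through_origin(x, 2 * x)
        assert res.slope == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.d_identity == pytest.approx(np.mean(x**2))

    def test_identity_points(self):
        x = np.array([0.5, 1.0, 2.0, 3.0])
        res = sg.regress_through_origin(x, x)
        assert res.slope == pytest.approx(1.0)
        assert res.d_identity == 0.0

    def test_identity_noise_distance_matches_variance(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(0.5, 2.0, 100)
        sigma = 0.1
        y = x + rng.normal(0, sigma, 100)
        res = sg.regress_through_origin(x, y)
        assert res.d_identity == pytest.approx(sigma**2, rel=0.2)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(1, 2, 20)
        y = 1.4 * x + rng.normal(0, 0.05, 20)
        s1 = sg.regress_through_origin(x, y).slope
        s2 = sg.regress_through_origin(3.0 * x, y).slope
        assert s2 == pytest.approx(s1 / 3.0, rel=1e-9)

    def test_all_zero_x_rejected(self):
        with pytest.raises(ValueError):
            sg.regress_through_origin(np.zeros(5), np.ones(5))


class TestCompareReadouts:
    def test_identical_readouts(self):
        v = np.array([1.0, 0.7, 0.5, 0.4])
        res, table = sg.compare_readouts(v, v)
        assert res.slope == pytest.approx(1.0)
        assert res.d_identity == 0.0
        assert len(table) == 4

    def test_normalization_invariance_under_rescaling(self):
        opt = np.array([0.3, 0.21, 0.15, 0.12])
        ele = np.array([2.0e-9, 1.4e-9, 1.0e-9, 0.8e-9])
        r1, _ = sg.compare_readouts(opt, ele, normalize=True)
        r2, _ = sg.compare_readouts(5.0 * opt, 0.2 * ele, normalize=True)
        assert r2.slope == pytest.approx(r1.slope, rel=1e-12)
        assert r2.d_identity == pytest.approx(r1.d_identity, rel=1e-12)

    def test_two_render_paths_linearly_related(self, depressing_train_10hz):
        protocol, pool, released, cfg, epsc, fluo = depressing_train_10hz
        metrics = sg.measure_train(epsc, protocol)
        dec = sg.linear_deconvolve(fluo.truth_dff, cfg.kernel.tau)
        per, _ = sg.cumulative_release(dec, protocol)
        res, _ = sg.compare_readouts(per, metrics.amplitude, normalize=True)
        assert res.slope == pytest.approx(1.0, rel=0.03)
        assert res.d_identity < 1e-3

    def test_saturation_detected_on_common_calibration(self, depressing_train_10hz):
        protocol, pool, released, cfg, epsc, fluo = depressing_train_10hz
        # optical path saturates (half-saturation at half the largest count);
        # both readouts expressed in quanta via their single-quantum gains
        sat = sg.render_fluorescence(
            sg.apply_saturation(released, 0.5 * released.max()), protocol, cfg
        ).truth_dff
        dec = sg.linear_deconvolve(sat, cfg.kernel.tau)
        per, _ = sg.cumulative_release(dec, protocol)
        dec_lin = sg.linear_deconvolve(fluo.truth_dff, cfg.kernel.tau)
        per_lin, _ = sg.cumulative_release(dec_lin, protocol)
        gain = per_lin[0] / released[0]  # single-quantum optical gain
        metrics = sg.measure_train(epsc, protocol)
        optical_quanta = per / gain
        electrical_quanta = metrics.amplitude / cfg.pool.quantal_amp
        res, _ = sg.compare_readouts(optical_quanta, electrical_quanta)
        assert res.slope < 0.97
        assert res.d_identity > 0


class TestWilcoxon:
    def test_separated_groups_exact_p(self):
        assert sg.wilcoxon_rank_sum([1, 2, 3, 4], [5, 6, 7, 8]) == pytest.approx(2 / 70)

    def test_identical_multisets_p_one(self):
        assert sg.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_exact_path_matches_brute_force(self):
        # independent enumeration oracle over random small samples
        rng = np.random.default_rng(77)
        for _ in range(15):
            na = int(rng.integers(3, 6))
            nb = int(rng.integers(3, 6))
            pooled = np.round(rng.normal(size=na + nb), 1)  # occasional ties
            a, b = pooled[:na], pooled[na:]
            ranks = sps.rankdata(pooled)
            w_obs = ranks[:na].sum()
            mu = na * (na + nb + 1) / 2
            count = sum(
                1
                for combo in itertools.combinations(range(na + nb), na)
                if abs(ranks[list(combo)].sum() - mu) >= abs(w_obs - mu) - 1e-9
            )
            expected = count / math.comb(na + nb, na)
            assert sg.wilcoxon_rank_sum(a, b) == pytest.approx(expected)

    def test_exact_path_matches_scipy_without_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = rng.normal(size=5)
            b = rng.normal(1.0, 1.0, size=5)
            expected = sps.mannwhitneyu(a, b, alternative="two-sided",
                                        method="exact").pvalue
            assert sg.wilcoxon_rank_sum(a, b) == pytest.approx(expected, rel=1e-9)

    def test_power_against_two_sigma_shift(self):
        rng = np.random.default_rng(21)
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            a = rng.normal(0, 1, 20)
            b = rng.normal(2.0, 1, 20)
            if sg.wilcoxon_rank_sum(a, b) < 0.05:
                rejections += 1
        assert rejections / n_sim > 0.9

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            sg.wilcoxon_rank_sum([1, 2], [3, 4, 5])


class TestBonferroni:
    def test_adjusted_levels(self):
        assert sg.bonferroni_alpha(0.05, 1) == 0.05
        # five quantal-event comparisons and four paired-pulse comparisons
        assert sg.bonferroni_alpha(0.05, 5) == pytest.approx(0.010)
        assert sg.bonferroni_alpha(0.05, 4) == pytest.approx(0.0125)

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            sg.bonferroni_alpha(0.05, 0)


def simulate_clustered(rng, effect=0.0, n_cells=6, n_per_cell=8,
                       sigma_cell=1.0, sigma_resid=1.0):
    values, cells, conds = [], [], []
    for c in range(2 * n_cells):
        cond = "B" if c >= n_cells else "A"
        u = rng.normal(0, sigma_cell)
        for _ in range(n_per_cell):
            values.append((effect if cond == "B" else 0.0) + u
                          + rng.normal(0, sigma_resid))
            cells.append(c)
            conds.append(cond)
    return values, cells, conds


class TestRandomInterceptModel:
    def test_matches_established_implementation(self):
        import pandas as pd
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(7)
        values, cells, conds = simulate_clustered(rng, effect=1.0, n_cells=12,
                                                  n_per_cell=25)
        df = pd.DataFrame({"y": values, "cell": cells, "cond": conds})
        for reml in (True, False):
            res = sg.random_intercept_effect(values, cells, conds, reml=reml)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ref = smf.mixedlm("y ~ cond", df, groups=df["cell"]).fit(reml=reml)
            assert res.effect == pytest.approx(ref.params["cond[T.B]"], rel=1e-3)
            assert res.se == pytest.approx(ref.bse["cond[T.B]"], rel=1e-3)
            assert res.sigma_resid == pytest.approx(math.sqrt(ref.scale), rel=1e-3)
            assert res.sigma_cell == pytest.approx(
                math.sqrt(ref.cov_re.iloc[0, 0]), rel=1e-3)

    def test_zero_cell_variance_collapses_to_mean_difference(self):
        values, cells, conds = [], [], []
        for c in range(6):
            cond = "B" if c >= 3 else "A"
            for k in range(4):
                values.append((2.0 if cond == "B" else 0.0) + 0.1 * k)
                cells.append(c)
                conds.append(cond)
        res = sg.random_intercept_effect(values, cells, conds)
        assert res.effect == pytest.approx(2.0, abs=1e-6)

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(99)
        rejections = 0
        n_sim = 50
        for _ in range(n_sim):
            values, cells, conds = simulate_clustered(rng, effect=0.0)
            if sg.random_intercept_effect(values, cells, conds).p < 0.05:
                rejections += 1
        assert abs(rejections / n_sim - 0.05) <= 0.08

    def test_effect_recovery_within_two_se(self):
        rng = np.random.default_rng(31)
        values, cells, conds = simulate_clustered(rng, effect=1.0, n_cells=12,
                                                  n_per_cell=300)
        res = sg.random_intercept_effect(values, cells, conds)
        assert abs(res.effect - 1.0) <= 2 * res.se

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError):
            sg.random_intercept_effect([1.0, 2.0], [0, 0], ["A", "B"])


class TestErrorPropagation:
    def test_ratio_closed_form(self):
        # f = x/y at x = 1 +- 0.1, y = 2 exactly: se = 0.1/2
        se = sg.propagate_se([0.1, 0.0], [1 / 2, -1 / 4])
        assert se == pytest.approx(0.05)

    def test_sum_equal_sigmas(self):
        se = sg.propagate_se([0.3, 0.3], [1.0, 1.0])
        assert se == pytest.approx(0.3 * math.sqrt(2))

    def test_ratio_against_monte_carlo(self):
        rng = np.random.default_rng(2)
        x0, y0, sx, sy = 10.0, 5.0, 0.5, 0.4  # CVs <= 0.1
        draws = rng.normal(x0, sx, 100_000) / rng.normal(y0, sy, 100_000)
        mc = float(np.std(draws))
        analytic = sg.propagate_se([sx, sy], [1 / y0, -x0 / y0**2])
        assert analytic == pytest.approx(mc, rel=0.10)
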