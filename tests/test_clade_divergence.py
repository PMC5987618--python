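"""Regime painting, two-regime BM likelihood and fitting, ratio tests."""

import math

import numpy as np
import pytest
from scipy import stats

from utr3evo import clade_divergence as cd
from utr3evo import synthetic_data as sd
from oracles import dense_cov_oracle, gls_profiled_loglik_oracle


def _dense_cov_oracle(tree, painting, s2f, s2b):
    return dense_cov_oracle(tree, painting, s2f, s2b, cd.FOCAL)


_gls_loglik_oracle = gls_profiled_loglik_oracle

FOCAL = set(sd.FOCAL_SPECIES)


class TestPaintRegimes:
    def test_focal_clade_gets_crown_plus_stem(self, default_tree):
        tree, painting = default_tree
        focal_branches = [n for n, lab in painting.items() if lab == cd.FOCAL]
        # 5-tip clade: 2*5-2 = 8 crown branches, plus the stem
        assert len(focal_branches) == 9
        assert len(painting) == 16  # all branches labeled

    def test_focal_equals_all_tips(self, default_tree):
        tree, _ = default_tree
        painting = cd.paint_regimes(
            tree, {lf.taxon.label for lf in tree.leaf_node_iter()}
        )
        assert set(painting.values()) == {cd.FOCAL}

    def test_non_monophyletic_focal_set_errors(self, default_tree):
        tree, _ = default_tree
        with pytest.raises(ValueError, match="monophyletic"):
            cd.paint_regimes(tree, {"M_zebra", "D_rerio"})

    def test_unknown_tip_errors(self, default_tree):
        tree, _ = default_tree
        with pytest.raises(ValueError, match="absent"):
            cd.paint_regimes(tree, {"M_zebra", "X_fish"})


class TestTreeChecks:
    def test_default_tree_is_ultrametric(self, default_tree):
        cd.check_ultrametric(default_tree[0])

    def test_non_ultrametric_rejected(self):
        tree = cd.read_tree("((A:1,B:2):1,C:3);", is_path=False)
        with pytest.raises(ValueError, match="ultrametric"):
            cd.check_ultrametric(tree)

    def test_missing_branch_length_rejected(self):
        with pytest.raises(ValueError):
            cd.read_tree("((A:1,B:1),C:2);", is_path=False)


class TestBmLoglik:
    def test_two_tip_closed_form(self):
        t = 3.0
        s2 = 1.7
        tree = cd.read_tree(f"(A:{t},B:{t});", is_path=False)
        painting = cd.paint_regimes(tree, {"A", "B"})  # all focal
        x = np.array([4.0, 9.0])
        d = x[0] - x[1]
        # profiled-mean bivariate normal, derived by hand:
        # V = s2*t*I2, mu_hat = mean(x), quad = d^2/(2 s2 t)
        expected = -0.5 * (
            2 * math.log(2 * math.pi) + 2 * math.log(s2 * t) + d * d / (2 * s2 * t)
        )
        got = cd.bm_loglik(x, tree, painting, s2, 1.0)  # background rate unused
        assert got == pytest.approx(expected, rel=1e-12)

    def test_equal_rates_reduce_to_single_rate_bm(self, default_tree, rng):
        tree, painting = default_tree
        model = cd.TwoRegimeBM(tree, painting)
        labels, v = _dense_cov_oracle(tree, painting, 1.4, 1.4)
        assert labels == model.tip_labels
        for _ in range(5):
            x = rng.normal(500, 40, size=9)
            assert model.loglik(x, 1.4, 1.4) == pytest.approx(
                _gls_loglik_oracle(x, v), abs=1e-8
            )

    def test_two_regime_matches_dense_matrix_oracle(self, rng):
        tree = cd.read_tree(
            "(((A:1,B:1):2,(C:2,D:1.0001):0.9999):1,E:4);".replace("1.0001", "2").replace("0.9999", "1"),
            is_path=False,
        )
        painting = cd.paint_regimes(tree, {"A", "B"})
        model = cd.TwoRegimeBM(tree, painting)
        for _ in range(5):
            s2f, s2b = rng.uniform(0.2, 3.0, size=2)
            labels, v = _dense_cov_oracle(tree, painting, s2f, s2b)
            x = rng.normal(0, 2, size=5)
            assert model.loglik(x, s2f, s2b) == pytest.approx(
                _gls_loglik_oracle(x, v), abs=1e-8
            )

    def test_singular_covariance_errors(self, bm_model):
        with pytest.raises(Exception):
            bm_model.loglik(np.arange(9.0), 0.0, 0.0)


class TestFitBmRates:
    def test_constant_trait_degenerate(self, bm_model):
        fit = bm_model.fit(np.full(9, 123.0))
        assert fit.sigma2_focal == fit.sigma2_background == 0.0
        assert "degenerate_constant" in fit.flags

    def test_ml_fit_maximizes_loglik(self, bm_model, rng):
        x = rng.normal(500, 30, size=9)
        fit = bm_model.fit(x, reml=False)
        ll_hat = bm_model.loglik(x, fit.sigma2_focal, fit.sigma2_background)
        for _ in range(20):
            s2f = fit.sigma2_focal * rng.uniform(0.5, 2.0)
            s2b = fit.sigma2_background * rng.uniform(0.5, 2.0)
            assert bm_model.loglik(x, s2f, s2b) <= ll_hat + 1e-6

    def test_scale_equivariance(self, bm_model, rng):
        x = rng.normal(800, 60, size=9)
        c = 3.7
        f1 = bm_model.fit(x)
        f2 = bm_model.fit(c * x)
        assert f2.sigma2_focal == pytest.approx(c**2 * f1.sigma2_focal, rel=1e-4)
        assert f2.sigma2_background == pytest.approx(
            c**2 * f1.sigma2_background, rel=1e-4
        )
        assert f2.log10_ratio == pytest.approx(f1.log10_ratio, abs=1e-5)

    def test_rate_recovery_under_2x_simulation(self, default_tree, bm_model):
        tree, painting = default_tree
        traits = sd.simulate_traits(tree, painting, 2.0, 1.0, 500.0, 400, seed=17)
        fits = bm_model.fit_many(traits[bm_model.tip_labels].to_numpy())
        ok = [f for f in fits if f.ok]
        assert len(ok) > 380
        mean_f = np.mean([f.sigma2_focal for f in ok])
        mean_b = np.mean([f.sigma2_background for f in ok])
        assert mean_f == pytest.approx(2.0, rel=0.15)
        assert mean_b == pytest.approx(1.0, rel=0.15)
        # log10 ratio distribution centered near log10(2) (small positive
        # bias from regime-size asymmetry is expected; see methods note)
        mean_lr = np.mean([f.log10_ratio for f in ok])
        assert mean_lr == pytest.approx(math.log10(2.0), abs=0.12)

    def test_two_tips_per_regime_required(self):
        tree = cd.read_tree("((A:1,B:1):1,(C:1,D:1):1);", is_path=False)
        painting = cd.paint_regimes(tree, {"A"})
        model = cd.TwoRegimeBM(tree, painting)
        with pytest.raises(ValueError, match="two tips per regime"):
            model.fit(np.array([1.0, 2.0, 3.0, 4.0]))


class TestLengthLogRatio:
    def test_equal_means_zero(self):
        x = {"a": 100.0, "b": 100.0, "c": 100.0, "d": 100.0}
        assert cd.length_log_ratio(x, ["a", "b"], ["c", "d"]) == 0.0

    def test_twofold_ratio(self):
        x = {"a": 200.0, "b": 200.0, "c": 100.0, "d": 100.0}
        assert cd.length_log_ratio(x, ["a", "b"], ["c", "d"]) == pytest.approx(
            math.log10(2), abs=1e-9
        )

    def test_matches_direct_recomputation(self, rng):
        tips = [f"t{i}" for i in range(9)]
        for _ in range(10):
            vals = dict(zip(tips, rng.uniform(50, 2000, size=9)))
            got = cd.length_log_ratio(vals, tips[:5], tips[5:])
            want = math.log10(
                np.mean([vals[t] for t in tips[:5]])
                / np.mean([vals[t] for t in tips[5:]])
            )
            assert got == pytest.approx(want, rel=1e-12)

    def test_zero_mean_errors(self):
        with pytest.raises(ValueError):
            cd.length_log_ratio({"a": 0.0, "b": 1.0}, ["a"], ["b"])


class TestOneSampleT:
    def test_symmetric_values_give_t_zero(self):
        t, p = cd.one_sample_t([-2.0, -1.0, 1.0, 2.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_constant_values_error(self):
        with pytest.raises(ValueError):
            cd.one_sample_t([3.0] * 10)

    def test_matches_formula_oracle(self, rng):
        values = rng.normal(0.1, 1.0, size=20)
        t, p = cd.one_sample_t(values)
        n = len(values)
        t_hand = values.mean() / (values.std(ddof=1) / math.sqrt(n))
        p_hand = 2 * stats.t.sf(abs(t_hand), df=n - 1)
        assert t == pytest.approx(t_hand, rel=1e-12)
        assert p == pytest.approx(p_hand, rel=1e-12)
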