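from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

from metasynopsis import (
    dl_tau2_from_effects,
    fixed_effect_pool,
    pool_effects,
    random_effects_pool,
    select_and_pool,
)


def exact_fraction_pool(thetas, ses, random=False):
    """Exact-rational oracle for inverse-variance and DL pooling."""
    thetas = [Fraction(t) for t in thetas]
    weights = [1 / Fraction(s) ** 2 for s in ses]
    sw = sum(weights)
    theta_fe = sum(w * t for w, t in zip(weights, thetas)) / sw
    q = sum(w * (t - theta_fe) ** 2 for w, t in zip(weights, thetas))
    df = len(thetas) - 1
    c = sw - sum(w**2 for w in weights) / sw
    tau2 = max(Fraction(0), (q - df) / c)
    if not random:
        return theta_fe, sw, q, tau2
    w_star = [1 / (Fraction(s) ** 2 + tau2) for s in ses]
    sw_star = sum(w_star)
    theta_re = sum(w * t for w, t in zip(w_star, thetas)) / sw_star
    return theta_re, sw_star, q, tau2


class TestFixedEffect:
    def test_three_study_hand_example(self, make_dataset):
        ds = make_dataset([0.2, 0.0, 0.4], [0.1, 0.1, 0.1])
        res = fixed_effect_pool(ds)
        assert res.theta_hat == pytest.approx(0.2)
        assert res.se_hat == pytest.approx(1 / np.sqrt(300), abs=1e-9)
        assert res.Q == pytest.approx(8.0)
        assert res.i2 == pytest.approx(75.0)

    def test_identical_studies_have_no_dispersion(self, make_dataset):
        ds = make_dataset([0.1, 0.1], [0.1, 0.1])
        res = fixed_effect_pool(ds)
        assert res.theta_hat == pytest.approx(0.1)
        assert res.Q == pytest.approx(0.0) and res.i2 == 0.0

    def test_single_study_passes_through_flagged(self, make_dataset):
        ds = make_dataset([0.3], [0.1])
        res = fixed_effect_pool(ds)
        assert res.model == "not_pooled"
        assert res.Q is None and res.i2 is None
        assert res.theta_hat == pytest.approx(0.3)


class TestDLTau2:
    def test_hand_example(self):
        assert dl_tau2_from_effects([0.2, 0.0, 0.4], [0.1, 0.1, 0.1]) == pytest.approx(
            0.03
        )

    def test_homogeneous_truncates_to_zero(self):
        assert dl_tau2_from_effects([0.1, 0.1, 0.1], [0.1, 0.2, 0.3]) == 0.0

    def test_q_below_df_truncates_exactly(self):
        tau2 = dl_tau2_from_effects([0.10, 0.11], [0.3, 0.3])
        assert tau2 == 0.0


class TestRandomEffects:
    def test_hand_example(self, make_dataset):
        ds = make_dataset([0.2, 0.0, 0.4], [0.1, 0.1, 0.1])
        res = random_effects_pool(ds)
        assert res.theta_hat == pytest.approx(0.2)
        assert res.se_hat == pytest.approx(1 / np.sqrt(75), abs=1e-9)
        assert res.tau2 == pytest.approx(0.03)

    def test_reduces_to_fixed_when_homogeneous(self, make_dataset):
        ds = make_dataset([0.1, 0.1, 0.1], [0.1, 0.2, 0.3])
        fe, re = fixed_effect_pool(ds), random_effects_pool(ds)
        assert re.theta_hat == pytest.approx(fe.theta_hat)
        assert re.se_hat == pytest.approx(fe.se_hat)

    def test_infinite_variance_study_drops_out(self, make_dataset):
        ds_small = make_dataset([0.2, 0.3, 0.25], [0.1, 0.1, 0.1])
        ds_big = make_dataset(
            [0.2, 0.3, 0.25, 5.0], [0.1, 0.1, 0.1, 1e6], variant="rs1"
        )
        res_small = fixed_effect_pool(ds_small)
        res_big = fixed_effect_pool(ds_big)
        assert res_big.theta_hat == pytest.approx(res_small.theta_hat, abs=1e-6)

    @given(
        st.lists(
            st.tuples(st.floats(-1, 1), st.floats(0.05, 0.5)), min_size=2, max_size=8
        )
    )
    def test_random_se_never_below_fixed_se(self, pairs):
        thetas = [p[0] for p in pairs]
        ses = [p[1] for p in pairs]
        tau2 = dl_tau2_from_effects(thetas, ses)
        fe = pool_effects(thetas, ses, method="fixed")
        re = pool_effects(thetas, ses, method="random", tau2=tau2)
        assert re.se_hat >= fe.se_hat - 1e-12


class TestExactFractionOracle:
    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_matches_rational_arithmetic_to_12_decimals(self, k):
        rng = np.random.default_rng(7)
        for _ in range(20):
            thetas = [
                Fraction(int(v), 1000) for v in rng.integers(-500, 500, size=k)
            ]
            ses = [Fraction(int(v), 100) for v in rng.integers(5, 60, size=k)]
            f_thetas = [float(t) for t in thetas]
            f_ses = [float(s) for s in ses]

            theta_fe, sw, q, tau2 = exact_fraction_pool(thetas, ses)
            fe = pool_effects(f_thetas, f_ses, method="fixed")
            assert fe.theta_hat == pytest.approx(float(theta_fe), abs=1e-12)
            assert fe.se_hat == pytest.approx(float(1 / sw) ** 0.5, abs=1e-12)
            assert fe.Q == pytest.approx(float(q), abs=1e-10)
            assert dl_tau2_from_effects(f_thetas, f_ses) == pytest.approx(
                float(tau2), abs=1e-12
            )

            theta_re, sw_star, _, _ = exact_fraction_pool(thetas, ses, random=True)
            re = pool_effects(f_thetas, f_ses, method="random", tau2=float(tau2))
            assert re.theta_hat == pytest.approx(float(theta_re), abs=1e-12)


class TestModelSelection:
    def test_high_heterogeneity_selects_random(self, make_dataset):
        ds = make_dataset([0.2, 0.0, 0.4], [0.1, 0.1, 0.1])  # I^2 = 75
        assert select_and_pool(ds).model == "random"

    def test_homogeneous_selects_fixed(self, make_dataset):
        ds = make_dataset([0.1, 0.1], [0.1, 0.1])
        assert select_and_pool(ds).model == "fixed"

    def test_switch_boundary_is_inclusive(self, make_dataset):
        ds = make_dataset([0.2, 0.0, 0.4], [0.1, 0.1, 0.1])
        i2 = fixed_effect_pool(ds).i2
        assert select_and_pool(ds, switch_i2=i2).model == "random"

    def test_ci_exponentiated_on_ratio_scale(self, make_dataset):
        ds = make_dataset([0.2, 0.1, 0.3], [0.1, 0.1, 0.1])
        res = select_and_pool(ds)
        assert 0 < res.ci_low < res.effect < res.ci_high
        assert res.effect == pytest.approx(np.exp(res.theta_hat))
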