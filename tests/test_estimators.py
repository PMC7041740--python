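import numpy as np
import pytest
import statsmodels.api as sm

from ivmr.core import HarmonizedInstrument, wald_ratio
from ivmr.estimators import (
    EstimatorConfig,
    METHOD_ORDER,
    WeightedInstrument,
    all_variants,
    egger_estimate,
    estimate,
    ivw_estimate,
    penalize_weights,
    robust_wls,
    weight_instruments,
)

from conftest import make_instruments


def random_instruments(rng, n):
    bx = rng.uniform(0.02, 0.12, n) * rng.choice([-1, 1], n)
    by = rng.normal(0.25 * bx, 0.02)
    sy = rng.uniform(0.01, 0.03, n)
    return make_instruments(bx, by, sy)


class TestIVW:
    def test_single_instrument_is_wald_ratio(self):
        inst = make_instruments([0.1], [0.02], [0.01])
        est = ivw_estimate(inst)
        theta, se = wald_ratio(inst[0])
        assert est.beta == pytest.approx(theta)
        assert est.se == pytest.approx(se)
        assert est.n_snps == 1

    def test_worked_three_snp_instance(self, worked_three_snp):
        est = ivw_estimate(worked_three_snp)
        assert est.beta == pytest.approx(7 / 30, abs=1e-12)
        assert est.se == pytest.approx(1 / 30, abs=1e-12)

    def test_equal_weight_pair_averages_ratios(self):
        inst = make_instruments([0.1, 0.1], [0.02, 0.03], [0.01, 0.01])
        thetas = [wald_ratio(i)[0] for i in inst]
        assert ivw_estimate(inst).beta == pytest.approx(np.mean(thetas))

    def test_order_and_allele_flip_invariance(self):
        rng = np.random.default_rng(42)
        inst = random_instruments(rng, 10)
        base = ivw_estimate(inst)
        shuffled = [inst[i] for i in rng.permutation(10)]
        assert ivw_estimate(shuffled).beta == pytest.approx(base.beta, rel=1e-12)
        flipped = [
            HarmonizedInstrument(i.snp_id, -i.beta_exposure, i.se_exposure,
                                 -i.beta_outcome, i.se_outcome)
            for i in inst
        ]
        est_f = ivw_estimate(flipped)
        assert est_f.beta == pytest.approx(base.beta, rel=1e-12)
        assert est_f.se == pytest.approx(base.se, rel=1e-12)

    def test_agrees_with_wls_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            inst = random_instruments(rng, int(rng.integers(2, 30)))
            est = ivw_estimate(inst)
            bx = np.array([i.beta_exposure for i in inst])
            by = np.array([i.beta_outcome for i in inst])
            w = np.array([i.se_outcome for i in inst]) ** -2.0
            oracle = sm.WLS(by, bx[:, None], weights=w).fit()
            assert est.beta == pytest.approx(oracle.params[0], abs=1e-10)

    def test_se_decreases_as_instruments_added(self):
        rng = np.random.default_rng(3)
        inst = random_instruments(rng, 12)
        ses = [ivw_estimate(inst[: j + 1]).se for j in range(1, 12)]
        assert all(a > b for a, b in zip(ses, ses[1:]))

    def test_multiplicative_model_never_shrinks_se(self):
        rng = np.random.default_rng(5)
        inst = random_instruments(rng, 15)
        fixed = ivw_estimate(inst, EstimatorConfig(method="ivw"))
        mult = ivw_estimate(inst, EstimatorConfig(method="ivw", variance_model="multiplicative"))
        assert mult.beta == pytest.approx(fixed.beta)
        assert mult.se >= fixed.se

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            ivw_estimate([])


class TestEgger:
    def test_exact_line_through_origin(self):
        inst = make_instruments([0.1, 0.2, 0.4, 0.3],
                                [0.01, 0.02, 0.04, 0.03], [0.01, 0.01, 0.02, 0.01])
        est = egger_estimate(inst)
        assert est.beta == pytest.approx(0.1, abs=1e-10)
        assert est.intercept_block.beta == pytest.approx(0.0, abs=1e-10)

    def test_exact_line_with_intercept(self):
        bx = np.array([0.1, 0.2, 0.4, 0.3])
        by = 0.01 + 0.2 * bx
        est = egger_estimate(make_instruments(bx, by, [0.01, 0.01, 0.02, 0.01]))
        assert est.beta == pytest.approx(0.2, abs=1e-10)
        assert est.intercept_block.beta == pytest.approx(0.01, abs=1e-10)

    def test_agrees_with_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            inst = random_instruments(rng, 10)
            est = egger_estimate(inst)
            bx = np.abs([i.beta_exposure for i in inst])
            by = np.array([i.beta_outcome for i in inst]) * np.sign(
                [i.beta_exposure for i in inst]
            )
            w = np.array([i.se_outcome for i in inst]) ** -2.0
            X = np.column_stack([np.ones(10), bx])
            coef = np.linalg.solve(X.T @ (X * w[:, None]), X.T @ (w * by))
            assert est.intercept_block.beta == pytest.approx(coef[0], abs=1e-10)
            assert est.beta == pytest.approx(coef[1], abs=1e-10)

    def test_orientation_makes_fit_flip_invariant(self):
        rng = np.random.default_rng(13)
        inst = random_instruments(rng, 8)
        base = egger_estimate(inst)
        flipped = [
            HarmonizedInstrument(i.snp_id, -i.beta_exposure, i.se_exposure,
                                 -i.beta_outcome, i.se_outcome)
            for i in inst
        ]
        est_f = egger_estimate(flipped)
        assert est_f.beta == pytest.approx(base.beta, rel=1e-12)
        assert est_f.intercept_block.beta == pytest.approx(
            base.intercept_block.beta, rel=1e-12
        )

    def test_too_few_instruments_raises(self):
        inst = make_instruments([0.1, 0.2], [0.02, 0.05], [0.01, 0.01])
        with pytest.raises(ValueError, match="at least 3"):
            egger_estimate(inst)

    def test_constant_exposure_effects_singular(self):
        inst = make_instruments([0.1, 0.1, -0.1], [0.02, 0.021, -0.019],
                                [0.01, 0.01, 0.01])
        with pytest.raises(ValueError, match="singular"):
            egger_estimate(inst)


class TestPenalizeWeights:
    def test_on_reference_theta_unchanged(self):
        wi = [WeightedInstrument("rs1", 0.25, 100.0)]
        out = penalize_weights(wi, theta_ref=0.25)
        assert out[0].penalty_j == 1.0
        assert out[0].w_j == 100.0

    def test_extreme_heterogeneity_zeroes_weight(self):
        wi = [WeightedInstrument("rs1", 50.0, 100.0)]
        out = penalize_weights(wi, theta_ref=0.0)
        assert out[0].penalty_j == pytest.approx(0.0, abs=1e-12)

    def test_chi2_boundary(self):
        # q = 3.8415 has upper-tail p = 0.05; penalty = min(1, 20*0.05) = 1
        q = 3.841458820694124
        wi = [WeightedInstrument("rs1", 0.0 + np.sqrt(q / 100.0), 100.0)]
        out = penalize_weights(wi, theta_ref=0.0)
        assert out[0].penalty_j == pytest.approx(1.0, abs=1e-9)

    def test_penalized_weights_never_exceed_raw(self):
        rng = np.random.default_rng(17)
        inst = random_instruments(rng, 20)
        weighted = weight_instruments(inst)
        out = penalize_weights(weighted, theta_ref=0.25)
        for raw, pen in zip(weighted, out):
            assert pen.w_j <= raw.w_j + 1e-15

    def test_homogeneous_instruments_unaffected(self):
        bx = np.array([0.05, 0.08, 0.11])
        inst = make_instruments(bx, 0.25 * bx, [0.01, 0.01, 0.01])
        plain = ivw_estimate(inst)
        pen = ivw_estimate(inst, EstimatorConfig(method="ivw", penalized=True))
        assert pen.beta == pytest.approx(plain.beta, rel=1e-12)
        assert pen.se == pytest.approx(plain.se, rel=1e-12)


class TestRobustWls:
    def test_clean_data_matches_wls(self):
        rng = np.random.default_rng(19)
        x = rng.uniform(0.5, 2.0, 30)
        y = 0.3 * x + rng.normal(0, 0.05, 30)
        w = rng.uniform(0.5, 2.0, 30)
        fit = robust_wls(x, y, w, intercept=False)
        wls = np.sum(w * x * y) / np.sum(w * x * x)
        assert fit.converged
        assert fit.coefficients[0] == pytest.approx(wls, abs=1e-2)

    def test_gross_outlier_rejected(self):
        x = np.linspace(0.5, 2.0, 21)
        y = 0.3 * x
        y[10] += 50 * 0.1  # displaced by 50 sigma
        fit = robust_wls(x, y, np.full(21, 100.0), intercept=False)
        assert fit.coefficients[0] == pytest.approx(0.3, abs=1e-6)
        assert fit.effective_weights[10] == 0.0

    def test_identically_zero_response(self):
        x = np.linspace(0.5, 2.0, 10)
        fit = robust_wls(x, np.zeros(10), np.ones(10), intercept=True)
        np.testing.assert_allclose(fit.coefficients, [0.0, 0.0], atol=1e-12)

    def test_matches_statsmodels_rlm_orientation(self):
        # independent bounded-influence fit: same data, comparable slope
        rng = np.random.default_rng(23)
        x = rng.uniform(0.5, 2.0, 50)
        y = 0.3 * x + rng.normal(0, 0.1, 50)
        y[:5] += 3.0  # cluster of outliers
        fit = robust_wls(x, y, np.ones(50), intercept=False)
        rlm = sm.RLM(y, x[:, None], M=sm.robust.norms.TukeyBiweight(4.685)).fit()
        assert fit.coefficients[0] == pytest.approx(rlm.params[0], abs=0.02)

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError):
            robust_wls(np.ones(3), np.ones(3), np.array([1.0, 0.0, 1.0]))


class TestVariantMatrix:
    def test_all_eight_labels(self, table1_floored):
        results = all_variants(table1_floored)
        assert list(results) == [
            "IVW", "Penalized IVW", "Robust IVW", "Penalized robust IVW",
            "MR-Egger", "Penalized MR-Egger", "Robust MR-Egger",
            "Penalized robust MR-Egger",
        ]
        for label, est in results.items():
            assert est.method == label
            assert est.ci_low <= est.beta <= est.ci_high
            assert est.se > 0
            assert (est.intercept_block is not None) == label.endswith("MR-Egger")

    def test_dispatch_matches_direct_calls(self, table1_floored):
        for cfg in METHOD_ORDER[:2]:
            assert estimate(table1_floored, cfg).beta == pytest.approx(
                ivw_estimate(table1_floored, cfg).beta
            )
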