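"""Tests of the goal function, per-gene fitting and the two-stage protocol."""

import numpy as np
import pytest

from xlnrdyn.data import TimeCourse
from xlnrdyn.estimation import (
    FitOptions,
    ProtocolConfig,
    ProtocolError,
    THETA2_NAMES,
    compare_repression_models,
    fit_gene,
    fold_change,
    goal_value,
    predict_timecourse,
    residuals,
    two_stage_protocol,
)
from xlnrdyn.kinetics import KineticParameters, simulate
from xlnrdyn.synthetic import SyntheticDesign, generate_study, xylose_profile

TIMES = np.linspace(0.0, 5.0, 16)


def noiseless_pair(params, strain="Wt", times=TIMES):
    """Exact model output observed without noise, as a condition pair."""
    tcs = []
    for cond in (1.0, 50.0):
        y = simulate(params, xylose_profile(cond), times,
                     strain=strain)["x_i"].to_numpy()
        tcs.append(TimeCourse("g", strain, cond, times, y, np.zeros_like(y), 3))
    return tcs


class TestResidualsAndGoal:
    def test_self_consistency_zero_residuals(self, default_params):
        tc1, tc50 = noiseless_pair(default_params)
        r1 = residuals(tc1, default_params, xylose_profile(1.0))
        r50 = residuals(tc50, default_params, xylose_profile(50.0))
        assert np.max(np.abs(r1)) < 1e-4
        assert np.max(np.abs(r50)) < 1e-4
        assert goal_value(r1, r50) < 1e-7

    def test_goal_equals_direct_summation(self):
        rng = np.random.default_rng(0)
        r1, r50 = rng.normal(size=16), rng.normal(size=16)
        brute = sum(v * v for v in r1) + sum(v * v for v in r50)
        assert goal_value(r1, r50) == pytest.approx(brute, rel=1e-12)

    def test_fast_predictor_matches_reference_integrator(self, default_params):
        for cond in (1.0, 50.0):
            u = xylose_profile(cond)
            ref = predict_timecourse(default_params, u, TIMES, fast=False)
            fast = predict_timecourse(default_params, u, TIMES)
            assert np.max(np.abs(ref - fast)) < 1e-4


class TestFitGene:
    def test_noiseless_recovery_of_gene_block(self, default_params):
        """With theta1 fixed at truth, the gene-specific block
        (k_is, K_i1, K_i2, k_id) is recovered within 5 % from exact data."""
        truth = default_params.replace(k_is_Wt=8.0, K_i1=0.08,
                                       K_i2_Wt=30.0, k_id=1.5)
        tc1, tc50 = noiseless_pair(truth)
        fr = fit_gene(tc1, tc50, default_params, THETA2_NAMES,
                      options=FitOptions(n_restarts=3), seed=5)
        assert fr.converged
        for name, true_val in (("k_is_Wt", 8.0), ("K_i1", 0.08),
                               ("K_i2_Wt", 30.0), ("k_id", 1.5)):
            assert getattr(fr.theta_hat, name) == pytest.approx(true_val, rel=0.05)

    def test_descent_from_initialization(self, default_params, small_study):
        ds_wt, _ = small_study
        tcs = [tc for tc in ds_wt.timecourses if tc.gene == "gene01"]
        tc1 = next(tc for tc in tcs if tc.condition == 1.0)
        tc50 = next(tc for tc in tcs if tc.condition == 50.0)
        r1 = residuals(tc1, default_params, xylose_profile(1.0))
        r50 = residuals(tc50, default_params, xylose_profile(50.0))
        J_init = goal_value(r1, r50)
        fr = fit_gene(tc1, tc50, default_params, THETA2_NAMES,
                      options=FitOptions(n_restarts=2), seed=1)
        assert fr.J_comb <= J_init + 1e-12
        assert fr.J_comb == fr.J1 + fr.J50

    def test_cv_matches_direct_formula(self, default_params, small_study):
        ds_wt, _ = small_study
        tcs = [tc for tc in ds_wt.timecourses if tc.gene == "gene02"]
        tc1 = next(tc for tc in tcs if tc.condition == 1.0)
        tc50 = next(tc for tc in tcs if tc.condition == 50.0)
        fr = fit_gene(tc1, tc50, default_params, THETA2_NAMES,
                      options=FitOptions(n_restarts=6), seed=3)
        best = fr.estimates()
        for i, name in enumerate(fr.free):
            vals = [e[1][name] for e in fr.ensemble]
            expected = np.std(vals) / best[name] if len(vals) > 1 else 0.0
            assert fr.cv[name] == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_chi_square_expectation_of_goal(self, default_params):
        """At the generating parameters, additive N(0, sigma^2) noise gives
        E[J_comb] = sigma^2 (N1 + N50); checked over 100 replicates."""
        sigma = 0.2
        tc1, tc50 = noiseless_pair(default_params)
        rng = np.random.default_rng(7)
        js = []
        for _ in range(100):
            j = 0.0
            for tc, cond in ((tc1, 1.0), (tc50, 50.0)):
                noisy = TimeCourse(tc.gene, tc.strain, cond, tc.times,
                                   tc.mean + rng.normal(0, sigma, tc.mean.size),
                                   tc.sd, 3)
                j += goal_value(residuals(noisy, default_params,
                                          xylose_profile(cond)))
            js.append(j)
        expected = sigma**2 * (len(tc1) + len(tc50))
        assert np.mean(js) == pytest.approx(expected, rel=0.2)


class TestFoldChange:
    def _converged_pair(self, k_wt, k_mt):
        from xlnrdyn.estimation import FitResult

        def mk(strain, k):
            p = KineticParameters().replace(**{f"k_is_{strain}": k})
            return FitResult("g", strain, p, (f"k_is_{strain}",), {},
                             0.0, 0.0, {}, {}, True, 1)
        return mk("Wt", k_wt), mk("Mt", k_mt)

    @pytest.mark.parametrize("k_wt, k_mt, lam", [(2.0, 6.0, 3.0),
                                                 (5.0, 5.0, 1.0),
                                                 (4.0, 1e-3, 0.00025)])
    def test_ratio(self, k_wt, k_mt, lam):
        fw, fm = self._converged_pair(k_wt, k_mt)
        assert fold_change(fw, fm) == pytest.approx(lam)

    def test_gene_mismatch_rejected(self):
        fw, fm = self._converged_pair(1.0, 2.0)
        fm.gene = "other"
        with pytest.raises(ValueError):
            fold_change(fw, fm)


class TestTwoStageProtocol:
    def test_single_gene_average_is_identity(self, default_params):
        """With one wild-type gene, the stage-1b average equals that gene's
        stage-1a estimate exactly (mean of one)."""
        truth = default_params.replace(k_is_Wt=12.0, K_i1=0.1, k_id=1.0)
        tc1, tc50 = noiseless_pair(truth)
        wt = [TimeCourse("geneA", "Wt", tc.condition, tc.times, tc.mean,
                         tc.sd, 3) for tc in (tc1, tc50)]
        cfg = ProtocolConfig(init=default_params,
                             options=FitOptions(n_restarts=1), seed=0)
        res = two_stage_protocol(wt, [], cfg)
        fr = res.stage1a["geneA"]
        for n in ("K_on", "K_off", "k1", "k2"):
            assert res.theta1_bar[n] == getattr(fr.theta_hat, n)

    def test_missing_wt_counterpart_rejected(self, small_study):
        ds_wt, ds_mt = small_study
        wt = [tc for tc in ds_wt.timecourses if tc.gene == "gene01"]
        mt = [tc for tc in ds_mt.timecourses if tc.gene in ("gene01", "gene02")]
        with pytest.raises(ProtocolError, match="gene02"):
            two_stage_protocol(wt, mt, ProtocolConfig())

    def test_protocol_reproducible_given_seed(self, small_study):
        ds_wt, ds_mt = small_study
        wt = [tc for tc in ds_wt.timecourses
              if tc.gene in ("gene01", "gene02")]
        cfg = ProtocolConfig(options=FitOptions(n_restarts=2), seed=9)
        a = two_stage_protocol(wt, [], cfg).params_frame()
        b = two_stage_protocol(wt, [], cfg).params_frame()
        assert a.equals(b)


class TestRepressionComparison:
    def test_nested_goal_ordering_and_freeing_parameters_helps(
            self, default_params, small_study):
        ds_wt, _ = small_study
        tcs = [tc for tc in ds_wt.timecourses if tc.gene == "gene03"]
        tc1 = next(tc for tc in tcs if tc.condition == 1.0)
        tc50 = next(tc for tc in tcs if tc.condition == 50.0)
        cmp_ = compare_repression_models(tc1, tc50, default_params,
                                         options=FitOptions(n_restarts=2),
                                         seed=2)
        assert cmp_.J_full <= cmp_.J_reduced + 1e-12
        assert cmp_.n_params_full == cmp_.n_params_reduced + 1
        assert 0.0 <= cmp_.p_value <= 1.0
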