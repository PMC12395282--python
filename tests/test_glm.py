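"""Task regressors, subject GLMs, PSC, group statistics and aggregation."""

import numpy as np
import pytest
from scipy import stats

from fpetkit.baselines import _poly_design
from fpetkit.glm import (BlockDesign, GlmResult, T_CAP, aggregate_parcels,
                         build_task_regressor, contiguous_grouping,
                         fdr_correct, fit_subject_glm, group_random_effects,
                         percent_signal_change, select_sham_regressors)
from fpetkit.kinetics import FramedTac

FM = (np.arange(356) + 0.5) * 16.0 / 60.0


class TestTaskRegressor:
    def test_boxcar_on_fraction(self):
        design = BlockDesign(10.0, 10.0, 0.0, 40.0)
        t = (np.arange(150) + 0.5) * (40.0 / 150.0)
        reg = build_task_regressor(design, t, shape="boxcar")
        on_frac = (reg.raw > 0).mean()
        assert abs(on_frac - 0.5) <= 1.0 / 150.0

    def test_ramp_final_value_is_total_on_time(self):
        design = BlockDesign(10.0, 10.0, 5.0, 95.0)
        reg = build_task_regressor(design, FM, shape="ramp")
        total_on = design.on_time(np.array([FM[-1]]))[0]
        assert abs(reg.raw[-1] - total_on) < 1e-12
        assert np.all(np.diff(reg.raw) >= 0)

    def test_shift_by_full_period_matches_on_overlap(self):
        d0 = BlockDesign(10.0, 10.0, 0.0, 200.0)
        d1 = BlockDesign(10.0, 10.0, 20.0, 200.0)
        t = np.arange(0.25, 150.0, 0.5)
        r0 = d0.boxcar(t - 20.0)
        r1 = d1.boxcar(t)
        overlap = t >= 20.0
        np.testing.assert_array_equal(r0[overlap], r1[overlap])

    def test_design_shorter_than_scan_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            build_task_regressor(BlockDesign(10, 10, 0, 40.0), FM)

    def test_demeaned(self):
        reg = build_task_regressor(BlockDesign(10, 10, 5.0, 95.0), FM)
        assert abs(reg.values.mean()) < 1e-12


class TestShamSelection:
    def test_reference_equal_to_candidate_gives_unit_r(self):
        design = BlockDesign(10, 10, 5.0, 95.0)
        ref = build_task_regressor(design, FM).values
        sel = select_sham_regressors([design, BlockDesign(10, 10, 12.0, 95.0)],
                                     ref, FM)
        assert sel.positive[0] is design
        assert sel.positive[2] == pytest.approx(1.0)

    def test_orthogonalized_reference_gives_zero_r(self):
        design = BlockDesign(10, 10, 5.0, 95.0)
        reg = build_task_regressor(design, FM).values
        rng = np.random.default_rng(0)
        noise = rng.standard_normal(len(FM))
        ref = noise - reg * (noise @ reg) / (reg @ reg)
        ref = ref - ref.mean()
        sel = select_sham_regressors([design], ref, FM)
        assert abs(sel.ranked[0][2]) < 1e-10

    def test_cohort_picks_have_expected_sign_pattern(self, sham_selection):
        """On the null cohort's P3MT residual the three picks order as
        (positive, near-zero, negative)."""
        r_pos = sham_selection.positive[2]
        r_null = sham_selection.null[2]
        r_neg = sham_selection.negative[2]
        assert r_pos > 0.1
        assert abs(r_null) < 0.1
        assert r_neg < -0.1

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError):
            select_sham_regressors([BlockDesign(10, 10, 0, 95.0)],
                                   np.ones(len(FM)), FM)


class TestSubjectGlm:
    def test_zero_task_amplitude(self):
        X = _poly_design(FM)
        rng = np.random.default_rng(1)
        coef = rng.standard_normal((4, 3))
        Y = X @ coef
        task = build_task_regressor(BlockDesign(10, 10, 5.0, 95.0), FM)
        res = fit_subject_glm(Y, X, task)
        assert np.max(np.abs(res.beta_task)) < 1e-8
        assert np.max(np.abs(res.residuals)) < 1e-8

    def test_exact_beta_recovery(self):
        X = _poly_design(FM)
        task = build_task_regressor(BlockDesign(10, 10, 5.0, 95.0), FM)
        Y = (X @ np.array([1.0, 2.0, -0.5, 0.1]))[:, None] + 0.7 * task.values[:, None]
        res = fit_subject_glm(Y, X, task)
        assert res.beta_task[0] == pytest.approx(0.7, abs=1e-10)
        assert res.dof == 356 - 5

    def test_null_type_one_error_calibrated(self):
        """White-noise data: |t| exceeds the two-sided 5% quantile at the
        nominal rate (10,000 replicate parcels)."""
        X = _poly_design(FM)
        task = build_task_regressor(BlockDesign(10, 10, 5.0, 95.0), FM)
        Y = np.random.default_rng(2).standard_normal((356, 10_000))
        res = fit_subject_glm(Y, X, task)
        crit = stats.t.ppf(0.975, res.dof)
        rate = (np.abs(res.t_task) > crit).mean()
        assert abs(rate - 0.050) < 0.006

    def test_collinear_design_warns_but_returns(self):
        task = build_task_regressor(BlockDesign(10, 10, 5.0, 95.0), FM)
        X = np.column_stack([np.ones_like(FM), task.values * (1 + 1e-12)])
        Y = np.random.default_rng(3).standard_normal((356, 2))
        with pytest.warns(RuntimeWarning, match="collinear"):
            res = fit_subject_glm(Y, X, task)
        assert res.collinear


class TestPsc:
    def _result(self, beta):
        n = len(FM)
        return GlmResult(beta_task=np.array([beta]), se_task=np.array([1.0]),
                         t_task=np.array([beta]), dof=n - 2,
                         residuals=np.zeros((n, 1)))

    def test_definitional_ratio(self):
        """beta * on_slope = 0.1 * late slope gives exactly 10%."""
        slope = 0.2
        baseline = (slope * FM)[:, None]
        task = build_task_regressor(BlockDesign(10, 10, 5.0, 95.0), FM)
        res = self._result(0.1 * slope)
        psc = percent_signal_change(res, baseline, task, FM)
        assert psc[0] == pytest.approx(10.0)

    def test_zero_beta_zero_psc(self):
        baseline = (0.2 * FM)[:, None]
        task = build_task_regressor(BlockDesign(10, 10, 5.0, 95.0), FM)
        psc = percent_signal_change(self._result(0.0), baseline, task, FM)
        assert psc[0] == 0.0

    def test_nonpositive_late_slope_flagged(self):
        baseline = (-0.1 * FM)[:, None]
        task = build_task_regressor(BlockDesign(10, 10, 5.0, 95.0), FM)
        psc = percent_signal_change(self._result(0.5), baseline, task, FM)
        assert np.isnan(psc[0])

    def test_invariant_to_global_rescaling(self):
        """PSC is a ratio: scaling a subject's data leaves it unchanged."""
        slope = 0.2
        baseline = (slope * FM)[:, None]
        task = build_task_regressor(BlockDesign(10, 10, 5.0, 95.0), FM)
        a = percent_signal_change(self._result(0.03), baseline, task, FM)
        b = percent_signal_change(self._result(0.03 * 7.0),
                                  baseline * 7.0, task, FM)
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_boxcar_regressor_rejected(self):
        task = build_task_regressor(BlockDesign(10, 10, 5.0, 95.0), FM,
                                    shape="boxcar")
        with pytest.raises(ValueError, match="ramp"):
            percent_signal_change(self._result(0.1), (0.2 * FM)[:, None],
                                  task, FM)


def _mock_results(betas):
    out = []
    for row in betas:
        row = np.atleast_1d(row)
        out.append(GlmResult(beta_task=row, se_task=np.ones_like(row),
                             t_task=row, dof=100,
                             residuals=np.zeros((2, len(row))),
                             psc=row * 10.0))
    return out


class TestGroup:
    def test_null_group_t_centred(self):
        rng = np.random.default_rng(4)
        betas = rng.standard_normal((24, 10_000))
        g = group_random_effects(_mock_results(betas))
        assert abs(g.group_t.mean()) < 0.1
        assert g.n_subjects == 24

    def test_zero_variance_capped(self):
        betas = np.full((5, 3), 2.0)
        betas[:, 1] = 0.0
        betas[:, 2] = -1.0
        g = group_random_effects(_mock_results(betas))
        assert g.group_t[0] == T_CAP
        assert g.group_t[1] == 0.0
        assert g.group_t[2] == -T_CAP
        assert g.capped.all()

    def test_shared_pattern_gives_uniform_positive_t(self, null_cohort,
                                                     sham_selection):
        """A residual pattern consistent across subjects and positively
        correlated with the regressor biases every parcel upward."""
        from fpetkit.baselines import BaselineSpec, detrend
        from fpetkit.glm import fit_subject_glm
        design = sham_selection.positive[0]
        results = []
        for tac in null_cohort.tacs_noisefree[:6]:
            fit = detrend(tac, BaselineSpec("P3"))
            task = build_task_regressor(design, fit.frame_mid)
            results.append(fit_subject_glm(tac.values[fit.frames_kept],
                                           fit.regressors, task))
        g = group_random_effects(results)
        assert np.all(g.group_t > 0)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            group_random_effects(_mock_results(np.zeros((2, 4))))


class TestFdr:
    def test_step_up_accepts_ordered_block(self):
        mask, cutoff = fdr_correct(np.array([0.01, 0.02, 0.03, 0.04]), 0.05)
        assert mask.all()
        assert cutoff == pytest.approx(0.04)

    def test_all_ones_rejects_everything(self):
        mask, cutoff = fdr_correct(np.ones(10), 0.05)
        assert not mask.any()
        assert cutoff == 0.0

    def test_single_p_reduces_to_raw_threshold(self):
        mask, cutoff = fdr_correct(np.array([0.04]), 0.05)
        assert mask.all()

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct(np.array([]))


class TestAggregate:
    def test_identity_grouping_returns_input(self, small_cohort):
        tac = small_cohort.tacs[0]
        out = aggregate_parcels(tac, np.arange(tac.n_parcels))
        np.testing.assert_array_equal(out.values, tac.values)

    def test_merging_identical_parcels_preserves_tac(self, ci_framed):
        tac = ci_framed.copy()
        tac.values = np.column_stack([tac.values[:, 0], tac.values[:, 0]])
        out = aggregate_parcels(tac, np.zeros(2, dtype=int))
        np.testing.assert_allclose(out.values[:, 0], tac.values[:, 0])

    def test_contiguous_grouping_covers_evenly(self):
        g = contiguous_grouping(500, 100)
        counts = np.bincount(g)
        assert len(counts) == 100
        assert counts.min() == counts.max() == 5

    def test_incomplete_grouping_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            aggregate_parcels(small_cohort.tacs[0], np.zeros(3))
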