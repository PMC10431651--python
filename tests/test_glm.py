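"""HRF, design-matrix and AR-IRLS fitting contracts."""

import numpy as np
import pytest

import nirsfeed as nf
from nirsfeed.glm import (
    _ar_whiten,
    _select_ar,
    build_design,
    canonical_hrf,
    fit_ar_irls,
    fit_glm,
    roi_activation,
    trial_t_table,
)
from nirsfeed.preprocess import bandpass, resample_4hz
from nirsfeed.probe_paradigm import DEFAULT_FS


@pytest.fixture(scope="module")
def hrf4():
    return canonical_hrf(4.0)


@pytest.fixture(scope="module")
def design_pooled(paradigm, hrf4):
    return build_design(paradigm, hrf4, 4081, mode="pooled",
                        selected_trials=list(range(1, 16)),
                        filter_band=(0.01, 0.09))


class TestHrf:
    def test_peak_at_four_seconds(self, hrf4):
        assert abs(np.argmax(hrf4.kernel) / 4.0 - 4.0) <= 1 / 4.0

    def test_zero_at_origin_and_unit_peak(self, hrf4):
        assert hrf4.kernel[0] == 0.0
        assert hrf4.kernel.max() == pytest.approx(1.0)

    def test_undershoot_ratio_one_sixth(self, hrf4):
        assert abs(-hrf4.kernel.min() / hrf4.kernel.max() - 1 / 6) <= 0.02

    def test_undershoot_located_late(self, hrf4):
        assert np.argmin(hrf4.kernel) / 4.0 == pytest.approx(16.0, abs=1.0)

    def test_support_limited_to_duration(self):
        h = canonical_hrf(DEFAULT_FS)
        assert len(h.kernel) == pytest.approx(32 * DEFAULT_FS, abs=2)


class TestDesign:
    def test_trialwise_column_count(self, paradigm, hrf4):
        X = build_design(paradigm, hrf4, 4081, sc_series=np.random.default_rng(0)
                         .standard_normal(4081), mode="trialwise")
        # 15 task + rest + sc + drift + intercept
        assert len(X.names) == 19
        X2 = build_design(paradigm, hrf4, 4081,
                          sc_series=np.zeros(4081) + np.arange(4081) % 7,
                          mode="trialwise", include_drift=False)
        assert len(X2.names) == 18

    def test_pooled_unselected_column(self, paradigm, hrf4):
        X = build_design(paradigm, hrf4, 4081, mode="pooled",
                         selected_trials=list(range(1, 11)))
        assert "task_unselected" in X.names
        X15 = build_design(paradigm, hrf4, 4081, mode="pooled",
                           selected_trials=list(range(1, 16)))
        assert "task_unselected" not in X15.names

    def test_task_column_peaks_within_trial_window(self, paradigm, hrf4):
        X = build_design(paradigm, hrf4, 4081, mode="trialwise")
        for i, onset in enumerate(paradigm.onsets):
            col = X.column(f"task_{i + 1:02d}")
            t_peak = np.argmax(col) / 4.0
            assert onset < t_peak < onset + 62.0

    def test_empty_selection_rejected(self, paradigm, hrf4):
        with pytest.raises(ValueError, match="selected_trials"):
            build_design(paradigm, hrf4, 4081, mode="pooled", selected_trials=[])

    def test_collinear_design_rejected(self, paradigm, hrf4):
        with pytest.raises(ValueError, match="rank"):
            build_design(paradigm, hrf4, 4081, sc_series=np.ones(4081),
                         mode="pooled", selected_trials=[1])


class TestFitArIrls:
    def test_reduces_to_ols_with_unit_weights_and_no_ar(self, design_pooled):
        rng = np.random.default_rng(0)
        X = design_pooled
        y = X.values @ rng.normal(0, 0.3, len(X.names)) + rng.normal(0, 0.5, 4081)
        fit = fit_ar_irls(y, X, robust=False, p_max=0)["ch0"]
        ols, *_ = np.linalg.lstsq(X.values, y, rcond=None)
        rel = np.max(np.abs(fit.beta - ols) / np.maximum(np.abs(ols), 1e-12))
        assert rel < 1e-6

    def test_ar1_noise_is_whitened(self):
        rng = np.random.default_rng(1)
        n = 4000
        e = rng.standard_normal(n)
        x = np.zeros(n)
        for i in range(1, n):
            x[i] = 0.8 * x[i - 1] + e[i]
        phi = _select_ar(x, 16)
        w = _ar_whiten(x, phi)
        assert abs(np.corrcoef(w[1:], w[:-1])[0, 1]) < 0.1

    def test_t_invariant_to_positive_rescaling(self, design_pooled):
        rng = np.random.default_rng(2)
        X = design_pooled
        y = X.values @ rng.normal(0, 0.3, len(X.names)) + rng.normal(0, 0.5, 4081)
        t1 = fit_ar_irls(y, X, robust=False, p_max=0)["ch0"].t
        import dataclasses

        X2 = dataclasses.replace(X, values=X.values * 3.0)
        t2 = fit_ar_irls(5.0 * y, X2, robust=False, p_max=0)["ch0"].t
        np.testing.assert_allclose(t1, t2, rtol=1e-8)

    def test_underdetermined_rejected(self):
        from nirsfeed.glm import DesignMatrix

        X = DesignMatrix(values=np.array([[1.0, 0.0], [0.0, 1.0]]),
                         names=["task", "const"], fs=4.0, task_columns=["task"])
        with pytest.raises(ValueError, match="insufficient"):
            fit_ar_irls(np.zeros(2), X)

    def test_recovers_known_amplitude_on_subject(self, responder_hemo, layout,
                                                 paradigm):
        res = fit_glm(responder_hemo, layout, paradigm, mode="pooled",
                      selected_trials=list(range(1, 16)), sc=True,
                      channels=["S1-D1", "S7-D5"])
        betas = [res[ch]["task"]["beta"] for ch in ("S1-D1", "S7-D5")]
        assert np.mean(betas) == pytest.approx(0.5, rel=0.15)


class TestRoiActivation:
    def _result(self, layout, pvals, betas):
        from nirsfeed.glm import ChannelFit, GLMResult

        fits = {}
        for ch, p, b in zip([c.name for c in layout.roi_channels("nf_dlpfc")],
                            pvals, betas):
            fits[ch] = ChannelFit(channel=ch, names=["task"], beta=np.array([b]),
                                  se=np.array([1.0]), t=np.array([b]),
                                  p=np.array([p]), dof=np.array([100.0]),
                                  ar_order=0, n_iter=1, converged=True,
                                  weight_mean=1.0)
        return GLMResult(fits=fits)

    def test_bonferroni_threshold_blocks_marginal_p(self, layout):
        res = self._result(layout, [0.04, 0.2, 0.3, 0.5], [1, 1, 1, 1])
        assert roi_activation(res, layout, "nf_dlpfc") == set()

    def test_small_p_passes(self, layout):
        res = self._result(layout, [0.01, 0.2, 0.3, 0.5], [1, 1, 1, 1])
        assert len(roi_activation(res, layout, "nf_dlpfc")) == 1

    def test_negative_beta_never_activated(self, layout):
        res = self._result(layout, [1e-6, 0.2, 0.3, 0.5], [-1, 1, 1, 1])
        assert roi_activation(res, layout, "nf_dlpfc") == set()

    def test_monotone_in_alpha(self, layout):
        res = self._result(layout, [0.004, 0.01, 0.02, 0.5], [1, 1, 1, 1])
        small = roi_activation(res, layout, "nf_dlpfc", alpha=0.01)
        large = roi_activation(res, layout, "nf_dlpfc", alpha=0.05)
        assert small <= large

    def test_unknown_roi_rejected(self, layout):
        res = self._result(layout, [0.5] * 4, [1] * 4)
        with pytest.raises(ValueError, match="roi"):
            roi_activation(res, layout, "occipital")


class TestTrialTable:
    def test_shape_and_orientation(self, responder_hemo, layout, paradigm):
        res = fit_glm(responder_hemo, layout, paradigm, mode="trialwise", sc=True,
                      channels=[c.name for c in layout.roi_channels("nf_dlpfc")])
        table = trial_t_table(res, layout)
        assert table.shape == (15, 4)
        assert list(table.index) == list(range(1, 16))
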