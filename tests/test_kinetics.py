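"""Cleavage-kinetics fitting: ln-linear kobs, biphasic model, fold changes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hhscan import (
    FitError,
    KineticsTrace,
    fit_biphasic,
    fit_kobs_linear,
    fold_change,
    simulate_trace,
)
from hhscan.kinetics import KineticsFit, format_fold_change


def _mono_grid(kobs, f_lo=0.02, f_hi=0.45, n=10):
    """Times whose noiseless fractions span the early reaction."""
    fs = np.linspace(f_lo, f_hi, n)
    return [-math.log(1.0 - f) / kobs for f in fs]


class TestLinearKobs:
    def test_noiseless_closed_form(self):
        times = _mono_grid(0.5, n=8)
        trace = simulate_trace(times, kobs=0.5)
        fit = fit_kobs_linear(trace)
        assert fit.kobs == pytest.approx(0.5, rel=1e-9)
        assert fit.model == "monophasic"

    def test_no_reaction_progress_errors(self):
        trace = KineticsTrace([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        with pytest.raises(FitError):
            fit_kobs_linear(trace, endpoint="observed")

    def test_too_few_window_points_errors(self):
        trace = KineticsTrace([1.0, 2.0, 3.0], [0.6, 0.8, 0.9])
        with pytest.raises(FitError, match="window"):
            fit_kobs_linear(trace)

    def test_endpoint_reached_in_window_errors(self):
        trace = KineticsTrace([1.0, 2.0, 3.0], [0.1, 0.5, 1.0])
        with pytest.raises(FitError, match="endpoint"):
            fit_kobs_linear(trace, window=(0.05, 1.0))

    def test_subsampling_invariance_noiseless(self):
        times = _mono_grid(0.2, n=16)
        trace = simulate_trace(times, kobs=0.2)
        full = fit_kobs_linear(trace).kobs
        sub = simulate_trace(times[::2], kobs=0.2)
        assert fit_kobs_linear(sub).kobs == pytest.approx(full, rel=1e-9)

    def test_partial_amplitude_with_known_endpoint(self):
        times = _mono_grid(0.3, n=10)
        trace = simulate_trace(times, kobs=0.3, amplitude=0.8)
        fit = fit_kobs_linear(trace, endpoint=0.8)
        assert fit.kobs == pytest.approx(0.3, rel=1e-9)


class TestBiphasic:
    TRUE = (0.6, 1.0, 0.3, 0.05)

    def _trace(self, sd=0.0, seed=0):
        times = list(np.linspace(0.2, 6, 12)) + list(np.linspace(8, 80, 10))
        return simulate_trace(times, biphasic=self.TRUE, noise_sd=sd, seed=seed)

    def test_noiseless_recovery(self):
        fit = fit_biphasic(self._trace())
        a, b, c, d = self.TRUE
        assert fit.a == pytest.approx(a, rel=0.01)
        assert fit.b == pytest.approx(b, rel=0.01)
        assert fit.c == pytest.approx(c, rel=0.01)
        assert fit.d == pytest.approx(d, rel=0.01)
        assert fit.b >= fit.d

    def test_nested_model_agreement_when_single_phase(self):
        times = _mono_grid(0.3, f_hi=0.95, n=20)
        trace = simulate_trace(times, kobs=0.3)
        mono = fit_kobs_linear(trace).kobs
        bi = fit_biphasic(trace)
        assert bi.b == pytest.approx(mono, rel=0.05)

    def test_decreasing_trace_rejected(self):
        trace = KineticsTrace(list(range(1, 8)), [0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3])
        with pytest.raises(FitError, match="decreases"):
            fit_biphasic(trace)

    def test_too_few_points_rejected(self):
        trace = KineticsTrace([1, 2, 3, 4], [0.1, 0.2, 0.3, 0.4])
        with pytest.raises(FitError, match="6 points"):
            fit_biphasic(trace)

    def test_summary_reports_both_phases(self):
        fit = fit_biphasic(self._trace())
        text = fit.summary()
        assert "fast phase" in text and "slow phase" in text and "min^-1" in text


class TestSimulate:
    def test_same_seed_identical(self):
        t = list(np.linspace(1, 10, 8))
        a = simulate_trace(t, kobs=0.2, noise_sd=0.02, seed=5)
        b = simulate_trace(t, kobs=0.2, noise_sd=0.02, seed=5)
        assert list(a.fraction_cleaved) == list(b.fraction_cleaved)

    def test_noiseless_limit_exact(self):
        t = [1.0, 2.0, 3.0]
        tr = simulate_trace(t, kobs=0.5, noise_sd=0.0)
        expected = [1 - math.exp(-0.5 * x) for x in t]
        assert np.allclose(tr.fraction_cleaved, expected)

    def test_noise_sd_calibrated(self):
        t = list(np.linspace(0.01, 10, 1000))
        tr = simulate_trace(t, kobs=0.1, noise_sd=0.02, seed=11)
        model = 1 - np.exp(-0.1 * np.asarray(t))
        resid = np.asarray(tr.fraction_cleaved) - model
        assert abs(float(np.std(resid)) - 0.02) < 0.004  # within 20%

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_trace([1, 2, 3], kobs=-1.0)
        with pytest.raises(ValueError):
            simulate_trace([1, 2, 3], kobs=0.5, noise_sd=-0.1)
        with pytest.raises(ValueError):
            simulate_trace([1, 2, 3])  # neither model given


class TestFoldChange:
    def test_equal_rates_give_one(self):
        assert fold_change(0.2, 0.2) == 1.0

    def test_simple_ratio(self):
        assert fold_change(1.2, 0.1) == pytest.approx(12.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fold_change(0.0, 0.1)
        with pytest.raises(ValueError):
            fold_change(0.1, -2.0)

    def test_three_sig_fig_formatting(self):
        assert format_fold_change(424.99999) == "425"
        assert format_fold_change(12.0) == "12"

    @given(
        st.floats(min_value=1e-6, max_value=1e3),
        st.floats(min_value=1e-6, max_value=1e3),
    )
    @settings(derandomize=True, max_examples=60)
    def test_reciprocal_product_is_one(self, x, y):
        assert math.isclose(fold_change(x, y) * fold_change(y, x), 1.0, rel_tol=1e-12)


class TestKineticsFitInvariants:
    def test_rate_positivity_enforced(self):
        with pytest.raises(ValueError):
            KineticsFit(model="monophasic", kobs=-0.1)

    def test_biphasic_conventions_enforced(self):
        with pytest.raises(ValueError):
            KineticsFit(model="biphasic", a=0.5, b=0.1, c=0.4, d=1.0)  # b < d
        with pytest.raises(ValueError):
            KineticsFit(model="biphasic", a=0.9, b=1.0, c=0.9, d=0.1)  # a+c > 1.05
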