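"""Single-neuron analysis: windows, circular variance, fits, dynamics."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vartune import stimuli, synthetic, tuning
from vartune.tuning import (
    TuningCurve,
    b_theta_max,
    best_window,
    circular_variance,
    delay_to_peak,
    direction_selectivity,
    early_late_ratio,
    fit_von_mises,
    fit_vtf,
    hwhh,
    tuning_significance,
)

THETAS = np.arange(12) * 15.0


class TestBestWindow:
    def test_burst_window_contains_burst(self):
        counts = np.zeros((4, 45))
        counts[0, 20:25] = 10.0  # burst at 200-250 ms in one condition
        start = best_window(counts)
        assert start <= 200.0 <= start + 300.0 - 50.0

    def test_stationary_ties_to_earliest(self):
        counts = np.ones((4, 45))
        counts[0] = 2.0
        assert best_window(counts) == 0.0

    def test_all_zero_warns_default(self):
        with pytest.warns(UserWarning):
            assert best_window(np.zeros((3, 45))) == 0.0

    def test_transient_neuron_early_window(self):
        """Difference-of-exponentials transient: enumerated windows agree."""
        t = np.arange(45) * 10.0 + 5.0
        kernel = np.exp(-t / 60.0) - np.exp(-t / 10.0)
        counts = np.stack([g * kernel for g in (0.2, 1.0, 3.0)])
        # brute-force oracle
        variances = [
            counts[:, s:s + 30].sum(axis=1).var() for s in range(16)]
        assert best_window(counts) == np.argmax(variances) * 10.0
        assert best_window(counts) < 100.0


class TestCircularVariance:
    def test_uniform_rates_cv_one(self):
        assert circular_variance(np.ones(12), THETAS) == pytest.approx(1.0)

    def test_single_rate_cv_zero(self):
        rates = np.zeros(12)
        rates[3] = 5.0
        assert circular_variance(rates, THETAS) == pytest.approx(0.0)

    def test_matches_complex_sum_oracle(self):
        rates = np.array([2, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1], dtype=float)
        num = sum(r * np.exp(2j * np.deg2rad(th))
                  for r, th in zip(rates, THETAS))
        oracle = 1 - abs(num) / rates.sum()
        assert circular_variance(rates, THETAS) == pytest.approx(
            oracle, abs=1e-12)

    def test_all_zero_flagged_as_one(self):
        with pytest.warns(UserWarning):
            assert circular_variance(np.zeros(12), THETAS) == 1.0

    @settings(derandomize=True, max_examples=30)
    @given(scale=st.floats(0.1, 100.0), rot=st.floats(0.0, 180.0),
           seed=st.integers(0, 1000))
    def test_invariant_to_scaling_and_rotation(self, scale, rot, seed):
        rng = np.random.default_rng(seed)
        rates = rng.uniform(0.1, 10.0, 12)
        cv = circular_variance(rates, THETAS)
        assert circular_variance(rates * scale, THETAS) == pytest.approx(cv)
        assert circular_variance(rates, THETAS + rot) == pytest.approx(cv)


class TestVonMisesFit:
    def _curve(self, y):
        return TuningCurve(b_theta=0.5, theta_values=THETAS, mean_rate=y,
                           sem=np.zeros(12), window=(0.0, 300.0))

    def test_noiseless_recovery(self):
        true = dict(r0=2.0, rmax=30.0, theta_pref=62.0, kappa=2.5)
        y = tuning._vm_model(THETAS, true["r0"], true["rmax"],
                             true["theta_pref"], true["kappa"])
        fit = fit_von_mises(self._curve(y))
        assert fit.r0 == pytest.approx(2.0, abs=1e-6)
        assert fit.r_max == pytest.approx(30.0, abs=1e-6)
        assert fit.theta_pref == pytest.approx(62.0, abs=1e-6)
        assert fit.kappa == pytest.approx(2.5, abs=1e-6)
        assert fit.r_squared > 0.999 and not fit.excluded

    def test_flat_curve_excluded(self):
        fit = fit_von_mises(self._curve(np.full(12, 3.0)))
        assert fit.excluded

    def test_noisy_theta_pref_recovery_rate(self):
        """Poisson noise, kappa=2, 15 trials: pref within half a grid step
        in >= 95% of simulations."""
        hits = 0
        n_sim = 200
        rng = np.random.default_rng(42)
        rate = tuning._vm_model(THETAS, 2.0, 25.0, 40.0, 2.0) * 0.3  # counts
        for _ in range(n_sim):
            y = rng.poisson(np.tile(rate, (15, 1))).mean(axis=0) / 0.3
            fit = fit_von_mises(self._curve(y))
            d = abs(fit.theta_pref - 40.0) % 180.0
            hits += min(d, 180.0 - d) <= 7.5
        assert hits / n_sim >= 0.95


class TestDirectionSelectivity:
    @pytest.mark.parametrize("pref,null,expect",
                             [(10.0, 10.0, 0.0), (10.0, 0.0, 1.0),
                              (20.0, 5.0, 0.75)])
    def test_values(self, pref, null, expect):
        assert direction_selectivity(pref, null) == pytest.approx(expect)

    def test_nonpositive_pref_flagged(self):
        with pytest.warns(UserWarning):
            assert np.isnan(direction_selectivity(0.0, 1.0))


class TestNKRFit:
    def test_half_rise_identity(self):
        """f(b50) - f0 = fmax/2 for any fitted parameters."""
        rng = np.random.default_rng(1)
        y = np.clip(rng.uniform(0.2, 0.9, 8), 0, 1)
        fit = fit_vtf(stimuli.B_THETA_GRID_DEG, np.sort(y))
        assert fit.predict(fit.b_theta50) - fit.f0 == pytest.approx(
            fit.f_max / 2.0, abs=1e-9)

    def test_flat_vtf_flagged(self):
        fit = fit_vtf(stimuli.B_THETA_GRID_DEG, np.full(8, 0.4))
        assert fit.f_max == pytest.approx(0.0, abs=1e-3)
        assert fit.flagged

    def test_monotone_nondecreasing(self):
        y = synthetic.vtf_value(stimuli.B_THETA_GRID_DEG, 0.3, 0.5, 3.0, 20.0)
        fit = fit_vtf(stimuli.B_THETA_GRID_DEG, y)
        dense = fit.predict(np.linspace(0.5, 44.0, 500))
        assert np.all(np.diff(dense) >= -1e-12)


class TestSignificance:
    def test_identical_vectors_not_significant(self):
        p = tuning_significance(np.full(15, 4.0), np.full(15, 4.0))
        assert np.isnan(p)  # no informative pairs

    def test_strong_contrast_detected(self):
        """Poisson(30) vs Poisson(2), 15 paired trials: significant in
        >= 99% of simulations."""
        rng = np.random.default_rng(0)
        hits = 0
        n_sim = 500
        for _ in range(n_sim):
            p = tuning_significance(rng.poisson(30, 15), rng.poisson(2, 15))
            hits += (p < 0.05)
        assert hits / n_sim >= 0.99

    def test_b_theta_max_rule(self):
        b = stimuli.B_THETA_GRID_DEG
        p = np.array([0.001, 0.01, 0.2, 0.03, 0.5, np.nan, 0.6, 0.9])
        assert b_theta_max(b, p) == b[3]
        assert np.isnan(b_theta_max(b, np.full(8, 0.5)))


class TestDynamics:
    def test_early_spikes_negative_ratio(self):
        spikes = np.random.default_rng(0).uniform(0, 90, 200)
        assert early_late_ratio(spikes) < -3.0

    def test_late_spikes_positive_ratio(self):
        spikes = np.random.default_rng(0).uniform(250, 440, 200)
        assert early_late_ratio(spikes) > 3.0

    def test_delay_impulse_at_250(self):
        centers = np.arange(0.0, 351.0, 10.0) + 50.0
        curves = []
        for c in centers:
            # 100 ms window catches a 250 ms impulse iff |center-250| <= 50
            amp = 1.0 if abs(c - 250.0) <= 50.0 else 0.0
            # sharper when centered
            curves.append([amp * (1 - abs(c - 250.0) / 100.0), 0.0])
        assert delay_to_peak(np.array(curves), centers) == 250.0


class TestHWHH:
    def test_boundary_value(self):
        assert hwhh(-np.log(0.5)) == pytest.approx(45.0)

    def test_kappa_two(self):
        expect = 0.5 * np.arccos((np.log(0.5) + 2.0) / 2.0)  # ~0.43 rad
        assert hwhh(2.0) == pytest.approx(np.rad2deg(expect), abs=1e-9)
        assert np.rad2deg(expect) == pytest.approx(24.6, abs=0.1)

    def test_narrow_limit(self):
        assert hwhh(1e6) < 0.1

    def test_domain_error(self):
        with pytest.raises(ValueError):
            hwhh(0.5)


class TestSummaries:
    def test_summary_fields_finite(self, summaries60):
        _, table = summaries60
        assert table["cv_low"].between(0, 1).all()
        assert table["cv_high"].between(0, 1).all()
        assert np.isfinite(table["early_late_low"]).all()
        assert np.isfinite(table["delay_low"]).all()

    def test_archetype_b_theta_max_ordering(self, summaries60, truth60):
        """Resilient neurons stay significantly tuned to higher variance."""
        _, table = summaries60
        labels = np.array([truth60[i].archetype
                           for i in table["neuron_id"]])
        bmax = table["b_theta_max"].to_numpy()
        assert (np.nanmedian(bmax[labels == "resilient"])
                > np.nanmedian(bmax[labels == "vulnerable"]))

    def test_preferred_orientation_stable_under_variance(self, summaries60):
        _, table = summaries60
        shifts = table["pref_shift_deg"].dropna()
        assert (shifts < 15.0).mean() >= 0.9

    def test_dynamics_separate_archetypes(self, summaries60, truth60):
        _, table = summaries60
        labels = np.array([truth60[i].archetype
                           for i in table["neuron_id"]])
        el = table["early_late_low"].to_numpy()
        assert (np.median(el[labels == "resilient"])
                > np.median(el[labels == "vulnerable"]))
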