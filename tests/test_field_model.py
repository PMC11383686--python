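"""Neural field model: transfer function, kernels, noise, Hopf tuning."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from phasecode.field_model import (FieldParams, InputSpec, LIFParams,
                                   fi_curve, hopf_frequency,
                                   jacobian_eigenvalues, ou_path,
                                   simulate_field, stimulus_profile,
                                   tune_to_hopf, weight_kernel)


# --------------------------------------------------------------------------
# F-I curve (Siegert formula)
# --------------------------------------------------------------------------

class TestFICurve:
    def test_deterministic_threshold(self):
        """With no noise, 1 nA brings the membrane exactly to threshold:
        just below it the neuron is silent."""
        lif = LIFParams(sigma=0.0)
        assert fi_curve(0.999, lif) == 0.0
        assert fi_curve(1.001, lif) > 0.0

    def test_refractory_ceiling(self):
        lif = LIFParams(sigma=0.0)
        assert fi_curve(1e6, lif) == pytest.approx(200.0, rel=1e-3)

    @pytest.mark.parametrize("sigma", [0.0, 0.5, 2.0])
    def test_monotone_and_bounded(self, sigma):
        lif = LIFParams(sigma=sigma)
        I = np.linspace(-2.0, 30.0, 40)
        r = fi_curve(I, lif)
        assert np.all(r >= 0)
        assert np.all(r <= 1000.0 / lif.t_ref + 1e-9)
        assert np.all(np.diff(r) >= -1e-9)

    def test_nonfinite_current_rejected(self):
        with pytest.raises(ValueError):
            fi_curve(np.nan)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            LIFParams(sigma=-1.0)

    def test_matches_stochastic_lif_simulation(self):
        """The Siegert rate agrees with a brute-force Euler-Maruyama
        simulation of the noisy LIF neuron within Monte-Carlo error."""
        lif = LIFParams(sigma=1.0)
        rng = np.random.default_rng(42)
        dt = 0.02           # ms
        n_neurons = 400
        t_total = 400.0     # ms per neuron -> 160 s simulated per point
        n_steps = int(t_total / dt)
        for I in [0.8, 1.0, 1.5, 2.5]:
            V = np.full(n_neurons, lif.Vl)
            refr = np.zeros(n_neurons)
            spikes = 0
            noise_scale = lif.sigma / lif.C * np.sqrt(dt)
            for _ in range(n_steps):
                active = refr <= 0
                dV = (lif.gl * (lif.Vl - V) + I) / lif.C * dt
                V = np.where(active, V + dV + noise_scale
                             * rng.standard_normal(n_neurons), V)
                refr = np.maximum(refr - dt, 0.0)
                fired = V >= lif.Vt
                spikes += int(fired.sum())
                V = np.where(fired, lif.Vl, V)
                refr = np.where(fired, lif.t_ref, refr)
            sim_rate = 1000.0 * spikes / (n_neurons * t_total)
            th = fi_curve(I, lif)
            se = 1000.0 * np.sqrt(max(spikes, 1)) / (n_neurons * t_total)
            assert sim_rate == pytest.approx(th, abs=max(4 * se, 0.05 * th
                                                         + 0.5))


# --------------------------------------------------------------------------
# spatial kernel and stimulus
# --------------------------------------------------------------------------

class TestKernelAndStimulus:
    def test_uniform_limit(self):
        theta = np.linspace(0, np.pi, 64, endpoint=False)
        W = weight_kernel(0.0, theta)
        assert np.allclose(W, 1.0 / np.pi)

    @pytest.mark.parametrize("kappa", [0.0, 0.5, 2.0, 6.0])
    def test_normalization(self, kappa):
        theta = np.linspace(0, np.pi, 64, endpoint=False)
        W = weight_kernel(kappa, theta)
        assert np.sum(W) * np.pi / 64 == pytest.approx(1.0, abs=1e-6)

    def test_peak_value_matches_bessel_series(self):
        """W(0) = e^kappa / (pi I0(kappa)); I0 via its power series."""
        kappa = 2.0
        from math import factorial
        i0_series = sum((kappa / 2) ** (2 * k) / factorial(k) ** 2
                        for k in range(40))
        W0 = weight_kernel(kappa, np.array([0.0]))[0]
        assert W0 == pytest.approx(np.exp(kappa) / (np.pi * i0_series),
                                   rel=1e-10)

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError):
            weight_kernel(-1.0, np.array([0.0]))

    def test_stimulus_profile_peak_and_antipode(self):
        spec = InputSpec(a=1, b=0, theta0=np.pi / 2, kappa_s=1.5)
        theta = np.array([np.pi / 2, 0.0])   # peak and orthogonal
        S = stimulus_profile(spec, theta)
        assert S[0] == pytest.approx(1.0)
        assert S[1] == pytest.approx(np.exp(-2 * 1.5))
        uniform = stimulus_profile(InputSpec(kappa_s=0.0),
                                   np.linspace(0, np.pi, 16))
        assert np.allclose(uniform, 1.0)


# --------------------------------------------------------------------------
# OU noise
# --------------------------------------------------------------------------

class TestOUPath:
    def test_zero_sigma_is_zero(self):
        assert np.all(ou_path(50.0, 0.0, 0.1, 1000, seed=0) == 0.0)

    def test_stationary_sd_and_autocorrelation(self):
        tau, sig, dt = 50.0, 1.0, 1.0
        y = ou_path(tau, sig, dt, 400_000, seed=3)
        n_eff = len(y) * dt / (2 * tau)       # effective sample count
        se = sig / np.sqrt(2 * n_eff)
        assert y.std() == pytest.approx(sig, abs=3 * se)
        lag = int(tau / dt)
        rho = pearsonr(y[:-lag], y[lag:])[0]
        assert rho == pytest.approx(np.exp(-1), abs=0.02)

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError):
            ou_path(50.0, 1.0, 60.0, 10, seed=0)

    def test_reproducible(self):
        a = ou_path(50.0, 1.0, 0.5, 100, seed=9)
        b = ou_path(50.0, 1.0, 0.5, 100, seed=9)
        assert np.array_equal(a, b)


# --------------------------------------------------------------------------
# Hopf tuning and simulation
# --------------------------------------------------------------------------

class TestHopfTuning:
    def test_threshold_near_default_operating_point(self, default_params):
        """The shipped baseline currents sit a few hundredths of a nA above
        the instability threshold found by bisection."""
        Istar = tune_to_hopf(default_params, I_lo=-0.3, I_hi=0.3)
        assert -0.08 < Istar < 0.0

    def test_linear_stability_flips_across_threshold(self, default_params):
        Istar = tune_to_hopf(default_params, I_lo=-0.3, I_hi=0.3)
        below = np.max(np.real(jacobian_eigenvalues(default_params,
                                                    Istar - 0.01)))
        above = np.max(np.real(jacobian_eigenvalues(default_params,
                                                    Istar + 0.01)))
        assert below < 0 < above

    def test_below_threshold_decays_to_fixed_point(self, quiet_trace):
        late = quiet_trace.u[-200:]
        assert late.std() < 1e-3 * max(late.mean(), 1e-12) + 1e-6

    def test_supercritical_branch_is_continuous(self, default_params):
        """Amplitude grows continuously from zero above threshold: no jump
        larger than a factor ~3 between adjacent drive levels."""
        Istar = tune_to_hopf(default_params, I_lo=-0.3, I_hi=0.3)
        amps = []
        for eps in [0.001, 0.004, 0.016]:
            p = default_params.replace(
                Ie0=default_params.Ie0 + Istar + eps,
                Ii0=default_params.Ii0 + Istar + eps, sigma_z=0.0)
            tr = simulate_field(p, InputSpec(a=0, b=0), duration=2500.0,
                                seed=1).after_transient()
            amps.append(np.sqrt(2) * (tr.lfp - tr.lfp.mean()).std())
        amps = np.array(amps)
        assert np.all(np.diff(amps) > 0)
        assert np.all(amps[1:] / amps[:-1] < 3.0)
        assert amps[0] < 0.5 * amps[-1]

    def test_no_crossing_raises_with_profile(self, default_params):
        weak = default_params.replace(wee=0.01, wie=0.01)
        with pytest.raises(RuntimeError, match="profile"):
            tune_to_hopf(weak, I_lo=-0.2, I_hi=0.2)

    def test_hopf_frequency_positive_at_threshold(self, default_params):
        Istar = tune_to_hopf(default_params, I_lo=-0.3, I_hi=0.3)
        assert hopf_frequency(default_params, Istar) > 5.0


class TestSimulateField:
    def test_lfp_is_theta_mean_and_rates_nonnegative(self, osc_trace):
        assert np.allclose(osc_trace.lfp, osc_trace.u.mean(axis=1))
        assert np.all(osc_trace.u >= 0)
        assert np.all(osc_trace.v >= 0)
        assert np.all(np.isfinite(osc_trace.u))

    def test_beta_band_spectral_peak_at_operating_point(self, osc_trace):
        x = osc_trace.lfp - osc_trace.lfp.mean()
        freqs = np.fft.rfftfreq(len(x), d=osc_trace.dt / 1000.0)
        power = np.abs(np.fft.rfft(x)) ** 2
        peak = freqs[(freqs > 5)][np.argmax(power[freqs > 5])]
        assert 14.0 <= peak <= 22.0

    def test_deterministic_given_seed(self, default_params):
        a = simulate_field(default_params, InputSpec(), 1500.0, seed=3)
        b = simulate_field(default_params, InputSpec(), 1500.0, seed=3)
        assert np.array_equal(a.u, b.u)
        assert np.array_equal(a.y, b.y)

    def test_step_size_convergence_fixed_point(self, default_params):
        """Halving dt changes the late-time solution by < 1% RMS (on a
        subthreshold run, where the solution is a fixed point and the
        comparison is not confounded by oscillator phase drift)."""
        p = default_params.replace(Ie0=default_params.Ie0 - 0.2,
                                   Ii0=default_params.Ii0 - 0.2,
                                   sigma_z=0.0)
        a = simulate_field(p, InputSpec(a=0, b=0), 1500.0, dt=0.1, seed=1,
                           record_stride=10)
        b = simulate_field(p, InputSpec(a=0, b=0), 1500.0, dt=0.05, seed=1,
                           record_stride=20)
        ua, ub = a.u[-500:], b.u[-500:]
        rms = np.sqrt(np.mean((ua - ub) ** 2)) / np.sqrt(np.mean(ua ** 2))
        assert rms < 0.01

    def test_step_size_convergence_limit_cycle(self, default_params):
        """On the oscillating branch, halving dt leaves the cycle's
        amplitude, mean and frequency within a few percent (pointwise
        comparison is meaningless there: an O(dt) frequency error dephases
        the cycle, and explicit Euler converges first-order in the cycle
        amplitude)."""
        p = default_params.replace(sigma_z=0.0)
        stats = []
        for dt, stride in ((0.1, 10), (0.05, 20)):
            tr = simulate_field(p, InputSpec(), 3000.0, dt=dt, seed=1,
                                record_stride=stride).after_transient()
            x = tr.lfp - tr.lfp.mean()
            zc = np.sum((x[:-1] < 0) & (x[1:] >= 0))
            stats.append((tr.lfp.mean(), np.sqrt(2) * x.std(), zc))
        for a_, b_ in zip(*stats):
            assert abs(a_ - b_) / abs(a_) < 0.03

    def test_wm_raises_frequency_amplitude_and_rate(self, default_params):
        """Stronger WM drive monotonically raises oscillation frequency,
        amplitude, and mean rate across levels 0..3."""
        p = default_params.replace(sigma_z=0.0)
        freqs, amps, rates = [], [], []
        for b in range(4):
            tr = simulate_field(p, InputSpec(a=0, b=b), 3000.0,
                                seed=2).after_transient()
            x = tr.lfp - tr.lfp.mean()
            zc = np.sum((x[:-1] < 0) & (x[1:] >= 0))
            freqs.append(zc / ((tr.time[-1] - tr.time[0]) / 1000.0))
            amps.append(np.sqrt(2) * x.std())
            rates.append(tr.lfp.mean())
        assert all(np.diff(freqs) > 0)
        assert all(np.diff(amps) > 0)
        assert all(np.diff(rates) > 0)

    def test_hdf5_roundtrip(self, tmp_path, default_params):
        tr = simulate_field(default_params, InputSpec(), 1000.0, seed=8)
        path = tmp_path / "trace.h5"
        tr.to_hdf5(path)
        back = tr.from_hdf5(path)
        assert np.array_equal(back.u, tr.u)
        assert back.params == tr.params
        assert back.inputs == tr.inputs
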