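"""Connectivity estimators: analytic signal, PLV, dwPLI, AEC, strength."""

import numpy as np
import pytest

from restconn.connectivity import (AnalyticEpochs, ConnectivityMatrix, aec,
                                   analytic_signal, connectivity_strength,
                                   dwpli, plv)
from restconn.spectral import BANDS

from conftest import phase_coupled_subject


def _phases_to_analytic(phases, band="theta", rate=250.0):
    return AnalyticEpochs(np.exp(1j * phases), BANDS[band], rate)


class TestAnalyticSignal:
    def test_in_band_tone_constant_envelope_and_phase_slope(self, rate):
        t = np.arange(int(rate * 10)) / rate
        x = np.cos(2 * np.pi * 10 * t)[None, :]
        an = analytic_signal(x, BANDS["alpha"], rate)
        env = np.abs(an.data[0, 0])
        assert env.std() / env.mean() < 0.05
        phase = np.unwrap(np.angle(an.data[0, 0]))
        slope = np.polyfit(np.arange(phase.size) / rate, phase, 1)[0]
        assert abs(slope - 2 * np.pi * 10) / (2 * np.pi * 10) < 0.01

    def test_stop_band_attenuation(self, rate):
        t = np.arange(int(rate * 10)) / rate
        x = np.cos(2 * np.pi * 10 * t)[None, :]
        in_band = np.abs(analytic_signal(x, BANDS["alpha"], rate).data).mean()
        out_band = np.abs(analytic_signal(x, BANDS["gamma"], rate).data).mean()
        assert out_band < 0.01 * in_band

    def test_real_part_is_bandpassed_input(self, rate):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, int(rate * 10)))
        from restconn._filters import bandpass
        bp = bandpass(x, 8.0, 13.0, rate)
        an = analytic_signal(x, BANDS["alpha"], rate, trim_s=0.1)
        trim = round(0.1 * rate)
        np.testing.assert_allclose(np.real(an.data[0]),
                                   bp[:, trim:-trim], atol=1e-8)

    def test_band_above_nyquist_rejected(self):
        from restconn.spectral import BandDefinition
        with pytest.raises(ValueError):
            analytic_signal(np.zeros((1, 1000)), BandDefinition("hi", 60, 80),
                            rate_hz=100.0)


class TestPlv:
    def test_identical_phases_give_one(self):
        rng = np.random.default_rng(1)
        ph = rng.uniform(0, 2 * np.pi, size=(5, 1, 300))
        x = _phases_to_analytic(np.concatenate([ph, ph], axis=1))
        assert np.isclose(plv(x).values[0, 1], 1.0)

    def test_constant_lag_invariance(self):
        rng = np.random.default_rng(2)
        ph = rng.uniform(0, 2 * np.pi, size=(5, 1, 300))
        x = _phases_to_analytic(np.concatenate([ph, ph + np.pi / 2], axis=1))
        assert np.isclose(plv(x).values[0, 1], 1.0)

    def test_independent_phases_match_analytic_null(self):
        """E[PLV] = sqrt(pi)/(2 sqrt(N)) for iid uniform phase differences."""
        rng = np.random.default_rng(3)
        n_samp, n_ep = 400, 200
        ph = rng.uniform(0, 2 * np.pi, size=(n_ep, 2, n_samp))
        vals = plv(_phases_to_analytic(ph)).values[0, 1]
        expect = np.sqrt(np.pi) / (2 * np.sqrt(n_samp))
        assert abs(vals - expect) / expect < 0.05

    def test_amplitude_scaling_invariance(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=(3, 4, 200)) + 1j * rng.normal(size=(3, 4, 200))
        a = plv(AnalyticEpochs(z, BANDS["theta"], 250.0)).values
        b = plv(AnalyticEpochs(7.3 * z, BANDS["theta"], 250.0)).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_monotone_in_planted_coupling_strength(self):
        """Mean PLV over replicate subjects rises with the mixing weight
        (the shared-signal variance fraction is the squared weight, so the
        curve is flat near zero and steep near one)."""
        means = []
        for c in (0.3, 0.7, 1.0):
            vals = []
            for seed in (7, 8, 9):
                sub = phase_coupled_subject(strength=c, duration=40.0,
                                            seed=seed)
                an = analytic_signal(sub.source_truth, BANDS["theta"], 250.0)
                vals.append(plv(an).values[0, 1])
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestDwpli:
    def test_zero_lag_coupling_invisible(self):
        rng = np.random.default_rng(5)
        ph = rng.uniform(0, 2 * np.pi, size=(5, 1, 300))
        x = _phases_to_analytic(np.concatenate([ph, ph], axis=1))
        res = dwpli(x)
        assert abs(res.values[0, 1]) < 1e-9
        assert res.degenerate

    def test_quarter_cycle_lag_saturates(self):
        rng = np.random.default_rng(6)
        ph = rng.uniform(0, 2 * np.pi, size=(5, 1, 300))
        x = _phases_to_analytic(np.concatenate([ph, ph + np.pi / 2], axis=1))
        assert dwpli(x).values[0, 1] > 0.999

    def test_independent_signals_debiased_to_zero_mean(self):
        rng = np.random.default_rng(7)
        vals = []
        for _ in range(40):
            ph = rng.uniform(0, 2 * np.pi, size=(4, 2, 250))
            vals.append(dwpli(_phases_to_analytic(ph)).values[0, 1])
        assert abs(np.mean(vals)) < 0.01

    def test_zero_lag_high_plv_dissociation(self):
        """Zero-lag planted coupling: PLV high, dwPLI near zero; lagged
        coupling: both high."""
        zero = phase_coupled_subject(strength=1.0, lag_rad=0.0)
        lag = phase_coupled_subject(strength=1.0, lag_rad=np.pi / 2)
        an0 = analytic_signal(zero.source_truth, BANDS["theta"], 250.0)
        anl = analytic_signal(lag.source_truth, BANDS["theta"], 250.0)
        assert plv(an0).values[0, 1] > 0.8
        assert abs(dwpli(an0).values[0, 1]) < 0.1
        assert dwpli(anl).values[0, 1] > 0.8


class TestAec:
    def test_self_orthogonalization_removes_everything(self):
        """A signal correlated with itself after orthogonalization: the
        collinear component vanishes, so the diagonal carries no signal."""
        rng = np.random.default_rng(8)
        z = rng.normal(size=(2, 1, 500)) + 1j * rng.normal(size=(2, 1, 500))
        x = AnalyticEpochs(np.concatenate([z, z], axis=1), BANDS["alpha"], 250.0)
        res = aec(x)
        # identical signals orthogonalize to an exactly-zero envelope: the
        # entry is flagged missing (zero-variance envelope) or zero
        v = res.values[0, 1]
        assert np.isnan(v) or abs(v) < 1e-6
        assert res.values[0, 0] == 0.0

    def test_planted_envelope_correlation_increases_with_rho(self):
        means = []
        for c in (0.0, 0.4, 0.8):
            vals = []
            for seed in (7, 8, 9):
                sub = phase_coupled_subject(strength=c, band="alpha",
                                            coupling="amplitude",
                                            duration=120.0, seed=seed)
                an = analytic_signal(sub.source_truth, BANDS["alpha"], 250.0)
                vals.append(aec(an).values[0, 1])
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]
        assert means[2] > 0.1

    def test_independent_narrowband_signals_near_zero(self, rate):
        rng = np.random.default_rng(9)
        from restconn._filters import bandpass
        x = bandpass(rng.normal(size=(4, int(rate * 60))), 8, 13, rate)
        an = analytic_signal(x[None], BANDS["alpha"], rate)
        off = aec(an).values[np.triu_indices(4, 1)]
        assert np.abs(off).mean() < 0.1

    def test_scaling_invariance(self):
        rng = np.random.default_rng(10)
        z = rng.normal(size=(2, 3, 400)) + 1j * rng.normal(size=(2, 3, 400))
        a = aec(AnalyticEpochs(z, BANDS["alpha"], 250.0)).values
        b = aec(AnalyticEpochs(4.2 * z, BANDS["alpha"], 250.0)).values
        np.testing.assert_allclose(a, b, atol=1e-10)


class TestConnectivityStrength:
    def test_uniform_matrix(self):
        vals = np.full((5, 5), 0.3)
        np.fill_diagonal(vals, 0)
        m = ConnectivityMatrix(vals, "plv", BANDS["theta"])
        np.testing.assert_allclose(connectivity_strength(m), 0.3)

    def test_single_edge(self):
        vals = np.zeros((6, 6))
        vals[1, 4] = vals[4, 1] = 1.0
        m = ConnectivityMatrix(vals, "plv", BANDS["theta"])
        s = connectivity_strength(m)
        assert np.isclose(s[1], 1.0 / 5)
        assert np.isclose(s[0], 0.0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(11)
        v = rng.uniform(size=(6, 6))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        m = ConnectivityMatrix(v, "plv", BANDS["theta"])
        perm = rng.permutation(6)
        mp = ConnectivityMatrix(v[np.ix_(perm, perm)], "plv", BANDS["theta"])
        np.testing.assert_allclose(connectivity_strength(mp),
                                   connectivity_strength(m)[perm])


class TestEmgControl:
    def test_emg_to_source_coupling_at_null_level(self):
        """Independent EMG channels show only null-level phase locking with
        the sources."""
        sub = phase_coupled_subject(strength=0.8, duration=60.0)
        combined = np.vstack([sub.source_truth[:1], sub.emg[:1]])
        an = analytic_signal(combined, BANDS["theta"], 250.0)
        emg_plv = plv(an).values[0, 1]
        # compare against the planted-pair PLV of the same subject
        an_src = analytic_signal(sub.source_truth, BANDS["theta"], 250.0)
        assert emg_plv < 0.3 * plv(an_src).values[0, 1]
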