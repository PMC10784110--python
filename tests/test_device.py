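"""Lead, amplifier and ADC layers: leakage law, nonlinearities, aliasing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mclfp as m
from mclfp.config import ConfigError


class TestLeakage:
    def test_matched_electrodes_reject_everything(self):
        assert m.leakage_amplitude(8.0, m.LeadModel(Z1=500, Z3=500)) == 0.0

    def test_published_calibration_point(self):
        # 5 V with a 1000 Ω mismatch over Z_b = 10 kΩ leaks 0.5 V (10%)
        lead = m.LeadModel(Z1=1000, Z3=2000, Z_b=1e4)
        assert m.leakage_amplitude(5.0, lead) == pytest.approx(0.5)

    def test_leakage_saturates_at_full_amplitude(self):
        lead = m.LeadModel(Z1=0, Z3=2e4, Z_b=1e4)
        assert m.leakage_amplitude(3.0, lead) == 3.0

    def test_negative_inputs_raise(self):
        with pytest.raises(ConfigError):
            m.LeadModel(Z1=-1, Z3=100)
        with pytest.raises(ConfigError):
            m.leakage_amplitude(-1.0, m.LeadModel())


class TestDifferentialStage:
    def _sources(self, **brain_kw):
        return m.assemble_sources(m.BrainConfig(**brain_kw), m.StimConfig(amplitude=8.0))

    def test_common_mode_cancellation(self):
        x1, _, s, orm = self._sources(orm_amplitude=0.0)
        lead = m.LeadModel(Z1=700, Z3=700)
        out = m.differential_stage(x1, x1, s, m.SourceSignal(np.zeros_like(s.samples), s.fs), lead)
        assert not np.any(out.samples)

    def test_no_stim_peak_with_matched_electrodes(self):
        x1, x3, s, orm = self._sources(seed=2)
        out = m.differential_stage(x1, x3, s, orm, m.LeadModel(Z1=900, Z3=900))
        p = np.abs(np.fft.rfft(out.samples)) ** 2
        f = np.fft.rfftfreq(len(out.samples), 1 / out.fs)
        i130 = np.argmin(np.abs(f - 130))
        nb = np.median(p[i130 - 60 : i130 + 60])
        assert p[i130 - 1 : i130 + 2].max() < 3 * nb

    def test_leaked_artifact_dominates_oscillation(self):
        # published settings: leaked stim RMS far above the oscillation RMS
        x1, x3, s, orm = self._sources(seed=3)
        lead = m.LeadModel(Z1=1000, Z3=2000)
        out = m.differential_stage(x1, x3, s, orm, lead)
        osc_rms = 2e-3 / np.sqrt(2)
        assert np.sqrt(np.mean(out.samples**2)) / osc_rms > 100

    def test_length_mismatch_raises(self):
        x1, x3, s, orm = self._sources()
        short = m.SourceSignal(x3.samples[:-1], x3.fs)
        with pytest.raises(ValueError):
            m.differential_stage(x1, short, s, orm, m.LeadModel())


class TestAmplifiers:
    def test_soft_clip_closed_form(self):
        amp = m.AmplifierConfig(model="soft_clip")
        assert m.soft_clip(np.array([0.0]), amp)[0] == 0.0
        assert m.soft_clip(np.array([0.5]), amp)[0] == pytest.approx(0.462117, abs=1e-6)
        assert m.soft_clip(np.array([1e6]), amp)[0] == pytest.approx(1.0)

    @given(v=st.floats(-50, 50), g1=st.floats(0.1, 5), g2=st.floats(0.1, 5))
    @settings(max_examples=50, deadline=None)
    def test_soft_clip_bounded_and_odd(self, v, g1, g2):
        amp = m.AmplifierConfig(model="soft_clip", g1=g1, g2=g2)
        y = m.soft_clip(np.array([v, -v]), amp)
        assert abs(y[0]) <= g2  # float64 tanh saturates to exactly 1
        assert y[0] == -y[1]

    def test_small_signal_equivalence(self):
        """Below 1% of the tanh scale the soft clip is linear to 0.01%."""
        rng = np.random.default_rng(0)
        v = rng.uniform(-0.01, 0.01, 1000)
        amp = m.AmplifierConfig(model="soft_clip")
        lin = m.linear_amp(v, amp)
        soft = m.soft_clip(v, amp)
        assert np.all(np.abs(soft - lin) <= 1e-4 * np.abs(lin) + 1e-15)

    def test_hard_clip_subthreshold_is_linear(self):
        amp = m.AmplifierConfig(model="hard_clip", clip_level=1.0)
        v = np.linspace(-0.99, 0.99, 101)
        assert np.allclose(m.hard_clip(v, amp), m.linear_amp(v, amp))

    def test_hard_clip_clamps(self):
        amp = m.AmplifierConfig(model="hard_clip", clip_level=1.0)
        assert m.hard_clip(np.array([2.0]), amp)[0] == 1.0

    def test_hard_clipped_sine_gains_odd_harmonics(self):
        fs, f0 = 4220, 130
        t = np.arange(0, 5, 1 / fs)
        v = 3.0 * np.sin(2 * np.pi * f0 * t)  # driven 3x past the clip level
        y = m.hard_clip(v, m.AmplifierConfig(model="hard_clip", clip_level=1.0))
        p = np.abs(np.fft.rfft(y)) ** 2
        f = np.fft.rfftfreq(len(y), 1 / fs)
        def level(k):
            return p[np.argmin(np.abs(f - k * f0))]
        floor = np.median(p)
        assert level(3) > 1e3 * floor and level(5) > 1e3 * floor
        assert level(2) < 10 * floor  # odd symmetry: no even harmonics


class TestAdc:
    def test_identity_at_factor_one(self):
        sig = m.SourceSignal(np.arange(100, dtype=float), 422.0)
        rec = m.adc_decimate(sig, m.ADCConfig(decimation=1))
        assert np.array_equal(rec.samples, sig.samples) and rec.fs == 422.0

    def test_published_grid_arithmetic(self):
        sig = m.SourceSignal(np.zeros(84_400), 4220.0)
        rec = m.adc_decimate(sig, m.ADCConfig(decimation=10))
        assert len(rec) == 8_440 and rec.fs == 422.0

    def test_tone_above_nyquist_folds(self):
        t = np.arange(0, 20, 1 / 4220)
        sig = m.SourceSignal(np.sin(2 * np.pi * 390 * t), 4220.0)
        rec = m.adc_decimate(sig, m.ADCConfig(decimation=10))
        p = np.abs(np.fft.rfft(rec.samples)) ** 2
        f = np.fft.rfftfreq(len(rec), 1 / rec.fs)
        assert abs(f[np.argmax(p)] - m.alias_frequency(390, 422)) <= f[1] - f[0]
        assert m.alias_frequency(390, 422) == 32.0

    def test_trailing_remainder_truncated(self):
        sig = m.SourceSignal(np.arange(105, dtype=float), 4220.0)
        rec = m.adc_decimate(sig, m.ADCConfig(decimation=10))
        assert len(rec) == 10 and rec.samples[-1] == 90.0

    def test_invalid_factor_raises(self):
        with pytest.raises(ConfigError):
            m.ADCConfig(decimation=0)


class TestSimulateRecording:
    def test_quiet_recording_census(self, quiet_sim):
        """No stimulation: only the oscillation and the marker stand out."""
        psd = m.welch_logpsd(quiet_sim)
        peaks = m.find_peaks(psd, [15.0, 105.5, 32.0, 64.0, 66.0])
        assert peaks[15.0].found and peaks[105.5].found
        assert not peaks[32.0].found and not peaks[64.0].found and not peaks[66.0].found

    def test_compression_census(self, default_sim, linear_sim):
        """Soft clip adds the 66 Hz intermodulation peak; the linear
        amplifier shows only the aliased shaping harmonics."""
        soft = m.find_peaks(m.welch_logpsd(default_sim), [32.0, 64.0, 66.0])
        lin = m.find_peaks(m.welch_logpsd(linear_sim), [32.0, 64.0, 66.0])
        assert all(soft[f].found for f in (32.0, 64.0, 66.0))
        assert lin[32.0].found and lin[64.0].found and not lin[66.0].found

    def test_meta_records_provenance(self, default_sim):
        meta = default_sim.meta
        assert meta["stim_amplitude"] == 6.0
        assert meta["amp_model"] == "soft_clip"
        assert meta["lead"]["Z3"] == 2000
        assert meta["seed"] == 1

    def test_zero_mismatch_stim_invariance(self):
        """With matched electrodes the during-stimulation recording is
        identical to the stimulation-free one."""
        lead = m.LeadModel(Z1=800, Z3=800)
        kw = dict(lead=lead, amp=m.AmplifierConfig(model="soft_clip"), adc=m.ADCConfig())
        on = m.simulate_recording(m.BrainConfig(seed=6), m.StimConfig(amplitude=8.0), **kw)
        off = m.simulate_recording(m.BrainConfig(seed=6), m.StimConfig(amplitude=0.0), **kw)
        assert np.array_equal(on.samples, off.samples)

    def test_imh_power_monotone_in_voltage(self, table_lead):
        prot = m.SweepProtocol(voltages=(2, 4, 6, 8), lead=table_lead,
                               amp=m.AmplifierConfig(model="soft_clip"))
        p66 = []
        for rec in m.run_sweep(prot):
            psd = m.welch_logpsd(rec)
            p66.append(psd.values[psd.nearest_bin(66.0)])
        assert np.all(np.diff(p66) > 0)
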