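import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import sosfreqz

from pupilsync.entrainment import (coherence_of_coefficients, compute_entrainment,
                                   drop_onset_window, epoch_phrases,
                                   highpass_zscore, phase_coherence,
                                   phrase_spectrum, _butter_highpass_sos)
from pupilsync.simulate import (PupilSimParams, TapSimParams,
                                simulate_paced_trial, simulate_pupil_trace)
from conftest import make_trace


def cue_grid(n=60, iti=500.0, start=1500.0):
    return start + iti * np.arange(n)


def trace_covering(cues, iti, fs=500.0, fill=0.0):
    n = int((cues[0] + len(cues) * iti + 1000.0) * fs / 1000.0)
    return make_trace(np.full(n, fill), sample_rate_hz=fs)


class TestDropOnsetWindow:
    def test_trim_starts_at_fifth_cue(self):
        cues = cue_grid()
        tr = trace_covering(cues, 500.0)
        out = drop_onset_window(tr, cues)
        assert out.timestamps_ms[0] >= cues[4]
        assert out.timestamps_ms[0] - cues[0] >= 2000.0

    def test_retained_span_is_56_intervals(self):
        cues = cue_grid()
        out = drop_onset_window(trace_covering(cues, 500.0), cues)
        assert out.duration_ms == pytest.approx(56 * 500.0, abs=2.0)

    def test_too_few_cues_rejected(self):
        cues = cue_grid(4)
        with pytest.raises(ValueError, match="at least 5"):
            drop_onset_window(trace_covering(cues, 500.0), cues)


class TestHighpassZscore:
    def test_constant_trace_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            highpass_zscore(make_trace(np.full(5000, 4000.0)))

    def test_passband_sine_preserved_and_unit_variance(self):
        fs = 50.0
        t = np.arange(int(200 * fs)) / fs
        x = np.sin(2 * np.pi * 1.0 * t)
        out = highpass_zscore(make_trace(4000.0 + 100.0 * x, sample_rate_hz=fs))
        assert np.std(out.pupil) == pytest.approx(1.0, rel=1e-9)
        c = slice(len(t) // 4, 3 * len(t) // 4)  # steady-state region
        r = np.corrcoef(out.pupil[c], x[c])[0, 1]
        assert r > 0.9999

    def test_drift_attenuated_per_filter_response(self):
        # closed-form oracle: forward-backward filtering applies |H(f)|^2;
        # compared in the steady-state (central) region of the trace
        fs = 50.0
        t = np.arange(int(400 * fs)) / fs
        slow = np.sin(2 * np.pi * 0.01 * t)
        fast = np.sin(2 * np.pi * 1.0 * t)
        out = highpass_zscore(make_trace(4000.0 + 100.0 * slow + 100.0 * fast,
                                         sample_rate_hz=fs))
        sos = _butter_highpass_sos(fs, 0.05, 3)
        w, h = sosfreqz(sos, worN=[0.01, 1.0], fs=fs)
        expected_ratio = np.abs(h[0]) ** 2 / np.abs(h[1]) ** 2
        c = slice(len(t) // 4, 3 * len(t) // 4)  # integer cycles of both
        amp = lambda f: 2 * np.abs(np.mean(
            out.pupil[c] * np.exp(-2j * np.pi * f * t[c])))
        assert amp(0.01) / amp(1.0) == pytest.approx(expected_ratio, rel=0.05)


class TestEpochPhrases:
    def prepared(self, n_cues, iti=500.0, fs=500.0, invalid_phrase=None):
        cues = cue_grid(n_cues, iti)
        rng = np.random.default_rng(0)
        tr = trace_covering(cues, iti, fs)
        tr.pupil = rng.normal(size=tr.n_samples)
        tr = drop_onset_window(tr, cues)
        if invalid_phrase is not None:
            n_len = int(round(4 * iti * fs / 1000.0))
            s = invalid_phrase * n_len
            tr.valid_mask[s:s + int(0.6 * n_len)] = False
        return tr, cues

    def test_sixty_cues_make_fourteen_phrases(self):
        tr, cues = self.prepared(60)
        ps = epoch_phrases(tr, cues)
        assert ps.n_phrases == 14
        assert int(ps.retained_mask.sum()) == 14

    def test_twenty_cues_make_four_phrases(self):
        tr, cues = self.prepared(20)
        assert epoch_phrases(tr, cues).n_phrases == 4

    def test_mostly_invalid_phrase_dropped(self):
        tr, cues = self.prepared(60, invalid_phrase=3)
        ps = epoch_phrases(tr, cues)
        assert ps.n_phrases == 14
        assert int(ps.retained_mask.sum()) == 13
        assert not ps.retained_mask[3]

    def test_phrase_length_spans_four_intervals(self):
        tr, cues = self.prepared(60, iti=692.34)
        ps = epoch_phrases(tr, cues)
        assert ps.phrase_len_samples == round(4 * 692.34 * 500.0 / 1000.0)


class TestPhraseSpectrum:
    def test_unit_sine_energy_at_bin_four(self):
        iti, fs = 500.0, 500.0
        n = int(round(4 * iti * fs / 1000.0))
        t = np.arange(n) / fs * 1000.0
        phrase = np.sin(2 * np.pi * t / iti)
        est = phrase_spectrum(phrase, iti, fs)
        # DFT closed form: |c_k| = N/2 for a unit sine on an exact bin
        assert abs(est.coefficients[0]) == pytest.approx(n / 2, rel=1e-9)
        assert abs(est.coefficients[1]) < 1e-8 * n

    def test_constant_phrase_has_zero_target_coefficient(self):
        iti, fs = 500.0, 500.0
        n = int(round(4 * iti * fs / 1000.0))
        est = phrase_spectrum(np.full(n, 3.3), iti, fs)
        assert abs(est.coefficients[0]) == pytest.approx(0.0, abs=1e-9)

    def test_target_bin_frequency_is_metronome_rate(self):
        iti, fs = 692.34, 500.0
        n = int(round(4 * iti * fs / 1000.0))
        est = phrase_spectrum(np.zeros(n), iti, fs)
        assert est.bin_freqs_hz[0] == pytest.approx(1000.0 / iti, rel=1e-3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            phrase_spectrum(np.zeros(100), 500.0, 500.0)


class TestPhaseCoherence:
    def test_identical_phasors_give_unity(self):
        pc, _, n = coherence_of_coefficients([1 + 1j] * 14)
        assert pc == pytest.approx(1.0)
        assert n == 14

    def test_antipodal_phasors_cancel(self):
        pc, _, _ = coherence_of_coefficients([1 + 0j, -1 + 0j])
        assert pc == pytest.approx(0.0, abs=1e-12)

    def test_zero_coefficients_dropped(self):
        pc, _, n = coherence_of_coefficients([0j, 1 + 0j, 1 + 0j])
        assert n == 2 and pc == pytest.approx(1.0)

    @given(st.lists(st.floats(-np.pi, np.pi), min_size=2, max_size=20),
           st.floats(0.1, 100.0))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_bounded_and_amplitude_blind(self, angles, scale):
        c = np.exp(1j * np.array(angles))
        pc1, _, _ = coherence_of_coefficients(c)
        pc2, _, _ = coherence_of_coefficients(scale * c)
        assert 0.0 <= pc1 <= 1.0 + 1e-12
        assert pc1 == pytest.approx(pc2, abs=1e-12)


class TestEndToEnd:
    def sim(self, kappa, seed, iti=500.0, noise=0.0, n_cues=60, fs=500.0):
        trial = simulate_paced_trial(TapSimParams(async_sd_ms=0, p_miss=0),
                                     iti, n_cues,
                                     rng=np.random.default_rng(seed))
        pp = PupilSimParams(phase_kappa=kappa, noise_sd_au=noise,
                            blink_rate_hz=0.0, drift_amp_au=0.0,
                            evoked_amp_au=0.0)
        tr, _ = simulate_pupil_trace(pp, trial,
                                     trial.cue_onsets_ms[-1] + iti + 1000.0,
                                     fs, rng=np.random.default_rng(seed + 1))
        return compute_entrainment(tr, trial.cue_onsets_ms, iti)

    def test_locked_oscillation_recovered(self):
        res = self.sim(np.inf, seed=1)
        assert res.phase_coherence > 0.99
        assert res.n_phrases_used == 14

    def test_uniform_phases_near_null_mean(self):
        pcs = [self.sim(0.0, seed=s, n_cues=20, fs=100.0).phase_coherence
               for s in range(60)]
        # null mean for 4 phrases ~ sqrt(pi)/(2 sqrt(4))
        assert np.mean(pcs) == pytest.approx(np.sqrt(np.pi) / 4, abs=0.08)

    def test_comparable_across_tempi(self):
        # equal phase concentration -> mean coherence matches across tempi
        means = []
        for iti in (553.9, 692.3, 830.8):
            pcs = [self.sim(3.0, seed=s, iti=iti, noise=5.0, n_cues=20,
                            fs=100.0).phase_coherence for s in range(25)]
            means.append(np.mean(pcs))
        assert max(means) - min(means) < 0.05

    def test_coherence_increases_with_snr(self):
        # median coherence non-decreasing as oscillation amplitude grows
        meds = []
        for amp in (2.0, 10.0, 40.0):
            pcs = []
            for s in range(20):
                trial = simulate_paced_trial(
                    TapSimParams(async_sd_ms=0, p_miss=0), 500.0, 20,
                    rng=np.random.default_rng(s))
                pp = PupilSimParams(phase_kappa=np.inf, osc_amp_au=amp,
                                    noise_sd_au=20.0, blink_rate_hz=0.0,
                                    drift_amp_au=0.0, evoked_amp_au=0.0)
                tr, _ = simulate_pupil_trace(
                    pp, trial, trial.cue_onsets_ms[-1] + 1500.0, 100.0,
                    rng=np.random.default_rng(1000 + s))
                pcs.append(compute_entrainment(
                    tr, trial.cue_onsets_ms, 500.0).phase_coherence)
            meds.append(np.median(pcs))
        assert meds[0] <= meds[1] + 1e-9 <= meds[2] + 2e-9
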