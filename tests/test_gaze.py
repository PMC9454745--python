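"""Sinusoid fitting, quick-phase detection and gain/phase estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gazelab as gl
from gazelab.gaze import wrap_phase

from conftest import make_recording, match_events


def _grid_search_fit(signal, frequency, time):
    """Brute-force oracle: scan (amplitude, phase, offset) on a fine grid,
    refined in two passes.  Independent of the normal-equations path."""
    best = None
    a_grid = np.linspace(0, 2 * np.max(np.abs(signal)) + 1e-9, 41)
    p_grid = np.linspace(-180, 180, 73)
    c_grid = np.linspace(signal.min(), signal.max() + 1e-9, 21)
    for _ in range(3):
        for a in a_grid:
            for p in p_grid:
                model_ap = a * np.sin(2 * np.pi * frequency * time
                                      + np.deg2rad(p))
                for c in c_grid:
                    sse = np.sum((signal - model_ap - c) ** 2)
                    if best is None or sse < best[0]:
                        best = (sse, a, p, c)
        _, a0, p0, c0 = best
        a_grid = np.linspace(max(0, a0 * 0.9), a0 * 1.1 + 1e-9, 21)
        p_grid = np.linspace(p0 - 10, p0 + 10, 41)
        c_grid = np.linspace(c0 - 1, c0 + 1, 21)
    return best[1], best[2], best[3]


class TestFitSinusoid:
    def test_exact_model_recovered(self):
        t = np.arange(2000) / 1000.0
        s = np.sin(2 * np.pi * 2.0 * t)
        amp, ph, off = gl.fit_sinusoid(s, 2.0, 1000.0)
        assert amp == pytest.approx(1.0, abs=1e-9)
        assert ph == pytest.approx(0.0, abs=1e-9)
        assert off == pytest.approx(0.0, abs=1e-9)

    def test_null_signal(self):
        s = np.zeros(2000)
        amp, ph, off = gl.fit_sinusoid(s, 2.0, 1000.0)
        assert amp == pytest.approx(0.0, abs=1e-12)
        assert off == pytest.approx(0.0, abs=1e-12)

    def test_matches_grid_search_oracle(self):
        t = np.arange(2000) / 100.0   # 20 s at 100 Hz keeps the oracle fast
        s = 12.8 * np.sin(2 * np.pi * 1.0 * t + np.deg2rad(30.0)) + 5.0
        amp, ph, off = gl.fit_sinusoid(s, 1.0, 100.0)
        assert amp == pytest.approx(12.8, abs=1e-6)
        assert ph == pytest.approx(30.0, abs=1e-6)
        assert off == pytest.approx(5.0, abs=1e-6)
        ga, gp, gc = _grid_search_fit(s, 1.0, t)
        assert amp == pytest.approx(ga, abs=0.05)
        assert ph == pytest.approx(gp, abs=0.5)
        assert off == pytest.approx(gc, abs=0.1)

    def test_equals_fourier_projection_on_integer_cycles(self):
        rng = np.random.default_rng(0)
        sr, f, n = 1000.0, 2.0, 10000   # exactly 20 cycles
        t = np.arange(n) / sr
        s = 3.2 * np.sin(2 * np.pi * f * t + 1.1) + 0.5 + rng.normal(0, 1, n)
        amp, ph, _ = gl.fit_sinusoid(s, f, sr)
        a = 2 / n * np.sum(s * np.sin(2 * np.pi * f * t))
        b = 2 / n * np.sum(s * np.cos(2 * np.pi * f * t))
        assert amp == pytest.approx(np.hypot(a, b), abs=1e-8)
        assert np.deg2rad(ph) == pytest.approx(np.arctan2(b, a), abs=1e-8)

    def test_too_few_unmasked_samples(self):
        s = np.sin(2 * np.pi * 2.0 * np.arange(2000) / 1000.0)
        mask = np.ones(2000, bool)
        mask[:5] = False
        with pytest.raises(gl.DegenerateInputError):
            gl.fit_sinusoid(s, 2.0, 1000.0, mask=mask)

    def test_invalid_frequency(self):
        with pytest.raises(gl.ValidationError):
            gl.fit_sinusoid(np.zeros(100), -1.0, 1000.0)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(offset=st.floats(-50, 50))
    def test_amplitude_invariant_to_offset(self, offset):
        t = np.arange(4000) / 1000.0
        s = 7.0 * np.sin(2 * np.pi * 1.0 * t + 0.4)
        amp0, ph0, _ = gl.fit_sinusoid(s, 1.0, 1000.0)
        amp1, ph1, off1 = gl.fit_sinusoid(s + offset, 1.0, 1000.0)
        assert amp1 == pytest.approx(amp0, abs=1e-9)
        assert ph1 == pytest.approx(ph0, abs=1e-9)
        assert off1 == pytest.approx(offset, abs=1e-9)


class TestDetectQuickPhases:
    def test_pure_sinusoid_yields_no_events(self):
        rec, _ = make_recording(gain=0.8)
        events, mask = gl.detect_quick_phases(rec)
        assert events == []
        assert not mask.any()

    def test_injected_pulses_detected_without_spurious(self):
        rec, truth = make_recording(gain=0.6, noise_sd=2.0, qp_rate=1.5,
                                    seed=21, duration=60.0)
        events, _ = gl.detect_quick_phases(rec)
        inj = truth["quick_phases"]
        assert len(inj) >= 20
        matched, spurious = match_events(events, inj)
        assert matched >= len(inj) - 1
        assert spurious == 0

    def test_detected_amplitudes_match_injected(self):
        rec, truth = make_recording(gain=0.6, noise_sd=2.0, qp_rate=1.5,
                                    seed=22, duration=60.0)
        events, _ = gl.detect_quick_phases(rec)
        inj = truth["quick_phases"]
        rel_errs = []
        for d in events:
            best = min(inj, key=lambda q: abs(q["onset"] - d.onset))
            rel_errs.append(abs(abs(d.amplitude) - abs(best["amplitude"]))
                            / abs(best["amplitude"]))
        assert np.median(rel_errs) < 0.10

    def test_saccade_dominated_trace_raises(self):
        rec, _ = make_recording(gain=0.1, noise_sd=0.0)
        # dense 40 ms / 200 °/s pulses: after margin dilation the mask
        # would cover > 80% of the trace
        pulse = (rec.time % 0.12) < 0.04
        rec.eye_vel = rec.eye_vel + 200.0 * pulse
        with pytest.raises(gl.DegenerateInputError, match="dominated|mis-set"):
            gl.detect_quick_phases(rec)


class TestEstimateGainPhase:
    def test_ideal_vor(self):
        rec, _ = make_recording(gain=1.0)
        fit = gl.estimate_gain_phase(rec)
        assert fit.gain == pytest.approx(1.0, abs=1e-12)
        assert fit.phase == pytest.approx(0.0, abs=1e-9)
        assert fit.vaf == pytest.approx(1.0, abs=1e-12)

    def test_absent_response_gives_zero_gain(self):
        rec, _ = make_recording(gain=0.0, noise_sd=1.0, seed=2)
        fit = gl.estimate_gain_phase(rec, desaccade=False)
        assert fit.gain == pytest.approx(0.0, abs=0.02)

    def test_parameter_recovery_with_noise_and_quick_phases(self):
        rec, _ = make_recording(gain=0.46, phase=5.0, noise_sd=2.0,
                                qp_rate=1.5, seed=23, duration=60.0)
        fit = gl.estimate_gain_phase(rec)
        assert fit.gain == pytest.approx(0.46, abs=0.02)
        assert fit.phase == pytest.approx(5.0, abs=2.0)

    def test_gain_invariant_to_eye_offset(self):
        rec, _ = make_recording(gain=0.7, noise_sd=1.0, seed=3)
        fit0 = gl.estimate_gain_phase(rec, desaccade=False)
        rec.eye_vel = rec.eye_vel + 4.2
        fit1 = gl.estimate_gain_phase(rec, desaccade=False)
        assert fit1.gain == pytest.approx(fit0.gain, abs=1e-9)

    def test_negating_eye_shifts_phase_180(self):
        rec, _ = make_recording(gain=0.7, phase=20.0)
        fit0 = gl.estimate_gain_phase(rec, desaccade=False)
        rec.eye_vel = -rec.eye_vel
        fit1 = gl.estimate_gain_phase(rec, desaccade=False)
        assert wrap_phase(fit1.phase - fit0.phase) == pytest.approx(
            180.0, abs=1e-9)

    def test_okr_following_convention(self):
        rec, _ = make_recording(gain=0.5, phase=-10.0, condition="OKR",
                                following=True)
        fit = gl.estimate_gain_phase(rec, desaccade=False)
        assert fit.gain == pytest.approx(0.5, abs=1e-10)
        assert fit.phase == pytest.approx(-10.0, abs=1e-9)

    def test_stimulus_absent_error(self):
        rec, _ = make_recording(gain=0.5)
        rec.head_vel = rec.head_vel * 0.0
        with pytest.raises(gl.DegenerateInputError, match="stimulus"):
            gl.estimate_gain_phase(rec)

    def test_desaccading_reduces_gain_bias(self):
        # with resetting quick phases the raw fit is biased; masking helps
        bias_raw, bias_desac = [], []
        for seed in range(5):
            rec, _ = make_recording(gain=0.6, noise_sd=2.0, qp_rate=1.5,
                                    seed=40 + seed, duration=60.0)
            raw = gl.estimate_gain_phase(rec, desaccade=False)
            des = gl.estimate_gain_phase(rec, desaccade=True)
            bias_raw.append(abs(raw.gain - 0.6))
            bias_desac.append(abs(des.gain - 0.6))
        assert np.mean(bias_desac) < np.mean(bias_raw)

    def test_variance_grows_with_noise_and_shrinks_with_duration(self):
        def gain_sd(noise_sd, duration):
            gains = [gl.estimate_gain_phase(
                make_recording(gain=0.6, noise_sd=noise_sd, seed=s,
                               duration=duration)[0],
                desaccade=False).gain for s in range(12)]
            return np.std(gains)

        assert gain_sd(4.0, 20.0) > gain_sd(0.5, 20.0)
        assert gain_sd(4.0, 80.0) < gain_sd(4.0, 20.0)

    def test_per_cycle_mode_agrees_on_clean_trace(self):
        rec, _ = make_recording(gain=0.7, phase=3.0, noise_sd=0.5, seed=6)
        whole = gl.estimate_gain_phase(rec, desaccade=False)
        cyc = gl.estimate_gain_phase(rec, desaccade=False, per_cycle=True)
        assert cyc.gain == pytest.approx(whole.gain, abs=0.02)
        assert cyc.phase == pytest.approx(whole.phase, abs=2.0)


class TestFrequencyResponse:
    def test_long_table_and_summary(self, small_cohort):
        out, _ = small_cohort
        from gazelab.io import read_manifest
        manifest = read_manifest(out / "manifest.json")
        table, summary = gl.frequency_response(out, manifest)
        # 6 animals x 3 conditions x 2 frequencies
        assert len(table) == 36
        sub = summary[(summary.genotype == "WT")
                      & (summary.condition == "VORd")
                      & (summary.frequency_hz == 2.0)]
        assert sub.iloc[0]["mean_gain"] == pytest.approx(0.80, abs=0.02)
        assert int(sub.iloc[0]["n"]) == 3

    def test_group_means_recover_truth(self, small_cohort):
        out, _ = small_cohort
        from gazelab.io import read_manifest
        manifest = read_manifest(out / "manifest.json")
        _, summary = gl.frequency_response(out, manifest)
        sca = summary[(summary.genotype == "SCA6")
                      & (summary.condition == "VORd")
                      & (summary.frequency_hz == 2.0)]
        assert sca.iloc[0]["mean_gain"] == pytest.approx(0.576, abs=0.02)

    def test_duplicate_manifest_entries_raise(self, small_cohort):
        out, _ = small_cohort
        from gazelab.io import read_manifest
        manifest = read_manifest(out / "manifest.json")
        gaze_entries = [e for e in manifest if e["condition"] == "VORd"]
        with pytest.raises(gl.ValidationError, match="duplicate"):
            gl.frequency_response(out, gaze_entries + gaze_entries[:1])

    def test_identical_recordings_have_zero_sem(self, tmp_path):
        from gazelab.io import write_trace_csv
        rec, _ = make_recording(gain=0.8, duration=5.0)
        manifest = []
        for i in range(3):
            fname = f"a{i}.csv"
            write_trace_csv(tmp_path / fname, rec)
            manifest.append(dict(file=fname, animal_id=f"a{i}",
                                 genotype="WT", condition="VORd",
                                 frequency_hz=2.0))
        _, summary = gl.frequency_response(tmp_path, manifest)
        assert summary.iloc[0]["sem_gain"] == pytest.approx(0.0, abs=1e-12)
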