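import numpy as np
import pytest

import fastripple as fr
from fastripple.detection import (
    screen_candidates,
    confirm_by_cwt,
    extract_parameters,
    associate_sharp_wave,
    line_noise_amplitude,
    FR_BAND,
)
from fastripple.io import EventWindow, Recording

FS = 5000.0


def _recording_with(extra, seed=9, duration=4.0, region="CA1"):
    """Default background plus an arbitrary additive component on one channel."""
    rec, _ = fr.generate_recording(fr.SynthConfig(duration_s=duration, seed=seed))
    data = rec.data.copy()
    data[rec.index_of(region)] += extra(rec.times)
    return Recording(data, fs=rec.fs)


class TestScreen:
    def test_mains_contamination_rejected(self):
        rec = _recording_with(lambda t: 20.0 * np.sin(2 * np.pi * 60.0 * t))
        w = EventWindow(region="CA1", center_index=int(2.0 * FS))
        report = screen_candidates(rec, [w])
        assert report.dispositions == ["rejected_line_noise"]

    def test_movement_artifact_rejected(self):
        step = lambda t: 200.0 * (t > 2.0) * (t < 2.1)
        rec = _recording_with(step)
        w = EventWindow(region="CA1", center_index=int(2.05 * FS))
        report = screen_candidates(rec, [w])
        assert report.dispositions == ["rejected_amplitude"]

    def test_clean_synthetic_event_accepted(self, single_event_recording):
        rec, gt = single_event_recording
        w = EventWindow(region="CA1", center_index=int(gt.events[0].t_center * rec.fs))
        report = screen_candidates(rec, [w])
        assert report.dispositions == ["accepted"]

    def test_amplitude_boundary_is_exact(self):
        """A window at exactly 150 µV peak-to-peak is retained; above is not."""
        t = np.arange(int(2 * FS)) / FS
        tone = np.sin(2 * np.pi * 350.0 * t)
        for amp, expected in ((75.0, "accepted"), (75.5, "rejected_amplitude")):
            data = np.zeros((3, len(t)))
            data[2] = amp * tone  # peak-to-peak = 2*amp exactly
            rec = Recording(data, fs=FS)
            w = EventWindow(region="CA1", center_index=len(t) // 2)
            assert screen_candidates(rec, [w]).dispositions == [expected]

    def test_empty_candidate_list(self, noise_recording):
        rec, _ = noise_recording
        assert screen_candidates(rec, []).dispositions == []

    def test_line_noise_measure_recovers_amplitude(self):
        t = np.arange(int(0.4 * FS)) / FS
        x = 20.0 * np.sin(2 * np.pi * 60.0 * t)
        assert line_noise_amplitude(x, FS) == pytest.approx(20.0, rel=0.05)


class TestCwtConfirmation:
    def test_synthetic_burst_confirmed_and_localized(self, single_event_recording):
        rec, gt = single_event_recording
        ev = gt.events[0]
        w = EventWindow(region="CA1", center_index=int(ev.t_center * rec.fs))
        ok, info = confirm_by_cwt(rec, w)
        assert ok
        assert abs(info["peak_time_s"] - ev.t_center) <= ev.duration_ms / 2000.0

    def test_broadband_transient_not_confirmed(self):
        def delta(t):
            out = np.zeros_like(t)
            k = int(2.0 * FS)
            out[k] = 120.0
            out[k + 1] = -100.0
            return out

        rec = _recording_with(delta)
        w = EventWindow(region="CA1", center_index=int(2.0 * FS))
        ok, info = confirm_by_cwt(rec, w)
        assert not ok
        assert not info["band_delimited"]

    def test_pure_noise_not_confirmed(self, noise_recording):
        rec, _ = noise_recording
        w = EventWindow(region="CA1", center_index=int(4.0 * rec.fs))
        ok, _ = confirm_by_cwt(rec, w)
        assert not ok

    def test_short_window_raises(self, noise_recording):
        rec, _ = noise_recording
        w = EventWindow(region="CA1", center_index=int(4.0 * rec.fs), pre_ms=2, post_ms=2)
        with pytest.raises(ValueError, match="cycles"):
            confirm_by_cwt(rec, w)


class TestParameterExtraction:
    def test_injected_event_parameters_recovered(self, single_event_recording):
        rec, gt = single_event_recording
        ev = gt.events[0]
        w = EventWindow(region="CA1", center_index=int(ev.t_center * rec.fs))
        out = extract_parameters(rec, w)
        assert out.power_frequency == pytest.approx(ev.carrier_freq, abs=10)
        assert out.amplitude_pp == pytest.approx(ev.amplitude_pp, rel=0.15)
        assert out.duration_ms == pytest.approx(ev.duration_ms, rel=0.25)

    def test_pure_sinusoid_closed_form(self):
        t = np.arange(int(2 * FS)) / FS
        data = np.zeros((3, len(t)))
        data[2] = 30.0 * np.sin(2 * np.pi * 300.0 * t)
        rec = Recording(data, fs=FS)
        w = EventWindow(region="CA1", center_index=len(t) // 2)
        out = extract_parameters(rec, w)
        assert out.amplitude_pp == pytest.approx(60.0, rel=0.02)
        assert out.power_frequency == pytest.approx(300.0, abs=5)
        assert out.mean_frequency == pytest.approx(300.0, abs=5)

    def test_two_tone_mean_frequency_between_tones(self):
        t = np.arange(int(2 * FS)) / FS
        data = np.zeros((3, len(t)))
        data[2] = 30.0 * (
            np.sin(2 * np.pi * 280.0 * t) + np.sin(2 * np.pi * 380.0 * t)
        )
        rec = Recording(data, fs=FS)
        w = EventWindow(region="CA1", center_index=len(t) // 2)
        out = extract_parameters(rec, w)
        assert 285 < out.mean_frequency < 375
        assert out.mean_frequency == pytest.approx(330.0, abs=15)


class TestSharpWaveAssociation:
    def _event_at(self, rec, t_center):
        return fr.FREvent(
            region="CA1", center_time=t_center, amplitude_pp=60, power_frequency=350,
            power=1.0, duration_ms=200, mean_frequency=350,
        )

    def test_long_deflection_associated(self, single_event_recording):
        rec, gt = single_event_recording
        ev = self._event_at(rec, gt.events[0].t_center)
        out = associate_sharp_wave(rec, ev)
        assert out.sharp_wave_associated
        assert out.sharp_wave_duration_ms == pytest.approx(150.0, rel=0.35)

    def test_short_deflection_not_associated(self):
        cfg = fr.SynthConfig(
            duration_s=4.0,
            event_specs=[
                fr.FREventSpec(
                    region="CA1", t_center=2.0, sharp_wave=True,
                    sharp_wave_duration_ms=50.0,
                )
            ],
            seed=5,
        )
        rec, gt = fr.generate_recording(cfg)
        out = associate_sharp_wave(rec, self._event_at(rec, 2.0))
        assert not out.sharp_wave_associated

    def test_no_slow_component_not_associated(self):
        cfg = fr.SynthConfig(
            duration_s=4.0,
            event_specs=[fr.FREventSpec(region="CA1", t_center=2.0, sharp_wave=False)],
            seed=5,
        )
        rec, _ = fr.generate_recording(cfg)
        out = associate_sharp_wave(rec, self._event_at(rec, 2.0))
        assert not out.sharp_wave_associated


class TestEndToEndDetection:
    def test_detected_events_stay_in_band(self, single_event_recording):
        rec, _ = single_event_recording
        events, _ = fr.detect_events(rec, "CA1")
        assert events
        for ev in events:
            assert FR_BAND[0] <= ev.power_frequency <= FR_BAND[1]
            assert ev.amplitude_pp <= 150.0
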