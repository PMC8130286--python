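import numpy as np
import pytest

import fastripple as fr
from fastripple.io import Recording
from fastripple.mua import MUAHistogram
from fastripple.synthetic import _spike_waveform

FS = 5000.0


class TestSpikeDetection:
    def test_known_transients_recovered(self):
        """Ten clean transients at known times, each found within 1 ms."""
        rng = np.random.default_rng(0)
        n = int(4 * FS)
        data = rng.normal(0, 1.0, (3, n))
        truth = np.arange(0.3, 3.3, 0.3)
        wf = _spike_waveform(FS, 40.0)
        half = len(wf) // 2
        for t0 in truth:
            k = int(t0 * FS)
            data[2, k - half : k - half + len(wf)] += wf
        rec = Recording(data, fs=FS)
        train = fr.detect_spikes(rec, "CA1")
        for t0 in truth:
            assert np.min(np.abs(train.times - t0)) < 1e-3
        # a high-passed biphasic transient rings, so each true spike may
        # produce a few threshold peaks beyond the 1-ms refractory
        assert len(train.times) <= len(truth) * 4

    def test_flat_signal_raises(self):
        rec = Recording(np.zeros((3, int(2 * FS))), fs=FS)
        with pytest.raises(ValueError, match="flat"):
            fr.detect_spikes(rec, "CA1")

    def test_noise_crossing_rate_matches_level_crossing_theory(self):
        """Threshold crossings of the z-scored filtered noise follow the
        analytic level-crossing rate of the sampled Gaussian process.

        For a sampled stationary Gaussian signal the expected rate of
        upward crossings of level u is fs · P(z_t < u, z_{t+1} > u), a
        bivariate-normal orthant probability in the lag-1 autocorrelation
        (the continuous-time Rice rate is its ρ→1 limit).
        """
        from scipy.stats import multivariate_normal, norm
        from fastripple.io import zero_phase_highpass

        rng = np.random.default_rng(1)
        n = int(20 * FS)
        rec = Recording(rng.normal(0, 5.0, (3, n)), fs=FS)

        hp = zero_phase_highpass(rec.channel("CA1"), 300.0, FS)
        z = np.abs((hp - hp.mean()) / hp.std())
        crossings = np.sum((z[1:] >= 2.0) & (z[:-1] < 2.0))
        measured_rate = crossings / (n / FS)

        xc = hp - hp.mean()
        rho1 = float(np.dot(xc[:-1], xc[1:]) / np.dot(xc, xc))
        bvn = multivariate_normal(mean=[0, 0], cov=[[1, rho1], [rho1, 1]])
        p_cross = norm.cdf(2.0) - bvn.cdf([2.0, 2.0])
        expected = 2.0 * FS * p_cross  # z upcrosses +2 or downcrosses -2
        assert measured_rate == pytest.approx(expected, rel=0.25)

        # the refractory-merged spike count can only be lower, but must
        # remain a sizable fraction of the raw excursion count
        train = fr.detect_spikes(rec, "CA1")
        merged_rate = len(train.times) / (n / FS)
        assert 0.2 * measured_rate <= merged_rate <= measured_rate


class TestEventLockedHistogram:
    def test_single_spike_probability_by_hand(self):
        train = fr.SpikeTrain(region="CA1", times=np.array([0.81]))
        h = fr.event_locked_histogram(train, np.array([1.0]), (0.0, 2.0))
        assert h.probability[0] == pytest.approx(1.0 / (1 * 0.020))
        assert np.all(h.probability[1:] == 0)

    def test_four_spikes_two_events_by_hand(self):
        times = np.array([0.81, 0.815, 2.81, 2.815])
        h = fr.event_locked_histogram(
            fr.SpikeTrain(region="CA1", times=times), np.array([1.0, 3.0]), (0.0, 4.0)
        )
        assert h.probability[0] == pytest.approx(4.0 / (2 * 0.020))

    def test_conservation_is_exact(self, spiking_cohort):
        rec, gt = spiking_cohort
        centers = np.array([e.t_center for e in gt.events])
        train = fr.SpikeTrain(region="CA3", times=gt.spike_times["CA3"])
        h = fr.event_locked_histogram(train, centers, (0.0, rec.duration))
        counted = sum(
            np.sum((train.times >= t - 0.2) & (train.times < t + 0.2)) for t in centers
        )
        assert h.total_spikes == pytest.approx(counted, abs=1e-9)

    def test_event_outside_span_skipped_with_warning(self):
        train = fr.SpikeTrain(region="CA1", times=np.array([0.5]))
        with pytest.warns(UserWarning, match="skipped"):
            h = fr.event_locked_histogram(train, np.array([0.1, 1.0]), (0.0, 2.0))
        assert h.n_observations == 1

    def test_no_events_raises(self):
        train = fr.SpikeTrain(region="CA1", times=np.array([0.5]))
        with pytest.raises(ValueError):
            fr.event_locked_histogram(train, np.array([]), (0.0, 2.0))


def _hist(probability):
    edges = np.arange(-200.0, 201.0, 20.0)
    return MUAHistogram(
        region="x", bin_edges_ms=edges, probability=np.asarray(probability, float),
        n_observations=1,
    )


class TestCumulativeDominance:
    def test_identical_histograms_show_none(self):
        p = np.ones(20)
        assert fr.cumulative_dominance(_hist(p), _hist(p)) == {"pre": "none", "post": "none"}

    def test_mass_first_bin_dominates_pre_mass_last_bin_dominates_post(self):
        h1 = _hist([1.0] + [0.0] * 19)
        h2 = _hist([0.0] * 19 + [1.0])
        out = fr.cumulative_dominance(h1, h2)
        assert out["pre"] == "h1"
        assert out["post"] == "h2"

    def test_mismatched_binning_raises(self):
        h1 = _hist(np.ones(20))
        h2 = MUAHistogram(
            region="y", bin_edges_ms=np.arange(-100.0, 101.0, 20.0),
            probability=np.ones(10), n_observations=1,
        )
        with pytest.raises(ValueError, match="binning"):
            fr.cumulative_dominance(h1, h2)

    def test_ca3_leads_pre_ca1_persists_post(self, spiking_cohort):
        rec, gt = spiking_cohort
        centers = np.array([e.t_center for e in gt.events])
        span = (0.0, rec.duration)
        h = {
            r: fr.event_locked_histogram(
                fr.SpikeTrain(region=r, times=gt.spike_times[r]), centers, span
            )
            for r in ("CA3", "CA1")
        }
        out = fr.cumulative_dominance(h["CA3"], h["CA1"])
        assert out == {"pre": "h1", "post": "h2"}
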