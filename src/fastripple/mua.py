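"""Multiunit activity: spike extraction and event-locked probabilities.

Multiunit activity (MUA) is unsorted spiking from neurons near an
electrode.  Spikes are separated from the LFP by > 300 Hz zero-phase
high-pass filtering, z-scoring the trace and marking local extrema whose
|z| reaches 2 (two-sided, because extracellular spikes are biphasic), with
a 1-ms refractory interval to avoid double-counting multi-sample
crossings.

Event-locked analysis takes 400-ms windows centered on each fast ripple's
maximum peak-to-peak sample, counts spikes in 20-ms bins, and converts the
counts to probabilities as count / (n_observations × bin_width).  The
cumulative distributions are compared for first-order stochastic dominance
before and after the event center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import Recording, zero_phase_highpass

SPIKE_THRESHOLD_Z = 2.0
REFRACTORY_MS = 1.0
WINDOW_MS = 400.0
BIN_MS = 20.0


@dataclass
class SpikeTrain:
    region: str
    times: np.ndarray  # seconds, strictly increasing
    threshold_z: float = SPIKE_THRESHOLD_Z


@dataclass
class MUAHistogram:
    region: str
    bin_edges_ms: np.ndarray  # relative to event center, 21 edges for 20 bins
    probability: np.ndarray  # per bin, spikes / (n_obs * bin_width_s)
    n_observations: int

    @property
    def bin_width_s(self) -> float:
        return (self.bin_edges_ms[1] - self.bin_edges_ms[0]) / 1000.0

    @property
    def total_spikes(self) -> float:
        return float(np.sum(self.probability) * self.bin_width_s * self.n_observations)

    def normalized_cumulative(self) -> np.ndarray:
        c = np.cumsum(self.probability)
        return c / c[-1] if c[-1] > 0 else c


def detect_spikes(
    rec: Recording,
    region: str,
    exclude_windows: list[tuple[float, float]] | None = None,
    threshold_z: float = SPIKE_THRESHOLD_Z,
) -> SpikeTrain:
    """Threshold-crossing spike extraction from the > 300 Hz trace.

    The z-normalization baseline excludes ``exclude_windows`` (event spans,
    in seconds) so event-driven variance does not inflate the threshold.
    """
    fs = rec.fs
    if rec.n_samples < fs:
        raise ValueError("recording shorter than 1 s: z-normalization unstable")
    hp = zero_phase_highpass(rec.channel(region), 300.0, fs)
    mask = np.ones(rec.n_samples, dtype=bool)
    for a, b in exclude_windows or []:
        mask[int(a * fs) : int(b * fs)] = False
    base = hp[mask] if mask.any() else hp
    sd = np.std(base)
    if sd == 0:
        raise ValueError("flat signal: cannot z-normalize")
    z = (hp - np.mean(base)) / sd
    dist = max(1, int(round(REFRACTORY_MS * fs / 1000.0)))
    peaks, _ = sps.find_peaks(np.abs(z), height=threshold_z, distance=dist)
    return SpikeTrain(region=region, times=peaks / fs + rec.start_time, threshold_z=threshold_z)


def event_locked_histogram(
    spikes: SpikeTrain,
    event_times: np.ndarray,
    recording_span: tuple[float, float],
    window_ms: float = WINDOW_MS,
    bin_ms: float = BIN_MS,
) -> MUAHistogram:
    """Spike probability in 20-ms bins over 400-ms event-centered windows.

    Events whose window exceeds the recording span are skipped (with the
    observation count adjusted).  The conservation identity
    Σ prob · bin_width · n_obs = total counted spikes holds exactly.
    """
    event_times = np.asarray(event_times, dtype=float)
    if event_times.size == 0:
        raise ValueError("need at least one event")
    half = window_ms / 2000.0
    lo_span, hi_span = recording_span
    usable = [t for t in event_times if t - half >= lo_span and t + half <= hi_span]
    n_skipped = len(event_times) - len(usable)
    if n_skipped:
        import warnings

        warnings.warn(f"{n_skipped} event window(s) outside recording span skipped")
    if not usable:
        raise ValueError("no usable event windows inside the recording span")

    edges_ms = np.arange(-window_ms / 2, window_ms / 2 + bin_ms / 2, bin_ms)
    counts = np.zeros(len(edges_ms) - 1)
    for t0 in usable:
        rel = (spikes.times - t0) * 1000.0
        sel = rel[(rel >= edges_ms[0]) & (rel < edges_ms[-1])]
        counts += np.histogram(sel, bins=edges_ms)[0]
    n_obs = len(usable)
    prob = counts / (n_obs * (bin_ms / 1000.0))
    return MUAHistogram(
        region=spikes.region, bin_edges_ms=edges_ms, probability=prob, n_observations=n_obs
    )


def cumulative_dominance(
    h1: MUAHistogram, h2: MUAHistogram, tol: float = 0.05
) -> dict[str, str]:
    """First-order stochastic dominance of normalized cumulative curves.

    Each histogram is normalized to unit total mass; on each side of the
    event center the accumulated mass is measured from that side's first
    bin.  The region that accumulates faster there (curve above) dominates
    that side: a region leading the event dominates the pre side, a region
    whose firing persists past the center dominates the post side.
    Reported per side as ``'h1'``, ``'h2'``, ``'none'`` or ``'crossing'``.
    ``tol`` (in units of normalized cumulative mass) absorbs counting noise
    in sparsely filled bins.
    """
    if not np.array_equal(h1.bin_edges_ms, h2.bin_edges_ms):
        raise ValueError("histograms have mismatched binning")
    c1, c2 = h1.normalized_cumulative(), h2.normalized_cumulative()
    centers = (h1.bin_edges_ms[:-1] + h1.bin_edges_ms[1:]) / 2.0
    out = {}
    for side, mask in (("pre", centers < 0), ("post", centers > 0)):
        a1, a2 = c1[mask], c2[mask]
        if side == "post" and np.any(~mask & (centers < 0)):
            last_pre = np.flatnonzero(centers < 0)[-1]
            a1 = a1 - c1[last_pre]
            a2 = a2 - c2[last_pre]
        d = a1 - a2
        if np.all(np.abs(d) <= tol):
            out[side] = "none"
        elif np.all(d >= -tol):
            out[side] = "h1"
        elif np.all(d <= tol):
            out[side] = "h2"
        else:
            out[side] = "crossing"
    return out
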