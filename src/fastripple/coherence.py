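"""Morlet CWT and pairwise wavelet coherence around fast-ripple events.

Wavelet coherence is the time-localized, frequency-resolved analogue of
magnitude-squared coherence, bounded in [0, 1].  Without smoothing it is
identically 1, so the cross- and auto-spectra are smoothed in time with a
boxcar whose length scales with the wavelet period at each frequency.

A 400-ms readout window centered on each event is split at the center
sample into 200-ms pre and post halves whose mean coherences are compared
pairwise (Wilcoxon signed-rank across events).  Because 400 ms covers
fewer than 3 theta cycles, the transform runs on a longer context window
(default 2 s centered on the event) and only the central 400 ms is read
out; the short window is the readout, not the computation, support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import stats
from scipy.ndimage import uniform_filter1d

from .detection import MORLET

THETA_BAND = (4.0, 7.0)
#: alternative theta band matching some figure conventions
THETA_BAND_WIDE = (3.0, 7.0)
GAMMA_BAND = (30.0, 90.0)
MIN_EVENTS_FOR_TEST = 6


@dataclass
class CoherenceResult:
    """Band-averaged coherence time course on one event's readout window."""

    pair: tuple[str, str]
    band: tuple[float, float]
    times: np.ndarray  # seconds relative to event center
    coherence: np.ndarray  # in [0, 1]
    mean_pre: float  # first 200 ms
    mean_post: float  # last 200 ms


def cwt_complex(x: np.ndarray, fs: float, freqs: np.ndarray) -> np.ndarray:
    scales = pywt.frequency2scale(MORLET, freqs / fs)
    coef, _ = pywt.cwt(
        np.asarray(x, float), scales, MORLET, sampling_period=1.0 / fs, method="fft"
    )
    return coef


def cwt_power(
    x: np.ndarray, fs: float, fmin: float, fmax: float, n_freqs: int = 40,
    normalize: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Morlet scalogram over [fmin, fmax]; optionally peak-normalized."""
    if fmax >= fs / 2:
        raise ValueError(f"band edge {fmax} Hz at/above Nyquist {fs / 2} Hz")
    n_cycles_min = len(x) / fs * fmin
    if n_cycles_min < 3:
        raise ValueError(
            f"signal holds {n_cycles_min:.1f} cycles at {fmin} Hz; need >= 3"
        )
    freqs = np.linspace(fmin, fmax, n_freqs)
    power = np.abs(cwt_complex(x, fs, freqs)) ** 2
    if normalize and power.max() > 0:
        power = power / power.max()
    return freqs, power


def wavelet_coherence(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    band: tuple[float, float],
    n_freqs: int = 12,
    smoothing_cycles: float = 4.0,
) -> np.ndarray:
    """Smoothed magnitude-squared wavelet coherence, averaged over the band.

    |⟨Wx·Wy*⟩|² / (⟨|Wx|²⟩·⟨|Wy|²⟩) with time smoothing over
    ``smoothing_cycles`` wavelet periods per frequency.  Symmetric in its
    arguments and invariant to per-channel amplitude scaling.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    if len(x) / fs * band[0] < 3:
        raise ValueError(
            f"signal covers fewer than 3 cycles at {band[0]} Hz; "
            "compute on a longer context window"
        )
    freqs = np.linspace(band[0], band[1], n_freqs)
    wx = cwt_complex(x, fs, freqs)
    wy = cwt_complex(y, fs, freqs)
    coh = np.empty((len(freqs), len(x)))
    for i, f in enumerate(freqs):
        win = max(5, int(round(smoothing_cycles * fs / f)))
        cross = wx[i] * np.conj(wy[i])
        sxy = uniform_filter1d(cross.real, win, mode="nearest") + 1j * uniform_filter1d(
            cross.imag, win, mode="nearest"
        )
        sxx = uniform_filter1d(np.abs(wx[i]) ** 2, win, mode="nearest")
        syy = uniform_filter1d(np.abs(wy[i]) ** 2, win, mode="nearest")
        coh[i] = np.abs(sxy) ** 2 / np.clip(sxx * syy, 1e-300, None)
    return np.clip(coh.mean(axis=0), 0.0, 1.0)


def event_coherence(
    rec,
    pair: tuple[str, str],
    center_time: float,
    band: tuple[float, float],
    readout_ms: float = 400.0,
    context_s: float = 2.0,
) -> CoherenceResult:
    """Coherence on the 400-ms readout around one event center.

    The transform is computed on ``context_s`` seconds centered on the
    event (clipped to the recording) and the central ``readout_ms`` is
    read out, split exactly at the center sample into pre/post means.
    """
    fs = rec.fs
    ci = int(round((center_time - rec.start_time) * fs))
    half_ctx = int(round(context_s * fs / 2))
    lo = max(ci - half_ctx, 0)
    hi = min(ci + half_ctx, rec.n_samples)
    half_read = int(round(readout_ms * fs / 2000.0))
    if ci - half_read < lo or ci + half_read > hi:
        raise ValueError("event too close to the recording edge for the readout")
    x = rec.channel(pair[0])[lo:hi]
    y = rec.channel(pair[1])[lo:hi]
    coh = wavelet_coherence(x, y, fs, band)
    a, c, b = ci - half_read - lo, ci - lo, ci + half_read - lo
    readout = coh[a:b]
    times = (np.arange(a, b) - c) / fs
    return CoherenceResult(
        pair=pair,
        band=band,
        times=times,
        coherence=readout,
        mean_pre=float(np.mean(coh[a:c])),
        mean_post=float(np.mean(coh[c:b])),
    )


def pre_post_comparison(results: list[CoherenceResult]) -> dict:
    """Paired Wilcoxon signed-rank test on (mean_pre − mean_post).

    Requires at least 6 events (the minimum for a two-sided exact test at
    α = 0.05); fewer events yield an ``insufficient n`` report instead of
    a p-value.
    """
    n = len(results)
    diffs = np.array([r.mean_pre - r.mean_post for r in results])
    report = {
        "n": n,
        "mean_pre": float(np.mean([r.mean_pre for r in results])) if n else np.nan,
        "mean_post": float(np.mean([r.mean_post for r in results])) if n else np.nan,
    }
    if n < MIN_EVENTS_FOR_TEST:
        report["status"] = "insufficient n"
        report["p_value"] = None
        return report
    report["status"] = "ok"
    if np.all(diffs == 0):
        report["p_value"] = 1.0
    else:
        report["p_value"] = float(stats.wilcoxon(diffs).pvalue)
    return report
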