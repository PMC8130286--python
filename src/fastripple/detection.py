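"""Fast-ripple detection: candidate screening, CWT confirmation, parameters.

A fast ripple (FR) is a pathological high-frequency oscillation in the
250–600 Hz band.  The workflow mirrors the classical offline procedure:

1. candidate windows are proposed automatically (band-limited envelope
   exceeding a rolling baseline) or supplied externally;
2. a screen rejects windows with mains contamination (60-Hz component
   amplitude > 15 µV) or movement artifacts (raw peak-to-peak > 150 µV);
3. a continuous Morlet wavelet transform bound to 250–600 Hz, normalized to
   its highest power, confirms that the spectral content is band-delimited
   and temporally co-localized with the candidate;
4. five parameters are extracted from the zero-phase band-filtered segment:
   peak-to-peak amplitude, power frequency (highest PSD peak), power (PSD
   at the power frequency, µV²/Hz), duration (envelope full width at half
   prominence) and PSD-weighted mean frequency;
5. a concurrent slow (< 30 Hz) deflection lasting > 70 ms marks the event
   as sharp-wave associated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps

from .io import Recording, EventWindow, zero_phase_bandpass, zero_phase_lowpass

FR_BAND = (250.0, 600.0)
LINE_FREQ = 60.0
LINE_NOISE_MAX_UV = 15.0
AMPLITUDE_MAX_UV = 150.0
SHARP_WAVE_MIN_MS = 70.0


@dataclass
class FREvent:
    """One confirmed fast ripple and its five scalar parameters."""

    region: str
    center_time: float
    amplitude_pp: float
    power_frequency: float
    power: float
    duration_ms: float
    mean_frequency: float
    sharp_wave_associated: bool = False
    sharp_wave_duration_ms: float | None = None
    event_id: int | None = None


@dataclass
class ScreenReport:
    """Per-candidate dispositions, order-preserving and mutually exclusive."""

    dispositions: list  # 'accepted' | 'rejected_line_noise' | 'rejected_amplitude'

    @property
    def accepted(self) -> list[int]:
        return [i for i, d in enumerate(self.dispositions) if d == "accepted"]


# ---------------------------------------------------------------------------
# Candidate proposal
# ---------------------------------------------------------------------------


def propose_candidates(
    rec: Recording,
    region: str,
    threshold_sd: float = 3.0,
    min_duration_ms: float = 6.0,
    baseline_window_s: float = 1.0,
    pre_ms: float = 200.0,
    post_ms: float = 200.0,
) -> list[EventWindow]:
    """Automated candidate screen standing in for visual inspection.

    Proposes a window wherever the 250–600 Hz envelope exceeds the rolling
    baseline mean + ``threshold_sd``·SD for at least ``min_duration_ms``.
    Externally supplied candidate tables can be used instead.
    """
    fs = rec.fs
    x = rec.channel(region)
    band = zero_phase_bandpass(x, *FR_BAND, fs)
    env = _smooth_envelope(band, fs)
    # rolling baseline on a robustly clipped envelope, so the events being
    # sought do not inflate their own detection threshold
    med = np.median(env)
    mad = np.median(np.abs(env - med))
    clipped = np.minimum(env, med + 3.0 * 1.4826 * mad)
    w = int(round(baseline_window_s * fs)) | 1
    kern = np.ones(w) / w
    mu = sps.fftconvolve(clipped, kern, mode="same")
    var = sps.fftconvolve(clipped**2, kern, mode="same") - mu**2
    sd = np.sqrt(np.clip(var, 0.0, None))
    above = env > mu + threshold_sd * sd

    min_len = int(round(min_duration_ms * fs / 1000.0))
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    stops = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(len(above))

    # bridge brief dips: a rising envelope can cross the threshold in short
    # bursts before the sustained excursion
    merge_gap = int(round(0.1 * fs))
    runs: list[list[int]] = []
    for a, b in zip(starts, stops):
        if runs and a - runs[-1][1] < merge_gap:
            runs[-1][1] = b
        else:
            runs.append([a, b])

    pre = int(round(pre_ms * fs / 1000.0))
    post = int(round(post_ms * fs / 1000.0))
    proposals: list[tuple[int, float]] = []
    for a, b in runs:
        if b - a < min_len:
            continue
        center = a + _max_pp_index(band[a:b])
        if center - pre < 0 or center + post > rec.n_samples:
            continue
        proposals.append((int(center), float(env[center])))

    # among proposals closer than half a window, keep the strongest
    proposals.sort()
    kept: list[tuple[int, float]] = []
    for c, e in proposals:
        if kept and c - kept[-1][0] < (pre + post) / 2:
            if e > kept[-1][1]:
                kept[-1] = (c, e)
        else:
            kept.append((c, e))
    return [
        EventWindow(region=region, center_index=c, pre_ms=pre_ms, post_ms=post_ms)
        for c, _ in kept
    ]


def _smooth_envelope(band: np.ndarray, fs: float, smooth_ms: float = 10.0) -> np.ndarray:
    """Hilbert envelope with a short moving average removing carrier ripple."""
    from scipy.ndimage import uniform_filter1d

    env = np.abs(sps.hilbert(band))
    w = max(3, int(round(smooth_ms * fs / 1000.0)) | 1)
    return uniform_filter1d(env, w, mode="nearest")


def _max_pp_index(band_seg: np.ndarray) -> int:
    """Sample index of the maximum peak-to-peak excursion of a band signal.

    Peak-to-peak is taken between consecutive extrema of the oscillation;
    the returned index is the larger-magnitude sample of the winning pair.
    """
    if len(band_seg) < 3:
        return int(np.argmax(np.abs(band_seg)))
    d = np.diff(band_seg)
    ext = np.flatnonzero(d[:-1] * d[1:] < 0) + 1
    if len(ext) < 2:
        return int(np.argmax(np.abs(band_seg)))
    vals = band_seg[ext]
    pp = np.abs(np.diff(vals))
    k = int(np.argmax(pp))
    pair = ext[k], ext[k + 1]
    return int(pair[0] if abs(band_seg[pair[0]]) >= abs(band_seg[pair[1]]) else pair[1])


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------


def line_noise_amplitude(x: np.ndarray, fs: float, line_freq: float = LINE_FREQ) -> float:
    """Amplitude (µV) of the mains Fourier component: 2·|X_k|/N at ~60 Hz."""
    n = len(x)
    spec = np.fft.rfft(x * np.hanning(n))
    # Hann window halves the main-lobe amplitude; compensate by 2/sum(w)
    wsum = np.hanning(n).sum()
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    k = int(np.argmin(np.abs(freqs - line_freq)))
    return 2.0 * np.abs(spec[k]) / wsum


def screen_candidates(rec: Recording, candidates: list[EventWindow]) -> ScreenReport:
    """Reject mains-contaminated or artifact-amplitude candidate windows.

    A window is rejected when its 60-Hz component exceeds 15 µV or its raw
    peak-to-peak amplitude strictly exceeds 150 µV; a window at exactly
    150 µV is retained.
    """
    dispositions = []
    for w in candidates:
        seg = rec.channel(w.region)[w.slice_for(rec)]
        if line_noise_amplitude(seg, rec.fs) > LINE_NOISE_MAX_UV:
            dispositions.append("rejected_line_noise")
        elif np.ptp(seg) > AMPLITUDE_MAX_UV:
            dispositions.append("rejected_amplitude")
        else:
            dispositions.append("accepted")
    return ScreenReport(dispositions)


# ---------------------------------------------------------------------------
# CWT confirmation
# ---------------------------------------------------------------------------

#: complex Morlet with the conventional center-frequency parameter 6
#: (pywt parametrization: bandwidth 2.0, center frequency 6/(2π) cycles)
MORLET = "cmor2.0-0.9549296585513721"


def morlet_power(
    x: np.ndarray, fs: float, fmin: float, fmax: float, n_freqs: int = 40,
    normalize: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Morlet scalogram over [fmin, fmax]; returns (freqs, power[f, t])."""
    if fmax >= fs / 2:
        raise ValueError(f"fmax {fmax} at/above Nyquist {fs / 2}")
    freqs = np.linspace(fmin, fmax, n_freqs)
    scales = pywt.frequency2scale(MORLET, freqs / fs)
    coef, _ = pywt.cwt(x, scales, MORLET, sampling_period=1.0 / fs)
    power = np.abs(coef) ** 2
    if normalize and power.max() > 0:
        power = power / power.max()
    return freqs, power


def confirm_by_cwt(
    rec: Recording,
    window: EventWindow,
    localization_ratio: float = 4.0,
    context_ms: float = 200.0,
) -> tuple[bool, dict]:
    """Confirm a candidate via its normalized Morlet scalogram.

    Confirmed iff (i) the 250–600 Hz wavelet power peaks inside the
    candidate window and stands out against the window median (temporal
    localization), and (ii) the high-frequency power is band-delimited:
    within >100 Hz content, the 250–600 Hz band holds the majority, which
    excludes broadband (delta-like) transients.  Returns the flag plus the
    time–frequency localization of the band power peak.
    """
    fs = rec.fs
    min_len = int(np.ceil(3.0 * fs / FR_BAND[0]))
    sl = window.slice_for(rec)
    if sl.stop - sl.start < min_len:
        raise ValueError(
            f"window of {sl.stop - sl.start} samples shorter than 3 cycles at {FR_BAND[0]} Hz"
        )
    ctx = int(round(context_ms * fs / 1000.0))
    lo = max(sl.start - ctx, 0)
    hi = min(sl.stop + ctx, rec.n_samples)
    x = rec.channel(window.region)[lo:hi]

    freqs, power = morlet_power(x, fs, FR_BAND[0], FR_BAND[1], normalize=True)
    band_tc = power.mean(axis=0)
    t_peak = int(np.argmax(band_tc))
    f_peak = float(freqs[np.argmax(power[:, t_peak])])
    in_window = sl.start - lo <= t_peak < sl.stop - lo
    localized = band_tc[t_peak] >= localization_ratio * np.median(band_tc)

    # band delimitation: power above 200 Hz must concentrate in the FR band,
    # which a broadband (delta-like) transient or plain 1/f noise cannot do
    seg = rec.channel(window.region)[sl]
    f, pxx = sps.periodogram(seg, fs=fs, window="hann")
    hf = f >= 200.0
    in_band = hf & (f >= FR_BAND[0]) & (f <= FR_BAND[1])
    out_band = hf & ~in_band
    band_delimited = pxx[in_band].sum() > pxx[out_band].sum()

    confirmed = bool(in_window and localized and band_delimited)
    info = {
        "peak_time_s": (lo + t_peak) / fs,
        "peak_freq_hz": f_peak,
        "localized": bool(localized),
        "band_delimited": bool(band_delimited),
    }
    return confirmed, info


# ---------------------------------------------------------------------------
# Parameter extraction
# ---------------------------------------------------------------------------


def extract_parameters(rec: Recording, window: EventWindow) -> FREvent:
    """Compute the five FR parameters on the band-filtered segment.

    The segment is 250–600 Hz zero-phase filtered (with surrounding context
    so the FIR never sees a too-short signal); the center is the sample of
    maximum peak-to-peak excursion; duration is the full width at half
    prominence of the Hilbert envelope; the PSD (Hann periodogram over the
    event duration) gives the power frequency, power and mean frequency.
    """
    fs = rec.fs
    band = zero_phase_bandpass(rec.channel(window.region), *FR_BAND, fs)
    sl = window.slice_for(rec)
    seg = band[sl]

    center_rel = _max_pp_index(seg)
    center = sl.start + center_rel
    env_full = _smooth_envelope(band, fs)
    env = env_full[sl]
    # baseline from the whole trace: long events can fill the window,
    # biasing a window-local median upward
    baseline = float(np.median(env_full))
    peak = float(env[center_rel])
    if peak < baseline * 0.95:
        raise ValueError("envelope never rises above baseline: not a valid event")
    if peak - baseline < 0.05 * baseline:
        # a sustained oscillation has a flat envelope: the event fills the
        # whole window and the half-prominence width is undefined
        a, b = 0, len(env) - 1
    else:
        thresh = baseline + 0.5 * (peak - baseline)
        above = env >= thresh
        a = center_rel
        while a > 0 and above[a - 1]:
            a -= 1
        b = center_rel
        while b < len(above) - 1 and above[b + 1]:
            b += 1
    duration_ms = (b - a + 1) / fs * 1000.0

    # the PSD needs at least ~3 cycles at the band floor for in-band bins
    min_seg = int(np.ceil(3.0 * fs / FR_BAND[0]))
    if b - a + 1 < min_seg:
        pad = (min_seg - (b - a + 1) + 1) // 2
        a = max(a - pad, 0)
        b = min(b + pad, len(seg) - 1)
    ev_seg = seg[a : b + 1]
    amplitude_pp = float(np.ptp(ev_seg))
    f, pxx = sps.periodogram(ev_seg, fs=fs, window="hann")
    in_band = (f >= FR_BAND[0]) & (f <= FR_BAND[1])
    fb, pb = f[in_band], pxx[in_band]
    k = int(np.argmax(pb))
    power_frequency = float(fb[k])
    power = float(pb[k])
    mean_frequency = float(np.sum(fb * pb) / np.sum(pb))

    return FREvent(
        region=window.region,
        center_time=center / fs + rec.start_time,
        amplitude_pp=amplitude_pp,
        power_frequency=power_frequency,
        power=power,
        duration_ms=duration_ms,
        mean_frequency=mean_frequency,
    )


def associate_sharp_wave(
    rec: Recording,
    event: FREvent,
    context_ms: float = 300.0,
    min_duration_ms: float = SHARP_WAVE_MIN_MS,
) -> FREvent:
    """Flag the event when a concurrent slow deflection lasts > 70 ms.

    The < 30 Hz low-passed trace around the event is searched for its peak
    excursion; the putative sharp-wave duration is the width of the
    contiguous region around that peak above 25 % of the peak excursion.
    The deflection must also stand out from the slow-band background
    (> 3 robust SDs), since smooth background rhythms are trivially
    wider than 70 ms at a quarter of their own height.
    """
    fs = rec.fs
    slow = zero_phase_lowpass(rec.channel(event.region), 30.0, fs)
    ci = int(round((event.center_time - rec.start_time) * fs))
    ctx = int(round(context_ms * fs / 1000.0))
    lo, hi = max(ci - ctx, 0), min(ci + ctx, rec.n_samples)
    med = np.median(slow)
    robust_sd = 1.4826 * np.median(np.abs(slow - med))
    seg = slow[lo:hi] - med
    exc = np.abs(seg)
    p = int(np.argmax(exc))
    peak = exc[p]
    if peak <= 0 or peak < 3.0 * robust_sd:
        event.sharp_wave_associated = False
        event.sharp_wave_duration_ms = None
        return event
    thresh = 0.25 * peak
    a = p
    while a > 0 and exc[a - 1] >= thresh:
        a -= 1
    b = p
    while b < len(exc) - 1 and exc[b + 1] >= thresh:
        b += 1
    dur_ms = (b - a + 1) / fs * 1000.0
    # the deflection must actually overlap the event center
    overlaps = (lo + a) <= ci <= (lo + b)
    if overlaps and dur_ms > min_duration_ms:
        event.sharp_wave_associated = True
        event.sharp_wave_duration_ms = float(dur_ms)
    else:
        event.sharp_wave_associated = False
        event.sharp_wave_duration_ms = None
    return event


# ---------------------------------------------------------------------------
# Full detection pass
# ---------------------------------------------------------------------------


def detect_events(
    rec: Recording,
    region: str,
    candidates: list[EventWindow] | None = None,
    **propose_kw,
) -> tuple[list[FREvent], ScreenReport]:
    """Propose (or take) candidates, screen, confirm and parametrize.

    Returns the confirmed events (with sharp-wave association) and the
    screen report for the candidate set.
    """
    if candidates is None:
        candidates = propose_candidates(rec, region, **propose_kw)
    report = screen_candidates(rec, candidates)
    events: list[FREvent] = []
    for i in report.accepted:
        w = candidates[i]
        try:
            ok, _ = confirm_by_cwt(rec, w)
        except ValueError:
            continue
        if not ok:
            continue
        try:
            ev = extract_parameters(rec, w)
        except ValueError:
            continue
        if not FR_BAND[0] <= ev.power_frequency <= FR_BAND[1]:
            continue
        events.append(associate_sharp_wave(rec, ev))
    for j, ev in enumerate(events):
        ev.event_id = j
    return events, report
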