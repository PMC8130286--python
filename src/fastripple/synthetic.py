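"""Synthetic multichannel hippocampal LFP with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, so every downstream stage has a known-answer test bed:

* 1/f ("pink") background noise — matches the broadband LFP spectrum and
  makes detection nontrivial;
* theta (4–7 Hz) oscillations with controllable inter-channel coherence,
  implemented by mixing a shared theta source into each channel with a
  time-varying weight (raised in the 200 ms before each event by default);
* gamma (30–90 Hz) band-limited activity, independent per channel;
* fast-ripple bursts: Gaussian-windowed sinusoids with carrier in
  250–600 Hz; ``duration_ms`` is the full width at half maximum of the
  envelope;
* sharp waves: slow (< 30 Hz) deflections time-locked to a burst, whose
  width at 25 % of peak excursion equals the requested duration;
* multiunit spikes: millisecond-scale biphasic transients drawn from an
  inhomogeneous Poisson process whose rate rises around events, earlier in
  CA3 than in CA1 by default;
* directed inter-channel coupling realized as a vector-autoregressive (VAR)
  component whose adjacency can switch in the 200-ms windows before and
  after each event, planting known Granger-causal structure.

All amplitudes are µV, times are seconds, and a fixed seed reproduces the
signal arrays bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import Recording, DEFAULT_REGIONS


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass
class FREventSpec:
    """Ground-truth description of one injected fast-ripple burst."""

    region: str
    t_center: float
    duration_ms: float = 200.0
    carrier_freq: float = 350.0
    amplitude_pp: float = 60.0
    sharp_wave: bool = False
    sharp_wave_duration_ms: float = 150.0
    sharp_wave_amplitude: float = 40.0

    def __post_init__(self) -> None:
        if not 250.0 <= self.carrier_freq <= 600.0:
            raise ValueError(f"carrier_freq {self.carrier_freq} outside 250–600 Hz")
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")


@dataclass
class ThetaCoherenceSchedule:
    """Shared-source mixing weights controlling pairwise theta coherence.

    ``baseline`` and ``pre_event`` are mixing levels in [0, 1]; the level is
    raised to ``pre_event`` during the ``pre_window_s`` seconds before each
    event center.  Magnitude-squared coherence between two channels is
    approximately the product of their levels.

    The default window spans the ~3 theta cycles preceding the event: at
    4–7 Hz a coherence estimator cannot resolve changes much faster than
    its cycle-scaled smoothing support, so a shorter synchronization
    burst would be invisible to any honest estimator.
    """

    baseline: float = 0.05
    pre_event: float = 0.95
    pre_window_s: float = 0.8

    def __post_init__(self) -> None:
        for v in (self.baseline, self.pre_event):
            if not 0.0 <= v <= 1.0:
                raise ValueError("coherence levels must lie in [0, 1]")


@dataclass
class VarCoupling:
    """Directed coupling between channels as a switching VAR process.

    ``baseline``, ``pre`` and ``post`` are lists of lag matrices (one
    ``(n, n)`` array per lag, entry [i, j] = weight of channel j's past on
    channel i); ``pre``/``post`` apply in the 200-ms analysis windows
    adjacent to each event's extent (a small ``window_margin_s`` covers
    transition transients).  ``scale`` sets the µV amplitude of the
    component added to the recording.

    The innovations feeding the recursion are colored with a smooth
    low-pass profile (``innovation_cutoff_hz``, roll-off order
    ``innovation_rolloff``) rather than the output being filtered: the
    recursion stays strictly causal, so the planted directed structure is
    preserved exactly, while the component still keeps out of the
    250–600 Hz detection band.  ``innovation_cutoff_hz=None`` uses white
    innovations.
    """

    baseline: list | None = None
    pre: list | None = None
    post: list | None = None
    window_s: float = 0.2
    window_margin_s: float = 0.02
    scale: float = 10.0
    innovation_cutoff_hz: float | None = 180.0
    innovation_rolloff: int = 6
    innovation_highpass_hz: float | None = None

    def regime_matrices(self, n: int) -> dict[str, np.ndarray]:
        out = {}
        for name in ("baseline", "pre", "post"):
            mats = getattr(self, name)
            if mats is None:
                mats = out.get("baseline")
                if mats is None:
                    mats = np.zeros((1, n, n))
            else:
                mats = np.asarray(mats, dtype=float)
                if mats.ndim == 2 and mats.shape == (n, n):
                    mats = mats[None]
                elif mats.ndim == 3 and mats.shape[1:] == (n, n):
                    pass
                else:
                    raise ValueError(f"{name} adjacency must be (lags, {n}, {n})")
            out[name] = np.asarray(mats, dtype=float)
        return out


@dataclass
class SpikeSchedule:
    """Inhomogeneous Poisson firing-rate profile around events (Hz).

    ``event_offset_ms`` places each region's rate bump relative to the event
    center; the default makes CA3 fire ~40 ms before CA1.
    """

    baseline_hz: float = 2.0
    event_peak_hz: float = 120.0
    event_width_ms: float = 40.0
    event_offset_ms: dict = field(
        default_factory=lambda: {"DG": -20.0, "CA3": -40.0, "CA1": 0.0}
    )
    amplitude: float = 25.0


@dataclass
class SynthConfig:
    """Full description of one synthetic recording."""

    duration_s: float = 10.0
    fs: float = 5000.0
    regions: tuple[str, ...] = DEFAULT_REGIONS
    noise_scale: float = 5.0
    theta_band: tuple[float, float] = (4.0, 7.0)
    theta_amplitude: float = 5.0
    theta_coherence_schedule: ThetaCoherenceSchedule = field(
        default_factory=ThetaCoherenceSchedule
    )
    gamma_band: tuple[float, float] = (30.0, 90.0)
    gamma_amplitude: float = 2.5
    var_coupling: VarCoupling = field(default_factory=VarCoupling)
    event_specs: list = field(default_factory=list)
    spike_schedule: SpikeSchedule | None = None
    seed: int = 0


@dataclass
class GroundTruth:
    """Everything the generator injected, for known-answer tests."""

    events: list
    coupling_edges: dict  # epoch -> list of (cause, effect) labels
    spike_times: dict  # region -> np.ndarray of seconds

    def to_json(self, path: str | Path) -> None:
        obj = {
            "events": [asdict(e) for e in self.events],
            "coupling_edges": self.coupling_edges,
            "spike_times": {r: list(map(float, t)) for r, t in self.spike_times.items()},
        }
        Path(path).write_text(json.dumps(obj, indent=1))


# ---------------------------------------------------------------------------
# Component builders
# ---------------------------------------------------------------------------


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # avoid div-by-zero; DC handled below
    spec = spec / np.sqrt(f)
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    return x / np.std(x)


def _band_noise(n: int, fs: float, band: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise confined to ``band`` by spectral masking."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec[(f < band[0]) | (f > band[1])] = 0.0
    x = np.fft.irfft(spec, n)
    sd = np.std(x)
    if sd == 0:
        return x
    return x / sd


def _fr_burst(t: np.ndarray, spec: FREventSpec) -> np.ndarray:
    """Gaussian-windowed sinusoid; envelope FWHM = duration, pp = amplitude."""
    sigma = spec.duration_ms / 1000.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    env = np.exp(-((t - spec.t_center) ** 2) / (2.0 * sigma**2))
    return (spec.amplitude_pp / 2.0) * env * np.sin(
        2.0 * np.pi * spec.carrier_freq * (t - spec.t_center)
    )


def _sharp_wave(t: np.ndarray, spec: FREventSpec) -> np.ndarray:
    """Negative slow deflection; width at 25 % of peak = requested duration."""
    width_s = spec.sharp_wave_duration_ms / 1000.0
    sigma = width_s / (2.0 * np.sqrt(2.0 * np.log(4.0)))
    main = -spec.sharp_wave_amplitude * np.exp(
        -((t - spec.t_center) ** 2) / (2.0 * sigma**2)
    )
    # small positive rebound makes the deflection biphasic without widening
    # the 25 %-height main lobe
    rebound = 0.15 * spec.sharp_wave_amplitude * np.exp(
        -((t - spec.t_center - 2.5 * sigma) ** 2) / (2.0 * sigma**2)
    )
    return main + rebound


def _spike_waveform(fs: float, amplitude: float) -> np.ndarray:
    """Biphasic ~1-ms transient (derivative of a Gaussian)."""
    sigma = 0.25e-3
    tt = np.arange(-4 * sigma, 4 * sigma, 1.0 / fs)
    w = -tt * np.exp(-(tt**2) / (2 * sigma**2))
    return amplitude * w / np.max(np.abs(w))


def _companion_spectral_radius(mats: np.ndarray) -> float:
    p, n, _ = mats.shape
    comp = np.zeros((n * p, n * p))
    comp[:n] = np.concatenate(list(mats), axis=1)
    if p > 1:
        comp[n:, : n * (p - 1)] = np.eye(n * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def _check_stable(mats: np.ndarray, name: str) -> None:
    rho = _companion_spectral_radius(mats)
    if rho >= 1.0:
        raise ValueError(
            f"{name} VAR adjacency is unstable (companion spectral radius "
            f"{rho:.3f} >= 1); reduce the coupling weights"
        )


def _colored_innovations(
    shape: tuple, rng: np.random.Generator, fs: float, cutoff_hz: float, rolloff: int,
    highpass_hz: float | None = None,
) -> np.ndarray:
    """Unit-variance noise with a smooth band-limited spectral profile."""
    eps = rng.standard_normal(shape)
    n = shape[-1]
    f = np.fft.rfftfreq(n, 1.0 / fs)
    gain = 1.0 / np.sqrt(1.0 + (f / cutoff_hz) ** (2 * rolloff))
    if highpass_hz is not None:
        with np.errstate(divide="ignore"):
            gain = gain / np.sqrt(1.0 + (highpass_hz / np.maximum(f, 1e-9)) ** 8)
    spec = np.fft.rfft(eps, axis=-1) * gain
    x = np.fft.irfft(spec, n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def simulate_var(
    mats: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
    n_series: int = 1,
    regime_index: np.ndarray | None = None,
    regime_mats: list[np.ndarray] | None = None,
    burn_in: int = 200,
    fs: float | None = None,
    innovation_cutoff_hz: float | None = None,
    innovation_rolloff: int = 6,
    innovation_highpass_hz: float | None = None,
) -> np.ndarray:
    """Simulate a (possibly regime-switching) VAR process.

    Returns an array of shape ``(n_series, n_channels, n_samples)`` with
    unit-variance innovations, optionally low-pass colored (the recursion
    itself stays causal, so directed structure is exact).  When
    ``regime_index``/``regime_mats`` are given, ``mats`` is ignored and
    the lag matrices switch per sample.
    """
    if regime_mats is not None:
        all_mats = regime_mats
        p = max(m.shape[0] for m in all_mats)
        n = all_mats[0].shape[1]
        padded = []
        for m in all_mats:
            q = np.zeros((p, n, n))
            q[: m.shape[0]] = m
            padded.append(q)
        stack = np.array(padded)  # (n_regimes, p, n, n)
        idx = np.concatenate([np.zeros(burn_in, dtype=int), regime_index])
        # equalize the stationary channel variance across regimes, so a
        # coupling switch changes the cross-structure but not the power
        inn_scale = np.array(
            [1.0 / np.sqrt(_stationary_mean_variance(m)) for m in padded]
        )
    else:
        mats = np.asarray(mats, dtype=float)
        p, n, _ = mats.shape
        stack = mats[None]
        idx = np.zeros(burn_in + n_samples, dtype=int)
        inn_scale = np.ones(1)

    total = burn_in + n_samples
    x = np.zeros((n_series, n, total))
    if innovation_cutoff_hz is not None:
        if fs is None:
            raise ValueError("fs required for colored innovations")
        eps = _colored_innovations(
            (n_series, n, total), rng, fs, innovation_cutoff_hz, innovation_rolloff,
            highpass_hz=innovation_highpass_hz,
        )
    else:
        eps = rng.standard_normal((n_series, n, total))
    x[..., :p] = eps[..., :p]
    for t in range(p, total):
        A = stack[idx[t]]
        acc = inn_scale[idx[t]] * eps[..., t]
        for k in range(p):
            acc += x[..., t - 1 - k] @ A[k].T
        x[..., t] = acc
    return x[..., burn_in:]


def _stationary_mean_variance(mats: np.ndarray) -> float:
    """Mean channel variance of the stationary VAR with unit innovations."""
    p, n, _ = mats.shape
    m = n * p
    comp = np.zeros((m, m))
    comp[:n] = np.concatenate(list(mats), axis=1)
    if p > 1:
        comp[n:, : n * (p - 1)] = np.eye(n * (p - 1))
    q = np.zeros((m, m))
    q[:n, :n] = np.eye(n)
    vec = np.linalg.solve(np.eye(m * m) - np.kron(comp, comp), q.ravel())
    sigma = vec.reshape(m, m)
    return float(np.mean(np.diag(sigma)[:n]))


# ---------------------------------------------------------------------------
# Main entry points
# ---------------------------------------------------------------------------


def generate_recording(config: SynthConfig) -> tuple[Recording, GroundTruth]:
    """Render all configured components into one multichannel recording.

    Returns the summed Recording (µV) and a GroundTruth listing every
    injected event, coupling edge and spike time.  Identical seeds give
    bit-identical arrays.
    """
    fs = config.fs
    n = int(round(config.duration_s * fs))
    n_ch = len(config.regions)
    t = np.arange(n) / fs
    rng = np.random.default_rng(config.seed)

    max_f = max(config.theta_band[1], config.gamma_band[1], 600.0)
    if fs <= 2 * max_f:
        raise ValueError(f"fs={fs} must exceed twice the highest generated frequency")
    for ev in config.event_specs:
        if not 0.0 <= ev.t_center <= config.duration_s:
            raise ValueError(f"event at t={ev.t_center}s outside recording span")
        if ev.region not in config.regions:
            raise ValueError(f"event region {ev.region!r} not in {config.regions}")

    data = np.zeros((n_ch, n))

    # 1/f background
    for i in range(n_ch):
        data[i] += config.noise_scale * _pink_noise(n, rng)

    # theta with scheduled shared-source coherence
    sched = config.theta_coherence_schedule
    shared = _band_noise(n, fs, config.theta_band, rng)
    c = np.full(n, sched.baseline)
    for ev in config.event_specs:
        lo = int(round((ev.t_center - sched.pre_window_s) * fs))
        hi = int(round(ev.t_center * fs))
        c[max(lo, 0) : max(hi, 0)] = sched.pre_event
    for i in range(n_ch):
        indep = _band_noise(n, fs, config.theta_band, rng)
        data[i] += config.theta_amplitude * (
            np.sqrt(c) * shared + np.sqrt(1.0 - c) * indep
        )

    # gamma, independent per channel
    for i in range(n_ch):
        data[i] += config.gamma_amplitude * _band_noise(n, fs, config.gamma_band, rng)

    # directed VAR coupling component
    vc = config.var_coupling
    regimes = vc.regime_matrices(n_ch)
    names = ["baseline", "pre", "post"]
    for nm in names:
        _check_stable(regimes[nm], nm)
    # coupling regimes occupy the analysis windows adjacent to the event
    # extent (center ± duration): pre = [start - window, start], post =
    # [end, end + window], padded by a small margin for switch transients
    regime_index = np.zeros(n, dtype=int)
    m = int(round(vc.window_margin_s * fs))
    for ev in config.event_specs:
        half = int(round(ev.duration_ms * fs / 1000.0))
        ci = int(round(ev.t_center * fs))
        w = int(round(vc.window_s * fs))
        regime_index[max(ci - half - w - m, 0) : max(ci - half + m, 0)] = 1
        regime_index[max(min(ci + half - m, n), 0) : min(ci + half + w + m, n)] = 2
    var = simulate_var(
        None,
        n,
        rng,
        n_series=1,
        regime_index=regime_index,
        regime_mats=[regimes[nm] for nm in names],
        fs=fs,
        innovation_cutoff_hz=vc.innovation_cutoff_hz,
        innovation_rolloff=vc.innovation_rolloff,
        innovation_highpass_hz=vc.innovation_highpass_hz,
    )[0]
    sd = var.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    data += vc.scale * var / sd

    # fast-ripple bursts and sharp waves
    for ev in config.event_specs:
        i = config.regions.index(ev.region)
        data[i] += _fr_burst(t, ev)
        if ev.sharp_wave:
            data[i] += _sharp_wave(t, ev)

    # multiunit spikes
    spike_times: dict[str, np.ndarray] = {r: np.array([]) for r in config.regions}
    if config.spike_schedule is not None:
        ss = config.spike_schedule
        wf = _spike_waveform(fs, ss.amplitude)
        half = len(wf) // 2
        for i, region in enumerate(config.regions):
            rate = np.full(n, ss.baseline_hz)
            off = ss.event_offset_ms.get(region, 0.0) / 1000.0
            w = ss.event_width_ms / 1000.0
            for ev in config.event_specs:
                rate += ss.event_peak_hz * np.exp(
                    -((t - (ev.t_center + off)) ** 2) / (2.0 * w**2)
                )
            hits = np.flatnonzero(rng.random(n) < rate / fs)
            # enforce a 2-ms dead time so transients do not pile up
            keep = []
            last = -np.inf
            for h in hits:
                if h - last >= 0.002 * fs:
                    keep.append(h)
                    last = h
            hits = np.array(keep, dtype=int)
            for h in hits:
                lo, hi = h - half, h - half + len(wf)
                wl, wh = max(lo, 0), min(hi, n)
                data[i, wl:wh] += wf[wl - lo : wh - lo]
            spike_times[region] = hits / fs

    edges = {}
    for nm in names:
        mats = regimes[nm]
        e = []
        for k in range(mats.shape[0]):
            for ii in range(n_ch):
                for jj in range(n_ch):
                    if ii != jj and mats[k, ii, jj] != 0.0:
                        e.append((config.regions[jj], config.regions[ii]))
        edges[nm] = sorted(set(e))

    rec = Recording(data, fs=fs, region_labels=tuple(config.regions))
    gt = GroundTruth(events=list(config.event_specs), coupling_edges=edges, spike_times=spike_times)
    return rec, gt


def generate_var_epochs(
    adjacency,
    lag: int,
    n_epochs: int,
    epoch_len: int,
    seed: int,
    noise_sd: float = 1.0,
) -> np.ndarray:
    """Independent realizations of a stationary VAR process.

    ``adjacency`` is ``(n, n)`` (applied at ``lag``; intermediate lags zero)
    or ``(lags, n, n)``.  Returns ``(n_epochs, n_channels, epoch_len)``.
    Spectral radius of the companion matrix must be < 1.
    """
    A = np.asarray(adjacency, dtype=float)
    if A.ndim == 2:
        n = A.shape[0]
        mats = np.zeros((lag, n, n))
        mats[lag - 1] = A
    else:
        mats = A
    _check_stable(mats, "epoch")
    if n_epochs == 0:
        return np.empty((0, mats.shape[1], epoch_len))
    rng = np.random.default_rng(seed)
    x = simulate_var(mats, epoch_len, rng, n_series=n_epochs)
    return noise_sd * x
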