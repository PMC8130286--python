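"""Recording containers, file I/O and the shared zero-phase filtering primitives.

All signals are local field potentials in microvolts (µV); all times are in
seconds internally.  A :class:`Recording` holds one equal-length trace per
hippocampal region, by default the trisynaptic-circuit regions DG, CA3 and
CA1, sampled at a common rate (5 kHz in the reference acquisition setup).

Two on-disk dialects are supported:

* CSV — header row with region names, optional leading ``time`` column,
  comma-separated with ``.`` decimal; lossless for small fixtures.
* EDF — standard 16-bit European Data Format, one signal per region.  Reading
  goes through :func:`mne.io.read_raw_edf`; writing uses a minimal native
  writer covering the uniform-rate multichannel case this package produces.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

DEFAULT_REGIONS = ("DG", "CA3", "CA1")

#: FIR order for every zero-phase filter in the pipeline.
DEFAULT_FIR_ORDER = 512


@dataclass
class Recording:
    """Multichannel LFP recording in µV.

    Parameters
    ----------
    data
        Array of shape ``(n_regions, n_samples)``, µV.
    fs
        Sampling rate in Hz.
    region_labels
        Ordered region names, one per row of ``data``.
    start_time
        Time of the first sample, seconds.
    """

    data: np.ndarray
    fs: float
    region_labels: tuple[str, ...] = DEFAULT_REGIONS
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_regions, n_samples)")
        if self.data.shape[0] != len(self.region_labels):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.region_labels)} labels"
            )
        if len(set(self.region_labels)) != len(self.region_labels):
            raise ValueError("region labels must be unique")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.fs

    def channel(self, region: str) -> np.ndarray:
        try:
            i = self.region_labels.index(region)
        except ValueError:
            raise KeyError(
                f"region {region!r} not in channel map {self.region_labels}"
            ) from None
        return self.data[i]

    def index_of(self, region: str) -> int:
        return self.region_labels.index(region)


@dataclass
class EventWindow:
    """A candidate analysis window around one event.

    ``center_index`` is the sample of maximum peak-to-peak amplitude;
    ``pre_ms``/``post_ms`` give the window extent on either side.
    """

    region: str
    center_index: int
    pre_ms: float = 200.0
    post_ms: float = 200.0

    def slice_for(self, rec: Recording) -> slice:
        lo = self.center_index - int(round(self.pre_ms * rec.fs / 1000.0))
        hi = self.center_index + int(round(self.post_ms * rec.fs / 1000.0))
        if lo < 0 or hi > rec.n_samples:
            raise ValueError(
                f"window [{lo}, {hi}) outside recording of {rec.n_samples} samples"
            )
        return slice(lo, hi)


# ---------------------------------------------------------------------------
# Zero-phase FIR filtering
# ---------------------------------------------------------------------------


def _fir_taps(low_hz: float | None, high_hz: float | None, fs: float, order: int) -> np.ndarray:
    """Windowed-sinc (Hamming) FIR design; ``order`` taps + 1, type I."""
    numtaps = order + 1
    if numtaps % 2 == 0:
        numtaps += 1
    nyq = fs / 2.0
    if low_hz is not None and high_hz is not None:
        if not 0 < low_hz < high_hz < nyq:
            raise ValueError(f"need 0 < low < high < fs/2, got ({low_hz}, {high_hz}) at fs={fs}")
        return sps.firwin(numtaps, [low_hz, high_hz], pass_zero=False, fs=fs, window="hamming")
    if low_hz is not None:  # high-pass
        if not 0 < low_hz < nyq:
            raise ValueError(f"cutoff {low_hz} outside (0, fs/2)")
        return sps.firwin(numtaps, low_hz, pass_zero=False, fs=fs, window="hamming")
    if not 0 < high_hz < nyq:
        raise ValueError(f"cutoff {high_hz} outside (0, fs/2)")
    return sps.firwin(numtaps, high_hz, pass_zero=True, fs=fs, window="hamming")


def _filtfilt(x: np.ndarray, taps: np.ndarray, order: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    padlen = 3 * order
    if x.shape[-1] <= padlen:
        raise ValueError(
            f"signal of {x.shape[-1]} samples too short for forward-backward "
            f"FIR of order {order} (needs > {padlen})"
        )
    # reflect ("even") padding of 3x order keeps edge transients out of
    # 200-ms analysis windows
    return sps.filtfilt(taps, [1.0], x, padtype="even", padlen=padlen)


def zero_phase_bandpass(
    x: np.ndarray, low_hz: float, high_hz: float, fs: float, order: int = DEFAULT_FIR_ORDER
) -> np.ndarray:
    """Forward-backward (zero-phase) band-pass FIR filter.

    The two-pass application squares the designed magnitude response and
    cancels the phase, so band-limited features keep their timing exactly.
    """
    return _filtfilt(x, _fir_taps(low_hz, high_hz, fs, order), order)


def zero_phase_highpass(
    x: np.ndarray, cutoff_hz: float, fs: float, order: int = DEFAULT_FIR_ORDER
) -> np.ndarray:
    """Forward-backward high-pass FIR filter (see :func:`zero_phase_bandpass`)."""
    return _filtfilt(x, _fir_taps(cutoff_hz, None, fs, order), order)


def zero_phase_lowpass(
    x: np.ndarray, cutoff_hz: float, fs: float, order: int = DEFAULT_FIR_ORDER
) -> np.ndarray:
    """Forward-backward low-pass FIR filter (see :func:`zero_phase_bandpass`)."""
    return _filtfilt(x, _fir_taps(None, cutoff_hz, fs, order), order)


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------


def write_recording_csv(rec: Recording, path: str | Path, include_time: bool = True) -> None:
    cols: dict[str, np.ndarray] = {}
    if include_time:
        cols["time"] = rec.times
    for i, lab in enumerate(rec.region_labels):
        cols[lab] = rec.data[i]
    # %.17g keeps the round trip lossless for float64
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_recording_csv(
    path: str | Path,
    fs: float | None = None,
    region_labels: tuple[str, ...] = DEFAULT_REGIONS,
) -> Recording:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [r for r in region_labels if r not in df.columns]
    if missing:
        raise ValueError(
            f"CSV {path} lacks region column(s) {missing}; channel map is "
            f"{list(df.columns)}"
        )
    start = 0.0
    if "time" in df.columns:
        t = df["time"].to_numpy(float)
        start = float(t[0])
        if fs is None:
            if len(t) < 2:
                raise ValueError("cannot infer fs from a single sample")
            fs = 1.0 / float(np.median(np.diff(t)))
    if fs is None:
        raise ValueError("fs must be given when the CSV has no time column")
    data = np.vstack([df[r].to_numpy(float) for r in region_labels])
    return Recording(data, fs=fs, region_labels=tuple(region_labels), start_time=start)


# ---------------------------------------------------------------------------
# EDF (16-bit) writer / reader
# ---------------------------------------------------------------------------


def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_recording_edf(rec: Recording, path: str | Path, physical_range: float = 1000.0) -> None:
    """Write a standard 16-bit EDF file, one signal per region.

    ``physical_range`` is the symmetric full scale in µV; samples are
    quantized to 16 bits over ±``physical_range``.  Data records are 0.1 s;
    a final partial record is zero-padded (the true length is recoverable
    from the CSV/JSON sidecars the pipeline writes alongside).
    """
    path = Path(path)
    ns = len(rec.region_labels)
    record_dur = 0.1
    spr = int(round(rec.fs * record_dur))  # samples per record per signal
    if spr < 1:
        raise ValueError("sampling rate too low for 0.1-s EDF records")
    n_records = int(np.ceil(rec.n_samples / spr))
    pmax = float(physical_range)
    if np.max(np.abs(rec.data)) > pmax:
        raise ValueError(
            f"signal exceeds physical range ±{pmax} µV; increase physical_range"
        )
    dmin, dmax = -32768, 32767

    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("synthetic", 80),
            _edf_field("synthetic LFP", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(str(256 * (1 + ns)), 8),
            _edf_field("", 44),
            _edf_field(str(n_records), 8),
            _edf_field(f"{record_dur:g}", 8),
            _edf_field(str(ns), 4),
        ]
    )
    fields = [
        [_edf_field(lab, 16) for lab in rec.region_labels],
        [_edf_field("", 80)] * ns,
        [_edf_field("uV", 8)] * ns,
        [_edf_field(f"{-pmax:g}", 8)] * ns,
        [_edf_field(f"{pmax:g}", 8)] * ns,
        [_edf_field(str(dmin), 8)] * ns,
        [_edf_field(str(dmax), 8)] * ns,
        [_edf_field("", 80)] * ns,
        [_edf_field(str(spr), 8)] * ns,
        [_edf_field("", 32)] * ns,
    ]
    header += b"".join(b"".join(f) for f in fields)

    scale = (dmax - dmin) / (2 * pmax)
    padded = np.zeros((ns, n_records * spr))
    padded[:, : rec.n_samples] = rec.data
    digital = np.clip(np.round((padded + pmax) * scale) + dmin, dmin, dmax).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())


def read_recording_edf(
    path: str | Path, region_labels: tuple[str, ...] = DEFAULT_REGIONS
) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    missing = [r for r in region_labels if r not in raw.ch_names]
    if missing:
        raise ValueError(
            f"EDF {path} lacks channel(s) {missing}; channel map is {raw.ch_names}"
        )
    fs_set = {raw.info["sfreq"]}
    if len(fs_set) != 1:
        raise ValueError("inconsistent sampling rate across channels")
    # mne converts EDF physical units to SI volts; restore µV
    data = np.vstack([raw.get_data(picks=[r])[0] for r in region_labels]) * 1e6
    return Recording(data, fs=float(raw.info["sfreq"]), region_labels=tuple(region_labels))


def read_recording(path: str | Path, dialect: str | None = None, **kw) -> Recording:
    """Read a recording; ``dialect`` is ``'edf'`` or ``'csv'`` (inferred from suffix)."""
    path = Path(path)
    if dialect is None:
        dialect = "edf" if path.suffix.lower() == ".edf" else "csv"
    if dialect == "edf":
        return read_recording_edf(path, **kw)
    if dialect == "csv":
        return read_recording_csv(path, **kw)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_recording(rec: Recording, path: str | Path, dialect: str | None = None, **kw) -> None:
    path = Path(path)
    if dialect is None:
        dialect = "edf" if path.suffix.lower() == ".edf" else "csv"
    if dialect == "edf":
        write_recording_edf(rec, path, **kw)
    elif dialect == "csv":
        write_recording_csv(rec, path, **kw)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------


def write_event_table(events, path: str | Path) -> None:
    """Write detected events as CSV (one row per event)."""
    rows = []
    for i, ev in enumerate(events):
        rows.append(
            {
                "event_id": getattr(ev, "event_id", i),
                "region": ev.region,
                "center_time_s": ev.center_time,
                "amplitude_pp_uV": getattr(ev, "amplitude_pp", np.nan),
                "power_freq_hz": getattr(ev, "power_frequency", np.nan),
                "power_uV2_per_hz": getattr(ev, "power", np.nan),
                "duration_ms": getattr(ev, "duration_ms", np.nan),
                "mean_freq_hz": getattr(ev, "mean_frequency", np.nan),
                "sw_flag": int(bool(getattr(ev, "sharp_wave_associated", False))),
                "sw_duration_ms": getattr(ev, "sharp_wave_duration_ms", np.nan),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_event_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
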