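"""Pairwise Granger causality on pre-/post-event LFP segments.

A signal X Granger-causes Y when X's past improves the prediction of Y
beyond Y's own past, assessed in a bivariate autoregressive model: the
restricted regression uses only Y's own lags, the unrestricted adds X's
lags, and the classical F statistic on the residual sums of squares gives
the directed p-value.  The model order is chosen by the Bayesian
information criterion (BIC) of the bivariate fit; segments must be
covariance-stationary (constant first two moments), screened by a
split-half moment comparison plus an autocorrelation-decay check.

For each fast ripple, 200-ms segments immediately before and after the
sample of maximum peak-to-peak amplitude are analyzed on the broadband
signal after linear detrending, yielding a 3×3 directed p-value matrix
(rows cause columns, diagonal undefined) per epoch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy import stats

SEGMENT_MS = 200.0
MAX_LAG_DEFAULT = 20


@dataclass
class StationarityReport:
    """Per-channel split-half moment drift and autocorrelation decay."""

    mean_drift_z: np.ndarray  # per channel, autocorrelation-adjusted
    var_drift_z: np.ndarray
    acf_decays: np.ndarray  # bool per channel
    channel_pass: np.ndarray  # bool per channel

    @property
    def passed(self) -> bool:
        return bool(np.all(self.channel_pass))


@dataclass
class CausalEpochResult:
    """Directed p-value matrices for one event's pre and post segments."""

    event_id: int
    regions: tuple[str, ...]
    pre_matrix: np.ndarray  # (n, n), row causes column, NaN diagonal
    post_matrix: np.ndarray
    pre_lags: dict = field(default_factory=dict)  # unordered pair -> lag
    post_lags: dict = field(default_factory=dict)
    pre_stationary: bool = True
    post_stationary: bool = True

    @property
    def usable(self) -> bool:
        return self.pre_stationary and self.post_stationary


# ---------------------------------------------------------------------------
# Stationarity screen
# ---------------------------------------------------------------------------


def _effective_n(x: np.ndarray, max_lag: int = 20) -> float:
    """Sample size corrected for autocorrelation (Bartlett-style)."""
    n = len(x)
    xc = x - x.mean()
    denom = np.dot(xc, xc)
    if denom == 0:
        return float(n)
    rho_sum = 0.0
    for k in range(1, min(max_lag, n - 1) + 1):
        rho = np.dot(xc[:-k], xc[k:]) / denom
        if rho <= 0:
            break
        rho_sum += rho
    return max(n / (1.0 + 2.0 * rho_sum), 4.0)


def _variance_effective_n(x: np.ndarray) -> float:
    """Effective sample size for a variance estimate: n / (1 + 2 Σ ρ(k)²)."""
    n = len(x)
    xc = x - x.mean()
    denom = np.dot(xc, xc)
    if denom == 0:
        return float(n)
    s = 0.0
    for k in range(1, n // 4 + 1):
        rho = np.dot(xc[:-k], xc[k:]) / denom
        s += rho * rho
    return max(n / (1.0 + 2.0 * s), 2.0)


def check_stationarity(segment: np.ndarray, acf_max_lag_frac: float = 0.25) -> StationarityReport:
    """Covariance-stationarity screen on a (channels, samples) segment.

    Passes per channel iff (i) split-half means and log-variances each
    differ by < 2 autocorrelation-adjusted standard errors, and (ii) the
    sample autocorrelation drops inside the white-noise 95 % band within
    a quarter of the segment length.
    """
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    n_ch, n = segment.shape
    if n < 100:
        raise ValueError(f"segment of {n} samples too short (need >= 100)")

    mean_z = np.empty(n_ch)
    var_z = np.empty(n_ch)
    decays = np.empty(n_ch, dtype=bool)
    half = n // 2
    for c in range(n_ch):
        x = segment[c]
        a, b = x[:half], x[half : 2 * half]
        na, nb = _effective_n(a), _effective_n(b)
        se = np.sqrt(np.var(a, ddof=1) / na + np.var(b, ddof=1) / nb)
        mean_z[c] = np.abs(a.mean() - b.mean()) / se if se > 0 else 0.0
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        if va > 0 and vb > 0:
            # for a Gaussian process var(sigma^2-hat) scales with
            # n / (1 + 2 sum rho(k)^2)  (rho of x squared equals rho^2), so
            # narrowband or rhythmic signals get the wide SE they deserve
            na2 = _variance_effective_n(a)
            nb2 = _variance_effective_n(b)
            se_lv = np.sqrt(2.0 / na2 + 2.0 / nb2)
            var_z[c] = np.abs(np.log(va / vb)) / se_lv
        else:
            var_z[c] = np.inf

        xc = x - x.mean()
        denom = np.dot(xc, xc)
        band = 1.96 / np.sqrt(n)
        max_lag = int(n * acf_max_lag_frac)
        decays[c] = False
        if denom > 0:
            for k in range(1, max_lag + 1):
                rho = np.dot(xc[:-k], xc[k:]) / denom
                if abs(rho) < band:
                    decays[c] = True
                    break

    ch_pass = (mean_z < 2.0) & (var_z < 2.0) & decays
    return StationarityReport(mean_z, var_z, decays, ch_pass)


# ---------------------------------------------------------------------------
# VAR fitting, BIC lag selection and the Granger F-test
# ---------------------------------------------------------------------------


def _lag_design(data: np.ndarray, lags: int) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix of lagged values (+ intercept) and same-time targets."""
    n_ch, n = data.shape
    t0 = lags
    Y = data[:, t0:].T  # (T, n_ch)
    cols = [np.ones(n - t0)]
    for k in range(1, lags + 1):
        for c in range(n_ch):
            cols.append(data[c, t0 - k : n - k])
    X = np.column_stack(cols)
    return X, Y


def select_lag(x: np.ndarray, y: np.ndarray, max_lag: int = MAX_LAG_DEFAULT) -> int:
    """BIC-minimizing order of the bivariate AR model over 1..max_lag.

    All candidate orders are scored on the common sample (first
    ``max_lag`` observations trimmed) so their likelihoods are comparable.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if max_lag >= n / 10:
        raise ValueError(f"max_lag {max_lag} too large for segment of {n} samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate (constant) channel")
    data = np.vstack([x, y])
    T = n - max_lag
    best_bic, best_p = np.inf, 1
    for p in range(1, max_lag + 1):
        X, Y = _lag_design(data, p)
        X, Y = X[-T:], Y[-T:]
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        sig = (resid.T @ resid) / T
        sign, logdet = np.linalg.slogdet(sig)
        if sign <= 0:
            continue
        k = X.shape[1] * 2  # estimated coefficients across both equations
        bic = T * logdet + k * np.log(T)
        if bic < best_bic:
            best_bic, best_p = bic, p
    return best_p


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("singular regression design")
    r = y - X @ beta
    return float(r @ r)


def granger_pair(x: np.ndarray, y: np.ndarray, lag: int) -> tuple[float, float]:
    """Directed Granger F-test p-values: (x causes y, y causes x).

    Each direction compares the restricted regression (target's own
    ``lag`` past values + intercept) against the unrestricted one adding
    the other channel's past, F(lag, T − 2·lag − 1) on the residual sums
    of squares.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("segments must have equal length")
    if lag < 1:
        raise ValueError("lag must be >= 1")

    def one_direction(cause: np.ndarray, effect: np.ndarray) -> float:
        n = len(effect)
        T = n - lag
        tgt = effect[lag:]
        own = np.column_stack(
            [np.ones(T)] + [effect[lag - k : n - k] for k in range(1, lag + 1)]
        )
        other = np.column_stack([cause[lag - k : n - k] for k in range(1, lag + 1)])
        full = np.hstack([own, other])
        try:
            rss_r = _ols_rss(own, tgt)
            rss_u = _ols_rss(full, tgt)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "singular regression design (identical or degenerate channels)"
            ) from None
        df_den = T - full.shape[1]
        if df_den <= 0 or rss_u <= 0:
            raise np.linalg.LinAlgError("degenerate regression: no residual freedom")
        F = ((rss_r - rss_u) / lag) / (rss_u / df_den)
        return float(stats.f.sf(max(F, 0.0), lag, df_den))

    return one_direction(x, y), one_direction(y, x)


# ---------------------------------------------------------------------------
# Event-level epochs
# ---------------------------------------------------------------------------


def _detrend(seg: np.ndarray) -> np.ndarray:
    from scipy.signal import detrend

    return detrend(seg, axis=-1, type="linear")


def epoch_causality(
    segments: dict[str, np.ndarray],
    regions: tuple[str, ...],
    max_lag: int = MAX_LAG_DEFAULT,
) -> tuple[np.ndarray, dict, bool]:
    """All directed tests on one detrended multichannel segment.

    Returns the (n, n) p-value matrix (row causes column), the selected
    lag per unordered pair, and the stationarity flag.
    """
    data = np.vstack([segments[r] for r in regions])
    data = _detrend(data)
    st = check_stationarity(data)
    n = len(regions)
    pmat = np.full((n, n), np.nan)
    lags: dict = {}
    if not st.passed:
        return pmat, lags, False
    for i, j in permutations(range(n), 2):
        if i < j:
            lag = select_lag(data[i], data[j], max_lag=max_lag)
            lags[(regions[i], regions[j])] = lag
            p_ij, p_ji = granger_pair(data[i], data[j], lag)
            pmat[i, j] = p_ij
            pmat[j, i] = p_ji
    return pmat, lags, True


#: decimation factor applied to causality segments (5 kHz -> 1 kHz); at the
#: recording rate the BIC-selected model order cannot span the LFP's
#: correlation time, which both starves the test of power and lets
#: under-fitted own-past models masquerade as reverse causality
DECIMATE_DEFAULT = 5


def event_causality(
    rec,
    center_time: float,
    event_id: int = 0,
    duration_ms: float = 0.0,
    segment_ms: float = SEGMENT_MS,
    max_lag: int = MAX_LAG_DEFAULT,
    decimate_factor: int = DECIMATE_DEFAULT,
) -> CausalEpochResult | None:
    """Pre/post directed p-value matrices for one fast ripple.

    Segments span ``segment_ms`` immediately before and after the event,
    taken adjacent to the event extent (maximum peak-to-peak sample
    ± one ``duration_ms``) so the burst itself stays outside the analyzed
    windows.  Returns ``None`` (with a warning) when a segment falls
    outside the recording; non-stationary segments yield NaN matrices
    with the stationarity flag cleared so the event can be excluded
    downstream.
    """
    fs = rec.fs
    ci = int(round((center_time - rec.start_time) * fs))
    # the burst envelope at half its FWHM still holds ~50% amplitude, so the
    # guard spans a full duration each side (~2.4 sigma, envelope < 7%)
    half = int(round(duration_ms * fs / 1000.0))
    w = int(round(segment_ms * fs / 1000.0))
    if ci - half - w < 0 or ci + half + w > rec.n_samples:
        warnings.warn(f"event {event_id} at {center_time:.3f}s too close to edge; skipped")
        return None
    regions = rec.region_labels

    def grab(sl: slice) -> dict:
        seg = {r: rec.channel(r)[sl] for r in regions}
        if decimate_factor > 1:
            from scipy.signal import decimate

            seg = {
                r: decimate(v, decimate_factor, ftype="fir", zero_phase=True)
                for r, v in seg.items()
            }
        return seg

    pre = grab(slice(ci - half - w, ci - half))
    post = grab(slice(ci + half, ci + half + w))
    n_seg = len(next(iter(pre.values())))
    eff_max_lag = min(max_lag, max(n_seg // 10 - 1, 1))
    pre_m, pre_l, pre_ok = epoch_causality(pre, regions, max_lag=eff_max_lag)
    post_m, post_l, post_ok = epoch_causality(post, regions, max_lag=eff_max_lag)
    return CausalEpochResult(
        event_id=event_id,
        regions=regions,
        pre_matrix=pre_m,
        post_matrix=post_m,
        pre_lags=pre_l,
        post_lags=post_l,
        pre_stationary=pre_ok,
        post_stationary=post_ok,
    )
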