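"""Coherence, cross-correlation and band-power analyses.

Magnitude-squared coherence between traces (and between traces and
behavioral variables) is estimated Welch-style with 2 min Hamming windows
at 98% overlap.  Because such heavily overlapped windows are strongly
correlated, confidence on the coherence is reported only through a
circular-shift shuffle control, never through analytic
degrees-of-freedom formulas.  Cross-correlation uses a 3 s maximum lag on
1 Hz low-passed traces.  The band-power profile and the same-axon
coherence limit quantify why the analysis band is restricted to <=1 Hz:
a slow calcium indicator carries little usable power above that.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .preprocess import lowpass_1hz


@dataclass
class CoherenceResult:
    freqs: np.ndarray
    msc: np.ndarray
    n_segments: int
    shuffle_band: np.ndarray | None = None     # null 95% envelope per freq

    def __post_init__(self) -> None:
        assert np.all(np.diff(self.freqs) > 0), "freqs must be increasing"


def _coherence_params(n: int, fs: float, window_s: float, overlap: float):
    nperseg = int(round(window_s * fs))
    if n < nperseg:
        raise ValueError(
            f"recording ({n / fs:.0f} s) shorter than the coherence window "
            f"({window_s:.0f} s); pass a shorter window_s")
    noverlap = int(np.floor(overlap * nperseg))
    step = nperseg - noverlap
    n_segments = 1 + (n - nperseg) // step
    if n_segments < 2:
        warnings.warn("fewer than 2 coherence segments; estimate is degenerate")
    return nperseg, noverlap, n_segments


def coherence(x: np.ndarray, y: np.ndarray, fs: float,
              window_s: float = 120.0, overlap: float = 0.98,
              n_shuffles: int = 0, min_shift_s: float = 10.0,
              rng: np.random.Generator | None = None) -> CoherenceResult:
    """Magnitude-squared coherence with a Hamming window.

    Defaults follow the standard neuromodulatory-imaging parameters:
    2 min windows, 98% overlap.  With ``n_shuffles > 0`` a null envelope
    (95th percentile across circular time shifts of ``y``) is attached.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("traces must have equal length")
    nperseg, noverlap, n_segments = _coherence_params(len(x), fs, window_s, overlap)
    win = sps.get_window("hamming", nperseg)

    def _msc(a, b):
        f, c = sps.coherence(a, b, fs=fs, window=win, nperseg=nperseg,
                             noverlap=noverlap)
        return f, c

    f, c = _msc(x, y)
    keep = f > 0
    band = None
    if n_shuffles:
        rng = rng or np.random.default_rng(0)
        min_shift = int(round(min_shift_s * fs))
        null = np.empty((n_shuffles, keep.sum()))
        for k in range(n_shuffles):
            sh = int(rng.integers(min_shift, len(y) - min_shift))
            _, ck = _msc(x, np.roll(y, sh))
            null[k] = ck[keep]
        band = np.percentile(null, 95.0, axis=0)
    return CoherenceResult(freqs=f[keep], msc=np.clip(c[keep], 0.0, 1.0),
                           n_segments=n_segments, shuffle_band=band)


@dataclass
class XCorrResult:
    lags_s: np.ndarray
    corr: np.ndarray
    peak_lag_s: float
    peak_r: float
    #: sign convention: a positive peak lag means x lags (follows) y
    convention: str = "positive lag = x lags y"


def xcorr_lag(x: np.ndarray, y: np.ndarray, fs: float,
              max_lag_s: float = 3.0,
              prefilter_hz: float | None = 1.0) -> XCorrResult:
    """Normalized cross-correlation on +/- ``max_lag_s``.

    Both traces are optionally 1 Hz low-passed first (the band where both
    the indicator and the behavioral variables carry their power), then
    z-scored.  ``corr[k]`` is the correlation of ``x(t)`` with
    ``y(t - lag_k)``; a positive peak lag means x lags y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("traces must have equal length")
    if prefilter_hz is not None:
        x = lowpass_1hz(x, fs, cutoff=prefilter_hz)
        y = lowpass_1hz(y, fs, cutoff=prefilter_hz)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance input; cross-correlation undefined")
    x = (x - x.mean()) / sx
    y = (y - y.mean()) / sy
    n = len(x)
    full = sps.correlate(x, y, mode="full") / n
    lags = sps.correlation_lags(n, n, mode="full") / fs
    keep = np.abs(lags) <= max_lag_s + 1e-12
    lags, full = lags[keep], full[keep]
    i = int(np.argmax(full))
    return XCorrResult(lags_s=lags, corr=full, peak_lag_s=float(lags[i]),
                       peak_r=float(full[i]))


@dataclass
class BandPowerResult:
    freqs: np.ndarray
    psd: np.ndarray
    frac_below: dict[float, float]


def band_power_profile(x: np.ndarray, fs: float, window_s: float = 60.0,
                       edges: tuple[float, ...] = (1.0, 2.0, 4.0)
                       ) -> BandPowerResult:
    """Welch power spectrum and the cumulative power fraction below 1/2/4 Hz."""
    x = np.asarray(x, dtype=float)
    if len(x) < 60 * fs:
        raise ValueError("trace must be at least 60 s long")
    nperseg = min(int(window_s * fs), len(x))
    f, p = sps.welch(x - x.mean(), fs=fs, nperseg=nperseg,
                     noverlap=nperseg // 2)
    total = np.trapezoid(p, f)
    frac = {}
    for e in edges:
        m = f <= e
        frac[e] = float(np.trapezoid(p[m], f[m]) / total) if total > 0 else np.nan
    return BandPowerResult(freqs=f, psd=p, frac_below=frac)


def half_coherence_frequency(res: CoherenceResult, f_min: float = 0.05) -> float:
    """First frequency above ``f_min`` at which the coherence falls below 0.5.

    Returns the Nyquist edge (last frequency bin) if coherence never drops
    below 0.5 — the noiseless same-trace case.
    """
    m = res.freqs >= f_min
    f, c = res.freqs[m], res.msc[m]
    below = np.flatnonzero(c < 0.5)
    if len(below) == 0:
        return float(f[-1])
    return float(f[below[0]])


def same_axon_coherence_limit(pairs: list[tuple[np.ndarray, np.ndarray]],
                              fs: float, window_s: float = 120.0,
                              overlap: float = 0.98) -> dict:
    """Per-pair coherence curves and half-coherence frequencies.

    Adjacent segments of one axon see (nearly) identical spiking, so the
    frequency at which their coherence drops below 0.5 marks the usable
    bandwidth of the recording method and justifies the 1 Hz analysis
    cutoff.  Returns ``results`` (list of CoherenceResult), ``limits_hz``
    and their median.
    """
    if not pairs:
        warnings.warn("no same-axon pairs labeled; skipping coherence limit")
        return {"results": [], "limits_hz": np.array([]), "median_limit_hz": np.nan}
    results, limits = [], []
    for x, y in pairs:
        r = coherence(x, y, fs, window_s=window_s, overlap=overlap)
        results.append(r)
        limits.append(half_coherence_frequency(r))
    limits = np.asarray(limits)
    return {"results": results, "limits_hz": limits,
            "median_limit_hz": float(np.median(limits))}
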