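"""Fluorescence trace conditioning and quality control.

Raw traces are upsampled to a uniform 100 Hz grid and low-pass filtered at
10 Hz (zero-phase Butterworth), a signal-to-noise criterion based on the
ratio of low-frequency signal power (0.05-0.5 Hz) to high-frequency power
(1-3 Hz) screens out unusable traces, and dF/F is computed against the
session median baseline.  A 1 Hz low-pass conditions traces for all
correlation analyses: a slow calcium indicator cannot faithfully report
activity above roughly 1 Hz, so restricting the band removes noise that
same-axon controls show to be uninformative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

SNR_THRESHOLD = float(np.log(20.0))


def _butter_lowpass(x: np.ndarray, fs: float, cutoff: float,
                    order: int = 3) -> np.ndarray:
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def condition_trace(raw: np.ndarray, fs_in: float, fs_out: float = 100.0,
                    lp_hz: float = 10.0) -> np.ndarray:
    """Upsample a trace to ``fs_out`` and low-pass filter at ``lp_hz``.

    Upsampling is linear interpolation onto a uniform grid (the indicator
    bandwidth is far below the input Nyquist, so interpolation error is
    negligible); filtering is zero-phase forward-backward Butterworth
    (order 3) to preserve event-alignment timing.

    Non-finite gaps shorter than 1 s are interpolated; longer gaps raise.
    """
    raw = np.asarray(raw, dtype=float)
    if fs_in < 5.0:
        raise ValueError("input sampling rate must be >= 5 Hz")
    if len(raw) < 10 * fs_in:
        raise ValueError("trace must be at least 10 s long")
    bad = ~np.isfinite(raw)
    if bad.any():
        # locate the longest contiguous non-finite run
        d = np.diff(bad.astype(np.int8))
        starts = np.flatnonzero(d == 1) + 1
        stops = np.flatnonzero(d == -1) + 1
        if bad[0]:
            starts = np.r_[0, starts]
        if bad[-1]:
            stops = np.r_[stops, len(bad)]
        longest = max(stops - starts)
        if longest > fs_in:
            raise ValueError(
                f"non-finite run of {longest / fs_in:.2f} s exceeds 1 s")
        idx = np.arange(len(raw))
        raw = raw.copy()
        raw[bad] = np.interp(idx[bad], idx[~bad], raw[~bad])
    t_in = np.arange(len(raw)) / fs_in
    t_out = np.arange(0.0, t_in[-1] + 0.5 / fs_out, 1.0 / fs_out)
    up = np.interp(t_out, t_in, raw)
    return _butter_lowpass(up, fs_out, lp_hz)


def snr_statistic(trace: np.ndarray, fs: float = 100.0,
                  signal_band: tuple[float, float] = (0.05, 0.5),
                  noise_band: tuple[float, float] = (1.0, 3.0),
                  window_s: float = 60.0) -> float:
    """Log ratio of peak low-frequency power to mean high-frequency power.

    The spectrum is a Welch estimate with 60 s Hann windows at 50% overlap.
    Returns ``log(maxP[0.05-0.5 Hz] / meanP[1-3 Hz])``; ``inf``/-``inf`` in
    the degenerate zero-power cases.
    """
    trace = np.asarray(trace, dtype=float)
    if len(trace) < 60 * fs:
        raise ValueError("trace must be >= 60 s to resolve 0.05 Hz")
    nperseg = min(int(window_s * fs), len(trace))
    f, p = sps.welch(trace, fs=fs, nperseg=nperseg, noverlap=nperseg // 2)
    sig = p[(f >= signal_band[0]) & (f <= signal_band[1])]
    noi = p[(f >= noise_band[0]) & (f <= noise_band[1])]
    num, den = sig.max(), noi.mean()
    if den == 0.0:
        return np.inf if num > 0 else -np.inf
    if num == 0.0:
        return -np.inf
    return float(np.log(num / den))


def snr_filter(trace: np.ndarray, fs: float = 100.0,
               threshold: float = SNR_THRESHOLD,
               log_scale: bool = True) -> dict:
    """Apply the SNR inclusion criterion to a conditioned trace.

    A trace passes if ``log(maxP[0.05-0.5] / meanP[1-3]) >= log(20)``
    (equivalently, the power ratio is at least 20).  With
    ``log_scale=False`` the threshold is compared against the raw ratio.

    Returns a TraceQCReport entry: ``snr``, ``passed``, ``flag``.
    """
    snr = snr_statistic(trace, fs=fs)
    stat = snr if log_scale else float(np.exp(snr))
    flag = ""
    if not np.isfinite(snr):
        flag = "degenerate band power"
        passed = bool(snr > 0 and stat >= threshold)
    else:
        passed = bool(stat >= threshold)
    return {"snr": snr, "passed": passed, "flag": flag}


def dff(trace: np.ndarray) -> np.ndarray:
    """dF/F against the session median baseline: ``(F - med) / med``."""
    trace = np.asarray(trace, dtype=float)
    med = np.median(trace)
    if med <= 0:
        raise ValueError("median fluorescence must be positive for dF/F")
    return (trace - med) / med


def lowpass_1hz(trace: np.ndarray, fs: float, cutoff: float = 1.0) -> np.ndarray:
    """Zero-phase 1 Hz low-pass used before all correlation analyses."""
    if fs < 10.0:
        raise ValueError("trace must be sampled at >= 10 Hz")
    return _butter_lowpass(np.asarray(trace, dtype=float), fs, cutoff)


def zscore(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Per-trace z-score; the normalization used in population statistics
    so large or bright objects do not dominate averages."""
    x = np.asarray(x, dtype=float)
    m = x.mean(axis=axis, keepdims=True)
    s = x.std(axis=axis, keepdims=True)
    s = np.where(s == 0, 1.0, s)
    return (x - m) / s


@dataclass
class TraceQCReport:
    """Per-trace QC outcome: SNR values, pass flags, baselines, provenance."""

    table: pd.DataFrame      # object_id, snr, passed, baseline, flag
    filters: str             # text provenance of applied conditioning

    @property
    def n_pass(self) -> int:
        return int(self.table["passed"].sum())

    @property
    def n_fail(self) -> int:
        return int((~self.table["passed"]).sum())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")


def preprocess_session(fluor: np.ndarray, fs_in: float,
                       object_ids=None, fs_out: float = 100.0,
                       lp_hz: float = 10.0,
                       snr_threshold: float = SNR_THRESHOLD,
                       log_scale: bool = True,
                       ) -> tuple[np.ndarray, TraceQCReport]:
    """Condition every trace, apply the SNR criterion, and compute dF/F.

    Returns ``(dff_matrix, report)`` where the dF/F matrix is at ``fs_out``
    for all traces (failed traces included; use ``report.table['passed']``
    to subset) and the report records SNR, pass flags, and baselines.
    """
    fluor = np.atleast_2d(np.asarray(fluor, dtype=float))
    if object_ids is None:
        object_ids = [f"obj{i:02d}" for i in range(fluor.shape[0])]
    conditioned = np.stack([condition_trace(tr, fs_in, fs_out, lp_hz)
                            for tr in fluor])
    rows, out = [], []
    for oid, tr in zip(object_ids, conditioned):
        entry = snr_filter(tr, fs=fs_out, threshold=snr_threshold,
                           log_scale=log_scale)
        baseline = float(np.median(tr))
        out.append(dff(tr))
        rows.append(dict(object_id=oid, snr=entry["snr"],
                         passed=entry["passed"], baseline=baseline,
                         flag=entry["flag"]))
    report = TraceQCReport(
        table=pd.DataFrame(rows),
        filters=(f"linear upsample {fs_in}->{fs_out} Hz; "
                 f"butterworth(3) zero-phase low-pass {lp_hz} Hz; "
                 f"snr=log(maxP[0.05-0.5]/meanP[1-3]) "
                 f"threshold={'log' if log_scale else ''}"
                 f"({np.exp(snr_threshold) if log_scale else snr_threshold:.3g})"),
    )
    return np.asarray(out), report
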