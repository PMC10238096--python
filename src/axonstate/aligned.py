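"""Event-triggered averages, responsiveness statistics, and sustainedness.

Responses are aligned to behavioral event onsets/offsets.  Per-object
responsiveness compares mean dF/F in the second after onset against the
second before; significance is assessed against a circular-shift shuffle
null of the same t statistic, which preserves trace autocorrelation and
keeps the false-positive rate at the nominal alpha (a plain t-test on
autocorrelated calcium samples is anti-conservative).  Duration-stratified
averages and the sustainedness index (late response over peak) quantify
how well activity tracks prolonged movement bouts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import EVENT_COLUMNS

DURATION_BINS = ((1.0, 2.0), (2.0, 3.0), (3.0, 4.0), (5.0, np.inf))


@dataclass
class AlignedTensor:
    """dF/F aligned to behavioral events.

    ``data`` has shape (n_objects, n_events, n_time); ``t`` is time
    relative to the alignment point; ``events`` are the retained events
    (edge events excluded).
    """

    data: np.ndarray
    t: np.ndarray
    events: pd.DataFrame
    fs: float
    align_to: str
    n_excluded: int = 0

    @property
    def n_events(self) -> int:
        return self.data.shape[1]


def align(dff: np.ndarray, fs: float, events: pd.DataFrame,
          window_s: tuple[float, float] = (2.0, 5.0),
          align_to: str = "onset") -> AlignedTensor:
    """Extract per-event windows of dF/F around event onsets or offsets.

    ``window_s = (pre, post)`` extends ``pre`` seconds before and ``post``
    seconds after the alignment point.  Events whose window does not fit
    inside the recording are excluded and counted in ``n_excluded``.
    """
    dff = np.atleast_2d(np.asarray(dff, dtype=float))
    n_obj, n = dff.shape
    pre, post = window_s
    n_pre, n_post = int(round(pre * fs)), int(round(post * fs))
    t_rel = np.arange(-n_pre, n_post + 1) / fs
    anchor_col = "onset_s" if align_to == "onset" else "offset_s"
    keep_rows, slabs = [], []
    for idx, ev in events.iterrows():
        c = int(round(ev[anchor_col] * fs))
        if c - n_pre < 0 or c + n_post + 1 > n:
            continue
        keep_rows.append(idx)
        slabs.append(dff[:, c - n_pre:c + n_post + 1])
    n_excluded = len(events) - len(keep_rows)
    if not slabs:
        warnings.warn("no events fully inside the recording window")
        data = np.zeros((n_obj, 0, len(t_rel)))
        kept = events.iloc[[]][EVENT_COLUMNS]
    else:
        data = np.stack(slabs, axis=1)
        kept = events.loc[keep_rows, EVENT_COLUMNS].reset_index(drop=True)
    return AlignedTensor(data=data, t=t_rel, events=kept, fs=fs,
                         align_to=align_to, n_excluded=n_excluded)


def aligned_mean_ci(at: AlignedTensor, n_boot: int = 1000, ci: float = 95.0,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-object mean aligned response with a percentile-bootstrap band.

    The bootstrap resamples events with replacement (``n_boot`` draws).
    Returns ``(mean, lo, hi)``, each (n_objects, n_time).
    """
    rng = rng or np.random.default_rng(0)
    x = at.data
    n_ev = x.shape[1]
    mean = x.mean(axis=1) if n_ev else np.zeros((x.shape[0], x.shape[2]))
    if n_ev == 0:
        return mean, mean, mean
    idx = rng.integers(0, n_ev, size=(n_boot, n_ev))
    boots = x[:, idx, :].mean(axis=2)          # (n_obj, n_boot, n_t)
    a = (100.0 - ci) / 2.0
    lo = np.percentile(boots, a, axis=1)
    hi = np.percentile(boots, 100.0 - a, axis=1)
    return mean, lo, hi


# ----------------------------------------------------------------------
# responsiveness with shuffle-calibrated significance
# ----------------------------------------------------------------------

@dataclass
class ResponsivenessResult:
    """Shuffle-calibrated event responsiveness.

    ``frac_events_per_object[i]``: fraction of events on which object ``i``
    showed a significant dF/F increase (post vs pre window);
    ``frac_objects_per_event[e]``: fraction of objects responding on event
    ``e``; ``null_fractions``: responding fractions obtained on held-out
    circular-shift shuffles, the empirical null of the observed fractions.
    """

    frac_events_per_object: np.ndarray
    frac_objects_per_event: np.ndarray
    significant: np.ndarray          # (n_obj, n_ev) bool
    t_obs: np.ndarray
    parametric_p: np.ndarray
    thresholds: np.ndarray           # per-object null t quantile at 1-alpha
    null_fractions: np.ndarray
    alpha: float
    n_skipped: int = 0


def _window_stats(x2: np.ndarray, s1: np.ndarray, s2: np.ndarray,
                  starts: np.ndarray, length: int):
    """Mean and unbiased variance of windows [start, start+length) per object.

    ``s1``/``s2`` are cumulative sums of the doubled trace and its square,
    shape (n_obj, 2N+1); ``starts`` is (n_obj, ...) integer start indices in
    [0, N).  Returns arrays shaped like ``starts``.
    """
    idx0 = starts
    idx1 = starts + length
    tot = np.take_along_axis(s1, idx1, axis=-1) - np.take_along_axis(s1, idx0, axis=-1)
    tot2 = np.take_along_axis(s2, idx1, axis=-1) - np.take_along_axis(s2, idx0, axis=-1)
    m = tot / length
    v = (tot2 - length * m ** 2) / max(length - 1, 1)
    return m, np.maximum(v, 0.0)


def responsiveness(dff: np.ndarray, fs: float, events: pd.DataFrame,
                   pre_window: tuple[float, float] = (-1.0, 0.0),
                   post_window: tuple[float, float] = (0.0, 1.0),
                   alpha: float = 0.01, n_shuffles: int = 1000,
                   min_shift_s: float = 10.0,
                   rng: np.random.Generator | None = None,
                   ) -> ResponsivenessResult:
    """Per-object probability of responding to behavioral events.

    The statistic per (object, event) is a Welch t comparing dF/F samples
    in ``post_window`` against ``pre_window`` around event onset.
    Significance thresholds are per-object ``1 - alpha`` quantiles of the
    same statistic computed after circularly shifting the trace by a random
    offset of at least ``min_shift_s`` (half of ``n_shuffles``); the other
    half of the shuffles is held out to provide the null distribution of
    responding fractions.  Parametric (Welch) p-values are also reported.
    """
    dff = np.atleast_2d(np.asarray(dff, dtype=float))
    rng = rng or np.random.default_rng(0)
    n_obj, n = dff.shape
    onsets = np.asarray([int(round(s * fs)) for s in events["onset_s"]])
    if len(onsets) < 2:
        raise ValueError("need at least two events for responsiveness")
    i_pre0 = int(round(pre_window[0] * fs))
    i_pre1 = int(round(pre_window[1] * fs))
    i_post0 = int(round(post_window[0] * fs))
    i_post1 = int(round(post_window[1] * fs))
    len_pre, len_post = i_pre1 - i_pre0, i_post1 - i_post0
    if len_pre < 2 or len_post < 2:
        raise ValueError("windows must contain at least two samples")

    doubled = np.concatenate([dff, dff], axis=1)
    s1 = np.concatenate([np.zeros((n_obj, 1)), np.cumsum(doubled, axis=1)], axis=1)
    s2 = np.concatenate([np.zeros((n_obj, 1)),
                         np.cumsum(doubled ** 2, axis=1)], axis=1)

    def _t_for(starts_pre: np.ndarray, starts_post: np.ndarray):
        m_pre, v_pre = _window_stats(doubled, s1, s2, starts_pre, len_pre)
        m_post, v_post = _window_stats(doubled, s1, s2, starts_post, len_post)
        se2 = v_post / len_post + v_pre / len_pre
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (m_post - m_pre) / np.sqrt(se2)
            dof = se2 ** 2 / (
                (v_post / len_post) ** 2 / (len_post - 1)
                + (v_pre / len_pre) ** 2 / (len_pre - 1))
        return t, dof

    base_pre = (onsets + i_pre0) % n
    base_post = (onsets + i_post0) % n
    t_obs, dof = _t_for(base_pre[None, :].repeat(n_obj, 0),
                        base_post[None, :].repeat(n_obj, 0))
    with np.errstate(invalid="ignore"):
        parametric_p = stats.t.sf(t_obs, np.maximum(dof, 1.0))

    min_shift = int(round(min_shift_s * fs))
    if n <= 2 * min_shift:
        raise ValueError("recording too short for the minimum shuffle shift")
    shifts = rng.integers(min_shift, n - min_shift,
                          size=(n_obj, n_shuffles))
    # t statistics under the null, chunked over shuffles to bound memory
    t_null = np.empty((n_obj, n_shuffles, len(onsets)))
    chunk = max(1, int(2e7 // (n_obj * len(onsets))))
    for k0 in range(0, n_shuffles, chunk):
        sh = shifts[:, k0:k0 + chunk, None]
        sp = (base_pre[None, None, :] + sh) % n
        spo = (base_post[None, None, :] + sh) % n
        nb = sp.shape[1]
        tt, _ = _t_for(sp.reshape(n_obj, -1), spo.reshape(n_obj, -1))
        t_null[:, k0:k0 + chunk, :] = tt.reshape(n_obj, nb, len(onsets))

    half = n_shuffles // 2
    calib, held = t_null[:, :half, :], t_null[:, half:, :]
    if alpha >= 1.0:
        thresholds = np.full(n_obj, -np.inf)
    else:
        thresholds = np.nanquantile(calib.reshape(n_obj, -1), 1.0 - alpha,
                                    axis=1)
    significant = t_obs > thresholds[:, None]
    n_skipped = int(np.sum(~np.isfinite(t_obs)))
    with np.errstate(invalid="ignore"):
        null_sig = held > thresholds[:, None, None]
    null_fractions = null_sig.mean(axis=(0, 2))

    return ResponsivenessResult(
        frac_events_per_object=significant.mean(axis=1),
        frac_objects_per_event=significant.mean(axis=0),
        significant=significant,
        t_obs=t_obs,
        parametric_p=parametric_p,
        thresholds=thresholds,
        null_fractions=null_fractions,
        alpha=alpha,
        n_skipped=n_skipped,
    )


# ----------------------------------------------------------------------
# duration stratification and sustainedness
# ----------------------------------------------------------------------

def duration_stratified(at: AlignedTensor,
                        bins: tuple = DURATION_BINS) -> dict:
    """Event counts and mean aligned responses per duration bin.

    Bins are half-open ``[lo, hi)``; durations falling in gaps between the
    bins (e.g. 4-5 s with the default bins) are assigned to none.
    """
    out = {}
    durs = at.events["duration_s"].to_numpy()
    for lo, hi in bins:
        label = f"{lo:g}-{hi:g}s" if np.isfinite(hi) else f">{lo:g}s"
        mask = (durs >= lo) & (durs < hi)
        entry = {"count": int(mask.sum()), "mean": None}
        if mask.any():
            entry["mean"] = at.data[:, mask, :].mean(axis=1)
        out[label] = entry
    return out


def sustainedness_index(mean_response: np.ndarray, t: np.ndarray,
                        peak_window: tuple[float, float] | None = None,
                        late_window: tuple[float, float] = (2.0, 3.0)) -> float:
    """Late response as a fraction of the peak.

    ``index = mean(response in late_window) / max(response in peak_window)``
    where ``peak_window`` defaults to onset through the end of the late
    window.  NaN (flagged) if the peak is not positive.
    """
    mean_response = np.asarray(mean_response, dtype=float)
    if peak_window is None:
        peak_window = (0.0, late_window[1])
    pk = mean_response[(t >= peak_window[0]) & (t <= peak_window[1])]
    lt = mean_response[(t >= late_window[0]) & (t <= late_window[1])]
    if len(pk) == 0 or len(lt) == 0:
        raise ValueError("response does not cover the requested windows")
    peak = pk.max()
    if peak <= 0:
        warnings.warn("peak response not positive; sustainedness undefined")
        return np.nan
    return float(lt.mean() / peak)


def sustainedness_test(at: AlignedTensor,
                       peak_window: tuple[float, float] | None = None,
                       late_window: tuple[float, float] = (2.0, 3.0)) -> dict:
    """Sustainedness of the population response, with a paired event-level test.

    The index is computed on the grand mean response; the paired t test
    compares, across events, the population-mean late value against the
    population-mean peak (the statistic the 93%-vs-11% sustained/transient
    contrast is built on).
    """
    grand = at.data.mean(axis=(0, 1))
    index = sustainedness_index(grand, at.t, peak_window, late_window)
    per_event = at.data.mean(axis=0)          # (n_ev, n_t)
    if peak_window is None:
        peak_window = (0.0, late_window[1])
    pk_mask = (at.t >= peak_window[0]) & (at.t <= peak_window[1])
    lt_mask = (at.t >= late_window[0]) & (at.t <= late_window[1])
    peaks = per_event[:, pk_mask].max(axis=1)
    lates = per_event[:, lt_mask].mean(axis=1)
    if len(peaks) >= 2:
        t_stat, p = stats.ttest_rel(lates, peaks)
    else:
        t_stat, p = np.nan, np.nan
    return {"index": index, "t": float(t_stat), "p": float(p),
            "n_events": int(at.n_events)}
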