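"""Behavioral traces, motion energy, and behavioral-event segmentation.

Behavioral state of a head-fixed mouse is read out from three channels:
wheel speed (cm/s, rotary encoder), pupil diameter, and facial motion
energy computed from video.  Movement events are segmented into whisker
*twitches* (brief, <0.5 s), *whisk bouts* (>1 s), and *walk bouts*
(speed >2.5 cm/s sustained for at least 2 s), each required to be flanked
by at least 1 s of stillness so that event-aligned averages start from a
quiescent baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EVENT_COLUMNS = ["kind", "onset_s", "offset_s", "duration_s"]

#: Closed set of behavioral event kinds.
EVENT_KINDS = ("twitch", "whisk", "walk")


def empty_event_table() -> pd.DataFrame:
    """An EventTable with no rows (kind, onset_s, offset_s, duration_s)."""
    return pd.DataFrame(
        {
            "kind": pd.Series(dtype=str),
            "onset_s": pd.Series(dtype=float),
            "offset_s": pd.Series(dtype=float),
            "duration_s": pd.Series(dtype=float),
        }
    )


@dataclass
class BehaviorTraces:
    """Uniformly sampled behavioral channels at the video rate.

    Parameters
    ----------
    time_s : array
        Sample times in seconds; must be uniformly spaced.
    wheel_speed : array
        Rotational wheel speed in cm/s (rectified, nonnegative).
    pupil : array
        Pupil diameter; raw units until :func:`normalize_pupil` is applied.
    mei_whisker, mei_snout, mei_jaw, mei_fullface : array
        Motion energy index traces (unitless, nonnegative).  The whisker
        trace is min-max normalized to [0, 1] per session before event
        detection.
    """

    time_s: np.ndarray
    wheel_speed: np.ndarray
    pupil: np.ndarray
    mei_whisker: np.ndarray
    mei_snout: np.ndarray
    mei_jaw: np.ndarray
    mei_fullface: np.ndarray
    wheel_vertical: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        n = len(self.time_s)
        for name in ("wheel_speed", "pupil", "mei_whisker", "mei_snout",
                     "mei_jaw", "mei_fullface"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match time_s")
        if n >= 2:
            dt = np.diff(self.time_s)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("time_s must be uniformly sampled")

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / float(self.time_s[1] - self.time_s[0])

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "time_s": self.time_s,
            "wheel_speed": self.wheel_speed,
            "pupil": self.pupil,
            "mei_whisker": self.mei_whisker,
            "mei_snout": self.mei_snout,
            "mei_jaw": self.mei_jaw,
            "mei_fullface": self.mei_fullface,
        }
        if self.wheel_vertical is not None:
            cols["wheel_vertical"] = self.wheel_vertical
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BehaviorTraces":
        kwargs = {}
        if "wheel_vertical" in df.columns:
            kwargs["wheel_vertical"] = df["wheel_vertical"].to_numpy()
        return cls(
            time_s=df["time_s"].to_numpy(),
            wheel_speed=df["wheel_speed"].to_numpy(),
            pupil=df["pupil"].to_numpy(),
            mei_whisker=df["mei_whisker"].to_numpy(),
            mei_snout=df["mei_snout"].to_numpy(),
            mei_jaw=df["mei_jaw"].to_numpy(),
            mei_fullface=df["mei_fullface"].to_numpy(),
            **kwargs,
        )


def motion_energy(frames: np.ndarray, roi: tuple[int, int, int, int]) -> np.ndarray:
    """Motion energy index of a video region.

    The MEI is the sum of the absolute change in pixel intensity within the
    region between adjacent frames.  Sample ``i`` of the output is the energy
    between frames ``i`` and ``i+1`` and is attributed to frame ``i+1``, the
    frame where the change is observed.

    Parameters
    ----------
    frames : (n_frames, height, width) array
        Image stack; at least two frames.
    roi : (row0, row1, col0, col1)
        Half-open rectangle within the frame bounds.

    Returns
    -------
    (n_frames - 1,) array of nonnegative motion energies.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a (n_frames, h, w) stack with >= 2 frames")
    r0, r1, c0, c1 = roi
    h, w = frames.shape[1:]
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"roi {roi} empty or outside frame bounds {(h, w)}")
    patch = frames[:, r0:r1, c0:c1].astype(float)
    return np.abs(np.diff(patch, axis=0)).sum(axis=(1, 2))


def normalize_pupil(raw: np.ndarray) -> np.ndarray:
    """Normalize a pupil-diameter trace to its session maximum.

    NaN samples are preserved; the maximum is taken over finite samples.
    """
    raw = np.asarray(raw, dtype=float)
    finite = np.isfinite(raw)
    if not finite.any():
        raise ValueError("pupil trace contains no finite samples")
    mx = raw[finite].max()
    if mx <= 0:
        raise ValueError("session max pupil diameter must be positive")
    return raw / mx


def normalize_whisker_mei(mei: np.ndarray) -> np.ndarray:
    """Min-max normalize a whisker-pad MEI trace to [0, 1] per session.

    Idempotent for a trace already spanning [0, 1].
    """
    mei = np.asarray(mei, dtype=float)
    lo, hi = np.nanmin(mei), np.nanmax(mei)
    if hi <= lo:
        raise ValueError("whisker MEI trace is constant; cannot normalize")
    return (mei - lo) / (hi - lo)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of contiguous True runs."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return []
    d = np.diff(m.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if m[0]:
        starts = np.r_[0, starts]
    if m[-1]:
        stops = np.r_[stops, len(m)]
    return list(zip(starts.tolist(), stops.tolist()))


def _gated_runs(mask: np.ndarray, gate_mask: np.ndarray, gap_n: int) -> list[tuple[int, int]]:
    """Runs of `mask` flanked by >= gap_n samples where `gate_mask` is False.

    Runs whose flanking window would extend past the recording edge cannot be
    verified and are dropped.
    """
    n = len(mask)
    out = []
    for i0, i1 in _runs(mask):
        if i0 - gap_n < 0 or i1 + gap_n > n:
            continue
        if gate_mask[i0 - gap_n:i0].any() or gate_mask[i1:i1 + gap_n].any():
            continue
        out.append((i0, i1))
    return out


def detect_events(
    b: BehaviorTraces,
    whisk_thresh: float = 0.20,
    walk_speed: float = 2.5,
    walk_min_s: float = 2.0,
    whisk_min_s: float = 1.0,
    twitch_max_s: float = 0.5,
    still_gap_s: float = 1.0,
    strict: bool = False,
) -> pd.DataFrame:
    """Segment behavior into twitches, whisk bouts, and walk bouts.

    Whisker events are supra-threshold runs of the session-normalized
    whisker-pad MEI: runs shorter than ``twitch_max_s`` are twitches, runs
    longer than ``whisk_min_s`` are whisk bouts, and runs in between are
    classified as neither (they still count as movement for the stillness
    gate).  Walk bouts are runs of wheel speed above ``walk_speed`` lasting
    at least ``walk_min_s``; they are detected independently of whisker
    events, so walk and whisk events may overlap.

    Every retained event must be preceded and followed by at least
    ``still_gap_s`` of stillness.  By default each event kind is gated on
    its own variable (whisker MEI below threshold for twitch/whisk, speed
    below ``walk_speed`` for walk); with ``strict=True`` all kinds are gated
    on joint stillness of both variables.

    Returns an EventTable: a DataFrame with columns
    ``kind, onset_s, offset_s, duration_s`` sorted by onset.
    """
    dt = 1.0 / b.fs
    if dt > still_gap_s:
        raise ValueError(
            f"sampling interval {dt:.3g} s exceeds still_gap_s={still_gap_s}; "
            "the stillness gate cannot be resolved"
        )
    gap_n = int(round(still_gap_s * b.fs))
    t = b.time_s

    w = normalize_whisker_mei(b.mei_whisker)
    whisk_mask = w > whisk_thresh
    walk_mask = b.wheel_speed > walk_speed
    either = whisk_mask | walk_mask

    whisk_gate = either if strict else whisk_mask
    walk_gate = either if strict else walk_mask

    rows: list[dict] = []
    for i0, i1 in _gated_runs(whisk_mask, whisk_gate, gap_n):
        dur = (i1 - i0) * dt
        if dur < twitch_max_s:
            kind = "twitch"
        elif dur > whisk_min_s:
            kind = "whisk"
        else:
            continue  # 0.5-1 s band: movement, but neither twitch nor whisk
        rows.append(dict(kind=kind, onset_s=t[i0], offset_s=t[i0] + dur,
                         duration_s=dur))
    for i0, i1 in _gated_runs(walk_mask, walk_gate, gap_n):
        dur = (i1 - i0) * dt
        if dur < walk_min_s - 1e-9:
            continue
        rows.append(dict(kind="walk", onset_s=t[i0], offset_s=t[i0] + dur,
                         duration_s=dur))

    if not rows:
        return empty_event_table()
    return (
        pd.DataFrame(rows, columns=EVENT_COLUMNS)
        .sort_values("onset_s", kind="stable")
        .reset_index(drop=True)
    )


def onset_lag_stats(events: pd.DataFrame, max_lead_s: float = 6.0) -> dict:
    """Whisk-to-walk onset lags: walk onset minus the onset of the
    overlapping or immediately preceding whisk bout.

    Walk bouts with no whisk onset within ``max_lead_s`` before their onset
    are flagged with a NaN lag.

    Returns a dict with per-bout ``lags`` (DataFrame) and summary statistics.
    """
    walks = events[events["kind"] == "walk"]
    whisks = events[events["kind"] == "whisk"]
    rows = []
    for _, wk in walks.iterrows():
        cand = whisks[
            (whisks["onset_s"] <= wk["onset_s"])
            & (whisks["onset_s"] >= wk["onset_s"] - max_lead_s)
        ]
        if len(cand):
            lag = wk["onset_s"] - cand["onset_s"].iloc[-1]
        else:
            lag = np.nan
        rows.append(dict(walk_onset_s=wk["onset_s"], lag_s=lag))
    lags = pd.DataFrame(rows, columns=["walk_onset_s", "lag_s"])
    vals = lags["lag_s"].dropna().to_numpy()
    return {
        "lags": lags,
        "n_walk": len(lags),
        "n_undefined": int(lags["lag_s"].isna().sum()),
        "mean_lag_s": float(np.mean(vals)) if len(vals) else np.nan,
        "median_lag_s": float(np.median(vals)) if len(vals) else np.nan,
    }
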