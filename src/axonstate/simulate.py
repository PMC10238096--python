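"""Synthetic imaging sessions with known ground truth.

The generator emulates the statistical structure of a head-fixed mouse
two-photon session: a semi-Markov behavioral-state process (still /
twitch / whisk / walk) at the video rate drives both the behavioral
channels (wheel speed, whisker-pad and other facial motion energy, pupil)
and a *common* activity drive shared by all simulated axons.  Each axon
additionally carries a private, slowly varying drive.  Axonal activity is
rectified, optionally attenuated after one second of sustained movement
(``sustain_frac`` mimics the sustained cholinergic vs transient
noradrenergic response profile), passed through a calcium-indicator
kernel (difference of exponentials, unit peak), sampled at the imaging
frame rate, and corrupted with Gaussian imaging noise.

Fixture populations mirror the experimental controls: *same-axon pairs*
(two traces rendered from a single drive with independent noise),
autofluorescent *blebs* (constant plus noise), and *mCherry* objects
(constant plus a shared low-frequency motion artifact scaled by per-object
gains drawn near zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .behavior import BehaviorTraces, empty_event_table
from .session import Session

STATE_NAMES = ("still", "twitch", "whisk", "walk")

#: Baseline common-drive amplitude per behavioral state.
STATE_AMPLITUDE = {"still": 0.0, "twitch": 0.8, "whisk": 1.0, "walk": 1.3}


@dataclass
class SimConfig:
    """Parameters of a simulated session.

    Durations, rates and kernel times are in seconds / Hz; drive amplitudes
    and SDs are unitless (the fluorescence scale is set separately by the
    per-object baseline and gain).
    """

    duration_s: float = 600.0
    frame_rate_hz: float = 15.0       # imaging rate, 10-30 Hz
    video_rate_hz: float = 30.0       # behavioral video rate
    n_axons: int = 12
    n_rois: int = 4
    roi_positions_mm: np.ndarray | None = None  # (n_rois, 2); default 0-4 mm line
    roi_size_um: float = 200.0

    common_gain: float | np.ndarray = 1.0   # per-axon coupling to shared drive
    private_sd: float | np.ndarray = 0.5    # per-axon private drive SD
    private_bandwidth_hz: float = 0.5       # low-pass corner of private drives
    noise_sd: float = 0.05                  # imaging noise SD (dF/F units)
    noise_highpass_hz: float | None = None  # shape imaging noise above this cutoff
    behavior_noise_sd: float = 0.02         # jitter on behavioral channels

    kernel_rise_s: float = 0.15
    kernel_decay_s: float = 1.5
    sustain_frac: float = 0.9               # drive retained after 1 s of movement
    sustain_onset_s: float = 1.0

    # semi-Markov state process: event rates (per second of still time) and
    # duration bounds.  The field's literature does not pin these
    # distributions; uniform durations within the stated bounds are used.
    state_rates: dict = field(default_factory=lambda: {
        "twitch": 0.05, "whisk": 0.03, "walk": 0.012})
    twitch_dur_s: tuple[float, float] = (0.1, 0.45)
    whisk_dur_s: tuple[float, float] = (1.2, 6.0)
    walk_dur_s: tuple[float, float] = (2.2, 6.0)
    whisk_lead_s: tuple[float, float] = (0.6, 4.9)   # whisk starts before walk
    whisk_tail_s: tuple[float, float] = (1.0, 3.0)   # whisk persists after walk
    min_gap_s: float = 1.2                            # stillness between bouts
    mean_still_s: float = 8.0

    pupil_tau_s: float = 4.0
    face_leakage: float = 0.5               # whisker MEI leaking into snout/jaw
    solo_face_rate: float = 0.02            # rare solo jaw/snout transients (per s)

    population: str = "ACh"
    n_same_axon_pairs: int = 2
    n_blebs: int = 2
    n_mcherry: int = 0
    mcherry_gain_sd: float = 0.05
    planted_pairs: tuple = ()               # ((axon_i, axon_j, shared_sd), ...)

    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.frame_rate_hz <= 2.0:
            raise ValueError(
                "frame_rate_hz must exceed 2 Hz (twice the 1 Hz analysis band)")
        if self.video_rate_hz <= 0:
            raise ValueError("video_rate_hz must be positive")
        if self.kernel_rise_s <= 0 or self.kernel_decay_s <= 0:
            raise ValueError("kernel times must be positive")
        if self.kernel_rise_s >= self.kernel_decay_s:
            raise ValueError("kernel_rise_s must be smaller than kernel_decay_s")
        if not 0.0 <= self.sustain_frac <= 1.0:
            raise ValueError("sustain_frac must be in [0, 1]")
        if np.any(np.asarray(self.noise_sd) < 0) or np.any(np.asarray(self.private_sd) < 0):
            raise ValueError("SDs must be nonnegative")
        if any(r < 0 for r in self.state_rates.values()):
            raise ValueError("state rates must be nonnegative")
        g = np.asarray(self.common_gain, dtype=float)
        if not np.all(np.isfinite(g)):
            raise ValueError("common_gain must be finite")

    def roi_xy(self) -> np.ndarray:
        if self.roi_positions_mm is not None:
            pos = np.asarray(self.roi_positions_mm, dtype=float)
            if pos.shape != (self.n_rois, 2):
                raise ValueError("roi_positions_mm must have shape (n_rois, 2)")
            return pos
        x = np.linspace(0.0, 4.0, self.n_rois) if self.n_rois > 1 else np.array([0.0])
        return np.c_[x, np.zeros_like(x)]


@dataclass
class GroundTruth:
    """Latent state of a simulated session."""

    t_video: np.ndarray
    state_sequence: np.ndarray            # per-video-frame label
    true_events: pd.DataFrame             # kind, onset_s, offset_s, duration_s
    drive_common: np.ndarray | None = None
    drive_private: np.ndarray | None = None   # (n_axons, n_video)


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stream]))


def _snap(x: float, fs: float) -> int:
    return int(round(x * fs))


def simulate_state_sequence(cfg: SimConfig, script: list[dict] | None = None) -> GroundTruth:
    """Draw (or script) the behavioral-state sequence at the video rate.

    The process is semi-Markov: still intervals of at least ``min_gap_s``
    separate movement bouts, whose kind is drawn from ``state_rates`` and
    whose duration is uniform within the per-kind bounds.  A walk bout is
    always embedded in a whisk bout that starts 0.5-5 s before walk onset
    and persists 1-3 s after walk offset.  All times are snapped to the
    video frame grid.

    ``script`` entries (dicts with ``kind``, ``onset_s``, ``duration_s`` and
    optionally ``lead_s``/``tail_s`` for walk, ``speed``/``level``) bypass
    the random draw; scripted events closer together than ``min_gap_s`` are
    re-spaced to restore the stillness gap.
    """
    fs = cfg.video_rate_hz
    n = int(round(cfg.duration_s * fs))
    t = np.arange(n) / fs
    states = np.full(n, "still", dtype=object)
    rng = _rng(cfg, 0)
    margin = max(2.0, cfg.min_gap_s + 2.0 / fs)

    bouts: list[dict] = []
    if script is not None:
        prev_end = margin
        for ev in script:
            ev = dict(ev)
            kind = ev["kind"]
            onset = float(ev["onset_s"])
            dur = float(ev["duration_s"])
            if kind == "walk":
                lead = float(ev.get("lead_s", rng.uniform(*cfg.whisk_lead_s)))
                tail = float(ev.get("tail_s", rng.uniform(*cfg.whisk_tail_s)))
                start = onset - lead
            else:
                lead = tail = 0.0
                start = onset
            if start < prev_end + (cfg.min_gap_s if bouts else 0.0):
                shift = prev_end + cfg.min_gap_s - start
                start += shift
                onset += shift
            end = (onset + dur + tail) if kind == "walk" else (onset + dur)
            bouts.append(dict(kind=kind, onset=onset, dur=dur, lead=lead,
                              tail=tail,
                              speed=ev.get("speed", np.nan),
                              level=ev.get("level", np.nan)))
            prev_end = end
    else:
        rates = cfg.state_rates
        total = sum(rates.values())
        cursor = margin - cfg.min_gap_s
        if total > 0:
            kinds = list(rates)
            probs = np.array([rates[k] for k in kinds]) / total
            while True:
                gap = cfg.min_gap_s + rng.exponential(1.0 / total)
                gap = min(gap, cfg.min_gap_s + 3 * cfg.mean_still_s)
                kind = rng.choice(kinds, p=probs)
                if kind == "twitch":
                    dur = rng.uniform(*cfg.twitch_dur_s)
                    lead = tail = 0.0
                elif kind == "whisk":
                    dur = rng.uniform(*cfg.whisk_dur_s)
                    lead = tail = 0.0
                else:
                    dur = rng.uniform(*cfg.walk_dur_s)
                    lead = rng.uniform(*cfg.whisk_lead_s)
                    tail = rng.uniform(*cfg.whisk_tail_s)
                start = cursor + gap
                onset = start + lead
                end = onset + dur + tail
                if end > cfg.duration_s - margin:
                    break
                bouts.append(dict(kind=kind, onset=onset, dur=dur, lead=lead,
                                  tail=tail, speed=np.nan, level=np.nan))
                cursor = end

    rows = []
    for b in bouts:
        kind = b["kind"]
        i_on = _snap(b["onset"], fs)
        n_dur = max(1, _snap(b["dur"], fs))
        # keep snapped durations inside the classification bands
        if kind == "twitch":
            n_dur = min(n_dur, int(np.ceil(0.5 * fs)) - 1)
        elif kind == "whisk":
            n_dur = max(n_dur, int(np.floor(1.0 * fs)) + 2)
        else:
            n_dur = max(n_dur, int(np.ceil(2.0 * fs)) + 1)
        i_off = i_on + n_dur
        if kind == "walk":
            n_lead = max(_snap(b["lead"], fs), int(np.ceil(0.5 * fs)))
            n_tail = max(1, _snap(b["tail"], fs))
            iw_on, iw_off = i_on - n_lead, i_off + n_tail
            if iw_on < 0 or iw_off > n:
                continue
            states[iw_on:iw_off] = "whisk"
            states[i_on:i_off] = "walk"
            rows.append(dict(kind="whisk", onset_s=t[iw_on],
                             offset_s=iw_off / fs,
                             duration_s=(iw_off - iw_on) / fs,
                             speed=np.nan, level=b["level"]))
            rows.append(dict(kind="walk", onset_s=t[i_on], offset_s=i_off / fs,
                             duration_s=n_dur / fs,
                             speed=b["speed"], level=np.nan))
        else:
            if i_on < 0 or i_off > n:
                continue
            states[i_on:i_off] = kind
            rows.append(dict(kind=kind, onset_s=t[i_on], offset_s=i_off / fs,
                             duration_s=n_dur / fs,
                             speed=np.nan, level=b["level"]))

    if rows:
        events = pd.DataFrame(rows).sort_values("onset_s").reset_index(drop=True)
    else:
        events = empty_event_table().assign(speed=pd.Series(dtype=float),
                                            level=pd.Series(dtype=float))
    return GroundTruth(t_video=t, state_sequence=np.asarray(states),
                       true_events=events)


def _lowpass(x: np.ndarray, fs: float, cutoff: float, order: int = 2) -> np.ndarray:
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def _first_order_lag(x: np.ndarray, fs: float, tau_s: float) -> np.ndarray:
    """Causal single-pole low-pass (exponential smoothing)."""
    alpha = 1.0 - np.exp(-1.0 / (fs * tau_s))
    b, a = [alpha], [1.0, -(1.0 - alpha)]
    return sps.lfilter(b, a, x)


def state_drive(gt: GroundTruth, cfg: SimConfig) -> np.ndarray:
    """Common drive implied by the state sequence, with sustain attenuation.

    Frames more than ``sustain_onset_s`` after the onset of a contiguous
    movement run are attenuated by ``1 - sustain_frac``.
    """
    amp = np.array([STATE_AMPLITUDE[s] for s in gt.state_sequence])
    fs = cfg.video_rate_hz
    moving = gt.state_sequence != "still"
    d = np.diff(moving.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if moving[0]:
        starts = np.r_[0, starts]
    if moving[-1]:
        stops = np.r_[stops, len(moving)]
    n_sustain = int(round(cfg.sustain_onset_s * fs))
    for i0, i1 in zip(starts, stops):
        if i1 - i0 > n_sustain:
            amp[i0 + n_sustain:i1] *= cfg.sustain_frac
    return amp


def render_behavior(gt: GroundTruth, cfg: SimConfig) -> BehaviorTraces:
    """Render behavioral channels from the state sequence at the video rate.

    Wheel speed exceeds the 2.5 cm/s walking threshold exactly over walk
    frames; whisker-pad MEI is high over twitch/whisk/walk frames; snout,
    jaw and full-face MEI leak from the whisker trace with rare solo
    transients; pupil diameter follows the state drive through a
    multi-second first-order lag.
    """
    rng = _rng(cfg, 1)
    fs = cfg.video_rate_hz
    n = len(gt.t_video)
    jit = cfg.behavior_noise_sd
    moving = np.isin(gt.state_sequence, ("twitch", "whisk", "walk"))
    walking = gt.state_sequence == "walk"

    # whisker-pad MEI: per-bout level, crisp threshold crossings
    whisker = 0.05 + np.clip(jit * np.abs(rng.standard_normal(n)), 0, 0.06)
    for _, ev in gt.true_events.iterrows():
        if ev["kind"] == "walk":
            continue
        i0, i1 = _snap(ev["onset_s"], fs), _snap(ev["offset_s"], fs)
        level = ev.get("level", np.nan)
        if not np.isfinite(level):
            level = rng.uniform(0.45, 0.9)
        seg = level + jit * rng.standard_normal(i1 - i0)
        whisker[i0:i1] = np.clip(seg, 0.35, 1.2)
    # twitches are separate rows too (handled above since kind != walk)

    speed = np.clip(jit * 10 * np.abs(rng.standard_normal(n)), 0, 1.5)
    for _, ev in gt.true_events.iterrows():
        if ev["kind"] != "walk":
            continue
        i0, i1 = _snap(ev["onset_s"], fs), _snap(ev["offset_s"], fs)
        sp = ev.get("speed", np.nan)
        if not np.isfinite(sp):
            sp = rng.uniform(3.5, 6.0)
        seg = sp + 5 * jit * rng.standard_normal(i1 - i0)
        speed[i0:i1] = np.clip(seg, 3.0, 12.0)

    # snout / jaw: leakage from the whisker trace plus rare solo transients
    def _solo(rate: float) -> np.ndarray:
        out = np.zeros(n)
        n_ev = rng.poisson(rate * cfg.duration_s)
        for _ in range(n_ev):
            i0 = rng.integers(0, n)
            ln = max(1, _snap(rng.uniform(0.3, 1.0), fs))
            out[i0:i0 + ln] += rng.uniform(0.3, 0.6)
        return out

    base = lambda: np.clip(jit * np.abs(rng.standard_normal(n)), 0, 0.08)
    snout = cfg.face_leakage * whisker + _solo(cfg.solo_face_rate) + base()
    jaw = cfg.face_leakage * 0.8 * whisker + _solo(cfg.solo_face_rate) + base()
    fullface = 0.5 * whisker + 0.25 * snout + 0.25 * jaw + base()

    drive = state_drive(gt, cfg)
    pupil = 2.0 + 1.0 * _first_order_lag(drive, fs, cfg.pupil_tau_s)
    if jit > 0:
        pupil = pupil + 0.5 * _lowpass(jit * rng.standard_normal(n), fs, 0.1)

    vertical = 0.2 * walking.astype(float) + jit * np.abs(rng.standard_normal(n))

    return BehaviorTraces(
        time_s=gt.t_video, wheel_speed=speed, pupil=pupil,
        mei_whisker=whisker, mei_snout=snout, mei_jaw=jaw,
        mei_fullface=fullface, wheel_vertical=vertical,
    )


def calcium_kernel(cfg: SimConfig, fs: float) -> np.ndarray:
    """Difference-of-exponentials indicator kernel, normalized to unit peak."""
    if cfg.kernel_rise_s <= 0 or cfg.kernel_decay_s <= 0:
        raise ValueError("kernel times must be positive")
    t = np.arange(0, 8 * cfg.kernel_decay_s, 1.0 / fs)
    k = np.exp(-t / cfg.kernel_decay_s) - np.exp(-t / cfg.kernel_rise_s)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate kernel")
    return k / peak


def _private_drive(rng: np.random.Generator, n: int, fs: float,
                   sd: float, bandwidth_hz: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    x = _lowpass(rng.standard_normal(n), fs, bandwidth_hz)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def render_fluorescence(gt: GroundTruth, cfg: SimConfig) -> tuple[np.ndarray, pd.DataFrame]:
    """Render raw-like fluorescence traces and object metadata.

    Per-axon drive is ``common_gain * drive_common + drive_private``,
    rectified, convolved with the indicator kernel, sampled at the imaging
    frame rate, and embedded in a raw fluorescence scale
    ``F = baseline * (1 + gain * activity + noise)``.  Also emits same-axon
    pair traces, bleb and mCherry control objects with population labels.

    Returns ``(F, objects)`` where ``F`` is (n_objects, n_frames) and
    ``objects`` has columns ``object_id, population, roi_id, pair_id``.
    """
    rng = _rng(cfg, 2)
    fs_v = cfg.video_rate_hz
    n_v = len(gt.t_video)
    n_f = int(round(cfg.duration_s * cfg.frame_rate_hz))
    t_f = np.arange(n_f) / cfg.frame_rate_hz
    kern = calcium_kernel(cfg, fs_v)

    common = state_drive(gt, cfg)
    gains = np.broadcast_to(np.asarray(cfg.common_gain, dtype=float),
                            (cfg.n_axons,)).copy()
    sds = np.broadcast_to(np.asarray(cfg.private_sd, dtype=float),
                          (cfg.n_axons,)).copy()

    private = np.stack([
        _private_drive(rng, n_v, fs_v, sds[i], cfg.private_bandwidth_hz)
        for i in range(cfg.n_axons)
    ]) if cfg.n_axons else np.zeros((0, n_v))
    for (i, j, sd) in cfg.planted_pairs:
        shared = _private_drive(rng, n_v, fs_v, float(sd), cfg.private_bandwidth_hz)
        private[int(i)] += shared
        private[int(j)] += shared

    gt.drive_common = common
    gt.drive_private = private

    def _render(drive_v: np.ndarray) -> np.ndarray:
        act = np.maximum(drive_v, 0.0)
        # continuous-time convolution: a unit-area impulse yields the
        # unit-peak kernel; a sustained unit drive settles near the
        # kernel integral (order 1), keeping dF/F and noise commensurate
        f_v = np.convolve(act, kern)[:n_v] / fs_v
        return np.interp(t_f, gt.t_video, f_v)

    def _noise() -> np.ndarray:
        w = rng.standard_normal(n_f)
        if cfg.noise_highpass_hz is not None:
            sos = sps.butter(3, cfg.noise_highpass_hz, btype="high",
                             fs=cfg.frame_rate_hz, output="sos")
            w = sps.sosfiltfilt(sos, w)
            s = w.std()
            if s > 0:
                w = w / s
        return cfg.noise_sd * w

    traces, meta = [], []
    roi_cycle = lambda k: int(k % cfg.n_rois)

    for i in range(cfg.n_axons):
        sig = _render(gains[i] * common + private[i])
        b0 = rng.uniform(80.0, 150.0)
        a = rng.uniform(0.8, 1.2)
        traces.append(b0 * (1.0 + a * sig + _noise()))
        meta.append(dict(object_id=f"ax{i:02d}", population=cfg.population,
                         roi_id=roi_cycle(i), pair_id=-1))

    for p in range(cfg.n_same_axon_pairs):
        g = float(np.mean(gains)) if cfg.n_axons else 1.0
        sd = float(np.mean(sds)) if cfg.n_axons else 0.5
        drive = g * common + _private_drive(rng, n_v, fs_v, sd,
                                            cfg.private_bandwidth_hz)
        sig = _render(drive)
        roi = roi_cycle(p)   # both segments in one ROI: distance 0
        for seg in "ab":
            b0 = rng.uniform(80.0, 150.0)
            a = rng.uniform(0.8, 1.2)
            traces.append(b0 * (1.0 + a * sig + _noise()))
            meta.append(dict(object_id=f"sa{p:02d}{seg}",
                             population=cfg.population, roi_id=roi, pair_id=p))

    for i in range(cfg.n_blebs):
        b0 = rng.uniform(30.0, 80.0)
        traces.append(b0 * (1.0 + _noise()))
        meta.append(dict(object_id=f"bleb{i:02d}", population="bleb",
                         roi_id=roi_cycle(i), pair_id=-1))

    if cfg.n_mcherry:
        artifact = _lowpass(rng.standard_normal(n_f), cfg.frame_rate_hz, 0.3)
        s = artifact.std()
        artifact = artifact / s if s > 0 else artifact
        for i in range(cfg.n_mcherry):
            g = rng.normal(0.0, cfg.mcherry_gain_sd)
            b0 = rng.uniform(50.0, 120.0)
            traces.append(b0 * (1.0 + g * artifact + _noise()))
            meta.append(dict(object_id=f"mch{i:02d}", population="mCherry",
                             roi_id=roi_cycle(i), pair_id=-1))

    F = np.asarray(traces) if traces else np.zeros((0, n_f))
    objects = pd.DataFrame(meta, columns=["object_id", "population", "roi_id",
                                          "pair_id"])
    return F, objects


def simulate_session(cfg: SimConfig, session_id: str = "sim",
                     script: list[dict] | None = None) -> Session:
    """Generate a complete synthetic session (fluorescence + behavior + truth)."""
    gt = simulate_state_sequence(cfg, script=script)
    behavior = render_behavior(gt, cfg)
    F, objects = render_fluorescence(gt, cfg)
    pos = cfg.roi_xy()
    rois = pd.DataFrame({
        "roi_id": np.arange(cfg.n_rois),
        "x_mm": pos[:, 0],
        "y_mm": pos[:, 1],
        "size_um": np.full(cfg.n_rois, cfg.roi_size_um),
    })
    truth_events = gt.true_events[["kind", "onset_s", "offset_s", "duration_s"]]
    return Session(
        session_id=session_id,
        fluor=F,
        fs_fluor=cfg.frame_rate_hz,
        behavior=behavior,
        rois=rois,
        objects=objects,
        truth_events=truth_events.reset_index(drop=True),
        provenance=[f"simulated seed={cfg.seed}"],
    )


def render_frames(mei: np.ndarray, shape: tuple[int, int] = (16, 16),
                  pixel: tuple[int, int] = (4, 4)) -> np.ndarray:
    """Tiny video renderer for testing the motion-energy operator.

    Produces a frame stack whose summed absolute inter-frame difference
    within any region containing ``pixel`` equals ``mei`` exactly: a single
    designated pixel alternates up/down by the target energy.
    """
    mei = np.asarray(mei, dtype=float)
    if np.any(mei < 0):
        raise ValueError("motion energy targets must be nonnegative")
    n = len(mei) + 1
    frames = np.zeros((n,) + shape)
    r, c = pixel
    val = 0.0
    for i, e in enumerate(mei):
        val = val + e if i % 2 == 0 else val - e
        frames[i + 1, r, c] = val
    return frames
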