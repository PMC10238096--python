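"""Pairwise correlation structure and the common-signal decomposition.

The central question this module answers: how much of the pairwise
correlation between simultaneously imaged axon segments is carried by one
global, behavioral-state-related signal?  For every pair, the *common
signal* is the average of all other simultaneously recorded traces
(leave-two-out: the pair itself is excluded, so the controlling variable
is not contaminated by the pair's own noise), and the *partial
correlation* is the correlation of the two traces' residuals after
regressing each on that common signal:

    r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2) (1 - r_yz^2))

If pairwise correlations arise only from shared coupling to the global
signal, partial correlations collapse to ~0; pairs with genuinely private
coupling (segments of the same axon being the extreme case) retain high
partial correlation.  Distance dependence, state-restricted comparisons
(full / stationary / still), and control populations (mCherry, blebs,
same-axon pairs) complete the decomposition.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import lowpass_1hz, zscore


# ----------------------------------------------------------------------
# primitive operations
# ----------------------------------------------------------------------

def partial_corr_from_r(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation from the three pairwise correlations."""
    if abs(r_xz) >= 1.0 or abs(r_yz) >= 1.0:
        warnings.warn("controlling variable perfectly correlated with an input; "
                      "partial correlation undefined")
        return np.nan
    den = np.sqrt((1.0 - r_xz ** 2) * (1.0 - r_yz ** 2))
    return float((r_xy - r_xz * r_yz) / den)


def partial_corr(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """Partial correlation of ``x`` and ``y`` given the controlling trace ``z``."""
    r = np.corrcoef(np.vstack([x, y, z]))
    return partial_corr_from_r(r[0, 1], r[0, 2], r[1, 2])


def partial_corr_residual(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """Partial correlation via explicit least-squares residualization.

    Algebraically identical to :func:`partial_corr`; kept as the
    regression-form definition (residuals of x on z correlated with
    residuals of y on z).
    """
    Z = np.column_stack([np.ones_like(z), z])
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        warnings.warn("residual variance is zero; partial correlation undefined")
        return np.nan
    return float(np.corrcoef(rx, ry)[0, 1])


def ordinary_corr(traces: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of the (already conditioned) traces."""
    return np.corrcoef(np.atleast_2d(traces))


def common_signal(traces: np.ndarray, exclude: tuple[int, int],
                  normalize: bool = True) -> np.ndarray:
    """Leave-two-out common signal: mean trace over all objects except the pair.

    Traces are z-scored before averaging (so bright objects do not dominate)
    unless ``normalize=False``.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    n = traces.shape[0]
    if n < 3:
        raise ValueError("common signal undefined with fewer than 3 objects")
    i, j = exclude
    keep = [k for k in range(n) if k not in (i, j)]
    T = zscore(traces[keep]) if normalize else traces[keep]
    return T.mean(axis=0)


# ----------------------------------------------------------------------
# Model / Results
# ----------------------------------------------------------------------

@dataclass
class CommonSignalResults:
    """Per-pair decomposition into ordinary and partial correlation.

    ``pairs`` columns: ``id_i, id_j, population, ordinary_r, partial_r,
    diff, distance_mm, same_axon``.
    """

    pairs: pd.DataFrame
    n_objects: int
    leave_two_out: bool
    positions_mm: np.ndarray | None = None
    object_rois: np.ndarray | None = None
    retained_s: float | None = None

    def _trend_pairs(self) -> pd.DataFrame:
        return self.pairs[~self.pairs["same_axon"]]

    def distance_trend(self, which: str = "ordinary", n_perm: int = 1000,
                       rng: np.random.Generator | None = None) -> dict:
        """Pearson correlation of pair distance with (ordinary|partial) r.

        The p-value is a pair-level permutation test: object-to-ROI position
        assignments are shuffled, pair distances recomputed, and the
        distance-correlation statistic re-evaluated.
        """
        rng = rng or np.random.default_rng(0)
        df = self._trend_pairs()
        col = "ordinary_r" if which == "ordinary" else "partial_r"
        vals = df[col].to_numpy()
        d = df["distance_mm"].to_numpy()
        ok = np.isfinite(vals) & np.isfinite(d)
        vals, d = vals[ok], d[ok]
        if len(vals) < 3 or np.std(d) == 0 or np.std(vals) == 0:
            return {"r": np.nan, "p": np.nan, "n_pairs": int(len(vals))}
        r_obs = float(np.corrcoef(d, vals)[0, 1])
        if self.positions_mm is None:
            return {"r": r_obs, "p": np.nan, "n_pairs": int(len(vals))}
        ii = df.loc[ok, "i"].to_numpy()
        jj = df.loc[ok, "j"].to_numpy()
        pos = self.positions_mm
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(self.n_objects)
            dp = np.linalg.norm(pos[perm[ii]] - pos[perm[jj]], axis=1)
            if np.std(dp) == 0:
                continue
            if abs(np.corrcoef(dp, vals)[0, 1]) >= abs(r_obs) - 1e-15:
                count += 1
        return {"r": r_obs, "p": (count + 1) / (n_perm + 1),
                "n_pairs": int(len(vals))}

    def summary(self) -> str:
        df = self.pairs
        het = df[~df["same_axon"]]
        sa = df[df["same_axon"]]
        lines = [
            "Common-signal decomposition "
            f"({'leave-two-out' if self.leave_two_out else 'session-mean'} control)",
            f"objects: {self.n_objects}   pairs: {len(df)} "
            f"({len(sa)} same-axon)",
            f"ordinary r:  {het['ordinary_r'].mean(): .3f} +/- "
            f"{het['ordinary_r'].std(): .3f}",
            f"partial r:   {het['partial_r'].mean(): .3f} +/- "
            f"{het['partial_r'].std(): .3f}",
            f"difference:  {het['diff'].mean(): .3f} +/- {het['diff'].std(): .3f}",
        ]
        if len(sa):
            lines.append(
                f"same-axon pairs: ordinary {sa['ordinary_r'].mean(): .3f}, "
                f"partial {sa['partial_r'].mean(): .3f}")
        for which in ("ordinary", "partial"):
            tr = self.distance_trend(which, n_perm=200)
            lines.append(f"distance vs {which} r: r={tr['r']: .3f} "
                         f"(p={tr['p']:.3g}, n={tr['n_pairs']})")
        return "\n".join(lines)

    def stats(self) -> dict:
        het = self._trend_pairs()
        return {
            "n_pairs": int(len(self.pairs)),
            "mean_ordinary_r": float(het["ordinary_r"].mean()),
            "sd_ordinary_r": float(het["ordinary_r"].std()),
            "mean_partial_r": float(het["partial_r"].mean()),
            "sd_partial_r": float(het["partial_r"].std()),
            "mean_diff": float(het["diff"].mean()),
        }

    def plot_partial_vs_ordinary(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        het = self._trend_pairs()
        sa = self.pairs[self.pairs["same_axon"]]
        ax.scatter(het["ordinary_r"], het["partial_r"], s=10, alpha=0.6,
                   label="pairs")
        if len(sa):
            ax.scatter(sa["ordinary_r"], sa["partial_r"], s=20, c="k",
                       label="same axon")
        ax.axhline(0, lw=0.5, c="gray")
        ax.plot([-1, 1], [-1, 1], lw=0.5, c="gray", ls="--")
        ax.set_xlabel("ordinary correlation")
        ax.set_ylabel("partial correlation | common signal")
        ax.legend(frameon=False)
        return ax


class CommonSignalModel:
    """Pairwise common-signal decomposition of a simultaneously recorded
    population.

    Parameters
    ----------
    traces : (n_objects, n_samples) array
        dF/F (or raw) traces on a common time grid.
    fs : float
        Sampling rate; required when ``lowpass_hz`` is set.
    lowpass_hz : float or None
        Zero-phase low-pass applied before any correlation (default 1 Hz,
        the usable indicator band).
    positions_mm : (n_objects, 2) array, optional
        ROI center coordinates; pairs within one ROI get distance 0.
    pair_ids : (n_objects,) int array, optional
        Same-axon pair labels (two objects sharing a nonnegative id are
        segments of one axon); -1 for unpaired.
    object_ids, population : optional metadata carried into the results.
    leave_two_out : bool
        Exclude the pair from the common signal (default).  The
        session-mean variant (pair included) exists for sensitivity
        analysis only; on small populations it biases partial correlations
        upward.
    """

    def __init__(self, traces: np.ndarray, fs: float | None = None,
                 lowpass_hz: float | None = 1.0,
                 positions_mm: np.ndarray | None = None,
                 pair_ids: np.ndarray | None = None,
                 object_ids=None, population=None,
                 leave_two_out: bool = True):
        T = np.atleast_2d(np.asarray(traces, dtype=float))
        if T.shape[0] < 3:
            raise ValueError("need >= 3 simultaneously recorded objects")
        if lowpass_hz is not None:
            if fs is None:
                raise ValueError("fs is required when lowpass_hz is set")
            T = np.stack([lowpass_1hz(tr, fs, cutoff=lowpass_hz) for tr in T])
        self.traces = T
        self.fs = fs
        self.n = T.shape[0]
        self.positions_mm = (np.asarray(positions_mm, dtype=float)
                             if positions_mm is not None else None)
        self.pair_ids = (np.asarray(pair_ids, dtype=int)
                         if pair_ids is not None
                         else np.full(self.n, -1, dtype=int))
        self.object_ids = (list(object_ids) if object_ids is not None
                           else [f"obj{i:02d}" for i in range(self.n)])
        self.population = (list(population) if population is not None
                           else ["?"] * self.n)
        self.leave_two_out = leave_two_out

    def fit(self, sample_mask: np.ndarray | None = None) -> CommonSignalResults:
        """Compute the pairwise decomposition, optionally on a sample subset.

        ``sample_mask`` restricts the correlation to retained samples (used
        by the state-restricted analysis); filtering has already been done
        on the full trace, so masking only selects samples.
        """
        T = self.traces if sample_mask is None else self.traces[:, sample_mask]
        retained_s = (T.shape[1] / self.fs) if self.fs else None
        Z = zscore(T)
        N = Z.shape[1]
        G = (Z @ Z.T) / N           # sample correlation matrix
        s = G.sum(axis=1)
        tot = G.sum()

        rows = []
        for i, j in itertools.combinations(range(self.n), 2):
            r_xy = G[i, j]
            if self.leave_two_out:
                cov_xz = s[i] - G[i, i] - G[i, j]
                cov_yz = s[j] - G[j, j] - G[i, j]
                var_z = (tot - 2.0 * (s[i] + s[j])
                         + G[i, i] + G[j, j] + 2.0 * G[i, j])
            else:
                cov_xz, cov_yz, var_z = s[i], s[j], tot
            if var_z <= 0:
                partial = np.nan
            else:
                r_xz = cov_xz / np.sqrt(var_z * G[i, i])
                r_yz = cov_yz / np.sqrt(var_z * G[j, j])
                d2 = (1.0 - r_xz ** 2) * (1.0 - r_yz ** 2)
                partial = (r_xy - r_xz * r_yz) / np.sqrt(d2) if d2 > 1e-24 else np.nan
            if self.positions_mm is not None:
                dist = float(np.linalg.norm(self.positions_mm[i]
                                            - self.positions_mm[j]))
            else:
                dist = np.nan
            same = bool(self.pair_ids[i] >= 0
                        and self.pair_ids[i] == self.pair_ids[j])
            pop_i, pop_j = self.population[i], self.population[j]
            rows.append(dict(
                i=i, j=j, id_i=self.object_ids[i], id_j=self.object_ids[j],
                population=pop_i if pop_i == pop_j else "mixed",
                ordinary_r=float(r_xy), partial_r=float(partial),
                diff=float(r_xy - partial), distance_mm=dist, same_axon=same))
        return CommonSignalResults(
            pairs=pd.DataFrame(rows), n_objects=self.n,
            leave_two_out=self.leave_two_out,
            positions_mm=self.positions_mm, retained_s=retained_s)


# ----------------------------------------------------------------------
# session-level drivers
# ----------------------------------------------------------------------

def decompose_session(session, dff_matrix: np.ndarray, fs: float,
                      population: str | None = None,
                      lowpass_hz: float | None = 1.0,
                      leave_two_out: bool = True) -> CommonSignalResults:
    """Run the common-signal decomposition on one session's population.

    Selects the objects of ``population`` (default: the session's main
    axon/cell population, i.e. everything that is neither bleb nor
    mCherry), attaches ROI distances and same-axon labels, and fits
    :class:`CommonSignalModel`.
    """
    obj = session.objects
    if population is None:
        mask = ~obj["population"].isin(["bleb", "mCherry"])
    else:
        mask = obj["population"] == population
    idx = np.flatnonzero(mask.to_numpy())
    if len(idx) < 3:
        raise ValueError(f"fewer than 3 objects in population "
                         f"{population or 'main'}")
    pos = session.roi_positions()[idx]
    model = CommonSignalModel(
        dff_matrix[idx], fs=fs, lowpass_hz=lowpass_hz,
        positions_mm=pos, pair_ids=obj["pair_id"].to_numpy()[idx],
        object_ids=list(obj["object_id"].to_numpy()[idx]),
        population=list(obj["population"].to_numpy()[idx]),
        leave_two_out=leave_two_out)
    return model.fit()


def state_masks(session, t: np.ndarray, whisk_thresh: float = 0.2,
                walk_speed: float = 2.5) -> dict[str, np.ndarray]:
    """Sample masks on time grid ``t`` for full / stationary / still modes."""
    beh = session.behavior_on(t)
    w = beh["mei_whisker"]
    rng_w = w.max() - w.min()
    wn = (w - w.min()) / rng_w if rng_w > 0 else w * 0.0
    walking = beh["wheel_speed"] > walk_speed
    whisking = wn > whisk_thresh
    return {
        "full": np.ones(len(t), dtype=bool),
        "stationary": ~walking,
        "still": ~walking & ~whisking,
    }


def state_restricted_decompose(session, dff_matrix: np.ndarray, fs: float,
                               modes: tuple[str, ...] = ("full", "stationary",
                                                         "still"),
                               min_duration_s: float = 60.0,
                               population: str | None = None,
                               lowpass_hz: float | None = 1.0,
                               whisk_thresh: float = 0.2,
                               walk_speed: float = 2.5) -> dict:
    """Ordinary/partial correlations recomputed on state-restricted samples.

    Modes: ``full`` (all samples), ``stationary`` (walking excluded),
    ``still`` (walking and whisking excluded).  Filtering happens on the
    full traces; retained samples are then concatenated.  A mode with less
    than ``min_duration_s`` of retained data is skipped (logged in the
    returned dict).  Includes a paired comparison of the
    ordinary-minus-partial difference across pairs between modes.
    """
    obj = session.objects
    if population is None:
        sel = ~obj["population"].isin(["bleb", "mCherry"])
    else:
        sel = obj["population"] == population
    idx = np.flatnonzero(sel.to_numpy())
    pos = session.roi_positions()[idx]
    model = CommonSignalModel(
        dff_matrix[idx], fs=fs, lowpass_hz=lowpass_hz, positions_mm=pos,
        pair_ids=obj["pair_id"].to_numpy()[idx],
        object_ids=list(obj["object_id"].to_numpy()[idx]),
        population=list(obj["population"].to_numpy()[idx]))
    t = np.arange(dff_matrix.shape[1]) / fs
    masks = state_masks(session, t, whisk_thresh, walk_speed)

    out: dict = {"modes": {}, "skipped": []}
    diffs: dict[str, np.ndarray] = {}
    for mode in modes:
        mask = masks[mode]
        if mask.sum() / fs < min_duration_s:
            out["skipped"].append(mode)
            continue
        res = model.fit(sample_mask=mask)
        entry = res.stats()
        entry["retained_s"] = float(mask.sum() / fs)
        entry["results"] = res
        out["modes"][mode] = entry
        diffs[mode] = res.pairs.loc[~res.pairs["same_axon"], "diff"].to_numpy()
    if "full" in diffs and "still" in diffs:
        t_stat, p = stats.ttest_rel(diffs["full"], diffs["still"])
        out["full_vs_still"] = {"t": float(t_stat), "p": float(p),
                                "mean_reduction": float(np.mean(
                                    diffs["full"] - diffs["still"]))}
    return out


def movement_decorrelation_control(dff_matrix: np.ndarray, fs: float,
                                   pair_ids: np.ndarray, session,
                                   walk_speed: float = 2.5,
                                   lowpass_hz: float | None = 1.0,
                                   min_samples: int = 100) -> dict:
    """Same-axon correlation within walking vs non-walking samples.

    Segments of one axon carry identical spiking, so a drop in their
    correlation during walking is a measurement artifact (signal-dependent
    noise, frequency-limited indicator), not biology.  The returned flag
    marks whether same-axon pairs decorrelate during walking — a warning
    that apparent state-dependent decorrelation of heterogeneous pairs
    should not be taken at face value.
    """
    pair_ids = np.asarray(pair_ids)
    t = np.arange(dff_matrix.shape[1]) / fs
    beh = session.behavior_on(t)
    walking = beh["wheel_speed"] > walk_speed
    if walking.sum() < min_samples:
        warnings.warn("no (or too few) walking samples; control skipped")
        return {"pairs": pd.DataFrame(), "flag_decorrelates": False,
                "skipped": True}
    T = dff_matrix
    if lowpass_hz is not None:
        T = np.stack([lowpass_1hz(tr, fs, cutoff=lowpass_hz) for tr in T])
    rows = []
    for pid in sorted(set(pair_ids[pair_ids >= 0])):
        members = np.flatnonzero(pair_ids == pid)
        if len(members) != 2:
            continue
        a, b = T[members[0]], T[members[1]]
        r_walk = float(np.corrcoef(a[walking], b[walking])[0, 1])
        r_still = float(np.corrcoef(a[~walking], b[~walking])[0, 1])
        rows.append(dict(pair_id=pid, r_walk=r_walk, r_still=r_still,
                         drop=r_still - r_walk))
    df = pd.DataFrame(rows)
    flag = bool(len(df) and df["drop"].mean() > 0.1)
    return {"pairs": df, "flag_decorrelates": flag, "skipped": False}
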