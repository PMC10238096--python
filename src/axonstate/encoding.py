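"""Ridge encoding models: behavioral prediction of axonal activity.

An :class:`EncodingModel` predicts dF/F from the six behavioral arousal
measures (pupil diameter, walking velocity, and whisker-pad, snout, jaw
and full-face motion energy) with ridge regression — the predictors are
strongly collinear, and the ridge penalty keeps per-predictor attributions
stable.  All signals are 1 Hz low-pass filtered first.  Cross-validation
uses contiguous time blocks (never shuffled samples) to respect the heavy
autocorrelation of both behavior and indicator traces; the penalty is
selected on inner folds.  Per-predictor explained variance is reported
both as cross-validated single-predictor R-squared and as the unique
contribution (full-model R-squared minus the model without that
predictor); out-of-sample R-squared can be negative.

The *session permutation* test guards against overfitting-driven
pseudo-relationships: the matched (simultaneously recorded) prediction
error is ranked against the null distribution of errors from all
mismatched session pairings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge
from sklearn.metrics import r2_score

from .preprocess import lowpass_1hz

PREDICTOR_NAMES = ("pupil", "wheel_speed", "mei_whisker", "mei_snout",
                   "mei_jaw", "mei_fullface")

DEFAULT_PENALTY_GRID = np.logspace(-3, 3, 10)


def _blocks(n: int, k: int) -> list[np.ndarray]:
    """Split sample indices into k contiguous time blocks."""
    edges = np.linspace(0, n, k + 1).astype(int)
    return [np.arange(edges[i], edges[i + 1]) for i in range(k)]


def _cv_predict(y: np.ndarray, X: np.ndarray, penalty_grid: np.ndarray,
                k_folds: int) -> tuple[np.ndarray, float]:
    """Blocked-CV out-of-sample predictions with inner-fold penalty selection.

    Returns pooled held-out predictions and the median selected penalty.
    """
    n = len(y)
    outer = _blocks(n, k_folds)
    yhat = np.empty(n)
    alphas = []
    for i, test in enumerate(outer):
        train = np.concatenate([b for j, b in enumerate(outer) if j != i])
        # inner blocked CV on the training samples to pick the penalty
        inner = _blocks(len(train), max(2, k_folds - 1))
        best_alpha, best_mse = None, np.inf
        for alpha in penalty_grid:
            mse = 0.0
            for j, itest in enumerate(inner):
                itrain = np.concatenate(
                    [b for m, b in enumerate(inner) if m != j])
                tr, te = train[itrain], train[itest]
                model = _fit_standardized(y[tr], X[tr], alpha)
                mse += np.mean((y[te] - model(X[te])) ** 2)
            if mse < best_mse:
                best_mse, best_alpha = mse, alpha
        model = _fit_standardized(y[train], X[train], best_alpha)
        yhat[test] = model(X[test])
        alphas.append(best_alpha)
    return yhat, float(np.median(alphas))


def _fit_standardized(y: np.ndarray, X: np.ndarray, alpha: float):
    """Ridge on train-standardized predictors; returns a predict callable."""
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    ridge = Ridge(alpha=alpha)
    ridge.fit((X - mu) / sd, y)
    return lambda Xnew: ridge.predict((Xnew - mu) / sd)


@dataclass
class EncodingResults:
    """Cross-validated explained variance per object and per predictor."""

    table: pd.DataFrame              # per object: full_r2, alpha, <name>_r2,
                                     # <name>_unique_dr2
    predictor_names: tuple[str, ...]
    k_folds: int
    dropped_predictors: tuple[str, ...] = ()

    @property
    def full_r2(self) -> np.ndarray:
        return self.table["full_r2"].to_numpy()

    def summary(self) -> str:
        lines = [
            "Ridge encoding model (blocked CV, inner-fold penalty selection)",
            f"objects: {len(self.table)}   folds: {self.k_folds}   "
            f"predictors: {', '.join(self.predictor_names)}",
        ]
        if self.dropped_predictors:
            lines.append(f"dropped (constant): {', '.join(self.dropped_predictors)}")
        lines.append(
            f"full-model R2: {np.nanmean(self.full_r2):.3f} "
            f"+/- {np.nanstd(self.full_r2):.3f} (mean +/- SD across objects)")
        mean_single = {
            p: np.nanmean(self.table[f"{p}_r2"]) for p in self.predictor_names}
        order = sorted(mean_single, key=mean_single.get, reverse=True)
        lines.append("single-predictor R2 (mean):")
        for p in order:
            lines.append(f"  {p:>14s}  {mean_single[p]: .3f}   "
                         f"unique dR2 {np.nanmean(self.table[f'{p}_unique_dr2']): .3f}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Bar plot of mean single-predictor R-squared."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        means = [np.nanmean(self.table[f"{p}_r2"]) for p in self.predictor_names]
        ax.bar(range(len(means)), means)
        ax.set_xticks(range(len(means)))
        ax.set_xticklabels(self.predictor_names, rotation=45, ha="right")
        ax.set_ylabel("cross-validated $R^2$")
        return ax


class EncodingModel:
    """Ridge encoding of dF/F from behavioral predictors.

    Parameters
    ----------
    endog : (n_objects, n_samples) or (n_samples,) array
        dF/F traces to predict (one model per object).
    exog : (n_samples, n_predictors) array
        Behavioral predictors aligned to the same time grid.
    predictor_names : sequence of str
    fs : float
        Common sampling rate; required when ``lowpass_hz`` is set.
    lowpass_hz : float or None
        Zero-phase low-pass applied to endog and exog before fitting
        (default 1 Hz, the usable indicator band).
    predictor_kernel : array or None
        Optional indicator kernel; when given, predictors are convolved
        with it before fitting so they live on the same temporal footing
        as the indicator-filtered response (standard practice in calcium
        encoding models).
    """

    def __init__(self, endog: np.ndarray, exog: np.ndarray,
                 predictor_names=PREDICTOR_NAMES, fs: float | None = None,
                 lowpass_hz: float | None = 1.0,
                 predictor_kernel: np.ndarray | None = None,
                 object_ids=None):
        Y = np.atleast_2d(np.asarray(endog, dtype=float))
        X = np.asarray(exog, dtype=float)
        if X.ndim != 2 or X.shape[0] != Y.shape[1]:
            raise ValueError("exog must be (n_samples, n_predictors) matching endog")
        names = list(predictor_names)[:X.shape[1]]
        if len(names) != X.shape[1]:
            names = [f"x{i}" for i in range(X.shape[1])]
        if predictor_kernel is not None:
            k = np.asarray(predictor_kernel, dtype=float)
            X = np.column_stack([np.convolve(X[:, j], k)[:X.shape[0]]
                                 for j in range(X.shape[1])])
        if lowpass_hz is not None:
            if fs is None:
                raise ValueError("fs is required when lowpass_hz is set")
            Y = np.stack([lowpass_1hz(y, fs, cutoff=lowpass_hz) for y in Y])
            X = np.column_stack([lowpass_1hz(X[:, j], fs, cutoff=lowpass_hz)
                                 for j in range(X.shape[1])])
        keep, dropped = [], []
        for j, nm in enumerate(names):
            if np.std(X[:, j]) == 0:
                dropped.append(nm)
                warnings.warn(f"constant predictor '{nm}' dropped")
            else:
                keep.append(j)
        self.endog = Y
        self.exog = X[:, keep]
        self.predictor_names = tuple(names[j] for j in keep)
        self.dropped_predictors = tuple(dropped)
        self.object_ids = (list(object_ids) if object_ids is not None
                           else [f"obj{i:02d}" for i in range(Y.shape[0])])

    @classmethod
    def from_session(cls, session, dff_matrix: np.ndarray, fs: float,
                     lowpass_hz: float | None = 1.0,
                     predictor_kernel: np.ndarray | None = None,
                     object_ids=None) -> "EncodingModel":
        """Build the six-predictor design from a session's behavior traces,
        interpolated onto the dF/F time grid."""
        t = np.arange(dff_matrix.shape[-1]) / fs
        beh = session.behavior_on(t)
        X = np.column_stack([beh[name] for name in PREDICTOR_NAMES])
        return cls(dff_matrix, X, predictor_names=PREDICTOR_NAMES, fs=fs,
                   lowpass_hz=lowpass_hz, predictor_kernel=predictor_kernel,
                   object_ids=object_ids)

    def fit(self, penalty_grid: np.ndarray = DEFAULT_PENALTY_GRID,
            k_folds: int = 5) -> EncodingResults:
        """Blocked cross-validated fit with per-predictor attribution."""
        rows = []
        X = self.exog
        p = X.shape[1]
        for oid, y in zip(self.object_ids, self.endog):
            yhat, alpha = _cv_predict(y, X, penalty_grid, k_folds)
            row = {"object_id": oid, "full_r2": r2_score(y, yhat),
                   "alpha": alpha}
            for j, nm in enumerate(self.predictor_names):
                yj, _ = _cv_predict(y, X[:, [j]], penalty_grid, k_folds)
                row[f"{nm}_r2"] = r2_score(y, yj)
            for j, nm in enumerate(self.predictor_names):
                rest = [m for m in range(p) if m != j]
                if rest:
                    ym, _ = _cv_predict(y, X[:, rest], penalty_grid, k_folds)
                    row[f"{nm}_unique_dr2"] = row["full_r2"] - r2_score(y, ym)
                else:
                    row[f"{nm}_unique_dr2"] = row["full_r2"]
            rows.append(row)
        return EncodingResults(table=pd.DataFrame(rows),
                               predictor_names=self.predictor_names,
                               k_folds=k_folds,
                               dropped_predictors=self.dropped_predictors)


@dataclass
class PermutationResult:
    """Session-permutation validation of encoding-model relationships."""

    matched_error: float
    null_errors: np.ndarray
    percentile: float          # of the matched error within the null, 0-100
    valid: bool                # matched error below the null 5th percentile

    def summary(self) -> str:
        return (f"session permutation: matched MSE {self.matched_error:.4g} "
                f"at percentile {self.percentile:.1f} of {len(self.null_errors)} "
                f"unmatched pairings -> {'valid' if self.valid else 'not validated'}")


def _derangements(m: int, max_enumerate: int = 8,
                  n_sample: int = 500,
                  rng: np.random.Generator | None = None) -> list[tuple[int, ...]]:
    """All (or sampled) permutations of range(m) with no fixed point."""
    import itertools
    if m <= max_enumerate:
        return [p for p in itertools.permutations(range(m))
                if all(p[i] != i for i in range(m))]
    rng = rng or np.random.default_rng(0)
    out = set()
    while len(out) < n_sample:
        p = tuple(rng.permutation(m).tolist())
        if all(p[i] != i for i in range(m)):
            out.add(p)
    return sorted(out)


def session_permutation(sessions: list[tuple[np.ndarray, np.ndarray]],
                        fs: float, lowpass_hz: float | None = 1.0,
                        penalty_grid: np.ndarray = DEFAULT_PENALTY_GRID,
                        k_folds: int = 5) -> PermutationResult:
    """Rank matched prediction error against unmatched session pairings.

    ``sessions`` is a list of ``(y, X)`` per session — a response trace
    (e.g. the session-average dF/F) and the predictor matrix.  For every
    ordered pair (i, j) the response of session i is predicted from the
    predictors of session j (truncated to the common length); blocked-CV
    mean squared error, normalized by response variance so sessions are
    comparable, is the prediction-error metric.  The matched error is the
    mean over the diagonal; the null is the set of mean errors over all
    permutations of unmatched session pairings (derangements), which
    makes the matched statistic exchangeable with the null when responses
    and predictors are truly unrelated.
    """
    m = len(sessions)
    if m < 3:
        raise ValueError("session permutation needs >= 3 sessions")
    n_common = min(len(y) for y, _ in sessions)
    ys = [np.asarray(y, dtype=float)[:n_common] for y, _ in sessions]
    Xs = [np.asarray(X, dtype=float)[:n_common] for _, X in sessions]
    if lowpass_hz is not None:
        ys = [lowpass_1hz(y, fs, cutoff=lowpass_hz) for y in ys]
        Xs = [np.column_stack([lowpass_1hz(X[:, j], fs, cutoff=lowpass_hz)
                               for j in range(X.shape[1])]) for X in Xs]

    def _cv_mse(y, X):
        yhat, _ = _cv_predict(y, X, penalty_grid, k_folds)
        return float(np.mean((y - yhat) ** 2) / np.var(y))

    err = np.array([[_cv_mse(ys[i], Xs[j]) for j in range(m)]
                    for i in range(m)])
    matched = float(np.mean(np.diag(err)))
    null = np.array([np.mean([err[i, p[i]] for i in range(m)])
                     for p in _derangements(m)])
    percentile = 100.0 * float(np.mean(null < matched)
                               + 0.5 * np.mean(null == matched))
    return PermutationResult(matched_error=matched, null_errors=null,
                             percentile=percentile,
                             valid=bool(percentile <= 5.0))
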