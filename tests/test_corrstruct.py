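"""Partial correlation and the common-signal decomposition.

The closed-form estimator is checked against an explicit
residual-regression oracle, against pingouin, and against the analytic
variance decomposition of a shared-drive population.
"""

import numpy as np
import pandas as pd
import pytest

from axonstate import SimConfig, simulate_session
from axonstate.corrstruct import (CommonSignalModel, common_signal,
                                  decompose_session,
                                  movement_decorrelation_control,
                                  partial_corr, partial_corr_from_r,
                                  partial_corr_residual,
                                  state_restricted_decompose)
from axonstate.preprocess import dff


def exact_correlated_triple(corr: np.ndarray, n: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Gaussian triple whose *sample* correlation matrix equals ``corr``.

    Random Gaussians are whitened (QR orthonormalization of the centered
    columns) and mixed by the Cholesky factor of the target, so the check
    of the estimator is deterministic rather than subject to sampling
    error.
    """
    X = rng.standard_normal((n, 3))
    X -= X.mean(axis=0)
    Q, _ = np.linalg.qr(X)
    L = np.linalg.cholesky(corr)
    return (Q @ L.T).T * np.sqrt(n)


class TestPartialCorrelation:
    def test_matches_residual_regression_oracle(self):
        """Closed form equals explicit least-squares residual correlation."""
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(300):
            x, y, z = rng.standard_normal((3, 200))
            # induce some shared structure so the test is not trivial
            x = x + 0.5 * z
            y = y + 0.8 * z
            worst = max(worst, abs(partial_corr(x, y, z)
                                   - partial_corr_residual(x, y, z)))
        assert worst < 1e-10

    def test_worked_value(self):
        """r_xy=0.5, r_xz=r_yz=0.7 gives (0.5-0.49)/0.51 = 0.0196..."""
        target = np.array([[1.0, 0.5, 0.7],
                           [0.5, 1.0, 0.7],
                           [0.7, 0.7, 1.0]])
        x, y, z = exact_correlated_triple(target, 100_000,
                                          np.random.default_rng(1))
        expect = (0.5 - 0.49) / (1 - 0.49)
        assert partial_corr(x, y, z) == pytest.approx(expect, abs=1e-3)
        assert partial_corr_from_r(0.5, 0.7, 0.7) == pytest.approx(expect,
                                                                   abs=1e-12)

    def test_pingouin_crosscheck(self):
        """Independent library computes the same partial correlation."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        z = rng.standard_normal(500)
        x = 0.6 * z + rng.standard_normal(500)
        y = 0.6 * z + rng.standard_normal(500)
        ours = partial_corr(x, y, z)
        theirs = pingouin.partial_corr(
            data=pd.DataFrame({"x": x, "y": y, "z": z}),
            x="x", y="y", covar="z")["r"].iloc[0]
        assert ours == pytest.approx(theirs, abs=1e-8)

    def test_uncorrelated_control_reduces_to_ordinary(self):
        """Controlling on a variable orthogonal to both leaves r unchanged."""
        rng = np.random.default_rng(3)
        X = rng.standard_normal((500, 3))
        X -= X.mean(axis=0)
        Q, _ = np.linalg.qr(X)
        x = Q[:, 0] + 0.5 * Q[:, 1]
        y = Q[:, 0] - 0.5 * Q[:, 1]
        z = Q[:, 2]                      # exactly orthogonal control
        r_xy = np.corrcoef(x, y)[0, 1]
        assert partial_corr(x, y, z) == pytest.approx(r_xy, abs=1e-12)

    def test_identical_traces_give_partial_one(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(400)
        z = 0.5 * x + rng.standard_normal(400)
        assert partial_corr(x, x.copy(), z) == pytest.approx(1.0, abs=1e-10)

    def test_degenerate_control_flagged(self):
        x = np.arange(100.0)
        with pytest.warns(UserWarning):
            assert np.isnan(partial_corr_from_r(0.5, 1.0, 0.5))


class TestCommonSignal:
    def test_mean_of_non_excluded(self):
        a, b, c, d = np.random.default_rng(0).standard_normal((4, 50))
        cs = common_signal(np.stack([a, b, c, d]), exclude=(0, 1),
                           normalize=False)
        np.testing.assert_allclose(cs, (c + d) / 2, atol=1e-12)

    def test_identical_traces(self):
        x = np.random.default_rng(1).standard_normal(50)
        cs = common_signal(np.stack([x, x, x, x]), exclude=(1, 2),
                           normalize=False)
        np.testing.assert_allclose(cs, x, atol=1e-12)

    def test_three_objects_single_contributor(self):
        a, b, c = np.random.default_rng(2).standard_normal((3, 50))
        cs = common_signal(np.stack([a, b, c]), exclude=(0, 1),
                           normalize=False)
        np.testing.assert_allclose(cs, c, atol=1e-12)

    def test_fewer_than_three_raises(self):
        with pytest.raises(ValueError):
            common_signal(np.zeros((2, 50)), exclude=(0, 1))


class TestSharedDriveVarianceDecomposition:
    @pytest.mark.parametrize("g", [0.5, 1.0, 2.0])
    def test_ordinary_r_matches_closed_form(self, g):
        """Two traces g*c + private(unit SD): r -> g^2 / (g^2 + 1)."""
        rng = np.random.default_rng(10)
        n = 200_000
        c = rng.standard_normal(n)
        x = g * c + rng.standard_normal(n)
        y = g * c + rng.standard_normal(n)
        expect = g ** 2 / (g ** 2 + 1.0)
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(expect, abs=0.01)


class TestCommonSignalModel:
    def test_pairwise_partial_matches_pairwise_oracle(self):
        """Vectorized leave-two-out partials equal the per-pair primitive."""
        rng = np.random.default_rng(5)
        c = rng.standard_normal(2000)
        T = np.stack([0.8 * c + rng.standard_normal(2000) for _ in range(5)])
        res = CommonSignalModel(T, lowpass_hz=None).fit()
        from axonstate.preprocess import zscore
        Z = zscore(T)
        for _, row in res.pairs.iterrows():
            i, j = int(row["i"]), int(row["j"])
            cs = common_signal(T, exclude=(i, j))
            assert row["partial_r"] == pytest.approx(
                partial_corr(Z[i], Z[j], cs), abs=1e-10)
            assert row["ordinary_r"] == pytest.approx(
                np.corrcoef(T[i], T[j])[0, 1], abs=1e-10)

    def test_global_signal_collapses_partial(self, common_drive_session):
        """All coupling via the common drive: ordinary high, partial ~ 0."""
        cfg, session = common_drive_session
        d = np.stack([dff(tr) for tr in session.fluor])
        res = decompose_session(session, d, cfg.frame_rate_hz)
        st = res.stats()
        assert st["mean_ordinary_r"] > 0.4
        # the leave-two-out control carries a finite-population bias of
        # ~1/(n-2) from the contributors' shared noise; with 28
        # contributors it stays within the 0.05 band
        assert abs(st["mean_partial_r"]) < 0.05

    def test_planted_private_pair_retained(self):
        """A privately coupled pair survives the common-signal control."""
        cfg = SimConfig(duration_s=240.0, frame_rate_hz=10.0, n_axons=30,
                        private_sd=0.0, noise_sd=0.3,
                        planted_pairs=((0, 1, 0.6),),
                        n_same_axon_pairs=0, n_blebs=0, seed=21)
        session = simulate_session(cfg)
        d = np.stack([dff(tr) for tr in session.fluor])
        res = decompose_session(session, d, cfg.frame_rate_hz)
        pairs = res.pairs
        planted = pairs[(pairs["i"] == 0) & (pairs["j"] == 1)]
        others = pairs[~((pairs["i"] == 0) & (pairs["j"] == 1))]
        assert planted["partial_r"].iloc[0] > 0.5
        assert abs(others["partial_r"].mean()) < 0.15

    def test_leave_two_out_exclusion_matters(self):
        """Controlling on the all-object mean (pair included) distorts the
        partial correlation relative to the leave-two-out control on n=3."""
        rng = np.random.default_rng(6)
        n = 5000
        c = rng.standard_normal(n)
        T = np.stack([c + rng.standard_normal(n) for _ in range(3)])
        lto = CommonSignalModel(T, lowpass_hz=None, leave_two_out=True).fit()
        sm = CommonSignalModel(T, lowpass_hz=None, leave_two_out=False).fit()
        p_lto = lto.pairs["partial_r"].to_numpy()
        p_sm = sm.pairs["partial_r"].to_numpy()
        # including the pair in its own control contaminates the regressor
        # with the pair's private noise and pulls the partial r down
        assert np.all(p_sm < p_lto - 0.05)

    def test_distance_trend_destroyed_by_permutation(self):
        """A built-in distance gradient is detected; shuffling ROI positions
        removes it."""
        rng = np.random.default_rng(7)
        n_obj, n = 12, 4000
        pos = np.c_[np.linspace(0, 4, n_obj), np.zeros(n_obj)]
        c = rng.standard_normal(n)
        local = rng.standard_normal(n)
        T = []
        for k in range(n_obj):
            w = 1.0 - pos[k, 0] / 4.0          # nearby objects share `local`
            T.append(c + 1.5 * w * local + 0.8 * rng.standard_normal(n))
        model = CommonSignalModel(np.stack(T), lowpass_hz=None,
                                  positions_mm=pos)
        res = model.fit()
        tr = res.distance_trend("ordinary", n_perm=300)
        assert tr["r"] < -0.2 and tr["p"] < 0.05
        perm_pos = pos[rng.permutation(n_obj)]
        res2 = CommonSignalModel(np.stack(T), lowpass_hz=None,
                                 positions_mm=perm_pos).fit()
        tr2 = res2.distance_trend("ordinary", n_perm=300)
        assert tr2["p"] > 0.05 or abs(tr2["r"]) < abs(tr["r"]) / 2

    def test_same_roi_pairs_distance_zero(self, default_session):
        cfg, session = default_session
        d = np.stack([dff(tr) for tr in session.fluor])
        res = decompose_session(session, d, cfg.frame_rate_hz)
        same_roi = res.pairs[res.pairs["same_axon"]]
        assert (same_roi["distance_mm"] == 0).all()


class TestStateRestriction:
    def test_movement_gated_common_signal(self):
        """Common drive active only during movement: removing movement
        periods shrinks the ordinary-minus-partial difference."""
        cfg = SimConfig(duration_s=400.0, frame_rate_hz=10.0, n_axons=8,
                        common_gain=1.2, private_sd=0.5, noise_sd=0.1,
                        n_same_axon_pairs=0, n_blebs=0, seed=31)
        session = simulate_session(cfg)
        d = np.stack([dff(tr) for tr in session.fluor])
        out = state_restricted_decompose(session, d, cfg.frame_rate_hz)
        assert "full" in out["modes"] and "still" in out["modes"]
        assert (out["modes"]["full"]["mean_diff"]
                > out["modes"]["still"]["mean_diff"])
        assert out["full_vs_still"]["mean_reduction"] > 0

    def test_mode_without_data_skipped(self, clean_session):
        cfg, session = clean_session
        d = np.stack([dff(tr) for tr in session.fluor])
        out = state_restricted_decompose(session, d, cfg.frame_rate_hz,
                                         min_duration_s=1e6)
        assert set(out["skipped"]) == {"full", "stationary", "still"}


class TestMovementDecorrelationControl:
    def test_signal_dependent_noise_decorrelates_during_walking(self):
        """Same-axon pair with activity-scaled noise: walking-state
        correlation drops below still-state correlation."""
        rng = np.random.default_rng(8)
        fs, n = 10.0, 4000
        t = np.arange(n) / fs
        walking = (t % 100) < 30
        sig = np.where(walking, 1.0, 0.2) * np.abs(
            np.convolve(rng.standard_normal(n), np.ones(30) / 30, "same"))
        noise_scale = 0.05 + 0.6 * walking
        pair = np.stack([sig + noise_scale * rng.standard_normal(n),
                         sig + noise_scale * rng.standard_normal(n)])

        class _Stub:
            def behavior_on(self, tt):
                return {"wheel_speed": np.interp(tt, t, 5.0 * walking),
                        "mei_whisker": np.zeros_like(tt)}

        out = movement_decorrelation_control(pair, fs, np.array([0, 0]),
                                             _Stub(), lowpass_hz=None)
        row = out["pairs"].iloc[0]
        assert row["r_walk"] < row["r_still"]
        assert out["flag_decorrelates"]
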