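"""Shared fixtures: small synthetic sessions generated at test time."""

import numpy as np
import pytest

from axonstate import SimConfig, simulate_session
from axonstate.behavior import BehaviorTraces

VIDEO_FS = 30.0


def make_behavior(n_s: float = 60.0, fs: float = VIDEO_FS, **channels
                  ) -> BehaviorTraces:
    """BehaviorTraces with all-zero channels unless overridden."""
    n = int(round(n_s * fs))
    t = np.arange(n) / fs
    zeros = np.zeros(n)
    base = dict(wheel_speed=zeros, pupil=np.full(n, 2.0),
                mei_whisker=zeros, mei_snout=zeros, mei_jaw=zeros,
                mei_fullface=zeros)
    base.update(channels)
    return BehaviorTraces(time_s=t, **base)


def put_run(trace: np.ndarray, fs: float, onset_s: float, dur_s: float,
            level: float) -> None:
    """Set trace to `level` over [onset, onset+dur)."""
    i0 = int(round(onset_s * fs))
    i1 = i0 + int(round(dur_s * fs))
    trace[i0:i1] = level


@pytest.fixture(scope="session")
def clean_session():
    """Noiseless session: exact event recovery, crisp behavioral traces."""
    cfg = SimConfig(duration_s=240.0, frame_rate_hz=10.0, n_axons=6,
                    n_same_axon_pairs=1, n_blebs=1, noise_sd=0.0,
                    behavior_noise_sd=0.0, seed=7)
    return cfg, simulate_session(cfg)


@pytest.fixture(scope="session")
def common_drive_session():
    """All inter-axon coupling through the common drive (private_sd = 0)."""
    cfg = SimConfig(duration_s=240.0, frame_rate_hz=10.0, n_axons=30,
                    common_gain=1.0, private_sd=0.0, noise_sd=0.3,
                    n_same_axon_pairs=0, n_blebs=0, seed=11)
    return cfg, simulate_session(cfg)


@pytest.fixture(scope="session")
def default_session():
    """Default-parameter session with controls attached."""
    cfg = SimConfig(duration_s=300.0, frame_rate_hz=10.0, n_axons=8,
                    n_same_axon_pairs=1, n_blebs=2, n_mcherry=4, seed=5)
    return cfg, simulate_session(cfg)
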