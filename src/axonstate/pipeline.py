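"""End-to-end pipeline: simulate -> detect -> preprocess -> align ->
spectral -> encode -> decompose, with a reproducibility manifest.

Every stage writes deterministic CSV/JSON outputs (fixed float format, no
timestamps); rerunning with the same seed and config reproduces the
result tables byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aligned import align, responsiveness, sustainedness_test
from .behavior import detect_events
from .config import load_config, resolve_threshold
from .corrstruct import decompose_session, state_restricted_decompose
from .encoding import EncodingModel
from .preprocess import preprocess_session
from .session import Session, load_session, save_hdf5
from .simulate import SimConfig, simulate_session
from .spectral import band_power_profile, coherence, xcorr_lag

logger = logging.getLogger("axonstate")

FMT = "%.10g"


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are preserved in the output directory."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def _downsample(x: np.ndarray, fs: float, fs_out: float):
    step = int(round(fs / fs_out))
    return (x[..., ::step], fs / step)


def run_pipeline(config=None, seed: int = 0, outdir: str | Path = "results",
                 session: Session | None = None) -> dict:
    """Run the configured stages and write a result bundle.

    Returns a dict with the per-stage results and writes CSV/JSON outputs
    plus ``manifest.json`` to ``outdir``.  Any stage failure raises
    :class:`PipelineError` naming the stage; outputs of completed stages
    remain on disk.
    """
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(cfg["stages"])
    completed: list[str] = []
    bundle: dict = {}
    manifest = {"seed": int(seed), "version": __version__, "config": cfg,
                "stages_completed": completed}

    def _write_manifest():
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str))

    current = "setup"
    try:
        if "simulate" in stages:
            current = "simulate"
            sim_cfg = SimConfig(**cfg["simulate"], seed=int(seed))
            session = simulate_session(sim_cfg, session_id=f"sim-{seed}")
            save_hdf5(session, outdir / "session.h5")
            completed.append(current)
            logger.info("simulated session: %d objects, %.0f s",
                        session.n_objects, session.duration_s)
        elif session is None:
            current = "load"
            session = load_session(cfg["input"])
        bundle["session"] = session

        events = None
        if "detect" in stages:
            current = "detect"
            d = cfg["detect"]
            events = detect_events(session.behavior, **d)
            events.to_csv(outdir / "events.csv", index=False, float_format=FMT)
            logger.info("detected %d events (thresholds: %s)", len(events), d)
            completed.append(current)
        bundle["events"] = events

        dff = None
        fs = None
        if "preprocess" in stages:
            current = "preprocess"
            p = cfg["preprocess"]
            dff, report = preprocess_session(
                session.fluor, session.fs_fluor,
                object_ids=list(session.objects["object_id"]),
                fs_out=p["fs_out"], lp_hz=p["lp_hz"],
                snr_threshold=resolve_threshold(p["snr_threshold"]),
                log_scale=p["log_scale"])
            fs = float(p["fs_out"])
            report.to_csv(outdir / "qc.csv")
            bundle["qc"] = report
            completed.append(current)
        bundle["dff"] = dff
        bundle["fs"] = fs

        if "align" in stages and events is not None and dff is not None:
            current = "align"
            a = cfg["align"]
            whisks = events[events["kind"] == "whisk"]
            at = align(dff, fs, whisks,
                       window_s=(a["window_pre_s"], a["window_post_s"]))
            rows = []
            if at.n_events >= 2:
                rng = np.random.default_rng(np.random.SeedSequence([seed, 10]))
                resp = responsiveness(dff, fs, at.events, alpha=a["alpha"],
                                      n_shuffles=a["n_shuffles"], rng=rng)
                sus = sustainedness_test(at)
                for oid, fr in zip(session.objects["object_id"],
                                   resp.frac_events_per_object):
                    rows.append(dict(object_id=oid, frac_events_responding=fr))
                bundle["responsiveness"] = resp
                bundle["sustainedness"] = sus
            pd.DataFrame(rows).to_csv(outdir / "responsiveness.csv",
                                      index=False, float_format=FMT)
            bundle["aligned"] = at
            completed.append(current)

        if "spectral" in stages and dff is not None:
            current = "spectral"
            sp = cfg["spectral"]
            main = ~session.objects["population"].isin(["bleb", "mCherry"])
            pop_mean = dff[main.to_numpy()].mean(axis=0)
            t = np.arange(dff.shape[1]) / fs
            whisker = session.behavior_on(t)["mei_whisker"]
            coh = coherence(pop_mean, whisker, fs, window_s=sp["window_s"],
                            overlap=sp["overlap"])
            pd.DataFrame({"freq_hz": coh.freqs, "msc": coh.msc}).to_csv(
                outdir / "coherence.csv", index=False, float_format=FMT)
            xc = xcorr_lag(pop_mean, whisker, fs,
                           max_lag_s=sp["xcorr_max_lag_s"],
                           prefilter_hz=sp["lowpass_hz"])
            bp = band_power_profile(pop_mean, fs)
            (outdir / "spectral_summary.json").write_text(json.dumps({
                "xcorr_peak_lag_s": xc.peak_lag_s,
                "xcorr_peak_r": xc.peak_r,
                "power_frac_below": {str(k): v
                                     for k, v in bp.frac_below.items()},
            }, indent=2, sort_keys=True))
            bundle["coherence"] = coh
            bundle["xcorr"] = xc
            bundle["band_power"] = bp
            completed.append(current)

        if "encode" in stages and dff is not None:
            current = "encode"
            e = cfg["encode"]
            main = ~session.objects["population"].isin(["bleb", "mCherry"])
            pop_mean = dff[main.to_numpy()].mean(axis=0)
            y_ds, fs_ds = _downsample(pop_mean, fs, e["fit_fs"])
            model = EncodingModel.from_session(
                session, y_ds[None, :], fs_ds, lowpass_hz=e["lowpass_hz"],
                object_ids=["population_mean"])
            enc = model.fit(k_folds=e["k_folds"])
            enc.table.to_csv(outdir / "encoding.csv", index=False,
                             float_format=FMT)
            bundle["encoding"] = enc
            completed.append(current)

        if "decompose" in stages and dff is not None:
            current = "decompose"
            dc = cfg["decompose"]
            res = decompose_session(session, dff, fs,
                                    lowpass_hz=dc["lowpass_hz"])
            res.pairs.to_csv(outdir / "pairs.csv", index=False,
                             float_format=FMT)
            state = state_restricted_decompose(
                session, dff, fs, modes=tuple(dc["modes"]),
                min_duration_s=dc["min_duration_s"],
                lowpass_hz=dc["lowpass_hz"])
            summary = {m: {k: v for k, v in entry.items() if k != "results"}
                       for m, entry in state["modes"].items()}
            summary["skipped"] = state["skipped"]
            if "full_vs_still" in state:
                summary["full_vs_still"] = state["full_vs_still"]
            (outdir / "decompose_summary.json").write_text(
                json.dumps(summary, indent=2, sort_keys=True))
            bundle["decompose"] = res
            bundle["state_restricted"] = state
            completed.append(current)
    except Exception as exc:                       # noqa: BLE001
        manifest["failed_stage"] = current
        _write_manifest()
        raise PipelineError(current, exc) from exc

    _write_manifest()
    bundle["manifest"] = manifest
    return bundle
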