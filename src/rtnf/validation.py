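"""Streaming-vs-offline equivalence studies.

The package's primary validation statistic mirrors how real-time fMRI
pipelines are checked against their offline reference: run the full
streaming pipeline (folder watcher, per-volume motion correction,
smoothing, motion QC, feedback engine) on a synthetic session, recompute
the same feedback series offline with :func:`rtnf.runner.batch_replay`,
and report the Pearson correlation between the two series over time.

Each helper generates its session from scratch, streams it through a
watched folder, and returns ``{"r": ..., "n": ...}`` where ``n`` is the
session length in volumes.
"""

from __future__ import annotations

from pathlib import Path

from .protocols import (connectivity_protocol, emotional_protocol,
                        motor_protocol)
from .runner import SessionConfig, batch_replay, run
from .synth import generate_session, stream_session

__all__ = ["roi_equivalence", "svm_equivalence", "connectivity_equivalence"]

_FWHM_MM = 6.0


def roi_equivalence(workdir: str | Path, seed: int = 1) -> dict:
    """Motor-protocol ROI feedback: streamed vs replayed activation index.

    300 volumes, 15-volume imagery/rest alternation, 2% ROI amplitude,
    1% noise, linear drift.
    """
    workdir = Path(workdir)
    manifest = generate_session(motor_protocol(seed=seed), workdir / "session")
    watch = workdir / "watch"
    stream_session(manifest, watch)
    config = SessionConfig(
        mode="roi", rfi=manifest["rfi"], design=manifest["design"],
        n_volumes=manifest["n_volumes"], baseline_name="REST",
        watch_dir=str(watch), out_dir=str(workdir / "out"),
        rois={"premotor": manifest["rois"]["premotor"]},
        roi_name="premotor", fwhm_mm=_FWHM_MM)
    log = run(config)
    result = batch_replay(config, manifest["volumes_dir"], log=log)
    return {"r": result["r"], "n": manifest["n_volumes"]}


def svm_equivalence(workdir: str | Path, train_seed: int = 2,
                    test_seed: int = 3) -> dict:
    """Emotional-protocol decoding: streamed vs replayed decision values.

    Two 296-volume sessions (22-volume emotional blocks, 15-volume neutral
    baselines): the first trains the linear SVM after |t| > 5.5 GLM feature
    selection, the second is streamed in feedback mode and batch-replayed.
    """
    workdir = Path(workdir)
    train_man = generate_session(emotional_protocol(seed=train_seed),
                                 workdir / "train_session")
    watch1 = workdir / "watch_train"
    stream_session(train_man, watch1)
    train_config = SessionConfig(
        mode="svm_train", rfi=train_man["rfi"], design=train_man["design"],
        n_volumes=train_man["n_volumes"], baseline_name="NEUTRAL",
        watch_dir=str(watch1), out_dir=str(workdir / "train_out"),
        fwhm_mm=_FWHM_MM, svm_window=3,
        feature_mode="t_threshold", t_threshold=5.5)
    train_log = run(train_config)
    model_path = Path(train_config.out_dir) / "decoder_model.json"

    test_man = generate_session(emotional_protocol(seed=test_seed),
                                workdir / "test_session")
    watch2 = workdir / "watch_test"
    stream_session(test_man, watch2)
    test_config = SessionConfig(
        mode="svm_feedback", rfi=test_man["rfi"], design=test_man["design"],
        n_volumes=test_man["n_volumes"], baseline_name="NEUTRAL",
        watch_dir=str(watch2), out_dir=str(workdir / "test_out"),
        fwhm_mm=_FWHM_MM, model_path=str(model_path))
    log = run(test_config)
    result = batch_replay(test_config, test_man["volumes_dir"], log=log)
    return {"r": result["r"], "n": test_man["n_volumes"],
            "accuracy": log.summary.get("cumulative_accuracy"),
            "n_features": train_log.summary.get("n_features")}


def connectivity_equivalence(workdir: str | Path, seed: int = 4) -> dict:
    """Dual-ROI sliding-correlation feedback: streamed vs replayed ρ series.

    360 volumes, two ROIs sharing a block-gated latent signal, window
    L = 10, first five volumes discarded.
    """
    workdir = Path(workdir)
    manifest = generate_session(connectivity_protocol(seed=seed),
                                workdir / "session")
    watch = workdir / "watch"
    stream_session(manifest, watch)
    config = SessionConfig(
        mode="connectivity", rfi=manifest["rfi"], design=manifest["design"],
        n_volumes=manifest["n_volumes"], baseline_name="SUBTRACT",
        watch_dir=str(watch), out_dir=str(workdir / "out"),
        rois={"atl": manifest["rois"]["atl"], "sgc": manifest["rois"]["sgc"]},
        roi_a="atl", roi_b="sgc", corr_window=10, sigmoid_n=10,
        sd_window=10, sd_k=1.0, discard_initial=5, fwhm_mm=_FWHM_MM)
    log = run(config)
    result = batch_replay(config, manifest["volumes_dir"], log=log)
    return {"r": result["r"], "n": manifest["n_volumes"]}
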