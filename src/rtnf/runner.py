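"""Session orchestration: run the streaming pipeline, log it, replay it offline.

:func:`run` drives one session end to end — watch the export folder,
motion-correct each volume to the RFI, score its motion, smooth, and feed
the configured engine — writing the motion and feedback logs as it goes.
:func:`batch_replay` recomputes the same feedback statistic offline, in one
pass over the stored volumes, with an independent vectorised implementation
of the engine arithmetic; the Pearson correlation between the streamed and
replayed series is the package's primary validation statistic.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .design import (DesignSpec, FeatureMask, build_design_matrix, fit_glm,
                     parse_design, select_features)
from .engines import (ConnectivityEngine, DecoderModel, FeedbackSample,
                      RoiEngine, SvmFeedbackEngine, activation_map,
                      build_examples, train_decoder,
                      DEFAULT_DISCARD_INITIAL)
from .motion import (MotionMonitor, MotionRecord, write_motion_log,
                     DEFAULT_RMS_THRESHOLD, DEFAULT_RMS_WINDOW)
from .registration import (RigidTransform, center_of_mass_world,
                           motion_correct, register_affine, smooth)
from .stream import DEFAULT_PATTERN, watch_folder
from .volume import Volume, read_volume, write_volume

__all__ = ["SessionConfig", "SessionLog", "run", "batch_replay",
            "series_correlation", "ReplayMismatchError"]

MODES = ("roi", "connectivity", "svm_train", "svm_feedback")


class ReplayMismatchError(RuntimeError):
    pass


@dataclass
class SessionConfig:
    """Everything one session needs; loadable from a YAML file."""

    mode: str
    rfi: str
    design: str
    n_volumes: int
    tr: float = 2.0
    baseline_name: str = "REST"
    watch_dir: str = ""
    out_dir: str = "."
    rai: str | None = None
    register_to_rai: bool = False
    rois: dict[str, str] = field(default_factory=dict)   # name -> mask path
    fwhm_mm: float = 0.0
    discard_initial: int = DEFAULT_DISCARD_INITIAL
    # motion QC
    rms_window: int = DEFAULT_RMS_WINDOW
    rms_threshold: float = DEFAULT_RMS_THRESHOLD
    brain_radius_mm: float = 80.0
    # roi engine
    roi_name: str | None = None
    roi_n_avg: int = 1
    roi_r_max: float = 0.02
    # connectivity engine
    roi_a: str | None = None
    roi_b: str | None = None
    corr_window: int = 10
    sigmoid_n: int = 10
    sd_window: int = 10
    sd_k: float = 1.0
    # svm
    model_path: str | None = None
    svm_window: int = 3
    svm_C: float = 1.0
    t_threshold: float = 5.5
    feature_mode: str = "t_threshold"      # or "top_percent"
    top_percent: float | None = None
    feature_roi: str | None = None
    n_bins: int = 5
    d_max_percentile: float = 95.0
    motion_in_glm: bool = False
    # stream
    stream_timeout: float = 30.0
    stream_pattern: str = DEFAULT_PATTERN
    # sham (non-contingent) feedback: None | "random" | "replay:<tsv path>"
    sham: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.n_volumes < 1:
            raise ValueError("n_volumes must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SessionConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


@dataclass
class SessionLog:
    mode: str
    samples: list[FeedbackSample]
    motion: list[MotionRecord]
    events: list[str]
    summary: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_motion_log(self.motion, out / "motion.tsv")
        write_feedback_log(self.samples, out / "feedback.tsv", mode=self.mode)
        (out / "events.json").write_text(json.dumps(self.events, indent=2))
        (out / "summary.json").write_text(json.dumps(self.summary, indent=2))


def write_feedback_log(samples: list[FeedbackSample], path: str | Path,
                       mode: str = "") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# mode={mode}\n")
        fh.write("index\tcondition\tengine\traw\tlevel\tfrozen\tpredicted\n")
        for s in samples:
            fh.write(f"{s.index}\t{s.condition}\t{s.engine}\t{s.raw:.10g}\t"
                     f"{s.level:.10g}\t{int(s.frozen)}\t{s.predicted or ''}\n")
    return path


def read_feedback_log(path: str | Path) -> tuple[str, list[dict]]:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("# mode="):
        raise ReplayMismatchError(f"{path}: missing or corrupt log header")
    mode = lines[0].split("=", 1)[1]
    rows = []
    for line in lines[2:]:
        f = line.split("\t")
        rows.append({"index": int(f[0]), "condition": f[1], "engine": f[2],
                     "raw": float(f[3]), "level": float(f[4]),
                     "frozen": bool(int(f[5])), "predicted": f[6] or None})
    return mode, rows


def _load_masks(config: SessionConfig, rfi: Volume) -> dict[str, np.ndarray]:
    masks = {}
    for name, path in config.rois.items():
        v = read_volume(path)
        if v.shape != rfi.shape:
            raise ValueError(f"ROI {name!r} shape {v.shape} != RFI {rfi.shape}")
        masks[name] = v.data > 0.5
    return masks


def _build_engine(config: SessionConfig, masks: dict[str, np.ndarray],
                  model: DecoderModel | None):
    if config.mode == "roi":
        if config.roi_name not in masks:
            raise ValueError("roi mode needs roi_name referencing a loaded mask")
        return RoiEngine(masks[config.roi_name], config.baseline_name,
                         n_avg=config.roi_n_avg, r_max=config.roi_r_max,
                         discard_initial=config.discard_initial)
    if config.mode == "connectivity":
        if config.roi_a not in masks or config.roi_b not in masks:
            raise ValueError("connectivity mode needs roi_a and roi_b masks")
        return ConnectivityEngine(masks[config.roi_a], masks[config.roi_b],
                                  window=config.corr_window,
                                  sigmoid_n=config.sigmoid_n,
                                  sd_window=config.sd_window, sd_k=config.sd_k,
                                  discard_initial=config.discard_initial)
    if config.mode == "svm_feedback":
        if model is None:
            raise ValueError("svm_feedback mode needs a trained DecoderModel")
        return SvmFeedbackEngine(model, config.baseline_name,
                                 n_bins=config.n_bins,
                                 discard_initial=config.discard_initial)
    return None  # svm_train collects volumes, trains offline


def _preprocess_stream(config: SessionConfig, rfi: Volume):
    """Yield (index, corrected+smoothed data, MotionRecord) per streamed volume."""
    com = center_of_mass_world(rfi)
    monitor = MotionMonitor(window=config.rms_window,
                            threshold=config.rms_threshold,
                            radius_mm=config.brain_radius_mm)
    prev_t: RigidTransform | None = None
    for vol in watch_folder(config.watch_dir, config.n_volumes,
                            timeout=config.stream_timeout,
                            pattern=config.stream_pattern):
        t0 = time.perf_counter()
        corrected, t = motion_correct(vol, rfi, center=com, start=prev_t)
        prev_t = t
        rec = monitor.update(vol.index, t)
        data = smooth(corrected, config.fwhm_mm).data
        elapsed = time.perf_counter() - t0
        yield vol.index, data, rec, elapsed


def run(config: SessionConfig, keep_volumes: bool = False) -> SessionLog:
    """Execute one streaming session; returns (and writes) the session log.

    ``keep_volumes=True`` additionally retains the preprocessed volumes in
    memory on the returned log (``log.volumes``) for in-process analysis.
    """
    rfi = read_volume(config.rfi)
    design = parse_design(config.design, config.n_volumes, config.baseline_name)
    masks = _load_masks(config, rfi)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    events: list[str] = []

    if config.register_to_rai:
        if config.rai is None:
            raise ValueError("register_to_rai requires an RAI path")
        rai = read_volume(config.rai)
        affine = register_affine(rfi, rai)
        affine.save_txt(out / "rfi_to_rai.mat")
        events.append("registered RFI to RAI (12-DOF affine)")

    model = DecoderModel.load(config.model_path) \
        if config.mode == "svm_feedback" else None
    engine = _build_engine(config, masks, model)
    rng = np.random.default_rng(config.seed)

    labels = design.labels
    collected: list[np.ndarray] = []
    kept_flags: list[bool] = []
    motion_params = np.zeros((config.n_volumes, 6))
    records: list[MotionRecord] = []
    samples: list[FeedbackSample] = []
    wall_times: list[float] = []

    sham_replay = None
    if config.sham and config.sham.startswith("replay:"):
        _, rows = read_feedback_log(config.sham.split(":", 1)[1])
        sham_replay = {r["index"]: r["level"] for r in rows}

    for index, data, rec, elapsed in _preprocess_stream(config, rfi):
        records.append(rec)
        motion_params[index] = rec.transform.params
        wall_times.append(elapsed)
        kept = not rec.excessive
        kept_flags.append(kept)
        if rec.excessive:
            events.append(f"volume {index}: excessive motion "
                          f"(rms {rec.rms_mm:.3f} mm); feedback frozen")
        if config.mode == "svm_train" or keep_volumes:
            collected.append(data)
        if engine is not None:
            s = engine.update(index, data, labels[index], kept)
            if s is not None:
                if config.sham == "random":
                    s.level = float(rng.uniform(0, 100))
                elif sham_replay is not None:
                    s.level = sham_replay.get(s.index, s.level)
                samples.append(s)

    summary: dict = {
        "mode": config.mode,
        "n_volumes": config.n_volumes,
        "n_discarded": int(sum(r.excessive for r in records)),
        "mean_wall_time_s": float(np.mean(wall_times)),
        "max_wall_time_s": float(np.max(wall_times)),
    }

    if config.mode == "svm_train":
        model, train_summary = _train_from_session(
            config, design, masks, collected, kept_flags, motion_params)
        model.save(out / "decoder_model.json")
        write_volume(Volume(model.weight_volume(), rfi.affine),
                     out / "svm_weight_map.nii")
        summary.update(train_summary)
        events.append(f"trained decoder: {train_summary}")
    elif config.mode == "roi":
        raws = np.array([s.raw for s in samples])
        block_means = {}
        for blk in design.blocks:
            vals = [s.raw for s in samples
                    if blk.start <= s.index < blk.end and not s.frozen]
            if vals:
                block_means.setdefault(blk.name, []).append(float(np.mean(vals)))
        summary["mean_psc_per_condition"] = {
            k: float(np.mean(v)) for k, v in block_means.items()}
    elif config.mode == "connectivity":
        summary["rho_trajectory_mean"] = float(np.nanmean(
            [s.raw for s in samples])) if samples else None
    elif config.mode == "svm_feedback":
        summary["cumulative_accuracy"] = engine.accuracy

    log = SessionLog(mode=config.mode, samples=samples, motion=records,
                     events=events, summary=summary)
    log.write(out)
    if keep_volumes:
        log.volumes = collected  # type: ignore[attr-defined]
    return log


def _train_from_session(config, design, masks, volumes, kept_flags,
                        motion_params):
    """Offline localizer GLM, feature selection and SVM fit after run 1."""
    kept_idx = [i for i, k in enumerate(kept_flags) if k]
    Y = np.stack([volumes[i] for i in kept_idx]).reshape(len(kept_idx), -1)
    motion = motion_params if config.motion_in_glm else None
    X_full, names = build_design_matrix(design, config.tr, motion=motion)
    X = X_full[kept_idx]
    glm = fit_glm(Y, X, names, spatial_shape=volumes[0].shape)
    roi = None
    if config.feature_roi is not None:
        roi = FeatureMask.from_bool(masks[config.feature_roi])
    mask = select_features(
        glm, config.feature_mode, t_threshold=config.t_threshold,
        top_percent=config.top_percent, roi=roi)
    Xex, y, _ = build_examples(volumes, design.labels, kept_flags, mask,
                               config.baseline_name, window=config.svm_window,
                               discard_initial=config.discard_initial)
    model = train_decoder(Xex, y, mask, window=config.svm_window,
                          C=config.svm_C,
                          d_max_percentile=config.d_max_percentile)
    return model, {
        "n_features": len(mask),
        "n_examples": len(y),
        "training_accuracy": model.training_accuracy,
        "classes": list(model.classes),
    }


# ---------------------------------------------------------------------------
# Offline batch replay (independent vectorised recomputation)

def _replay_preprocess(config: SessionConfig, rfi: Volume,
                       volumes_dir: str | Path):
    """Cold-start motion correction + smoothing over all stored volumes."""
    com = center_of_mass_world(rfi)
    monitor = MotionMonitor(window=config.rms_window,
                            threshold=config.rms_threshold,
                            radius_mm=config.brain_radius_mm)
    paths = sorted(Path(volumes_dir).glob("vol_*.nii"))[:config.n_volumes]
    if len(paths) != config.n_volumes:
        raise ReplayMismatchError(
            f"expected {config.n_volumes} stored volumes, found {len(paths)}")
    data = []
    for i, p in enumerate(paths):
        vol = read_volume(p, index=i)
        corrected, t = motion_correct(vol, rfi, center=com)
        monitor.update(i, t)
        data.append(smooth(corrected, config.fwhm_mm).data)
    kept = [not r.excessive for r in monitor.records]
    return data, kept


def _baseline_means(data, labels, kept, baseline_name, discard):
    """Per-volume lookup of the previous completed baseline block mean.

    Returns a list where entry t is the per-voxel mean of the most recent
    baseline block fully completed before volume t (QC-kept volumes only,
    indices >= discard), or None while undefined. Blocks with no usable
    volume leave the previous mean in force.
    """
    n = len(data)
    spec = DesignSpec(labels=list(labels), baseline_name=baseline_name)
    finals = []  # (block_end, mean) at completion time
    for blk in spec.blocks:
        if blk.name != baseline_name:
            continue
        use = [i for i in range(max(blk.start, discard), blk.end) if kept[i]]
        if use:
            finals.append((blk.end, np.mean(np.stack([data[i] for i in use]),
                                            axis=0)))
    out = []
    for t in range(n):
        current = None
        for end, mean in finals:
            if end <= t:
                current = mean
        out.append(current)
    return out


def _replay_roi(data, labels, kept, mask, config: SessionConfig):
    base = _baseline_means(data, labels, kept, config.baseline_name,
                           config.discard_initial)
    mask = np.asarray(mask).astype(bool)
    raw = np.full(len(data), np.nan)
    recent: list[float] = []
    for t in range(config.discard_initial, len(data)):
        if not kept[t]:
            continue
        recent.append(float(data[t][mask].mean()))
        if base[t] is None:
            continue
        b = float(base[t][mask].mean())
        m = float(np.mean(recent[-config.roi_n_avg:]))
        raw[t] = (m - b) / b
    return raw


def _replay_connectivity(data, labels, kept, mask_a, mask_b,
                         config: SessionConfig):
    mask_a = np.asarray(mask_a).astype(bool)
    mask_b = np.asarray(mask_b).astype(bool)
    raw = np.full(len(data), np.nan)
    pairs: list[tuple[float, float]] = []
    L = config.corr_window
    for t in range(config.discard_initial, len(data)):
        if not kept[t]:
            continue
        pairs.append((float(data[t][mask_a].mean()),
                      float(data[t][mask_b].mean())))
        if len(pairs) >= L:
            win = np.array(pairs[-L:])
            if win[:, 0].std() > 0 and win[:, 1].std() > 0:
                raw[t] = float(np.corrcoef(win[:, 0], win[:, 1])[0, 1])
    return raw


def _replay_svm(data, labels, kept, model: DecoderModel,
                config: SessionConfig):
    base = _baseline_means(data, labels, kept, config.baseline_name,
                           config.discard_initial)
    raw = np.full(len(data), np.nan)
    w = config.discard_initial
    win = model.window
    for t in range(max(w, win - 1), len(data)):
        lo = t - win + 1
        if lo < w:
            continue
        lab = labels[t]
        if lab == config.baseline_name or base[t] is None:
            continue
        if any(labels[s] != lab or not kept[s] for s in range(lo, t + 1)):
            continue
        avg = np.mean(np.stack([data[s] for s in range(lo, t + 1)]), axis=0)
        ratio = activation_map(avg, base[t])
        vec = ratio.ravel()[model.mask.indices]
        raw[t] = float(np.dot(vec, model.w) + model.b)
    return raw


def batch_replay(config: SessionConfig, volumes_dir: str | Path,
                 log: SessionLog | None = None) -> dict:
    """Recompute the feedback statistic offline from the stored volumes.

    Runs cold-start motion correction over every stored volume in one
    batch pass, then evaluates the configured engine's raw statistic with
    a vectorised implementation that shares no state machinery with the
    streaming engines. If a streamed ``log`` is given, the Pearson r
    between streamed and replayed raw series (over indices defined in
    both) is included in the result.
    """
    rfi = read_volume(config.rfi)
    design = parse_design(config.design, config.n_volumes, config.baseline_name)
    masks = _load_masks(config, rfi)
    data, kept = _replay_preprocess(config, rfi, volumes_dir)
    labels = design.labels
    if config.mode == "roi":
        raw = _replay_roi(data, labels, kept, masks[config.roi_name], config)
    elif config.mode == "connectivity":
        raw = _replay_connectivity(data, labels, kept, masks[config.roi_a],
                                   masks[config.roi_b], config)
    elif config.mode == "svm_feedback":
        model = DecoderModel.load(config.model_path)
        raw = _replay_svm(data, labels, kept, model, config)
    else:
        raise ValueError(f"batch_replay does not apply to mode {config.mode!r}")
    result = {"raw": raw, "kept": kept}
    if log is not None:
        if log.mode != config.mode:
            raise ReplayMismatchError(
                f"log mode {log.mode!r} != config mode {config.mode!r}")
        streamed = np.full(config.n_volumes, np.nan)
        for s in log.samples:
            if not s.frozen:
                streamed[s.index] = s.raw
        result["r"] = series_correlation(streamed, raw)
        result["streamed"] = streamed
    return result


def load_session_log(out_dir: str | Path) -> SessionLog:
    """Rebuild a minimal SessionLog from a written feedback.tsv."""
    mode, rows = read_feedback_log(Path(out_dir) / "feedback.tsv")
    samples = [FeedbackSample(index=r["index"], engine=r["engine"],
                              condition=r["condition"], raw=r["raw"],
                              level=r["level"], frozen=r["frozen"],
                              predicted=r["predicted"]) for r in rows]
    return SessionLog(mode=mode, samples=samples, motion=[], events=[],
                      summary={})


def series_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r over the indices where both series are defined."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 jointly defined time points")
    return float(np.corrcoef(a[ok], b[ok])[0, 1])
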