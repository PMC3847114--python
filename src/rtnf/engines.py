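"""Feedback engines: ROI percent-signal-change, dual-ROI sliding-window
correlation, and linear-SVM decoding.

All three engines consume the same per-volume stream of preprocessed
(motion-corrected, smoothed) volumes together with the design label and the
motion-QC keep/discard flag, and emit one :class:`FeedbackSample` per
volume after the initial discard prefix. Signal normalisation is anchored
to the most recently *completed* baseline block: each engine subtracts (and
divides by) the per-voxel or per-ROI mean of that block, which removes slow
scanner drift without ever looking ahead in time.

QC contract: a volume flagged for excessive motion freezes the displayed
level at its previous value and is excluded from every estimator — baseline
means, ROI sliding means, correlation buffers and decoder example windows.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

from .design import FeatureMask

__all__ = [
    "FeedbackSample",
    "BaselineState",
    "BaselineTracker",
    "RoiEngine",
    "ConnectivityEngine",
    "SvmFeedbackEngine",
    "DecoderModel",
    "sliding_correlation",
    "sigmoid_weights",
    "thermometer_scale",
    "activation_map",
    "build_examples",
    "train_decoder",
    "decode_bin",
    "cumulative_accuracy",
    "DEFAULT_DISCARD_INITIAL",
]

DEFAULT_DISCARD_INITIAL = 5


@dataclass
class FeedbackSample:
    """Per-volume engine output.

    ``raw`` is the engine statistic (PSC ratio, sliding ρ, or SVM decision
    value; NaN when undefined), ``level`` the display value (0–100 for
    thermometers, bin index for figure grids). Frozen samples repeat the
    previous level.
    """

    index: int
    engine: str
    condition: str
    raw: float
    level: float
    frozen: bool
    predicted: str | None = None


@dataclass
class BaselineState:
    """Per-voxel mean of the most recently completed baseline block."""

    mean: np.ndarray
    block_start: int
    n_used: int

    def roi_mean(self, mask: np.ndarray) -> float:
        return float(self.mean[mask].mean())


class BaselineTracker:
    """Watches the label stream and finalises baseline-block means.

    The per-voxel mean is recomputed at each baseline-block *completion*
    (transition away from the baseline label), never mid-block, and uses
    only QC-kept volumes. If every volume of a block was discarded the
    previous state is retained and a warning is recorded.
    """

    def __init__(self, baseline_name: str):
        self.baseline_name = baseline_name
        self.state: BaselineState | None = None
        self.warnings: list[str] = []
        self._accum_sum: np.ndarray | None = None
        self._accum_n = 0
        self._block_start: int | None = None
        self._in_baseline = False

    def update(self, index: int, data: np.ndarray, label: str, kept: bool) -> None:
        is_base = label == self.baseline_name
        if is_base and not self._in_baseline:
            self._accum_sum = None
            self._accum_n = 0
            self._block_start = index
            self._in_baseline = True
        if not is_base and self._in_baseline:
            self._finalize()
            self._in_baseline = False
        if is_base and kept:
            if self._accum_sum is None:
                self._accum_sum = data.astype(float).copy()
            else:
                self._accum_sum += data
            self._accum_n += 1

    def _finalize(self) -> None:
        if self._accum_n > 0:
            self.state = BaselineState(
                mean=self._accum_sum / self._accum_n,
                block_start=self._block_start,
                n_used=self._accum_n,
            )
        else:
            self.warnings.append(
                f"baseline block starting at volume {self._block_start} had no "
                "usable volumes; retaining previous baseline state"
            )


# ---------------------------------------------------------------------------
# ROI percent-signal-change engine

def activation_map(current_mean: np.ndarray, baseline_mean: np.ndarray) -> np.ndarray:
    """Voxelwise (current − baseline) / baseline map; baseline-0 voxels → 0."""
    out = np.zeros_like(baseline_mean, dtype=float)
    ok = baseline_mean != 0
    out[ok] = (current_mean[ok] - baseline_mean[ok]) / baseline_mean[ok]
    return out


class RoiEngine:
    """Single-ROI percent-signal-change thermometer.

    raw = (m − b) / b where m is the sliding mean of the last ``n_avg``
    kept ROI means and b the ROI mean of the previous baseline block;
    level = clip(raw / r_max, 0, 1) · 100 with full-scale ``r_max``
    (default 2% signal change).
    """

    name = "roi"

    def __init__(self, mask: np.ndarray, baseline_name: str,
                 n_avg: int = 1, r_max: float = 0.02,
                 discard_initial: int = DEFAULT_DISCARD_INITIAL,
                 map_window: int = 3):
        self.mask = np.asarray(mask).astype(bool)
        if not self.mask.any():
            raise ValueError("ROI mask is empty")
        self.baseline = BaselineTracker(baseline_name)
        self.n_avg = int(n_avg)
        self.r_max = float(r_max)
        self.discard_initial = int(discard_initial)
        self.map_window = int(map_window)
        self._roi_means: deque[float] = deque(maxlen=self.n_avg)
        self._recent: deque[np.ndarray] = deque(maxlen=self.map_window)
        self._last_level = 0.0
        self.samples: list[FeedbackSample] = []

    def _frozen(self, index: int, condition: str) -> FeedbackSample:
        return FeedbackSample(index, self.name, condition, float("nan"),
                              self._last_level, True)

    def update(self, index: int, data: np.ndarray, label: str, kept: bool
               ) -> FeedbackSample | None:
        if index < self.discard_initial:
            return None
        self.baseline.update(index, data, label, kept)
        if not kept:
            s = self._frozen(index, label)
        else:
            self._roi_means.append(float(data[self.mask].mean()))
            self._recent.append(data)
            base = self.baseline.state
            if base is None:
                s = self._frozen(index, label)
            else:
                b = base.roi_mean(self.mask)
                if b == 0:
                    raise ZeroDivisionError(
                        "baseline ROI mean is zero; degenerate mask")
                m = float(np.mean(self._roi_means))
                raw = (m - b) / b
                level = float(np.clip(raw / self.r_max, 0.0, 1.0) * 100.0)
                s = FeedbackSample(index, self.name, label, raw, level, False)
                self._last_level = level
        self.samples.append(s)
        return s

    def current_activation_map(self) -> np.ndarray:
        """Ratio map of the mean of the last ``map_window`` kept volumes."""
        if self.baseline.state is None or not self._recent:
            raise RuntimeError("no baseline state or no volumes yet")
        cur = np.mean(np.stack(list(self._recent)), axis=0)
        return activation_map(cur, self.baseline.state.mean)


# ---------------------------------------------------------------------------
# Dual-ROI sliding-window correlation engine

def sliding_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation over one window of paired ROI means.

    Direct evaluation of ρ = Σ(aₖ−ā)(bₖ−b̄) / √(Σ(aₖ−ā)² Σ(bₖ−b̄)²).
    Returns NaN when either window has zero variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    da = a - a.sum() / a.size
    db = b - b.sum() / b.size
    denom = np.sqrt((da * da).sum() * (db * db).sum())
    if denom == 0:
        return float("nan")
    return float((da * db).sum() / denom)


def sigmoid_weights(n: int) -> np.ndarray:
    """Logistic recency weights w_j = 1/(1+exp(j − n/2)), j=0 (newest)…n−1.

    Strictly decreasing in j; slope 1 on the logistic. Not normalised —
    callers divide by the sum.
    """
    j = np.arange(n, dtype=float)
    return 1.0 / (1.0 + np.exp(j - n / 2.0))


def thermometer_scale(rho_history: list[float], sigmoid_n: int = 10,
                      sd_window: int = 10, sd_k: float = 1.0
                      ) -> tuple[float, float, float] | None:
    """Adaptive thermometer bounds from the recent ρ history.

    midline: sigmoid-recency-weighted mean of the last ``sigmoid_n`` ρ
    values (newest gets the largest weight); bounds: midline ∓ k·sd of the
    last ``sd_window`` ρ values. Returns None when the scale is degenerate
    (fewer than 2 values, or zero sd) — the caller holds previous bounds.
    """
    h = np.asarray(rho_history, dtype=float)
    if h.size < 2:
        return None
    recent = h[-sigmoid_n:][::-1]            # newest first
    w = sigmoid_weights(len(recent))
    midline = float((w * recent).sum() / w.sum())
    sd = float(np.std(h[-sd_window:], ddof=1))
    if sd == 0:
        return None
    return midline, midline - sd_k * sd, midline + sd_k * sd


class ConnectivityEngine:
    """Dual-ROI sliding-window Pearson-correlation thermometer.

    On each kept volume the pair of ROI means is pushed into a ring buffer;
    once ``window`` kept pairs have accumulated (after the initial discard
    prefix) ρ is the Pearson correlation of the last ``window`` pairs.
    The display scale floats: the midline is a sigmoid-recency-weighted
    mean of recent ρ values and the bounds sit ``sd_k`` standard deviations
    of recent ρ away. Before the buffer fills, samples are emitted frozen
    at the midline level (50).
    """

    name = "connectivity"

    def __init__(self, mask_a: np.ndarray, mask_b: np.ndarray,
                 window: int = 10, sigmoid_n: int = 10,
                 sd_window: int = 10, sd_k: float = 1.0,
                 discard_initial: int = DEFAULT_DISCARD_INITIAL):
        self.mask_a = np.asarray(mask_a).astype(bool)
        self.mask_b = np.asarray(mask_b).astype(bool)
        if not self.mask_a.any() or not self.mask_b.any():
            raise ValueError("both ROI masks must be non-empty")
        self.window = int(window)
        self.sigmoid_n = int(sigmoid_n)
        self.sd_window = int(sd_window)
        self.sd_k = float(sd_k)
        self.discard_initial = int(discard_initial)
        self._pairs: deque[tuple[float, float]] = deque(maxlen=self.window)
        self.rho_history: list[float] = []
        self._bounds: tuple[float, float, float] | None = None
        self._last_level = 50.0
        self.samples: list[FeedbackSample] = []

    def update(self, index: int, data: np.ndarray, label: str, kept: bool
               ) -> FeedbackSample | None:
        if index < self.discard_initial:
            return None
        if not kept:
            s = FeedbackSample(index, self.name, label, float("nan"),
                               self._last_level, True)
            self.samples.append(s)
            return s
        self._pairs.append((float(data[self.mask_a].mean()),
                            float(data[self.mask_b].mean())))
        if len(self._pairs) < self.window:
            s = FeedbackSample(index, self.name, label, float("nan"),
                               self._last_level, True)
            self.samples.append(s)
            return s
        pairs = np.array(self._pairs)
        rho = sliding_correlation(pairs[:, 0], pairs[:, 1])
        if np.isnan(rho):
            s = FeedbackSample(index, self.name, label, float("nan"),
                               self._last_level, True)
            self.samples.append(s)
            return s
        self.rho_history.append(rho)
        scale = thermometer_scale(self.rho_history, self.sigmoid_n,
                                  self.sd_window, self.sd_k)
        if scale is not None:
            self._bounds = scale
        if self._bounds is None:
            level = 50.0     # ρ at the midline by convention
        else:
            _, lower, upper = self._bounds
            level = float(np.clip((rho - lower) / (upper - lower), 0, 1) * 100)
        self._last_level = level
        s = FeedbackSample(index, self.name, label, rho, level, False)
        self.samples.append(s)
        return s


# ---------------------------------------------------------------------------
# Linear-SVM decoding engine

@dataclass
class DecoderModel:
    """Two-class linear SVM in voxel space: decision value = x·w + b."""

    w: np.ndarray                    # weights over mask voxels
    b: float
    classes: tuple[str, str]         # (negative-side, positive-side)
    mask: FeatureMask
    window: int = 3
    d_max: float = 1.0               # full-scale |decision| for display bins
    C: float = 1.0
    training_accuracy: float | None = None

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.size != len(self.mask):
            raise ValueError("weight vector length must equal mask size")

    def decision(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        if x.size != self.w.size:
            raise ValueError(
                f"feature vector length {x.size} != mask size {self.w.size}")
        return float(x @ self.w + self.b)

    def predict(self, x: np.ndarray) -> str:
        return self.classes[1] if self.decision(x) >= 0 else self.classes[0]

    def weight_volume(self) -> np.ndarray:
        """Weight map in reference-functional space (0 outside the mask)."""
        grid = np.zeros(int(np.prod(self.mask.shape)))
        grid[self.mask.indices] = self.w
        return grid.reshape(self.mask.shape)

    def save(self, path: str | Path) -> None:
        payload = {
            "w": self.w.tolist(), "b": self.b, "classes": list(self.classes),
            "mask_indices": self.mask.indices.tolist(),
            "mask_shape": list(self.mask.shape),
            "window": self.window, "d_max": self.d_max, "C": self.C,
            "training_accuracy": self.training_accuracy,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "DecoderModel":
        d = json.loads(Path(path).read_text())
        mask = FeatureMask(np.array(d["mask_indices"]), tuple(d["mask_shape"]))
        return cls(w=np.array(d["w"]), b=d["b"], classes=tuple(d["classes"]),
                   mask=mask, window=d["window"], d_max=d["d_max"], C=d["C"],
                   training_accuracy=d.get("training_accuracy"))


def build_examples(
    volumes: list[np.ndarray],
    labels: list[str],
    kept: list[bool],
    mask: FeatureMask,
    baseline_name: str,
    window: int = 3,
    discard_initial: int = DEFAULT_DISCARD_INITIAL,
) -> tuple[np.ndarray, list[str], list[int]]:
    """Sliding-window-averaged, baseline-normalised training examples.

    For each volume t with a non-baseline label, an example is the masked
    voxel vector of the mean of volumes t−window+1..t, provided all of them
    share the same label, none was QC-discarded, and a completed baseline
    block exists; the vector is normalised voxelwise as (x − b)/b against
    the current baseline mean. Windows straddling a label change or a
    discarded volume are skipped. Returns (X, y, volume_indices).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    tracker = BaselineTracker(baseline_name)
    X: list[np.ndarray] = []
    y: list[str] = []
    idx: list[int] = []
    for t, (data, lab, keep) in enumerate(zip(volumes, labels, kept)):
        if t < discard_initial:
            continue
        tracker.update(t, data, lab, keep)
        if lab == baseline_name or not keep:
            continue
        lo = t - window + 1
        if lo < discard_initial:
            continue
        if any(labels[s] != lab or not kept[s] for s in range(lo, t + 1)):
            continue
        base = tracker.state
        if base is None:
            continue
        avg = np.mean(np.stack(volumes[lo:t + 1]), axis=0)
        vec = mask.extract(activation_map(avg, base.mean))
        X.append(vec)
        y.append(lab)
        idx.append(t)
    return (np.array(X) if X else np.empty((0, len(mask)))), y, idx


def train_decoder(X: np.ndarray, y: list[str], mask: FeatureMask,
                  window: int = 3, C: float = 1.0,
                  d_max_percentile: float = 95.0) -> DecoderModel:
    """Fit the two-class soft-margin linear SVM on prepared examples.

    Stores the hyperplane (w, b) in voxel space so a weight map can be
    exported, the training-set accuracy, and the display full-scale
    ``d_max`` (the given percentile of |decision| over training examples).
    """
    classes = sorted(set(y))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    counts = {c: y.count(c) for c in classes}
    if min(counts.values()) < 2:
        raise ValueError(f"need >= 2 examples per class, got {counts}")
    svc = SVC(kernel="linear", C=C)
    svc.fit(X, y)
    w = svc.coef_.ravel()
    b = float(svc.intercept_[0])
    dec = X @ w + b
    d_max = float(np.percentile(np.abs(dec), d_max_percentile))
    if d_max == 0:
        d_max = 1.0
    pred = [classes[1] if d >= 0 else classes[0] for d in dec]
    acc = 100.0 * np.mean([p == t for p, t in zip(pred, y)])
    return DecoderModel(w=w, b=b, classes=(classes[0], classes[1]), mask=mask,
                        window=window, d_max=d_max, C=C,
                        training_accuracy=float(acc))


def decode_bin(decision: float, cued: str, model: DecoderModel,
               n_bins: int = 5) -> int:
    """Map a decision value onto the feedback figure grid for the cued class.

    The cue picks the figure family; the decision value picks distortion:
    bin 0 is the most distorted figure (confidently classified as the
    *other* class), bin ``2·n_bins − 1`` the smoothest (confidently the
    cued class). Signed distance toward the cued class is
    ``+decision`` when the cue is the positive-side class, ``−decision``
    otherwise; it is clipped at ±d_max and mapped uniformly onto the bins.
    """
    signed = decision if cued == model.classes[1] else -decision
    z = np.clip(signed / model.d_max, -1.0, 1.0)
    return int(min(np.floor((z + 1.0) / 2.0 * 2 * n_bins), 2 * n_bins - 1))


def cumulative_accuracy(n_correct: int, n_scored: int) -> float:
    """Running classification accuracy in percent."""
    if n_scored < 1:
        raise ValueError("need at least one scored scan")
    return 100.0 * n_correct / n_scored


class SvmFeedbackEngine:
    """Real-time decoding feedback from a trained linear SVM.

    Each kept non-baseline volume ends a ``window``-volume averaging window;
    if the window is clean (single label, no discards) the averaged,
    baseline-normalised, masked pattern is projected on the hyperplane
    (x·w + b). The decision value is emitted as ``raw``, the figure-grid
    bin as ``level``, and the running cumulative accuracy against the cued
    condition is tracked.
    """

    name = "svm"

    def __init__(self, model: DecoderModel, baseline_name: str,
                 n_bins: int = 5,
                 discard_initial: int = DEFAULT_DISCARD_INITIAL):
        self.model = model
        self.baseline = BaselineTracker(baseline_name)
        self.n_bins = int(n_bins)
        self.discard_initial = int(discard_initial)
        w = model.window
        self._recent: deque[tuple[str, bool, np.ndarray]] = deque(maxlen=w)
        self.n_correct = 0
        self.n_scored = 0
        self._last_level = float(self.n_bins)  # boundary bin
        self.samples: list[FeedbackSample] = []

    @property
    def accuracy(self) -> float | None:
        if self.n_scored == 0:
            return None
        return cumulative_accuracy(self.n_correct, self.n_scored)

    def update(self, index: int, data: np.ndarray, label: str, kept: bool
               ) -> FeedbackSample | None:
        if index < self.discard_initial:
            return None
        self.baseline.update(index, data, label, kept)
        self._recent.append((label, kept, data))
        base = self.baseline.state
        eligible = (
            kept
            and label != self.baseline.baseline_name
            and base is not None
            and len(self._recent) == self.model.window
            and all(l == label and k for l, k, _ in self._recent)
        )
        if not eligible:
            s = FeedbackSample(index, self.name, label, float("nan"),
                               self._last_level, True)
            self.samples.append(s)
            return s
        avg = np.mean(np.stack([d for _, _, d in self._recent]), axis=0)
        vec = self.model.mask.extract(activation_map(avg, base.mean))
        decision = self.model.decision(vec)
        predicted = self.model.classes[1] if decision >= 0 else self.model.classes[0]
        self.n_scored += 1
        if predicted == label:
            self.n_correct += 1
        level = float(decode_bin(decision, label, self.model, self.n_bins))
        self._last_level = level
        s = FeedbackSample(index, self.name, label, decision, level, False,
                           predicted=predicted)
        self.samples.append(s)
        return s
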