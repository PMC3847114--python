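"""Head-motion quality control.

Each realigned volume gets a scalar root-mean-square (RMS) displacement —
the mean displacement a rigid transform imposes on the voxels of a sphere
of brain-like radius — and is flagged as excessive when its RMS deviates
from a moving average of the recent history by more than a fixed threshold
(0.4 mm over a 40-volume window by default). Flagged volumes freeze the
displayed feedback at its previous level and are excluded from every
estimator downstream: baseline means, ROI averages, correlation buffers
and decoder example averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .registration import RigidTransform

__all__ = [
    "MotionRecord",
    "rms_displacement",
    "classify_motion",
    "MotionMonitor",
    "write_motion_log",
    "DEFAULT_RMS_WINDOW",
    "DEFAULT_RMS_THRESHOLD",
    "DEFAULT_BRAIN_RADIUS_MM",
]

DEFAULT_RMS_WINDOW = 40
DEFAULT_RMS_THRESHOLD = 0.4  # mm, absolute deviation from the moving mean
DEFAULT_BRAIN_RADIUS_MM = 80.0


@dataclass
class MotionRecord:
    index: int
    transform: RigidTransform
    rms_mm: float
    flag: str  # "ok" | "excessive"

    @property
    def excessive(self) -> bool:
        return self.flag == "excessive"


def rms_displacement(
    t: RigidTransform,
    radius_mm: float = DEFAULT_BRAIN_RADIUS_MM,
) -> float:
    """RMS voxel displacement of a rigid transform over a spherical brain.

    Evaluated in the frame centred on the rotation centre, where the
    homogeneous matrix is ``T = [[R, t], [0, 1]]``. With
    ``M = T - I = [[A, b], [0, 0]]`` the mean squared displacement over a
    uniform solid sphere of radius R centred there is

        RMS^2 = (1/5) R^2 trace(A^T A) + b^T b

    (⟨x xᵀ⟩ = R²/5 · I over the ball). The identity transform gives 0 and a
    pure translation gives its Euclidean norm.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    M = t.matrix(np.zeros(3)) - np.eye(4)
    A = M[:3, :3]
    b = M[:3, 3]
    return float(np.sqrt(0.2 * radius_mm**2 * np.trace(A.T @ A) + b @ b))


def classify_motion(
    history: list[float] | np.ndarray,
    window: int = DEFAULT_RMS_WINDOW,
    threshold: float = DEFAULT_RMS_THRESHOLD,
) -> str:
    """Flag the newest RMS value against the moving mean of its predecessors.

    ``history`` is the RMS series up to and including the current volume.
    The flag is ``"excessive"`` iff the current value deviates from the mean
    of the last ``window`` prior values by strictly more than ``threshold``.
    During warm-up the mean uses whatever prior values exist; the first
    volume is always ok.
    """
    h = np.asarray(history, dtype=float)
    if h.size == 0:
        raise ValueError("history must be non-empty")
    if h.size == 1:
        return "ok"
    current = h[-1]
    prior = h[:-1][-window:]
    return "excessive" if abs(current - prior.mean()) > threshold else "ok"


class MotionMonitor:
    """Streaming wrapper: feed per-volume transforms, get MotionRecords."""

    def __init__(
        self,
        window: int = DEFAULT_RMS_WINDOW,
        threshold: float = DEFAULT_RMS_THRESHOLD,
        radius_mm: float = DEFAULT_BRAIN_RADIUS_MM,
    ):
        self.window = window
        self.threshold = threshold
        self.radius_mm = radius_mm
        self.records: list[MotionRecord] = []
        self._rms_history: list[float] = []

    def update(self, index: int, t: RigidTransform) -> MotionRecord:
        rms = rms_displacement(t, self.radius_mm)
        self._rms_history.append(rms)
        flag = classify_motion(self._rms_history, self.window, self.threshold)
        rec = MotionRecord(index=index, transform=t, rms_mm=rms, flag=flag)
        self.records.append(rec)
        return rec


_LOG_HEADER = ("index", "rot_x_rad", "rot_y_rad", "rot_z_rad",
               "trans_x_mm", "trans_y_mm", "trans_z_mm", "rms_mm", "flag")


def write_motion_log(records: list[MotionRecord], path: str | Path) -> Path:
    """Motion log as TSV: index, 3 rotations (rad), 3 translations (mm), RMS, flag."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(_LOG_HEADER) + "\n")
        for r in records:
            row = [str(r.index)]
            row += [f"{v:.8g}" for v in r.transform.rotations]
            row += [f"{v:.8g}" for v in r.transform.translations]
            row += [f"{r.rms_mm:.8g}", r.flag]
            fh.write("\t".join(row) + "\n")
    return path
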