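"""Block design parsing, GLM localizer fitting and voxel feature selection.

The experimental design arrives as a plain ASCII file with one condition
token per line (line *i* labels volume *i*, 0-based; ``#`` starts a
comment). Exactly one condition is designated the baseline ("condition of
no interest") and is interleaved between task blocks so every feedback
computation can normalise against the most recent completed baseline.

The functional-localizer GLM is an ordinary least-squares fit, voxel by
voxel, of the preprocessed time series on boxcar regressors convolved with
a canonical double-gamma hemodynamic response function, an intercept, and
optionally the six rigid motion parameters as nuisance regressors. Feature
selection thresholds the |t| map (pooling all pairwise contrasts) or keeps
the top percentage of voxels within an anatomical region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
from scipy.stats import gamma as gamma_dist

__all__ = [
    "Block",
    "DesignSpec",
    "parse_design",
    "hrf_double_gamma",
    "build_design_matrix",
    "GLMResult",
    "fit_glm",
    "FeatureMask",
    "select_features",
    "DesignError",
    "EmptySelectionError",
]


class DesignError(ValueError):
    pass


class EmptySelectionError(ValueError):
    """Feature selection produced no voxels; advise lowering the threshold."""


@dataclass(frozen=True)
class Block:
    start: int      # first volume index, inclusive
    end: int        # one past the last volume, half-open
    name: str

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class DesignSpec:
    """Per-volume condition labels plus derived block structure."""

    labels: list[str]
    baseline_name: str

    def __post_init__(self) -> None:
        if self.baseline_name not in self.labels:
            raise DesignError(
                f"baseline condition {self.baseline_name!r} never occurs in the design"
            )

    @property
    def n_volumes(self) -> int:
        return len(self.labels)

    @property
    def conditions(self) -> list[str]:
        """Condition names in order of first appearance."""
        seen: list[str] = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(lab)
        return seen

    @property
    def task_conditions(self) -> list[str]:
        return [c for c in self.conditions if c != self.baseline_name]

    @property
    def blocks(self) -> list[Block]:
        out: list[Block] = []
        start = 0
        for i in range(1, len(self.labels) + 1):
            if i == len(self.labels) or self.labels[i] != self.labels[i - 1]:
                out.append(Block(start, i, self.labels[i - 1]))
                start = i
        return out

    def boxcar(self, condition: str) -> np.ndarray:
        return np.array([1.0 if l == condition else 0.0 for l in self.labels])


def parse_design(path: str | Path, n_volumes: int, baseline_name: str) -> DesignSpec:
    """Parse the ASCII design file: one whitespace-trimmed token per line.

    Blank lines and ``#`` comments are ignored. The number of tokens must
    equal ``n_volumes`` and the baseline condition must appear.
    """
    labels: list[str] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            labels.append(line)
    if len(labels) != n_volumes:
        raise DesignError(
            f"design file {path} has {len(labels)} condition entries "
            f"but the session expects {n_volumes} volumes"
        )
    return DesignSpec(labels=labels, baseline_name=baseline_name)


def hrf_double_gamma(t: np.ndarray, peak_shape: float = 6.0,
                     undershoot_shape: float = 16.0,
                     ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at times ``t`` (seconds).

    Positive lobe Gamma(6, 1), undershoot Gamma(16, 1) scaled by 1/6 —
    the default family of the standard fMRI GLM toolchains. Normalised to
    unit peak.
    """
    t = np.asarray(t, dtype=float)
    h = gamma_dist.pdf(t, peak_shape) - ratio * gamma_dist.pdf(t, undershoot_shape)
    m = h.max()
    return h / m if m > 0 else h


def build_design_matrix(
    design: DesignSpec,
    tr: float,
    motion: np.ndarray | None = None,
) -> tuple[np.ndarray, list[str]]:
    """HRF-convolved design matrix, one column per task condition.

    Columns: one convolved boxcar per non-baseline condition (order of
    first appearance), an intercept, then optionally the six rigid motion
    parameters. The baseline condition is modelled implicitly through the
    intercept. Returns ``(X, column_names)``.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    tasks = design.task_conditions
    if not tasks:
        raise DesignError("design contains no non-baseline condition to model")
    n = design.n_volumes
    # HRF long enough to cover the undershoot (~32 s)
    t_hrf = np.arange(0, 32.0 + tr, tr)
    h = hrf_double_gamma(t_hrf)
    cols = []
    names = []
    for cond in tasks:
        reg = np.convolve(design.boxcar(cond), h)[:n]
        cols.append(reg)
        names.append(cond)
    cols.append(np.ones(n))
    names.append("intercept")
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (n, 6):
            raise ValueError(f"motion regressors must be (n_volumes, 6), got {motion.shape}")
        for j in range(6):
            cols.append(motion[:, j])
            names.append(f"motion_{j}")
    return np.column_stack(cols), names


@dataclass
class GLMResult:
    """Voxelwise OLS fit: betas, t maps per contrast, residual dof."""

    beta: np.ndarray                 # (p, n_voxels)
    t_maps: dict[str, np.ndarray]    # contrast name -> (n_voxels,)
    dof: int
    column_names: list[str]
    contrasts: dict[str, np.ndarray] = field(default_factory=dict)
    shape: tuple[int, ...] | None = None  # spatial shape for unraveling

    def t_volume(self, contrast: str) -> np.ndarray:
        if self.shape is None:
            raise ValueError("GLMResult carries no spatial shape")
        return self.t_maps[contrast].reshape(self.shape)


def default_contrasts(column_names: list[str], task_names: list[str]) -> dict[str, np.ndarray]:
    """All pairwise contrasts among task conditions and the implicit baseline.

    Task-vs-baseline contrasts are the task regressor alone (baseline lives
    in the intercept); task-vs-task contrasts are +1/−1 pairs.
    """
    p = len(column_names)
    out: dict[str, np.ndarray] = {}
    for cond in task_names:
        c = np.zeros(p)
        c[column_names.index(cond)] = 1.0
        out[f"{cond}_vs_baseline"] = c
    for a, b in combinations(task_names, 2):
        c = np.zeros(p)
        c[column_names.index(a)] = 1.0
        c[column_names.index(b)] = -1.0
        out[f"{a}_vs_{b}"] = c
    return out


def fit_glm(
    Y: np.ndarray,
    X: np.ndarray,
    column_names: list[str],
    contrasts: dict[str, np.ndarray] | None = None,
    spatial_shape: tuple[int, ...] | None = None,
) -> GLMResult:
    """Ordinary least squares per voxel with classical t statistics.

    ``Y`` is (n_volumes_used, n_voxels); rows corresponding to QC-discarded
    volumes must already be dropped from both ``Y`` and ``X``.
    t = cᵀβ̂ / sqrt(σ̂² · cᵀ(XᵀX)⁻¹c), σ̂² = RSS/dof, dof = n − rank(X).
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if Y.shape[0] != X.shape[0]:
        raise ValueError(f"{Y.shape[0]} data rows vs {X.shape[0]} design rows")
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the offending columns for the error message
        _, R = np.linalg.qr(X)
        bad = [column_names[j] for j in range(p) if abs(R[j, j]) < 1e-10 * abs(R).max()]
        raise DesignError(f"design matrix is rank deficient (suspect columns: {bad})")
    dof = n - rank
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y                       # (p, n_voxels)
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / dof          # (n_voxels,)
    if contrasts is None:
        task_names = [c for c in column_names
                      if c != "intercept" and not c.startswith("motion_")]
        contrasts = default_contrasts(column_names, task_names)
    t_maps: dict[str, np.ndarray] = {}
    for name, c in contrasts.items():
        c = np.asarray(c, dtype=float)
        var_scale = float(c @ XtX_inv @ c)
        denom = np.sqrt(sigma2 * var_scale)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(denom > 0, (c @ beta) / denom, 0.0)
        t_maps[name] = t
    return GLMResult(beta=beta, t_maps=t_maps, dof=dof,
                     column_names=column_names, contrasts=dict(contrasts),
                     shape=spatial_shape)


@dataclass
class FeatureMask:
    """A set of voxel flat-indices in reference-functional space."""

    indices: np.ndarray          # sorted flat voxel indices
    shape: tuple[int, ...]       # spatial grid shape
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.indices = np.unique(np.asarray(self.indices, dtype=np.int64))

    def __len__(self) -> int:
        return int(self.indices.size)

    def as_bool(self) -> np.ndarray:
        m = np.zeros(int(np.prod(self.shape)), dtype=bool)
        m[self.indices] = True
        return m.reshape(self.shape)

    @classmethod
    def from_bool(cls, mask: np.ndarray, provenance: dict | None = None) -> "FeatureMask":
        mask = np.asarray(mask).astype(bool)
        return cls(indices=np.flatnonzero(mask.ravel()), shape=mask.shape,
                   provenance=provenance or {"explicit_mask": True})

    def extract(self, data: np.ndarray) -> np.ndarray:
        """Masked voxel vector from a volume grid."""
        return data.ravel()[self.indices]


def select_features(
    glm: GLMResult,
    mode: str,
    t_threshold: float | None = None,
    top_percent: float | None = None,
    roi: FeatureMask | None = None,
    contrasts: list[str] | None = None,
) -> FeatureMask:
    """Select informative voxels from the localizer fit.

    ``mode="t_threshold"``: union over the named contrasts (default: all)
    of voxels with |t| strictly greater than ``t_threshold``.

    ``mode="top_percent"``: the ⌈q·m⌉ voxels of highest |t| (max over
    contrasts) inside ``roi`` (required), ties broken by ascending voxel
    index.
    """
    if glm.shape is None:
        raise ValueError("GLMResult needs a spatial shape for feature selection")
    names = contrasts if contrasts is not None else list(glm.t_maps)
    abs_t = np.max(np.abs(np.stack([glm.t_maps[n] for n in names])), axis=0)

    if mode == "t_threshold":
        if t_threshold is None:
            raise ValueError("t_threshold mode needs a threshold")
        sel = np.flatnonzero(abs_t > t_threshold)
        if roi is not None:
            sel = np.intersect1d(sel, roi.indices)
        if sel.size == 0:
            raise EmptySelectionError(
                f"no voxel exceeds |t| > {t_threshold}; lower the threshold"
            )
        return FeatureMask(sel, glm.shape, {"t_threshold": t_threshold,
                                            "contrasts": names})
    if mode == "top_percent":
        if top_percent is None or roi is None:
            raise ValueError("top_percent mode needs a percentage and an ROI")
        m = len(roi)
        k = int(np.ceil(top_percent / 100.0 * m))
        if k <= 0:
            raise EmptySelectionError(f"top {top_percent}% of {m} voxels is empty")
        roi_t = abs_t[roi.indices]
        # sort by (-|t|, voxel index): ties broken by ascending index
        order = np.lexsort((roi.indices, -roi_t))
        sel = roi.indices[order[:k]]
        return FeatureMask(sel, glm.shape, {"top_percent": top_percent,
                                            "roi_size": m, "contrasts": names})
    raise ValueError(f"unknown feature-selection mode {mode!r}")
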