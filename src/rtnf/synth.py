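"""Synthetic real-time session generator.

Produces everything a real session provides — reference anatomical (RAI)
and functional (RFI) volumes, a stream of echo-planar volumes, the ASCII
design file, binary ROI masks and a ground-truth manifest — with the
statistical structure the feedback engines assume: block-design BOLD
modulation convolved with the hemodynamic response, low-frequency linear
drift, i.i.d. Gaussian noise, and optional injected rigid-body motion
events.

The phantom is a smooth ellipsoidal "head" with internal intensity
gradients (so registration has structure to lock onto) at a baseline level
of 1000 arbitrary units. Per-condition activation amplitudes are fractions
of the local baseline, so a 0.02 amplitude is a 2% signal change wherever
it applies. The voxel model is

    s_t(v) = base(v) · (1 + Σ_c a_c(v)·m_c(t) + drift·t) + ε,   ε ~ N(0, sd·1000)

with m_c the condition boxcar, HRF-convolved unless disabled. Identical
configs (including seed) produce bit-identical sessions.
"""

from __future__ import annotations

import json
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .design import DesignSpec, hrf_double_gamma
from .registration import RigidTransform, resample_rigid, center_of_mass_world
from .volume import Volume, write_volume

__all__ = ["SimConfig", "generate_session", "stream_session",
            "make_phantom", "make_labels"]

BASELINE_INTENSITY = 1000.0


def make_labels(block_lengths: list[tuple[str, int]]) -> list[str]:
    """Expand (condition, length) pairs into a per-volume label list."""
    labels: list[str] = []
    for name, n in block_lengths:
        labels.extend([name] * n)
    return labels


@dataclass
class SimConfig:
    """Full specification of one synthetic session (see module docstring)."""

    labels: list[str]
    baseline_name: str = "REST"
    shape: tuple[int, int, int] = (16, 16, 12)
    voxel_sizes: tuple[float, float, float] = (3.75, 3.75, 5.0)
    tr: float = 2.0
    # roi name -> (center voxel ijk, radius mm)
    rois: dict[str, tuple[tuple[int, int, int], float]] = field(default_factory=dict)
    # condition -> roi name -> fractional amplitude
    amplitudes: dict[str, dict[str, float]] = field(default_factory=dict)
    noise_sd: float = 0.01          # fraction of the 1000 au baseline
    drift: float = 0.0              # fraction of baseline per volume
    motion_events: dict[int, tuple[float, ...]] = field(default_factory=dict)
    # optional shared latent signal: stochastic per-volume fluctuation common
    # to the listed ROIs, gated by a condition's (convolved) boxcar
    latent_rois: list[str] = field(default_factory=list)
    latent_condition: str | None = None
    latent_sd: float = 0.0          # fractional sd of the shared fluctuation
    amplitudes_additive: bool = False
    hrf: bool = True
    seed: int = 0

    @property
    def n_volumes(self) -> int:
        return len(self.labels)

    def affine(self) -> np.ndarray:
        A = np.diag(list(self.voxel_sizes) + [1.0])
        # center the FOV on the world origin
        A[:3, 3] = -(np.asarray(self.shape) - 1) / 2.0 * np.asarray(self.voxel_sizes)
        return A


def make_phantom(shape, voxel_sizes, texture_amp: float = 0.15) -> np.ndarray:
    """Ellipsoidal head with internal structure, baseline 1000 au.

    Combines smooth low-frequency gradients with a fine band-passed random
    texture (fixed internal seed, so the phantom is identical across
    sessions of the same shape): registration needs high-frequency content
    to pin down sub-voxel rotations, exactly as real echo-planar images
    provide.
    """
    grids = np.meshgrid(*[np.linspace(-1, 1, s) for s in shape], indexing="ij")
    r2 = sum(g**2 for g in grids) / 0.8**2
    inside = r2 < 1.0
    # smooth falloff at the edge + internal structure for registration
    envelope = np.clip(1.0 - r2, 0.0, None) ** 0.5
    texture = (0.85
               + 0.10 * np.sin(3.0 * np.pi * grids[0])
               + 0.10 * np.cos(2.5 * np.pi * grids[1])
               + 0.08 * np.sin(2.0 * np.pi * grids[2]))
    fine = ndimage.gaussian_filter(
        np.random.default_rng(12345).standard_normal(shape), 0.8)
    fine /= np.abs(fine).max()
    return (BASELINE_INTENSITY * envelope * (texture + texture_amp * fine)
            * inside)


def _sphere_mask(shape, voxel_sizes, center_ijk, radius_mm) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    d2 = sum(((g - c) * vs) ** 2
             for g, c, vs in zip(grids, center_ijk, voxel_sizes))
    return d2 <= radius_mm**2


def _condition_regressors(design: DesignSpec, tr: float, use_hrf: bool
                          ) -> dict[str, np.ndarray]:
    n = design.n_volumes
    regs = {}
    if use_hrf:
        t_hrf = np.arange(0, 32.0 + tr, tr)
        h = hrf_double_gamma(t_hrf)
        h = h / h.sum()   # unit plateau: a sustained block reaches the
        # configured amplitude exactly once the response has risen
    for cond in design.task_conditions:
        box = design.boxcar(cond)
        regs[cond] = np.convolve(box, h)[:n] if use_hrf else box
    return regs


def generate_session(config: SimConfig, out: str | Path) -> dict:
    """Write a full synthetic session to ``out``; return the manifest.

    Layout: ``rai.nii``, ``rfi.nii``, ``design.txt``, ``roi_<name>.nii``,
    ``volumes/vol_NNNN.nii`` and ``manifest.json``. The manifest records
    every injected quantity (amplitudes, drift, noise sd, motion events,
    seed) so recovery tests are self-verifying.
    """
    out = Path(out)
    (out / "volumes").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    design = DesignSpec(labels=list(config.labels),
                        baseline_name=config.baseline_name)
    affine = config.affine()
    base = make_phantom(config.shape, config.voxel_sizes)

    rfi = Volume(base.copy(), affine)
    # anatomical reference: same head, different tissue contrast
    rai = Volume(np.sqrt(np.clip(base, 0, None) / BASELINE_INTENSITY)
                 * BASELINE_INTENSITY, affine)
    write_volume(rfi, out / "rfi.nii")
    write_volume(rai, out / "rai.nii")

    roi_masks = {}
    for name, (center, radius) in config.rois.items():
        m = _sphere_mask(config.shape, config.voxel_sizes, center, radius)
        if not m.any():
            raise ValueError(f"ROI {name!r} is empty")
        roi_masks[name] = m
        write_volume(Volume(m.astype(np.float64), affine),
                     out / f"roi_{name}.nii")

    # per-voxel amplitude map for each condition
    amp_maps: dict[str, np.ndarray] = {}
    claimed = np.zeros(config.shape, dtype=int)
    for cond, roi_amps in config.amplitudes.items():
        a = np.zeros(config.shape)
        for roi_name, amp in roi_amps.items():
            if amp != 0.0:
                a[roi_masks[roi_name]] += amp
                claimed += roi_masks[roi_name].astype(int)
        amp_maps[cond] = a
    if not config.amplitudes_additive and (claimed > 1).any():
        raise ValueError(
            "overlapping ROI amplitude assignments; set amplitudes_additive=True"
        )

    regs = _condition_regressors(design, config.tr, config.hrf)
    latent = None
    if config.latent_rois:
        if config.latent_condition not in regs:
            raise ValueError("latent_condition must be a task condition")
        latent = rng.standard_normal(config.n_volumes) * config.latent_sd
        latent_mask = np.zeros(config.shape, dtype=bool)
        for rn in config.latent_rois:
            latent_mask |= roi_masks[rn]

    com = center_of_mass_world(rfi)
    motion_records = {}
    for t in range(config.n_volumes):
        mod = np.zeros(config.shape)
        for cond, a in amp_maps.items():
            if cond in regs:
                mod += a * regs[cond][t]
        if latent is not None:
            mod += latent_mask * latent[t] * regs[config.latent_condition][t]
        signal = base * (1.0 + mod + config.drift * t)
        noise = rng.standard_normal(config.shape) * (config.noise_sd
                                                     * BASELINE_INTENSITY)
        vol = Volume(signal + noise, affine, index=t)
        if t in config.motion_events:
            params = np.asarray(config.motion_events[t], dtype=float)
            tr_ev = RigidTransform.from_params(params)
            vol = resample_rigid(vol, tr_ev, com, order=3)
            motion_records[t] = params.tolist()
        write_volume(vol, out / "volumes" / f"vol_{t:04d}.nii")

    (out / "design.txt").write_text(
        "# synthetic session design: one condition per line\n"
        + "\n".join(design.labels) + "\n")

    manifest = {
        "dir": str(out),
        "rai": str(out / "rai.nii"),
        "rfi": str(out / "rfi.nii"),
        "design": str(out / "design.txt"),
        "volumes_dir": str(out / "volumes"),
        "rois": {n: str(out / f"roi_{n}.nii") for n in roi_masks},
        "n_volumes": config.n_volumes,
        "tr": config.tr,
        "baseline_name": config.baseline_name,
        "ground_truth": {
            "amplitudes": config.amplitudes,
            "noise_sd": config.noise_sd,
            "drift": config.drift,
            "motion_events": motion_records,
            "latent_sd": config.latent_sd,
            "latent_rois": config.latent_rois,
            "hrf": config.hrf,
            "seed": config.seed,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def stream_session(manifest: dict, watch_dir: str | Path,
                   interval: float = 0.0, n_volumes: int | None = None) -> None:
    """Copy session volumes into a watched folder at a fixed cadence.

    ``interval`` is the per-volume delay in seconds (0 dumps everything at
    once; the watcher still yields in index order). ``n_volumes`` can
    truncate the stream to exercise stall handling.
    """
    watch_dir = Path(watch_dir)
    watch_dir.mkdir(parents=True, exist_ok=True)
    src = sorted(Path(manifest["volumes_dir"]).glob("vol_*.nii"))
    if n_volumes is not None:
        src = src[:n_volumes]
    for p in src:
        if interval > 0:
            time.sleep(interval)
        tmp = watch_dir / (p.name + ".part")
        shutil.copyfile(p, tmp)
        tmp.rename(watch_dir / p.name)
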