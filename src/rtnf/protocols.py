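"""Canonical synthetic study protocols.

Three ready-made :class:`~rtnf.synth.SimConfig` builders emulating the
block designs the three feedback modes are validated on:

* **motor**: 300 volumes, 15-volume motor-imagery blocks alternating with
  15-volume rest blocks; a single premotor ROI carries a 2% signal change.
* **emotional**: 296 volumes; four 22-volume blocks per emotional class
  (positive / negative), each interleaved with a 15-volume neutral
  baseline block; the two classes activate disjoint ROIs at 2%.
* **connectivity**: 360 volumes; eight 35-volume emotion blocks interleaved
  with 10-volume mental-subtraction baselines; two ROIs share a common
  block-gated latent fluctuation on top of 2% activation.

All use the default 16x16x12 grid (3.75x3.75x5 mm voxels), TR 2 s, noise
sd 1% of baseline, and HRF-convolved boxcars.
"""

from __future__ import annotations

from .synth import SimConfig, make_labels

__all__ = ["motor_protocol", "emotional_protocol", "connectivity_protocol"]


def motor_protocol(seed: int = 1, drift: float = 1e-5,
                   motion_events: dict | None = None) -> SimConfig:
    labels = make_labels([("REST", 15), ("IMAGERY", 15)] * 10)
    return SimConfig(
        labels=labels,
        baseline_name="REST",
        rois={"premotor": ((5, 8, 6), 8.0)},
        amplitudes={"IMAGERY": {"premotor": 0.02}},
        noise_sd=0.01,
        drift=drift,
        motion_events=motion_events or {},
        seed=seed,
    )


def emotional_protocol(seed: int = 2, amplitude: float = 0.02) -> SimConfig:
    block = [("NEUTRAL", 15), ("POSITIVE", 22), ("NEUTRAL", 15),
             ("NEGATIVE", 22)]
    labels = make_labels(block * 4)
    assert len(labels) == 296
    return SimConfig(
        labels=labels,
        baseline_name="NEUTRAL",
        rois={"limbic_a": ((5, 8, 6), 8.0), "limbic_b": ((11, 8, 6), 8.0)},
        amplitudes={"POSITIVE": {"limbic_a": amplitude},
                    "NEGATIVE": {"limbic_b": amplitude}},
        noise_sd=0.01,
        seed=seed,
    )


def connectivity_protocol(seed: int = 4, latent_sd: float = 0.01) -> SimConfig:
    labels = make_labels([("SUBTRACT", 10), ("EMOTION", 35)] * 8)
    assert len(labels) == 360
    return SimConfig(
        labels=labels,
        baseline_name="SUBTRACT",
        rois={"atl": ((5, 8, 6), 8.0), "sgc": ((11, 8, 6), 8.0)},
        amplitudes={"EMOTION": {"atl": 0.02, "sgc": 0.02}},
        latent_rois=["atl", "sgc"],
        latent_condition="EMOTION",
        latent_sd=latent_sd,
        noise_sd=0.01,
        seed=seed,
    )
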