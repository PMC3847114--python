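import numpy as np
import pytest

from rtnf.registration import center_of_mass_world
from rtnf.synth import SimConfig, generate_session, make_labels, make_phantom
from rtnf.volume import Volume


def _affine(shape, voxel_sizes):
    A = np.diag(list(voxel_sizes) + [1.0])
    A[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * np.asarray(voxel_sizes)
    return A


@pytest.fixture(scope="session")
def reg_phantom():
    """Finer-grid head phantom for registration fidelity tests.

    Sub-voxel rotation recovery needs more spatial samples than the small
    default streaming grid provides, so registration accuracy is assessed
    at 32x32x20 (3x3x3.5 mm).
    """
    shape, vox = (32, 32, 20), (3.0, 3.0, 3.5)
    vol = Volume(make_phantom(shape, vox), _affine(shape, vox))
    return vol


@pytest.fixture(scope="session")
def reg_center(reg_phantom):
    return center_of_mass_world(reg_phantom)


@pytest.fixture(scope="session")
def spike_session(tmp_path_factory):
    """Small streamed session with two injected motion spikes (default grid)."""
    out = tmp_path_factory.mktemp("spike_session")
    cfg = SimConfig(
        labels=make_labels([("REST", 10), ("TASK", 10)] * 3),
        rois={"premotor": ((5, 8, 6), 8.0)},
        amplitudes={"TASK": {"premotor": 0.02}},
        noise_sd=0.01,
        drift=1e-5,
        seed=11,
        motion_events={30: (0, 0, 0.02, 0, 2.0, 0),
                       45: (0.015, 0, 0, 0, 0, -1.5)},
    )
    manifest = generate_session(cfg, out)
    return cfg, manifest


@pytest.fixture(scope="session")
def clean_session(tmp_path_factory):
    """Spike-free ROI session reused by engine and runner tests."""
    out = tmp_path_factory.mktemp("clean_session")
    cfg = SimConfig(
        labels=make_labels([("REST", 10), ("TASK", 10)] * 3),
        rois={"premotor": ((5, 8, 6), 8.0), "other": ((11, 8, 6), 8.0)},
        amplitudes={"TASK": {"premotor": 0.02}},
        noise_sd=0.01,
        drift=1e-5,
        seed=7,
    )
    manifest = generate_session(cfg, out)
    return cfg, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
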