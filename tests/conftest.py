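"""Shared fixtures: a reduced-resolution sensor and torso for fast tests.

The reduced sensor keeps the real field of view and frame rate but ~4x
coarser pixels and a shorter record, so full renders stay cheap; the
full-size configuration is exercised in the acceptance tests.
"""

import numpy as np
import pytest

from tofspiro import (
    DepthFrame,
    DepthSequence,
    SensorGeometry,
    TorsoModel,
    make_breath_waveform,
    render_depth_sequence,
)


@pytest.fixture(scope="session")
def small_geometry() -> SensorGeometry:
    return SensorGeometry(n_rows=56, n_cols=43)


@pytest.fixture(scope="session")
def torso() -> TorsoModel:
    return TorsoModel()


@pytest.fixture(scope="session")
def short_waveform():
    """12 s record: one tidal breath, maximal inspiration, forced expiration."""
    return make_breath_waveform(n_tidal=1, duration_s=12.0)


@pytest.fixture(scope="session")
def small_scene(torso, short_waveform, small_geometry):
    """Noiseless reduced-resolution render with its ground truth."""
    waveform, truth = short_waveform
    seq = render_depth_sequence(torso, waveform, geometry=small_geometry)
    return seq, truth


def flat_sequence(
    distance_mm: float,
    n_frames: int = 3,
    geometry: SensorGeometry | None = None,
) -> DepthSequence:
    """Static scene: a flat wall filling the frame."""
    geometry = geometry or SensorGeometry(n_rows=56, n_cols=43)
    dt = geometry.sampling_interval_s
    frames = [
        DepthFrame(np.full(geometry.shape, float(distance_mm)), k * dt)
        for k in range(n_frames)
    ]
    return DepthSequence(frames, geometry)
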