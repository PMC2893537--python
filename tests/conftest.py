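"""Shared fixtures: scenes, protocols, and one rendered single-flash video.

The rendered video and its measurements are session-scoped — they back both
the unit tests and the end-to-end recovery checks without re-rendering.
"""

from __future__ import annotations

import numpy as np
import pytest

from pupilkit.detect import DetectConfig, ROI, measure_sequence
from pupilkit.synthetic import (EyeSceneSpec, PLRModel, generate_ground_truth,
                                render_sequence, single_flash_protocol)


@pytest.fixture(scope="session")
def detect_config() -> DetectConfig:
    return DetectConfig()


@pytest.fixture(scope="session")
def scene() -> EyeSceneSpec:
    # fractional pupil center: exercises sub-pixel localization throughout
    return EyeSceneSpec(pupil_center_px=(120.3, 160.7))


@pytest.fixture(scope="session")
def full_roi(scene) -> ROI:
    h, w = scene.image_size_px
    return ROI(0, 0, h, w)


@pytest.fixture(scope="session")
def single_flash_setup():
    """(model, protocol, truth) for the default single-flash experiment."""
    model = PLRModel()
    protocol = single_flash_protocol()
    truth = generate_ground_truth(model, protocol)
    return model, protocol, truth


@pytest.fixture(scope="session")
def single_flash_video(scene, single_flash_setup):
    """Rendered 90-frame video of the default single-flash reflex."""
    _, _, truth = single_flash_setup
    return render_sequence(scene, truth)


@pytest.fixture(scope="session")
def single_flash_measured(single_flash_video, full_roi, detect_config):
    """Detection results over the rendered single-flash video."""
    measurements, iris = measure_sequence(single_flash_video, full_roi,
                                          detect_config, fps=30.0)
    return measurements, iris
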