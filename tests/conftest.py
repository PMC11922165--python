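import numpy as np
import pytest

from specband import datasets
from specband.camera_calibration import CalibrationTarget
from specband.pipeline import calibrate_rig
from specband.synthetic import (
    distorted_camera,
    forward_capture_array,
    ideal_camera,
    make_checker_spectra,
    make_low_rank_checker_spectra,
)


@pytest.fixture(scope="session")
def illum_e():
    return datasets.illuminant("e")


@pytest.fixture(scope="session")
def illum_led():
    return datasets.illuminant("led")


@pytest.fixture(scope="session")
def cmf():
    return datasets.color_matching_functions()


@pytest.fixture(scope="session")
def checker_spectra():
    """Smooth 24-patch checker reflectances (18 chromatic + 6 neutral)."""
    return make_checker_spectra(0)


@pytest.fixture(scope="session")
def low_rank_rig(illum_e):
    """Noise-free ideal camera on a rank-3 checker family, calibrated exactly.

    The closure fixture: basis fitted uncentered at k = data rank, so the
    whole pipeline is an exact round trip.
    """
    spectra = make_low_rank_checker_spectra(1)
    camera = ideal_camera()
    rgb = forward_capture_array(spectra, camera, illum_e)
    target = CalibrationTarget(rgb=rgb, spectra=spectra)
    artifacts = calibrate_rig(target, illum_e, k=3, center=False)
    return target, artifacts


@pytest.fixture(scope="session")
def distorted_rig(illum_e, checker_spectra):
    """Cubic-distorted, noise-free camera on the smooth checker, k=12."""
    camera = distorted_camera(3)
    rgb = forward_capture_array(checker_spectra, camera, illum_e)
    target = CalibrationTarget(rgb=rgb, spectra=checker_spectra)
    artifacts = calibrate_rig(target, illum_e, k=12)
    return target, artifacts, camera
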