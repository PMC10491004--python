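"""Shared fixtures: the reference simulation conditions used across tests.

The canonical scenario mirrors a 40x non-telecentric DHM recording on a
512 x 512 crop of a 5.86-um-pitch camera at 532 nm: carrier offset
(170, 170) spectral bins, spherical curvature 3.5e5 um with vertex at
pixel (273, 247), and a Siemens-star phase target of the QPT nominal
height 2.1497 rad whose edges are smoothed by sigma = 2 px to emulate the
finite-NA band limit.  The star sits on the ring where the distorting
paraboloid crosses its field mean, so the phase/paraboloid covariance does
not bias the SD cost landscape.
"""

import math

import numpy as np
import pytest

import holophase as hp

DXY = 5.86      # um
LAM = 0.532     # um
SIZE = 512
C_TRUE = 3.5e5  # um
VERTEX = (273.0, 247.0)
STAR_CENTER = (421, 395)
STAR_HEIGHT = 2.1497  # rad, 2*pi*(1.52-1)*0.350/0.532
CARRIER_OFFSET = (170, 170)  # spectral bins
ROI = hp.SpectrumROI(P=256 - 170, Q=256 - 170, M=165, N=165)
APODIZE = 0.3


def sin_theta(offset_bins: int, n: int = SIZE, dxy: float = DXY, lam: float = LAM) -> float:
    return offset_bins * lam / (n * dxy)


def tilt_for(offset: tuple[int, int], n: int = SIZE) -> hp.TiltAngles:
    return hp.TiltAngles(
        math.asin(sin_theta(offset[0], n)), math.asin(sin_theta(offset[1], n))
    )


@pytest.fixture(scope="session")
def params512() -> hp.AcquisitionParams:
    return hp.AcquisitionParams(X=SIZE, Y=SIZE, delta_xy=DXY, wavelength=LAM)


@pytest.fixture(scope="session")
def star_pattern() -> hp.PhaseMap:
    return hp.make_pattern(
        "star", SIZE, STAR_HEIGHT, radius_frac=0.17, center=STAR_CENTER, edge_sigma=2.0
    )


@pytest.fixture(scope="session")
def star_truth(params512, star_pattern) -> hp.SimulationTruth:
    sphere = hp.SphericalWavefront(C_TRUE, C_TRUE, h=VERTEX[0], g=VERTEX[1], sign=1)
    return hp.SimulationTruth(
        params=params512,
        tilt=tilt_for(CARRIER_OFFSET),
        sphere=sphere,
        object_phase=star_pattern,
    )


@pytest.fixture(scope="session")
def star_hologram(star_truth) -> hp.HologramImage:
    return hp.simulate_hologram(star_truth)


@pytest.fixture(scope="session")
def sphere_only_truth(params512) -> hp.SimulationTruth:
    sphere = hp.SphericalWavefront(C_TRUE, C_TRUE, h=VERTEX[0], g=VERTEX[1], sign=1)
    return hp.SimulationTruth(
        params=params512,
        tilt=tilt_for(CARRIER_OFFSET),
        sphere=sphere,
        object_phase=hp.PhaseMap(np.zeros((SIZE, SIZE)), wrapped=True),
    )


@pytest.fixture(scope="session")
def sphere_only_hologram(sphere_only_truth) -> hp.HologramImage:
    return hp.simulate_hologram(sphere_only_truth)


@pytest.fixture(scope="session")
def sphere_only_field(sphere_only_truth, sphere_only_hologram) -> hp.ComplexField:
    """Tilt-compensated filtered field of the sphere-only hologram."""
    spectrum = hp.compute_spectrum(sphere_only_hologram)
    h_f = hp.filter_plus_one(spectrum, ROI, apodize=APODIZE)
    return hp.compensate_tilt(h_f, sphere_only_truth.tilt)
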