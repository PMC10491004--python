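"""Domain types and closed-form spectral relations for off-axis DHM.

Off-axis digital holographic microscopy (DHM) records the interference of an
object wave and a tilted plane reference wave on a pixelated sensor.  The
tilt shifts the object spectrum (the +1 diffraction order) away from the DC
term; when the imaging system is non-telecentric, a spherical wavefront of
curvature ``C`` additionally broadens the +1 order into a rectangular compact
support.  Two measurements on the centered hologram spectrum therefore encode
the two aberrations to compensate:

* the +1-order centroid ``(P, Q)`` gives the interference tilt
  ``sin(theta_x) = (u0 - P) * lambda / (X * dxy)`` (and likewise along y);
* the +1-order support size ``(M, N)`` gives the curvature
  ``C_x = (X * dxy)**2 / (lambda * M)`` (and likewise ``C_y``).

Coordinate conventions used throughout the package:

* arrays are indexed ``[row, col]`` = ``[n, m]`` with shape ``(Y, X)``;
* the spectrum is FFT-shifted so the DC bin sits at the 0-based position
  ``(u0, v0) = (X // 2, Y // 2)``;
* all lengths (pixel pitch, wavelength, curvature) are in micrometers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger("holophase")

__all__ = [
    "AcquisitionParams",
    "SpectrumROI",
    "TiltAngles",
    "SphericalWavefront",
    "ComplexField",
    "PhaseMap",
    "HolophaseError",
    "InvalidCarrierError",
    "DegenerateROIError",
    "InvalidInputError",
    "SuggestionFailedError",
    "CenterNotFoundError",
    "AliasingError",
    "EvaluationFailedError",
    "tilt_from_roi",
    "curvature_from_roi",
    "percent_error",
    "wrap_phase",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class HolophaseError(Exception):
    """Base class for all package errors."""


class InvalidCarrierError(HolophaseError):
    """The spectral offset implies |sin(theta)| > 1 (carrier beyond Nyquist)."""


class DegenerateROIError(HolophaseError):
    """A +1-order region of interest with non-physical extents."""


class InvalidInputError(HolophaseError):
    """Input array contains NaN/Inf or violates a type invariant."""


class SuggestionFailedError(HolophaseError):
    """Automatic +1-order detection found no sideband; select the ROI manually."""


class CenterNotFoundError(HolophaseError):
    """No ring-like region survived segmentation of the wrapped phase."""


class AliasingError(HolophaseError):
    """Simulation parameters put the carrier or the +1 support out of band."""


class EvaluationFailedError(HolophaseError):
    """Cost evaluation returned a non-finite value during optimization."""


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionParams:
    """Sensor geometry and illumination wavelength.

    Parameters
    ----------
    X, Y:
        Sensor pixel counts along the horizontal and vertical axes (>= 8).
    delta_xy:
        Pixel pitch in micrometers (square pixels).
    wavelength:
        Illumination wavelength in micrometers (same unit as ``delta_xy``).
    """

    X: int
    Y: int
    delta_xy: float
    wavelength: float

    def __post_init__(self) -> None:
        if int(self.X) != self.X or int(self.Y) != self.Y:
            raise InvalidInputError("pixel counts X, Y must be integers")
        if self.X < 8 or self.Y < 8:
            raise InvalidInputError("pixel counts X, Y must be >= 8")
        if not (self.delta_xy > 0 and math.isfinite(self.delta_xy)):
            raise InvalidInputError("delta_xy must be finite and > 0")
        if not (self.wavelength > 0 and math.isfinite(self.wavelength)):
            raise InvalidInputError("wavelength must be finite and > 0")
        if self.X % 2 or self.Y % 2:
            logger.warning(
                "odd sensor size (%d x %d): DC bin at (floor(X/2), floor(Y/2)); "
                "even sizes are recommended", self.X, self.Y,
            )

    @property
    def u0(self) -> int:
        """DC-bin column of the centered spectrum (0-based)."""
        return self.X // 2

    @property
    def v0(self) -> int:
        """DC-bin row of the centered spectrum (0-based)."""
        return self.Y // 2

    @property
    def wavenumber(self) -> float:
        """k = 2*pi/lambda, in rad/micrometer."""
        return 2.0 * math.pi / self.wavelength

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape ``(Y, X)`` = (rows, cols)."""
        return (self.Y, self.X)

    @property
    def nyquist_sin(self) -> float:
        """Largest |sin(theta)| the pixel pitch can sample: lambda/(2*dxy)."""
        return self.wavelength / (2.0 * self.delta_xy)


@dataclass(frozen=True)
class SpectrumROI:
    """Rectangular +1-order region in the centered spectrum.

    ``(P, Q)`` is the center (column, row) in 0-based spectral pixels and
    ``(M, N)`` the width and height.  The covered bins are the half-open
    integer ranges ``[P - M//2, P - M//2 + M)`` x ``[Q - N//2, Q - N//2 + N)``.
    """

    P: int
    Q: int
    M: int
    N: int

    def __post_init__(self) -> None:
        if self.M < 1 or self.N < 1:
            raise DegenerateROIError(f"ROI extents must be >= 1 (got M={self.M}, N={self.N})")

    @property
    def col_range(self) -> tuple[int, int]:
        lo = self.P - self.M // 2
        return lo, lo + self.M

    @property
    def row_range(self) -> tuple[int, int]:
        lo = self.Q - self.N // 2
        return lo, lo + self.N

    def contains_bin(self, col: int, row: int) -> bool:
        c0, c1 = self.col_range
        r0, r1 = self.row_range
        return c0 <= col < c1 and r0 <= row < r1

    def validate_for(self, params: AcquisitionParams) -> None:
        """Raise unless the rectangle is in-bounds and excludes the DC bin."""
        c0, c1 = self.col_range
        r0, r1 = self.row_range
        if c0 < 0 or c1 > params.X or r0 < 0 or r1 > params.Y:
            raise DegenerateROIError(
                f"ROI cols [{c0},{c1}) x rows [{r0},{r1}) exceeds "
                f"spectrum bounds {params.X} x {params.Y}"
            )
        if self.contains_bin(params.u0, params.v0):
            raise DegenerateROIError(
                f"ROI contains the DC bin ({params.u0}, {params.v0}); "
                "the +1 order must exclude DC"
            )


@dataclass(frozen=True)
class TiltAngles:
    """Off-axis interference angles (radians) between object and reference."""

    theta_x: float
    theta_y: float

    def check_nyquist(self, params: AcquisitionParams) -> None:
        limit = params.nyquist_sin
        for name, th in (("x", self.theta_x), ("y", self.theta_y)):
            if abs(math.sin(th)) > limit + 1e-15:
                raise AliasingError(
                    f"|sin(theta_{name})| = {abs(math.sin(th)):.6g} exceeds the "
                    f"Nyquist carrier limit lambda/(2*dxy) = {limit:.6g}"
                )


@dataclass(frozen=True)
class SphericalWavefront:
    """Spherical wavefront distorting a non-telecentric reconstruction.

    ``C_x``, ``C_y`` are curvature magnitudes in micrometers (the physical
    curvature is C = f_TL^2/(f_TL - z)); ``(h, g)`` is the vertex (column,
    row) in pixels; ``sign`` is +1 for a converging and -1 for a diverging
    wavefront.  A telecentric system (z = f_TL, C -> infinity) is the
    sentinel ``telecentric=True``, for which the spherical factor is unity.
    """

    C_x: float | None
    C_y: float | None
    h: float | None = None
    g: float | None = None
    sign: int = 1
    telecentric: bool = False

    def __post_init__(self) -> None:
        if self.telecentric:
            return
        for name, c in (("C_x", self.C_x), ("C_y", self.C_y)):
            if c is None or not math.isfinite(c) or c == 0:
                raise InvalidInputError(
                    f"{name} must be finite and nonzero unless telecentric"
                )
        if self.sign not in (1, -1):
            raise InvalidInputError("sign must be +1 (converging) or -1 (diverging)")

    def with_center(self, h: float, g: float) -> "SphericalWavefront":
        return replace(self, h=h, g=g)

    def with_curvatures(self, C_x: float, C_y: float) -> "SphericalWavefront":
        return replace(self, C_x=C_x, C_y=C_y)

    def flipped(self) -> "SphericalWavefront":
        return replace(self, sign=-self.sign)


@dataclass
class ComplexField:
    """Image-plane (or spectral) complex amplitude on the sensor grid."""

    values: np.ndarray
    params: AcquisitionParams

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.shape != self.params.shape:
            raise InvalidInputError(
                f"field shape {self.values.shape} != sensor shape {self.params.shape}"
            )

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    def phase_map(self) -> "PhaseMap":
        return PhaseMap(np.angle(self.values), wrapped=True)


@dataclass
class PhaseMap:
    """2D phase array in radians; wrapped values lie in (-pi, pi]."""

    values: np.ndarray
    wrapped: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.wrapped:
            v = self.values
            if v.size and (v.min() <= -math.pi - 1e-12 or v.max() > math.pi + 1e-12):
                raise InvalidInputError("wrapped phase must lie in (-pi, pi]")


# ---------------------------------------------------------------------------
# Closed-form relations
# ---------------------------------------------------------------------------

def tilt_from_roi(roi: SpectrumROI, params: AcquisitionParams) -> TiltAngles:
    """Interference angles from the +1-order centroid.

    ``theta_x = asin((u0 - P) * lambda / (X * dxy))`` and likewise along y:
    the spectral offset of the +1 order from DC, converted to a spatial
    frequency, equals ``sin(theta)/lambda``.
    """
    roi.validate_for(params)
    angles = {}
    for axis, (center, offset, npix) in {
        "x": (params.u0, params.u0 - roi.P, params.X),
        "y": (params.v0, params.v0 - roi.Q, params.Y),
    }.items():
        arg = offset * params.wavelength / (npix * params.delta_xy)
        if abs(arg) > 1.0:
            raise InvalidCarrierError(
                f"axis {axis}: spectral offset {offset} implies sin(theta) = "
                f"{arg:.6g}, outside [-1, 1]"
            )
        angles[axis] = math.asin(arg)
    return TiltAngles(theta_x=angles["x"], theta_y=angles["y"])


def curvature_from_roi(roi: SpectrumROI, params: AcquisitionParams) -> SphericalWavefront:
    """Spherical-wavefront curvature from the +1-order support size.

    The non-telecentric spherical factor broadens the +1 order into a
    rectangle of size ``M x N`` with ``M = (X*dxy)**2/(lambda*C)``; inverting
    gives ``C_x = (X*dxy)**2/(lambda*M)`` and ``C_y = (Y*dxy)**2/(lambda*N)``.
    The center ``(h, g)`` and the converging/diverging sign are not
    determined by the support size and are left unset here.
    """
    if roi.M < 1 or roi.N < 1:
        raise DegenerateROIError(f"degenerate ROI extents M={roi.M}, N={roi.N}")
    C_x = (params.X * params.delta_xy) ** 2 / (params.wavelength * roi.M)
    C_y = (params.Y * params.delta_xy) ** 2 / (params.wavelength * roi.N)
    return SphericalWavefront(C_x=C_x, C_y=C_y)


def percent_error(estimate: float, reference: float) -> float:
    """PE = |estimate - reference| / |reference| * 100 (percent)."""
    if reference == 0:
        raise ZeroDivisionError("percent error undefined for zero reference")
    return abs(estimate - reference) / abs(reference) * 100.0


def wrap_phase(values: np.ndarray) -> np.ndarray:
    """Wrap phase values into (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(values, dtype=np.float64)))
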