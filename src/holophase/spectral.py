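"""Hologram spectrum computation, +1-order ROI selection and spatial filtering.

The hologram intensity ``h = |u_IP + r|**2`` splits in the Fourier domain
into a DC term (the two intensities) and the two conjugate sidebands
``u_IP * conj(r)`` and ``conj(u_IP) * r``.  Isolating the +1 sideband with a
rectangular crop and inverse-transforming yields the filtered complex field
``h_F = conj(r) * u_IP``, from which amplitude (``|h_F|``) and phase (after
tilt and spherical compensation) are reconstructed.

The DFT convention is numpy's unnormalized forward transform, FFT-shifted so
the DC bin sits at ``(u0, v0) = (X//2, Y//2)``; Parseval then reads
``sum(|H|**2) / (X*Y) == sum(h**2)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .core import (
    AcquisitionParams,
    ComplexField,
    InvalidInputError,
    SpectrumROI,
    SuggestionFailedError,
)

__all__ = [
    "HologramImage",
    "load_hologram",
    "compute_spectrum",
    "suggest_roi",
    "filter_plus_one",
    "sideband_width",
    "export_spectrum_image",
]


@dataclass
class HologramImage:
    """Recorded hologram intensity on the sensor grid (finite, non-negative)."""

    values: np.ndarray
    params: AcquisitionParams

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.params.shape:
            raise InvalidInputError(
                f"hologram shape {self.values.shape} != sensor shape {self.params.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("hologram contains NaN/Inf pixels")
        if self.values.size and self.values.min() < 0:
            raise InvalidInputError("hologram intensities must be non-negative")


def load_hologram(path: str | Path, params: AcquisitionParams) -> HologramImage:
    """Read a single-channel TIFF/PNG hologram (8/16-bit integer or float)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse an accidental RGB to one channel
        arr = arr[..., 0]
    return HologramImage(values=arr.astype(np.float64), params=params)


def compute_spectrum(holo: HologramImage) -> ComplexField:
    """Centered 2D DFT of the hologram (DC relocated to ``(u0, v0)``)."""
    spec = np.fft.fftshift(np.fft.fft2(holo.values))
    return ComplexField(values=spec, params=holo.params)


def suggest_roi(
    spectrum: ComplexField,
    dc_exclusion_radius: float | None = None,
) -> SpectrumROI:
    """Automatic +1-order bounding box (optional seed for the user's crop).

    Masks a disc of ``dc_exclusion_radius`` (default ``max(X, Y)/20``) around
    DC, thresholds ``log(1 + |H|)`` by recursive Otsu and returns the
    bounding box of the largest connected component whose centroid lies in
    the half-plane above DC (row < v0, the +1 sideband by this package's
    convention; ties broken toward the smaller row index).  The box is
    clipped below the DC row so it can never contain the DC bin.
    """
    p = spectrum.params
    if dc_exclusion_radius is None:
        dc_exclusion_radius = max(p.X, p.Y) / 20.0
    logmag = np.log1p(np.abs(spectrum.values))
    n, m = np.mgrid[0 : p.Y, 0 : p.X]
    dc_mask = (m - p.u0) ** 2 + (n - p.v0) ** 2 <= dc_exclusion_radius**2
    work = logmag.copy()
    work[dc_mask] = 0.0
    if work.max() <= 0:
        raise SuggestionFailedError(
            "spectrum carries no energy outside the DC exclusion disc; "
            "select the +1-order ROI manually"
        )
    # recursive Otsu: the chirp sidebands' slow spectral tails give the
    # log-magnitude a broad unimodal background that a single Otsu pass
    # splits internally; re-thresholding the foreground isolates the peaks
    thr = threshold_otsu(work)
    for _ in range(8):
        above = work[work > thr]
        if above.size < 64 or (work > thr).mean() <= 0.02:
            break
        thr = threshold_otsu(above)
    binary = work > thr
    binary[dc_mask] = False
    labels = label(binary)
    candidates = [
        r for r in regionprops(labels) if r.centroid[0] < p.v0
    ]
    if not candidates:
        raise SuggestionFailedError(
            "no spectral component found above the DC row; "
            "select the +1-order ROI manually"
        )
    candidates.sort(key=lambda r: (-r.area, r.centroid[0]))
    best = candidates[0]
    r0, c0, r1, c1 = best.bbox  # half-open
    r1 = min(r1, p.v0)  # exclusion of the DC bin by construction
    if r1 <= r0:
        raise SuggestionFailedError("+1 component collapses onto the DC row")
    M = c1 - c0
    N = r1 - r0
    P = c0 + M // 2
    Q = r0 + N // 2
    roi = SpectrumROI(P=P, Q=Q, M=M, N=N)
    roi.validate_for(p)
    return roi


def filter_plus_one(
    spectrum: ComplexField, roi: SpectrumROI, apodize: float = 0.0
) -> ComplexField:
    """Spatially filter the +1 order: crop-in-place and inverse transform.

    All bins outside the ROI rectangle are zeroed (hard rectangular mask,
    matching the manual crop workflow) and the spectrum is inverse-shifted
    and inverse-transformed.  The sideband is *not* recentered, so the
    returned field ``h_F`` still carries the interference tilt, which is
    compensated separately in the spatial domain.

    ``apodize`` in (0, 1] replaces the hard edge by a raised-cosine (Tukey)
    taper of that fractional width, suppressing the crop's ringing at the
    price of attenuating the outermost retained frequencies.
    """
    p = spectrum.params
    roi.validate_for(p)
    c0, c1 = roi.col_range
    r0, r1 = roi.row_range
    cropped = np.zeros_like(spectrum.values)
    cropped[r0:r1, c0:c1] = spectrum.values[r0:r1, c0:c1]
    if apodize > 0:
        from scipy.signal.windows import tukey

        win = np.outer(tukey(r1 - r0, apodize), tukey(c1 - c0, apodize))
        cropped[r0:r1, c0:c1] *= win
    field = np.fft.ifft2(np.fft.ifftshift(cropped))
    return ComplexField(values=field, params=p)


def sideband_width(
    spectrum: ComplexField,
    roi_hint: SpectrumROI,
    axis: str = "x",
    pad: int = 8,
) -> int:
    """Measured +1-order support extent (bins) along one axis.

    Takes the column (``axis='x'``) or row (``axis='y'``) magnitude profile
    (max over the other axis) inside a window ``roi_hint`` padded by ``pad``,
    zeroes the DC bin, and measures the width at half the plateau level
    (median magnitude over the central quarter of the hinted support).  The
    Fresnel edge of the chirp-broadened sideband crosses half-plateau at the
    nominal support boundary, so this width estimates
    ``M = (X*dxy)**2/(lambda*C)`` directly.
    """
    p = spectrum.params
    mag = np.abs(spectrum.values).copy()
    mag[p.v0, p.u0] = 0.0
    c0, c1 = roi_hint.col_range
    r0, r1 = roi_hint.row_range
    r0, r1 = max(0, r0 - pad), min(p.Y, r1 + pad)
    c0, c1 = max(0, c0 - pad), min(p.X, c1 + pad)
    window = mag[r0:r1, :] if axis == "x" else mag[:, c0:c1]
    profile = window.max(axis=0) if axis == "x" else window.max(axis=1)
    center = roi_hint.P if axis == "x" else roi_hint.Q
    extent = roi_hint.M if axis == "x" else roi_hint.N
    half = max(3, extent // 8)
    plateau = np.median(profile[center - half : center + half + 1])
    if plateau <= 0:
        raise SuggestionFailedError("no sideband energy in the hinted window")
    above = np.where(profile >= 0.5 * plateau)[0]
    return int(above[-1] - above[0] + 1)


def export_spectrum_image(spectrum: ComplexField, path: str | Path) -> Path:
    """Write ``log(1 + |H|)`` as a 32-bit float TIFF for visual inspection."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, np.log1p(np.abs(spectrum.values)).astype(np.float32))
    return path
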