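"""Forward model of off-axis non-telecentric hologram formation.

The simulator builds a hologram ``h = |u_IP + r|**2`` on the sensor grid,
where the reference is a unit-amplitude plane wave tilted by
``(theta_x, theta_y)``,

    r(m, n) = exp(i * 2*pi/lambda * dxy * ((m - u0) sin(theta_x)
                                           + (n - v0) sin(theta_y))),

and the image-plane object field carries the non-telecentric spherical
phase factor of curvature ``C`` centered at pixel ``(h, g)``:

    u_IP(m, n) = a0 * exp(i * (phi0 + s)),
    s(m, n)    = sign * pi/(lambda*C) * ((m-h)**2 + (n-g)**2) * dxy**2.

The physical curvature is ``C = f_TL**2 / (f_TL - z)`` with ``f_TL`` the
tube-lens focal length and ``z`` the aperture-stop-to-tube-lens distance;
``z = f_TL`` is the telecentric limit where the factor is unity.  The finite
pupil of the objective is treated as infinite (no convolution); objects can
be band-limited explicitly through ``make_pattern``'s ``edge_sigma``.

Every simulation is described by a :class:`SimulationTruth` record which
round-trips losslessly through a JSON manifest, so reconstruction accuracy
can always be scored against known ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import (
    AcquisitionParams,
    AliasingError,
    InvalidInputError,
    PhaseMap,
    SpectrumROI,
    SphericalWavefront,
    TiltAngles,
)
from .spectral import HologramImage

__all__ = [
    "SimulationTruth",
    "make_pattern",
    "simulate_hologram",
    "write_truth_manifest",
    "read_truth_manifest",
    "carrier_roi",
]

PATTERN_KINDS = ("star", "bars", "wedding_cake", "blobs", "disc")


# ---------------------------------------------------------------------------
# Ground-truth record
# ---------------------------------------------------------------------------

@dataclass
class SimulationTruth:
    """Complete, reproducible description of one simulated hologram.

    ``sphere`` holds the physical curvature magnitude and center; when built
    from ``(f_TL, z)`` via :meth:`from_optics` the two descriptions are kept
    consistent (``C = f_TL**2/(f_TL - z)``, telecentric iff ``z == f_TL``).
    ``magnification`` and ``path_length`` only scale/offset the field by a
    global constant and default to 1 and 0.
    """

    params: AcquisitionParams
    tilt: TiltAngles
    sphere: SphericalWavefront
    object_phase: PhaseMap
    object_amplitude: np.ndarray | None = None
    f_TL: float | None = None
    z: float | None = None
    noise_sd: float = 0.0
    rng_seed: int = 0
    magnification: float = 1.0
    path_length: float = 0.0

    def __post_init__(self) -> None:
        if self.object_amplitude is None:
            self.object_amplitude = np.ones(self.params.shape)
        self.object_amplitude = np.asarray(self.object_amplitude, dtype=np.float64)
        if self.object_amplitude.shape != self.params.shape:
            raise InvalidInputError("object_amplitude shape mismatch")
        if self.object_phase.values.shape != self.params.shape:
            raise InvalidInputError("object_phase shape mismatch")
        if self.f_TL is not None and self.z is not None:
            if self.z == self.f_TL:
                if not self.sphere.telecentric:
                    raise InvalidInputError("z == f_TL requires a telecentric sphere")
            else:
                C = self.f_TL**2 / (self.f_TL - self.z)
                if self.sphere.telecentric or not (
                    math.isclose(abs(C), self.sphere.C_x, rel_tol=1e-9)
                    and math.isclose(abs(C), self.sphere.C_y, rel_tol=1e-9)
                    and self.sphere.sign == (1 if C > 0 else -1)
                ):
                    raise InvalidInputError(
                        "sphere inconsistent with C = f_TL**2/(f_TL - z) "
                        f"= {C:.6g}"
                    )

    @classmethod
    def from_optics(
        cls,
        params: AcquisitionParams,
        tilt: TiltAngles,
        f_TL: float,
        z: float,
        object_phase: PhaseMap,
        center: tuple[float, float] | None = None,
        **kwargs,
    ) -> "SimulationTruth":
        """Build the truth record from tube-lens optics ``(f_TL, z)``."""
        if z == f_TL:
            sphere = SphericalWavefront(None, None, telecentric=True)
        else:
            C = f_TL**2 / (f_TL - z)
            h, g = center if center is not None else (params.u0, params.v0)
            sphere = SphericalWavefront(
                C_x=abs(C), C_y=abs(C), h=h, g=g, sign=1 if C > 0 else -1
            )
        return cls(
            params=params, tilt=tilt, sphere=sphere, object_phase=object_phase,
            f_TL=f_TL, z=z, **kwargs,
        )


# ---------------------------------------------------------------------------
# Phase-target patterns
# ---------------------------------------------------------------------------

def make_pattern(
    kind: str,
    size: int,
    height: float,
    *,
    n_steps: int = 3,
    n_spokes: int = 16,
    radius_frac: float | None = None,
    center: tuple[float, float] | None = None,
    edge_sigma: float = 0.0,
    rng_seed: int = 0,
) -> PhaseMap:
    """Synthesize a known object-phase target.

    ``star`` is a Siemens-star resolution target, ``bars`` a three-bar
    resolution pattern at several scales, ``wedding_cake`` a stack of
    ``n_steps`` concentric discs with equal phase steps, ``blobs`` a smooth
    sum of Gaussians, ``disc`` a single flat disc.  The background is exactly
    zero; ``height`` is the phase step in radians (for ``wedding_cake`` the
    per-step increment, top level ``n_steps * height``).

    ``radius_frac`` scales the target's outer radius (fraction of ``size``;
    per-kind default), ``center`` places it at an arbitrary pixel (column,
    row), and ``edge_sigma`` (pixels) Gaussian-smooths the edges to emulate
    the band limit of real finite-NA imaging — sharp by default, in which
    case stepped patterns take exactly their nominal phase levels.
    """
    if size < 64:
        raise InvalidInputError("pattern size must be >= 64")
    if kind not in PATTERN_KINDS:
        raise InvalidInputError(f"unknown pattern kind {kind!r}; choose from {PATTERN_KINDS}")
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    cx, cy = center if center is not None else ((size - 1) / 2.0, (size - 1) / 2.0)
    r = np.hypot(xx - cx, yy - cy)
    out = np.zeros((size, size))

    if kind == "disc":
        out[r <= size * (radius_frac or 0.30)] = height
    elif kind == "star":
        rf = radius_frac or 0.40
        phi = np.arctan2(yy - cy, xx - cx)
        spokes = np.cos(n_spokes * phi) > 0
        out[spokes & (r <= size * rf) & (r >= size * rf / 10.0)] = height
    elif kind == "wedding_cake":
        radii = np.linspace(size * (radius_frac or 0.35), size * 0.08, n_steps)
        for radius in radii:
            out[r <= radius] += height
    elif kind == "bars":
        # three-bar groups, horizontal and vertical, at halving scales
        w = size // 10
        for scale in range(3):
            bw = max(2, w // (2**scale))  # bar width
            x0 = int(size * 0.15) + scale * int(size * 0.28)
            y0 = int(size * 0.2)
            for k in range(3):
                out[y0 : y0 + 5 * bw, x0 + 2 * k * bw : x0 + (2 * k + 1) * bw] = height
            y1 = int(size * 0.6)
            for k in range(3):
                out[y1 + 2 * k * bw : y1 + (2 * k + 1) * bw, x0 : x0 + 5 * bw] = height
    elif kind == "blobs":
        rng = np.random.default_rng(rng_seed)
        for _ in range(6):
            bx, by = rng.uniform(size * 0.2, size * 0.8, size=2)
            sd = rng.uniform(size * 0.03, size * 0.08)
            out += np.exp(-((xx - bx) ** 2 + (yy - by) ** 2) / (2 * sd**2))
        peak = out.max()
        if peak > 0:
            out *= height / peak
        # zero the far background so "background exactly 0" holds
        out[out < 1e-3 * abs(height)] = 0.0
    if edge_sigma > 0:
        from scipy.ndimage import gaussian_filter

        out = gaussian_filter(out, edge_sigma)
        out[np.abs(out) < 1e-3 * abs(height)] = 0.0
    # object phase is an optical path delay; it need not fit in (-pi, pi]
    return PhaseMap(out, wrapped=False)


# ---------------------------------------------------------------------------
# Hologram formation
# ---------------------------------------------------------------------------

def _spherical_phase(sphere: SphericalWavefront, params: AcquisitionParams) -> np.ndarray:
    """s(m, n) in radians on the sensor grid (0 when telecentric)."""
    if sphere.telecentric:
        return np.zeros(params.shape)
    h = params.u0 if sphere.h is None else sphere.h
    g = params.v0 if sphere.g is None else sphere.g
    n, m = np.mgrid[0 : params.Y, 0 : params.X].astype(np.float64)
    return (
        sphere.sign
        * (math.pi / params.wavelength)
        * ((m - h) ** 2 / sphere.C_x + (n - g) ** 2 / sphere.C_y)
        * params.delta_xy**2
    )


def _tilt_phase(tilt: TiltAngles, params: AcquisitionParams) -> np.ndarray:
    """t(m, n) in radians, with pixel coordinates centered on the DC bin."""
    n, m = np.mgrid[0 : params.Y, 0 : params.X].astype(np.float64)
    return (
        (2.0 * math.pi / params.wavelength)
        * params.delta_xy
        * ((m - params.u0) * math.sin(tilt.theta_x) + (n - params.v0) * math.sin(tilt.theta_y))
    )


def carrier_roi(truth: SimulationTruth, pad: int = 4) -> SpectrumROI:
    """Ground-truth +1-order ROI for a simulated hologram.

    Center ``(P, Q) = (u0 - X*dxy*sin(theta_x)/lambda, ...)`` per the tilt,
    extents ``M = (X*dxy)**2/(lambda*C_x)`` (+ ``2*pad``) per the curvature,
    minimum 2*pad+1 bins in the telecentric limit.
    """
    p = truth.params
    P = round(p.u0 - p.X * p.delta_xy * math.sin(truth.tilt.theta_x) / p.wavelength)
    Q = round(p.v0 - p.Y * p.delta_xy * math.sin(truth.tilt.theta_y) / p.wavelength)
    if truth.sphere.telecentric:
        M = N = 2 * pad + 1
    else:
        M = int(round((p.X * p.delta_xy) ** 2 / (p.wavelength * truth.sphere.C_x))) + 2 * pad
        N = int(round((p.Y * p.delta_xy) ** 2 / (p.wavelength * truth.sphere.C_y))) + 2 * pad
    return SpectrumROI(P=P, Q=Q, M=max(1, M), N=max(1, N))


def simulate_hologram(truth: SimulationTruth) -> HologramImage:
    """Render ``h = |u_IP + r|**2`` for the given ground truth.

    Raises :class:`AliasingError` when the carrier exceeds the Nyquist limit
    (the message names the maximum usable tilt) or when the +1 support would
    overlap the DC bin without at least a one-pixel guard.
    """
    p = truth.params
    limit = p.nyquist_sin
    for name, th in (("theta_x", truth.tilt.theta_x), ("theta_y", truth.tilt.theta_y)):
        s = abs(math.sin(th))
        if s > limit + 1e-15:
            raise AliasingError(
                f"{name}: |sin| = {s:.6g} exceeds Nyquist; the maximum usable "
                f"tilt is asin(lambda/(2*dxy)) = {math.asin(min(1.0, limit)):.6g} rad"
            )
    if not truth.sphere.telecentric:
        # +1 support rectangle must not reach the DC bin (1-px guard)
        off_x = abs(p.X * p.delta_xy * math.sin(truth.tilt.theta_x) / p.wavelength)
        off_y = abs(p.Y * p.delta_xy * math.sin(truth.tilt.theta_y) / p.wavelength)
        M = (p.X * p.delta_xy) ** 2 / (p.wavelength * truth.sphere.C_x)
        N = (p.Y * p.delta_xy) ** 2 / (p.wavelength * truth.sphere.C_y)
        if off_x <= M / 2 + 1 and off_y <= N / 2 + 1:
            raise AliasingError(
                f"+1 support ({M:.1f} x {N:.1f} bins) overlaps the DC bin at "
                f"carrier offset ({off_x:.1f}, {off_y:.1f}); increase the tilt "
                "or the curvature"
            )

    a0 = truth.object_amplitude
    peak = a0.max()
    if peak > 0:
        a0 = a0 / peak  # keep the +1 term below the unit reference
    phi0 = truth.object_phase.values
    s = _spherical_phase(truth.sphere, p)
    t = _tilt_phase(truth.tilt, p)
    k = 2.0 * math.pi / p.wavelength
    u_ip = (
        (1.0 / truth.magnification)
        * np.exp(1j * k * truth.path_length)
        * a0
        * np.exp(1j * (phi0 + s))
    )
    r = np.exp(1j * t)
    holo = np.abs(u_ip + r) ** 2
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.rng_seed)
        holo = np.clip(holo + rng.normal(0.0, truth.noise_sd, holo.shape), 0.0, None)
    return HologramImage(values=holo, params=p)


# ---------------------------------------------------------------------------
# Manifest I/O
# ---------------------------------------------------------------------------

def _sphere_to_json(s: SphericalWavefront) -> dict:
    if s.telecentric:
        return {"telecentric": True}
    return {
        "telecentric": False, "C_x": s.C_x, "C_y": s.C_y,
        "h": s.h, "g": s.g, "sign": s.sign,
    }


def write_truth_manifest(truth: SimulationTruth, path: str | Path) -> Path:
    """Serialize a truth record (arrays included) to a JSON manifest."""
    path = Path(path)
    doc = {
        "params": {
            "X": truth.params.X, "Y": truth.params.Y,
            "delta_xy": truth.params.delta_xy,
            "wavelength": truth.params.wavelength,
        },
        "tilt": {"theta_x": truth.tilt.theta_x, "theta_y": truth.tilt.theta_y},
        "sphere": _sphere_to_json(truth.sphere),
        "object_phase": truth.object_phase.values.tolist(),
        "object_phase_wrapped": truth.object_phase.wrapped,
        "object_amplitude": truth.object_amplitude.tolist(),
        "f_TL": truth.f_TL,
        "z": truth.z,
        "noise_sd": truth.noise_sd,
        "rng_seed": truth.rng_seed,
        "magnification": truth.magnification,
        "path_length": truth.path_length,
    }
    path.write_text(json.dumps(doc))
    return path


def read_truth_manifest(path: str | Path) -> SimulationTruth:
    doc = json.loads(Path(path).read_text())
    sp = doc["sphere"]
    if sp.get("telecentric"):
        sphere = SphericalWavefront(None, None, telecentric=True)
    else:
        sphere = SphericalWavefront(
            C_x=sp["C_x"], C_y=sp["C_y"], h=sp["h"], g=sp["g"], sign=sp["sign"]
        )
    return SimulationTruth(
        params=AcquisitionParams(**doc["params"]),
        tilt=TiltAngles(**doc["tilt"]),
        sphere=sphere,
        object_phase=PhaseMap(np.array(doc["object_phase"]),
                              wrapped=doc["object_phase_wrapped"]),
        object_amplitude=np.array(doc["object_amplitude"]),
        f_TL=doc["f_TL"],
        z=doc["z"],
        noise_sd=doc["noise_sd"],
        rng_seed=doc["rng_seed"],
        magnification=doc["magnification"],
        path_length=doc["path_length"],
    )
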