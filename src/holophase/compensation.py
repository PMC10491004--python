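"""Tilt and spherical-wavefront compensation of the filtered object field.

After +1-order filtering the field is ``h_F = a0 * exp(i*(phi0 + s - t))``:
the object phase ``phi0`` buried under the linear carrier ``-t`` (off-axis
tilt) and the spherical distortion ``s`` (non-telecentric curvature).  Both
are pure phase factors, so compensation is pointwise multiplication by
unit-modulus conjugate waves and never alters the amplitude:

* ``r_D(m, n) = exp(i * 2*pi/lambda * dxy * ((m-u0) sin(theta_x) +
  (n-v0) sin(theta_y)))`` cancels the carrier;
* ``u_S*(m, n) = exp(-i * pi/lambda * ((m-h)**2/C_x + (n-g)**2/C_y) *
  dxy**2)`` cancels the spherical factor.

The sphere center ``(h, g)`` is found by segmenting the ring pattern of the
tilt-compensated wrapped phase (Otsu binarization, connected components,
lowest eccentricity); the converging/diverging sign, which the spectral
support size cannot determine, is resolved by trying both and keeping the
one with the lower phase standard deviation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.restoration import unwrap_phase as _skimage_unwrap

from .core import (
    AcquisitionParams,
    CenterNotFoundError,
    ComplexField,
    HolophaseError,
    InvalidInputError,
    PhaseMap,
    SpectrumROI,
    SphericalWavefront,
    TiltAngles,
    curvature_from_roi,
    logger,
    tilt_from_roi,
    wrap_phase,
)
from .spectral import (
    HologramImage,
    compute_spectrum,
    filter_plus_one,
    sideband_width,
    suggest_roi,
)

__all__ = [
    "digital_reference_wave",
    "compensate_tilt",
    "estimate_sphere_center",
    "conjugate_spherical_wave",
    "compensate_sphere",
    "unwrap_phase",
    "subtract_blank",
    "reconstruct",
    "ReconstructOptions",
    "ReconstructionResult",
]


def digital_reference_wave(tilt: TiltAngles, params: AcquisitionParams) -> ComplexField:
    """Unit-modulus digital reference wave cancelling the off-axis carrier."""
    n, m = np.mgrid[0 : params.Y, 0 : params.X].astype(np.float64)
    phase = (
        (2.0 * math.pi / params.wavelength)
        * params.delta_xy
        * (
            (m - params.u0) * math.sin(tilt.theta_x)
            + (n - params.v0) * math.sin(tilt.theta_y)
        )
    )
    return ComplexField(values=np.exp(1j * phase), params=params)


def compensate_tilt(fld: ComplexField, tilt: TiltAngles) -> ComplexField:
    """Multiply by the digital reference wave; centers the carrier on DC."""
    r_d = digital_reference_wave(tilt, fld.params)
    return ComplexField(values=fld.values * r_d.values, params=fld.params)


def estimate_sphere_center(
    phase: PhaseMap, min_area_fraction: float = 0.001
) -> tuple[float, float]:
    """Sphere vertex ``(h, g)`` from the ring pattern of a wrapped phase map.

    The wrapped residual spherical phase shows concentric fringes; the
    innermost ring (or central disc) is the most circular segmented region.
    The map is normalized to [0, 1], binarized at Otsu's global threshold,
    labelled, and the connected component with the lowest eccentricity among
    those with area >= ``min_area_fraction`` of the image is selected; its
    bounding-box center is returned as ``(h, g)`` = (column, row).  Ties on
    eccentricity go to the larger area.
    """
    if not phase.wrapped:
        raise InvalidInputError("sphere-center estimation expects a wrapped phase map")
    v = phase.values
    span = v.max() - v.min()
    if span <= 0:
        raise CenterNotFoundError("constant phase map: no rings to segment")
    norm = (v - v.min()) / span
    thr = threshold_otsu(norm)
    binary = norm > thr
    if not binary.any() or binary.all():
        raise CenterNotFoundError("degenerate binarization: no rings to segment")
    min_area = min_area_fraction * v.size
    regions = [r for r in regionprops(label(binary)) if r.area >= min_area]
    if not regions:
        raise CenterNotFoundError(
            f"no connected component above the area floor ({min_area:.0f} px)"
        )
    regions.sort(key=lambda r: (r.eccentricity, -r.area))
    r0, c0, r1, c1 = regions[0].bbox
    return ((c0 + c1 - 1) / 2.0, (r0 + r1 - 1) / 2.0)


def conjugate_spherical_wave(
    sphere: SphericalWavefront, params: AcquisitionParams
) -> ComplexField:
    """Unit-modulus conjugated spherical wavefront ``u_S*``.

    ``u_S*(m, n) = exp(-i * sign * pi/lambda * ((m-h)**2/C_x +
    (n-g)**2/C_y) * dxy**2)``; the phase is exactly zero at the vertex
    ``(h, g)``.  The telecentric sentinel yields a constant unit field.
    """
    if sphere.telecentric:
        return ComplexField(values=np.ones(params.shape, dtype=complex), params=params)
    h = params.u0 if sphere.h is None else sphere.h
    g = params.v0 if sphere.g is None else sphere.g
    n, m = np.mgrid[0 : params.Y, 0 : params.X].astype(np.float64)
    phase = (
        -sphere.sign
        * (math.pi / params.wavelength)
        * ((m - h) ** 2 / sphere.C_x + (n - g) ** 2 / sphere.C_y)
        * params.delta_xy**2
    )
    return ComplexField(values=np.exp(1j * phase), params=params)


def compensate_sphere(fld: ComplexField, sphere: SphericalWavefront) -> PhaseMap:
    """Wrapped object phase after removing the spherical wavefront."""
    u_s = conjugate_spherical_wave(sphere, fld.params)
    return PhaseMap(np.angle(fld.values * u_s.values), wrapped=True)


def unwrap_phase(phase: PhaseMap) -> PhaseMap:
    """2D phase unwrapping (reliability-sorting algorithm from scikit-image).

    The output is congruent to the input modulo 2*pi at every pixel and
    continuous along any path in a simply connected noiseless region.
    """
    if not phase.wrapped:
        raise InvalidInputError("input phase is already unwrapped")
    out = np.asarray(_skimage_unwrap(phase.values))
    return PhaseMap(out, wrapped=False)


def subtract_blank(sample_phase: PhaseMap, blank_phase: PhaseMap) -> PhaseMap:
    """Dual-shot baseline: wrapped difference of sample and blank phases.

    A blank (sample-free) hologram reconstructed with tilt compensation only
    carries the same spherical distortion as the sample; subtracting the two
    wrapped maps cancels it without estimating the curvature.
    """
    if sample_phase.values.shape != blank_phase.values.shape:
        raise InvalidInputError("sample and blank phase shapes differ")
    return PhaseMap(wrap_phase(sample_phase.values - blank_phase.values), wrapped=True)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class ReconstructOptions:
    """Options for :func:`reconstruct`.

    ``telecentric`` skips the spherical stage entirely; ``optimize`` selects
    the fine-tuning minimizer (``None`` disables the stage); ``sphere_seed``
    overrides the spectrally estimated wavefront as the optimizer's starting
    point; ``unwrap`` adds a 2D-unwrapped phase to the result.
    """

    telecentric: bool = False
    optimize: Literal[
        "FMC", "FMU", "FSO", "SA", "PTS", "GA", "PS", "GA_PS", None
    ] = None
    cost: Literal["J1", "J2"] = "J2"
    refine_center: bool = False
    rng_seed: int = 0
    unwrap: bool = False
    sphere_seed: SphericalWavefront | None = None
    auto_roi: bool = False
    apodize: float = 0.0


@dataclass
class ReconstructionResult:
    phase: PhaseMap
    amplitude: np.ndarray
    unwrapped: PhaseMap | None
    tilt: TiltAngles
    sphere: SphericalWavefront | None
    roi: SpectrumROI
    provenance: dict = field(default_factory=dict)


def _resolve_sign(
    fld: ComplexField, sphere: SphericalWavefront
) -> tuple[SphericalWavefront, PhaseMap, float]:
    """Try both wavefront signs; keep the one with the lower phase SD."""
    from .optimize import cost_J2

    best = None
    for cand in (sphere, sphere.flipped()):
        pm = compensate_sphere(fld, cand)
        j2 = cost_J2(pm)
        if best is None or j2 < best[2]:
            best = (cand, pm, j2)
    return best


def reconstruct(
    holo: HologramImage,
    roi: SpectrumROI | None = None,
    options: ReconstructOptions | None = None,
) -> ReconstructionResult:
    """Run the full spectral-analysis reconstruction pipeline.

    Stages: spectrum -> +1 filtering -> tilt from ROI centroid -> tilt
    compensation -> curvature from ROI size -> sphere-center estimation
    (image-center fallback) -> sign-resolved spherical compensation ->
    optional cost-driven fine-tuning -> optional unwrapping.  All estimated
    parameters are recorded in ``provenance``.
    """
    options = options or ReconstructOptions()
    params = holo.params
    prov: dict = {"stages": []}

    def stage(name):
        prov["stages"].append(name)

    stage("compute_spectrum")
    spectrum = compute_spectrum(holo)

    if roi is None:
        if not options.auto_roi:
            raise InvalidInputError("no ROI given and auto_roi disabled")
        stage("suggest_roi")
        roi = suggest_roi(spectrum)
    roi.validate_for(params)
    prov.update(P=roi.P, Q=roi.Q, M=roi.M, N=roi.N)

    stage("filter_plus_one")
    h_f = filter_plus_one(spectrum, roi, apodize=options.apodize)
    amplitude = np.abs(h_f.values)

    stage("tilt_from_roi")
    tilt = tilt_from_roi(roi, params)
    prov.update(theta_x=tilt.theta_x, theta_y=tilt.theta_y)

    stage("compensate_tilt")
    flat = compensate_tilt(h_f, tilt)

    if options.telecentric:
        stage("telecentric_skip_sphere")
        phase = PhaseMap(np.angle(flat.values), wrapped=True)
        sphere = None
    else:
        stage("curvature_from_roi")
        # users are advised to overestimate the crop rectangle, which would
        # bias the curvature low; measure the actual +1 support inside the
        # ROI (half-plateau width) and fall back to the ROI extents
        try:
            m_meas = sideband_width(spectrum, roi, axis="x")
            n_meas = sideband_width(spectrum, roi, axis="y")
            eff = SpectrumROI(P=roi.P, Q=roi.Q, M=m_meas, N=n_meas)
            prov.update(M_measured=m_meas, N_measured=n_meas)
        except HolophaseError:
            eff = roi
        sphere = curvature_from_roi(eff, params)
        prov.update(C_x=sphere.C_x, C_y=sphere.C_y)

        stage("estimate_sphere_center")
        raw_phase = PhaseMap(np.angle(flat.values), wrapped=True)
        try:
            h, g = estimate_sphere_center(raw_phase)
        except CenterNotFoundError:
            logger.info("sphere center not found; falling back to the image center")
            h, g = float(params.u0), float(params.v0)
            prov["center_fallback"] = True
        sphere = sphere.with_center(h, g)
        prov.update(h=h, g=g)

        # resolve converging/diverging on the spectral estimate, where the
        # residual is small enough for the J2 comparison to be decisive
        stage("compensate_sphere")
        sphere, phase, j2 = _resolve_sign(flat, sphere)
        prov.update(sign=sphere.sign, cost_J2_initial=j2)

        if options.sphere_seed is not None:
            # an explicit wavefront is authoritative (curvatures and sign);
            # only the center falls back to the ring-pattern estimate
            seed = options.sphere_seed
            sphere = seed
            if seed.h is None or seed.g is None:
                sphere = sphere.with_center(h, g)
            phase = compensate_sphere(flat, sphere)
            prov["sphere_seed_override"] = True

        if options.optimize is not None:
            from .optimize import OptimizationSpec, minimize

            stage(f"optimize_{options.optimize}")
            # the pre-optimization sign comparison is only decisive when the
            # curvature estimate is already close; optimize both signs and
            # keep the lower final cost so a plateau-level tie cannot lock
            # in the wrong branch
            result = None
            for cand in (sphere, sphere.flipped()):
                spec = OptimizationSpec(
                    cost=options.cost,
                    algorithm=options.optimize,
                    seed_params=cand,
                    refine_center=options.refine_center,
                    rng_seed=options.rng_seed,
                )
                r = minimize(spec, lambda s: compensate_sphere(flat, s))
                if result is None or r.cost_value < result.cost_value:
                    result = r
            sphere = result.best
            phase = compensate_sphere(flat, sphere)
            prov.update(
                C_x=sphere.C_x, C_y=sphere.C_y, h=sphere.h, g=sphere.g,
                cost_value=result.cost_value,
                cost_evaluations=result.evaluations,
                optimizer=options.optimize,
                cost_function=options.cost,
                rng_seed=options.rng_seed,
            )

    unwrapped = None
    if options.unwrap:
        stage("unwrap_phase")
        unwrapped = unwrap_phase(phase)

    return ReconstructionResult(
        phase=phase,
        amplitude=amplitude,
        unwrapped=unwrapped,
        tilt=tilt,
        sphere=sphere,
        roi=roi,
        provenance=prov,
    )


def write_phase_outputs(
    result: ReconstructionResult,
    outdir: str | Path,
    stem: str = "reconstruction",
    preview: bool = True,
) -> dict[str, Path]:
    """Write phase/amplitude TIFFs, optional PNG preview and provenance JSON."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _tif(name: str, arr: np.ndarray) -> None:
        p = outdir / f"{stem}_{name}.tif"
        tifffile.imwrite(p, arr.astype(np.float32))
        paths[name] = p

    _tif("phase", result.phase.values)
    _tif("amplitude", result.amplitude)
    if result.unwrapped is not None:
        _tif("unwrapped", result.unwrapped.values)
    if preview:
        import imageio.v3 as iio

        v = result.phase.values
        img = ((v - v.min()) / max(v.max() - v.min(), 1e-12) * 255).astype(np.uint8)
        p = outdir / f"{stem}_phase_preview.png"
        iio.imwrite(p, img)
        paths["preview"] = p
    prov_path = outdir / f"{stem}_provenance.json"
    prov_path.write_text(json.dumps(result.provenance, indent=2, default=float))
    paths["provenance"] = prov_path
    return paths
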