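# holophase

Quantitative phase reconstruction for **off-axis digital holographic
microscopy (DHM) in the non-telecentric regime**, from a single hologram and
just two numbers: the camera pixel pitch Δ<sub>xy</sub> and the laser
wavelength λ.

## The problem

Off-axis DHM records the interference of the object wave and a tilted plane
reference on a camera. Reconstruction must remove two phase aberrations
before the sample's optical-path delay can be read quantitatively:

* the **linear carrier** t(x, y) = (2π/λ)(x sin θ<sub>x</sub> + y sin θ<sub>y</sub>)
  from the off-axis tilt θ = (θ<sub>x</sub>, θ<sub>y</sub>), and
* the **spherical wavefront** s(x, y) = (π/λC)·r² of curvature
  C = f²<sub>TL</sub>/(f<sub>TL</sub> − z) introduced whenever the microscope
  objective and tube lens are not in the afocal (telecentric) configuration —
  which is the common case in practice.

Both parameters are read directly off the hologram spectrum. Writing
(u₀, v₀) for the DC bin, (P, Q) for the +1-order centroid and M × N for its
rectangular compact support:

```
sin θx = (u0 − P)·λ/(X·Δxy)          sin θy = (v0 − Q)·λ/(Y·Δxy)
C_x    = (X·Δxy)²/(λ·M)              C_y    = (Y·Δxy)²/(λ·N)
```

The pipeline: FFT → +1-order crop → inverse FFT → multiply by the conjugate
digital reference wave r<sub>D</sub> (tilt gone) → locate the sphere vertex
(h, g) from the residual ring pattern (Otsu binarization, lowest-eccentricity
region) → multiply by the conjugate spherical wavefront u*<sub>S</sub> →
optionally fine-tune (C<sub>x</sub>, C<sub>y</sub>) by minimizing a cost on
the compensated phase — J1 (count of non-white pixels of the binarized map)
or J2 (phase standard deviation) — with one of eight minimizers including a
hybrid genetic-algorithm + pattern-search (GA+PS, population 15, ±50% bounds).
A forward simulator of the full imaging model generates holograms with known
ground truth, so every estimator is verifiable by parameter recovery.

## Worked example

Simulate a non-telecentric hologram of a Siemens-star phase target
(512², Δ<sub>xy</sub> = 5.86 µm, λ = 0.532 µm, C = 3.5×10⁵ µm, star height
2.1497 rad — the QPT nominal 2π(1.52−1)·0.350/0.532), then reconstruct it
with GA+PS/J2 fine-tuning, then score it against the ground-truth manifest:

```
$ holophase simulate examples/scenario.yaml -o demo
star_nontelecentric: hologram + manifest written to demo

$ holophase reconstruct demo/star_nontelecentric_hologram.tif \
    --pixel-size 5.86 --wavelength 0.532 --roi 86 86 165 165 \
    --optimize ga_ps --cost j2 --seed 1 --unwrap -o demo/rec
phase: demo/rec/reconstruction_phase.tif
amplitude: demo/rec/reconstruction_amplitude.tif
unwrapped: demo/rec/reconstruction_unwrapped.tif
preview: demo/rec/reconstruction_phase_preview.png
provenance: demo/rec/reconstruction_provenance.json

$ holophase evaluate demo/rec/reconstruction_phase.tif \
    --truth demo/star_nontelecentric_truth.json \
    --provenance demo/rec/reconstruction_provenance.json -o demo/metrics.json
{
  "percent_error": {
    "theta_x": 6.002046780213257e-05,
    "theta_y": 6.002046780213257e-05,
    "C_x": 0.0702120356341059,
    "C_y": 0.08466718595937293,
    "h": 0.0,
    "g": 0.0
  }
}
```

Reading the numbers: the tilt is recovered essentially exactly (the +1
centroid falls on the true spectral bin), the sphere vertex (h, g) is found
to the pixel, and the curvature — seeded by the spectral support measurement
and refined by GA+PS — lands within 0.07–0.08% of the simulated truth
(provenance records C_x = 349 754 µm vs. 350 000 µm true, J2 falling from
0.562 to 0.385 over 1682 cost evaluations). The unwrapped phase map then
shows the star at its nominal 2.15 rad height on a flat background.

The same functions are importable (`holophase.reconstruct`,
`holophase.simulate_hologram`, `holophase.minimize`, …) for scripted use.

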