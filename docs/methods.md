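# Methods

## Imaging model

A Mach–Zehnder off-axis DHM records h = |u_IP + r|² on an X×Y sensor of
pixel pitch Δxy. The reference is a unit plane wave
r = exp[i·(2π/λ)·Δxy·((m−u0)·sinθx + (n−v0)·sinθy)], written on 0-based
pixel indices (m, n) centered on the DC bin (u0, v0) = (⌊X/2⌋, ⌊Y/2⌋); the
1-based convention (X/2+1) used in much of the DHM literature coincides
with this for even sensors. The image-plane object field is
u_IP = a0·exp[i(φ0 + s)] with the non-telecentric spherical factor
s = sign·(π/λC)·((m−h)² + (n−g)²)·Δxy², C = f_TL²/(f_TL−z). All lengths are
micrometers internally; loaders convert. The finite pupil of the objective
is not modeled (infinite-aperture assumption), so the forward model is a
pure phase-factor model; an optional Gaussian edge smoothing on the object
patterns stands in for the band limit a real finite-NA system imposes
(a 40×/0.75 NA system at 5.86 µm pitch resolves ≈ 5 image-plane pixels, so
ideal hard-edged targets are not physically realizable there).

Two printed spectral phase expressions in the source formulation carry
typographic artifacts (a stray summation over pixel indices, one "y−g" for
"n−g", and an inverted curvature factor in the image-field equation); the
implemented per-pixel forms above are the dimensionally consistent set,
matching the support-size relations used for estimation.

## Parameter estimation

* **Tilt** from the +1-order centroid: sinθx = (u0−P)·λ/(X·Δxy). Exact
  when the carrier sits on a spectral bin; the generic error is half a bin,
  λ/(2XΔxy) in sin θ.
* **Curvature** from the +1-order compact support, C_x = (XΔxy)²/(λM). The
  support is measured as the width of the sideband magnitude profile at
  **half its plateau level** (median over the central region). The
  chirp-broadened sideband has Fresnel edges that cross half-plateau at the
  nominal support boundary; a small-fraction-of-peak threshold is *not*
  usable because the Fresnel tails decay only as 1/ν (measured: a
  1%-of-peak threshold overestimates M by 80–600 px on a 1024 grid, while
  half-plateau agrees within ±2 px across C = 1×10⁵–1×10⁶ µm, R² ≥ 0.9999
  against 1/C). Inside `reconstruct` the support is measured within the
  user's crop rectangle rather than taken from its extents: users are
  advised to overestimate the rectangle, which would otherwise bias C low
  by the padding ratio and can push the truth outside the optimizer's
  bounds.
* **Vertex (h, g)** from the ring pattern of the tilt-compensated wrapped
  phase: normalize to [0,1], Otsu-binarize, label, drop components below
  0.1% of the image area, pick the lowest-eccentricity region (ties →
  larger area) and return its bounding-box center. Fails cleanly (with an
  image-center fallback in the pipeline) below ~3 wraps.
* **Sign** (converging/diverging), which the support size cannot give: both
  signs are compensated and the lower phase SD kept. When the optimization
  stage runs, both signs are *optimized* and the lower final cost kept —
  at a poor curvature seed both raw signs sit on the wrap-saturated SD
  plateau and the pre-refinement comparison is a coin flip.

## +1-order filtering

Hard rectangular crop of the centered spectrum (the manual-workflow
behavior), optional raised-cosine (Tukey) edge of fractional width
`apodize` to suppress crop ringing. The automatic ROI suggester masks a DC
disc of radius max(X,Y)/20, thresholds log(1+|H|) with *recursive* Otsu
(re-thresholding the foreground until it is ≤ 2% of pixels — a single pass
splits the broad unimodal tail background instead of isolating the peaks),
and returns the bounding box of the largest component above the DC row.

## Cost-driven fine-tuning

J1 counts below-threshold pixels of the Otsu-binarized normalized phase
(all-white = fully compensated); J2 is the SD of the wrapped phase. Both
are minimized over (C_x, C_y) — optionally (h, g), bounds ±10% of image
size — inside box bounds seed·(1 ± 0.5).

Minimizers: Powell with bounds (FMC), Nelder–Mead unbounded with final
clamping (FMU), Nelder–Mead with bounds (FSO), scipy dual-annealing with a
pattern-search polish (SA), compass pattern search with opportunistic
polling and step halving (PS), the same with decaying threshold acceptance
and seeded poll order (PTS), a real-coded GA (population 15, tournament-3,
BLX-0.5 crossover, Gaussian mutation decaying to a 2%-of-span floor, one
elite, three uniform random immigrants per generation), and the hybrid
GA_PS (GA to convergence, then PS from its optimum; never worse than GA
alone by construction). GA convergence: relative best-cost improvement
< 1e-6 over 50 generations, cap 200 — the common toolbox defaults for a
two-variable search. The immigrants and mutation floor matter because a
strongly aberrated wrapped phase makes the cost landscape a plateau at the
uniform-phase SD (≈ 2π/√12) with a narrow basin around the truth (halfwidth
≈ 2π/s_max per axis, s_max the corner value of the residual paraboloid in
radians): global coverage, not gradient signal, finds the basin. All
stochastic stages are reproducible from a single integer seed.

A caveat the tests quantify: with an object in the field, the J2 minimum is
displaced from the true curvature by −Cov(φ0, q)/Var(q) radians of residual
paraboloid q (object sitting where q is below its mean ⇒ minimum at
slightly weaker compensation). The reference test scene therefore places
the target centroid on the ring where q crosses its field mean, making the
landscape assessment covariance-neutral; vertex-centered large targets show
a 0.5–2% displacement, which is a property of the SD cost, not of the
search.

## Reference test conditions

Chosen once, used by the test suite and `scripts/acceptance.py`:
512² sensor, Δxy = 5.86 µm, λ = 0.532 µm; carrier offset (170, 170) bins;
C = 3.5×10⁵ µm (the experimental range of such systems; a worked curvature
in the source material is ≈ 0.58 m), vertex (273, 247); Siemens star of
height 2.1497 rad (2π·(1.52−1)·0.350/0.532, the QPT nominal), outer radius
0.17·size, centroid (421, 395), edges smoothed with σ = 2 px; crop
(P, Q, M, N) = (86, 86, 165, 165) with Tukey-0.3 edge. The support-vs-1/C
check runs on a 1024² grid at Δxy = 4.5 µm (at 5.86 µm the largest support
in the prescribed C decade would not separate from DC) with the carrier
purely along y, so both ±1 orders share the column span and the x-width
measurement is overlap-free. The noise check uses 256² at SNR 20 dB
(additive Gaussian, σ = std(h)/10, clipped at 0). Problem sizes were picked
so the whole suite and the acceptance script each finish in minutes on one
CPU.

## Unwrapping, metrics, baseline

2D unwrapping is the reliability-sorting algorithm of scikit-image
(congruent mod 2π by construction; exact on ramps, RMS ≤ 0.01 rad on
multi-wrap paraboloids). SSIM uses scikit-image defaults on jointly
rescaled maps (shared min/max → [0,1], data_range 1). PE =
|est − ref|/|ref|·100. The dual-shot baseline subtracts a blank-hologram
phase (wrapped difference); with a matched blank it reproduces the
single-shot method up to a constant (circular SD of the difference ≤ 0.05
rad under the reference conditions), and a 5% curvature-mismatched blank
degrades the background by orders of magnitude — the single-shot method's
advantage when acquisition drifts.

## What the simulations do not show

The simulator omits the finite pupil (no diffraction blur beyond the
optional pattern smoothing), partial coherence, speckle, and camera
physics beyond additive Gaussian noise with optional quantization. Passing
recovery tests therefore demonstrates the correctness of the spectral
estimators and compensation algebra under the stated model, not robustness
to the full optics of a physical instrument. Limits worth knowing: center
estimation needs ≥ 3 wraps; curvature estimation degrades for supports
below ~10 bins (Fresnel edge comparable to the support); carriers must
keep the +1 support separated from DC by at least a pixel, or the
simulator refuses the scene.
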