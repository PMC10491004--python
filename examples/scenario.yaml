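# A 512 x 512 off-axis non-telecentric hologram of a Siemens-star phase
# target: carrier offset (170, 170) spectral bins, spherical curvature
# 3.5e5 um with vertex at pixel (273, 247).  Lengths in micrometers,
# angles in radians.
scenarios:
  - name: star_nontelecentric
    params: {X: 512, Y: 512, delta_xy: 5.86, wavelength: 0.532}
    tilt: {theta_x: 0.030148, theta_y: 0.030148}
    sphere: {C_x: 350000.0, C_y: 350000.0, h: 273.0, g: 247.0, sign: 1}
    pattern:
      kind: star
      height: 2.1497
      radius_frac: 0.17
      center: [421, 395]
      edge_sigma: 2.0
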