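# Methods

## Scope and model structure

The package models the 3D detection volume of a magnetron-based marine
X-band pulse radar (12 kW, 9410 MHz, 31.6 dBi slotted waveguide antenna,
0.07 µs pulse) for small airborne targets, together with the effect of a
clutter shielding fence (CSF).  Five components chain together:

1. **Link budget** (`radar_link`): the monostatic radar equation with
   all system losses folded into a single calibrated minimum detectable
   signal power P_min.
2. **Sphere RCS** (`rcs`): exact Mie backscatter for conducting and
   dielectric spheres; the optical-region formula σ = f·k·πr².
3. **Fence diffraction** (`diffraction`): sharp-edge (knife-edge)
   Fresnel diffraction of spherical waves at the fence's top edge.
4. **Image analysis** (`ppi`): 32-level quantized PPI images,
   clutter-threshold visibility masks, and the echo-visibility rule for
   stacks of consecutive scans.
5. **Volume integration** (`volume`): V = Σ_p A_px·h(d_p) over visible
   pixels, sector extrapolation, acoustic-detector comparison, and the
   fence-height × threshold optimization sweep.

`synth` generates seeded synthetic scenes so the whole chain is testable
without field imagery; `antenna` supplies the vertical gain pattern;
`config`/`cli` are serialization and a thin command-line wrapper.

## Physical constants and conventions

- Speed of light c = 2.998×10⁸ m/s; the link budget uses λ = c/f =
  3.186 cm at 9410 MHz throughout (an explicit `wavelength_override_m`
  exists for sensitivity checks against the coarser data-sheet 3.1 cm;
  c/f closes the 2.8 cm² → −74 dBm → 12.7 cm² calibration triangle,
  the rounded value does not).
- Gains are stored linear, accepted in dBi at the interface; RCS is
  stored in m², reported in cm²; powers in watts, reported in dBm.
- Pixel coordinates are (row, col) with row 0 at the top; bearings run
  clockwise from north; pixel distances are center-to-center; sectors
  are half-open [start, end) so that a sector and its complement
  partition the circle exactly.

## Mie series

The conducting-sphere backscatter uses the standard Bohren–Huffman sum
σ = (λ²/4π)·|Σₙ (−1)ⁿ(2n+1)(aₙ−bₙ)|² with Riccati–Bessel coefficients
aₙ = ψₙ′(x)/ξₙ′(x), bₙ = ψₙ(x)/ξₙ(x), truncated at
n_max = x + 4x^⅓ + 10.  Both the Rayleigh limit (σ/πr² → 9x⁴) and the
optical limit (σ/πr² → 1), and the classic first-resonance peak
(σ/πr² ≈ 3.6 near x ≈ 1) are verified in the tests against an
independently coded recurrence oracle.

The dielectric sphere (water) uses the logarithmic-derivative downward
recurrence for the interior functions (scipy's spherical Bessel
functions are real-argument only).  The sign convention is e^(−iωt):
the complex refractive index carries a **positive** imaginary part.
Water permittivity defaults to a single-Debye model at 20 °C
(ε_s = 80.2, ε_∞ = 5.6, τ = 9.4 ps), overridable per sphere and never
load-bearing for calibration: it yields 7.34 cm² for the 30 ml
water-sphere bat torso, inside the 7–8.5 cm² band of published
water-sphere values, vs 6.54 cm² from the optical formula with k = 0.56.

Scattering-regime labels follow the circumference rule: optical at
2πr ≥ 10λ, Rayleigh below 2πr < λ, Mie between.  The 1 cm calibration
sphere (2πr = 0.99λ) is labelled Rayleigh by this rule even though it
sits at the resonance peak — the label is descriptive only.

## Antenna pattern

The manufacturer's measured vertical diagram is not available.  The
default is a parametric Gaussian main lobe, quadratic in dB:
G_dB(φ) = peak − 3(φ/10°)², i.e. −3 dB at ±10° (typical for a marine
slot antenna), sampled at 0.1° over ±90° and interpolated linearly in
dB.  Consequence: boresight quantities (the 800 m maximum range) are
faithful because they depend only on the peak gain, but absolute
detection *heights* depend on the unknown real pattern shape and are
not reproduced — the boundary logic is instead validated against the
closed-form circular arc h(d) = h_R + √(R_max²−d²) of an isotropic
pattern, and by grid-refinement stability.  Sidelobes are omitted by
default; tabulated patterns may include them.

## Knife-edge diffraction

The fence is treated as a single infinite straight opaque edge at the
fence-top height, at the horizontal fence radius (the hexagonal ring's
5.99–6.08 m radii collapse to the 6 m average).  For a target at
distance d and height h the edge offset is
z = h_CF − [h_R + (h−h_R)·d_CFR/d] (positive = shadowed), and
v₁ = z√(2(ρ₀+r₀)/(λρ₀r₀)) with ρ₀ = d_CFR, r₀ = d − d_CFR.  Assumptions:

- Fresnel obliquity factor ≡ 1 (edge offsets ≪ ρ₀, r₀);
- distances measured horizontally (slant corrections < 0.1 %);
- perfectly opaque fence (measured mesh attenuation 20–25 dB one-way
  dwarfs the diffracted field);
- the factor applies at *all* elevations, which produces the physical
  interference maxima/minima above the edge; no clamping;
- the fence's ~110° azimuthal extent is handled by sector restriction
  in the volume layer, not in the diffraction formula.

The two-way echo factor is (I_P/I₀)², i.e. the suppression doubles in
dB.  For the study geometry (h_CF = 2.2 m, h_R = 2 m, d_CFR = 6 m) the
one-way ground-region suppression is 11.4–16.9 dB, comfortably above
the 10 dB design figure from early fence studies.

## Detection field and boundary

The power field is evaluated on a (distance × height) grid — default
5 m × 1 m over 5–1200 m × 0–300 m, starting beyond the fence radius in
advanced mode — from the antenna phase center at (0, h_R).  Detectable
cells satisfy P ≥ P_min; per-distance runs of detectable cells form the
height intervals of the boundary, and the detection height at a pixel's
distance is the summed interval extent at the nearest grid column (no
interpolation).  Elevations beyond the sampled pattern span contribute
zero gain; with the default pattern the gain is already −60 dB at 45°,
so this never shapes the boundary.  Earth curvature and refraction are
ignored (ranges ≤ 1.5 km).

## Echo-visibility procedure

A sample point's echo in one scan is analysed as the 3×3 pixel matrix
around the brightest pixel within an 11×11 search window centered on
the declared sample point; the scan passes when the matrix mean is
≥ 25 of 31 levels.  Over a stack of 11 consecutive scans the point is
"visible" when more than 5 scans pass (> 50 %).  Ties in the brightest-
pixel search go to the candidate nearest the sample point (then
row-major), so a uniform echo block is analysed at its center.  The
≥ comparison at level 25 is configurable; both printed exemplar
signatures (mean 31 visible, mean 18 invisible) are insensitive to the
choice.

Visibility masking of an image uses level ≤ threshold (a pixel is
clutter-free when its intensity does not exceed the tolerated clutter
level); the detection volume is therefore non-decreasing in the
threshold, which the tests assert.

## Synthetic scenes

The generator emulates the *structure* of onshore PPI imagery — extended
clutter regions with scan-to-scan level fluctuation, and 3×3 point
echoes at polar positions — not its physics: no Weibull/K clutter
statistics, no beam smearing, no range-dependent intensity falloff.
Passing tests on synthetic scenes therefore validate the analysis
pipeline (geometry, thresholds, integration — e.g. exact agreement with
a brute-force per-pixel volume oracle, and bit-exact recovery of
planted per-frame pass patterns), but say nothing about level
calibration on real Furuno imagery, whose 32-color palette is not
published.  The with/without-fence pair converts the two-way suppression
to display levels at 3 dB/level — an invented, documented fixture
constant (32 levels ≈ 96 dB displayed dynamic range); nothing in the
display standard fixes this mapping.

## Numerical choices

- Fresnel integrals: `scipy.special.fresnel` (note scipy returns (S, C);
  the package returns (C, S)); the test oracle is adaptive quadrature of
  the defining integrands, abs. error < 1e-8.
- Mie truncation: n_max = x + 4x^⅓ + 10; doubling changes σ by
  < 1e-10 relative.
- Degenerate inputs: zero RCS gives zero power (flagged by the dBm
  conversion refusing non-positive power); an uncalibrated system
  raises on any P_min-dependent query; `max_visible_distance` returns
  None (not 0) when no distance qualifies.
- The optimization sweep varies h_CFR by moving the antenna against a
  fixed fence (h_R = h_CF − h_CFR), matching the adjustable-mast field
  setup.

## Design choices on open points

- The 360° extrapolation of the sector volume uses the 105° section
  angle for the acoustic comparison (the alternative 95° reading of the
  25°–120° image section does not reproduce the published rounded ratio
  of 270; the inconsistency is inherited, not resolvable here).
- The detection height in the fence case is the summed extent of all
  detectable intervals at that distance (upper minus lower per
  interval), consistent with "everything inside the boundary is
  detectable".
- P_min calibration uses the exact Mie value (2.84 cm²) rather than the
  rounded 2.8 cm²; both round to −74 dBm.

## Known limitations

- Absolute detection heights (and hence absolute volumes on real
  imagery) depend on the unavailable manufacturer antenna diagram.
- Real-image ingestion is limited to grayscale/text levels; the
  proprietary color palette is out of scope.
- The fence model is a single knife edge: panel seams, finite width,
  mesh transmission and multiple diffraction are not modelled.
- RCS is treated as a constant average; aspect-dependent fluctuation of
  live animals is outside the model (the stack rule absorbs scan-to-scan
  fluctuation empirically).
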