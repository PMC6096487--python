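# Methods

This note records the models, conventions and numerical choices behind
`edgeom`, in the spirit of a software methods section. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Frames and conventions

* Right-handed lab frame; the nominal incident beam propagates along `+z`,
  the goniometer rotation axis along `+x`, detector panels nominally
  perpendicular to the beam. Positive scan angles are right-handed rotations
  about the axis; the inverted-handedness hypothesis is the negated axis.
* Angles are degrees at every public interface (radians internally);
  distances mm; reciprocal space 1/Å. Physical constants are CODATA 2018,
  frozen in one place (`geometry.py`).
* Pixel coordinates are 0-based continuous `(X fast, Y slow)` from the outer
  corner of pixel (0, 0); pixel centres sit at half-integer coordinates.
* The crystal is `U · B`: `B` is the upper-triangular Cholesky factor of the
  reciprocal metrical matrix `g*` (Busing–Levy convention, `a*` along the
  first Cartesian axis), and `U` a proper rotation. `g*` is computed as the
  inverse of the real-space metric tensor, which makes
  `cell ↔ g*` exactly involutive.

## Reflection prediction

The rotation-method diffraction condition reduces to
`A cos φ + B sin φ = C` after decomposing `r0 = U B hkl` along and
perpendicular to the rotation axis; both roots are evaluated in closed form.
Reflections parallel to the axis (blind region) or beyond the limiting
sphere have no roots. A brute-force 0.001°-step sign-change scan exists only
in the tests as an independent oracle.

Printed crossing angles embed an arbitrary starting orientation, so only
angle *differences* are orientation-free. `calibrate_crossing` fixes the
gauge by pre-rotating the crystal about the goniometer axis so a named
reflection's *entering* crossing (moving from outside to inside the sphere)
lands at a named angle; the entering branch is consistent across a collinear
family, making absolute angles comparable. Axial pre-rotations leave
differences exactly invariant; general pre-rotations do not (they change
each point's inclination to the axis), which is why the invariance test uses
axial offsets.

Predicted rays are intersected with each panel plane in order; the first
panel whose pixel bounds contain the hit receives the record. During
refinement, predictions are instead matched one-to-one to observations (the
crossing nearest the observed φ, intersected with the observation's own
panel plane, without bound checks) so the residual vector stays a smooth
function of the parameters for finite differencing.

## Image preparation

* **Timepix expansion**: the double-width boundary rows/columns (1-based 256
  and 257) are split into three pixels each, *replicating* the count — the
  resulting six-pixel-wide cross then carries ≈3× gain, and all non-cross
  pixels are multiplied by 3, so the whole 516×516 frame has a uniform
  multiplicative gain of 3.0.
* **Distortion maps** store `corrected − raw` offsets in pixels, evaluated at
  raw pixel positions, one pair of arrays per panel. px→mm applies the
  *reverse* correction first (fixed-point iteration on the
  nearest-neighbour lookup, ≤ 5 iterations, 0.01 px tolerance); mm→px
  computes the raw coordinate and applies the correction. No interpolation
  anywhere. The elliptical generator models the recorded pattern as the true
  pattern scaled by `scale_major` along `axis_angle` and `scale_minor`
  perpendicular, about a centre; the `(scale_major, scale_minor,
  axis_angle)` parameterization is this package's documented choice.
* **Spot finding** uses the dispersion criterion: a pixel is strong iff the
  local index of dispersion exceeds `gain·(1 + σ_b√(2/(n−1)))`, the count
  exceeds the local mean by `σ_strong·√(gain·mean)`, and the count exceeds a
  global threshold; 8-connected components smaller than `min_spot_size` are
  dropped and centroids are intensity-weighted. Defaults: σ_b = 6,
  σ_strong = 3, `min_spot_size` = 2, window 7×7 — the full width equivalent
  of the conventional half-width-3 local kernel (a literal 3×3 window makes
  the dispersion test marginal for realistic spot sizes).
* **Axis azimuth**: the rotation axis projects to a line through the beam
  centre along which few spots appear; a 36-bin azimuthal histogram
  (mod 180°), smoothed with a circular 3-bin moving average, is minimized.
  Results are flagged low-confidence below 50 spots or when the minimum is
  within 20% of the mean density.

## Refinement

Residuals are ordered X-block, Y-block, φ-block (px, px, deg), weighted by
inverse centroid standard deviations (unit weights where variances are
absent). Parameters and units:

| label | meaning | unit |
|---|---|---|
| `mu1` | beam rotation about the goniometer axis (fixed by default: equivalent to a crystal setting rotation) | mrad |
| `mu2` | beam rotation about the axis ⊥ (goniometer axis, beam) | mrad |
| `phi1..3` | orientation missets about lab x, y, z, composed ahead of U₀ | mrad |
| `g11..` | free `g*` elements × 10⁵ (so all Jacobian columns have comparable natural magnitudes) | scaled Å⁻² |
| `dist`, `shift1/2` | detector translations along the reference normal / fast / slow | mm |
| `tau1..3` | detector rotations about the reference normal / fast / slow, acting at the detector centre | mrad |

The default single-panel static set is 13 free parameters for an
orthorhombic crystal. Derivatives are central finite differences with steps
of 10⁻⁴ of characteristic scales (1 mrad; 10⁻⁶ Å⁻²; 0.01 mm): with
double-precision prediction the relative derivative error is ~10⁻⁸–10⁻⁶,
validated in the tests against an independent five-point stencil. The exact
rotation axes for `mu` and `tau` are this package's definitions.

Levenberg–Marquardt: damping starts at `10⁻³·max(diag JᵀJ)`, ×10 on a
rejected step, ÷10 on acceptance; termination when every residual
dimension's r.m.s.d. improves by < 0.01% over a step, at 100 iterations
(default cap), or when no improving step exists (reported as converged if
the residuals are at the numerical floor). Unit-cell restraints append one
pseudo-observation row `√w(a − a_t)` per active real-cell parameter
(`w = 1/σ²`; σ ≈ 0.001 for strong, ≈ 0.1 for weak restraints); restraints on
symmetry-constrained parameters are dropped, scan-varying cells cannot be
restrained, and restraint rows never enter diagnostics. Outliers are flagged
by per-dimension Tukey fences at 3×IQR between refinement rounds (a
documented stand-in for a method the surrounding literature leaves
unspecified); flags are set, rows never deleted.

Scan-varying parameters carry `n` smoother sub-parameters sampled evenly
over the scan; values interpolate with Gaussian weights
`exp(−(Δ/σ_s)²)` over the nearest three samples (all samples when n ≤ 3),
σ_s = 1 sample spacing. Defaults: 3 samples per orientation angle and — when
beam drift is modelled — 2 per beam angle, the simplest model, which design
analysis shows already tracks a 0.5 mrad half-cosine drift to ≈ 0.02 mrad
RMS. The detector is always held at its static values during the
scan-varying stage. A constant beam tilt is nearly degenerate with an
in-plane detector shift, so *absolute* beam tracks are only meaningful with
a calibrated (fixed) detector; the drift-recovery test fixes the detector
for exactly this reason.

## Diagnostics

Corrgrams are Pearson correlations between weighted Jacobian columns,
computed separately per residual block (the three centroid dimensions come
from different distributions and must not be pooled). Columns with norm
below 10⁻⁸ of the block's largest are omitted — the threshold sits above
finite-difference noise so analytically-zero columns (detector parameters in
the φ block; `phi1` in X/Y) are dropped consistently. κ(J) is the singular
value ratio of the weighted Jacobian, +∞ below a 10⁻¹⁴ relative floor;
restraint rows are excluded from both diagnostics, which therefore describe
the bare geometric problem. The handedness test refines orientation angles
only under both axis hypotheses and compares angular r.m.s.d.s, declaring
ambiguity when they differ by < 10% (or both vanish, e.g. a single image).

## Simulator

The generator's defaults are the study conditions: λ_ED = 0.02508 Å with
effective distance 2000 mm; λ_MX = 1.0332 Å with the distance that puts
d_min at the panel edge; one 1024×1024 panel of 55 µm pixels with the beam
centre at the panel centre; orthorhombic 32 × 68 × 105 Å cell with the short
axis nearest the rotation axis (tilted 6°/4° so low-order axial reflections
are not exactly blind); a 40° wedge at 0.1°/image; d_min = 6 Å giving ~10³
reflections; Gaussian centroid noise 0.3 px / 0.02° with true variances
recorded. ED and MX share the crystal, scan, axis and candidate reflection
list, so conditioning comparisons isolate the geometry. Beam drift is a
half-cosine ramp (smooth, zero-slope at both ends) about the axis
⊥ (goniometer axis, beam), with per-image truth stored for recovery tests.
Frames are Poisson backgrounds plus 2-D Gaussian blobs at the (panel-local)
centroids. All randomness flows from a single explicit seed; fixed seed
means bitwise-identical output.

What the simulator does **not** emulate — and hence what passing tests do
not demonstrate about real data: dynamical and inelastic scattering,
mosaicity and finite reflection profiles (reflections are geometric points),
partiality/multiplicity effects, detector point spread, shutter or
rotation-rate jitter, and non-smooth beam motion. Real-data per-set
statistics are outside the package's scope.

## Notable design choices and limitations

* The shared-reflection-list ED/MX pair forces both geometries to the same
  d_min (6 Å), so the MX case scatters only to 2θ ≈ 10°. The φ-block
  corrgram contrast (higher correlations for ED) and the κ(J) contrast are
  robust under these conditions; the X/Y-block mean correlations come out
  statistically equal rather than ED-higher, and the cell/distance
  degeneracy contrast is therefore demonstrated with a dedicated high-angle
  X-ray configuration (2θ > 45°).
* Restraint derivative rows and all model derivatives are finite
  differences; there is no analytic-gradient path.
* Vendor image formats are out of scope; frames enter as arrays (TIFF or a
  documented npz container). No polarization model, no multi-axis
  goniometry, no intensity physics beyond Gaussian blobs, no integration or
  scaling.
* Nearest-integer index assignment given a known model is the only indexing
  plumbing provided; basis search and Bravais testing are prior art and out
  of scope.
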