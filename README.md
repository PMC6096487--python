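# edgeom

Diffraction-geometry modelling, refinement and diagnostics for
continuous-rotation **electron diffraction** (ED), with a matched X-ray (MX)
reference geometry.

## The problem

Protein nanocrystals can be measured by the rotation method in a transmission
electron microscope. At 200 keV the electron wavelength is λ ≈ 0.02508 Å —
roughly 40 times shorter than a typical 12 keV X-ray wavelength (1.0332 Å) —
so the Ewald sphere of radius 1/λ is nearly flat: even 1 Å reflections
scatter at only 2θ ≈ 1.44° (versus 62.2° for X-rays). That flatness has
consequences all through data processing:

* the detector must sit at a large *effective* distance D (set by the
  projector lenses, not mechanically measurable), and D becomes almost
  perfectly degenerate with a uniform scale of the unit cell — in the
  small-angle limit the relative cell error equals the relative
  distance-calibration error;
* inverting the assumed sense of rotation still produces a nearly regular
  reconstructed reciprocal lattice, so the handedness must be decided by
  comparing angular residuals, not by inspection;
* lens aberrations distort the recorded pattern (circles become ellipses) and
  the beam direction can drift during the scan.

`edgeom` implements the ED-specific machinery this requires: Timepix quad
frame preparation, distortion-map generation and application,
dispersion-threshold spot finding, Ewald-construction centroid prediction,
restraint-stabilized Levenberg–Marquardt geometry refinement (static and
scan-varying), and Jacobian-based conditioning diagnostics, together with a
simulator that generates matched ED/MX experiments with known ground truth.

## The model

An experiment is `beam + detector (multi-panel) + goniometer + scan +
crystal`. The crystal is an orientation `U` (proper rotation) plus the
reciprocal metrical matrix `g* = BᵀB` whose free elements (three for an
orthorhombic cell) parameterize the unit cell. Reflection `hkl` diffracts at
rotation angles φ solving

    |R(φ) U B hkl + s0| = 1/λ,          s0 = beam direction / λ,

which the package solves in closed form. Refinement minimizes weighted
residuals Δr = (X−X_o, Y−Y_o, φ−φ_o) over up to 13 parameters (6 detector,
1 beam angle, 3 orientation missets, 3 cell elements) by Levenberg–Marquardt
on the linearized subproblem `J Δp ≈ −Δr`; unit-cell restraints enter as
pseudo-observations `w(a − a_t)²`. Conditioning is quantified by per-block
corrgrams (pairwise correlations of Jacobian columns in the X, Y and φ
blocks) and the condition number κ(J) = σ_max/σ_min.

## Worked example

Simulate the standard ED experiment (lysozyme-like 32 × 68 × 105 Å cell,
λ = 0.02508 Å, D = 2000 mm, 40° wedge, 0.3 px / 0.02° centroid noise),
refine it with the stabilized protocol, and diagnose the conditioning:

```sh
$ edgeom --seed 1 simulate --preset ED --out-experiment exp.json --out-reflections refl.csv
simulated 981 reflections (seed 1)

$ edgeom --seed 1 refine exp.json refl.csv --fix dist,tau2,tau3 \
      --out-experiment refined.json --out-report report.json
refined: rmsd X=0.2955 px, Y=0.3095 px, phi=0.01912 deg (5 iterations, converged)

$ edgeom diagnose exp.json refl.csv --out-dir diag
condition number kappa(J) = 1.979e+05 (13 parameters)
```

The refined r.m.s.d.s land on the simulated noise floor (0.3 px, 0.02°),
confirming the model fits to the accuracy of the data. The condition number
of the full 13-parameter ED problem is ~2 × 10⁵; the same crystal and
reflection list refined in the X-ray geometry gives ~7 × 10², and fixing
{distance, τ₂, τ₃} cuts the ED value by roughly two orders of magnitude —
the quantitative statement of why ED geometry refinement needs stabilizing.

The same operations are available as a library:

```python
from edgeom import ed_preset, simulate_reflections, refine, RefinementProtocol

spec = ed_preset(seed=1)
experiment, observations = simulate_reflections(spec)
result = refine(experiment, observations,
                RefinementProtocol(fix=("dist", "tau2", "tau3")))
print(result.static_report.final_rmsd)   # (0.2955 px, 0.3095 px, 0.01912 deg)
```

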