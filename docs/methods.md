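# Methods

`capstress` models the mechanical effect of expanding cholesterol crystals on
the fibrous cap of an idealized atherosclerotic coronary cross-section, and
provides the µOCT image-analysis stage that supplies the crystal dimensions.
This note records the model, its assumptions, the numerical choices, and what
the synthetic data can and cannot establish.

## Geometry reconstruction

The cross-section is idealized as concentric circles: a circular lumen of
area `A_l = 5.77 mm²` (radius `r_l = √(A_l/π) = 1.3552 mm`), a fibrous cap of
thickness `t_c = 0.091 mm` (population range 25–370 µm), a necrotic core
shaped as an annular sector of arc `φ = 84.65°` and area `A_c = 2.22 mm²`
abluminal of the cap, and an outer arterial wall. All radii follow in closed
form:

- core inner radius `r_ci = r_l + t_c = 1.4462 mm`;
- core outer radius from inverting the sector area,
  `r_co = √(r_ci² + A_c·360/(φπ)) = 2.2576 mm`;
- vessel outer radius from the area-stenosis definition
  `s = 1 − A_l/(π r_v²)` with `s = 0.7053`, giving `r_v = 2.4965 mm`
  (reference EEM area 19.58 mm²).

The three printed *relative* metrics (relative core area 19.17%, relative
core thickness 49.41%, stenosis 70.53%) are mutually inconsistent with the
primary parameters under any single standard definition, so stenosis is
treated as the binding constraint (it pins the one free radius) and the
relative core metrics are reported as diagnostics
(`geometry_diagnostics`), not enforced. The wall (media + adventitia)
thickness is never printed; by default the plaque/artery interface sits at
the core outer radius, making the wall `r_v − r_co = 0.239 mm` — a realistic
coronary wall — and it can be overridden (`wall_thickness`).

Only annular-sector shapes are reconstructible from printed arc/area/thickness
numbers; the source diagram shows a smooth, lens-like core end that cannot be
quantified. This choice has a load-bearing consequence discussed under
*Known limitations*.

## Mesh

The half model (180°, symmetric loading) is meshed with a structured polar
grid of 8-node serendipity quadrilaterals: radial bands for the inner cap
(2 layers), a one-element-thick *crystal slot* ring at the abluminal cap face
(crystal thickness, 3 µm), the core band (8 layers) and the wall (6 layers),
with 72 angular columns — 17 × 72 = 1224 elements at default refinement,
matching the element count of the reference analysis. One angular column
boundary is aligned exactly with the core-arc edge, so the core sector is
angle-exact for any arc (region area errors ~1e-8). Midside nodes sit on the
circular arcs. The slot ring exists in every mesh (tagged plaque outside
crystal bands) so control and crystal runs share one discretization and PCS
differences are never meshing artifacts.

Crystals are bands of slot-ring elements, `⌈length/element width⌉` columns
long, centred at their angular station: cap center = 0°, shoulder = core-arc
end (42.325° off the symmetry axis), halfway = 21.16°. A centre crystal
straddles the symmetry line, so the half model carries half its length.

## Constitutive model

Artery and plaque are linearly elastic and transversely isotropic about the
radial axis (isotropy plane = circumferential/axial), with stiffness axes
following the polar frame around the lumen centre:

| tissue  | E_r (kPa) | E_θ = E_z (kPa) | ν_rθ | ν_θz | G_rθ (kPa) |
|---------|-----------|-----------------|------|------|------------|
| plaque  | 50        | 1000            | 0.01 | 0.27 | 500        |
| artery  | 10        | 100             | 0.01 | 0.27 | 50         |

The necrotic core is a soft incompressible isotropic solid (E = 1 kPa,
ν = 0.49); crystals are isotropic with E = 100 kPa, ν = 0.49. The unlisted
constants are fixed by transverse isotropy (`ν_rz = ν_rθ`, `G_rz = G_rθ`,
`G_θz = E_θ/2(1+ν_θz)`) and compliance symmetry (`ν_θr = ν_rθ·E_θ/E_r`,
e.g. 0.2 for plaque). The plane-strain 3×3 stiffness is obtained by building
the full 6×6 compliance, verifying positive definiteness, inverting, and
taking the in-plane block (ε_z = 0); the σ_zz row is kept for recovery.

## Loading and boundary conditions

A static pressure of 110 mmHg (14.6 kPa, as printed) acts on the lumen
surface as work-equivalent nodal forces on the quadratic edges of the
undeformed configuration (linear kinematics throughout; the geometric and
material nonlinearity of the source's Mooney–Rivlin re-analysis is out of
scope). Crystal growth by `d` µm in the thickness (radial) direction is a
stress-free eigenstrain `ε*_rr = d/thickness` in the crystal band — the
thermal-expansion analogy. A free crystal would expand by exactly `d`; an
embedded one loads its surroundings through its own stiffness, and the
eigenstrain force is exactly proportional to `d`, so expansions compose
under superposition (the device the source uses to emulate multiple
crystals). When several crystals load simultaneously each receives the same
default expansion (2 µm, the printed comparison value).

Symmetry-line nodes move only radially (u_y = 0 on both cut edges). That
constraint set leaves rigid translation *along* the symmetry axis in the
null space — a u_y = 0 field — so one u_x pin is added at the outer-boundary
symmetry node. For the symmetric loads of this model its reaction is at
round-off level (asserted in the equilibrium tests); the solution is
unaffected. The constrained system is symmetric positive definite and solved
by sparse LU with fixed COLAMD ordering: runs are deterministic, and the
relative residual is checked against 1e-10.

## Stress recovery and PCS

Stresses are evaluated in the polar frame at the 3×3 Gauss points
(σ = D(ε − ε*) inside crystals), extrapolated to nodes by the standard
biquadratic scheme, and averaged **within regions only**: cap/core and
cap/crystal interface nodes keep one value per material side, so interfacial
peaks are not smeared. σ_zz comes from the plane-strain condensation row.

Peak circumferential stress (PCS) — the rupture-risk surrogate — is the
maximum σ_θθ over cap recovery points: plaque-region nodes radially between
the lumen surface and the core interface, angularly within the half core arc
plus one element margin. Interface nodes are included (their cap-side
value); points interior to crystal elements are not.

Validation: Q8 patch test to 1e-9; pressurized isotropic annulus against the
Lamé closed form (0.4% at default refinement, monotone under refinement);
pressurized *polar-orthotropic* annulus against an independent 1D two-point
boundary-value solve of the axisymmetric equilibrium ODE (≤1%); equilibrium
of reactions against applied loads to 1e-8 in every scenario.

## Scenarios and sweeps

The roster runs eight cases in fixed order: control, three single-crystal
placements, three two-crystal combinations, and all three stations loaded.
Sweeps: expansion 0–400 µm in 21 steps at the shoulder (least-squares slope
in kPa/µm, with a flag reporting whether the PCS arg-max stayed at one
point — superposition makes PCS affine in `d` only on such stretches);
pressure 70–200 mmHg at the printed endpoint conversions (9.3 and 26.6 kPa)
with interiors at the same conversion; crystal-stiffness factors
{0.5, 1, 2, 5, 11} (−50% to +1000% of 100 kPa) across all scenarios.

## µOCT morphometry and the synthetic B-scan generator

Calibration follows the imaging geometry: 0.872 mm over 512 A-lines
(1.703 µm/px lateral), 1.4 mm height with a default of 1024 axial pixels
(1.367 µm/px optical; the axial pixel count is not printed and is
configurable), refractive index 1.33, resolution 1.3 µm axial × 2.5 µm
transverse (FWHM). Axial distances are optical paths: physical thickness =
optical separation / n. Lateral pixels are treated as physical (the lateral
pitch does not involve n).

The detector automates the source's manual per-crystal workflow so the stage
is testable: per column inside a (optionally manual) ROI, the two dominant
axial peaks of the PSF-scale-smoothed image are traced; a column is valid if
both peaks clear an adaptive floor (median + 3·MAD of the ROI, k
configurable) *and* half the robust ridge level (median column-maximum among
candidate ridge columns) — the half-maximum rule places crystal ends at
their true position under symmetric beam blur. Columns whose surfaces merge
below the axial resolution show a single peak and are excluded rather than
given zero thickness. Length = (last − first + 1 valid columns) × lateral
pitch; thickness = mean peak separation × axial pitch / n; cohorts are
summarized by mean and sample (n−1) SD.

The generator renders crystals as two bright ridges separated by the optical
thickness (dimensions quantized to whole pixels; the emitted ground truth
reports the quantized values), convolves with the Gaussian PSF, and applies
fully developed multiplicative speckle — unit-mean exponential gain blended
by a contrast parameter (default 0.5) — plus additive background. The source
specifies no noise model; contrast is the single realism knob and is
validated only through recovery tolerances: noiseless round trips are exact
to pixel quantization, and at default contrast the median error over 100
crystals is ≤1 axial px (thickness) and ≤2 lateral px (length). What these
tests show is internal consistency of renderer + detector at the instrument
scales; they cannot certify performance on real tissue, which adds
attenuation, refraction, confocal gating and oblique crystals that the
generator deliberately omits. Cohort draws use the printed statistics
(length 269.1 ± 80.16 µm, thickness 3.0 ± 0.33 µm). The morphology sampler
draws cap thickness uniformly over the printed 25–370 µm range, jitters the
other parameters ±10% about their printed means, and resamples
geometrically infeasible draws.

## Known limitations and observed behaviour

- **The shoulder corner is a weak singularity.** The annular-sector core
  meets the cap in a re-entrant bimaterial corner; the control PCS there
  grows with refinement (373 → 445 → 502 kPa at refinements 1–3). Absolute
  PCS values are therefore tied to the 1224-element discretization that the
  element-count target pins; the reference analysis, whose corner geometry
  and meshing are not printed (its diagram suggests a rounded core end),
  reports 275.6 kPa. Comparisons *between* scenarios on the shared mesh are
  meaningful; absolute kPa values carry this reconstruction uncertainty.
- **Small expansions barely load the cap.** A 2 µm expansion of a 3 µm
  crystal (ε* ≈ 0.67) displaces mostly into the 1 kPa core and perturbs PCS
  by only ~−2% (slightly *unloading* the pressurized shoulder peak); the
  distributed-crystal cases land below the control, reproducing the
  "distributed crystals counteract blood pressure" effect. The source's
  figure values for 2 µm (+78.85% at the shoulder) are two orders of
  magnitude larger than its own expansion-sweep slope (0.442 kPa/µm →
  +0.9 kPa at 2 µm) allows; the two printed results cannot both describe
  the same functional. This package reproduces each under its stated setup
  and reports what the mechanics gives: at expansions of ~100–500 µm — the
  regime the source's own slope implies for its figure values — PCS
  collocates with the crystal and the shoulder > halfway > center ordering
  emerges, exactly as the figures describe.
- **The expansion sweep is piecewise affine.** The PCS arg-max switches from
  the shoulder corner to the crystal band end near d ≈ 50 µm; the affinity
  and pressure-invariance properties hold exactly on stretches where the
  arg-max is constant, and the sweep reports that flag.
- Crystal orientation is tangential only; contact, fracture, residual
  stress, 3D and fluid–structure effects are out of scope.

## Problem sizes

Default runs use the 1224-element mesh (~7700 unknowns, direct solve in
tens of milliseconds); the full acceptance recomputation (8 scenarios, a
21-point expansion sweep, and a 36-run stiffness sensitivity) completes in
well under a minute on one CPU. Image tests use 256 × 512 scenes; the
recovery study uses 100 crystals.
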