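# Methods

`valvetrack` tracks the aortic valve between its two extreme imaged
states — mid-systole (open) and mid-diastole (closed) — by combining a
hyperelastic membrane closure simulation with multi-resolution
diffeomorphic image registration, and then quantifies leaflet strain
from the tracked geometry. This note records the models, the numerical
choices, and the limits of what the synthetic validation can show.

## Why a biomechanical prior

Direct deformable registration between the open and closed frames must
bridge a large, rapid shape change of a structure about one voxel
thick, in images with limited contrast. The framework therefore first
*simulates* valve closure from the open geometry, producing
intermediate configurations that are easy to register stepwise
(open → middle → synthetic closed, both binary), and only asks the
image data for a final, small correction (synthetic closed → imaged
closed). Segmentation propagation uses the composed map
`phi3 ∘ phi2 ∘ phi1`.

## Constitutive model

Leaflet tissue is modeled as an isotropic Lee–Sacks solid, a
neo-Hookean matrix plus a Fung-type exponential term:

    Psi = c0/2 (I1b − 3) + c1/2 (exp(c2 (I1b − 3)^2) − 1) + k/2 (J − 1)^2

with defaults `c0 = 67 kPa`, `c1 = 13 kPa`, `c2 = 35`, `k = 5000 kPa`
(literature values for valve tissue fitted to equibiaxial data). `I1b`
is the **isochoric** first invariant `J^(−2/3) tr(C)`. An
interpretation with the full invariant `tr(C)` exists in parts of the
literature, but only the isochoric form leaves the reference state
stress-free — a requirement here, because the open configuration is by
assumption the strain-free reference. The full-invariant variant is
available via `MaterialParams(isochoric=False)`.

Stress `S = 2 ∂Psi/∂C` and the tangent `∂S/∂C` are analytic and
verified against finite differences of the energy (relative 1e-6 /
1e-5). The tangent scale factor `TF` multiplies only the
exponential-term block of the tangent (a stabilization device; the
residual is never scaled), so `TF = 1` is exact Newton. The exponent
of the exponential term is capped at 50 in the vectorized FE kernels so
that line-search trial states stay finite; the cap binds only far
outside the physiological strain range.

Shell elements use a plane-stress membrane reduction: the thickness
stretch follows local incompressibility, `lambda3 = 1/det(F2d)`, which
condenses the out-of-plane stress into a closed-form effective in-plane
stress. The bulk modulus therefore only enters fully 3D evaluation
paths.

## Closure simulation

* Constant-strain triangles, uniform thickness (1.2 mm adult / 1.0 mm
  pediatric presets), total Lagrangian membrane kinematics.
* Follower pressure on the deformed surface (75 mmHg adult / 45 mmHg
  pediatric, converted at 0.133322 kPa/mmHg), oriented from the aortic
  toward the ventricular side; orientation fixed by winding
  propagation from a seed element and a radial/annulus-plane check.
* The annulus is displacement-driven; values are sampled from the
  direct open→closed registration at the annulus nodes and smoothed
  along the annulus polyline (the root is a stiff fibrous ring; raw
  dense-field samples carry voxel-scale jitter that a prescribed
  boundary condition would imprint on the leaflets). Free edges are
  unconstrained.
* Implicit Newmark stepping with numerical damping (`gamma = 0.9`,
  `beta = 0.49`), mass-proportional damping, lumped mass
  (density 1.1e-3 g/mm^3). At these masses the inertial terms are
  negligible by the final frame (checked: < 1% of the pressure force),
  so the scheme behaves as a heavily damped quasi-static continuation.
* Newton with batched element-level finite-difference tangents for
  the membrane, an analytic dihedral-angle gradient for the bending
  forces, and a Gauss-Newton (positive-semidefinite) hinge stiffness;
  Levenberg-style diagonal regularization on indefinite tangents;
  adaptive step halving; relative residual tolerance 1e-4 against the
  external-force norm.
* A hinge bending penalty (default 5 kPa·mm^3 in the pipeline, about
  13% of the physical plate stiffness E t^3/12 at t = 1.2 mm)
  regularizes membrane wrinkling. A pure membrane (`bending_stiffness
  = 0`, the `build_shell_model` default) reproduces the patch test and
  the clamped-membrane benchmark but does not converge through the
  wrinkling regimes of full valve closure.
* Convergence in maximum displacement under refinement is part of the
  test suite (0.8/0.6/0.4 mm targets, < 2% change between the two
  finest levels).

### Load schedule and horizon

The pipeline completes the annulus-displacement ramp early (by
pseudo-time 0.3) while the pressure ramps linearly to full, so the
membrane stays taut while the root moves and every frame past 0.3
carries the whole estimated root motion. The exported "synthetic
closed" frame is not always the final frame: because the effective
transvalvular load is patient-specific, the accepted step whose mean
free-edge travel best matches the image-estimated motion (from the
direct registration) is chosen as the closure horizon, with the frame
set {initial, midpoint, horizon}. Degenerate regimes follow
naturally: if the two frames show no motion at all (identical
acquisitions), the biomechanical prior is skipped entirely
(`phi1 = phi2 = identity`, `phi3 =` the direct map); if the estimated
motion is explained by the root motion alone, the closure is re-run at
5% pressure so the synthetic closed state tracks the boundary-driven
deformation. Standalone `simulate_closure` keeps the plain linear
ramps and the {0, 0.5, 1} export of its contract.

## Registration

Pull-back convention: a transform maps fixed-space world points to
moving-space points, which is what resampling a moving image onto the
fixed grid requires. Meshes are pushed forward through inverses (exact
for affines; `exp(−v)` for stationary velocity fields).

* **Affine**: three-level Gaussian pyramid (100×50×10 iterations),
  intensity-center initialization, backtracking gradient descent with
  a translation-only capture phase, a full-affine phase, and a
  translation polish. Metrics: SSD (binary) or local NCC (grayscale,
  box kernel radius 2 voxels).
* **Deformable**: greedy stationary-velocity-field optimization.
  Per-iteration metric forces are smoothed (`gradient_sigma = 1.7`
  voxels), folded into the velocity with a first-order Lie-bracket
  (BCH) correction, re-smoothed (`field_sigma = 0.7` voxels), and
  exponentiated by scaling-and-squaring (6 doublings). Every update
  must improve the metric (else the step scale halves) and must keep
  the Jacobian determinant positive — unguarded greedy accumulation
  was observed to diverge on noisy thin-shell images.
* The local-NCC force floors each local variance at (0.3 × global
  standard deviation)^2: patches without structure (background, pure
  noise) otherwise dominate the normalized force field.
* Label resampling: per-label Gaussian pre-smoothing at 0.2 voxel and
  argmax voting, so propagated label sets are subsets of the input.

## Strain

With the open configuration as the strain-free reference:

* Step 1 (FE): per-element `E = 1/2(F^T F − I)` from the simulated
  deformation gradients at the synthetic-closed frame, and areal
  strain `(Ad − Ar)/Ar`.
* Step 2 (registration correction): in-plane Green–Lagrange strain
  computed directly from nodal coordinates of the synthetic-closed
  mesh and its `phi3`-corrected image. The correction displacement is
  first smoothed over the mesh graph: a registration field on a
  blurred thin shell carries no reliable deformation content below the
  image blur scale, and raw voxel-level jitter otherwise dominates the
  differentiated strain.
* Totals: `E_total = E_FE + E_2D(3D)` with both addends expressed in
  the per-element frame of the synthetic-closed configuration (tensor
  sums are frame-dependent; the correction lives in the deformed
  frame; a `reference_local` policy is provided). Total areal strain
  is the additive `eA1 + eA2`; for large compressive two-step
  deformations the additive total can fall below −1, which is an
  artifact of additivity — the exact multiplicative composition is
  exposed as a diagnostic.
* Scalars: effective strain `eeff = |E'|_F` (Frobenius norm of the
  deviator — without the sqrt(2/3) von-Mises prefactor, which matches
  the magnitude range of reported valve strains; a switch would be a
  one-line change) and magnitude `eGL = |E|_F`, so `eeff <= eGL`
  always. Per-leaflet summaries are area-weighted.

## Synthetic phantom

No clinical data ship with the package; every study runs on a seeded
parametric phantom:

* Trileaflet / bicuspid (optionally fused, single label) / unicuspid
  medial surfaces: leaflets as parabolic-sag patches between a
  crown-shaped attachment ring (annulus, radius 12 mm, commissure
  height 9 mm) and scalloped free edges, welded at commissures, plus a
  smooth seeded irregularity so every phantom is unique.
* Ground-truth closure is an explicit differentiable point map
  ("closure billow": radial/axial contraction scaled by height and a
  radial falloff), so strain and correspondence are known in closed
  form. The default amplitude (7 mm) is the largest the smooth map
  family supports before element inversion and produces free-edge
  travel of several millimetres, at the cost of compressive strain
  magnitudes beyond the clinically reported ranges; a strain-realistic
  variant (amplitude 3 mm, mean effective strain ~15%, extrema within
  reported ranges) is used wherever strain values themselves are under
  test. Full Y-shaped coaptation cannot be represented by any smooth
  map of this family.
* Images: thickened-surface rasterization (foreground iff the voxel
  center is within thickness/2 of the surface), Gaussian blur, seeded
  additive Gaussian noise. The TEE preset (blur 1.2 mm, noise SD 12,
  0.6 mm voxels) is calibrated so that *direct* registration degrades
  the way the clinical baseline does; the CT preset is sharper and
  cleaner. No speckle or modality physics is simulated — passing tests
  show robustness to blur/noise/large motion, not to dropout, shadowing
  or anisotropic point-spread functions.

## Known limitations

* The phantom cannot reach leaflet coaptation, so contact-dominated
  closure mechanics (and the multi-millimetre direct-registration
  failures they cause clinically) are only approximated; improvement
  percentages on the phantom suite are accordingly smaller and noisier
  than clinically reported figures.
* Step-2 strain rests on the assumption that the registration
  correction is small and smooth; tangential motion at a thin shell is
  fundamentally unidentifiable from images (aperture problem), and the
  graph smoothing of the correction is the package's explicit choice
  of regularization.
* In-plane strain that is neither an equilibrium response to the
  boundary conditions and pressure nor visible in the images cannot be
  recovered by *any* stage. A uniform affine stretch of the valve is
  the clean counterexample: the curved leaflet absorbs a ring
  expansion largely by flattening (geometric slack) rather than
  stretching, the registration sees only the surface geometry, and the
  recovered median areal strain misses the analytic value by ~8-11
  percentage points (measured on the affine-closure phantom;
  compressive affine maps are worse still, since a membrane buckles
  instead of carrying in-plane compression). The corresponding
  acceptance test is expected to fail and documents this limit.
* Secant per-triangle strain carries an O(edge × curvature) error
  (~1-3% relative at 0.5 mm edges on this geometry); affine
  deformations are exact to machine precision.
* No fluid–structure interaction, no leaflet contact by default, no
  fiber anisotropy, no residual strain in the open state.
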