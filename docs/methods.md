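# Methods

femvox turns a quantitative CT (QCT) scan of a proximal femur into a
homogenized voxel finite element (hvFE) model and simulates a
displacement-controlled one-legged-stance compression to failure. This note
documents the model, its assumptions, the numerical choices, what the
synthetic femur generator does and does not emulate, and the known
limitations.

## Pipeline

1. **Calibration.** The CT grayscale (Hounsfield units, HU) is mapped to
   equivalent bone mineral density (BMD, mg HA/cm³) by a linear law fitted by
   ordinary least squares of the known insert densities on the *mean* HU of
   each calibration-phantom insert ROI. ROI means rather than voxelwise
   regression suppress image noise; with five inserts the fit has five
   points. A non-positive slope is rejected as an implausible calibration.
   Calibrated values are clamped to [−100, 1400] mg HA/cm³ to restrict
   residual air and bright artefacts (both bounds are configurable).
2. **Stance alignment.** A rigid rotation in the plane spanned by the shaft
   and neck axes brings the shaft axis to 20° from the vertical loading axis;
   the sense is chosen so the femoral head moves toward the vertical through
   the distal shaft. The image is resampled trilinearly; landmarks are
   transformed consistently.
3. **Segmentation.** Binarization at a user-chosen threshold (the one manual
   input of the chain; 100 mg HA/cm³ in the pipeline default), followed by a
   3-D 6-connectivity flood fill of the background from the image border.
   Everything not reachable is bone, so enclosed marrow cavities are kept;
   the largest connected component is retained.
4. **Coarsening.** The masked image is averaged onto a 3 × 3 × 3 mm grid
   (each coarse voxel takes the mean of its masked fine voxels); a coarse
   voxel is kept when its masked-volume fraction is ≥ 0.5. The coarse voxel
   size simulates clinically realistic QCT resolution and fixes the element
   size of the model.
5. **BV/TV mapping.** BMD converts to bone volume fraction by the linear
   relation BV/TV[%] = 0.093·BMD + 1.077, read on a percent scale (it gives
   ≈ 19.7 at a typical trabecular BMD of 200 mg HA/cm³) and clamped to
   [ρ_min, 1] with ρ_min = 0.01. Elements that fall below ρ_min are removed
   as voids — zero-stiffness elements would make the system singular.
6. **Meshing.** Every kept coarse voxel becomes one 8-node hexahedral
   element. A polyurethane layer (E = 1.36 GPa, ν = 0.3) fills the gap
   between the cranial head surface and a flat steel plate (E = 210 GPa,
   ν = 0.3), replicating the experimental embedding; the plate is one voxel
   layer thick by default.
7. **Boundary conditions.** The cranial-most plate node layer is rigidly
   coupled to a reference point at its mean position. The reference point's
   vertical translation is prescribed (−5 mm compression in 50 increments by
   default); its horizontal translations and all rotations are free,
   mimicking the axle bearing of the physical setup. All translations of the
   bottom (distal) node layer are fixed.
8. **Outcome extraction.** Stiffness is the least-squares slope of |F| vs
   |u| over the 0–1 mm window (the elastic-test protocol, so simulation and
   experiment are commensurable); failure load is the curve maximum (ties →
   earlier displacement); the fracture region is the damage-weighted
   (D·volume) arg-max over the subcapital / neck / intertrochanteric atlas
   at the peak-load increment, with ties broken to the proximal-most region.

## Constitutive model

Bone is isotropic and elastic-damage. The references describing the original
law give its constraints but not a reprintable closed form, so femvox fixes
a concrete law honouring every constraint; all constants are package
defaults, overridable through `MaterialParams`.

- Elasticity: E(ρ) = E₀·ρ^p with E₀ = 12 GPa, p = 2, ν = 0.3. E₀ and the
  strengths are the poreless-bone (ρ = 1) cortical-corrected values.
- Yield/ultimate: a piecewise quadratic (von-Mises-radius) criterion with
  distinct branches selected by the sign of tr σ: radius σc₀·ρ^q in
  compression (σc₀ = 180 MPa), σt₀·ρ^q in tension (σt₀ = 110 MPa), q = 1.8.
  In uniaxial stress it reduces to |σ| = σ₀·ρ^q. With equal radii it
  degenerates to a von Mises criterion.
- Damage: a scalar D ∈ [0, 1) multiplies (1 − D) onto the stiffness. Past
  the criterion the compressive response plateaus exactly at the ultimate
  (no softening in compression) while the tensile response softens
  exponentially, σ = σ_u·exp(−(s̃/σ_u − 1)/h) with softening rate h = 0.5
  chosen for brittle tensile bone failure. D is the history maximum of
  1 − target/effective-stress, hence non-decreasing and path-independent
  under monotone loading; the inelastic measure κ ≡ −ln(1 − D)/κ_c
  (κ_c = 200) satisfies D = 1 − exp(−κ_c·κ) identically. Unloading follows
  the secant (1 − D)·E(ρ).

One parameter set covers trabecular and cortical bone; density alone
differentiates them.

## Solver

Small-strain FE with 2×2×2 Gauss hexahedra on the regular voxel grid. All
elements share one geometry, so each element stiffness is a weighted sum of
eight precomputed per-Gauss-point unit matrices with weights E·(1 − D);
assembly is vectorized. The rigid coupling is a sparse transformation onto
six master degrees of freedom (three translations, three small rotations).

Each displacement increment iterates the damage fixed point with the secant
stiffness. Three numerical safeguards matter:

- **Linear solves.** One sparse LU per refactorization, reused as a CG
  preconditioner across iterations and increments while it converges
  quickly; refactorized when the damaged system drifts.
- **Damage rate cap.** Damage growth is limited to ΔD ≤ 0.2 per increment
  and integration point — a viscous-delay-style regularization. Without it
  the displacement-controlled iteration can jump catastrophically over the
  quasi-static post-peak branch at localization (tensile softening makes the
  local problem snap back at 3 mm element size). With 50 increments the cap
  only engages during localization and bounds the per-increment load drop.
- **Monotone iterates.** Within an increment the damage iterate is ratcheted
  (max with the previous iterate, bounded by the cap), which turns an
  otherwise flip-flopping iteration at the cap boundary into a monotone
  bounded — hence convergent — sequence.

Convergence requires both a small damage change (‖ΔD‖∞ < 1e−7) and a small
equilibrium residual (‖r‖ ≤ 1e−6 × the running force scale). Non-converged
increments are halved up to four levels; exhaustion returns a truncated,
flagged result. The two distal-most element layers are kept linear-elastic:
they sit inside the experimental embedding, and letting the fully fixed
boundary damage produces a spurious failure mode at the clamp. Softening
makes the post-peak branch mesh-size-sensitive; the fixed 3 mm element acts
as the regularization length. The solver has no random component; repeated
runs are bit-identical.

## Synthetic femur and phantom generator

The generator emulates the scan a cadaveric specimen would produce: a
constructive-solid femur — head sphere, neck cylinder at the CCD angle
(default 125°), vertical shaft cylinder — immersed in saline above five
calibration insert cylinders of known BMD (0/100/200/400/800 mg HA/cm³; the
insert hardware dimensions do not scale with the bone). The neck cortex is
angularly graded from 3.5 mm inferomedially to 1.0 mm superolaterally,
reproducing the load-adapted asymmetry that makes inferomedial lesions
mechanically worse. Materials carry uniform BMD (trabecular 200, cortical
1100 mg HA/cm³); HU = 1.2·BMD − 5 plus Gaussian noise (σ = 10 HU); partial
volume at boundaries is approximated by 2×2×2 sub-voxel averaging. Native
voxel size is 0.33 × 0.33 × 1 mm. Ground truth (landmarks, bone mask,
region atlas, true calibration, eroded pure-insert ROIs) replaces the manual
operator inputs of a real study.

The default geometry (head radius 26 mm, neck radius 17 mm × 55 mm, shaft
radius 16 mm × 80 mm) yields ≈ 6,700 elements / 8,500 nodes at 3 mm — the
scale of a clinical proximal-femur model. Virtual osteolytic lesions remove
a 120° wedge (one third of the circumference) of the neck, centered on the
superolateral or inferomedial direction, over the whole neck length and down
to the neck axis, by setting the wedge to saline density on the fine image
before alignment — total bone removal, the osteolytic worst case.

What the generator does **not** emulate: trochanters and anatomical shaft
flare, curved neck–shaft blending, marrow heterogeneity, beam hardening,
scatter, or a scanner PSF. Consequences: the intact synthetic femur
concentrates bending failure at the neck base (the sharp neck–shaft
junction) rather than subcapitally as most intact cadaver femora do, and
absolute stiffness/failure values sit at the low end of the reported
cadaveric ranges. Passing tests therefore demonstrate the correctness and
the qualitative biomechanics of the chain (lesion-site ordering, neck-level
failure of lesioned femora, stiffness–strength correlation), not
quantitative agreement with any individual cadaver.

### Region atlas

Bone is partitioned by the signed distance of each voxel's projection onto
the neck axis from the head–neck junction (positive toward the shaft):
subcapital below 0.35 of the junction→neck-base distance (the head itself is
negative, hence subcapital), neck up to the neck base, intertrochanteric
beyond (trochanter level and shaft). The cuts are configurable.

### Problem sizes used in tests and the acceptance script

The full-size default femur is meshed (element/node counts) and, in the
acceptance script, not re-solved; the solved studies use geometrically
scaled femora generated at 1 mm spacing — scale 0.55 for the matched lesion
triplet (≈ 1,400 elements), scale 0.45 for the 20-femur correlation batch
and determinism checks (≈ 500–1,100 elements). These sizes are the package's
choice of test conditions: they preserve roughly 6 voxels across the neck at
the 3 mm model resolution, which is the minimum at which the cortical
asymmetry and lesion wedges remain resolved, while keeping a full study
re-runnable on a laptop. The randomized batch varies overall scale (±15%),
CCD angle (120–135°), cortical thicknesses (±30%) and densities (trabecular
140–260, cortical 950–1250 mg HA/cm³).

## Degenerate inputs and tie-breaks

- Curves shorter than the 1 mm stiffness window use the available range and
  warn; all-zero curves return 0 stiffness with a degenerate warning.
- A monotonically rising curve (no interior maximum) reports the endpoint
  with a no-peak warning.
- Zero damage at peak load yields fracture region "other".
- Equal failure-load maxima report the earlier displacement; equal region
  damage scores report the proximal-most region.
- A lesion wedge that removes no voxels warns rather than fails; voxels
  exactly on the neck axis count toward the wedge only when it is at least a
  half-space.
- Calibration with identical ROI means, overlapping ROIs, or a non-positive
  slope fails loudly, as does double calibration.

## Known limitations

- Isotropic bone with one damage law for cortical and trabecular bone; no
  fabric, no viscoelasticity, no strain-rate effects.
- Small strains, no contact, no geometric nonlinearity; the bearing is
  idealized by the rigid coupling.
- The constitutive constants are package defaults, not fitted to specimens;
  absolute failure loads are expected to be biased low, consistent with the
  factor-two underestimation typical of coarse-voxel hvFE models.
- The post-peak branch depends on the damage rate cap and element size;
  failure load and stiffness (pre-peak quantities) are insensitive to both.
- The wedge lesion is a geometric idealization of a milled defect; real
  osteolytic lesions are irregular and may be mixed rather than purely
  lytic.
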