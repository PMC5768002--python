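# Methods

This note documents the models, parameters, and design choices behind
`arcdmd`: what is simulated, what is deliberately simplified, and what the
passing tests do and do not demonstrate about clinical data.

## 1. Synthetic phantoms

Each case is a voxelized thorax on a regular mm grid (axes x: left–right,
y: posterior–anterior, z: inferior–superior; world origin at the grid
centre; binary masks by voxel-centre inclusion, no partial volume):

* **Body**: ellipsoid, relative electron density 1.0 (water).
* **Lungs**: two ellipsoids derived from the body semi-axes
  (0.40 a, 0.70 b, 0.80 c at ±0.47 a), density 0.26 — a typical average
  CT-derived lung density.
* **Tumor (ITV)**: density 1.0, one of four analytic shapes — sphere,
  axis-aligned ellipsoid, bilobed (two overlapping spheres along z; the
  only concave shape), or capped cylinder (capsule along z).  Shape
  parameters are solved exactly from a requested volume (volume scales as
  the cube of the linear scale).
* **PTV**: Euclidean 5 mm isotropic expansion of the ITV (distance
  transform with anisotropic spacing honoured), clipped to the body.

Two presets: the default 2 mm / 128³ grid (256 mm cube) and a coarse
3 mm / 64³ grid (192 mm cube) with the thorax scaled to (90, 70, 86) mm
semi-axes so that the largest cohort target still fits inside a lung.  All
cohort-level results in the tests and the acceptance script use the coarse
preset — the method's behaviour is governed by shape and penumbra, not by
grid resolution, and the coarse grid keeps a two-arm ten-case study in the
low minutes on one CPU.

The **cohort sampler** emulates the target mix of an early-stage NSCLC
SBRT series: ITV volumes log-uniform on [0.56, 69.39] cc (log-uniform
because the clinical distribution is strongly right-skewed — median well
below mean), at least one bilobed target per block of five cases, random
laterality, tumor placement by rejection sampling with a conservative
bounding-box-in-ellipsoid criterion, and fractionation drawn as
3×18 / 5×11 / 8×7.5 Gy with probabilities 0.35 / 0.40 / 0.25.  The
generator does **not** model respiratory motion (the ITV is taken as
given), lobar anatomy, chest wall, mediastinal organs, or CT texture.

## 2. Beam geometry and apertures

Coplanar isocentric delivery: the gantry rotates about z through the
isocenter (the aperture-fitting target's centroid), source at
SAD = 1000 mm, couch and collimator fixed at 0°.  An arc is a uniform set
of control points over a 340° span; the unused 20° sector faces the
contralateral lung.  Default control-point spacing is 2°; cohort runs use
10° (the dose difference between 10° and finer spacing is below 1 % of the
maximum, see the convergence test).

**BEV projection** is computed exactly: a BEV pixel (isocenter plane,
pitch ≤ 1 mm) is open iff the ray from the source through the pixel centre
intersects at least one target voxel — equivalently, the pixel centre lies
inside the point-source projected footprint of some voxel.  This is
evaluated with an Amanatides–Woo DDA traversal, so there is no sampling
step or tolerance.

**MLC fitting**: 60 leaf pairs of 5 mm projected width, leaf travel along
the in-plane BEV axis, stacked along z.  The band grid places one leaf
band centred on the beam axis.  Per band, the leaf edges are the min/max
open-pixel extent (pixel outer edges) ± the aperture margin (default 0 mm);
bands without open pixels are closed.  No deliverability constraints
(leaf speed, interdigitation, tongue-and-groove) are modelled.

## 3. Dose engine

A declared, simplified model — *not* a convolution/superposition
algorithm.  Per voxel v and control point:

    dose(v) = T(v) · f(r(v)) · exp(−μ_eff · d_eff(v)) · (SAD / dist(v))²

* **T** — aperture transmission at v's BEV position, after a 2-D Gaussian
  blur of the binary aperture (the penumbra), sampled bilinearly.  The
  transmission image grid is anchored to absolute coordinates and
  zero-padded, which makes dose exactly monotone under aperture
  enlargement.
* **f(r) = max(0, 1 − k·r)** — conical FFF-like radial profile,
  k = 0.0015 /mm at the isocenter plane, f(0) = 1.
* **d_eff** — radiological path length from the body surface to v: the
  exact line integral of relative electron density along the source ray
  (Siddon-style per-voxel chord × density via the same DDA traversal;
  exact for piecewise-constant voxel densities, no step-size parameter).
* **μ_eff = 0.0046 /mm** — effective 6 MV linear attenuation in
  water-equivalent depth.
* Inverse square from the point source; control points are summed with
  equal weight (constant dose rate).  No build-up region, no scatter
  kernels, no electron transport, absolute output (MU) is out of scope —
  doses are meaningful only after normalization to a prescription.

**Penumbra width.** `penumbra_sigma_mm = 6.5` is the effective *in-lung*
penumbra for 6 MV: lateral electron transport in ≈ 0.26-density lung
broadens the 20–80 % falloff to roughly 10 mm, several times the in-water
collimator-only value (σ ≈ 3 mm).  This single parameter is what gives a
conformal arc its clinical failure modes — after 95 % coverage
normalization the prescription isodose bulges into normal tissue in the
rotation plane while the cranio-caudal target tips stay cold.  With a
water-like σ the engine produces unrealistically conformal arc plans and
there is nothing for margin deformation to correct.

The engine caches the aperture-independent factors (d_eff, inverse square,
off-axis, BEV coordinates) per control point, so the deformation loop's
re-planning costs only a blur and a bilinear lookup per control point.

## 4. Planning and normalization

A conventional DCA plan fits one aperture per control point to the PTV
silhouette (0 mm margin).  After dose computation the prescription isodose
is normalized to cover 95 % of the target: dose is linear in the plan
scale, so the smallest sufficient scale is Rx / D95, where D95 is the
k-th smallest in-target voxel dose with k = ⌊0.05 N⌋ + 1.  The covered
fraction then lands in [0.95, 0.95 + 1/N] for distinct voxel doses (one
float-ulp guard keeps the covering voxel at ≥ Rx).  Normalization is
idempotent and refuses targets with > 5 % zero-dose voxels.  The reported
"prescription isodose level" is Rx as a fraction of the scaled maximum
dose; on the synthetic cohort it falls around 70–85 %, the usual SBRT
prescription window.

DVH statistics are computed on the sorted in-mask voxel doses (linear
interpolation between order statistics); the binned cumulative curve
(width max(0.1 Gy, Dmax/2000)) is only for export.

## 5. The deformation loop

The clinical procedure this automates is manual slice-by-slice contour
editing; the central re-interpretation of this package is replacing it
with a reproducible morphological update.  Per iteration, with hot/cold
regions always classified against the **original** PTV at the full
prescription:

1. grow = dilate(cold, step) ∩ dilate(target, step) — expansion only
   within one step of the current surface, adjacent to cold;
2. shrink = dilate(hot, step) ∩ {target surface band of depth step} — a
   distant hot island can never punch a hole through the interior;
3. target ← close((target ∪ grow) \ shrink, smooth_radius), kept ⊇ ITV
   (default) and ⊆ body.

All morphology uses Euclidean distance transforms, so anisotropic voxels
are handled correctly and the update is local by construction (the
symmetric difference stays within step + smooth_radius of the previous
surface).  Defaults: step = 1 voxel, smoothing radius 2 mm, at most 10
iterations, stop when hot and cold volumes fall below 0.2 cc.  Note that
with 95 % normalization about 5 % of the PTV is below Rx *by definition*,
so for targets above ~4 cc the cold volume cannot reach the tolerance and
the loop runs to the iteration cap; this is intentional — the returned
plan is the iteration whose CI is closest to 1 (ties → fewer iterations),
mirroring a planner who keeps the best attempt.  Failures inside the loop
(collapsed target, unattainable coverage) return the best previous
iteration with a warning rather than raising.

Because every iteration is renormalized to 95 % coverage of the original
PTV, coverage is invariant across the loop; deformation trades only
conformity, never coverage.

## 6. Metrics and statistics

All isodose volumes are voxel-centre counts with a ≥ threshold, restricted
to the body so dose in surrounding air never inflates an index; the
declared accuracy limit is one voxel layer (no sub-voxel surfaces).  D2cm
uses a Euclidean distance transform from the PTV with anisotropic spacing.
Lung metrics are computed on lungs minus ITV by default (the common
"lung − GTV/ITV" convention; a flag restores whole-lung values) on
absolute Gy via the prescription total.

The two-arm comparison uses the Wilcoxon signed-rank test: exact two-sided
p for n ≤ 25 pairs, computed from the full sign-assignment distribution by
convolution with midranks doubled to integers (so tied |differences| are
handled exactly — this is why the test is implemented here rather than
delegated); the normal approximation with tie correction above.  Spearman
correlation delegates to scipy (average ranks).  α = 0.05, no
multiple-testing correction.  VMAT is out of scope (it requires an inverse
optimizer), so cohorts compare conventional DCA against DCA-DMD only; the
report schema keeps the arm column extensible.

## 7. What the synthetic results do and do not show

The pipeline reproduces the *mechanism* and the *direction* of the
clinical finding: on non-spherical targets the deformation arm lowers CI,
CΔ, D2cm and HI, raises CI_Paddick and D98, preserves 95 % coverage
exactly, and CΔ correlates positively with CI and negatively with
CI_Paddick across plans.  Absolute index values depend on the simplified
engine and 3 mm voxelization and are generally *worse* at baseline than a
clinical TPS would report (small targets on a coarse grid can reach
CI > 2), so only directions, orderings and invariants — not magnitudes —
should be compared against clinical tables.  Known limitations: no
build-up or scatter modelling, single generic beam model (no 10FFF arm),
no MU/delivery-time accounting, no OARs beyond the lungs, no deformable
image registration (the "deformation" is contour editing, as in the
clinical procedure), and no noncoplanar arcs.
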