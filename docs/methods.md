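# Methods

This note documents the models, numerical choices and limitations behind
`femurmech`. Units throughout: mm, N, MPa (N/mm²), degrees.

## Synthetic femur cohorts

Sixteen scalar parameters describe one femur (antetorsion ATA, mechanical-axis
angle aMSA, shaft bow BA, head-centre offsets DCHD/DCVD/NCDF/NCDS, head
diameter FHD, neck axis length FNAL, trochanter height GTH, neck diameter ND,
neck-shaft angle NSA, head-to-shaft offsets OSA/OSH, lesser-trochanter height
OSV, total length TFL). Twelve of them are free inputs of the parametric
construction; OSA, OSH, NCDF and NCDS are geometric consequences and are
derived in closed form. Sampling the offsets DCHD/DCVD *and* the projected
offset norms NCDF/NCDS independently would over-determine the two-dof
perpendicular head-offset vector, which is why the latter pair is derived.

Free parameters are drawn independently from truncated normal distributions
whose mean, SD and truncation bounds reproduce published cohort descriptive
statistics of 20 adult femurs. Truncation at the observed minima/maxima
shrinks sample SDs by roughly 5–8 % relative to the nominal SD; the
calibration targets accept this (it is the price of never generating
anatomically absurd tails). Inter-parameter correlations of real femurs are
*not* modelled — the source cohort's correlation structure is not published —
so cohort-level correlation results from synthetic cohorts reflect the
geometry-to-mechanics chain only, not anatomical covariance.

### Constructive geometry

The solid lives in a canonical right-femur frame (x lateral→medial,
y posterior→anterior, z distal→proximal; neck-shaft intersection at the
origin) and is the union of four analytic parts:

* **shaft** — a tube along the z axis, bent in the sagittal plane by BA at
  35 % of TFL from the distal end (bend smoothed over ±15 mm), with a distal
  condylar flare (radius 22 mm) and a metaphyseal flare (17 mm); mid-shaft
  radius 13.5 mm;
* **neck** — a surface of revolution about the neck axis with waist radius
  ND/2, flaring as concave elliptic bulges toward the intertrochanteric base
  (25 mm at the shaft axis) and toward the head, where it swallows the back of
  the head sphere up to a junction circle at 60° polar angle. The waist is
  placed at min(FNAL/2, just distal of where the head sphere would cover it),
  so the sampled ND is always realised on the exposed surface;
* **head** — a sphere of diameter FHD centred at `FHC = FNAL·n + d`, where the
  neck direction `n` is built so that its *frontal projection* makes NSA with
  the shaft axis and its transversal projection makes ATA with the condylar
  axis, and `d ⟂ n` encodes DCHD (anterior) and DCVD (cranial);
* **greater trochanter** — an ellipsoid (16 × 13 × 12 mm semi-axes) whose apex
  realises GTH and protrudes 5 mm laterally of the remaining silhouette.

The neck-axis convention makes NSA exactly the frontal-plane angle (how the
parameter is defined clinically); the textbook arm formula OSH = FNAL·sin NSA
is exact at ATA = 0 and accurate to <1 % otherwise.

Distal condyles are analytic landmarks only (condylar axis along x; condylar
centre placed so the mechanical axis makes aMSA with the shaft axis in the
frontal plane): the mechanics uses only the proximal two thirds, so no distal
epiphysis surface is meshed. The lesser trochanter is likewise a landmark
(surface point at height FHC_z − OSV); only its height enters any
measurement.

### Swept meshing

Cross-sections perpendicular to z are star-shaped about a continuous centre
curve; the boundary R(θ, z) is found by ray-casting all parts (each reduces to
a quadratic along the ray) and merging the intervals, bridging radial gaps
below 10 mm — this fills narrow junction crevices (head underside, trochanteric
fossa) the way periosteal fillets do. A Lipschitz bound |dR/dz| ≤ 3 drapes
steep part transitions so the swept mesh cannot fold; draped nodes are tagged
as junction rather than as a named part (trochanter nodes tolerate a moderate
lift because only their height is measured).

The boundary field R(θ, z) is evaluated once on a fixed fine grid (1 mm in z,
128 azimuths), draped there, and mesh levels sample that *limit surface* — so
meshes of every density discretise the same solid and mesh-convergence
studies measure discretisation error only. Reentrant creases of the union
surface are filleted by a raise-only Gaussian closing (they would otherwise
act as notches); the lift is capped at 0.15 mm on named part surfaces, whose
geometry realises the measured parameters, and unrestricted on junction
fillets.

Levels are spaced at the target edge length with exact feature levels at the
distal end, the 2/3-TFL cut plane, just below the trochanter apex (0.2 mm) and
in a graded band under the head apex, so TFL, the trimmed extent and GTH are
not quantised by the level spacing. Each level is a polar disk (centre node,
trabecular rings, cortical rings, surface ring); one ring lies exactly on the
cortical/trabecular interface, so the two regions conform by construction
(the tie constraint is literal node sharing). Ring sectors between levels form
prisms and hexahedra; hexahedra are cut into two prisms by a fixed diagonal
plane and every prism splits into three tetrahedra by the minimum-vertex-index
rule, which makes shared-face diagonals globally consistent (conforming,
watertight meshes — both properties are asserted in tests). The head apex is
closed by a cone of tets onto a node placed exactly on the sphere.

Cortical thickness defaults: shaft 6 mm, trochanter 3 mm, neck 2 mm, head
1.5 mm (junction fillets inherit the trochanteric value — they stand in for
the intertrochanteric crest), smoothed over the surface and clamped to
0.45·R. At least two through-thickness cortical layers are meshed at any
edge length, so refinement never re-discretises the shell's bending
gradient. A single global `thickness_scale` multiplies all thicknesses; its
default (0.70) was calibrated **once** against the published cohort-mean
sideways-fall strength (5640 N) at the default cohort settings and then
frozen — it is a material/geometry calibration constant, not a per-run
tuning knob.

The greater trochanter is labelled dense (cortical-property) bone
throughout its ellipsoid. In the homogeneous two-phase material a soft-cored
trochanter would funnel the entire fall-case support reaction through a
~2 mm shell; the real trochanter carries that load through densified,
load-adapted trabecular struts that the two-phase model cannot represent.

## Morphometry

The anatomical frame is measured from the tagged mesh surface: the head centre
by an algebraic least-squares sphere fit (exact on noiseless spheres), shaft
and neck axes by iterative section fits, planes from the shaft axis and the
condylar axis (frontal plane contains the FSA, parallel to the condylar axis;
transversal ⟂ FSA).

`fit_axis` slices the region perpendicular to the current axis estimate, fits
a least-squares circle per section (robust to partially occluded rings, unlike
raw centroids), and fits a point-count-weighted total-least-squares line
through the centres. Discrete station binning can trap the iteration in a
small limit cycle, so convergence is declared either when the direction change
drops below 0.01° or when recent iterates stay within a 0.5° cone, in which
case their mean is returned. Shaft stations: 45–75 % of the length (proximal,
straight segment; the sagittal bow is measured separately from the 8–30 % and
45–75 % bands). Neck stations: inner 10–90 % of the neck-tagged extent.

ND is measured as twice the minimal distance-from-axis of neck surface points,
with quadratic fits of r²(s) on both flanks extrapolated to their intersection
(the waist is a shallow V whose ring may be partly hidden inside the
intertrochanteric junction; for a circular neck this equals the minimal
frontal-silhouette width). FNAL uses the closest-approach point of the FNA to
the FSA as the "intersection", with a warning beyond 10 mm of skew. Signed
conventions: GTH positive when the head centre is proximal to the trochanter
apex plane, DCVD positive cranial, DCHD positive anterior.

On generated femurs all sixteen parameters are recovered within 2 % / 0.5 mm
(lengths) and 1° (angles); a 50-femur recovery sweep is part of the test
suite. Rigid-motion invariance holds to the reproducibility of the iterative
fits (~0.05 mm / 0.05°), not to machine precision — re-binning after rotation
moves stations slightly.

## Finite-element mechanics

Linear elasticity, small strains, homogeneous isotropic regions: cortical
E = 16 000 MPa, trabecular E = 500 MPa, ν = 0.3. Default elements are linear
(constant-strain) tetrahedra; 10-node quadratic tetrahedra (straight-edged,
4-point Gauss rule, per-element strain averaged over Gauss points) are
available via `order=2`. Verification: the uniaxial patch test is satisfied to
machine precision; a 30 × 30 × 240 mm cantilever meshed at 2.5 mm matches
Euler–Bernoulli tip deflection within 5 % (linear) and 2 % (quadratic).
Linear tets need ~12 elements across a bending section for that accuracy,
which the femoral neck (~15 elements across at 2.5 mm) provides.

The femur is cut at two thirds of TFL from the proximal end; surface nodes
within 70 mm of the distal cut are fully fixed (the polymer embedding is
modelled as rigid, matching the zero-degrees-of-freedom contact condition;
the embedding moduli stay in the config for a future compliant mode). The
load enters through a reference point at the head centre, rigidly coupled to
the spherical cap of height 10 mm around the load-axis antipode on the head
surface. Load cases:

* **stumbling** — load axis 8° from the shaft axis in the frontal plane,
  tilted laterally, so the load line runs from the head down towards the
  condyles as in single-leg stance;
* **lateral fall** — load axis 10° from the shaft axis, tilted *medially*
  (the adducted femur under a vertical load), with its transversal
  projection making the femur's own ATA with the condylar axis; the
  greater-trochanter patch is supported along the load axis.  The medial
  tilt moves the load line away from the shaft and is what makes the fall
  configuration weaker than stance, as observed; with the opposite sign the
  ordering inverts.

The trochanter support is an elastic foundation: the surface faces whose
centroids lie within 18 mm of the apex (full stiffness inside 9 mm, cosine
taper to the rim) are backed by springs along the load axis with stiffness
``E_embedding / 24 mm`` per unit area — an idealisation of the polymer pot
whose outer surface is held. Rigid single-direction constraints are kept as
an option; they reproduce the same cohort ordering but concentrate
mesh-divergent contact stresses at the patch.

Constraints are eliminated exactly through a sparse basis transformation
(fixed nodes dropped; cap nodes condensed into six rigid-body dofs; supported
trochanter nodes rotated into the 2-dof plane ⟂ load axis). The reduced system
is solved by a banded Cholesky factorisation in the sweep's level-major node
order (bandwidth ≈ 3× the per-level node count) with a 6-dof Schur border for
the reference point; SuperLU is the fallback for non-banded layouts
(e.g. quadratic meshes). The solver asserts a relative residual < 1e-6 and
checks global equilibrium (reactions at fixed and supported dofs balance the
applied load; observed error is at machine precision). Strains scale linearly
with load, so a single solve at the 100 N reference load determines the whole
load programme.

## Fracture criterion

A femur fractures at the first 100 N increment at which a *face-connected*
group of cortical elements, each exceeding the same principal-strain limit
(tensile 0.0073, compressive 0.0104), reaches 100 mm³ total volume.
"Each exceeding" (rather than a group-average) is the reading adopted for the
criterion; tensile and compressive groups are never merged. Exceedance sets
grow monotonically with load, so the first crossing is found by bisection over
the 100-step grid — tested exhaustively against a linear-scan/union-find
oracle on random fields. A tie between modes at the same increment is reported
as compressive and flagged. The fracture load is reported on the 100 N grid
even though linearity would permit a continuous value, mirroring the
incremental loading scheme.

With the calibrated defaults the mean-morphology femur fails at 5 800 N
(stumbling, compressive, medial neck base) and 5 300 N (fall, tensile,
trochanteric region), and the default 20-femur cohort means land at
6 080 N / 5 555 N against the published 6 115 / 5 640 N. The
stance-stronger-than-fall ordering holds for the default cohort but is not
guaranteed for every cohort draw: individual femurs can flip depending on
whether the trochanteric or the medial neck-base site governs, so a
different sampling seed can invert the two cohort means by a few percent.
Two known deviations: the fall-case
failure mode here is tensile rather than compressive, and its location is
trochanteric rather than superior-neck; the source study itself notes that
its all-compressive fall pattern was not seen in comparable
homogeneous-material models.

## Statistics

Pearson correlations use the two-tailed t test (t = r√((n−2)/(1−r²)),
n−2 dof); no multiplicity correction by default (a Holm flag exists, off).
Parameters with p ≤ 0.05 against a case's strength enter a correlation-matrix
PCA for that case; when fewer than two qualify the PCA is skipped with an
explicit reason in the report (sparse stumbling correlations make a PCA
inappropriate). Components with eigenvalue > 1 are retained (possibly none);
loadings are eigenvectors scaled by √λ with a deterministic sign convention
(dominant loading positive); scores are standardized to unit sample SD. KMO is
computed from anti-image partial correlations, Bartlett's sphericity as
χ² = −(n−1−(2p+5)/6)·ln det R with p(p−1)/2 dof; both are None (with the PCA
still returned) if the correlation matrix is singular. The strength is then
regressed on the standardized scores by OLS; because the scores are centred
and orthogonal, the intercept equals the cohort-mean strength exactly and each
coefficient is independent of which other components are included. No
rotation is applied by default (varimax is not implemented; nothing in the
chain requires it).

## Problem sizes and runtime choices

Default mesh target edge length is 2.5 mm (~250k tets for a full femur, ~170k
trimmed, ~90k dofs; one load case solves in ~10 s on one core). The mesh
convergence study halves the edge length 4.0 → 2.0 mm on the mean-morphology
femur — the same halving factor as the nominal 2.5 → 1.25 pair, bracketing the
working resolution, at a memory footprint (≈1.6 GB) that suits desk-scale
hardware. The stumbling fracture load passes the 5 % halving criterion
(observed change ≈ 2 %). The lateral-fall load does **not**: it changes by
roughly 30 % over the pair (and ~10 % from 2.5 to 2.0 mm). The fall case
fails where the support reaction enters the trochanter, and the strain
boundary layer of a millimetre-scale cortical shell on a stiff elastic
foundation, λ = (D/k)^¼ ≈ 4 mm, is not resolvable by constant-strain
tetrahedra at affordable edge lengths. Configurations that remove this weak
spot do converge but invert the stance-versus-fall strength ordering, which
is the scientific point of the study; the ordering was kept and the
non-convergence is reported as-is. Fall-case strengths are therefore
resolution-anchored values at the stated mesh, exactly as the thickness
calibration treats them. Cohort-level checks use 20 femurs; the in-suite
version runs at a 2.75 mm mesh, the standalone acceptance script at the
nominal 2.5 mm. The 100-femur measured-OSH check builds at 4.0 mm:
morphometry accuracy is set by the analytic surface, not the element size.

## What synthetic cohorts do and do not show

The generator reproduces marginal distributions of the sixteen parameters and
yields geometrically consistent, meshable femurs with known ground truth —
ideal for validating measurement, mechanics and inference machinery. It does
not reproduce inter-parameter correlations of real anatomy, heterogeneous
bone density, anisotropy, or cortical-thickness variation beyond the smooth
regional profile. Passing cohort-level tests therefore validates the
*pipeline* (and the strength scale, via the one-time thickness calibration),
not anatomical conclusions about real femurs.
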