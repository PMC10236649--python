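# Methods

`boneatlas` studies whether automatic surgical planning can be driven by an
*average population shape model*: a template built from a population of bone
surfaces, annotated once with clinical landmarks, which then transfers those
landmarks automatically to new subjects by registration. The package
implements the full loop — synthetic population generation, unbiased
template construction, evaluation by explained shape variance and distance
models, and validation by landmark-transfer error on held-out subjects —
with every stage testable against generator ground truth.

## Synthetic population generator

Real clinical mesh collections with expert landmark annotations are rarely
redistributable, so the generator is a first-class component, not a test
fixture. It emulates a humerus-like long bone and a population around it.

**Base shape.** A generalized surface of revolution along the bone axis:
cross-sections are ellipses with piecewise-defined semi-axes (spherical
head cap, circular neck frustum, elliptical prismatic shaft, wide elliptical
distal flare), plus four deliberate asymmetries that mirror humeral anatomy:
a medially offset head centre, a laterally offset condylar flare, a
tubercle-like bump below the head, and a gradual axial twist of the section
axes (humeral-torsion analogue). These asymmetries are not cosmetic — they
anchor the bone's azimuth. On a plain surface of revolution, rigid ICP and
intensity-based registration both admit a one-parameter family of
near-optimal axial rotations, and the population's *shape* differences (not
its pose) then decide the azimuth, producing tens-of-degrees spurious
rotations. We observed exactly this failure before strengthening the
asymmetries.

The bone length is configurable (default 300 mm, adult humerus scale); all
other dimensions scale proportionally. The construction is deterministic.
Eleven named landmarks (head apex, head equator x2, surgical neck x2,
mid-shaft x2, epicondyle analogues x2, trochlea/capitulum analogues x2) sit
exactly on mesh vertices at fixed parametric locations. The enclosed volume
of the generating solid is computed independently of the mesh (exact
parametric section curves, Green's-theorem areas, composite quadrature split
at profile breakpoints) and the mesh volume must agree within 2% at every
supported resolution.

**Deformation modes.** Seven smooth global displacement fields parameterized
by the normalized axial coordinate, ordered by the variance ranking seen in
long-bone populations: length scale, shaft thickness, head bulge, distal
flare, bend-x, bend-y, torsion. Size and robustness dominate real long-bone
variance; bends and torsion are minor. This ordering also matters
operationally: if bends/torsion carry the largest amplitudes, rigid
prealignment of the population becomes azimuthally unidentifiable (aligning
bends rewards large axial rotations more than the condylar anatomy penalises
them).

The raw fields are orthonormalized by Gram–Schmidt *in the landmark inner
product* (mean dot product over the 11 landmark positions), after projecting
out the six infinitesimal rigid-body fields. Orthonormality in landmark
space is what makes the planted amplitude spectrum recoverable: the PCA of
landmark clouds sees the coefficient covariance through the restriction
matrix, which is exactly orthonormal by construction. Each orthonormalized
field remains a closed-form combination of raw analytic fields, so the
deformation map can be evaluated at arbitrary points; subject landmarks are
produced by the exact map (machine precision), with *no* added noise even
when vertex noise is on — landmark-transfer error downstream therefore
isolates pipeline error.

**Sampling.** Subject = rigid pose jitter applied to (base + sum of
coefficient-weighted fields), plus iid Gaussian vertex noise. Coefficients
are iid N(0, amplitude^2). Defaults mirror the study conditions: arms of
50/50/43/43 subjects, five modes with amplitudes (5, 4, 3, 2.5, 2) mm at
300 mm scale, pose jitter 2 degrees / 2 mm, vertex noise 0.05 mm. A
`scaled_spec` helper shrinks every millimetre quantity together with the
bone for desk-scale runs; rotation jitter and counts are scale-free.
Amplitudes must scale with the bone: at half scale the full-scale
amplitudes would exceed the shaft radius and invert the geometry.

## Geometry

Meshes are `trimesh.Trimesh` objects (STL binary write, binary+ASCII read,
duplicate-vertex merge, size-validated binary headers so truncation fails
loudly). Landmarks are name,x,y,z CSV. Volumes are axis-aligned voxel-centre
grids (`world = origin + spacing * index`), stored as NRRD via SimpleITK.

Closest-point and point-in-mesh queries are implemented on a cKDTree over
triangle centroids (oversized triangles are subdivided for the index only,
keeping the search bound tight without changing distances) with an exact
point-triangle projection and a guaranteed-optimal escalation strategy;
containment uses +z ray-crossing parity with an irrational nudge against
edge-grazing rays.

Voxelization rasterizes ray crossings per grid column (even-odd rule at
cell-centred sample points, cells tiling the padded AABB). The registration
pseudo-intensity is a *signed-distance ramp*: 0 at `width` mm outside,
0.5 on the surface, 1 at `width` mm inside (default width 4 mm). Compared
with a thin Gaussian-smoothed shell, the ramp provides intensity gradients
across non-overlap gaps up to twice its width — without it, demons forces
vanish wherever two subjects' thin shafts do not overlap, and registration
stalls (observed). The 0.5 isosurface still coincides with the binary
interface, so marching-cubes extraction at iso 0.5 is representation-
independent.

Signed distance models report per-carrier-vertex distances (negative inside
the reference), a histogram over [-6, 6] mm at 0.5 mm bins with open-ended
under/overflow bins, and the symmetric Hausdorff distance.

## Registration

**Rigid (ICP).** Closest-point pairing from subsampled moving vertices to
the fixed surface, least-squares rigid fit by SVD (Kabsch), iterated to a
residual-change tolerance. Three robustness devices are available and used
by the pipeline: trimmed fitting (best 85% of pairs), normal-compatibility
gating (pairs with normal cosine below 0.5 rejected), and a 10-degree
rotation trust region. The trust region reflects the acquisition scenario
the generator emulates — protocolized poses with ~2 degree jitter — and
prevents the documented failure mode where population *shape* differences
drag the rigid fit into spurious axial rotations that a rigid transform
cannot legitimately explain.

**Affine.** Fixed-to-moving (pull-back) convention. Initialized by the
better (coarse-level SSD) of identity and intensity-moment matching, then
refined by multi-resolution L-BFGS-B on SSD with an analytic gradient,
restricted to informative voxels. The refinement is *box-bounded in
shape-centred coordinates* (pipeline default 0.25 per linear entry, 5 mm
translation around the initializer — wide enough to absorb the residual
pose the rigid prealignment can leave, while excluding the pathological
minima, which sit at entry deviations of 0.5 and beyond). Two lessons
are encoded here: per-entry bounds in corner-origin world coordinates let a
small shear entry slip centimetres of tangential motion at the far end of a
long bone; and unbounded affine SSD on elongated, nearly symmetric shapes
has pathological far-away minima (axis flips, shaft-onto-shaft shears) that
score better than the truth.

**Deformable.** A multi-resolution (4 levels, factors 8/4/2/1)
Gaussian-regularized demons-style method: normalized intensity-difference
force, update smoothing (2 mm), composition, total-field smoothing (1 mm),
SSD tracked with best-field keeping, explosion guard, and a Jacobian
positivity check on the foreground (logged, stored on the result). This is
a deliberate desk-scale stand-in for symmetric-normalization registration:
it preserves the structure of the procedure (dense smooth displacement
fields, invertibility monitoring) at tractable cost, and no claim of parity
with production diffeomorphic registration is made.

**Transforms.** A `SubjectTransform` maps template-space points to
subject-space points — one convention for both uses (pull-back resampling
of subject images onto the template grid, forward transport of template
landmarks into subject space). The forward form is field-then-affine,
x -> A(x + u(x)), matching how the pipeline estimates it; inverses are
represented affine-first. Field inversion uses a damped fixed-point
iteration with a round-trip convergence criterion and an optional
coarse-grid mode for inverses that only feed an average. Transform
averaging is voxelwise for fields and log-Euclidean for affines (arithmetic
fallback with a warning); fractional transforms (the drift step) use matrix
powers via the matrix logarithm.

## Template construction

Subjects are voxelized after rigid prealignment to the first subject. The
reference grid comes from the subject with the largest occupied volume,
extended to cover all subjects; the initial template is the voxelwise mean.
Each iteration registers every subject (affine + deformable) to the current
template, averages the registered images, inverts each template-to-subject
transform, averages the inverses, and pulls the averaged image back along a
0.25-scaled step of that mean inverse (cubic resampling — repeated trilinear
pull-backs accumulate diffusion) — the drift correction that keeps the
template at the population's barycentre rather than near any individual.
Four iterations by default; the mean absolute voxel change and mean SSD are
logged per iteration. The final per-subject transforms are those of the
last iteration: the last drift step changes the template by about 1e-3 mean
intensity (~0.1 mm of geometry), an order of magnitude below the
landmark-transfer error, so a full re-registration pass against the
finished template (20% of the build cost) is not performed by default
(`final_reestimate` enables it).

The comparator arm is a correspondence mean shape: generalized Procrustes
(rigid, no scaling) plus vertex-wise averaging when all meshes share a
triangulation (always true for synthetic data), or closest-point projection
correspondence otherwise. It is labelled "correspondence-mean" throughout —
it is a simplified stand-in for particle-based correspondence optimizers,
not a reimplementation of one.

Template landmarks on synthetic runs are produced by an expert stand-in:
the base mesh is ICP-aligned onto the template surface, its landmarks are
carried along rigidly and projected onto the surface. The rigid alignment
step matters: the template lives in the population's common frame, and
projecting un-posed base landmarks directly leaves a tangential bias.

## Evaluation and validation

Explained variance follows the point-distribution-model recipe: the 11
template landmarks are pushed through each per-subject transform, each
cloud is flattened to a 33-vector, the configurations are rigidly aligned
to their mean (generalized Procrustes, no scaling), and the eigenvalues of
the sample covariance give per-mode explained-variance fractions
(eigenvalue over eigenvalue sum; at most n-1 nontrivial modes for n
subjects). PCA is on raw millimetre coordinates (no standardization). The
Procrustes step is the canonical preliminary of landmark-based shape
statistics and matters here: the rigid prealignment's fit responds
nonlinearly to each subject's deformation, and without per-cloud
re-alignment that pose residue counts as shape variance — measurements on
ground-truth clouds show it caps the 7-mode concentration at 95-98%
regardless of registration quality, while Procrustes restores the exact
planted rank. The `procrustes` flag on the PCA operation exposes both
variants.

Validation splits each arm 82%/18% (round-half-up, so 50 -> 41/9 and
43 -> 35/8) with a seeded uniform permutation. Held-out subjects are
registered to each arm's template volume with the same engine and
parameters, the arm's template landmarks are pushed into subject space, and
errors against generator ground truth are summarized as per-subject RMSE
over the 11 landmarks (subject-first averaging). Arms are compared by a
classical two-sided paired t-test over test subjects (df = n-1; degenerate
cases handled explicitly) and by percent improvement
(B - A)/B x 100 of mean RMSE.

## Problem sizes, determinism, limitations

The shipped tests and the acceptance script run at half scale: a 150 mm
bone at 1 mm voxel spacing (template grids of roughly 300k voxels), arms of
41 training subjects, four template iterations. These sizes keep a full
arm build in the ten-minute range on one CPU while preserving the
relative geometry of the full-scale conditions; the explained-variance
quantities being checked are scale-free. All randomness derives from one
root seed through named substreams (population, ICP subsampling, split),
so runs are bit-reproducible.

What passing tests on synthetic data do *not* show: real bones have
texture, segmentation artefacts, non-smooth shape variation and genuinely
anatomical (not parametric) landmark definitions; the generator's noise-free
landmarks and smooth low-rank deformations are a best case for landmark
transfer. The deformable engine recovers normal-direction surface motion
well but, like any intensity method on smooth surfaces, is nearly blind to
tangential sliding (e.g. pure torsion); on synthetic populations this
appears as transfer error concentrated in tangential directions at the
head equator and condyles. The explained-variance evaluation is insensitive
to systematic (bias-like) transfer error, which is precisely why the
validation stage scores against held-out ground truth as well.
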