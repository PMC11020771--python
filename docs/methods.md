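# Methods

This note documents the models implemented in `craniomech`, their
assumptions, the parameters that matter, and the choices made where the
methodology left the design open.

## Landmark data and dataset variants

A landmark configuration is an ordered set of 2D points in mm, each
flagged as a traditional landmark or a semilandmark with a curve index.
TPS records are read in the tpsDig convention: the `SCALE=` factor
multiplies raw digitised coordinates to yield mm; a record without a
scale line falls back to scale 1 with a logged warning. Coordinates
follow the convention x increasing anteriorly (rostral) and y dorsally,
which fixes the sign of all downstream lever and load directions.

Fragmentary material forces a trade-off between landmark resolution and
taxon coverage; this is modelled as *dataset variants* — designs with a
declared number of traditional landmarks plus curves of semilandmarks.
Four presets (a–d) carry 10+6×7 = 52, 13+9×7 = 76, 19+17×11 = 206 and
21+19×11 = 230 points; custom variants need a total of at least 3.
Configurations missing points are excluded from a variant (by
subsetting), never imputed. Left/right facing is standardised only via
an explicit reflection applied by the caller; the package never mirrors
silently.

## Generalized Procrustes analysis

GPA centres each configuration, scales it to unit centroid size
(centroid size = √Σ‖pᵢ − p̄‖², the standard geometric-morphometric size
measure), and iteratively rotates each configuration onto the running
consensus using the orthogonal Procrustes solution with det(R) = +1
enforced — reflections are excluded so left/right anatomy cannot be
mirrored during superimposition. Iteration stops when the consensus
moves less than `tol` (default 1e-8, Frobenius norm); exceeding
`max_iter` (default 100) raises with the last residual. The aligned set
is finally put into a canonical orientation derived from the consensus'
own principal axes (largest-magnitude first-axis coordinate positive),
which makes the output invariant — not merely equivalent up to rotation —
under arbitrary per-specimen similarity transforms of the input. The
consensus is stored as the arithmetic mean of the aligned set.

Semilandmarks are treated as fixed points: no sliding (bending-energy or
Procrustes-distance) is performed, because no sliding criterion is part
of the modelled procedure. Positions along their curves are therefore
data, and between-specimen differences in curve parametrisation
contribute to shape variance; the synthetic generator samples curves
consistently by arc length so this contribution is small and unbiased.

## Shape PCA, outliers, allometry

PCA is computed by SVD of the centred, unstandardised flattened aligned
coordinates. Eigenvalues are scaled by 1/(n−1); variance fractions sum
to one over the retained min(n−1, 2k) components; a deterministic sign
convention (largest-magnitude loading entry positive) makes scores
reproducible across runs. An orthogonal tangent-space projection at the
mean shape is available (`tangent_project=True`) but off by default —
for small shape variation the Procrustes hemisphere is locally flat and
the projection changes nothing of note.

Outlier tests are Tukey boxplot fences: values strictly outside
Q1 − 1.5·IQR or Q3 + 1.5·IQR are flagged with their side. Quartiles use
linear interpolation between order statistics ("type 7", numpy's
default), configurable, since the 1.5·IQR rule does not by itself fix a
quartile estimator. Allometry regressions (PC scores or functional
metrics against centroid size) are ordinary least squares with a t-test
on the slope and adjusted R².

## Mechanical advantage

`MA = ‖insertion − joint‖ / ‖bite − joint‖`, dimensionless and invariant
under similarity transforms. Two jaw-adductor groups visible in lateral
view are modelled: the temporal group (mAMES, mAMEM, mAMEP, mPSTs) and
the quadrate group (mAMP, mPSTp). The pterygoid group is omitted: its
measurement points are not visible in lateral view. Each insertion is a
single representative point (region centroid when the attachment is an
area); anatomical placement is the caller's responsibility. ΔMA is
quadrate MA minus temporal MA, computed exactly. A posterior bite point
is optional and adds posterior-MA columns to the table; values are kept
at full precision, with rounding (3 decimals) applied only at
presentation.

## Plane-strain finite elements

Elements are 3-node constant-strain triangles — the simplest element
that passes the patch test; mesh refinement substitutes for higher-order
elements. Plane strain (ε_zz = 0) is assumed because bone thickness is
not available for lateral-view-only material; the constitutive matrix is
E/((1+ν)(1−2ν)) · [[1−ν, ν, 0], [ν, 1−ν, 0], [0, 0, (1−2ν)/2]] in a
consistent mm–N–MPa system. Default material: E = 20 490 MPa, ν = 0.4
(compact bone values used across comparable archosaur skull models).

The anterior bite is modelled by constraining the most anterior tooth
node dorsoventrally and the jaw-joint node in both directions, and
loading the temporal and quadrate attachment node sets. The total load
is split between the groups by a configurable fraction (default
0.5/0.5 — the procedure specifies a single combined load condition but
no partition); within a group the force is divided equally among
attachment nodes, each directed from the node toward the group's
insertion point, and per-node magnitudes sum to the scaled total. Loads
are scaled between models by F_B = F_A·√(A_B/A_A) with the reference
force (default 30 N) on the smallest model, which keeps the stress state
constant across model sizes: scaling geometry by s and force by s leaves
the strain field unchanged (verified to 1e-6 relative).

Edge tractions are converted to nodal forces by tributary-length
lumping (each node weighted by half its adjacent segment lengths), which
reproduces a uniform traction exactly for CST meshes and is required for
the patch test to hold to machine precision; equal lumping remains
available as an option but perturbs the end nodes of an edge chain.

The reduced stiffness must be symmetric positive definite. Rigid-body
modes restricted to the free DOFs are checked explicitly (Rayleigh
quotients of the translation and rotation vectors) and a singular system
is rejected naming the free mode; the solver never regularises silently.
Dense Cholesky is used up to 3000 free DOFs, a symmetric sparse
factorisation with positive-pivot verification beyond.

Strain summaries: MWAM = Σ(ε_i·A_i)/ΣA_i corrects for uneven element
sizes. The scalar entering MWAM and the intervals method is the von
Mises-type equivalent strain of the plane-strain tensor,
ε_eq = √(2/3·e:e) with e the deviatoric strain — a single non-negative
number per element, as the reported summary requires; signed principal
strains (ε1 ≥ ε2, with the larger-magnitude one defining the
tensile/compressive field) are retained for contour maps. The intervals
method bins element areas into equal-width half-open bands
[0, u/n), …, [(n−1)u/n, ∞); the band edges are not part of the modelled
procedure, so the upper bound u is a configuration parameter. Its
default, 250 με, matches the strain scale produced by the synthetic
generator's default conditions under the 30 N-scaled bite and is held
fixed across models of one study so their percentages are comparable.
Percentages sum to 100 by construction. Fenestra/surface ratios divide
hole polygon areas (shoelace) by the meshed solid area, total and per
opening (orbit, antorbital fenestra, lateral temporal fenestra, naris).

## Phylogenetic comparative methods

All statistics assume Brownian motion on a user-supplied or simulated
time-calibrated tree. The tip covariance C has C[i,j] equal to the
root-to-MRCA path length (diagonal: root-to-tip depth), assembled from
patristic distances and validated symmetric PSD. Polytomies are allowed;
zero-length branches are flagged but tolerated.

Blomberg's K is (MSE₀/MSE) / E[MSE₀/MSE], with MSE₀ the mean squared
deviation of tip values from the phylogenetic GLS mean
â = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹x, MSE = (x−â)ᵀC⁻¹(x−â)/(n−1), and the expectation
(tr C − n/1ᵀC⁻¹1)/(n−1). K_mult applies the identical machinery to the
rows of a trait matrix (sums of squares replaced by traces) and reduces
exactly to K for one variable. Under BM both average ≈ 1 (verified over
200 simulations on a 32-tip tree). Significance comes from permuting
tip rows: p = (#{K_perm ≥ K_obs} + 1)/(B + 1), default B = 999 (the
conventional default of the standard toolchain), deterministic under a
seed; p-values live in {1/(B+1), …, 1}.

PGLS whitens the design with the Cholesky factor of C and solves the
normal equations; the slope gets a two-sided t-test on n−2 degrees of
freedom. The reported pseudo adjusted R² is
1 − (RSS/TSS_GLS)·(n−1)/(n−2) computed in the whitened space, where
TSS_GLS is taken about the GLS mean — with C = I this is exactly OLS
adjusted R². Each predictor is regressed individually against each
response with no multiple-testing correction, mirroring standard
reporting in this literature; a correction can be layered on by the
caller. BM simulation draws tips from N(root, rate·C) via Cholesky
(eigenvalue fallback for semidefinite C).

## Synthetic studies

The generator emulates the empirical situation the analyses were built
for: lateral-view theropod-like skull outlines whose dominant variation
is snout elongation and depth plus fenestra size, meshes with fenestra
holes, lever points, and traits evolving by BM on a small tree.

The template is a 15-vertex outline (200 mm reference length) with four
elliptical fenestrae (orbit, antorbital, lateral temporal, naris), five
lever points, and two muscle-attachment disc regions. Four linearly
independent deformation modes act on template vertices *before* landmark
sampling, so landmarks, levers and meshes deform consistently:
snout elongation (anterior x-stretch, 30 mm per unit weight at the tip),
snout depth (vertical scaling of the snout, 60 % per unit weight at the
tip), fenestra size (radial scaling of each ring about its centre, 15 %
per unit weight), and quadrate inclination (posterior shear). Mode
weights are simulated under BM on a pure-birth tree (unit rate, rescaled
to unit depth; built from exponential waiting times with a final
extension so no terminal branch is zero). Default BM rates
(0.2/0.05/0.05/0.02 per unit depth) make snout elongation dominate, as
in the empirical shape axes this emulates. Isotropic Gaussian
digitisation noise (default 0.5 mm, about 0.25 % of skull length) is
added to every geometry vertex; in the rare case the noise makes a small
ring self-intersect, it is redrawn (bounded, deterministic under the
seed). Deformations that break polygon validity raise, naming the
largest-magnitude weight.

Traditional landmarks come from an ordered pool of anatomical anchors
(tip, joint region, outline corners, fenestra extrema); semilandmark
curves are sampled uniformly by arc length along outline segments and
fenestra arcs. Meshing densifies boundary rings, lays a staggered
interior grid with an offset boundary layer, thins crowded points,
applies Laplacian smoothing, triangulates (Delaunay), and keeps
triangles whose centroids fall in the solid region; the effective
element size is capped by the finest boundary feature and the narrowest
solid band, and the mesh must reach a 20° minimum angle and cover the
polygon area to 0.1 % or the call fails with a refinement hint.

What the generator does *not* emulate: real cranial suture geometry,
heterogeneous bone material, taphonomic distortion, landmark
correspondence error between observers, and non-Brownian evolution.
Passing the recovery tests therefore demonstrates the pipeline's
correctness and calibration on data satisfying its assumptions, not the
biological fidelity of any particular empirical result.

## Pipeline defaults and problem sizes

The report pipeline defaults to E = 20.49 GPa, ν = 0.4, 30 N reference
force, 0.5/0.5 muscle partition, 4 intervals with a 250 με upper bound,
999 permutations, and type-7 quartiles. Skull length for the
length-vs-MWAM regressions is the horizontal extent (max x − min x) of
the calibrated configuration, a configurable chord definition. Tests
and the acceptance script use 5–8-taxon studies with ~2500–6000-element
meshes, 200-replicate calibrations on 32- and 64-tip trees, and 19–199
permutations — sizes at which every stage's behaviour is already fully
resolved while a complete run stays fast. All randomness flows through
seeds recorded in the run log; reruns with the same configuration are
byte-identical.

## Known limitations

* CST elements are first-order: strain fields near load application
  points and re-entrant corners need fine meshes; MWAM convergence under
  refinement is the practical check.
* The FE model is the upper jaw only (no lower jaw contact, no muscle
  wrapping); absolute strain magnitudes are comparative, not predictive.
* K_mult permutation tests inherit the usual low power at small n; with
  fewer than ~10 tips, non-significant signal is weakly informative.
* The TPS reader supports the common LM/IMAGE/ID/SCALE dialect only
  (no CURVES blocks); curve membership is carried by dataset variants.
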