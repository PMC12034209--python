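# Methods

## The two morphometric branches

`morphoatlas` implements and compares two routes from a population of
triangulated surfaces to a low-dimensional shape space.

**Landmark branch.** Homologous point configurations (fixed landmarks plus
curve semilandmarks) are resampled to equal arc-length spacing, slid along
reference tangent directions to minimise thin-plate-spline bending energy,
superimposed by generalized Procrustes analysis (GPA), and decomposed by
ordinary PCA of the flattened aligned coordinates.

**Landmark-free branch (deterministic atlas).** A template surface `T` is
deformed onto every specimen by a diffeomorphic flow parameterised by
control points `q` and per-specimen momenta `mu`.  The velocity field is

    X(x) = sum_i K_sigma(x, q_i) mu_i,        K_sigma(x, y) = exp(-|x - y|^2 / sigma^2)

and `(q(t), mu(t))` follow the Hamiltonian geodesic equations

    dq/dt  =  K[q, q] mu
    dmu/dt = -1/2 grad_q { K[q, q] mu' mu }

integrated over `t in [0, 1]` by midpoint Runge–Kutta (default, 10 steps) or
Euler.  Template vertices are advected through the same time-varying field.
The estimation loss is

    f(T, q, mu) = sum_i [ d^2(Phi_{q,mu_i}(T), C_i) / (2 s_n^2) + 1/2 mu_i' K(q,q) mu_i ]

where `d^2` is a kernel distance between oriented face sets (centres `c_p`,
area-weighted normals `n_p`):

  * current:  sum_pq K_w(c_p, c_q) (n_p . n_q)
  * varifold: sum_pq K_w(c_p, c_q) (n_p . n_q)^2 / (|n_p| |n_q|)

expanded as `<A,A> - 2<A,B> + <B,B>`.  The varifold form ignores orientation
sign and is the default.  The regulariser is the geodesic kinetic energy of
the initial momenta (the standard LDDMM norm); `s_n` is the noise scale
(default 10.0), read as the data-term standard deviation.

The fitted momenta (one `p x 3` block per specimen) are flattened and
linearised by kernel PCA: Gram matrix `G_ij = exp(-gamma |m_i - m_j|^2)`,
double-centred, dense symmetric eigendecomposition, scores = eigenvectors
scaled by the square roots of the eigenvalues, at most `n - 1` axes.

## Optimisation

Atlas estimation is joint gradient descent on template vertices, control
points and all momenta.  Gradients are hand-derived adjoints of the exact
discretised forward computation (reverse sweeps through the Runge–Kutta
steps, with the kernel-pairwise contractions reduced to matrix products);
they agree with central finite differences to ~1e-9 relative error, which a
dedicated test enforces at 1e-4.

The "initial step size" (default 0.01) is interpreted as a fraction of the
template bounding-box diagonal: each parameter block is rescaled by the
max-norm of its initial gradient so the first accepted update moves no
coordinate by more than `step x diagonal`.  The step halves whenever a trial
increases the loss (that step is re-tried) and doubles after five
consecutive accepted steps.  Momenta start at zero, control points on an
axis-aligned grid at kernel-width spacing over the padded template bounding
box (padding sigma/2 per side; per-axis node count
`ceil(padded extent / sigma) + 1`), and the template starts at a chosen
specimen.  Everything is deterministic; there is no randomness anywhere in
the fit.

## Key parameters

| parameter | unit | default | role |
|---|---|---|---|
| `sigma` | mm | — (per study) | deformation kernel width; smaller = finer deformations, more control points |
| `sigma_w` | mm | `sigma / 2` | attachment kernel width; sets the spatial scale at which surface mismatch is felt |
| `noise_sigma` | — | 10.0 | data-term scale; larger = more regularisation |
| `step` | fraction | 0.01 | initial relative step of the optimiser |
| `max_iter` | — | 150 | optimisation iterations |
| `n_steps` | — | 10 | time steps of the geodesic integrator |
| `gamma` (kPCA) | 1/mm² | 2.5e-6 | Gram kernel width; at momenta scales of tens of mm this is the near-linear regime; `"auto"` (1/median squared distance) gives a strongly non-linear embedding |

## Synthetic study populations

The generator produces populations with known ground truth so every stage
is testable without external data.  The base shape is a subdivided
icosahedron (analytic control of topology and vertex count) of radius 40 mm
(an 80 mm, cranium-scale object).  Per-specimen momenta on the true control
grid are

    mu_i = a_i * M_stretch + BM_i + eps_i

* `a_i ~ N(0, elongation_sd^2)` with `M_stretch` proportional to each
  control point's signed coordinate along the x axis, normalised so a unit
  coefficient gives an initial pole velocity equal to the radius — a smooth
  elongation mimicking the dolichocephalic–brachycephalic axis of cranial
  variation (default sd 0.15, i.e. roughly ±15% length changes);
* `BM_i`: Brownian motion on a pure-birth phylogeny (unit depth), rate 1.0
  mm² per unit branch length per momentum coordinate — clade-structured
  variation carrying phylogenetic signal;
* `eps_i`: iid N(0, 0.5² mm²) individual noise per coordinate.

Specimens are produced by geodesic shooting of the base mesh, so atlas
estimation is a well-posed parameter-recovery problem; a `vertex_jitter_sd`
option adds non-model noise for robustness checks.  Landmarks are tracked
base-mesh vertices carried through the same flow — exactly homologous by
construction (30 fixed by farthest-point sampling + 4 curves x 6
semilandmarks on shortest edge-graph paths; scaled down automatically on
meshes under 160 vertices).  Group labels follow the clades at the root
split.  One global seed feeds named sub-streams (tree, elongation, BM,
noise, modality, jitter), so components are independently reproducible and
all text outputs are byte-identical across runs.

**Modality artifact.** A seeded subset (`floor(open_fraction * n)`) of
specimens becomes "open": 12 shallow surface patches (radius a quarter of
the base radius, ~19% of the total area, each with sub-2 mm cap height) are
removed at fixed farthest-point-spread locations.  This emulates CT-derived
meshes, which lack many distributed openings, while keeping each opening
shallow enough that watertight closing nearly restores the true surface.
The open/closed assignment is a seeded draw stratified on the elongation
coefficient, so the modality split cannot be confounded with the dominant
biological axis by sampling accident.  In practice the artifact expresses
on the second or third shape axis (point-biserial correlations of 0.5–0.8)
rather than dominating PC1: with a biological elongation axis of realistic
strength, the regularised deformation response to missing surface patches
saturates at roughly 10–15% of total shape variance regardless of
attachment mode or kernel width.  What passing tests show is therefore that
the artifact appears as a distinct leading axis, that watertight
standardisation removes it from PC1, and that the landmark-vs-atlas
concordance improves after standardisation — not that the artifact
overwhelms all biology, which in real data depends on how much surface is
missing.

What the generator does **not** emulate: realistic cranial anatomy,
scan-specific noise spectra, segmentation errors, landmarking error (the
synthetic landmarks are exact, so landmark-branch results are an upper
bound on real-data performance), and allometry.

## Mesh standardisation

**Watertight closing** replaces a surface-reconstruction workflow with an
equivalent watertight-output contract: rasterise the surface on a padded
voxel grid, morphologically close at a healing radius (sealing boundary
holes up to about twice that radius), flood-fill the exterior from the grid
boundary, erode back, and extract a smoothed-indicator isosurface.  Defaults:
voxel = bounding-box diagonal / 200, healing radius = diagonal / 10.  The
output is always closed and consistently outward-oriented; the Hausdorff
distance to a closed input is bounded by `2 * voxel * sqrt(3)` (tested
against a brute-force point-to-triangle oracle).  Because the morphology is
computed on a binary lattice, re-applying the operation moves the surface
by up to ~2 voxels (the lattice repeatability limit), and healed patches
bridge holes with a near-chordal membrane — deep concavities are not
extrapolated.  Convex shapes are unaffected by the closing radius.

**Decimation** is greedy quadric-error edge collapse with a link-condition
check (manifoldness preserved), normal-flip rejection, and a strict
boundary policy: boundary vertices are never collapsed, so open meshes keep
their boundary exactly.  The face count lands within 2% of the target on
well-conditioned inputs; if the guards make the target unreachable the
achieved count is returned.

**Alignment** onto landmark configurations is least-squares rigid (Kabsch,
reflections disallowed — anatomical meshes must never be mirrored
silently), with optional pre-scaling by the ratio of centroid sizes.

## Landmark pipeline numerics

* TPS uses the 3-D kernel `U(r) = -r`; bending energy is `tr(W' K W)`,
  which vanishes exactly on affine maps.  The bending-energy matrix is the
  upper-left block of the inverted bordered system.
* Sliding moves interior curve points along reference tangent lines
  (endpoints and fixed landmarks immobile), one Gauss–Seidel sweep of
  exact 1-D minimisations per iteration, three sweeps by default; energy is
  monotonically non-increasing by construction.  The reference is the
  Procrustes consensus when driven from the pipeline.
* GPA iterates centre / scale-to-unit-centroid-size / rotate-to-consensus
  until the consensus moves by less than 1e-10, then rotates everything
  into the consensus principal frame with a deterministic sign rule — the
  output is invariant to rigid motions of the inputs, not merely invariant
  up to rotation.
* PCA and kPCA fix axis signs (largest-magnitude loading, respectively
  score, positive); kPCA eigenvalues below 1e-12 of the leading one are
  zeroed as numerical null space.

## Concordance and macroevolution conventions

* Mantel: Pearson correlation of strictly-lower-triangle entries, one-sided
  (greater) permutation test permuting rows and columns jointly; exhaustive
  enumeration with `n_perm="all"`.  Sampled p-values use the
  `(1 + hits) / (1 + n_perm)` convention; exhaustive ones count the
  identity among the `n!` relabelings.
* PROTEST: both matrices column-centred and scaled to unit total sum of
  squares; `m2 = 1 - (sum of singular values)^2`; correlation
  `sqrt(1 - m2)`; `rmse = sqrt(m2 / n)`; rows of the second matrix permuted.
* Phylogenetic signal is the multivariate generalisation of Blomberg's K:
  the ratio of Euclidean to phylogenetically-metric summed squared
  distances of tips from the GLS root estimate, divided by the Brownian
  expectation `(tr(C) - n / (1' C^-1 1)) / (n - 1)`.  With this divisor the
  univariate case reduces exactly to Blomberg's K and a star phylogeny
  gives K = 1 for any data.  Significance permutes tip rows (99 by
  default).
* Group rates: `sigma2_g` is the mean squared norm of phylogenetically
  transformed residuals (symmetric inverse square root of C, residuals
  about the GLS root) over the group's tips, divided by the trait
  dimension; the max/min ratio is tested against 100 seeded single-rate
  Brownian simulations on the same tree.  GLS solves use a Cholesky factor
  of C; a non-positive-definite C (duplicated tips) raises rather than
  being regularised silently.
* Disparity is the Procrustes variance `sum_i |y_i - ybar_g|^2 / n_g`, with
  pairwise differences tested by permutation of group labels.

## Problem sizes used by the test suite and acceptance script

Parameter-recovery runs use 20 specimens on level-3 icospheres (642
vertices, 1280 faces) with sigma 25 mm and 30 optimisation iterations; the
standardisation experiment and the acceptance script use level-2 icospheres
(162 vertices, 320 faces) with 20 iterations, voxel size diagonal/50 and a
320-face budget after closing.  These sizes were chosen so a full pipeline
run completes on a single CPU core in minutes while leaving every
qualitative contract testable; all of them are configuration, not
constants, and scale up unchanged.

## Known limitations

* The voxel-morphology closing cannot extrapolate missing geometry; large
  or deep holes are bridged by near-flat membranes.
* The optimiser is first-order; very small kernel widths (many control
  points) converge slowly and would benefit from preconditioning.
* The Python quadric decimator is quadratic-ish in collapse count and is
  sized for 1e5-face inputs, not raw scan resolution.
* Kernel sums are exact dense `O(f^2)`/`O(p^2)` computations; no fast
  multipole or grid approximations are provided.
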