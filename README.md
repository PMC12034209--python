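# morphoatlas

Landmark-free morphometrics by deterministic atlas estimation, side by side
with classical landmark-based geometric morphometrics, for populations of
triangulated surfaces (crania and other skeletal elements scanned by CT or
photogrammetry).

Comparative morphologists quantify shape either by digitising homologous
landmarks and semilandmark curves (Procrustes superimposition + PCA) or,
increasingly, by landmark-free registration: a template surface is deformed
diffeomorphically onto every specimen and the deformation parameters become
the shape data.  This package implements the full landmark-free pipeline —
mesh standardisation, large-deformation (LDDMM) atlas estimation with
control points and momenta, kernel PCA of the momenta — together with the
landmark branch and the statistics used to compare the two: distance-matrix
correlations (Mantel), Procrustean randomisation (PROTEST), eigenvalue-
spectrum regression, per-vertex heatmap distances, and downstream
macroevolutionary measures (multivariate phylogenetic signal K_mult, group
disparity, and simulation-tested evolutionary rates).

## The model

Deformations are generated by control points `q_i` with per-specimen
momenta `mu_i` through a Gaussian kernel velocity field

    X(x) = Σ_i K_σ(x, q_i) μ_i,   K_σ(x, y) = exp(−‖x−y‖²/σ²),

whose Hamiltonian geodesic flow

    q̇ = K[q,q] μ,   μ̇ = −½ ∇_q (K[q,q] μᵀμ)

carries the template onto each specimen.  The atlas (template, control
points, all momenta) minimises

    f = Σ_i  d²(Φ_{q,μ_i}(T), C_i) / (2σ_n²)  +  ½ μ_iᵀ K(q,q) μ_i

where `d²` is a current or varifold distance between oriented face sets —
no point correspondence is ever required.  Momenta are linearised into at
most n−1 shape axes by kernel PCA of the Gaussian Gram matrix.  Gradients
of `f` are exact adjoints of the discretised flow, verified against finite
differences in the test suite.

A fully synthetic study generator (icosphere populations deformed by a
known elongation axis plus Brownian-motion clade structure on a simulated
phylogeny, with exactly homologous tracked landmarks and an optional
open-surface modality artifact) makes every stage testable end to end
without external scan data.  See `docs/methods.md` for the numerical
details and design choices.

## Worked example

```python
import numpy as np
from morphoatlas import (PopulationSpec, build_study, KernelSpec,
                         estimate_atlas, kpca, generalized_procrustes,
                         landmark_pca, mantel_test, score_distance_matrix, kmult)
from morphoatlas.atlas import AtlasConfig

spec = PopulationSpec(n_specimens=12, subdivision_level=2, seed=4)
study = build_study(spec)                      # meshes, landmarks, tree, labels

model = estimate_atlas(study.meshes, study.meshes[0],
                       KernelSpec(sigma=25.0, sigma_w=12.5),
                       AtlasConfig(max_iter=15, noise_sigma=10.0))
print(f"loss: {model.loss_trace[0]:.1f} -> {model.loss_trace[-1]:.1f} "
      f"({len(model.control_points.positions)} control points)")

daa = kpca(model.momenta)                      # landmark-free shape space
print(f"kPCA PC1 variance: {daa.percent_variance[0]:.1f}%  "
      f"r(PC1, true elongation) = "
      f"{np.corrcoef(daa.scores[:, 0], study.elongation_coefficients)[0, 1]:+.3f}")

lm = landmark_pca(generalized_procrustes(study.landmarks))
r, p = mantel_test(score_distance_matrix(lm), score_distance_matrix(daa),
                   n_perm=999, seed=0)
print(f"Mantel r (landmark vs atlas branch) = {r:.3f}, p = {p:.3f}")

daa.specimen_ids = study.specimen_ids
k, pk = kmult(daa, study.tree, n_perm=99, seed=0)
print(f"K_mult = {k:.3f}, p = {pk:.2f}")
```

prints (seed 4):

```
loss: 148738.0 -> 2033.3 (252 control points)
kPCA PC1 variance: 52.6%  r(PC1, true elongation) = +0.974
Mantel r (landmark vs atlas branch) = 0.954, p = 0.001
K_mult = 0.713, p = 0.01
```

The atlas fit reduces the total loss ~70-fold; the first kernel-PCA axis of
the fitted momenta recovers the population's true elongation coefficient
(r = 0.97); the landmark and landmark-free shape spaces agree strongly
(Mantel r = 0.95); and the clade-structured component of the simulated
variation shows up as significant phylogenetic signal (K_mult = 0.71,
p = 0.01 over 99 permutations).

The same pipeline is scriptable from the shell:

```sh
morphoatlas simulate --n 20 --seed 1 --out study/
morphoatlas standardise --in study/ --out std/ --voxel-size 2.5 --target-faces 320
morphoatlas atlas --in std/ --sigma 25 --out atlas/
morphoatlas kpca --momenta atlas/momenta.csv --out scores.csv
morphoatlas landmarks --in study/ --out lm_scores.csv
morphoatlas compare --scores-a lm_scores.csv --scores-b scores.csv \
    --perm 9999 --seed 1 --out report.json
morphoatlas macroevo --scores scores.csv --tree study/tree.nwk \
    --groups study/metadata.csv --out macro.json
```

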