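# boneatlas

Average-shape bone templates and automatic surgical-landmark transfer.

Orthopaedic planning tools need anatomical landmarks on every patient's
bone. Annotating them by hand is expensive; an alternative is to build one
*average population model* (template) from a training set of bone surfaces,
have an expert annotate the template once, and transfer those landmarks to
any new subject automatically by image registration. `boneatlas`
implements and validates that whole loop for humerus-like long bones:

* a **synthetic population generator** with known ground truth — a
  parametric humerus-like solid, latent deformation modes, pose jitter,
  vertex noise, and 11 clinical-style landmarks carried through every
  deformation analytically;
* **geometry**: STL / landmark-CSV / NRRD I/O, watertight-mesh
  voxelization, distance-ramp registration intensities, marching-cubes
  surface extraction, signed surface-distance models with histograms;
* **registration**: robust rigid ICP, bounded multi-resolution affine, and
  a desk-scale Gaussian-regularized demons-style deformable engine with
  displacement-field inversion and transform averaging;
* **template construction**: the iterative unbiased average-image template
  (register all subjects to the current template, average, drift-correct by
  the scaled mean inverse transform, iterate — four iterations by default),
  plus a correspondence mean shape as comparator arm;
* **evaluation & validation**: landmark transfer to training subjects,
  Procrustes-aligned covariance PCA with per-mode explained variance
  (fraction lambda_i / sum lambda), signed distance models between the two
  template arms, an 82/18 train/test split, landmark RMSE on held-out
  subjects, paired t-tests and percent improvement.

## Worked example

```python
import numpy as np
from boneatlas import (PopulationSpec, make_base_shape, make_population,
                       scaled_spec, icp_align, voxelize, soft_occupancy,
                       build_template, annotate_template,
                       transfer_landmarks_to_training, pca_explained_variance)

# a half-scale (150 mm) humerus-like population: 12 subjects, 5 shape modes
base, landmarks = make_base_shape(resolution=2, length=150.0)
spec = scaled_spec(PopulationSpec(n_subjects=12, n_modes=5, seed=1), 0.5)
population = make_population(base, landmarks, spec)

# preprocessing: rigid ICP alignment to the first subject, then voxelize
aligned = [icp_align(s.mesh, population[0].mesh, subsample=1200, seed=0,
                     trim=0.85, normal_cos=0.5, max_rotation_deg=10.0)[1]
           for s in population]
volumes = [soft_occupancy(voxelize(m, spacing=1.0, padding=6), 4.0)
           for m in aligned]

# iterative unbiased template (4 iterations), expert-stand-in annotation
result = build_template(volumes, n_iterations=4)
template_lm = annotate_template(base, landmarks, result.surface)

# transfer the 11 landmarks to every training subject and run PCA
clouds = transfer_landmarks_to_training(template_lm,
                                        result.per_subject_transforms)
pca = pca_explained_variance(clouds, procrustes=True)
print("cumulative explained variance, modes 1..7:")
print(np.round(100 * pca.cumulative_fraction[:7], 2))
```

Output:

```
cumulative explained variance, modes 1..7:
[77.35 88.96 94.61 97.35 98.66 99.51 99.86]
```

Five planted deformation modes dominate the transferred landmark clouds;
by mode 7 over 99% of the population's shape variation is explained —
the template "sees" the population's true low-dimensional structure.
Per-iteration convergence of the template build is in
`result.iteration_log` (mean absolute voxel change and mean SSD).

A command-line front end wraps the same pipeline:

```bash
bone-atlas synth --seed 1 --outdir run/      # populations as STL + CSV
bone-atlas run   --seed 1 --outdir run/      # templates, evaluation, validation
bone-atlas report --outdir run/              # combined markdown report
```

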