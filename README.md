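# morphotraj

Geometric-morphometric analysis of growth and development for dense 3D
landmark configurations, with a deformation (per-facet area change)
perspective. The package provides:

- **synthetic_data** — bilaterally symmetric, face-like template meshes and
  simulated landmark cohorts with analytic ground truth: age curves for
  centroid size (logistic growth), mean-shape trend, emerging sexual
  dimorphism, age-increasing shape variance with one "diversifying"
  direction, and small bilateral asymmetry.
- **shape_core** — centroid size, generalized Procrustes analysis (partial
  Procrustes, unit centroid size), object-symmetry decomposition into
  symmetric/asymmetric components, PCA of symmetrized coordinates with an
  explained-variance retention threshold (default 99%), Procrustes
  distance, and score-to-shape reconstruction.
- **trajectories** — kernel-weighted PLS regression of size or shape on
  age with Gaussian weights `w_i = (1/sqrt(2*pi)) exp(-(x_i-x_m)^2 / (2*sigma^2))`
  (default bandwidths 2.25 for size, 3.0 for shape; half-year grids over
  4–38 y and 5–37 y), instantaneous rate vectors, a sex-label permutation
  test of the male–female predicted-shape distance, and a penalized-spline
  trend smoother (GCV-selected smoothing, approximate F-test).
- **disparity** — Procrustes variance per 1-year age bin, for group-mean or
  nonlinearly modelled (trajectory-residual) shape, pairwise two-sample
  permutation tests, and a nonlinear variance trend.
- **relative_pca** — relative eigenanalysis of two age groups' covariance
  matrices in a leading-PC subspace (default 5), generalized-variance
  ratio, proportionality likelihood-ratio test (chi-square and permutation
  modes), and successive-eigenvalue tests with Benjamini–Hochberg FDR.
- **deformation** — per-facet percentage area-change fields between
  shapes on a shared triangulation, rate-effect and dimorphism fields, and
  Pearson correlations between fields.
- **pipeline_io** — CSV/OBJ/PLY formats, sequential roster exclusion
  accounting (quality → completeness → anthropometrics), YAML run
  configuration and the end-to-end orchestrator with a deterministic JSON
  manifest and a markdown report.

## CLI

```bash
morphotraj simulate --config cohort.yaml --out data/ --seed 1
morphotraj align --landmarks data/landmarks.csv --meta data/metadata.csv \
    --template data/template.obj --pairing data/pairing.csv --out aligned/
morphotraj trajectory --aligned aligned/ --what cs --out traj_cs.csv
morphotraj dimorphism --aligned aligned/ --n-perm 1000 --seed 1 --out dim.csv
morphotraj variance --aligned aligned/ --bins 1 --range 5 37 --n-perm 1000 \
    --seed 1 --out var/
morphotraj relpca --aligned aligned/ --group-a 6 9 --group-b 18 20 --p 5 \
    --mode perm --out relpca/
morphotraj deform --source a.obj --target b.obj --out field.ply
morphotraj run --config run.yaml --out run_out/ --seed 1
morphotraj report --run-dir run_out/
```

`morphotraj run` with no config simulates a 300-individual cohort and runs
the full analysis; all stochastic stages record their seeds in
`manifest.json` and reruns are byte-reproducible (timings live in
`run.log`).

Units: columns are suffixed with their units (`age_y` years, `cs_mm`
millimetres, deformation fields in percent area change); shape scores and
Procrustes distances are dimensionless quantities in the
unit-centroid-size frame.

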