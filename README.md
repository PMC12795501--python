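# geomrep

Analysis pipeline for studying the **geometric regularity effect** in
human shape perception: the finding that quadrilaterals rich in
discrete regularities (right angles, parallel sides, equal sides and
angles) are perceived, discriminated and neurally encoded differently
from irregular ones. The package re-implements, as a tested library,
the computational chain used in behavioral + MEG + fMRI studies of this
effect — from stimulus construction through representational similarity
analysis and nonparametric group inference — and exercises it end to
end on synthetic data with planted, recoverable structure. It is aimed
at cognitive-neuroscience researchers who want the analysis machinery
(or a reference implementation of it) without the original recordings.

## What is inside

* **Stimuli** (`geomrep.stimuli`) — the 11 regularity-graded
  quadrilateral families (square … random), matched on mean pairwise
  vertex distance (mpd), with similarity transforms, without-replacement
  scale/rotation sampling, and corner-displacement deviants
  (‖Δv‖ = 0.45 · mpd, four diagonal directions).
* **Feature model** (`geomrep.features`) — the discrete geometric code:
  22 boolean predicates per shape at tolerance τ = 12.5% (4 right
  angles, 6 equal-angle, 6 equal-side, 6 parallel pairs), regularity
  score = feature count, dissimilarity = Hamming distance between
  feature vectors.
* **Behavior** (`geomrep.behavior`) — empirical dissimilarity from
  visual-search trials, `d(i,j) = mean accuracy / mean RT`, symmetrized
  and z-scored; OLS regression of RDMs on model RDMs; ordinal MDS with
  seeded restarts; property projection with bootstrap significance.
* **RSA core** (`geomrep.rsa`) — RDM container, shrinkage noise
  covariance, cross-validated Mahalanobis (crossnobis) distances
  `d(i,j) = mean over fold pairs of (x_i^m − x_j^m)ᵀ Σ⁻¹ (x_i^n − x_j^n)/P`
  (unbiased, may be negative), and whitened RDM correlation.
* **Decoding** (`geomrep.decoding`) — time-resolved reference-vs-oddball
  logistic decoding with the six-split run scheme, per-shape ROC AUC,
  100 ms smoothing, regularity correlation, and the 57%-threshold
  latency statistic.
* **Cluster statistics** (`geomrep.cluster`) — temporal sign-flip and
  volumetric sign-swap cluster-mass permutation tests, corrected
  p = k/N (3 exceedances of 10,000 swaps → p = 0.0003).
* **Searchlight** (`geomrep.searchlight`) — 93-voxel spheres (radius 3
  voxels, strict), >50% brain-coverage filter, crossnobis-per-sphere
  maps, mask-aware smoothing, cross-validated top-decile subject ROIs.
* **Synthetic data** (`geomrep.synth`) — oddball miniblock designs
  (30 items, 4 oddballs, constrained placement), intruder displays,
  psychometric visual-search simulation, MEG-like epochs with two
  planted representational geometries in early/late time windows and
  regularity-scaled oddball responses, and fMRI-like beta volumes with
  a planted two-region double dissociation.
* **I/O + CLI** (`geomrep.io`, `geomrep` command) — CSV/JSON RDMs, TSV
  trials, HDF5 epochs, NIfTI volumes, a validated pipeline runner with
  provenance reports, and subcommands
  `stimuli · features · behavior-rdm · rdm-regress · mds · simulate ·
  decode · rsa-time · searchlight · cluster-test · pipeline`.

## Worked example

Build the stimulus set, derive the feature-model RDM, simulate an
online visual-search cohort, and ask whether the empirical
dissimilarities recover the generating model:

```python
import numpy as np
from scipy.stats import spearmanr
from geomrep import behavior, features, stimuli, synth

shapes = stimuli.make_reference_shapes(bottom_side_length=1.0)
feat_rdm = features.feature_rdm(shapes, tolerance=0.125)
scores = {n: features.regularity_score(features.feature_vector(q))
          for n, q in shapes.items()}
print("regularity scores:", scores)

trials = synth.simulate_behavior(feat_rdm, n_participants=50, rng_seed=0)
emp = behavior.empirical_rdm(trials)          # pooled accuracy / RT, z-scored
truth = feat_rdm.subset(emp.labels)
rho = spearmanr(emp.z_values, truth.values).statistic
print(f"rank correlation with the feature model: rho = {rho:.3f}")

control = synth.random_geometry_rdm(emp.labels, rng_seed=1)
fit = behavior.rdm_regression(emp.as_rdm(),
                              [truth.zscored(), control.zscored()],
                              model_names=["features", "control"])
print(f"regression weights: features = {fit.coefficients[0]:.3f}, "
      f"control = {fit.coefficients[1]:.3f} (R^2 = {fit.r_squared:.3f})")
```

Output:

```
regularity scores: {'square': 18, 'rectangle': 14, 'isoTrapezoid': 4, 'parallelogram': 6, 'losange': 10, 'kite': 3, 'rightKite': 5, 'hinge': 1, 'rightHinge': 2, 'trapezoid': 1, 'random': 0}
rank correlation with the feature model: rho = 0.992
regression weights: features = 0.992, control = 0.003 (R^2 = 0.985)
```

The square carries the maximal regularity score (18 of 22 features) and
the fully irregular family carries none; 50 simulated participants
suffice for the pooled accuracy/RT estimator to recover the generating
dissimilarity structure almost perfectly (ρ = 0.99), and the RDM
regression puts essentially all weight on the generating model rather
than on an unrelated control geometry.

The same stages are available from the shell, e.g.:

```bash
geomrep stimuli --out shapes.json --svg shapes.svg
geomrep simulate behavior --seed 1 --n-participants 50 --out trials.tsv
geomrep behavior-rdm trials.tsv --out rdm.csv
geomrep mds rdm.csv --out coords.csv
```

See `docs/methods.md` for the models, estimators, numerical choices and
the exact conditions the synthetic generators emulate.

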