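# chemoarch

Analysis pipeline for cortical **chemoarchitecture**: relating regional
neurotransmitter receptor/transporter density profiles to connectome
structure, function, oscillatory dynamics, cognition and disorder maps —
with the spatial null models needed to make those associations honest.

## Who this is for

Systems/network neuroscientists working with parcellated brain data: a
region × receptor density matrix (e.g. 100 cortical regions × 19 PET-derived
receptor maps), dense structural and functional connectomes, regional target
maps (band power, cortical-abnormality effect sizes), and region × term
meta-analytic activation matrices. All inputs are plain delimited text.

## What it computes

- **Receptor similarity** — Pearson correlation r(i, j) between the
  z-scored receptor fingerprints of regions i and j; its exponential decay
  with Euclidean distance, sim = a·e^(−b·d) + c; and the principal
  receptor gradient (PC1 of the z-scored atlas).
- **Spin tests** — spatial-autocorrelation-preserving permutations: parcel
  spherical coordinates are randomly rotated per hemisphere (the right
  hemisphere gets the mirror-conjugate rotation) and each parcel is
  reassigned the value of the nearest rotated parcel. p = (1 + k)/(1 + N).
- **Rewired connectome nulls** — degree-preserving double-edge swaps
  restricted to Euclidean edge-length bins; density, degree sequence and
  per-bin edge counts are preserved exactly.
- **Structure–function coupling** — per region, the adjusted R² of
  regressing the FC profile on the communicability profile
  (exp(S^(−1/2) A S^(−1/2))), with and without the region's receptor
  similarity profile as a second predictor; the gain is tested against
  spun similarity profiles (one-sided, BH-FDR across regions).
- **Multilinear models + dominance analysis** — OLS prediction of a
  regional map from all receptors; model significance against spun
  targets; predictor importance by full-subset dominance: R² of all
  2^p − 1 submodels, each predictor's total dominance = its average
  incremental R², summing exactly to the full-model R².
- **PLS correlation** — SVD of the cross-covariance XᵀY/(n−1) of the
  receptor and term blocks; scores, loadings, covariance explained
  s²ₖ/Σs², singular-value spin significance.
- **Distance-dependent cross-validation** — each region once as a source
  node; train on its 75% nearest regions, test on the remaining 25%, to
  limit spatial leakage.
- **Synthetic data with planted ground truth** (`chemoarch.synthgen`) —
  two-hemisphere spherical parcellations, Gaussian fields with
  covariance σ²·e^(−d/λ), receptor atlases with a planted gradient,
  distance-dependent connectomes with a planted receptor contribution to
  FC, target maps with known active receptors, and paired matrices with a
  planted shared latent component — so every stage above is testable.

The fit-shaped stages are scikit-learn-style estimators
(`MultilinearModel`, `DominanceAnalysis`, `PLSCorrelation`); module-level
functions (`fit_multilinear`, `dominance`, `pls_decompose`, ...) wrap them.

## Worked example

```python
import numpy as np
import chemoarch as ca

geom = ca.generate_parcellation(100, seed=1)
atlas, truth = ca.generate_receptor_atlas(geom, n_receptors=19,
                                          n_latent=1, noise_sd=0.2, seed=2)

pc1, varexp = ca.principal_gradient(atlas)
print(f"PC1 explains {100 * varexp[0]:.1f}% of receptor variance; "
      f"r with planted gradient = {abs(np.corrcoef(pc1, truth.gradient)[0, 1]):.3f}")

sim = ca.receptor_similarity(atlas)
decay = ca.fit_distance_decay(sim, geom)
print(f"similarity decay rate b = {decay.rate:.4f} per mm")

maps, mt = ca.generate_target_maps(atlas, active_set=[0, 4, 9], snr=10, seed=3)
dom = ca.dominance(atlas.densities, maps[:, 0])
print("top-3 receptors by dominance:",
      sorted(np.argsort(dom.total_dominance)[::-1][:3].tolist()))
```

prints

```
PC1 explains 87.6% of receptor variance; r with planted gradient = 0.996
similarity decay rate b = 0.0340 per mm
top-3 receptors by dominance: [0, 4, 9]
```

The gradient of a rank-1 planted atlas is recovered almost perfectly; the
receptor-similarity matrix decays with distance at a rate set by the
generator's 20 mm field length scale plus the atlas noise; and dominance
analysis identifies exactly the three receptors that truly drive the
target map.

A command-line interface mirrors the library:
`chemoarch synth | atlas | nulls | sfc | mlr | pls | run --config config.yaml`.

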