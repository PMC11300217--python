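# sparsemet

Sparse-testing design evaluation for multi-environment trials (METs) with
genomic prediction.

Breeding programs evaluate candidate genotypes across several
location-year environments, but phenotyping every genotype-in-environment
combination is expensive — especially for clonally propagated crops such
as sugarcane, where planting material is scarce. *Sparse testing* observes
only a subset of combinations and predicts the rest with genomic
prediction models. The design question is how to spend a fixed phenotyping
budget: test many genotypes once each (maximal coverage), test few
genotypes everywhere (maximal overlap for learning G×E), or mix the two.

`sparsemet` implements the full experiment for studying that trade-off on
synthetic sugarcane-like trials: a data generator with a controlled
variance structure, marker QC and VanRaden kinship, stage-1 BLUP
adjustment of plot data, the allocation-design algebra, three Bayesian
GBLUP models, and per-environment evaluation of predictive ability.

## The designs

With A non-overlapping genotypes per environment (each tested exactly
once), B overlapping genotypes (tested in all T environments), an `A/B`
design requires (A+B)·T phenotypes covering A·T+B unique genotypes, an
average of (A+B·T)/(A+B) phenotypes per genotype. For 186 genotypes and
T = 6, the fixed-budget spectrum runs from 31/0 (186 unique genotypes,
1 phenotype each) through 16/15 (111 unique, 3.42 each) to 0/31
(31 unique, 6 each). A = 0 realises the CV1 cross-validation scheme —
every predicted genotype is entirely unobserved; all other designs are
CV2-like.

## The models

For adjusted phenotypes y_ij of genotype i in environment j, three nested
random-effect models are fitted by Gibbs sampling:

- **M1**: y_ij = μ + E_j + L_i + ε_ij, with E ~ N(0, Z_E Z_E′ σ²_E),
  L ~ N(0, Z_L Z_L′ σ²_L) — genotypes are independent, so nothing links
  observed to unobserved genotypes.
- **M2**: adds the genomic value g ~ N(0, Z_L G Z_L′ σ²_g), where G is the
  VanRaden genomic relationship matrix W W′ / Σ 2p_k(1−p_k) built from
  marker dosages on the polyploid 0–2 scale.
- **M3**: adds the reaction-norm interaction
  gE ~ N(0, (Z_E Z_E′) ⊙ (Z_L G Z_L′) σ²_gE), the Hadamard product that
  restricts genomic covariance to cell pairs sharing an environment.

Variance components carry scaled-inverse-χ² priors; chains run 12,000
iterations with 2,000 burn-in and thinning 5 by default. Accuracy is the
Pearson correlation between adjusted and predicted values within each
environment, averaged over 10 random partitions.

## Worked example

```python
import sparsemet as sm

config = sm.SimulationConfig(trait_preset="SA-like", seed=7)
markers = sm.simulate_marker_matrix(config)
kinship = sm.vanraden_grm(markers)
truth = sm.simulate_true_signals(markers, config)
phenotypes = sm.simulate_adjusted_phenotypes(truth, config)

design = sm.AllocationDesign(A=16, B=15)          # the 16/15 design
metrics = sm.design_metrics(design.A, design.B, design.T)
print(f"design {design.label}: {metrics.n_phenotypes} phenotypes, "
      f"{metrics.n_unique_genotypes} unique genotypes, "
      f"{metrics.avg_phenotypes_per_genotype:.2f} phenotypes/genotype")

partition = sm.sample_partition(design, list(phenotypes.index),
                                list(phenotypes.columns), seed=1)
fit = sm.fit_model("M3", phenotypes, kinship, partition.calibration,
                   sm.MCMCSettings(seed=1))
result = sm.evaluate_partition(sm.predict(fit, partition, phenotypes),
                               list(phenotypes.columns))
for m in result.per_env:
    print(f"{m.env}: r = {m.pearson_r:.3f}, MSE = {m.mse:.3f} ({m.n_cells} cells)")
print(f"mean accuracy across environments: {result.mean_r:.3f}")
```

prints

```
design 16/15: 186 phenotypes, 111 unique genotypes, 3.42 phenotypes/genotype
E1: r = 0.531, MSE = 0.480 (155 cells)
E2: r = 0.379, MSE = 0.401 (155 cells)
E3: r = 0.377, MSE = 0.509 (155 cells)
E4: r = 0.398, MSE = 0.458 (155 cells)
E5: r = 0.485, MSE = 0.408 (155 cells)
E6: r = 0.439, MSE = 0.498 (155 cells)
mean accuracy across environments: 0.435
```

The 186 calibration phenotypes (16 genotypes unique to each environment
plus 15 common to all six) train M3 to predict the 930 held-out cells; the
per-environment correlations are the predictive abilities a breeder would
act on. `sm.run_grid` repeats this over all 39 (size, design) pairs, three
models and replicated partitions, returning tidy result tables. A `sparsemet`
command-line tool wraps the same steps (`simulate`, `kinship`, `adjust`,
`design`, `fit`, `run-grid`).

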