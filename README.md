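# frogmorph

Phylogenetic ecomorphometrics of anuran skeletal proportions: how much of
the variation in frog skeletons is explained by how they move, where they
live, and who they are related to?

Frogs share a conserved body plan yet span locomotor modes from terrestrial
and arboreal jumping (TJ, AJ) through walking-hopping (WH) and
burrowing (BWH) to aquatic swimming (AQ). This package implements, as a
tested library plus an analysis pipeline, the comparative toolkit used to
dissect that variation in linear skeletal measurements (skull, vertebral
column, pelvis, sacral-diapophysis expansion ESD, limb segment lengths and
widths, iliac angle) across a species-level phylogeny:

- **Size correction** — Mosimann shape variables: each specimen's
  measurements divided by their geometric mean, so shape is dimensionless
  and the log-shape values of a specimen sum to zero.
- **Ordination** — phylogenetic PCA (pPCA) of log-shape under Brownian
  motion, using the GLS mean `a = (1'C⁻¹1)⁻¹1'C⁻¹X` and evolutionary
  covariance `R = (X−1a)'C⁻¹(X−1a)/(n−1)` where `C_ij` is the shared
  root-to-MRCA branch length; and shape PCA (SPCA) in isometry-free shape
  space, with **PCA ratio spectra** — orderings of one axis's loadings in
  which the gap between two variables approximates the variance explained
  by their log-ratio — bootstrapped over species (68% intervals).
- **Inference** — PERMANOVA (Anderson's pseudo-F, Euclidean distances,
  free permutations, pairwise contrasts with Bonferroni adjustment) and
  PGLS with maximum-likelihood Pagel's λ, compared across candidate
  predictor sets by AIC.
- **Discriminant prediction** — classical LDA and phylogenetic flexible
  discriminant analysis (pFDA): class means and pooled covariance
  estimated after whitening predictors and class indicators by the inverse
  Cholesky factor of C(λ), with λ chosen by the whitened-regression
  likelihood; includes case-wise posteriors, secondary-label checks and
  prediction of held-out tips through the conditional phylogenetic
  covariance.
- **Synthetic data** — a generator producing trees (Yule, unit height),
  Mk-evolved locomotor regimes, Brownian traits with regime mean shifts, a
  latent size factor and measurement noise, with full ground truth for
  recovery tests.

## Worked example

```sh
python analysis/01_simulate_dataset.py
python analysis/02_descriptives.py
python analysis/03_ordination_spectra.py
python analysis/04_permanova_pgls.py
python analysis/05_discriminant_prediction.py
```

On the default study-sized dataset (164 species, regime shifts of ~0.16
log-units on ecologically targeted traits) this prints, among other lines:

```
highest size-corrected ESD mean: AQ
highest HL/FL ratio mean:        TJ
pPCA: PC1 43.3%, PC2 7.6%
SPCA full: PC1 32.8%, PC2 21.7%
  PC1 dominant ratio: ESD/tib
PERMANOVA locomotor_mode: F=15.84 R2=0.285 p=0.0010
PGLS PC1: best model 'PC1 ~ LM+Habitat' lambda=0.937 AIC=-71.8
locomotor_mode: LDA 100.0% | pFDA 95.7% (lambda=0.97) | agreement 95.7%
  held-out Neobatrachia predicted (pFDA): {'Hyloidea': 8, 'Ranoidea': 2}
```

Reading this: swimmers carry the widest sacral expansions and terrestrial
jumpers the longest hindlimbs relative to forelimbs, exactly the contrasts
the generator planted; the dominant PC1 ratio (ESD against tibiofibula
length) recovers the planted jumper-versus-swimmer/burrower axis; shape
separates significantly by locomotor mode; PC1 carries strong phylogenetic
signal (λ̂ ≈ 0.94); and the discriminants classify locomotor mode nearly
perfectly at this effect size, with the phylogenetic variant slightly more
conservative. The ten held-out "Neobatrachia" species are assigned to the
derived clades from their morphology alone.

There is also a CLI for single analyses:

```sh
frogmorph simulate --n-tips 64 --seed 7 --out d/
frogmorph permanova --measurements d/measurements.csv --grouping habitat
frogmorph pfda --measurements d/measurements.csv --tree d/tree.nwk
```

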