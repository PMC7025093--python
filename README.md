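# phenoscreen

Single-cell morphological phenotyping and penetrance analysis for
high-content microscopy screens of yeast endocytosis markers.

## The problem

In an imaging screen, each mutant strain is observed as a *population* of
segmented single cells, each described by a table of CellProfiler-style
morphology features (area, shape, intensity, texture of the whole cell, the
screened compartment and the cytoplasm). Most mutant phenotypes are
*incompletely penetrant*: only a fraction of an isogenic population shows
the defect. Population-averaged statistics wash that signal out, so the
analysis has to work cell by cell:

1. **Standardize** every feature per 384-well plate against the wild-type
   control cells grown in the 76 border wells, so one control standard
   deviation is the unit of all downstream thresholds.
2. **Filter** segmentation artifacts: per-feature bounds, images with < 5
   cells, wells with < 2 good fields (of 3), and a 3-class network ensemble
   that removes lone small buds and badly segmented cells when their mean
   artifact probability is ≥ 85%.
3. **Detect outliers without labels**: PCA keeping the fewest components
   explaining ≥ 80% of the variance, a one-class SVM (RBF kernel, ν = 0.5,
   γ = 1/N_PCs) fitted on wild-type cells, and an outlier threshold at the
   20th percentile of the control cells' decision distances. The percentage
   of outlier cells is the strain's *unsupervised penetrance*.
4. **Classify with labels**: per marker, an ensemble of 10 fully connected
   networks (hidden layers 54 and 18, ReLU, softmax, SGD) sharing one
   training set and differing only in initialization. A cell gets the class
   with the highest mean probability, or "None" if that probability is
   below 2/N (N = number of classes). Five-fold cross-validation flags
   training cells misclassified in ≥ 2 initializations as candidate
   mislabels.
5. **Call mutants**: penetrance = 100 × (1 − fraction of wild-type-classified
   cells). The penetrance-mutant threshold is the 95th percentile of the
   wild-type replicate penetrances; a call additionally needs ≥ 50 good
   cells and a Bonferroni-corrected hypergeometric p < 0.05 against the
   pooled wild-type background. The specific-phenotype threshold per class
   is the 98th percentile of wild-type fractions (floored at 0.05), with a
   stringent variant str = (max − thr) × 0.25 + thr; SPM calls also need
   ≥ 10 cells of the phenotype. Genes qualify when half or more of their
   alleles do.
6. **Mine profiles**: per-gene 17-dimensional aberrant-fraction profiles,
   Pearson correlations, average-linkage clustering on 1 − PCC, phenotype
   pair-overlap tests (one-sided Fisher, Benjamini–Hochberg FDR),
   randomized-network complex/pathway enrichment, GO hypergeometric
   enrichment and gene-feature panels.
7. **Explain incomplete penetrance**: replicative-age binning by bud-scar
   intensity (6 bins of 50/25/12.5/6.25/3.125/3.125% of cells) and
   stress-response binning (10 equal-count bins of size-normalized reporter
   intensity) with k-means clustering of the per-strain response profiles.

A synthetic-screen generator (`phenoscreen.simulate`) emulates the full data
model — per-class Gaussian feature distributions, per-plate batch shifts,
border-well controls, strain mixtures with known penetrance, labeled
training sets with optional planted mislabels, and toy annotation standards
— so every stage is testable against planted ground truth without any
imaging data.

## Worked example

Run the default synthetic screen end to end (30 vacuole-marker mutant
strains on one 384-well plate, wild-type controls in the border wells):

```sh
phenoscreen run --seed 3 --out run/
cat run/report.json
```

```json
{
 "seed": 3,
 "marker": "vacuole",
 "n_strains": 30,
 "n_cells": 6434,
 "n_good_cells": 6433,
 "n_pcs": 11,
 "penetrance_threshold": 6.870460048426152,
 "n_penetrance_mutants": 27,
 "n_spms": 27
}
```

Reading the report: 6,433 of 6,434 generated cells pass quality control;
11 principal components explain 80% of the feature variance; the 95th
percentile of the wild-type border-well penetrances calibrates the
penetrance-mutant threshold to ≈ 6.9 penetrance points, and 27 of the 30
planted mutant strains (those with enough cells and penetrance above
threshold) are called both penetrance mutants and specific phenotype
mutants. Per-strain detail is in `run/mutant_calls.tsv`:

```
strain_id    gene_id   allele_id is_penetrance_mutant p           p_bonferroni penetrance_bin penetrance n_good_cells
gene0000-a1  gene0000  a1        True                 1.38247e-51 4.14742e-50  intermediate   67.6471    68
gene0001-a1  gene0001  a1        True                 4.12581e-13 1.23774e-11  low            30.3571    56
```

`gene0000-a1` has 67.6% of its 68 good cells in non-wild-type classes —
an intermediate-penetrance mutant (bin boundaries: high ≥ 75, intermediate
≥ 50, low < 50) — with overwhelming significance against the pooled
wild-type background.

Each stage is also available separately (`phenoscreen simulate | qc |
detect-outliers | train | classify | call | profile | enrich | report`) and
as library functions.

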