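# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they hold, what the synthetic generator does and does not
emulate, and the numerical conventions used throughout.

## Data model

The unit of analysis is the segmented single cell. A `FeatureTable` holds
one row per cell: opaque metadata keys (plate, well, field, strain, allele,
marker, screen type, condition), a `qc_status` flag, and named numeric
morphology features. The default schema mimics what CellProfiler emits for
three segmented objects (whole cell, screened compartment, cytoplasm) —
10 area/shape, 6 intensity and 14 texture measures each, 90 features in
total — but every operation works on any set of named numeric columns.
Two derived features are appended from raw geometry: the fraction of the
cell occupied by the compartment (compartment area / cell area) and the
compartment max/min Feret diameter ratio; zero denominators yield missing
values and a `bad_shape` flag.

The phenotype taxonomy covers four endocytic compartment markers — actin
patch, coat patch, late endosome, vacuole — each with exactly one wild-type
class and respectively 4, 4, 3 and 6 aberrant classes: 21 classes, 17
aberrant, hence 136 unordered aberrant-class pairs.

Missing values are represented explicitly (NaN) and excluded pairwise from
statistics. Filters only ever *mark* `qc_status`; nothing is deleted, and
every downstream statistic consumes `qc_status == "good"` rows only. This
keeps the QC audit trail in the table itself and makes the filters
idempotent.

## Per-plate standardization and quality control

Features are z-scored per plate with the mean and unbiased (n−1) SD of the
good wild-type cells in that plate's control wells (the 76 border wells of
a 384-well plate). This removes additive per-plate batch effects and makes
"one control SD" the unit of all later thresholds. A feature whose control
SD is zero on a plate carries no information there and is dropped for that
plate with a warning.

Hard filters: per-feature bounds (default ±6 control SDs on cell area and
the segmentation-channel mean intensity — the rule class is fixed, the
numbers are configuration because published pipelines do not agree on
them); images with fewer than 5 cells; wells with fewer than 2 good fields
of the 3 acquired. The artifact network filter uses a 3-class ensemble
(wild-type / small bud / bad) and excludes a cell when its mean probability
for either artifact class is ≥ 0.85 — the threshold is inclusive.

Because bounds are interpreted in the table's current units, the pipeline
standardizes before applying them.

## Unsupervised outlier detection

PCA is fitted on the complete good-cell data of a screen (controls plus
mutants — the variance target refers to the whole dataset) and truncated at
the smallest number of components whose cumulative explained variance
reaches 80%. A one-class SVM with RBF kernel, ν = 0.5 and γ = 1/N_PCs is
fitted on the projected wild-type cells; ν = 0.5 deliberately draws a
tight boundary around the densest half of the control population. Signed
decision distances are thresholded at the 20th percentile of the control
distances (linear-interpolation percentile; ties: strictly-below =
outlier, so the rule is deterministic). By construction ≈ 20% of the
calibration controls are flagged; this is the false-positive floor the
percentile choice accepts in exchange for sensitivity to subtle shifts.
The threshold is computed per screen (recomputing per plate is possible by
running the detector per plate, but per-screen is the default because
plate effects are already removed by standardization).

Unsupervised penetrance is the outlier percentage among a strain's good
cells. Its significance is a hypergeometric upper-tail test (equivalently
a one-sided Fisher test) of the strain's outlier count against the pooled
per-screen wild-type background, Bonferroni-corrected over the mutant
strains tested.

## Supervised classification

Each marker's classifier is an ensemble of fully connected networks with
two hidden layers (54 and 18 ReLU units) and a softmax output over the
marker's classes, trained with SGD on the standardized feature vectors
(not the PCA projection). The ensemble members share the training set and
all hyper-parameters and differ only in random initialization; this
whole-training-set ensembling generalizes better for multi-modal loss
surfaces than bagging, and the mean class probability across members is
the cell's score. Optimizer defaults — learning rate 0.01, momentum 0.9,
200 epochs, batch size 32 — are ordinary small-network SGD settings and
are exposed in `ClassifierConfig`; tests and the default pipeline use
fewer epochs and members because the synthetic classes are well separated
and converge quickly. The implementation uses scikit-learn's
`MLPClassifier` for training; trained weights are extracted into plain
arrays, prediction is an explicit ReLU/softmax forward pass, and models
persist as JSON + one `.npz` per member.

A cell is assigned the argmax of the mean probabilities (ties broken by
lowest class index) unless that maximum is strictly below 2/N, where N is
the class count of the marker's classifier (whether N should count only
aberrant classes is ambiguous in principle; counting all classes is the
default and the factor is configurable). With N = 7 the "None" threshold
is ≈ 0.286; with the factor set to 0 no cell is ever "None".

Evaluation uses stratified five-fold cross-validation: each fold is
trained `n_inits` times, so every labeled cell receives `n_inits` held-out
predictions. Cells misclassified in two or more initializations are
flagged as candidate mislabels; by default they are only flagged (the
workflow this mirrors inspects before removing), with `auto_remove` as the
config switch. The validation split (20% of the training portion) is used
for loss monitoring only; early stopping is off by default. Class
imbalance is not reweighted.

## Penetrance and mutant calling

Penetrance is 100 × (1 − wild-type fraction); the "None" class counts as
non-wild-type, consistent with that definition (switchable). Replicate
summaries combine across screen types as the replicate-number-weighted
mean — weights are the biological replicate counts behind each screen-type
estimate, the only reading that lets a genome-wide and a secondary value
combine sensibly. Cell-count support (≥ 50 good cells) is evaluated on the
combined strain.

Thresholds are calibrated from the wild-type replicate distribution
(border wells give hundreds to thousands of WT replicates per screen):

* specific phenotype: thr = max(P98(WT fractions), 0.05); stringent
  str = (max − thr) × 0.25 + thr with max the highest observed fraction of
  that phenotype across all strains of the run (within phenotype and
  condition);
* penetrance: P95(WT penetrances).

All percentiles use linear interpolation between order statistics (one
convention shared with the outlier threshold). By construction ~2% of WT
replicates exceed each SPM threshold and ~5% exceed the penetrance
threshold.

SPM calls require fraction ≥ thr, ≥ 50 good cells and ≥ 10 cells of the
phenotype; stringent SPMs use str. Penetrance-mutant calls require
penetrance ≥ threshold, ≥ 50 good cells and Bonferroni-corrected
hypergeometric p < 0.05, the family being the mutant strains tested per
marker and condition (configurable). Called mutants are binned high
(≥ 75), intermediate (≥ 50) or low (< 50). Gene-level consensus requires
half or more of a gene's alleles to qualify; consensus penetrance is the
maximum over qualifying alleles.

Replicate reproducibility uses TP/TN/FP/FN counts over replicate pairs
(accuracy = (TP+TN)/total, FPR = FP/(FP+TN), FNR = FN/(FN+TP)); both
replicates qualifying is a TP, neither a TN. For discordant pairs the
first replicate of the pair is treated as the reference (reference
positive → FN, reference negative → FP), which makes the split
deterministic for ordered pairs.

The bootstrap minimum-cell-count samples n cells with replacement (grids
10–100 by 10 and 125–1,000 by 25; 100 samplings) and reports the first n
whose relative SD of penetrance falls below 0.2. For a Bernoulli outlier
process the closed form is rel SD = sqrt((1−p)/(np)), which the sampled
SDs track within sampling error; a generative mode draws binomially from a
given p instead of resampling flags.

## Profile mining

A gene's phenotype profile is its 17-vector of aberrant-class fractions,
averaged across alleles; genes missing any of the four markers are
excluded from correlation analyses. Profile similarity is the Pearson
correlation; clustering is average linkage on 1 − PCC. Phenotype-pair
overlap uses one-sided Fisher tests with Benjamini–Hochberg FDR
(significant at p < 0.05, q < 0.2). Dendrograms export as Newick.

Randomized-network enrichment: per (phenotype, term), the observed overlap
P1 and a one-sided Fisher p are compared against overlaps in randomized
phenotype–gene association networks; a record is significant when
p < 0.05 *and* P1 exceeds the 95th percentile of the randomized overlaps.
For the shared-SPM sets of phenotype pairs the rule is p < 0.01, at least
2 shared components, and the same null-percentile condition. The default
null redraws each phenotype's hit set uniformly from the universe
(preserving set sizes); a degree-preserving bipartite shuffle (also
preserving per-gene phenotype counts) is provided because the exact
randomization scheme is genuinely open — with a single phenotype the
degree-preserving null is degenerate, so the label-permutation null is
the default. 1,000 randomizations by default, seeded.

GO enrichment is the hypergeometric upper tail with Bonferroni correction
and fold = (hits in term / hits) / (term size / universe). Gene-feature
panels use one-sided Mann–Whitney U for numeric features — reported as the
median z of hits under a robust normalization by the median and SD of
non-hits, which centres non-hits at 0 — and one-sided Fisher for binary
features, reported as log(f_hits/f_nonhits) (natural log; 0 when the
fractions are equal). Category-wise profile-similarity comparisons (e.g.
direct contact vs indirect contact vs different complex, or co-complex /
co-pathway / co-expressed) group the pairwise PCCs by category and apply
one-sided Mann–Whitney tests between categories; the same machinery with
complexes as categories yields mean within-complex profile PCCs. The gene
universe defaults to all screened genes in the run.

## Incomplete-penetrance covariates

Replicative age: cells are sorted by bud-scar (WGA) staining intensity and
cut at cumulative fractions 50, 75, 87.5, 93.75, 96.875 and 100% — a
halving scheme whose bins correspond approximately to 0, 1, 2, 3, 4 and
≥ 5 divisions; the oldest bin holds 3.125% of cells (printed 3.13%). For
populations not divisible by 32 the cut uses floors with the remainder in
the final bin, which conserves cell counts deterministically. Per-bin
outlier fractions and their ratio to wild type (missing where the WT bin
fraction is 0) are the outputs; bins are reported as bins, not ages.

Stress response: reporter intensity is divided by cell area (cell-size
normalization), cells are sorted into 10 equal-count bins, and the
per-bin outlier fraction forms the strain's response profile. Profiles are
clustered with k-means (fixed seed); k is a free parameter chosen by the
analyst per marker. Outlier flags may come from the unsupervised detector
or from classifier non-wild-type assignment; the source is a parameter.

## Synthetic screens

The generator emulates: per-class multivariate Gaussian feature
distributions (spherical, unit variance; a heavy-tailed Student-t option
with matched variance exists because real morphology features are skewed
and the percentile logic should be exercised under both); aberrant-class
means placed `separation` control SDs from the wild-type mean along
class-specific random directions (default 6 — clearly separated but
overlapping in single features); additive per-plate batch shifts (SD 0.5
control units); 384-well plates with wild-type controls in all 76 border
wells; 3 fields per well with Poisson cell counts (default mean 20 per
field, ≈ 60 cells per well — the order of magnitude of a well-imaged
strain); strain mixtures with exact known penetrance; labeled training
sets with optional planted label swaps; covariate intensities linked to
outlier probability through a calibrated logistic; and toy annotation
standards whose terms are planted gene groups plus random decoys.

It does **not** emulate: correlated feature blocks, segmentation-error
artifacts with structured feature signatures, spatial plate gradients
(shifts are plate-wide), cell-cycle structure, or multiplicative batch
effects. Passing tests therefore demonstrate the correctness of the
statistical machinery under the stated model, not performance on real
imaging data, where class overlap, feature correlation and non-Gaussian
tails make accuracies and thresholds dataset-dependent.

## Numerical conventions and problem sizes

Percentiles: linear interpolation everywhere. Ties at the outlier
threshold: strictly below = outlier. Argmax ties: lowest class index.
SD: unbiased (n−1). Binary log-fold: natural log. Half-up rounding for
printed percentages (3.125 → 3.13). Every stochastic step takes a seed;
the pipeline derives all stage seeds from the single run seed and echoes
them in the run log.

The shipped tests and the acceptance script run the method at desk scale —
thousands of cells, tens of strains, hundreds of wild-type replicates,
ensembles of 2–3 members trained for 30–60 epochs — sizes chosen so the
full suite exercises every stage end to end in well under a minute per
module while leaving the production defaults (10 members, 200 epochs,
full plates) available in configuration.

## Known limitations

* The calling thresholds assume abundant wild-type replicates; below ~20
  the calibration warns and percentiles are noisy.
* The Bonferroni family for penetrance significance is a configuration
  choice; there is no automatic handling of strains screened in multiple
  conditions.
* The degree-preserving enrichment null requires at least two phenotypes
  to be non-degenerate.
* `evaluate_cv` reduces the fold count when a class has fewer cells than
  folds (with a warning) rather than failing.
* The classifier persists weights, not training state; retraining a loaded
  model is not supported.
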