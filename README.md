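# chromtx

Two-step chromatin-feature models of gene expression.

Histone modifications, the histone variant H2A.Z, and DNase I hypersensitivity
track transcriptional activity closely enough that gene expression can be
predicted from chromatin signal alone. `chromtx` implements the modeling
framework behind that observation as a reusable library and command line for
regulatory genomicists: it bins chromatin signal over extended gene models,
finds each feature's most informative bin, optimizes log-transform
pseudocounts, and fits a two-step predictor that handles the large fraction of
silent promoters explicitly.

## The model

For gene *i* and chromatin feature *j*, let X<sub>ij</sub> be the mean signal
density of feature *j* in its selected bin. Expression is predicted as

  ŷ<sub>i</sub> = C(X<sub>i</sub>) · R(X<sub>i</sub>)

where

* **C** is a random-forests classifier of expression status (1 = "on",
  0 = "off"). Roughly 40% of promoters in a typical dataset are not expressed
  at all; regressing over that point mass at zero directly would bias a single
  model, and the features that switch genes on (promoter marks: H3K4me3,
  H3K9ac, DNase) differ from those tracking expression level.
* **R** is a regressor — linear by default — of log₂ expression, fitted on
  expressed genes only: log₂(y<sub>i</sub>) = b₀ + Σ<sub>j</sub> b<sub>j</sub>
  log₂(X<sub>ij</sub> + a<sub>j</sub>) + ε. Structural marks (H3K79me2,
  H3K36me3) dominate this step.

Two preprocessing choices are themselves fitted, on a held-aside selection set
D1 (one third of genes; the remaining two thirds, D2, are modeled under
ten-fold cross-validation):

* **bestbin** — each gene longer than 4,100 bp is extended by 2 kb on each
  side and cut into 81 bins (40 × 100 bp across the TSS flank, one gene-body
  bin, 40 × 100 bp across the TTS flank; 41 bins in TSS-anchored mode). The
  bin whose signal correlates most strongly (in absolute value) with
  expression becomes the feature's representative. Fixed alternatives
  (`tssbin`, `allbins`, `best5bins`) are provided for comparison.
* **pseudocount** — a<sub>j</sub> is chosen from a log-spaced grid spanning
  0–20% of the feature's maximal signal to maximize the correlation of
  log₂(X + a) with log expression. A rankit (normal-scores) transform is
  available as the pseudocount-free alternative.

Accuracy is reported as Pearson's r and RMSE between measured and predicted
log₂ expression on pooled out-of-fold predictions (zeros included on both
sides), plus the classifier's AUC. Per-feature contributions come from the
LMG R² decomposition (linear regressor) and Gini impurity decrease (forests).
Randomization controls (shuffled expression, independently shuffled feature
columns, swapped feature labels at test time), cross-context model transfer,
feature-category subsets, CpG-class strata, and cumulative expression-decile
analyses are built in.

Because the framework is validated end-to-end on synthetic data, the package
ships a first-class generator (`chromtx.simulate`) that plants known
informative bins, on/off logit weights, level coefficients, and noise — so
every claim above is testable against ground truth without any downloads.

## Worked example

Simulate a 1,000-gene dataset at the default study conditions (40% silent
genes, planted achievable correlation 0.9), then cross-validate the two-step
model:

```
$ chromtx simulate --n 1000 --seed 7 --out example
wrote 1000 genes, 13 features to example (achievable r=0.900, zero fraction=0.405)

$ chromtx cv example --seed 7
{
 "pcc_r": 0.8657189319093789,
 "rmse": 1.088821793569952,
 "auc": 0.9110015957946119,
 "classification_accuracy": 0.8470764617691154,
 "n_genes": 667
}
```

The pooled out-of-fold correlation (0.87 at this desk scale; ≈0.90 at
n = 5,000) approaches the planted ceiling of 0.9 — the model recovers nearly
all the predictable signal. `chromtx fit` prints the fitted level regression;
structural marks carry the largest slopes, as planted:

```
$ chromtx fit example --seed 7 --out example_model
Two-step expression model
============================================================
method: linear    seed: 7
genes: 667  on: 402  off: 265
level-regression R^2 (training, on genes): 0.7867
------------------------------------------------------------
feature                     coef     std err
const                   -18.0159      1.2415
DNase                     0.5836      0.0586
...
H3K36me3                  0.7554      0.0391
H3K79me2                  1.4278      0.0761
...
```

The same objects are available as a library:

```python
from chromtx import simulate_dataset, make_split, FeatureTransform, crossvalidate

ds = simulate_dataset(n=1000, seed=7)
plan = make_split(list(ds.gene_ids), seed=7)
ft = FeatureTransform().fit(ds.binned, ds.y, plan.d1_ids)   # bestbin + pseudocount on D1
X = ft.transform(ds.binned)                                  # genes x features, log2(x + a)
cv = crossvalidate(X, ds.y, plan, method="linear", seed=7)   # ten-fold CV on D2
print(cv.result.pcc_r, cv.result.auc)
```

Real data enter through the same surface: `chromtx annotate` (GTF/BED12 +
FASTA → filtered TSSs with CpG classes), `chromtx quantify` (CAGE/RNA-PET-style
tag counting in 101 bp TSS windows, RPM-normalized), `chromtx bin`
(bedGraph/bigWig → genes × bins matrices), and `chromtx run` (staged pipeline
from a YAML config, with a content-hash manifest and byte-reproducible
outputs).

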