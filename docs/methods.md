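# Methods

This note documents the models and procedures implemented in
`methsubtype`, the parameters that matter, the synthetic data they are
validated on, and the numerical choices made where the design was open.

## Preprocessing

Beta values are computed as `β = M / (M + U + offset)` with offset 100
(configurable; 100 is the conventional regularizer for 450K arrays). With
a positive offset the output is strictly below 1 for finite intensities;
`β = 1` is unreachable, which the intensity generator enforces as a
precondition. Probe QC removes a probe when its detection p-value exceeds
0.05 in strictly more than 5% of samples (a probe failing in exactly 5%
is kept). Blacklisting removes sex-chromosome (X/Y) and SNP-overlapping
probes in one pass, preserving the order of survivors.

Quantile normalization is plain column normalization: each column is
mapped onto the row-wise mean of the per-column sorted values, preserving
within-column ranks. Ties receive the average of the target values over
the tied ranks, so equal inputs stay equal and the map is idempotent up
to tie handling. This deliberately replaces stratified, probe-type-aware
normalization (which needs array-internal metadata the package does not
consume): the contract — identical post-normalization distributions across
samples — is the same.

## Similarity network fusion and label transfer

Per view, samples are z-scored per feature and the scaled exponential
kernel is applied to the squared-distance matrix:

    W(i,j) = exp( −d²(i,j) / (μ · ε(i,j)) ),
    ε(i,j) = ( mean_{k∈KNN(i)} d²(i,k) + mean_{k∈KNN(j)} d²(j,k) + d²(i,j) ) / 3

The kernel operates on squared distances throughout (both in the exponent
and in ε), a self-consistent convention matching the reference SNF
implementations. Defaults: K = 51 neighbours, μ = 0.85. For cohorts with
n ≤ K the neighbour count is clamped to n − 1 with a logged warning.

Fusion is cross-diffusion between the views' transition kernels: P is the
full kernel with diagonal ½ and off-diagonal row mass ½; S is the
row-normalized K-NN mask; each of t = 120 iterations updates
`P_v ← S_v · mean(P_other) · S_vᵀ`, re-normalizes, and symmetrizes; the
final fused affinity is the average of the views' P.

Spectral clustering is the standard normalized (NJW) construction:
symmetric-normalized Laplacian, bottom-k eigenvectors, row normalization,
k-means with 50 restarts at a fixed seed (ties in eigenvalues resolved by
index order from the symmetric eigensolver). k = 4 by default, one
cluster per subgroup.

NMI is normalized by the geometric mean of the entropies,
`I(a;b)/√(H(a)H(b))`, with the convention NMI = 1 when both labelings are
constant. Cluster-to-subgroup relabeling solves the maximum-agreement
assignment exactly with the Hungarian algorithm on the contingency table
rather than greedily — greedy majority matching is ambiguous when no
cluster dominates a class.

The fused labels replace the original labels **for training only**. All
evaluation is against the original labels; the pipeline enforces this
asymmetry so that label switching in the fusion step cannot inflate
reported metrics.

## Feature selection

The variance screen ranks probes by unscaled MAD,
`median |x − median(x)|` (the 1.4826 consistency factor never changes
ranks), keeping the top 5,000; ties break lexicographically by probe id
so the ranking is total and reproducible. The importance stage grows a
300-tree random forest and ranks probes by out-of-bag permutation
importance computed per class and averaged: for each tree, each feature
the tree actually splits on is permuted among the tree's out-of-bag
samples and the drop in per-class OOB accuracy is recorded; unused
features contribute exactly zero for that tree. This is the classic
mean-decrease-in-accuracy importance, restricted to used features for
speed (the restriction is exact, not an approximation). Impurity (Gini)
importance is available as `method="gini"`. The panel size (default 399)
and screen size (5,000) are configuration defaults, not derived
quantities.

## Class balancing

SMOTE creates `perc_over/100` synthetic samples per minority sample by
interpolating toward one of its k = 5 nearest minority neighbours with a
fresh U(0,1) weight, so every synthetic coordinate lies within the
segment between its two parents (asserted per point in the tests). The
default workflow oversamples the training partition only; a
`oversample_before_split` flag instead oversamples the full cohort before
splitting, which reproduces a common but leakage-prone ordering and is
documented as such. A balancing wrapper can also top up every non-majority class toward
the majority size using whole SMOTE rounds.

## Classifiers

All seven families share one train/predict contract (labels, class
probabilities summing to 1, low-confidence flags). Fixed hyperparameters:
RF 300 trees with at most 6 terminal nodes per tree; KNN k = 3; naive
Bayes flags predictions whose maximum posterior is below 0.8 (the argmax
label is still emitted — there is no reject class); SVM uses an RBF
kernel with library-default C and γ; XGBoost and LDA use library
defaults. All resolved values, including library defaults filled in at
run time, are written to the run log.

The neural net is a compact numpy feed-forward implementation: dense
layers of 40, 30, 10, and k units; leaky-ReLU (slope 0.3, the common
Keras default) on the hidden layers and softmax on the output; inverted
dropout at rates 0.5/0.4/0.1; an L2 penalty of 0.009 on the second
layer's weights; categorical cross-entropy; mini-batch SGD (batch 16)
with Nesterov momentum 0.05, learning rate 0.03 decayed per optimizer
step as `lr/(1 + 6·10⁻⁵·step)` (per-step rather than per-epoch decay — the
convention of the SGD implementations this mirrors); at most 200 epochs
with early stopping after 5 epochs without validation-loss improvement,
restoring the best weights. A NaN/inf training loss aborts with guidance
to lower the learning rate. He-normal initialization from the config
seed makes training deterministic.

## Evaluation

Confusion matrices have true classes as rows. Per-class metrics are
computed one-vs-rest from TP/FP/TN/FN with the elementary formulas;
undefined ratios (0/0) are reported as NaN, never silently as 0, and the
macro row is the plain mean of the per-class values. Per-class accuracy
is one-vs-rest accuracy — the only reading under which per-subgroup
accuracy rows can differ. Multiclass AUC is the Hand–Till construction:
the mean over unordered class pairs of the symmetrized rank-based
pairwise AUC, with ties given half credit.

The PCA decision grid fits a 2-component PCA on the training set only,
projects both sets, and retrains a fresh classifier of the same
family/configuration on the projected training data to label an
r × r grid spanning the projected ranges with a 5% margin — classifying
in PC space, matching how such decision-boundary plots are constructed.
t-SNE embedding and the clustered-heatmap export (correlation distance,
average linkage, leaf orders only) are thin, seeded wrappers over
scikit-learn/scipy; rendering is left to any plotting layer.

## Shapley interpretation

The Štrumbelj–Kononenko sampling estimator: each of m draws samples a
feature permutation and one background row, walks the permutation
switching features from the background value to the instance value, and
credits each feature with the induced change in predicted probability
(one batched model call of d + 1 points per draw). Contributions are
averaged over draws; Monte-Carlo standard errors are reported per
(feature, class). The default m = 1,000 keeps the local-accuracy residual
(Σφ vs prediction − baseline) within ~3 standard errors on the bundled
benchmarks. Explanations are on the probability scale per class, not the
logit scale, so per-subgroup panels are directly comparable. One instance
per subgroup is explained, with contributions reported for every class.

## Gene networks

Edges enter the correlation graph iff Pearson r is strictly above 0.6 (an
edge at exactly the threshold is removed); self-loops and duplicates never
enter; vertices with fewer than two remaining edges are removed in a
single pass (not iterated to a k-core — the filters are applied once, in
order). Vertex display size is mean beta × 10. Constant genes, whose
correlation is undefined, are excluded with a warning. The minimum
spanning tree uses Prim's algorithm under weight 1 − r, so the tree
retains the strongest correlations (the weight direction is a package
choice; the alternative would keep the weakest). Communities are
Girvan–Newman: edges of maximal betweenness are removed iteratively (ties
broken by the lexicographically smallest edge, making the procedure
deterministic) and the partition with maximal unweighted modularity over
the whole removal sequence is returned.

Cluster augmentation greedily appends candidate genes in rank order
(global forest-importance rank by default) and keeps an addition iff
macro-F1 improves by at least `min_gain` (default 0.01), stopping when
every per-class F1 reaches the target; every trial is recorded in a
trace.

## Survival analysis

Each biomarker is dichotomized at the candidate cut-off (mean, median,
lower/upper quartile) whose Cox fit maximizes |log HR| of the
methylation-group coefficient — the absolute value so that protective
markers are captured too — subject to both groups holding at least 10% of
samples (the floor prevents degenerate cut-offs with inflated HRs). Cox
models adjust for age, sex, and subgroup (one-hot against a reference
class, default WNT), use Efron tie handling via lifelines with a
tightened Newton tolerance (1e-9) so small-sample estimates match the
partial-likelihood optimum to ~1e-4, and report per-coefficient HRs with
95% CIs and Wald p-values plus the model likelihood-ratio test. The
log-rank test is the standard k-group chi-square; Kaplan–Meier curves are
product-limit estimates per group. Raw p-values are reported; multiple-
testing correction across a 399-marker panel is left to the caller.

## Synthetic data

The generator emulates the statistical shape of a 4-subgroup 450K cohort.
Informative probes draw a random non-constant hyper/hypo pattern over the
subgroups with beta means 0.5 ± δ/2; values are sampled on the logit
scale with Gaussian noise (σ = `noise_sd`) and inverse-transformed, which
keeps betas in [0, 1] and reproduces the bimodality of real arrays (noise
probes get bimodal baselines at logit ±2). The expression view mixes a
random linear map of the one-hot subgroup factor with unit-variance noise
at weight `coupling` (first half of the genes; the rest are pure noise),
giving the two views a shared latent block structure so SNF fusion is
testable. Intensities invert the beta formula exactly under a log-normally
jittered total intensity (falling back to the U = 0 solution where the
jitter cannot reach the target), and detection p-values are near zero
except on designated failing probes. Survival times are exponential with
per-subgroup rate `0.1 · exp(log_hr)` per year and independent
exponential censoring calibrated to the requested censoring fraction.

Default cohort composition is {WNT: 70, SHH: 200, Group3: 150,
Group4: 343}: the minority size (70) and total (763) mirror the reference
cohort structure this generator emulates; the split among the other three
subgroups is an arbitrary, documented choice (their true sizes are not
published). Defaults δ = 0.4 and noise 0.05 give a clearly separated
cohort — the regime in which the pipeline's contracts (NMI 1.0, ≥ 95%
balanced accuracy for all families) are asserted.

What passing these tests shows: the machinery is implemented correctly —
counts, formulas, and oracle equivalences hold, signal present in the
data flows through selection, fusion, and classification without leakage
(the label-permutation control sits at chance, 0.25 balanced accuracy).
What it does not show: performance on real cohorts, which carry batch
effects, probe-type bias, continuous subgroup gradients, and much weaker
effect sizes than the generator's clean block structure. Cohort-level
published accuracies are external-data claims and are deliberately not
asserted anywhere in the suite.

## Problem sizes and tolerances

Test and acceptance workloads are sized for a single CPU: SNF benchmarks
use 60–200 samples with the full 120 iterations; the feature-count chain
uses 6,000 probes × 200 samples; the classification benchmark uses the
default 763-sample imbalanced cohort with a 300 → 60 probe chain; Cox
oracles use n ≤ 8 fixtures (agreement to 1e-4), the log-rank oracle
agrees to 1e-6, MST is checked against exhaustive enumeration on graphs
of ≤ 6 vertices, and Shapley sampling is checked against full coalition
enumeration at d = 4 within 3 Monte-Carlo standard errors. Macro-level
accuracy assertions use balanced accuracy (macro-averaged recall), whose
chance level is 1/k = 0.25 regardless of class imbalance.

## Known limitations

- No IDAT parsing, background/dye-bias correction, or probe-type
  normalization; the package consumes matrices.
- SNF is implemented for two views (methylation + expression); weighted
  >2-view schemes are out of scope.
- The SVM/XGB/LDA hyperparameters beyond those fixed above are library
  defaults — recorded in the run log rather than tuned.
- Survival analysis assumes proportional hazards and right censoring;
  time-dependent covariates and competing risks are not modelled.
- Girvan–Newman community detection is O(E²·V)-ish and intended for the
  small (tens of genes) networks produced after correlation filtering.
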