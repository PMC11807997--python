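# Methods

## The analysis model

`uromet` implements the canonical untargeted-metabolomics staging workflow
for a three-group case-control design. Its statistical core is the
OPLS-DA/VIP screen: for each pairwise stage comparison (CN-AD, CN-MCI,
MCI-AD, reference always the earlier stage) the complete, autoscaled
feature matrix X (samples × features) is decomposed as

    X = t_p p_pᵀ + Σ_o t_o p_oᵀ + E,

where the orthogonal components (t_o, p_o, w_o) carry systematic variation
uncorrelated with the class indicator and the single predictive component
t_p = X_filtered w carries all class-correlated variation. The predictive
weight starts from w ∝ Xᵀy; each orthogonal round computes p = Xᵀt/(tᵀt),
w_o ∝ p − (wᵀp)w, t_o = Xw_o, p_o = Xᵀt_o/(t_oᵀt_o) and deflates
X ← X − t_o p_oᵀ. By construction t_p is exactly orthogonal to every t_o
(asserted to 1e-8 in the tests). The response is the centred 0/1 group
indicator; R²Y = 1 − RSS/TSS on that response. With zero orthogonal
components the predictive scores coincide with the first NIPALS PLS-DA
component — an equivalence the suite asserts to 1e-8.

Variable importance uses the predictive component only:
VIP_j = √p · |w_j| / ‖w‖, which makes mean(VIP²) = 1 an exact algebraic
identity on every fit. This variant was chosen over multi-component VIP
because the screen is defined on the first (predictive) component.

Model validity is assessed two ways. Q² = 1 − PRESS/TSS from stratified
k-fold cross-validation (default 7 folds) in which both the scaling
parameters and the model are refit inside each training fold, held-out
samples being scaled with training parameters. The permutation test refits
the full model — including Q² — under uniformly permuted labels (default
200 permutations, same orthogonal-component count as the observed model,
a like-for-like null) and reports p = (1 + #{null ≥ observed})/(n_perm+1),
so 1/201 is the smallest attainable p and is attained on separable data.

## Screen, enrichment, staging

A feature is differential for a comparison when all three hold strictly:
VIP > 1, two-sided Wilcoxon rank-sum p < 0.05 (exact enumeration when both
groups ≤ 8 and untied, tie- and continuity-corrected normal approximation
otherwise), and fold change outside [0.8, 1.25]. Fold change is the ratio
of raw-intensity arithmetic means with the later disease stage in the
numerator; a zero reference mean flags the record and forces "ns". The
three criteria are conjunctive, so relaxing any one can only increase call
counts (tested). No multiple-testing correction enters the call itself —
that mirrors the screening protocol this pipeline operationalises — but a
Benjamini-Hochberg column is emitted for information.

Pathway over-representation is the hypergeometric upper tail over a
background of annotated, QC-passing features, with ion modes merged
(pathway identity is mode-agnostic) and BH adjustment across tested
pathways. Zero overlap reports p = 1.

The staging model selects up to 10 key metabolites per comparison with a
CART classification tree (Gini impurity, depth ≤ 5, fixed seed) fitted on
the autoscaled differential features restricted to those annotated to
significantly enriched pathways (raw p < 0.05); if that restriction leaves
fewer than 10 candidates the tree sees all differential features. Features
are ranked by total impurity decrease, ties broken by smaller screening p
then feature id, and a panel shorter than 10 (shallow trees often split on
few features) is padded from the VIP ranking. A logistic regression with a
weak L2 penalty (strength 1e-4, i.e. C = 1e4) on the autoscaled panel
gives the staging probability; the penalty exists purely to keep the MLE
finite under complete separation, which the planted cohorts regularly
produce. The headline "combined AUC" is computed on the modelling data, as
is conventional for this design; the honest generalisation estimate is the
200-iteration stratified 70/30 resampling report (AUC and 0.5-threshold
accuracy on each held-out split, model and scaling refit per split). AUC
uses the rank formula with 0.5 credit for ties and is asserted equal to
the trapezoidal area under the constructed ROC curve and to brute-force
pair counting.

## Preprocessing

QC CV is computed per feature on raw QC intensities with the sample (n−1)
standard deviation — CV is conventionally a raw-scale metric — and
features with CV strictly above 0.30 are removed ("over 30%" read as
strict). Undefined CVs (zero mean, fewer than two observed replicates) are
excluded. Filtering precedes imputation because the QC CV needs observed
QC values.

Imputation is KNN within each diagnostic group independently, with
k = max(1, round(0.10 · group size)) (round half-up). The sentence that
ties k to the group size is read as also restricting the donor pool to the
group, which avoids borrowing values across diagnostic groups. Distance
between samples is the Euclidean distance over features observed in both,
divided by the shared-feature count (root mean squared difference), so
sparsely overlapping samples are not spuriously close; ties break on
sample id for determinism. The imputed value is the unweighted mean of the
k nearest donors observed for that feature, skipping donors that lack it.
A caveat the null-calibration experiments made explicit: on data with *no*
group differences, group-wise imputation still imprints weak group
structure (imputed cells shrink toward local group means), enough to lift
a null staging AUC above 0.6 at 10% missingness. The model-calibration
null experiments therefore simulate without missingness; the screen's
false-call control is tested with missingness present.

## The synthetic cohort generator

The generator is the package's ground-truth instrument, not a fixture. Per
feature i, a baseline log-intensity μ_i ~ N(13, 1) (natural log; ~4×10⁵
raw units, a typical LC-MS peak-area magnitude) and a biological
within-group log-sd of 0.4 (≈ 42% CV, mid-range for urine features).
A planted effect (feature, comparison, FC) adds ln FC to the case group's
mean, so the ratio of group means equals FC in expectation — verified by
Monte-Carlo at n = 500/group to 5%. Defaults follow the staged design the
package targets: groups 62/43/57, 80 negative- and 120 positive-mode
features, 20 pooled-QC injections, and 20 planted effects per comparison
(10 at FC 2.0, 10 at FC 0.5), disjoint across comparisons.

QC replicates are log-normal around the pooled biological mean with a
mean-preserving parameterisation whose CV is exactly the feature's
technical CV; 5% of non-planted features draw their CV from (0.35, 0.60)
(the filter-worthy stratum; planted features are kept below the threshold
so preprocessing cannot silently delete the ground truth), the rest from
(0.05, 0.25). Missingness combines left-censoring (cells below the 5th
intensity percentile drop with probability 0.5) with 2% missing completely
at random, applied to biological samples. The pathway map has 12 pathways
of 10 metabolites; three are "enriched": 8 of their 10 members are planted
features of one comparison each, the rest drawn from never-planted
features.

One property of this design is worth stating plainly: a feature planted
for CN-AD shifts only the AD group, so it is genuinely differential in the
MCI-AD contrast too, and with FC = 2.0 no assignment of three group means
can confine an effect to a single contrast (the no-call band allows at
most 1.25² < 2 across two steps). Recovery is therefore scored per
comparison against that comparison's own planted set, false calls are
counted only among never-planted features, and pathway recovery asks that
each comparison's own enriched pathway outranks every background pathway.

What the generator does **not** emulate: feature-feature correlation
(metabolites of a shared pathway co-vary in real urine), batch and drift
effects, creatinine/dilution variation, retention-time or adduct
structure, and non-log-normal heavy tails. Passing tests therefore show
that the algorithms recover what the model plants under realistic noise,
missingness and technical-QC conditions — not that real cohorts will
behave as cleanly.

## Numerical and design choices

- Scaling: log₁₀(x + 1e-9) then mean-centring and unit-variance (n−1)
  scaling. Constant features are flagged and given scale 1. Autoscaling
  after log transform is the default for untargeted LC-MS; the transform
  is configurable off.
- One orthogonal component by default; at the default cohort's effect
  sizes additional components do not improve Q² by a meaningful margin.
  Permutation refits reuse the observed component count.
- Predictive score signs are fixed so the later disease stage has positive
  mean score (reproducible plots); orthogonal components are sign-free.
- Chi-square tests use no continuity correction — the convention that
  reproduces the reference staged cohort's covariate p-values from its
  printed counts, all nine to three decimals.
- Kruskal-Wallis is used as the three-group omnibus before pairwise
  Mann-Whitney U tests (Bonferroni factor 3); the normality gate is
  Shapiro-Wilk per group at α = 0.05, with n < 3 or constant groups routed
  non-parametric with a warning. Hotelling's T² is reserved for
  low-dimensional summaries; its one-dimensional case equals the squared
  pooled-variance t statistic (asserted numerically).
- Seeds thread explicitly through every stochastic step (simulation,
  cross-validation folds, permutations, tree, resampling); default 20250127.

## Problem sizes and runtime

The default cohort (162 biological samples + 20 QC, 200 features) runs the
full pipeline, including 200-permutation tests for six mode × comparison
models and 200 resampling iterations for three staging models, in well
under a minute on one CPU. The replicated experiments use deliberately
modest sizes chosen to keep their Monte-Carlo error small relative to the
margins they certify: 5 replicate cohorts for the VIP rank correlation
(Spearman over 20 planted features is noisy in any single cohort), 20
repeats for pathway-enrichment ranking, 20 seeds for key-panel recovery,
and 40-100 null repeats at 50 permutations for the calibration checks.

## Known limitations

- The screen's error control is per-comparison and uncorrected by design;
  the BH column is informational.
- "Combined AUC" on the modelling data is optimistically biased; use the
  resampling report for generalisation claims.
- Group-wise KNN imputation can imprint group structure (see above); with
  heavy missingness consider reporting the imputation-free sensitivity.
- OPLS-DA handles binary contrasts only; the three-group view comes from
  the overall PLS-DA and the three pairwise models, not a multi-class
  OPLS.
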