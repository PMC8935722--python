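# Methods

## The problem

Given a training set of N individuals with binary case/control outcomes
y ∈ {0,1} and p biallelic SNPs coded additively (0 = homozygous
reference, 1 = heterozygous, 2 = homozygous variant), a genetic risk
score is a fitted function GRS: {0,1,2}^p → [0,1] estimating
P(Y = 1 | x).  The package constructs such scores with five learners and
evaluates them on independent test data.  All construction uses genetic
data only; environmental covariates enter the association analysis but
never the score.

## Data model and codings

Genotype matrices reject missing values and entries outside {0,1,2} at
load time — the generative framework has no missingness, and silently
imputing would change every downstream estimate.  Two codings are
derived from the additive matrix:

* additive (identity) — used by forests and, by convention, the elastic
  net;
* dominant/recessive binarization, SNP_D = 1(SNP ≠ 0) and
  SNP_R = 1(SNP = 2), interleaved per SNP — used by logic regression
  and available to the elastic net as the `binary_01` coding.  The
  recessive column is elementwise ≤ the dominant one, and the pair is a
  lossless recoding (R=1 → 2; D=1,R=0 → 1; else 0).

A PLINK `.raw`-style reader is included; its PHENOTYPE column uses the
1=control/2=case dialect, and codes 0/−9/NA raise an error rather than
becoming silent missing values.

## The simulator

Replicate case-control datasets are generated from logistic models over
independent SNPs (emulating LD-pruned/clumped panels):

1. **marginal**: logit P(Y=1) = β₀ + Σᵢ₌₁⁶ βᵢ·SNP_{i,D} with a common
   odds ratio exp(βᵢ) ∈ {1.2, 1.5, 1.8}; 4/14/44 noise SNPs;
   N ∈ {500, 1000, 2000} — a 27-setting sweep.
2. **gene-gene**: three marginal SNPs at OR 1.2 plus
   β₄·SNP_{j,D}·SNP_{k,D} with OR ∈ {1.2,…,2.4}, (j,k) ∈ {(1,2), (1,4),
   (4,5)} (both / one / neither interacting SNP has a marginal effect);
   5/15/45 noise SNPs; N = 2000 — 45 settings.
3. **gene-environment**: marginal ORs 1.2/1.5/1.8, a fixed
   SNP1×SNP4 interaction (OR 1.8), a marginal environmental variable E1
   (OR 1.2 per IQR) and an interaction E2·SNP_{j,D} with OR per IQR in
   {1.2,…,2.4}, j ∈ {2,5}; (E1,E2) bivariate normal with mean 20,
   variance 10, correlation ρ ∈ {0.5, 0.9}; 45 noise SNPs; N = 2000 —
   20 settings.

Per replicate, each SNP's minor-allele frequency is drawn uniformly from
[0.15, 0.45] and genotypes are sampled as Binomial(2, MAF) — the
Hardy-Weinberg choice, the standard generative assumption when only MAFs
are specified.  The minor allele is always the risk allele.
Environmental odds ratios are converted to coefficients via the
theoretical normal IQR, β = log(OR) / (2·z₀.₇₅·σ); using the theoretical
rather than per-sample empirical IQR keeps the generating model
identical across replicates.

**Intercept calibration.**  β₀ is chosen once per setting by bisection
on [−20, 20] so that the Monte-Carlo mean of logistic(β₀ + η) over a
calibration sample of 200 000 individuals is within 0.005 of the target
case fraction (0.5).  The calibration sample redraws the MAFs *per
individual*, marginalizing over the MAF distribution: replicates redraw
their MAF vectors, so the intercept must balance the case fraction on
average over draws.  Individual replicates still fluctuate around 50%
cases by a few percentage points — that variation is part of the design.
Per-replicate sub-seeds are spawned from the design seed
(`numpy.random.SeedSequence`), making every sweep reproducible and the
replicates mutually independent.

What the simulator does *not* emulate: linkage disequilibrium between
SNPs, population stratification, genotyping error or missingness,
quantitative traits, and covariate confounding.  Passing tests therefore
demonstrate correct behavior under clean, independent-SNP case-control
sampling — not robustness to the correlation structure of real panels.

## Probability-estimation forests

Trees are grown on bootstrap samples (N draws with replacement); at each
node `mtry` candidate features are drawn uniformly **without
replacement**, and both ordered genotype cut points per feature are
scored by the weighted binary Gini impurity i(t) = 2·p₁(1−p₁).  A node
becomes a leaf when it is pure, smaller than 2·min_node_size, or no
split reduces impurity while leaving ≥ min_node_size in-bag samples in
both children; leaves store the in-bag case fraction.  The forest risk
is the exact arithmetic mean of leaf probabilities — unlike vote
averaging, which would report 100% for any stratum whose true risk all
trees recognize as > 50%.  Split ties break toward the lowest feature
index, then the lower cut, for determinism.

Defaults follow the published grid conventions: num_trees = 2000 at full
scale (the experiment harness defaults to 500 and exposes
`MethodScale.paper_scale()`), mtry defaults to ⌊√p⌋ with the tuning grid
⌊(0.5, 1, 2)·⌊√p⌋⌋, and min_node_size grid ⌊(0.01, 0.05, 0.1)·N⌋ —
large terminal nodes matter for probability (rather than class)
estimation.

**Permutation importance** uses each tree's out-of-bag rows: importance
of a feature is the mean over trees of the OOB misclassification
increase (classification at threshold 0.5) after permuting that feature
among the tree's OOB rows.  Features unused by a tree contribute exactly
zero for that tree.

**Shadow-variable selection** (the "random forests VIM" pre-step): per
iteration, every feature gets an independently permuted shadow copy, a
forest is fitted on the doubled feature set, and a feature scores a hit
when its importance exceeds the maximum shadow importance.  After
n_iterations (default 100; 50 in the desk-scale harness), exact binomial
tests against p = 0.5 at the 1% threshold label features confirmed /
rejected / tentative.  Simplifications relative to the canonical
algorithm: a fixed iteration count, no progressive removal of decided
features between iterations, and tentative features are *not* selected —
the simplest scheme consistent with hit-counting against the max-shadow
rule.  With no confirmed feature the model degrades to the constant
training prevalence, which carries no association evidence.

## Logic regression and logic bagging

Logic trees hold AND/OR in inner nodes and possibly negated binary
features in leaves; M trees enter a logistic model scored by deviance
(−2·log-likelihood).  The neighborhood of a model consists of:
alternating a leaf's literal, alternating an operator, splitting a leaf
into an operator node with a fresh literal (leaf budget permitting),
pruning an operator node to one of its children, and adding or deleting
a single-literal tree (an empty model is the intercept-only fit).  This
move set connects the state space under the budgets.  `nleaves` is the
**total** leaf budget across trees, matching the convention of the
established implementation; the tuning grid pairs ntrees 1–6 with
nleaves 1–10 and skips infeasible pairs (nleaves < ntrees).

*Greedy search* starts from the intercept-only model and moves to the
best-scoring neighbor until no neighbor improves the deviance;
enumeration order (move type, tree, node, feature, negation) fixes tie
breaks.  *Simulated annealing* proposes one uniformly random neighbor
per iteration and accepts worsening moves with probability
exp(−Δdeviance/T) under geometric cooling (default 50 000 iterations at
desk scale, 500 000 at paper scale); the best model visited is returned.
When temperatures are not given, a pilot random walk of 200 accepted
moves estimates the distribution of worsening steps and sets the start
temperature for ~90% initial acceptance and the end temperature so late
worsening moves are essentially never accepted.

Coefficients are fitted by IRLS (deviance tolerance 1e−8, ≤ 50
iterations) on the tree columns, with duplicated columns collapsed onto
their first occurrence and constant columns absorbed into the intercept.
Under complete separation the coefficient vector is rescaled onto the
box max|β| = 15 rather than clipped per coordinate: rescaling preserves
the separating direction, so separated fits saturate their predictions
(risks within ~1e−3 of 0/1) instead of collapsing.

*Logic bagging* fits one greedy logic regression per bootstrap sample
(500 bags at paper scale, 100 at desk scale; greedy search for
computational reasons) and averages member probabilities.  Degenerate
single-class bootstrap samples produce intercept-only members.
Out-of-bag rows play no role here.

## Elastic net

The objective −(1/N)·ℓ(β₀, β) + λ·R_α(β) with
R_α(β) = ½(1−α)‖β‖₂² + α‖β‖₁ (intercept unpenalized) is solved by
scikit-learn's saga solver, warm-started down a geometric λ path of 30
values from λ_max = max_j |x_jᵀ(y − ȳ)|/(N·max(α, 0.001)) to
λ_max·1e−4, on internally standardized features (coefficients are
reported on the original scale).  Because saga's stopping rule can leave
the single unpenalized coordinate short of optimum, the intercept is
refit exactly by one-dimensional Newton steps after every solve — this
makes fully shrunk models predict exactly the training prevalence.  λ is
selected by stratified K-fold (default 10) cross-validated deviance at
its minimum; the one-standard-error rule is implemented but non-default,
as it tends to shrink away weak polygenic signal entirely.  The α grid
is {0.5, 0.75, 0.9, 0.99}.  The default coding is additive {0,1,2} (the
standard GRS convention); `binary_01` splits each SNP into
dominant/recessive indicators, which a linear model needs to express a
pure recessive effect.  No interaction terms are expanded: for 50 SNPs
there are already 2⁵⁰ − 51 ≈ 1.1·10¹⁵ possible interaction terms.

## Evaluation

Raw risks are clipped to [1e−6, 1 − 1e−6] and logit-transformed (logic
and forest models can emit exact 0/1), then used as the single predictor
of a univariate logistic association model fitted on the *test*
replicate; a two-sided Wald test on the slope decides significance.  A
constant transformed score is degenerate: slope 0, p = 1 — an
intercept-only model carries no evidence, and this convention is what
makes heavily shrunk elastic-net fits conservative under the null.  The
adjusted gene-environment model adds E, GRS·E and covariates, with a
rank check that names collinear columns.

AUC is computed in Mann-Whitney form from average ranks, giving exact
half credit to ties — essential because genotype-based scores are
discrete (the equal-effect marginal true model takes exactly 7 distinct
values).  Classification metrics (accuracy, sensitivity, specificity)
are computed at threshold 0.5 from the association model's predicted
probabilities, without prevalence adjustment (the designs are balanced).
Power (type-I error) is the fraction of significant Wald tests at level
0.05 across replicates of an influential (null) design, reported with
its binomial standard error.  Null datasets reuse the design shell with
every effect odds ratio set to 1 and intercept 0.

## The experiment harness

The cyclic scheme makes R independent replicates serve as R
train/validation/test triples: replicate i trains, i−1 (wrapping to R)
validates, i+1 (wrapping to 1) tests, so no information flows from test
to training or tuning.  Hyperparameters are tuned once per setting by
averaging validation AUC over the first 10 tuning iterations (fidelity
to the original protocol rather than statistical efficiency) with common
random numbers across grid points, ties keeping the first grid point.
For real-data-style analyses, `repeated_split_scheme` produces repeated
stratified 50/50 train/test splits with a stratified 75/25 tuning
sub-split (floor on the validation count per class); stratification is a
deliberate choice to protect small case counts.

## Problem sizes in the acceptance script

`scripts/acceptance.py` uses desk-scale sizes chosen to keep the full
recomputation at a few minutes on one core while leaving Monte-Carlo
error well inside the reported precision: the distinct-risk-level count
is exact over all 3⁶ genotype patterns; the gene-environment power uses
20 train/test replicate pairs at N = 2000 (forest with 200 trees,
elastic net at α = 0.5); the null type-I rate uses 100 pairs at N = 1000
(forest with 100 trees).  All randomness derives from the `--seed`
argument.

## Known limitations

* Simulated annealing re-enumerates the neighbor list each iteration;
  at paper-scale iteration counts a logic-regression fit takes minutes,
  not seconds.
* The Boruta variant is the simplified fixed-iteration scheme described
  above, not the adaptive original.
* The simulator's independence assumptions (no LD, no stratification)
  bound what the evaluation can claim about real panels; the real-data
  pipeline pieces (readers, repeated splits, adjusted GxE model) are
  provided but no real cohort ships with the package.
* Wald inference in the association model is asymptotic; under complete
  separation on a test set the reported p-value follows the usual
  GLM/IRLS behavior (inflated standard errors) rather than an exact
  test.
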