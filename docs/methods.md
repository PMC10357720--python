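# Methods

## The model

`puvote` prioritizes genes that co-pattern with a curated "seed" pathway
gene set across cancer transcriptomes by positive-unlabeled (PU) bagging.
The transposed learning problem is the key idea: **genes are the samples
and patients are the features**.  The seed set (e.g. the TNFα-signaling-
via-NFκB hallmark) supplies the positives; genes belonging to any other
curated hallmark set are *excluded* from training to avoid teaching the
model competing expression programs; every remaining gene is treated as a
negative even though it is merely unlabeled — the PU setting.

Each of the M member classifiers is a linear SVM (hinge loss, L2 penalty,
C = 1.0) fit on **all** positives plus a fresh uniform draw of
`np_ratio × n_positives` negatives without replacement.  Within each
member, a stratified 70/30 hold-out provides a test precision; precision
on the full labeled set ("initial" precision) measures how the member
behaves at the true class imbalance.  The trained member is then applied
to *every* gene in the matrix — including the excluded ones — and the
ensemble's confidence in a gene is its **vote**: the number of members
whose decision rule `sign(w·x + b)` calls it positive, in `[0, M]`.

Cohort ensembles are combined by the pan-cancer rule: a gene's
**prevalence** is the number of cohorts giving it ≥ 1 vote, and its
**average vote** is the mean vote over *only those* cohorts.  For ranking
(ROC curves, enrichment input) we use the average vote with prevalence as
a tie-breaker and unvoted genes scored 0.

### Preprocessing

The inputs are assumed normalized (TPM-like).  Features are `log2(x+1)`
transformed, then each patient-feature is standardized with mean/sd fit on
the member's 70% training split and applied unchanged when scoring the
full transcriptome, so no statistics leak from scored genes into the fit.
Both the transform and the standardization are configurable
(`log_transform`, `standardize`) because the upstream study conditions are
not fully determined.

### NP-ratio calibration

`calibrate_np_ratio` sweeps candidate ratios (default 1, 10, 15, 20, 25,
30), trains `members_per_ratio` members per ratio per cohort, and picks
the smallest ratio whose pooled median initial precision exceeds 0.5 — the
weak-classifier bar.  Held-out test precision falls as the ratio grows
(the hold-out becomes more imbalanced) while initial precision rises; the
rule generalizes the published choice of 20 deterministically.  On clean
synthetic data even ratio 1 clears the bar, so the rule returns 1 there;
the default working ratio remains 20.

## Enrichment machinery

The enrichment score is the classic Kolmogorov–Smirnov running sum with
weight exponent p: hits add `|score|^p / Σ_hits |score|^p`, misses
subtract `1/(N − N_hits)`, ES = signed maximum deviation, leading edge =
hits at or before the extremum.  The default is p = 0 (increments
`1/N_hits`), which makes the ES a pure rank statistic — invariant under
monotone transforms of the scores and exactly checkable by enumeration on
small universes; p = 1 is available.  Ties in the ranking are broken by
stable order after a seed-fixed shuffle, so results are deterministic
without a systematic ordering bias.

Significance uses a permutation null.  Permuting the gene→score assignment
("scores" scheme) and permuting set membership ("labels" scheme) place the
hits uniformly at random on a fixed ranked vector, so one engine serves
both.  z = (ES − null mean)/null sd, and p uses the add-one estimator
`(1 + #{|ES_null| ≥ |ES_obs|})/(1 + n_perm)`, which can never return 0;
ties within 1e-12 count toward the tail so that cumsum rounding cannot
drop exact ties.  Defaults mirror the study: 10,000 permutations for gene
enrichment, 1,000 for module activity.

Companion statistics: two-sided Fisher's exact test (scipy's conditional
odds ratio; zero-margin tables give p = 1 with missing OR), Jaccard
functional similarity over evidence-filtered annotation term sets (default
filter: the experimental GO codes EXP/IDA/IPI/IMP/IGI/IEP), one-sided
Wilcoxon rank-sum with pooled-sd Cohen's d, and a univariate logistic
(Wald) association between a per-gene covariate and voted status with
explicit complete-separation flagging.

## Functional modules

A candidate is a voted non-seed gene.  "Highly voted" defaults to vote ≥
the median vote among voted candidates — a parameter-free cut tied to the
vote distribution (top-k and explicit thresholds are available).  For each
functional term, the interaction subgraph induced by the highly-voted
candidates annotated to that term is taken and its largest connected
component kept if it reaches `min_size` (default 3).  Each module is
scored by vote-ranked permutation GSEA over all candidates and modules are
ranked by z; each positively-enriched module's **relative significance**
is its share of the total positive z (shares sum to 1).  This term-induced
largest-component construction is a deliberate reconstruction: it is the
simplest procedure consistent with "functional modules formed by the
highly-voted candidates", and we document it as such.

Module activity in a patient contrast ranks genes by
`log2((mean_A+1)/(mean_B+1))` fold-change (a deliberately simple,
pluggable statistic — any moderated fit can substitute its own ranking)
and runs the same permutation GSEA; activated iff ES > 0.  Module subtype
classifiers are logistic regressions on the module genes' standardized
log2 expression, evaluated over repeated stratified 60/40 hold-outs
(default 100), reporting AUC and AUCPR mean ± sd.  The per-gene effect z
for hub ranking is mean/sd of the standardized coefficient across
hold-outs; hubs rank lexicographically by (module degree, |z|), and genes
with |z| > 2 are highlighted.

## Survival and subtype analyses

Risk scores are `Σ_g coef(g) · log2(expr(g,p)+1)` over a pre-trained
proportional-hazards signature; patients split at the median score with
ties assigned to the low group (deterministic).  Kaplan–Meier curves and
the two-group log-rank test are delegated to lifelines after
administrative censoring at the horizon (default 5 years).  Model
*fitting* (Cox, additive hazards) is intentionally out of scope:
coefficients come in, summaries go out.  Stage trends report per-stage
median/IQR, one-sided rank-sum tests between adjacent stages, and a
strict-monotonicity flag.  Subtype enrichment ranks patients by their
**signed** ensemble weight (the per-patient mean of member weight vectors
on the standardized feature scale) and GSEA-tests each subtype's patients
as the hit set; signed ranking is the default because the ensemble
assigns positive weight to patients on whom the pathway genes are
elevated, whereas |weight| cannot distinguish the two tails of the latent
pathway activity and, at realistic M, per-patient mean-weight noise from
member sampling does not average away.

## The synthetic study

The generator emulates exactly the structure the method assumes, and
deliberately nothing more.  Per cohort, each patient has a latent pathway
activity `a ~ N(0,1)`; seed and hidden-member genes are
`softplus(baseline + factor_strength·a + ε)`, decoys and excluded-set
stand-ins drop the factor; `ε ~ N(0, noise_sd)`.  The softplus link keeps
expression non-negative without truncating rank structure.  Defaults — the
canonical desk-scale study every property test references — are 3 cohorts,
2,000 genes (60 seed / 40 hidden / 200 excluded), 150 patients per cohort,
factor strength 1.5, noise sd 1.0, master seed 17.  Around the expression:

- **Subtype flag**: the top 20% of patients by `a` (thresholded, not
  sampled, so the flag deterministically tracks the factor the classifier
  weights respond to).  ER/PR status is the complement, HER2 random.
- **Survival**: exponential event times with log-hazard equal to the
  centered risk score of the bundled signature (positive coefficients on
  seed∪hidden genes); uniform censoring; stages assigned by quantiles of a
  noisy copy of the risk score so stage medians increase.
- **Annotations**: shared pathway terms carried by the six core genes and
  random subsets of the non-module truth genes; one term marking exactly
  the planted interaction module; 40 background terms; some decoy records
  carry only electronic (IEA) evidence, which the experimental filter must
  drop.  Planted-module members are excluded from the shared pathway terms
  so that the module's own term stays its unique marker — otherwise every
  shared term would induce a near-copy of the planted subgraph.
- **Interaction graph**: a Barabási–Albert backbone (400 nodes, attachment
  2) with a planted connected module of 12 hidden genes (spanning path
  plus random chords at density 0.4).

One RNG stream per cohort (and per shared structure) is derived from the
master seed by fixed spawn keys, so adding cohorts never perturbs existing
ones and output is byte-identical under a fixed seed.

### What the synthetic study does and does not show

The generator has a single latent factor and iid noise: no batch effects,
library-size artifacts, or gene–gene covariance beyond the planted factor.
Passing tests therefore demonstrate that the machinery is correct and that
the method detects a planted co-expression signal at realistic effect
sizes — not that it reproduces real-data numbers.  Two documented
consequences of this idealization (analyzed in the test suite, where the
corresponding checks are deliberately strict and fail):

1. **In-bag memorization under the null.**  Votes are tallied over all
   genes by members trained on all positives.  With 150 iid
   patient-features a C = 1 linear SVM partially separates the 60 fixed
   positives in-sample even when the factor is off, so the null-config
   seed-gene AUC saturates instead of sitting at 0.5 (held-out test
   precision stays at the base rate — the effect is pure memorization).
   In real transcriptomes, strong gene–gene correlation lowers the
   features' effective rank and damps this.
2. **Vote stability.**  Independent 250-member ensembles agree strongly on
   genes both vote for (Spearman ρ ≈ 0.85) but the union of voted genes is
   dominated by decoys with one or two noise votes in exactly one
   ensemble, capping ρ ≈ 0.65; near-perfect real-data stability relies on
   persistent gene-specific structure the generator omits by design.

## Problem sizes and numerical choices

Desk-scale settings used by the tests and the reproduction script: M = 200
members per cohort (60 for the module-recovery sweep, 250 for stability),
calibration at ratios {1, 5, 20} with 50–100 members per ratio, 300–2,000
permutations where the analysis calls for 1,000–10,000 at full scale.
These sizes are the package's canonical desk-scale study; all full-scale
defaults (M = 1000, 10,000/1,000 permutations) remain the configured
defaults.  Other conventions: empty-prediction precision is missing (not
0) and excluded from medians; zero-variance genes get missing correlation
scores and rank below all finite scores in AUCs; a zero permutation sd
yields a missing z with p still reported; LinearSVC runs with
`max_iter=20000, tol=1e-4` and a seed-derived `random_state` so fits are
reproducible.
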