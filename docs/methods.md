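# Methods

## The generative model behind the synthetic studies

Every stage of the pipeline is exercised on simulated longitudinal
studies with known ground truth.  The generator is logistic-normal +
multinomial: species `j` has a population mean log-abundance
`mu_j ~ N(0, mu_spread²)`; subject `i` draws a personal baseline
`m_ij ~ N(mu_j, sigma_b2)`; every visit adds independent within-subject
noise `N(0, sigma_w2)`; a softmax across species turns latent
log-abundances into a composition and reads are multinomial at a fixed
depth.  Because between- and within-subject variance add on the log
scale, the latent visit-to-visit correlation of each species is exactly

    rho = sigma_b2 / (sigma_b2 + sigma_w2),

recorded per feature as ground truth, and the expected mean-of-two-visits
reliability is the Spearman–Brown value `2*rho/(1+rho)`.

Default parameters and why:

| parameter | default | rationale |
|---|---|---|
| `n_subjects` | 50 per arm | typical single-cohort size in longitudinal gut studies |
| `n_species` | 150 | order of detected species per stool metagenome |
| `mu_spread` | 2.0 (log units) | abundances span ~4 orders of magnitude |
| `sigma_b2` | 1.0 | strong inter-individual signature (latent rho ≈ 0.83 with the default sigma_w2) |
| `sigma_w2` | 0.2 | calibrated so control 1–2-day Bray–Curtis fluctuation ≈ 0.24, the range reported for healthy adults (~0.2–0.35) |
| `depth` | 50,000 | desk-scale stand-in for per-sample read counts |
| `effect_size` | 5.0 log units on a random 30% of taxa | a strong intervention: shifted taxa change ~150-fold, enough to restructure the community the way antibiotic cocktails do |
| `responder_fraction` | 0.5 | balanced planted classes |
| `n_informative` / `informative_effect` | 8 species / 2.0 log units | planted baseline biomarkers of responsiveness, alternating sign |

Intervention cohorts apply the `effect_size` shift only to post-baseline
visits of planted responders (each responder draws their own random 30%
of taxa, mimicking personalised response); the `n_informative` species
additionally differ between responder and non-responder subjects already
at baseline, so the prediction stage has recoverable signal.  Pathway
tables are exact stratified sums: pathway abundance is a weighted sum of
its contributing species' relative abundances, rescaled to CPM with fixed
UNMAPPED (15%) and UNINTEGRATED (5%) mass, one stratified row per
contributor.

What the generator does **not** emulate: temporal autocorrelation beyond
the subject effect (visits are exchangeable), taxon-taxon ecological
interactions (except through compositional closure), realistic phylogeny
(the emitted Newick tree is a random coalescent-like topology, present
only so UniFrac runs), batch effects, or varying sequencing depth.
Passing tests therefore demonstrate correctness of the estimators under
the stated model, not robustness to those real-data complications.

## Attenuation of the ICC through the compositional observation chain

The ICC estimator itself is unbiased on its own scale: fed measurements
drawn from the two-way Gaussian model it converges exactly to
`2*rho/(1+rho)` (measured 0.6647 at n = 200,000 subjects for rho = 0.5).
The *observed* per-species ICC of arcsine-√ relative abundances is
however systematically smaller than that closed form whenever per-species
log-scale variance is large.  The reason: for a rare species, `asin(√p) ≈
√p ≈ exp((z − L)/2)` with `z` the latent Gaussian and `L` the shared
log-normaliser, and the Pearson correlation of bivariate lognormals is
attenuated, `corr = (e^{c} − 1)/(e^{s²} − 1) < rho` with `s² ≈
(sigma_b2+sigma_w2)/4`.  At `sigma_b2 = sigma_w2 = 1` the predicted
observed ICC(A,2) is ≈ 0.61 versus the latent-scale 0.667, and the
pipeline measures ≈ 0.59.  At the package defaults (total log variance
1.2) the attenuation is mild, and in the low-variance regime
(`sigma_b2 = 0.3, sigma_w2 = 0.1`) the per-species profile recovers the
Spearman–Brown value within 0.05.  The acceptance script reports both
routes: `icc_spearman_brown_recovery` (measurement-scale recovery, the
estimator's contract) and `icc_compositional_route` (the attenuated
end-to-end value, a property of the observation chain, not an estimator
defect).

## Estimators and numerical choices

**ICC.** Two-way crossed ANOVA mean squares; ICC(A,k) per McGraw & Wong's
absolute-agreement, average-of-k-ratings definition.  Negative estimates
are truncated to 0 (the stability scale runs 0–1); fewer than 3 complete
subjects, or zero total variance (e.g. a species absent everywhere),
yields an *invalid* result rather than an exception, mirroring the
"non-valid ICC" category in cohort summaries.  Confidence intervals are
percentile bootstrap over subjects (the exchangeable unit in a
repeatability design), 1000 resamples by default, widened if necessary to
contain the point estimate.  The stability call is strict (ICC > 0.5),
exposed as a threshold argument.  Diversity indexes are Gaussianised with
the rank-based inverse-normal transform (Blom offsets, ties sharing mean
ranks) — deterministic and distribution-free, unlike automatic
transform-selection tools; relative abundances use arcsine-√.

**Responder rule.** Control fluctuation pools all within-subject sample
pairs 1–2 days apart (window configurable) across subjects and uses the
sample SD.  The first-peak selector compresses plateaus to their earliest
day, picks the earliest point strictly greater than its successor and not
smaller than its predecessor, and falls back to the last point of a
monotone non-decreasing trajectory.  Both cutoffs belong to the
partial-responder interval (closed on both ends); responders are strictly
above mean + 2·SD.

**PERMANOVA.** Anderson's pseudo-F from among/within sums of squared
distances, R² = SS_among/SS_total, permutation p with the +1 correction
under free label permutation (baseline samples only, one per subject, so
no strata are needed).  On Euclidean distances the pseudo-F equals the
classical one-way ANOVA F; this algebraic identity is asserted to 1e-8 in
the tests.

**Ordinal regression.** Cumulative-logit proportional-odds likelihood,
`P(Y ≤ j) = logistic(theta_j − beta·x)` with the arcsine-√ abundance as
the only covariate, maximised by a damped Newton iteration with analytic
gradient and observed Hessian, vectorised across features (a whole
200-feature screen fits in ~70 ms, which is what makes the 1000-replicate
null-FDR measurement feasible).  Covariates are standardised internally
for conditioning and the slope rescaled back.  Wald p-values from the
observed information; monotone separation (|beta| > 30 on the
standardised scale or exploding standard error) sets a flag and switches
that feature to a likelihood-ratio p-value against the intercept-only
model.  The fit agrees with statsmodels' cumulative-logit implementation
to ~1e-5 in both slope and p-value, and the score at the optimum is
checked below 1e-6 in max-norm.  BH thresholds per analysis (species
q < 0.2, pathways/KOs/correlations q < 0.1) are configuration, not
constants.

**Wilcoxon screen.** Rank-sum with normal approximation and tie
correction; `log2FC = log2((mean_R + eps)/(mean_NR + eps))` with `eps`
half the smallest nonzero table value, so the pseudo-count follows the
table's unit (CPM vs proportions).

**SparCC.** Log-ratio variances `t_ij = var(log(x_i/x_j))` after adding a
pseudo-count of 0.5 to counts (the conventional zero replacement,
configurable); basis variances solved from the linear system implied by
the sparsity assumption; one most-correlated pair excluded per iteration
(up to 20) while its |rho| exceeds 0.1.  Pseudo p-values come from null
datasets built by resampling each feature's samples independently with
replacement — this breaks all cross-feature association, unlike a joint
bootstrap, which would recentre the null on the observed correlation.
Networks keep edges with BH q below 0.1; closeness centrality is
component-normalised on the unweighted significance-filtered graph
(isolates get 0), and group differences use Welch t-tests on per-node
values.

**Prediction.** Near-zero-variance filter (frequency ratio > 95/5 *and*
unique fraction < 10%), z-scoring with training-split statistics only,
recursive feature elimination with a gradient-boosted base learner
(halving to ≤ 2× the target, then one-at-a-time; a lighter 50-tree
learner ranks importances), grid-tuned boosting by pooled out-of-fold
AUC — leave-one-out by default, k-fold as the documented fallback for
repeated-split runs — and evaluation on the held-out 20% at probability
threshold 0.5 (configurable; sensitivity/specificity are threshold-bound,
AUC is not).  Selection frequency is the fraction of repeated splits in
which a feature survives RFE.  External cohorts are joined by terminal
clade name; features absent externally are imputed as zero abundance
before scaling, which biases external scores conservatively.

## Problem sizes

The shipped tests and the acceptance script run at desk scale: cohorts of
30–100 subjects, 40–300 species, read depth 50,000, 100 repeated splits
with 3-fold tuning on a 2×2 hyper-parameter grid, 500 PERMANOVA null
replicates, 1000 null ordinal screens, SparCC at 50 taxa × 200 samples.
These sizes were chosen so the full evidence base recomputes in minutes
while keeping every Monte-Carlo standard error well inside the asserted
tolerances.

## Known limitations

* ICC assumes exchangeable occasions; ordered-visit (trend) designs and
  covariate-adjusted (REML) repeatability are out of scope.
* The responder rule inherits the compositional and depth sensitivity of
  Bray–Curtis; no alternative dissimilarities are offered for
  classification.
* SparCC p-values are pseudo p-values from 100 null datasets by default —
  resolution 1/101 — and the exclusion heuristic can leave pairs
  unestimable in tiny feature sets (flagged, not silently dropped).
* The gradient-boosting stage is a binary classifier; partial-responders
  are excluded before training rather than modelled ordinally.
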