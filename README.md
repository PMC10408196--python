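# microresist

Quantifying the stability of the human gut microbiome and predicting who
will respond to an intervention.

Longitudinal shotgun-metagenomics studies show that some people's gut
communities barely move under dietary, exercise or even antibiotic
pressure while others restructure substantially.  `microresist`
implements the full analysis pipeline for this question on MetaPhlAn-style
taxonomic and HUMAnN-style functional profiles:

* **Stability** — per-measurement intraclass correlation coefficients
  (ICC) across repeated visits.  For a subjects × occasions table the
  two-way random-effects, absolute-agreement, mean-rating form is used:

  `ICC(A,k) = (MS_R − MS_E) / (MS_R + (MS_C − MS_E)/n)`

  with subject/occasion/residual mean squares from the crossed ANOVA,
  truncated to [0, 1], percentile-bootstrap CIs over subjects, and the
  convention that ICC > 0.5 marks a stable target.  Diversity indexes are
  rank-inverse-normal transformed and relative abundances arcsine-√
  transformed first.
* **Responder classification** — the day-to-day Bray–Curtis dissimilarity
  `BC(x,y) = Σ|x_i − y_i| / Σ(x_i + y_i)` of no-intervention subjects
  (sample pairs 1–2 days apart) defines cutoffs mean + SD and mean + 2·SD;
  each intervention subject is scored at the first peak of their
  baseline-to-post BC trajectory and labelled non-responder
  (< mean+SD), partial-responder ([mean+SD, mean+2SD]) or responder
  (> mean+2SD).
* **Biomarkers** — PERMANOVA on baseline Bray–Curtis, proportional-odds
  (ordinal) regression of each feature across the three ordered groups,
  Wilcoxon rank-sum screens with log2 fold changes, chi-square enrichment,
  Spearman species–pathway association, and stratified contribution
  linking of species to pathways.
* **Networks** — SparCC co-abundance networks per response group from
  log-ratio variances, significance-filtered edges (BH q < 0.1), degree
  and closeness centrality comparison.
* **Prediction** — gradient-boosted trees on baseline abundances with
  recursive feature elimination to 30 features, grid-tuned by
  cross-validated AUC (LOOCV or k-fold), evaluated over 100 stratified
  80/20 splits and on external cohorts joined by terminal clade name.
* **Synthetic studies** — a logistic-normal + multinomial generator with
  known per-species visit-to-visit correlation ρ = σ²_b/(σ²_b+σ²_w),
  planted responder labels, planted discriminative species and stratified
  pathway tables, so every stage is testable without any downloads.

## Worked example

```python
import microresist as mr

# a no-intervention cohort (two visits one day apart) sets the cutoffs
ctl = mr.simulate_control_cohort(mr.SimulationConfig(n_subjects=50, seed=11))
base = mr.estimate_daily_fluctuation(ctl.relative(), ctl.metadata)
print(f"control fluctuation: mean={base.mean:.3f} sd={base.sd:.3f} "
      f"cutoffs=({base.cutoff1:.3f}, {base.cutoff2:.3f})")

# an intervention cohort with planted responders
iv = mr.simulate_intervention_cohort(mr.SimulationConfig(
    n_subjects=100, timepoints=(0, 28), effect_size=5.0,
    responder_fraction=0.5, seed=12), baseline=base)
calls = mr.assess_cohort(iv.relative(), iv.metadata, base)
print(calls["label"].value_counts().to_dict())
```

prints

```
control fluctuation: mean=0.236 sd=0.085 cutoffs=(0.321, 0.405)
{'responder': 50, 'non_responder': 47, 'partial_responder': 3}
```

i.e. the pooled short-interval Bray–Curtis fluctuation of the 50 control
subjects is 0.236 ± 0.085, every one of the 50 planted responders exceeds
the mean + 2·SD cutoff of 0.405 at their first-peak time point, and the
unshifted half of the cohort stays almost entirely below it (3 subjects
land in the partial band between the two cutoffs).

The same flow runs from the shell:

```bash
microresist simulate --out study/ --seed 11
microresist validate --taxonomy study/taxonomic_profiles.tsv \
    --metadata study/metadata.tsv
microresist run --config pipeline.yaml
```

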