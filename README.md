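# uropep

A tested, reusable implementation of a urinary-peptide biomarker workflow
for discriminating **significant prostate cancer** (Gleason score ≥ 7, "Sig
PCa") from non-significant disease in men referred for prostate biopsy.

Prostate-specific antigen (PSA) lacks specificity in the 4–10 ng/ml range,
so many men undergo biopsies that find only indolent disease. Urinary
peptidomics by capillary electrophoresis–mass spectrometry (CE–MS) offers a
non-invasive alternative: each urine sample yields a peak list of
deconvoluted peptides characterised by molecular mass (kDa), normalised
migration time (min) and signal intensity (arbitrary units, AU), with
intensity 0 meaning "not detected". `uropep` implements the full analysis
that turns a cohort of such peak lists into a validated multi-peptide
classifier and quantifies its clinical utility.

## The pipeline

1. **Normalisation** — intensities are scaled per sample against ~29
   endogenous collagen-fragment peptides that are generally unaffected by
   disease (internal standards), then natural-log transformed. Non-detects
   stay at the censoring floor, tied below every detected value.
2. **Cohort split** — a stratified 2/3–1/3 random split into discovery and
   validation sets, preserving the case/control ratio per class.
3. **Biomarker discovery** — per peptide, a two-sided Wilcoxon rank-sum
   test comparing cases and controls, restricted to peptides detected in
   ≥ 70 % of at least one group, with Benjamini–Hochberg (BH) correction.
   The whole analysis is repeated on five random 70 % subsamples of the
   discovery set; only peptides with BH-adjusted p < 0.05 in **all five**
   stability runs enter the panel.
4. **Classification** — a support vector machine over the panel peptides
   (one dimension per biomarker) trained on the discovery set only, with a
   decision cutoff established on the discovery scores and a Platt-type
   monotone map from score to risk.
5. **Validation & clinical utility** — ROC with DeLong AUC variance and
   confidence intervals, sensitivity/specificity with exact Clopper–Pearson
   binomial intervals, paired DeLong AUC comparisons against PSA and an
   external risk-calculator column, Kruskal–Wallis score comparison across
   Gleason strata, logistic-regression odds ratios, a nomogram combining
   biomarker score + PSA + age through the regression equation, and
   decision-curve analysis of net benefit
   NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t) against treat-all/treat-none.

Because no patient-level data are deposited for this design, the package
ships a **synthetic cohort generator** (`uropep.simulate`) that reproduces
the statistical structure the analysis assumes — log-normal detected
intensities, per-peptide Bernoulli detection, disease-invariant internal
standards, planted case–control effects, and clinical covariates with
realistic group differences — plus the ground truth needed to test every
stage. See `docs/methods.md` for the model and its limitations.

## Worked example

```python
import uropep as up

# a full-scale synthetic cohort: 823 samples (146 cases / 677 controls),
# 5000 peptides, 29 internal standards, 19 planted markers
matrix, samples, truth = up.simulate_study_scale(seed=7)

logm = up.log_transform(
    up.apply_normalisation(matrix, up.fit_normalisation(matrix)))
split = up.stratified_split(samples, seed=7)          # 548 / 275 samples
panel = up.discover_panel(logm, samples, split, seed=7)
print(len(panel), sorted(set(panel.peptide_ids) & set(truth.marker_effects))[:4])

model = up.train_svm(logm, samples, split, panel=panel)
scored = up.score_samples(model, logm, samples, split.validation_ids)
roc = up.roc_curve(scored["score"], scored["outcome"] == "sig")
ss = up.sens_spec_at_cutoff(scored, model.cutoff)
print(f"validation AUC {roc.auc:.3f}  "
      f"sens {ss['sensitivity'].estimate:.2f}  "
      f"spec {ss['specificity'].estimate:.2f}")
```

prints

```
19 ['P00048', 'P00260', 'P00619', 'P01993']
validation AUC 0.999  sens 1.00  spec 0.98
```

i.e. the discovery stage recovers all 19 planted markers with no false
positives, and the downstream SVM separates the validation cases almost
perfectly at the strong planted effect size (1.5 log-AU). The same
functions run on real peak-list TSVs via `up.read_peptide_matrix` /
`up.read_sample_table`, or from the shell:

```sh
uropep simulate --seed 7 --out cohort/
uropep preprocess --matrix cohort/matrix.tsv --samples cohort/samples.tsv --out prep/
uropep split --samples cohort/samples.tsv --seed 7 --out split.tsv
uropep discover --matrix prep/log.tsv --samples cohort/samples.tsv \
    --split split.tsv --seed 7 --out disc/
uropep train --matrix prep/log.tsv --samples cohort/samples.tsv \
    --split split.tsv --panel disc/panel.tsv --out model.json
uropep score --model model.json --matrix prep/log.tsv \
    --samples cohort/samples.tsv --out scores.tsv
uropep evaluate --scores scores.tsv --samples cohort/samples.tsv \
    --cutoff -0.07 --out eval/
uropep dca --scores scores.tsv --samples cohort/samples.tsv --out dca.tsv
```

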