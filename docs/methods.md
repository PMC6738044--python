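# Methods

This note documents the statistical model behind `uropep`, the choices made
where the design was genuinely open, and what the synthetic cohorts do and
do not show about real data.

## Data model

A CE–MS peak list characterises each deconvoluted urinary peptide by
molecular mass (kDa), normalised migration time (min) and signal intensity
(AU). Intensity 0 encodes "not detected"; detection-limited censoring, not
a measured zero. On disk the matrix is a wide TSV with peptides as rows
(peptide count, thousands, far exceeds sample count); in memory rows are
samples. All delimited I/O is UTF-8, tab-separated, `.` decimal. The
clinical annotation carries the binary outcome (significant prostate
cancer, Gleason ≥ 7) derived from the Gleason stratum, plus age, PSA
(inclusion requires PSA < 15 ng/ml), digital rectal examination, prior
biopsy count, prostate volume (may be missing), 5-alpha-reductase-inhibitor
(5-ARI) flag, urinary creatinine and an optional external risk-calculator
probability.

## Normalisation and transformation

Per-sample multiplicative factors are fitted against the internal-standard
peptides (endogenous collagen fragments assumed disease-invariant): each
standard's reference level is its median detected intensity across samples,
and a sample's factor is the median over its detected standards of
(reference / observed). The median-of-ratios form is robust to individual
standard dropout; standards undetected in a sample are excluded from that
sample's factor, and a sample with no detected standard is an error. One
subtlety is documented deliberately: a *full* refit on an already
normalised matrix recomputes reference levels and therefore returns factors
only approximately 1 (within the spread of the median-ratio estimator);
refitting against the *stored* reference levels returns factors exactly 1,
which is the idempotence property the tests assert. After scaling, detected
intensities are natural-log transformed. Non-detects are represented as
`-inf` on the log scale so that every rank-based statistic treats them as
left-censored values tied below all detected values — the standard
conservative choice for detection-limited data.

## Discovery

The cohort is split 2/3–1/3 into discovery and validation, stratified by
outcome; per class, round(fraction · n) samples (round half away from zero)
enter discovery, so the realised counts are reported rather than assumed
(e.g. 146 cases give 97 discovery cases). Discovery statistics are:

- **Frequency filter**: keep peptides detected in ≥ 70 % of cases *or*
  ≥ 70 % of controls (boundary inclusive), applied before testing.
- **Wilcoxon rank-sum test**, two-sided, per peptide. Exact enumeration of
  the null distribution when the combined sample size is ≤ 12 and there are
  no ties; otherwise the normal approximation with tie and continuity
  correction. A vectorised implementation of the asymptotic path handles
  thousands of peptides at once and is cross-checked column-wise against
  scipy in the tests.
- **Benjamini–Hochberg** step-up adjustment within each analysis. The BH
  family is the frequency-passing peptides by default (the filter precedes
  testing, so the family must be explicit); a config switch
  (`bh_family="all"`) corrects across every profiled peptide instead.
- **Stability runs**: the filter + test + BH analysis is repeated on five
  random subsamples retaining 70 % of the discovery samples per outcome
  class (stratified, since the discovery set is ~18 % cases and an
  unstratified draw risks class collapse). The panel is the set of peptides
  passing the full-set filter and significant in **all** runs. Significance
  means BH-adjusted p < 0.05 by default; `use_adjusted_p=False` switches to
  raw p, since the source description is genuinely ambiguous on this point.
  The procedure subsamples rather than permutes labels, and is named
  accordingly. Run k draws from the k-th spawned child of the seed, so
  shortening or lengthening the run list never changes earlier runs — this
  yields the unanimity-monotonicity property (the 5-run panel is a subset
  of the 1-run panel on the same stream).

Regulation direction is the sign of (case median − control median) of the
log intensities with censored values at the tied minimum; exact ties
resolve to "up in significant PCa".

## Classifier

A support vector machine over the panel peptides, one dimension per
biomarker. The feature pipeline is frozen on the discovery set: censored
non-detects enter as the peptide's discovery-set minimum detected log value
minus a fixed offset (default 1 natural-log unit — an explicit numeric
floor, since an SVM cannot consume a censoring sentinel), and features are
standardised with discovery means and standard deviations. The kernel is
radial-basis by default with C = 1 and γ = 1/n_panel (the reference
software's kernel and tuning are unpublished, so the defaults are explicit
and frozen; a linear kernel is available, and an optional grid search on
the discovery set exists but is off by default). The decision function is
evaluated from the stored support coefficients, so a model reloaded from
its JSON bundle reproduces scores bit-exactly, and training never sees
validation samples — permuting validation outcomes leaves the model
bit-identical (tested).

The decision cutoff is established on the discovery scores, by default at
the Youden point (maximising sensitivity + specificity − 1 over midpoints
of adjacent distinct scores, ties resolved toward the lower cutoff to
favour sensitivity — the clinical intent is a rule-out test); a
target-sensitivity criterion is available. Scores map to risks through a
Platt-type logistic calibration fitted on discovery scores with a light L2
penalty (keeps the map defined under perfect separation); the map is
monotone whenever the fitted slope is non-negative, which holds by
construction when higher scores accompany cases.

## Evaluation

AUC is tie-aware (Mann–Whitney U / n₁n₀, equal to the trapezoid of the full
step curve — asserted to 1e-12). Its variance and the paired comparison of
two correlated AUCs use DeLong's placement-value estimator with
normal-approximation confidence intervals clipped to [0, 1]; a degenerate
zero-variance self-comparison returns p = 1 by convention. Sensitivity and
specificity at a cutoff (score ≥ cutoff ⇒ predicted significant, ties to
positive) carry exact Clopper–Pearson beta-quantile intervals — "exact
binomial" is read as Clopper–Pearson for proportions while the AUC interval
stays normal-approximation, and both choices are stated here because mixed
conventions exist in commercial tools. Kruskal–Wallis (tie-corrected, χ²
with k−1 df, p = 1 when all values are equal) compares scores across
Gleason strata; with two groups H equals the squared tie-corrected rank-sum
deviate (tested at 1e-9). Baseline-characteristics tables use Mann–Whitney
for continuous and Pearson chi-squared for categorical variables (no Yates
correction by default; flag available), with prostate-volume missingness
handled pairwise and the per-group n reported.

## Clinical utility

Predictors are compared by maximum-likelihood logistic regression
(statsmodels Newton IRLS; complete cases with the used n reported; perfect
separation flagged with coefficients still reported from a quasi-Newton
fit; rank deficiency raises naming the collinear predictors). The nomogram
is the inverse-logit of the fitted linear predictor over biomarker score,
PSA and age. Decision-curve analysis computes net benefit
NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t) at "biopsy if risk ≥ p_t" over a
default grid 0.01–0.50 in steps of 0.01 (the clinically relevant low-risk
range), against treat-all and treat-none. DCA operates on calibrated
probabilities — the Platt map for SVM scores — because net benefit is
defined on risk thresholds. Model comparisons involving PSA exclude
samples on 5-ARI therapy (the drug lowers PSA) and report the reduced n.
The external risk calculator is represented only as a user-supplied
probability column; its coefficients are not re-implemented.

## Synthetic cohorts

The generator emulates the structure the analysis assumes: detected
log-intensities are Normal(μ₀ + group·effect, σ) with μ₀ = 7 log-AU and
σ = 1 by default; each cell is independently censored to zero with one
minus its peptide's detection probability (uniform in (0.2, 0.99) for
ordinary peptides, 0.95 for planted markers, 0.999 for the 29 internal
standards, which carry zero group effect). Effects are additive on the log
scale (multiplicative on AU, matching the log-transform-then-test
workflow); a scalar effect size is given random signs with ~70 % of
markers up-regulated, the balance typical of collagen-fragment panels.
Covariates use normal/lognormal marginals with medians and IQRs matched to
a biopsy-referral cohort (cases older — 68 vs 63 years; higher PSA — 6.1
vs 5.1 ng/ml, rejection-sampled under the < 15 inclusion limit; fewer
prior biopsies — 85.6 % vs 70.9 % biopsy-naive; smaller prostates), with
no covariate–peptide correlation by default. An optional external-risk
column is drawn as a logistic transform of a binormal latent calibrated to
AUC 0.69. One global seed spawns named sub-streams per generator, so
adding a generator never perturbs the others.

The full-scale preset draws 823 samples (146 cases / 677 controls) and
5000 peptides — a realistic breadth for a urinary CE–MS peak list, chosen
once as the package's study condition — with 19 planted markers at
|effect| = 1.5 log-AU. A deterministic `reference_cohort()` fixture
reproduces the reference study composition exactly (543 discovery with 98
cases, 280 validation with 48, Gleason strata 63/20/9/6 and 32/9/5/2, 480
of 677 controls and 125 of 146 cases biopsy-naive) for count bookkeeping;
its covariates are constants. One published inconsistency is handled
explicitly: the control-group prior-biopsy counts (187 + 480) do not sum
to the group total (677), so the group totals and the no-prior count 480
are taken as authoritative, which means the discovery/validation
prior-biopsy margins cannot be matched simultaneously.

What passing tests show — and what they do not: the synthetic cohorts have
independent peptides, independent Bernoulli censoring, no batch or drift
structure, no covariate–peptide coupling and exactly log-normal detected
intensities. Recovery of 19/19 planted markers with zero false positives
and validation AUC ≈ 1 at effect 1.5 log-AU therefore demonstrates that
the pipeline's selection and classification machinery is correct and leak
free, not that real urinary cohorts would yield comparable performance;
real peptide panels face correlated features, weaker effects and
acquisition drift that the generator deliberately does not model.

## Numerical choices and problem sizes

Exact Wilcoxon enumeration switches to the asymptotic path above a
combined n of 12; U exactly at its null mean returns p = 1 (maximal under
symmetry). BH inputs must lie in (0, 1]. All-equal inputs give p = 1 in
rank tests and Kruskal–Wallis and χ² = 0 in contingency tests; degenerate
margins raise. The acceptance script runs 100 null cohorts of 400 × 300
(effect-free), 20 full-scale cohorts for marker recovery with the SVM
trained on the first 10, and 100 binormal replicates for CI coverage —
sizes chosen to estimate each rate with useful Monte-Carlo precision while
completing in about a minute on one CPU. Monte-Carlo checks of expectation
bounds (the null FDR ≤ 0.05) are asserted by one-sided binomial
consistency rather than by comparing a noisy estimate to its own
expectation. The DeLong normal-approximation interval is mildly
anticonservative at small case counts (measured coverage ~93.5 % with 48
cases, ~94.5 % with 146, nominal 95 %); coverage checks are therefore run
at the full-cohort group sizes.
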