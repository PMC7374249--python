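# Methods

This note documents the statistical model behind `tolsig`, the
numerical choices, the synthetic-cohort generator and its calibration,
and the limitations a user should know about.

## The problem and the model

The pipeline discriminates kidney transplant recipients with
operational tolerance (TOL, off all immunosuppression) from treated
non-tolerant recipients (stable, ST, and chronic rejectors, CR) using
peripheral-blood RT-qPCR expression on the −ΔCt scale
(reference-gene Ct minus target-gene Ct; log2 relative expression,
higher = more expressed). Because the comparison classes differ
systematically in drug exposure, any discriminative model fitted on raw
expression is free to learn pharmacology rather than tolerance biology.
The pipeline therefore removes the linear drug component first
("in-silico drug withdrawal") and only then calibrates the classifier.

### Drug adjustment

Per gene, on treated non-tolerant baseline samples only:

    −ΔCt_gene = β0 + β1·PRED_on + β2·CNI_cyc + β3·CNI_tac
                + β4·AP_aza + β5·AP_mmf + ε

Three-level factors (calcineurin inhibitor, antiproliferative) are
dummy-coded with "off" as reference; doses are deliberately not in the
model (indicator effects are the primary parameterization; dose–response
models live in the evaluation battery). Adjusted expression is the
residual observed − predicted, with TOL and healthy-control samples
evaluated at the all-off regimen, i.e. observed − intercept. On the fit
set the residuals are exactly orthogonal to the design; for everyone
else the adjustment is an extrapolation (see Limitations).

### Penalized calibration

The signature model is logistic regression with the elastic-net
penalty in the glmnet parameterization:

    min  −(1/n)·Σ [y_i η_i − log(1 + e^{η_i})]
         + λ·Σ_j [ α·|β_j| + (1−α)/2·β_j² ]

with an unpenalized intercept, predictors standardized internally to
zero mean and unit population SD (divisor n), and coefficients reported
on the input scale. α = 0.05 for calibrating a fixed gene-set (near
ridge: correlated genes are retained) and α = 0.95 for consensus gene
selection (near lasso: exact zeros). The solver is IRLS with cyclic
coordinate descent on the weighted quadratic approximation, using
covariance updates (the weighted Gram matrix is formed once per IRLS
step, so each coordinate update is O(p)); λ paths of 100 log-spaced
points run from λ_max = max_j |⟨x_j^std, y − ȳ⟩| / (n·max(α, 10⁻³))
down to λ_max·10⁻⁴ (n > p) or 10⁻² otherwise, warm-started. KKT
residuals at convergence are < 10⁻⁶ (typically ~10⁻¹¹), the λ = 0 fit
agrees with the unpenalized MLE to < 10⁻⁴, and fixed-λ solutions match
R glmnet coefficients to ~10⁻⁶.

λ is selected per fit as the median over repeated stratified internal
cross-validation of either the out-of-fold-deviance-minimizing λ
("min", the default for calibration) or the largest λ within one
standard error of that minimum ("1se", the default for the consensus
selection stage). The two-rule split is a deliberate design choice: the
min rule is liberal enough to retain genes whose association with the
18-patient tolerant group is pure chance (~0.4 SD shifts), which
defeats the purpose of a stability-selection stage; the 1-SE rule is
the standard conservative companion for selection tasks. Both rules are
available everywhere via `lambda_rule`.

Numerical details: IRLS working weights are floored at 10⁻⁵ and linear
predictors clipped at ±30 when computing probabilities; coefficients
with |β| < 10⁻⁸ (standardized scale) are reported as exact zeros; path
fits stop early once > 99.5% of the null deviance is explained (the data
are then effectively separated; remaining path entries repeat the last
solution, which cannot win a deviance-based selection tie because ties
resolve to the largest λ); even-sized ensembles use the mean of the two
middle values as the median.

### Cross-validation engine

100 repeats of six-fold cross-validation, stratified by clinical group
(18 TOL split 3 per fold), re-estimating *everything* — drug-adjustment
models on the treated members of the training fold, λ, and the
penalized fit — inside each training fold; held-out samples receive
probabilities from models that never saw them (verified by a corruption
probe). Healthy controls are never trained on; they are only scored by
the final model. The final model is the coefficient-wise median over
the 600 CV models; the exported bundle stores two drug-adjustment
variants (full-data fit and CV medians — the published coefficient
tables do not say which was used, so both are kept; CV medians are the
prediction default) and the classification cut-off, defined as the
median predicted probability among tolerant patients. The
strictly-greater-than rule at that cut-off fixes sensitivity at exactly
50% whenever the tolerant group has an even size with distinct
probabilities. One master seed drives everything; repeat r of the outer
loop uses the derived stream (seed, r).

The inner λ search defaults to 10 repeats of six-fold internal CV; a
single-repeat "reduced" search is what the packaged acceptance runs
use, and a 100-repeat search is one keyword away. Structural outputs
(600 models, out-of-fold probability matrices) do not depend on this
setting.

### Consensus selection

Stage 1 fits the 24-gene union of the five published signature sets,
drug-adjusted, at α = 0.95 (λ by the 1-SE rule); stage 2 keeps genes
with non-zero coefficients in at least 75% of the 600 models
(inclusive); stage 3 re-runs the full drug-adjusted CV from scratch at
α = 0.05 on the selected genes — the parsimonious signature is a fresh
calibration, not a coefficient subset.

### Evaluation battery

* AUC as the Mann–Whitney statistic (ties half), DeLong
  structural-component variance for 95% CIs (matches R pROC to ~10⁻⁶)
  and the paired two-sided test for curves on the same samples.
* Cohen's kappa from the 2×2 contingency; κ defined as 1 when both
  classifications are constant and equal.
* Drug influence: OLS of prediction log-odds (probabilities clipped at
  10⁻¹²) on the five drug dummies over treated baseline samples; R² and
  per-drug Wald p-values, no multiple-testing correction (by design —
  the evaluation mirrors unadjusted reporting).
* Dose–response: the drug's indicator replaced by dose in mg/day (zero
  when off), samples on the paired same-class drug excluded
  (cyclosporine↔tacrolimus, azathioprine↔mycophenolate), doses above
  the 97.5th centile of treated samples excluded, remaining drug-class
  dummies retained.
* Rank-sum comparisons: exact enumeration for ≤ 25 tie-free
  observations, tie-corrected normal approximation otherwise.
* Per-cycle statistics are summarized as median and 2.5th–97.5th
  centiles (linear-interpolation quantiles).

## The synthetic generator

`tolsig.simulate` generates cohorts with the structure the analysis
assumes; it exists because the original data are access-restricted.

    −ΔCt(g, i) = μ_g + Σ_d δ_{g,d}·I(drug d) + τ_g·I(TOL)
                 + π_{patient(i), g} + ε_{g,i}

* **Cohort structure:** 18 TOL / 186 ST / 34 CR / 12 HC at baseline;
  follow-up samples ~6 months later for 12/43/15 patients, reusing the
  patient effects and (with probability 0.9 per factor) the regimen.
* **Regimens:** drawn per treated group from the observed frequencies
  (e.g. stable: prednisolone 41.9%, cyclosporine 51.6%, tacrolimus
  30.1%, azathioprine 36.0%, mycophenolate 46.2%); the three factors
  are sampled independently within group — the source tables give only
  marginals, and independence is the minimal assumption. Log-normal
  doses around the observed medians (tacrolimus 4 mg/day, mycophenolate
  1000 mg/day, ...).
* **Drug effects:** qualitative directions as reported per gene
  (prednisolone lowers most B-cell and consensus genes but raises
  *BCL2A1*, *NFKBIA*, *H6PD*, *KLF6*; CNIs raise the immunoglobulin
  genes and *IGLC1*/*ID3*; azathioprine lowers *BNC2*, *AKR1C3*,
  *CD40*, *TCL1A*; mycophenolate lowers the immunoglobulin genes and
  *MZB1*). Where a drug-variance fraction is reported the effect vector
  is rescaled analytically so the regimen term explains exactly that
  fraction of total variance under the treated-group regimen mixture:
  0.5 for *TCL1A*, 0.2–0.3 for the genes reported at that level.
* **Patient effects** π are gene-specific and patient-stable
  (SD 1.3 vs measurement noise SD 1.0, i.e. six-month ICC ≈ 0.63).
  They are *not* shared across genes within a sample: relative
  quantification against housekeeping references cancels shared
  sample-level shifts by construction (the optional Ct emission models
  precisely that cancellation), and a shared intercept would inject
  cross-gene correlated noise that penalized selection exploits as a
  noise canceller — an artefact of the generator, not of the assay.
* **Tolerance effects** τ on the seven consensus genes (positive for
  *CD40*, *IGKV4-1*, *NR3C2*; negative for *CTLA4*, *HSD11B1*, *MZB1*,
  *RAB40C*), magnitudes 1.25–1.5 −ΔCt units. True effect magnitudes are
  not published; (τ, π SD) were calibrated jointly against the two
  printed observables that constrain them — cross-validated AUC ≈ 0.92
  for the consensus signature and six-month positivity agreement
  κ ≈ 0.65 — landing at CV AUC ≈ 0.87–0.95 and pooled κ ≈ 0.54.

What the generator does **not** emulate: gene–gene co-expression beyond
drug- and tolerance-driven structure, joint regimen dependence (e.g.
patients off CNI preferentially on prednisolone), drug-dose effects on
expression (off by default; hooks exist), mTOR-inhibitor arms, eGFR and
other clinical covariates, and longitudinal drug tapering. Tests passing
on these cohorts show the machinery is correct under the stated model;
they do not validate the biology of any real signature.

## Known limitations and caveats

* **Intercept extrapolation under the null.** The all-drugs-off cell is
  rare among treated patients (~2% off all three classes), so each
  per-gene adjustment intercept carries sampling error of about
  0.24 residual SD (√leverage). That error shifts all tolerant samples
  of a cohort coherently, and because CV training sets overlap, the
  shift is learnable: on cohorts with *no* tolerance effects a
  drug-adjusted 7-gene signature shows median out-of-fold AUC ≈ 0.6
  rather than 0.5. In-silico withdrawal buys confounder control at the
  price of mild optimism wherever the off-treatment regimen is poorly
  represented.
* **Stability selection near the noise floor.** With 18 tolerant
  patients, chance standardized shifts of null genes reach 0.5–0.9 SD
  per cohort; planted effects of ~1.5 SD (total) are retained reliably,
  but a clean separation of planted from drug-only genes across cohorts
  is not achievable at these magnitudes — the packaged
  consensus-recovery check succeeds in roughly 6 of 10 cohorts, with
  failures split between a dropped planted gene and a retained
  chance-associated gene. The outcome is a property of the sample size,
  not of the selection rule (verified against R glmnet).
* **Binary positivity agreement is unstable at n(TOL) = 12.** The
  median-TOL cut-off sits in the middle of the tolerant probability
  distribution, so borderline patients flip between timepoints;
  single-cohort κ estimates range 0.1–1.0 and only pooled estimates are
  meaningful at this size.
* The outlier rule (Tukey 3·IQR outer fences, recode to the nearest
  retained value) and the imputation neighbourhood (k = 10, gene-space,
  Euclidean distance) are conventions chosen here; the source analysis
  names neither.
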