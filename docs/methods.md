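# Methods note

`ptbcv` implements a two-timepoint maternal-blood transcriptomic pipeline for
predicting spontaneous preterm birth (sPTB), together with a synthetic-cohort
generator with known ground truth, so that the pipeline's statistical behavior
— calibration, data-leakage inflation, and overfitting signatures — can be
measured rather than assumed. This note records the model, its parameters, the
generator's realism assumptions, the numerical choices, and the limitations.

## 1. Data model

A study is a complete log2-intensity matrix (genes × samples) plus a sample
sheet mapping each sample to a subject, a timepoint (T1, early gestation; T2,
later gestation) and an outcome (`sPTB` = positive class, `term`). Every
subject contributes exactly one T1 and one T2 sample; subjects with a single
timepoint are dropped at ingestion with a logged count, reflecting designs in
which early deliveries preclude the second draw.

## 2. Gene filtering

A gene is kept when its standard deviation across all supplied samples lies in
`[sd_low, sd_high]` (defaults 0.001 and 3.0) and at most `max_low_samples`
samples (default 35, or a configurable fraction of the fold size) fall below
the expression floor (default 5.0 on the log2 scale). In leakage-safe runs the
filter sees training-fold samples only.

## 3. Repeated-measures moderated differential expression

Per gene we fit a four-cell means model (term·T1, term·T2, sPTB·T1, sPTB·T2)
by generalized least squares under compound symmetry: each subject's (T1, T2)
residual pair shares one **consensus correlation** ρ estimated across genes.
Because the design is balanced within subject, the GLS cell means coincide
with ordinary per-cell sample means; ρ enters through the whitened residual
variance,

    s²_g = Σ_i (r²_{i1} + r²_{i2} − 2ρ r_{i1} r_{i2}) / ((1 − ρ²) (N − 4)),

with N the number of samples, and through the contrast variance factors:
`1/n_case + 1/n_ctrl` for the between-group contrasts at T1 and T2,
`2(1 − ρ)/n_group` for the within-group T2 − T1 contrasts, and
`2(1 − ρ)(1/n_case + 1/n_ctrl)` for the trajectory contrast — exactly the
paired-difference variances, verified against explicit Ω-matrix algebra in the
test suite to 1e-10.

ρ is estimated as the tanh of a 10%-trimmed mean of atanh-transformed per-gene
correlations of (T1, T2) cell-mean residual pairs, clipped to [0, 0.99].

Per-gene variances are moderated by empirical Bayes: a scaled
inverse-chi-square prior (d₀, s₀²) is fitted by method of moments on log s²_g
(digamma/trigamma moment equations; trigamma inverted by Newton's method, d₀
capped at 10⁶), giving posterior variances
`s²_post = (d₀ s₀² + d s²_g)/(d₀ + d)` and moderated t statistics on d₀ + d
degrees of freedom. Five contrasts are tested (sPTB vs term at T1, at T2;
T2 vs T1 within each group; the trajectory difference). Benjamini–Hochberg
correction is applied per contrast across genes (a pooled option exists); a
gene is differentially expressed when any contrast's adjusted p < α = 0.05.
The BH step-up is hand-rolled (sort, p·m/rank, reverse cumulative minimum,
cap at 1) and tested against an independent reference implementation.

This stage is also exposed as a fittable model object,
`RepeatedMeasuresDE(study).fit() → DEResults` with a text `summary()`.

## 4. Features and stepwise additive selection (SAS)

Each selected gene contributes three base features per subject — T1, T2 and
dT = T2 − T1 — plus three within-gene product terms (T1·T2, T1·dT, T2·dT)
flagged as interaction candidates.

SAS is a greedy forward search: starting from an empty model (score defined
as 0.5), each remaining candidate is scored by the mean validation AUROC of an
unregularized logistic regression over 5 stratified inner folds (redrawn every
iteration); the best candidate is admitted when it beats the current score by
ε = 0.015. Three consecutive failures terminate (patience), as do the caps of
30 features and 5 interactions. Candidate scoring is vectorized: all
candidates are fitted simultaneously by a batched Newton solver for the
logistic likelihood (ridge 1e-8 and step damping stabilize separable folds;
with the iteration cap this plays the role of the usual iteration-limited
maximum-likelihood fit and leaves the candidate ranking unchanged, verified
against per-candidate scikit-learn refits). Ties break to the higher score,
then lexicographically.

## 5. Model families

Five families sit behind one train/predict contract: unregularized logistic
regression (LR; Newton-CG), ridge logistic regression (LR_reg; C tuned on a
log grid by stratified 5-fold AUROC), elastic net (LR_ELN; saga, C × l1_ratio
grid; internal selection = nonzero coefficients), random forest (RF; 200
trees, depth/min-split/min-leaf grid; internal selection = impurity importance
above the uniform share 1/p), and a two-hidden-layer MLP implemented in NumPy
(Leaky ReLU 0.01, batch norm, dropout, Adam on logistic loss with weight
decay) tuned by successive halving (budget 20 by default, 500 at full scale,
reduction factor 4, 250-epoch cap, stratified 80/20 validation split, winner
refit on all training rows). All families except the scale-invariant RF
consume features standardized with training-row statistics only; constant
training columns are dropped with a warning; an all-constant matrix yields a
declared no-skill model scoring 0.5.

## 6. Orchestration: safe vs prone, permutation control

An experiment is a repeated stratified subject-level k-fold plan (default
2×5 = 10 outer iterations). In **safe** mode, filtering, ρ estimation, DE,
gene selection, feature construction and SAS are computed inside each
training partition; held-out and external subjects meet only a frozen model.
In **prone** mode (the leakage probe) DE gene selection — and by default SAS
too (`prone_scope = de_and_sas`; `de_only` is available) — is computed once on
all subjects before splitting, then the identical CV loop runs. The default
scope is selection-level because, with a calibrated BH gate, outcome-null data
passes essentially no outcome-contrast genes, so gene-list leakage alone is
invisible on null cohorts; pre-split SAS is the mechanism that measurably
inflates internal-test AUROC. The elastic net and RF consume the post-DE base
feature space directly (their internal selection substitutes for SAS); LR,
LR_reg and the MLP consume SAS output. A subject-level label-permutation
switch provides the scrambled-label overfitting control. Iterations whose DE
stage selects zero genes are recorded as degenerate and scored as a constant
no-skill classifier so null experiments complete. All randomness derives from
one root seed via `SeedSequence.spawn`; reports are bitwise reproducible. A
canary audit perturbs a held-out subject and verifies that safe-mode gene
lists and SAS traces are unchanged.

Metrics: Mann–Whitney AUROC (ties half-counted), a confusion panel at a score
threshold (undefined ratios reported as NaN and excluded from aggregation with
a logged count), and cross-fold means with normal-approximation 95% CIs
(clipping to [0, 1] is display-only).

## 7. Synthetic-cohort generator

Defaults mirror a 49-case / 114-control paired training cohort with a
34/64 external cohort. Per gene: baseline ~ U(3, 12), SD ~ U(0.2, 1.2) on the
log2 scale, with designated fractions re-drawn as low-variance (2%,
SD ~ U(1e-5, 9e-4)), high-variance (2%, SD ~ U(3.2, 4.5)) and low-expression
(6%, baseline ~ U(2.5, 4.5)) so the filters have real work. Residuals are
bivariate normal within subject with correlation ρ (default 0.5). Ten percent
of genes carry a gestational-age drift: a T2 mean shift ~ N(0, 0.75) applied
identically in both classes. This is a deliberate realism choice — maternal
blood expression depends strongly on gestational age, and without such genes
the two within-group contrasts are vacuous and an outcome-null cohort would
pass no genes at all, leaving nothing for null-mode experiments to act on.
Planted signals add class-difference shifts at T1, T2 or in the trajectory
(realized at T2) in disjoint gene sets recorded as ground truth; shifts that
would drive a cell mean negative raise an error rather than clamp. The
external cohort shares the gene-level truth and adds a per-gene baseline
offset ~ N(0, shift) emulating a site/batch shift.

## 8. Numerical and scale choices

The acceptance-style tests run the replicated experiments at a desk scale of
900 genes (chosen so that ≥500 genes survive filtering) while keeping the
subject counts, fold structure, replicate counts and all thresholds at their
production values; consensus-correlation recovery is tested at 5,000 genes.
These sizes are package choices for a single-CPU run budget; the pipeline
itself has no scale-dependent switches. Batched linear algebra (einsum-based
Newton solves, vectorized rank-based AUROC) keeps the SAS inner loop the only
expensive stage.

## 9. Limitations

- The generator is Gaussian and additive on the log2 scale: no heavy tails,
  probe-level artifacts, batch structure within a cohort, or mean–variance
  dependence beyond the designated fractions.
- Compound symmetry is both generated and assumed; the consensus-correlation
  model is therefore well-specified here, which flatters the DE stage relative
  to real arrays.
- The external shift moves only per-gene baselines; real site effects also
  change variances and correlations.
- The no-penalty logistic fits rely on iteration caps / tiny ridge for
  separable folds; coefficients on separable data are not meaningful even
  though rankings (AUROC) are stable.
- The permutation control retrains models on features chosen from the
  unpermuted data, mirroring the original design; it therefore measures
  memorization capacity, not end-to-end selection bias (the prone mode
  measures that).
- Confidence intervals across folds use a normal approximation with the fold
  count as n; folds share subjects across repeats, so these CIs are
  descriptive, not inferential.
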