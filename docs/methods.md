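# Methods

This note documents the models, the numerical choices, what the synthetic
data does and does not emulate, and the places where the design was
genuinely open.

## In vitro → in vivo extrapolation

Under competitive Michaelis–Menten inhibition the apparent Michaelis
constant is K_m,i = K_m (1 + [I]/K_i). Because pharmacokinetic AUC is
inversely proportional to intrinsic clearance and V_max is unchanged by a
competitive inhibitor, the AUC fold change is R = 1 + [I]/K_i; at low
substrate concentration the Cheng–Prusoff relation
K_i = IC50 / (1 + [S]/K_m) collapses to K_i ≈ IC50, giving R = 1 + [I]/IC50.
The relation also holds for noncompetitive inhibition; uncompetitive or
multi-enzyme kinetics are out of scope.

**Inhibitor concentration.** The dose-based variants convert the maximum
recommended daily dose as [I] (µM) = MRDD (mg/kg/day) × BA / MW (g/mol) ×
1000, i.e. daily µmol per kg of body mass read as µmol/L (1 kg of body mass
≈ 1 L of distribution volume). This is the only conversion consistent with
the bundled extrapolation table: it reproduces the printed R values of
glibenclamide, diltiazem, losartan, nifedipine and methoxsalen exactly at
two decimals. Variants: R-1 uses the reported oral bioavailability, R-2 a
predicted (ADME-model) bioavailability supplied as a column (prediction
itself is out of scope), R-3 forces BA = 100%, R-4 uses C_max directly.

**Confidence intervals** on R are propagated by interval inversion of the
IC50 CI: lower = 1 + [I]/IC50_hi, upper = 1 + [I]/IC50_lo, with +∞ when the
IC50 CI touches zero. Single-measurement IC50s get a ±6.90 µM CI (the
average standard error of the multiply-measured compounds), clipped at 0.

**Categorization.** P if R > 2 and the CI lower bound > 2; W if
1.25 ≤ R ≤ 2 with the CI inside [1.25, 2]; otherwise ND. The bundled table
contains three cells where the published calls deviate from this rule
(methoxsalen C-1 printed W at R = 1.07; omeprazole C-1/C-3 printed W with
threshold-crossing CIs; ketoconazole C-4 printed P with a CI lower bound of
exactly 2.00). The implementation follows the stated rule and reports these
rows as divergences rather than special-casing them.

**Display rounding** is half-up to two decimals; computation is full
precision. Rows whose printed IC50 carries more than 1% relative rounding
error (clotrimazole 0.07, ketoconazole 0.13 µM) are flagged: their printed
R cannot be reproduced exactly from printed inputs, only to within the
interval implied by IC50 ± 0.005 µM. Because the compound table prints
integer molecular weights, a few cells (e.g. irbesartan R-1, diltiazem R-3)
differ from the published values by one unit in the second decimal.

## Molecular-weight banding

The fraction of HTS-active compounds rises with MW to a plateau near 0.5.
The band threshold is the intersection of a logistic fit
y = a/[1 + (x0/x)^b] (MW ≤ 950 Da) with a straight line fitted on
150–550 Da, solved by bracketing plus Brent root-finding, taking the root
nearest the upper end of the linear range; a four-parameter Weibull peak
(SigmaPlot parameterization) is fitted over the full domain for the
bell-shaped family. Fits are unweighted by default (matching the
plotting-tool workflow that produced the published r² values); per-bin
total-count weighting is available. Histogram bins are 50 Da wide and
anchored at 0; empty bins are excluded from fitting. A near-flat line
(|slope| < 1e-6) cannot define a threshold and flags the intersection.

Proportion statistics use the Wilson score interval without continuity
correction and the pooled-variance one-tailed two-proportion z-test, both
with the exact normal quantile (1.959964…; a switch restores the textbook
1.96). Power uses the normal approximation
z_power = (|p1 − p2| − z_α·SE0)/SE1 with SE0 pooled under H0 and SE1
unpooled; the exact formula behind the published β = 0.0676 is unknown
(proprietary software internals), and this approximation reproduces the
93% power to within ±0.02, which is the tolerance the tests assert.
Expected-count intervals scale the Wilson interval of a prior proportion to
the evaluated set size and round to the nearest integers.

## Docking-score logistic regression (DLR)

Scores are standardized per column with training-set mean and sample SD
(n − 1; a convention switch exists — the source convention is unstated),
and apply-time data reuse the stored statistics. Fitting is maximum
likelihood (Newton/IRLS via statsmodels) with Wald χ² = (coef/SE)² from the
observed information. When the likelihood separates (a real risk with 28
correlated columns on 121 compounds) the model is refit with a small L2
penalty (α = 0.01, intercept unpenalized) and Wald statistics come from the
penalized information; such models are flagged and their statistics treated
as stabilized approximations.

Selection procedures: *forward* adds the best Wald-significant column while
p ≤ α = 0.05 (Wald on a refit rather than a score test, for
reproducibility); *backward* starts full and drops the worst while p > α;
*manual* keeps the columns significant at α in the full model and, if the
training ROC AUC is ≤ 0.8, adds the fewest full-model columns with p < 0.10
best-first until the AUC clears the floor (unreachable floors are flagged,
not forced). Ties on p break by larger |coefficient|, then column name.

ROC analysis tabulates sensitivity/specificity over a 0.01 probability-
cutoff grid with named points A (highest cutoff at maximal specificity with
nonzero sensitivity), B (maximal accuracy, ties to the larger cutoff), C
(minimal |sens − spec|), D (lowest cutoff at maximal sensitivity); these
operational definitions are this package's own, since only the point names
are published. The AUC is computed exactly over all unique-score
thresholds, which makes it identical to the Mann–Whitney rank statistic
(ties counted half) — a fixed grid cannot guarantee that identity.

The published seven-score model ships as a fixed-coefficient scorer
(`published_model`), so compounds can be scored without re-running any docking
software; the fitting path is exercised on synthetic score matrices. The
truncated applicability domain (TD-DLR) restricts training and application
to MW > 450 Da; excluded compounds are reported as outside the domain, and
boundary compounds (MW = 450) fall in the low band.

## Spectral classifier (SDAR)

Predicted ¹³C and ¹⁵N shifts are binned at 1 and 5 ppm with bin index
floor(shift/width) on the raw predicted scale (the published bin labels'
reference scale is unstated, so only relative binning is meaningful). The
bin value is the integer peak count; a `--binary-bins` switch records
presence only. Bins populated by fewer than three distinct compounds are
dropped. Forward selection enters the bin with the largest partial F,
computed through the Wilks-Λ increment F = (Λ_p/Λ_{p+1} − 1)(n − 2 − p),
while F > 4.0; candidates that would make the within-class scatter singular
(e.g. duplicated bins) are skipped. No F-to-remove step is implemented
(entry-only, a documented divergence risk). The final discriminant is a
two-class LDA with equal priors regardless of training imbalance; the
posterior is the logistic of the discriminant score, and a row with no hits
in any selected bin is classified from the intercept and flagged
low-information. Implausible shifts (¹³C outside −20…250 ppm, ¹⁵N outside
−50…950 ppm) warn but are kept.

## Descriptor forest (SAR)

Descriptor columns are filtered by Shannon entropy of their discretized
values (columns with ≤ 10 distinct values treated as categorical, otherwise
10 equal-width bins), threshold 1.0 bit by default — the threshold that
leaves exactly 327 of the synthetic generator's 777 columns, calibrating
the mechanism rather than claiming anything about the real descriptor
software. Trees are binary CART: every (descriptor, midpoint-threshold)
pair is scanned, the split maximizing the Gini-impurity decrease is taken
(ties to the earlier column, then smaller threshold), growth stops at
purity, fewer than 2 × min_leaf = 10 compounds, or no positive decrease;
there is no pruning. The forest grows five trees sequentially, excluding
every descriptor already used — the "distinct but comparable trees" idea is
implemented as descriptor disjointness, the single biggest reimplementation
assumption in the package. A leaf predicts its class fraction; the forest
averages the five tree outputs without weights and calls potent at ≥ 0.5.
If descriptors run out the forest is returned short with a flag.

## Consensus and audits

Votes are P, W, or OUTSIDE_DOMAIN (e.g. TD-DLR below 450 Da). Out-of-domain
votes leave the denominator. Majority calls P on > 50% of in-domain votes;
conjunction and disjunction are available for comparison (their published
counts, 5 and 60 of 120, both fell outside expectation). Confidence in a
potent classification: *probable* requires all three methods able to vote
and agreeing P (a 2-of-2 unanimous vote earns only *plausible* unless
`--allow-two-voter-probable`); *plausible* is > 50% agreement; everything
else — including exactly 50%, which is untestable with three voters — is
*uncertain*. Fewer than two in-domain votes force *uncertain* with a flag.
Count audits compare potent-call counts (overall and per band) with the
expectation interval scaled from a prior; out-of-range counts are reported,
never suppressed — including the published tension where the majority
consensus called 23 of 120 against an expectation of 24–43.

## Cross-validation

Repeated k-fold (default k = 10): each repeat shuffles compounds into k
near-equal portions (unstratified by default, matching "randomly divided";
a stratified option exists), retrains from scratch on each 90% and
evaluates on the held-out 10%, with no information carried between folds.
Repeats default to 1 for the docking model and 10 for the spectral and
descriptor models. A fold whose training part lacks a class is redrawn
once, then errors. Reports give mean and SD over all folds × repeats for
sensitivity, specificity, correct classification and the two error types.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical* structure the pipeline assumes,
not chemistry:

* **Library**: log₁₀ MW ~ N(2.47376, 0.17161), solved numerically (two
  moment conditions) so that compounds accepted by the published activity
  sigmoid y = 0.5047/[1 + (285.1/x)^6.266] have exactly the reported active
  log₁₀ mean 2.578 and SD 0.1313; the high-MW band then comes out ≈ 49–50%
  active. Activity is Bernoulli at the sigmoid value.
* **Inhibitor sets** (training/evaluation cohorts) encode the clinical
  composition directly: high band with probability 39/121, MW from the
  inhibitor lognormal (log₁₀ mean 2.578, SD 0.1885) truncated to the band,
  potency Bernoulli at 15/82 (low) or 18/39 (high). A clinical cohort is
  not an HTS draw, so these marginals are imposed, not emergent.
* **Docking scores**: 28 columns mixing an MW latent, a single per-compound
  binding-affinity latent (potent compounds shifted by 2.0 against unit
  noise) loading at 0.6 on seven catalytic-site columns, and independent
  noise. Routing all class signal through one latent reflects that the four
  programs rescore the same binding event, and it keeps the joint signal
  bounded so the full logistic model does not separate. Noise vectors are
  orthonormalized in-sample, so each column's realized correlation with
  log₁₀ MW equals its drawn target inside [0.35, 0.75] exactly. Column
  structure (signs, targets) is shared between training and evaluation
  sets; only compound-level noise differs.
* **Spectra**: ¹³C peak count ~ Poisson(MW/13) — a crude carbon-count
  proxy, a synthetic convention, not chemistry — scattered uniformly over
  0–200 ppm, plus Poisson(2) ¹⁵N peaks over 0–400 ppm; three carbon bins
  and two nitrogen bins receive class-conditional extra peaks (potent hit
  probability 0.95, weak 0.03).
* **Descriptors**: 450 low-information columns (constants and rare
  indicators, entropy < 1 bit), 25 informative columns (class shift 2.0,
  some also loading on MW), 302 noise columns; the entropy filter then
  passes exactly 327.

The three views are conditionally independent given (class, MW); the real
data share chemistry across views, so real correlated errors are not
emulated. Effect sizes were chosen once so that held-out performance orders
as docking ≥ descriptors ≈ spectra and the end-to-end consensus is
calibrated (potent-call counts on a fresh 120-compound set fall inside the
24–43 expectation interval in ≥ 90% of seeds); passing tests therefore
demonstrate the pipeline's statistical correctness on data with known
structure, not field performance on real compounds. One visible consequence
of the synthetic data's separability: forest trees need only ~3 descriptors
each, versus the 6.6 average reported on real descriptor tables, so that
figure is checked as an order of magnitude only.

All randomness flows from one integer seed through named NumPy
`SeedSequence` spawn keys (library 0, score structure 1, per-dataset noise
streams 10+/20+/30+/40+), giving bit-identical output across runs and
platforms.

## Problem sizes in the test suite

Tests run the study-sized problems (121 training, 120 evaluation
compounds, 28 scores, 777 descriptors). Stochastic properties use 10–100
fixed seeds: 100 for the selection-frequency and consensus-calibration
checks, 10 for accuracy-band checks; the full suite completes in a few
minutes on one CPU.

## Known limitations

* The published calls in three extrapolation-table cells deviate from the
  stated categorization rule; the package reports, and does not reproduce,
  those cells.
* Isoniazid's published R-1 equals its R-3 despite 80% bioavailability; the
  package computes 9.83 from the stated inputs and leaves the discrepancy
  visible.
* Wald-based stepwise selection differs from score-test-based entry used by
  some commercial implementations; selected subsets can differ on
  borderline columns.
* The L2-stabilized fallback under separation gives conservative,
  approximate Wald statistics; flagged models should not be interpreted
  inferentially.
* Real cross-validation means from the study are not reproducible without
  the proprietary docking scores, predicted spectra, and descriptor tables;
  they are covered by structural and calibration tests only.
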