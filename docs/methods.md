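# Methods

This note documents the statistical procedures, their assumptions, the
parameter defaults and the numerical choices made where the design was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Grey relational analysis

Deng-style GRA treats each assay's activity series across samples as the
reference series and each compound's abundance series as a comparison
series. Series are first normalized; the default is mean normalization
(x/mean(x)), which is invariant to sample ordering and to a common
rescaling of all series — appropriate for heterogeneous-scale data where
initial-value normalization would hinge on an arbitrary first sample.
Initial-value, min–max and no normalization are selectable for
sensitivity analysis.

The distinguishing coefficient defaults to ρ = 0.5, the near-universal
GRA convention. Δmin and Δmax are taken over **all** compounds and
samples of an assay jointly (the global convention); a per-compound
variant exists in the literature and would change absolute GRD values
but rarely rankings. Because commercial statistics platforms do not
disclose their normalization/ρ/Δ conventions, printed GRD tables from
other software are treated as rank fixtures, not as values to reproduce
digit-for-digit.

Properties relied on and tested: ξᵢ(k) ∈ (0,1]; GRD = 1 exactly when
the normalized series coincide; GRD non-decreasing in ρ and → 1 as
ρ → ∞; exact agreement with a naive loop evaluation of the definition.

## PLS regression

Single-response NIPALS with deflation of both X and y. Preprocessing
defaults to autoscaling (unit variance, ddof = 1) of X and y — the
standard in chemometrics suites, and required for the coefficient
threshold of 0.1 to be meaningful (it is a standardized-coefficient
scale). A zero-variance predictor column is a hard error naming the
compound. NIPALS uses a weight-change tolerance of 1e-12 with a
500-iteration cap; with a single response the loop converges in one
pass, the cap guards a future multi-response extension.

- R²Y(cum) is the summed per-component explained y-variance on training
  data (components are orthogonal, so contributions add).
- Q²(A) = 1 − PRESS(A)/TSS from K-fold cross-validation, K = 7 by
  default, fold assignment by contiguous blocks after a seeded shuffle,
  preprocessing re-estimated inside each training fold, TSS around the
  full-sample mean. Q²cum is reported as the single number 1 − PRESS/TSS
  at the selected A rather than the multiplicative per-component form.
- Component selection: smallest A whose Q² is within 0.01 of the
  maximum ("max_q2", default), or grow-while-ΔQ² > 0.05
  ("gain_threshold"). All-negative Q² profiles fall back to A = 1 with a
  warning rather than refusing to fit.
- VIP_j = sqrt(p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a) with
  SSY_a = q_a²·t_aᵀt_a; mean(VIP²) = 1 is asserted to 1e-8.
- Standardized coefficients b = W(PᵀW)⁻¹q on the scaled metric; at
  A = rank(X) they coincide with standardized OLS.

The permutation test shuffles y (default 199 permutations, giving p
resolution 1/200), refits the model and the CV Q² for each shuffle, and
reports the empirical one-sided p-value
(1 + #{Q²_perm ≥ Q²_obs})/(n_perm + 1) plus intercepts of the
statistic-vs-|cor(y_perm, y)| regression lines, the observed model
included at |r| = 1 (the convention of the common validation plot).

## Screening rules

Candidates per assay: VIP > 1 and coefficient > 0.1, both strict — a
compound sitting exactly on a threshold is excluded. The coefficient is
signed by default (a positive-contribution reading); an absolute-value
mode is available because the convention is ambiguous when negative
contributors are plausible. Candidate sets of assays probing the same
activity are unioned (antioxidant = DPPH ∪ FRAP), recording which
assay(s) selected each compound. GRD annotates candidates with a flag
when below the 0.9 floor but never removes them: in the motivating data
all 22 GRDs exceeded 0.9, so GRA corroborates rather than filters.

## Synthetic cohorts

The generator emulates the study design so that recovery is testable:

- 31 samples in two species groups (17 + 14); 22 compounds, 9
  phenylpropionic acids and 13 flavonoids.
- log-normal peak areas; per-compound log-means span ~2 decades around
  1e6 (arbitrary area units) with log-SD 0.4, and the marker acid stored
  as peak "7" set ~30-fold above the rest, matching its dominant-content
  role. Same-class compounds share a latent factor giving log-scale
  correlation 0.3. Group 2 has −0.5 log-shift on the phenolic-acid
  actives and +0.3 on luteolin, giving the species contrast that PCA
  should resolve.
- activities: intercept + scale·(Σ w_j z_j + ε) with z_j the autoscaled
  abundances, weights equal to the printed standardized coefficients of
  the corresponding study models, and ground truth recorded. The
  antioxidant assays share their active set {1,3,5,7,18}; NO-inhibition
  uses {8,9,13,17,18,19,20,21}.
- noise: ε ~ N(0, sd²) with sd 0.37 (DPPH), 0.50 (FRAP), 0.62
  (NO-inhibition), calibrated once so the median fitted R²Y at the
  CV-selected A lands near 0.90 / 0.86 / 0.62 — the difficulty regime
  the method is meant for. Assay intercept/scale pairs (40/18, 70/22,
  42/9) only place readouts in plausible percent / µmol-Fe(II)/g ranges
  and cancel from all scale-free statistics.
- one global seed spawns per-stage substreams (`numpy` SeedSequence), so
  peaks and activities are individually reproducible.

What the generator does **not** emulate: retention-time drift, censored
or below-LOQ areas, missing cells, non-linear dose–activity saturation,
non-Gaussian assay noise. Passing recovery tests therefore show the
chain works under its own linear-response assumptions, not that those
assumptions hold for any particular real dataset.

## Bioassay arithmetic

All core functions return fractions; percent formatting is a
presentation concern. DPPH scavenging = 1 − (A₂ − A₀)/A₁, strictly
decreasing in the sample absorbance; it is invariant to a common
rescaling of all three absorbances only when the blank A₀ = 0, which the
tests document in both directions. FRAP uses an OLS ferrous-sulfate
calibration (≥ 3 standards, r² floor 0.99 as a warning); below-blank
readings are returned negative with a flag, never clipped. Trolox
equivalents are a ratio of dose-response slopes — an assumption of
linearity over the compared range, stated rather than hidden.
NO-inhibition = (stimulated − treated)/(stimulated − unstimulated),
clipped to [0,1] with a flag.

IC50: four-parameter logistic fit (lower, upper, hill, ic50) by
nonlinear least squares, hill initialized positive but unconstrained in
sign, response on the inhibition scale. A dose responding at exactly 50%
is its own IC50 (interpolation fixed point); a failed or out-of-range
fit falls back to log-linear interpolation between the doses bracketing
50% and sets a flag; a curve never reaching 50% is censored and reported
as "IC50 > max dose" (or "< min dose"), matching assay-reporting
convention.

## Drug-likeness and admission

The rule engine evaluates editable threshold tables transcribed from the
original publications (Lipinski 2001 with ≤ 1 violation tolerated; Ghose
1999; Veber 2002; Egan 2000; Muegge 2001). Missing descriptors make a
rule "not evaluable": it leaves the denominator rather than silently
passing or failing, with a warning. RDKit supplies the Wildman–Crippen
logP; Moriguchi and XLOGP3 estimators are not available in it, so the
Lipinski and Muegge logP bounds fall back to WLOGP and the adapter
records that substitution.

GI absorption is a point-in-rotated-ellipse test in the (TPSA, WLOGP)
plane using the published BOILED-Egg white-region ellipse (center
(71.05, 2.29), axes 142.08 × 8.74, rotation −1.03°) as the default; the
boundary counts as inside. Admission: (GA high ∧ ≥ 3 of 5 rule sets
pass) ∨ (content > 20× the median of the other constituents). "Over
two rules" is read strictly as ≥ 3; both the count and the fold are
configurable because the phrasing is ambiguous.

## Problem sizes and determinism

Statistical checks run at sizes chosen to make their Monte-Carlo error
small relative to the asserted margins: 100 random instances for oracle
equivalences, 100 seeds for active-set recovery, 50 repeats × 99
permutations for the null calibration of the permutation test, 30 seeds
for the median model-quality statistics. All randomness flows through
explicit integer seeds; rerunning any test, driver or the acceptance
script with the same seed reproduces its numbers exactly.

## Known limitations

- Single-response PLS only; multi-response (PLS2) screening and OPLS are
  out of scope.
- The screening thresholds are fixed conventions, not estimated; no
  uncertainty is attached to VIP or coefficient values (bootstrap
  selection stability would be a natural extension).
- GRA values depend on undisclosed platform conventions, so cross-tool
  numerical agreement is not attempted.
- The content override uses mean peak area as the content proxy;
  response-factor differences between compounds are ignored.
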