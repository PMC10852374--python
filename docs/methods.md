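# Methods

This note documents the statistical models, the numerical choices, the
synthetic-data design and the known limitations of `quickrasch`.

## The measurement model

Responses to each QuickDASH item are ordered categories coded 0 (best,
"no difficulty") to m (worst, "unable"; m = 4 before any merging).  The
partial credit model (PCM) — the polytomous Rasch model — gives

    P(X_i = k | θ) ∝ exp( Σ_{j≤k} (θ − δ_ij) ),    δ_i0 ≡ 0,

where θ is the person's latent level (hand function for items 1–6, symptom
severity for items 9–11) and δ_ij are the item's step difficulties, all in
logits.  Two properties drive the whole pipeline:

- the δ_ij are the **Andrich thresholds**: the trait values at which
  adjacent category curves cross.  When they do not increase with category
  severity ("disordered"), adjacent response options fail to occupy
  distinct stretches of the trait and are candidates for merging;
- the raw sum Σ_i X_i is a **sufficient statistic** for θ, which is what
  licenses a sum-score-to-interval-score conversion table at all.

All probabilities are evaluated with log-sum-exp stabilisation.

## Estimation

`PartialCreditModel` fits by marginal maximum likelihood with a normal
latent prior, the same identification convention as mainstream IRT
software: prior mean fixed at 0; prior SD either estimated (default) or
fixed at 1 (`estimate_prior_sd=False`) — the study software's behaviour on
this point is not documented, so both are provided.

- **Quadrature**: 61 equally spaced nodes on [−6, 6] logits with
  renormalised normal-density weights.  Deterministic and accurate to well
  below the reporting precision for scales of 3–6 items (EAP agrees with a
  10× finer grid within 1e-3 logits; tested).
- **EM**: the E-step computes each person's posterior over the grid; the
  M-step solves each item's expected-score-matching equations by BFGS with
  the analytic gradient (the objective is concave in the cumulative
  parametrisation), and updates the prior SD by a bounded 1-D
  maximisation of the expected prior log-weight, which keeps the EM ascent
  property exactly.  The marginal log-likelihood is monitored and never
  decreases (tested to 1e-8 per cycle).
- **Convergence**: largest absolute parameter change < 1e-4 logits, at
  most 500 cycles; non-convergence returns a fit flagged
  `converged_ = False` with a warning rather than raising.
- Every category of every item must be observed at least once; otherwise
  fitting stops with an error instructing a recode (an unobservable step
  difficulty is not estimable).

Person scores are expected a posteriori (EAP) means with posterior SDs,
computed on the same grid.

## Threshold disorder and collapsing

A threshold gap g_k = δ_{k+1} − δ_k is *disordered* when g_k ≤ 0 and
*close* when 0 < g_k < 0.2 logits.  The closeness tolerance is a package
choice (exposed as a knob): "close" is a qualitative judgement in the
source literature, and 0.2 logits is small relative to the ~0.5-logit
spacing of well-behaved five-category items.  `auto_collapse` merges one
category pair at a time — the pair straddling the globally worst (most
negative) gap, ties broken toward the most severe categories, mirroring
how the published analysis merged "severe difficulty" with "unable" — and
refits until no flags remain; a per-item budget (initial categories − 2)
guarantees termination above 2 categories.

## Fit diagnostics

**Standardized residuals.** The default residual conditions each response
on the *other* items: for item i the person's posterior is built from the
rest of the pattern, and z = (x − E)/√W uses the predictive mean and
variance under that rest-posterior.  Given the rest responses, x then has
exactly mean E and variance W under the model, so infit and outfit are
centred at 1 by construction — verified by simulation (per-item medians
within [0.9, 1.1] across 200 replicates).  The classical plug-in
construction (model moments at the full-pattern EAP) is available as
`method="plugin"`; on a six-item scale its mean squares sit near 0.85
under the model because the trait estimate adapts to the response it is
judged against.  The plug-in flavour is the one under which redundant,
quasi-deterministic items produce the famous mean squares below 0.5, so
the overfit flag is assessed on it.  The acceptance band (0.5, 1.7) is the
conventional one.

**Item chi-square.** A rest-score (Orlando–Thissen S-X²-style) statistic:
persons are grouped by their sum over the other items, model-expected
category frequencies per rest score come from the Lord–Wingersky
distribution integrated over the prior, adjacent cells with expected
count < 5 are pooled, and rows reduced to a single cell are dropped.
Degrees of freedom are Σ_rows (cells − 1), minus the item's step
parameters when the model was estimated from the same data (each row
carries a sum constraint because expected counts are scaled to the
observed row total).  Type-I error is calibrated: rejection rate 0.02–0.10
at nominal 0.05 across simulation replicates (tested).  This construction
was chosen over ability-binned Pearson tests because it reuses the
sum-score recursion and avoids arbitrary binning; it is not guaranteed to
match the unnamed chi-square variant of any particular software.

**Local dependence.** Yen's Q3: Pearson correlations of the residual
columns; pairs above 0.2 are flagged.  Under local independence Q3 sits
slightly below zero (it is computed from residuals on a finite scale);
testlet-induced dependence with loading γ ≈ 1.5 at n = 2000 cleanly
crosses the 0.2 flag (tested).

**Scale-level fit.** A limited-information chi-square: the residual
between observed and model-implied univariate and bivariate margin
proportions (category 0 dropped per item), in a quadratic form weighted by
the pseudo-inverse of the empirical covariance of the per-person margin
indicators.  The inverse is taken by eigen-decomposition, discarding
directions with eigenvalues below 1e-2 of the largest: those directions
are poorly estimated at cohort-sized n and would otherwise inflate the
statistic (T/df ≈ 1.5–2 under the model; with truncation T/df ≈ 1).
Degrees of freedom are the retained rank minus the number of estimated
parameters; the baseline for CFI/TLI is the independence model with
observed univariate margins; RMSEA = √(max(0, (χ²−df)/(df·n))).  SRMR is
the RMS difference between observed and model-implied inter-item Pearson
correlations with model moments by quadrature.  Because parameter
estimation is not propagated into the weight matrix the chi-square is
mildly conservative; the index cutoffs (CFI/TLI ≥ 0.950, RMSEA < 0.060,
SRMR ≤ 0.080, α in (0.7, 0.95)) are met on model-consistent cohorts and
violated under two-dimensional misfit (tested).  The global χ² p-value is
expected to be significant at these sample sizes and is reported but not
used as a pass criterion.

**Option curves.** Observed option proportions are smoothed against the
*item-rest* EAP by local-linear Gaussian-kernel regression (Silverman
bandwidth, floor 0.3 logits); the expected curve applies the identical
smoother to the rest-posterior predictive probability, so under the model
the two curves coincide up to sampling noise (max deviation < 0.05 on the
central grid at n = 2000; tested).  Smoothing against the full-pattern EAP
and comparing with the raw ICC — the naive construction — leaves a
shrinkage artifact of ~0.1 even under perfect fit.  The raw ICC is
included as a third column for plotting.

**Targeting.** The item-person summary reports the trait-estimate
histogram, all threshold locations, the person-minus-threshold mean gap,
the sample skewness of the trait estimates, and floor/ceiling percentages
(persons at the all-best/all-worst pattern estimate).

## Crosswalks

For each attainable sum s, EAP(θ | S = s) is computed from the
Lord–Wingersky distribution and the prior; scores are rescaled linearly in
logits so the extremes map to 0 and 100, then rounded half-up.  Endpoint
behaviour is the only rescaling convention verifiable against the
published tables, which print integers with endpoints 0 and 100.  Fitted
crosswalks are labelled by condition and subscale and lookups enforce the
labels: the Dupuytren and CTS scores are not interchangeable.  The four
published tables ship as packaged CSV reference data tagged
`provenance="paper"`; the Dupuytren symptoms table always loads with a
warning that those items are not recommended in that condition.

## Synthetic cohorts

The study's patient data are not deposited, so `quickrasch.simulate`
generates PCM cohorts that reproduce the published findings qualitatively:

- `cts_tasks` / `cts_symptoms`: n = 1851 (the CTS complete-case count),
  trait N(0, 1), ordered steps spanning the trait — well targeted, no
  disorder, Mokken H comfortably above 0.3.
- `dupuytren_tasks` / `dupuytren_symptoms`: n = 731 (the Dupuytren
  complete-case count), negatively skewed trait (skew-normal, shape −10,
  SD 1.1, mean 0) and items whose two top steps are reversed
  (δ_top < δ_{top−1}) around hard-end anchors 1–1.5 logits above the
  person mean.  The lower steps reach well down (anchor − 2.8) so the
  skewed lower tail is resolved rather than clumped at the floor; with
  items floored, EAP compression would otherwise erase the sample
  skewness the fixture exists to exhibit.  Across seeds this geometry
  yields trait-estimate skewness ≈ −0.33 to −0.46, top-step disorder
  detected on ≥ 5 of 6 items, and H ≈ 0.36–0.42.

Randomness uses one root seed with independent child streams for trait,
testlet and response draws, so adding a zero-loading testlet does not
perturb the other draws.  `inject_ld` adds a shared standard-normal
person component with loading γ to a chosen item pair.

What these fixtures do *not* emulate: real response styles, missingness,
differential item functioning, multidimensionality beyond the explicit
testlets, and the actual (unknown) threshold locations of the clinical
cohorts.  Passing tests on them demonstrates that each pipeline stage
detects what it claims to detect under controlled conditions — not that
the published item parameters are reproduced, which is impossible without
the patient data.

## Problem sizes

Calibration and recovery checks run at n = 2000 (six 5-category items),
the fixtures at their cohort sizes (1851 / 731), replicate-based
calibration at 150–200 replicates of n = 250–500 with the statistic
evaluated at the known generating parameters (no refit per replicate).
At these sizes step-difficulty recovery RMSE is ≈ 0.08 logits and fitted
crosswalks deviate at most 1 point from the generating model's table.

## Known limitations

- Conditional maximum likelihood, WLE person estimates, the rating scale
  model, free-slope (generalized partial credit) models and DIF analysis
  are out of scope.
- The scale-level chi-square uses an empirical weight matrix with
  eigenvalue truncation rather than the full M2 machinery; its p-value is
  conservative and should be read alongside the indices.
- The published conversion tables are transcribed reference data; the
  package can reproduce their *shape* (ranges, monotonicity, endpoints)
  and scoring-rule anchors from simulation, but their exact interior
  values depend on the undeposited cohorts.
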