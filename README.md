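# quickrasch

Rasch-measurement tooling for interval-level rescoring of the QuickDASH
questionnaire in two common hand conditions, Dupuytren disease and carpal
tunnel syndrome (CTS).

The QuickDASH scores 11 upper-limb items on a five-point Likert scale
("no difficulty" … "unable") and sums them as if the steps between options
were equally spaced.  They are not: the raw sum is ordinal, and treating it
as continuous can hide or invent clinically relevant change.  This package
implements the full Rasch workflow that turns two QuickDASH subscales —
the task-based items 1–6 and the symptoms-based items 9–11 — into
interval-level 0–100 scales:

1. **Mokken scalability screening** — Loevinger's
   *H<sub>ij</sub> = cov(X_i, X_j) / cov_max(X_i, X_j)* with the
   comonotonic maximum, scale coefficients as ratios of summed covariances
   (acceptable above 0.3).
2. **Partial credit model (PCM) calibration** — for item *i* with step
   difficulties δ<sub>i1</sub>…δ<sub>im</sub>,

   P(X_i = k | θ) = exp( Σ_{j≤k} (θ − δ_ij) ) / Σ_h exp( Σ_{j≤h} (θ − δ_ih) ),

   estimated by marginal maximum likelihood (EM on a fixed quadrature
   grid) with a normal latent prior, mean 0, SD estimated or fixed.
3. **Threshold diagnostics and category collapsing** — the Andrich
   thresholds are the δ<sub>ik</sub>; disordered (δ<sub>ik</sub> ≥
   δ<sub>i,k+1</sub>) or close thresholds trigger merging of the adjacent
   response options, iterating fit → flag → merge → refit.
4. **Fit assessment** — infit/outfit mean squares with the (0.5, 1.7)
   band, a rest-score item chi-square, Yen's Q3 for local dependence
   (flag > 0.2), Cronbach's alpha, and limited-information scale indices
   (χ², CFI, TLI, RMSEA, SRMR) with the usual cutoffs, plus smoothed
   empirical option curves and item–person targeting summaries.
5. **Sum-score EAP crosswalks** — the Lord–Wingersky recursion gives
   P(S = s | θ); the posterior mean trait per sum score is rescaled so
   the attainable extremes map to 0 and 100.

The published condition-specific scoring rules ship with the package: in
Dupuytren disease the two worst options of items 1–6 score equally; in CTS
items 1–6 need no modification, items 9–10 merge the two best options and
item 11 additionally the two worst.  The four published raw-to-Rasch
conversion tables are included as reference data.  The study cohorts
themselves are not publicly deposited, so a synthetic-cohort generator
(`quickrasch.simulate`) reproduces their qualitative structure — a
well-targeted CTS-like cohort and a negatively skewed, mis-targeted
Dupuytren-like cohort with disordered top thresholds — making every stage
testable end to end.

## Worked example

```python
from quickrasch import (simulate, paper_like_fixture, scale_H,
                        PartialCreditModel, build_crosswalk,
                        andrich_thresholds)

cohort = simulate(paper_like_fixture("cts_tasks", seed=1))
print(f"cohort: {cohort.n_persons} persons x {cohort.n_items} items")

mok = scale_H(cohort)
print(f"Loevinger H (scale) = {mok.H_scale:.3f}")

pcm = PartialCreditModel().fit(cohort)          # sklearn-style estimator
print(f"converged in {pcm.n_cycles_} EM cycles; prior SD = {pcm.prior_sd_:.3f}")

report = andrich_thresholds(pcm, tol=0.2)
print(f"items with disordered thresholds: {report.n_disordered_items()}")

table = build_crosswalk(pcm, "cts", "tasks")
print(table.to_frame().head(4).to_string(index=False))
```

prints

```
cohort: 1851 persons x 6 items
Loevinger H (scale) = 0.453
converged in 28 EM cycles; prior SD = 0.962
items with disordered thresholds: 0
 raw_score  theta_eap  rasch_score
         6  -2.427980            0
         7  -2.130745            6
         8  -1.867760           12
         9  -1.630629           16
```

The scale coefficient clears the 0.3 gate, no response options need
merging, and the crosswalk maps each raw questionnaire sum (6 = best
possible on six items) to its posterior-mean trait in logits and a 0–100
interval score.  `PartialCreditModel.transform` returns each person's EAP
trait estimate and posterior SD, and composes with scikit-learn pipelines.

Scoring real responses with the published rules instead:

```sh
quickrasch score responses.csv --condition cts --subscale tasks
quickrasch run --input responses.csv --condition dupuytren \
    --subscale tasks --collapse paper --out-dir results/
```

`quickrasch run` executes the whole pipeline (Mokken gate → PCM →
thresholds → collapse → diagnostics → crosswalk) and writes a versioned
JSON/CSV report bundle; `--collapse auto` lets the data drive the merging
instead of the published rules.

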