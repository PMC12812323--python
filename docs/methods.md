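# Methods

## The scoring model

One encounter is scored at a time. `classify_regimen` reduces raw orders to
the best prescription per GDMT class: within a class (and within the RASI
slot across ACEI/ARB/ARNI subtypes) the order with the highest fraction of
its own drug's target daily dose wins, and fractions are never summed across
drugs or subtypes (co-prescribed RASI subtypes raise a warning). Dose credit
is continuous (`dose/target`, capped at 1), not per titration step, so small
intensifications (e.g. carvedilol 25 → 50 mg/day) move the score.

Eligibility is assessed per class with configurable strict-threshold rules.
Defaults: contraindication of the MRA at K⁺ > 5.0 mmol/L or eGFR < 30, the
SGLT2 inhibitor at eGFR < 20, the RASI at K⁺ > 5.5 or SBP < 90 mmHg, the
beta-blocker at pulse < 55 bpm; up-titration (not continuation) of
RASI/beta-blocker is blocked at SBP < 95, and of the beta-blocker at
pulse < 60. Intolerant and contraindicated classes leave numerator and
denominator (equivalently treated, since a rule-contraindicated patient is
no more able to take the drug than an intolerant one); an escalation-blocked
class already on drug earns its full point. A missing vital or lab needed by
a rule is conservative: the rule does not fire and the gap is annotated, so
patients are never excluded on absent data. If every class is excluded the
score is returned as undefined with a flag — never silently 0 or 100.

Class weights are equal (one possible point each). The deployed clinical
algorithm's exact internal point table is proprietary/unpublished, so the
weights live in configuration; equal weighting preserves the printed 0–100
fraction-of-target semantics. Race is accepted and stored but drives no
scoring rule by default (hydralazine/isosorbide is outside the four scored
classes).

Comparators follow their printed schemes exactly. HFC: 0/1/2 by the 50%
threshold (closed at 0.5) for beta-blocker and ACEI/ARB, 2 for any MRA dose,
3 for any ARNI dose (ARNI supersedes ACEI/ARB in the RASI slot), range 0–7;
a contraindicated class earns its slot maximum, and the RASI slot maximum is
taken as 3 (whether a never-attempted ARNI should cap at 2 is unstated —
the slot maximum is used and flagged here). mHFC: the ARNI is scored as its
sacubitril and valsartan components (0–2 each); because the combination is
fixed-ratio, each component sits at the same fraction of its component
target as the total dose. MRA uses the same 0/1/2 rule in mHFC (the printed
"each class" rule), unlike its any-dose rule in HFC. KCMO averages
prescribed-to-target proportions over eligible classes with the MRA binary.

## Risk indices

The CCI ships the original 17-group integer weights with the three standard
hierarchies (diabetes ± complications, liver disease severity, malignancy vs
metastasis); inputs are condition-group labels, not ICD codes. Categories:
mild 1–2, moderate 3–4, severe ≥ 5; a score of 0 is binned with mild and
annotated rather than dropped. The HFPSI point map (thresholds on BUN at
20/30/40 mg/dL and BNP at 300/900/1800 pg/mL, one point each for NYHA ≥ 3,
diabetes, AF/flutter and recent hospitalization, cuts 2/4/6 onto classes
1–4) is an explicitly configurable stand-in with the correct monotone
structure — the published derivation weights are not reproduced — and any
component absent makes the index missing, which drives cohort exclusion.

## Exposure construction

Encounters are binned into half-open 182-day intervals from the index date
(k = ⌊days/182⌋, capped at 7 by default; the index encounter is interval 0).
Per-interval exposure is the arithmetic mean MOS; visit-free intervals carry
the last observed interval mean forward (the analysis is silent on gaps;
carry-forward is the package's choice and the lagged cumulative exposure is
unaffected because it averages raw encounters). The model-C exposure at
interval k ≥ 1 is the mean of all encounter-level MOS values strictly before
day 182k — recomputed per at-risk row, so an interval after a visit gap
still sees every prior encounter — and the baseline interval mean at k = 0.
Tertiles use linear-interpolation 33rd/67th percentiles with ties going
down; a degenerate distribution yields all-T1 with a warning. Counting
process rows are [182k, min(182(k+1), T)) with the event on the terminal row
only; boundary events close the earlier row; person-years = risk days /
365.25.

## Survival models

Cox fits use the Efron tie correction (day-granular data produce ties), a
Newton solver tightened to 1e-9 (so small-sample coefficients agree with the
brute-force partial-likelihood maximum to 1e-4), and normal-approximation
95% CIs on the log-HR scale. Model A: baseline MOS/10, single spell per
patient. Model B adds age/10, sex, race, ethnicity, HFPSI class (reference
1) and CCI category (reference mild); model-based SEs are used for A/B,
cluster-robust (by patient) for the counting-process model C — robust SEs
are stated only for the time-varying models. Covariates that are constant in
a given sample are dropped with a warning rather than failing the fit. The
proportional-hazards diagnostic regresses scaled Schoenfeld residuals on
ranked event time; the "global" row is a Bonferroni combination of the
per-covariate p-values (a screen, not a joint test). KM curves use Greenwood
variance with log(−log) confidence bands, and the reporting layer plots
1 − S(t).

## The marginal structural model

The continuous exposure makes IPTW a density ratio. Both exposure models are
linear regressions of current MOS with homoscedastic Gaussian residuals
(residual SD from SSR/df); the numerator conditions on exposure history
(prior MOS, baseline MOS, and the observed titration rate so far — all
legitimate stabilization terms), baseline demographics and categorical
interval indicators (no linearity imposed on baseline drift); the
denominator adds one-interval-lagged HFPSI and CCI, the lag ensuring
conditioning only on information available before the exposure. The
history terms matter in practice: they absorb the patient-specific random
titration slope, which is not otherwise observable, and roughly a third of
the MSM estimator's sampling SD with it. IPCW uses pooled logistic models of
dropout (loss to follow-up before the administrative end of study) with the
same structure plus baseline distance in both models; administrative
censoring is treated as uninformative. Interval 0 carries weight 1 (no prior
MOS exists to model). Cumulative weights are within-patient running
products; IPTW and IPCW are each winsorized at their own pooled 1st/99th
percentiles before the row-wise product (truncating the streams separately,
then multiplying, with a documented alternative of truncating the product).
The outcome model is a weighted Cox fit of current-interval MOS/10 with
baseline-covariate adjustment and patient-clustered sandwich SEs. With
identical numerator and denominator models every weight is exactly 1 and
the fit reduces to the unweighted one.

## Trend model

REML estimates of `MOS = β0 + β1·t + u0 + u1·t + ε` with bivariate-normal
random effects; time is the 6-month interval index (the interval reading of
"per quarter (6 months)" matches the panel structure; the unit is just the
time column's scale). A singular random-effects covariance triggers a
diagonal refit (correlation fixed at 0, flagged). The random-slope LRT uses
ML refits and the 50:50 χ²(1)/χ²(2) boundary mixture. Patients at MOS = 100
at baseline are excluded upstream of the trend analysis.

## The synthetic generator

Each patient draws from an independent substream
(`default_rng([seed, index])`) with a fixed, documented draw order, so
trajectories are exactly replayable and invariant to cohort size; identical
parameters give byte-identical tables. Baseline marginals follow the target
cohort (age 64.7 ± 14.3, 35% female, 75.5/19.0/5.5% race mix, SBP
121 ± 17.3, K⁺ 4.4 ± 0.45, MOS 56 ± 21 truncated below 100, HFPSI
46.4/23.0/18.5/12.1%, CCI 19.9/21.0/59.1%). Dynamics per 182-day interval:
MOS gains `titration_mean_pp` (7.3 at reference severity) plus a patient
slope (SD 2) minus 4 pp per HFPSI level above 1, plus N(0,5) noise, clipped
to [0,100] — a net average of about +3.3 pp/interval at the baseline
severity mix, with the sickest de-escalating; HFPSI moves by a rounded
latent step with drift +0.45 and −0.08 per 10 prior MOS points (so therapy
improves severity); events follow a discrete-time hazard
`1 − exp(−h·exp(lp))` with h = 0.13 and lp = log(0.88)/10·MOS +
(0.19, 0.17, 0.69) for HFPSI 2–4 + (−0.15, 0.10) for moderate/severe CCI +
0.15·age/10, giving an overall event rate near 40 per 100 person-years and
follow-up near 1.1 years; dropout is logistic in distance (intercept −2.4,
+0.004/km on lognormal(3.7, 0.9) km distances). Event days are uniform
within the interval (the analysis consumes counting-process rows, not
continuous times); the death/hospitalization split is configurable and
ignored by the composite endpoint. Eight intervals (0–7) are generated by
default, with the count exposed as a parameter.

Medication-level generation inverts the score: per-class dose fractions are
filled greedily in a fixed class order to sum to 4·MOS/100, doses emitted as
fraction × target (exact, so the scoring engine reproduces the latent MOS to
float precision; an optional snap-to-titration-grid mode uses the nearest
representable score and logs the adjustment). Vitals/labs are drawn around
the cohort means but clipped strictly inside every eligibility threshold so
all four classes stay eligible — intolerances default to none — and
encounter counts per interval are Poisson(3) with the index encounter fixed
at day 0.

What the generator does *not* emulate: pharmacokinetics and adherence,
competing risks, within-interval ordering of encounters relative to events,
informative visit timing, measurement error in labs, and correlation between
baseline MOS and baseline severity (baseline exposure is deliberately
unconfounded so that interval-0 rows, which carry weight 1, do not bias the
MSM). Passing tests therefore show estimator correctness under the assumed
structure, not robustness to these real-data features.

## Known numerical and inferential limitations

* The MSM's linear-Gaussian exposure density is misspecified at the score
  bounds (≈11% of exposure rows sit at 100 under defaults); together with
  the mediated pathway past-MOS → severity → hazard that a
  current-exposure-only outcome model partially absorbs, this leaves a small
  negative offset (≈ −0.02 log-HR at n = 2000) in the MSM estimate relative
  to the conditional truth. An outcome model with both current and
  cumulative exposure removes the mediation issue in principle but is too
  collinear at 8 intervals to be useful (estimator SD quadruples); the
  current-exposure model is kept and the offset documented. The MSM remains
  markedly less biased than the severity-omitting naive fit.
* Weighted Cox with the Efron correction treats a weighted event row as a
  single event, so integer-weight/duplication equivalence is exact only when
  event rows carry unit weights (the equivalence test is built that way).
* MixedLM on noise-free data recovers the OLS slope to optimizer precision
  (~1e-4), not machine precision.
* The logistic censoring models are fitted by IRLS without penalization;
  with very sparse dropout per interval the interval indicators can be
  weakly identified (probabilities are clipped away from 0/1 when weights
  are formed).

## Problem sizes

Simulation-based checks use n = 2000 patients × 8 intervals for comparative
recovery (25 replicates), n = 1000 for null coverage (50 replicates), and
n = 100–600 patients for trend-model calibration — sizes at which the
Monte-Carlo error of each check is small relative to its acceptance margin
while the whole suite stays interactive.
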