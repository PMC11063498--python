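# Methods

This note records the models, conventions, and numerical choices behind the
package, and what the synthetic cohorts do and do not establish.

## The score

A deceleration carries four categorical axes — baseline rate (bradycardia /
normal / tachycardia), variability (absent / minimal / moderate / marked),
deceleration type (early / late / variable / prolonged), and severity (mild /
severe) — and receives a five-tier risk level 1–5 by table lookup. A
clinician-annotated level override always wins over the lookup, since
source data may carry expert-assigned levels.

The score of a 30-minute window (start, end] is

* Σ level over non-prolonged decelerations whose **nadir** lies in the
  window (nadir defaults to onset + duration/2 when not annotated), plus
* Σ level × round(in-window overlap, nearest minute) over prolonged
  decelerations.

Conventions the source material leaves open, fixed here:

* **Boundary membership.** Nadir-in-window for non-prolonged events;
  overlap-prorating for prolonged events, so a prolonged deceleration never
  double-counts across adjacent windows of a trajectory.
* **Rounding.** Nearest whole minute, half-up (`floor(x/60 + 0.5)`); an
  overlap under 30 s therefore contributes nothing.
* **Prolonged** means duration in [2 min, 10 min); a dip of ≥ 10 min is
  treated as a baseline change and rejected at event validation.
* **Time base** is seconds from recording start, with half-open windows
  (start, end]; the nearest-minute rounding happens only at the final step.
* **Coverage.** The DCS/RCT variants require the full 30 minutes of CTG
  before their anchor (mirroring the usual study-design exclusion of
  interrupted tracings); a window reaching before the recording start, or
  overlapping an annotated coverage gap under strict coverage, is an error.
  Sliding-score trajectories may relax this explicitly.
* An event without an assigned level is a scoring **error**, never silently
  defaulted — the level is clinical input and a default would bias scores.

## The five-tier level table

The exact published cell values of the five-tier grid are not available in
machine-readable form, so the default table ships as editable YAML
(`data/five_tier_jsog_v1.yaml`) constructed additively: a deceleration
type/severity base (none 0; early 1; variable 1–2; late 2–3; prolonged 2–3)
plus a variability-degradation term (moderate/marked 0, minimal +1, absent
+2) plus a baseline-rate term (normal 0, tachycardia +1, bradycardia +2),
clipped to 1..5. The construction satisfies the structural constraints any
five-tier dialect must have — a reassuring pattern maps to level 1, severity
and variability degradation are monotone — and every downstream computation
is table-agnostic: supply any complete, monotone table to use another
dialect. Validation of these invariants runs at table load.

## Diagnostic-accuracy statistics

* **AUC** is the Mann–Whitney probability estimate with ties counted ½,
  identical to trapezoidal integration of the ROC polygon (asserted
  exactly in the test suite). ROC points come from all distinct score
  thresholds with positivity rule *score ≥ cutoff*, matching a
  "high-score group" stratification.
* **CI**: DeLong structural-components variance with a normal interval on
  the logit scale. The plain-scale interval measurably undercovers with few
  positive outcomes (≈89% at 11 positives in our simulations of a binormal
  AUC-0.8 model), while the logit-scale interval restores ≈93% and is
  bounded in (0,1) by construction; the variance itself agrees with the
  pROC reference implementation to 1e-9.
* **Youden cutoff**: smallest maximizer of J = sens + spec − 1 among all
  candidate thresholds (favoring sensitivity, the clinically conservative
  side for this outcome), with a 1e-12 tolerance so algebraically tied J
  values are not split by floating-point noise.
* **Test selection.** Continuous variables: Shapiro–Wilk screen in every
  group (α = 0.05, configurable) chooses Welch's t test / one-way ANOVA
  versus Mann–Whitney U / Kruskal–Wallis. Proportions: chi-square, falling
  back to Fisher's exact test when any expected cell is below 5 (2×2). All
  p-values are two-sided except the one-sided sample-size design. No
  multiple-testing correction is applied; reported p-values are raw.
* **Sample size** solves the Hanley–McNeil power equation
  `z_α √V₀ + z_β √V₁ = A − ½` with the variance
  `V(A) = [A(1−A) + (m−1)(Q₁−A²) + (n−1)(Q₂−A²)]/(mn)`,
  `Q₁ = A/(2−A)`, `Q₂ = 2A²/(1+A)`, for the *continuous* number of
  positives m (negatives = ratio × m), rounds m to the nearest integer and
  scales by the ratio. For the design A = 0.80, power 0.90, one-sided
  α = 0.05, ratio 9 this gives m ≈ 8.11 → 8 positives, 72 negatives, 80
  total; a Monte-Carlo power grid (10⁴ replicates per candidate m) agrees
  within one positive.

Known data quirk documented rather than resolved: published summary tables
of this design can be internally inconsistent (e.g., an overall event count
that differs by one from the sum of its subgroup cells); the report builders
take the cohort they are given as-is.

## The synthetic cohort generator

The generator produces the statistical structure the analysis assumes — it
is a stand-in for an unavailable clinical dataset, not a physiological
model. Mechanism, per case:

1. a latent severity class (low / mid / high, probabilities 0.38 / 0.52 /
   0.10) sets the deceleration rate per 30 min (3 / 6.5 / 9.5) and the
   class-conditional level mix;
2. decelerations arrive as a time-inhomogeneous Poisson stream whose rate
   ramps from 0.6× to 1.4× over the recording (distress escalates toward
   delivery); each event's target level is drawn from the mix and its
   categorical axes are drawn from the default table's preimage of that
   level, so table classification reproduces the drawn level;
3. **recent burden** (the score of the final monitored 30 minutes, i.e. the
   RCT window) drives PCO₂: `PCO₂ = 42 + 0.30·B_recent + N(0,5)` mm Hg;
   **cumulative burden** (whole-recording score) drives base excess:
   `BE = −1 − 0.022·B_total + N(0,1.4)` mEq/L. Recent burden is anchored at
   transducer removal rather than delivery because the event stream is
   unobservable after the transducer comes off, and the typical
   removal-to-delivery gap (median 45 min) would otherwise empty the window;
4. pH solves Henderson–Hasselbalch `pH = 6.1 + log₁₀(HCO₃/(0.03·PCO₂))`
   jointly with the simplified Van Slyke relation
   `BE = HCO₃ − 24.4 + 14.83(pH − 7.4)` (Brent's method on [6.51, 7.59]);
   HCO₃ is then back-computed from pH so every panel satisfies
   Henderson–Hasselbalch exactly, and BE is re-derived for internal
   consistency. Lactate increases in the base deficit; Apgar scores fall
   linearly with pH below 7.3; the NICU flag is a logistic function of pH
   centred at 7.05 (the pH–Apgar and pH–NICU couplings are plausible but
   arbitrary, and configurable);
5. timelines are lognormal around published medians: removal→delivery
   45 min (clipped to 15–99), decision→removal 24 min, recording length
   150 min (floored so the pre-decision window is always fully covered).

The coupling gains were calibrated once with `analysis/00_calibrate.py` so
that default cohorts hit the anchors of a term eCD-for-NRFS population:
acidemia prevalence ≈ 0.10, mean pH ≈ 7.29, mean PCO₂ ≈ 49 mm Hg, mean BE ≈
−3 mEq/L, pre-removal score median ≈ 22, and a clear mixed-acidosis contrast
across the high-score stratum. A deterministic feasibility check rejects
configurations whose extreme severity tail cannot reach the acidemia
threshold at all (target prevalence unreachable).

Randomness: one integer seed; case *i* uses `SeedSequence(seed,
spawn_key=(i,))`, so cohorts are bit-reproducible and case streams are
stable under changes of `n_cases`.

**What passing tests show — and don't.** On these cohorts the pipeline
recovers configured discrimination, the metabolic gain (by regression of BE
on cumulative burden, within 10% at n = 1000), and the ordering
AUC(RCT) ≥ AUC(DCS) in most replicates. They do not validate the score on
real tracings: the generator has no signal-level noise in the annotations,
no inter-rater disagreement, no confounding between severity and timeline,
and its covariates are independent of outcome except through burden.

## Trace rendering and detection

`render_trace` emits 4 Hz FHR/uterine signals (constant 140 bpm baseline,
sinusoidal variability, half-sine deceleration dips of 25/45 bpm for
mild/severe, Gaussian contraction bumps every ~3 min). The detector flags
sustained drops ≥ 15 bpm lasting ≥ 15 s below the median baseline, merges
gaps < 5 s, calls ≥ 2 min prolonged, separates late from variable by the
nadir's lag behind the preceding contraction peak (> 15 s), and grades
severity by depth (≥ 35 bpm). Because the rendered dip ramps gradually, the
detected onset trails the annotated onset by roughly duration/9 for a deep
half-sine dip; round-trip tests therefore require onset agreement within
15 s for ordinary events. These components exist to exercise the event
pipeline from the signal level; they are deliberately simple, with no
baseline drift tracking or accelerations.

## Limitations

* The default five-tier table is a constructed dialect, not a verified
  transcription of any published grid; swap in your own YAML where
  fidelity to a specific guideline matters.
* The generator's acid-base couplings are linear with Gaussian noise;
  real cohorts show heavier tails and confounded timelines.
* Youden cutoffs computed on simulated cohorts are illustrative only and
  carry no clinical meaning.
* Group-comparison p-values are raw; with ~20 variables per table some
  nominally significant contrasts are expected by chance.
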