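# Methods

This note documents the statistical model behind `sermir`, the defaults
it ships, the design choices that were genuinely open, and what the
synthetic-data generator does and does not emulate.

## Quantification model

RT-qPCR reports the threshold cycle CT; under the ideal-efficiency
assumption one cycle is one doubling, so abundance is proportional to
2^−CT. Serum has no consensus housekeeping miRNA, and small nuclear
RNAs (U6 and relatives) are unstable in serum; the pipeline therefore
normalizes each sample against the composite of let-7d, let-7g and
let-7i, a trio with demonstrated cross-cohort stability in serum. The
composite reference CT is the arithmetic mean of the available
reference CTs, which equals the geometric mean of their linear
abundances — the natural average for log-scale quantities. Then

* ΔCT = CT_target − CT_reference (cycles),
* relative expression = 2^−ΔCT (dimensionless),
* pooled-screening fold change = 2^−ΔΔCT with
  ΔΔCT = ΔCT_case − ΔCT_comparator (> 1 means up in the case pool).

No amplification-efficiency correction or inter-plate calibration is
applied; the model assumes efficiency 2 throughout.

Censoring: an assay that never crosses threshold ("Undetermined", or a
CT above `max_cycles`, default 40) is carried as censored. A censored
target yields a MISSING expression value — never an imputed one;
prevalence-based exclusion happens downstream. A sample with one or two
censored reference assays is normalized on the remaining references and
flagged as degraded; with all three censored it is dropped. Technical
replicates are collapsed by arithmetic mean of CT before any other
step; the source protocol does not state its replicate handling, and
mean-CT collapse is the field convention.

Exact laws the implementation preserves (and property tests check):
ΔCT+1 halves expression; adding a constant to every CT of a sample
leaves its ΔCTs unchanged; fold change is reciprocal under swapping the
pools. In floating point these hold to round-off (about one ulp for the
halving law — halving itself is exact, `exp2` rounds), which is the
sense in which "exactly" is asserted.

## Screening criteria

An assay in the pooled discovery arm is a candidate iff all of:

1. raw case-pool CT < 28 cycles (strict, matching "< 28");
2. fold change of at least 5 versus *either* comparator pool, counted
   in magnitude: max(FC, 1/FC) ≥ 5 (inclusive, matching "at least").
   The magnitude reading is required because validated candidates
   include down-regulated miRNAs;
3. membership in a user-supplied literature whitelist. Curation cannot
   be automated, so an empty whitelist (the default) disables the
   criterion.

Fold change is computed on normalized pool ΔCT. The pooled-array
internal control is configurable: mean CT of the designated reference
assays within the pool (default) or global-mean normalization. An assay
quantified in the case pool but in no comparator is flagged
indeterminate and never a candidate. Monotonicity holds by
construction: relaxing either cutoff can only add candidates.

## Group comparison

* Low-expression rule: an assay is excluded when Cq > 35 (or censored)
  in *strictly more than half* of the measured samples. "Most samples"
  has no stated threshold in the source protocol; the strict majority
  is our operationalization, and both the cutoff (35) and the fraction
  (0.5) are configurable.
* Two-group test: pooled-variance Student's t (df = n₁+n₂−2), because
  that is the named test; Welch is available behind a flag for
  sensitivity analysis. Tests run on the 2^−ΔCT scale by default to
  match how group means are reported; a ΔCT-scale option exists since
  the testing scale is otherwise unstated. Zero pooled variance with
  equal means returns t = 0, p = 1; with unequal means it is an error.
* Categorical demographics: Pearson χ² on 2×2 tables without continuity
  correction (df = 1), correction behind a flag; zero margins are
  errors.
* Summaries report mean, SD and SEM = SD/√n over non-missing values.
* No multiple-testing correction by default, mirroring the original
  analysis; Benjamini–Hochberg is provided as an explicitly labelled
  extension.

## Risk-score panel

Directions are fixed from training group means (case mean above control
mean ⇒ UP) before any weight fitting and are never re-estimated on
validation data. Per miRNA:

* Threshold τ: 95th (UP) or 5th (DOWN) percentile of *training control*
  expression, by linear interpolation between order statistics
  (position 1 + (n−1)p, numpy's `linear` method). The reference
  interval's computation is not specified by the source; this is the
  common clinical-chemistry definition. Fewer than 20 controls warns
  that the percentile is unstable.
* Binarization: s = 1 iff expression > τ (UP) or < τ (DOWN), strictly;
  ties and MISSING values score 0. The below-the-lower-bound rule for
  down-regulated markers is the only one consistent with risk
  semantics — the literal protocol sentence ("higher than … the lower
  5% reference interval") would score nearly every sample 1 and is read
  as a typographical slip; the literal variant remains selectable
  (`down_rule="above_lower"`) for sensitivity analysis.
* Weight W: slope of a univariate logistic regression of disease status
  on s, fitted by Newton–Raphson (statsmodels `Logit`). For a binary
  predictor without separation this equals ln of the sample odds
  ratio — the closed form serves as an independent oracle in the test
  suite, never as the implementation. A zero cell in the s×label table
  (certain with small groups such as 15 carcinoma patients) makes the
  MLE infinite; the weight then falls back to the Haldane–Anscombe
  correction (add 0.5 to all four cells) and carries a SEPARATION flag.
  A constant s is uninformative: weight 0, DEGENERATE flag.
* RSF_i = Σ_j W_j·s_ij, evaluated exactly. With correct directions all
  weights are expected nonnegative, making RSF nondecreasing in every
  s_ij.

The model is fitted on the training phase and frozen; validation
samples are scored with the stored thresholds and weights. Whether the
published panel was refit on the combined set before the combined-set
ROC is unknowable from the text; `fit_on="combined"` provides that
variant, with training-only fitting as the default (the conservative,
leakage-free choice).

## ROC analysis

AUC is the tie-corrected concordance probability, computed from
mid-ranks (identical to the pairwise definition with ties worth ½).
Curves enumerate every distinct score as a threshold under the rule
score > threshold ⇒ case, plus ±∞ endpoints, so the trapezoidal area
reproduces the pairwise AUC to 1e−12. Down-regulated single markers are
re-oriented (scores negated) so reported AUCs are ≥ 0.5, with the flip
recorded; panel RSFs are never re-oriented.

Confidence intervals are normal-approximation intervals on the AUC:
DeLong's variance from placement values by default (tie-robust), or
Hanley–McNeil as the legacy-software-compatible alternative, clipped to
[0, 1]. An AUC of exactly 1 gives zero DeLong variance; the interval
then degenerates to (1, 1) and is flagged, matching how perfect
separation prints in clinical reports. Which CI procedure produced the
published intervals is unstated; output labels the method used.

## Synthetic-data generator

The generator emits CT-level data matching the structure the analysis
assumes. Per sample, a shared input-amount shift (the composite
reference CT) is drawn N(25, 1) cycles; per target miRNA, biological
variation is placed on ΔCT — i.e. lognormal relative expression — with
the ΔCT mean offset by ln2·σ²/2 so the *arithmetic* mean of 2^−ΔCT
equals the configured group mean exactly; every measured CT adds
N(0, 0.25) technical noise; CTs above 40 become censored. Pools average
member *linear* abundances (mixing equal serum volumes mixes molecules,
not CTs) and convert back to pool ΔCT; the screening universe is padded
to 756 assays with null assays on a fixed abundance ladder.

Shipped conditions (`default_study_config`): group sizes 100 PTC / 91
benign / 15 MTC / 89 controls; training split 36/36/32 with the rest
(64/55/57) in validation; six-panel-miRNA group means taken from the
published validation-set summary table (e.g. miR-222-3p 0.415 PTC,
0.390 benign, 0.290 control) with MTC means from the matched-subset
table (0.731, 2.719, 0.803 for the three up-regulated markers);
biological CVs derived from the control-group SEMs as CV = SEM·√n/mean
(0.35–0.56); two decoy assays at mean level 2^−11.5 so their Cq sits
mostly above 35, exercising the exclusion rule. `mtc_arm_config` is the
matched 15/15/15 design at the matched-subset effect sizes;
`null_config` sets every fold change to 1.

What the generator does *not* emulate: plate/batch effects beyond the
single per-sample shift, amplification-efficiency variation, hemolysis
or other pre-analytical artifacts, correlation between miRNAs
(generated independently given the shared shift), and the clinical
matching algorithm for the carcinoma subsets (matched demographics are
drawn, not matched post hoc — the original matching procedure is
unstated). Passing tests therefore demonstrate the *procedure's*
correctness and calibration under a clean data-generating model, not
the clinical performance of the markers on real sera.

Determinism: the same config and seed yield bit-identical matrices,
CSVs and pipeline reports; the run manifest deliberately records no
wall-clock timestamp so reruns compare byte-equal.

## Orchestration choices

The two study arms use different technologies: the pooled card profiles
hundreds of assays, while the individual-sample qPCR plate is loaded
only with curated candidates. The pipeline therefore takes the
training-phase candidate set from the columns of the individual-sample
CT table (they *are* the candidate list), and runs pool screening as
its own stage whenever pool data is supplied; `restrict_to_screen`
additionally intersects the two when both arms share an assay universe.
Training retention requires p < 0.05 in the configured comparison(s)
(default: case vs control; a list plus all/any mode is configurable).
The carcinoma arm reuses the frozen normalization and ROC machinery on
the up-regulated markers with matched subsets of 15.

## Calibration and problem sizes

The shipped Monte-Carlo studies use 100 seeds for full-study recovery,
200 seeds for the carcinoma-arm ordering, and 1,000–2,000 replicates
for null calibration — sizes at which the binomial error on a 5% rate
is ±0.5–1.5 percentage points, adequate for the calibration claims
made. Measured under the null: per-miRNA training retention ≈ 0.05 and
mean validation panel AUC ≈ 0.50. At the shipped ~1.2–1.4-fold effect
sizes the 36-vs-32 training split has limited power (per-miRNA
retention 0.5–1.0), so single seeds typically confirm four to six of
the six planted markers — a faithful property of the design, not a
defect of the generator.

## Known limitations

* The risk score discards within-interval information by construction;
  at modest effect sizes the binarized panel can trail the best
  continuous single-marker AUC even when it beats most markers.
* Percentile thresholds from 32 training controls (or 15 in the
  carcinoma arm) are noisy; the implementation warns below 20 controls.
* Student's t on lognormal expression is only approximately calibrated
  in small, skewed samples; the ΔCT-scale option (exactly normal under
  the generator) is provided for sensitivity analysis.
* The separation-corrected weight is a finite stand-in for an infinite
  MLE; its magnitude depends on group sizes and should be read
  qualitatively.
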