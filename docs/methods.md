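# Methods

## The score

BIND-M grades four bedside findings of acute bilirubin encephalopathy
(ABE): mental status, muscle tone and cry on ordinal levels 0–3, and
paralysis of upward gaze as an all-or-nothing sign scored 0 or 3.  The
total is the plain sum, 0–12.  Gaze is stored as its point value {0, 3}
rather than as a binary flag so the total needs no special casing; with
gaze excluded the score reduces to a 0–9 scale.  The a-priori severity
bands are closed integer intervals (0 none; 1–4 mild; 5–6 moderate; ≥7
severe); the empirical screening threshold defaults to total ≥ 3 and is
overridable per call.  Both framings are deliberately kept: the bands
express the intended clinical meaning, the threshold the observed
screening behaviour.

## Inter-rater agreement

Paired resident/consultant ratings are cross-tabulated over the field's
*full declared category space* (zero rows and columns are retained), so
kappa is always computed on the rubric's scale rather than on whichever
levels happened to occur.  Cohen's kappa is

    kappa = (p_o − p_e) / (1 − p_e),
    p_o = Σ w_ij p_ij,   p_e = Σ w_ij p_i· p_·j,

with identity weights (simple kappa) or Cicchetti–Allen linear weights
`w_ij = 1 − |c_i − c_j| / (c_max − c_min)`.  The linear weights are driven
by the category *values*, not their ranks; this is irrelevant for
consecutive levels and for any two-point scale, but it is the defined
behaviour for unevenly spaced categories.  At k = 2 the linear weights
degenerate to the identity, so weighted and simple kappa coincide — the
reason only a simple kappa exists for the binary gaze sign.

The standard error is the Fleiss–Cohen–Everitt asymptotic (non-null)
variance of weighted kappa,

    var = [ Σ p_ij { w_ij(1−p_e) − (w̄_i· + w̄_·j)(1−p_o) }²
            − (p_o p_e − 2 p_e + p_o)² ] / ( n (1−p_e)⁴ ),

where `w̄_i·` and `w̄_·j` are the marginal expected weights.  Confidence
intervals are Wald, `kappa ± 1.96·se`, clipped to kappa's range [−1, 1].
This estimator reproduces every published CI of the evaluation study to
all four printed decimals and agrees with
`statsmodels.stats.inter_rater.cohens_kappa` to 1e-10 (the test suite
checks both, and additionally checks the estimate against a plain
summation oracle to 1e-12 and the SE against the Monte-Carlo sampling SD
of multinomial resamples within 15%).  Kappa is undefined when `p_e = 1`
(all mass in one marginal category for both raters); this raises an
explicit error rather than returning a coerced value.  Comparisons against
printed 4-decimal values use round-half-even.

## Diagnostic threshold analysis

An infant tests positive at cutoff c when total ≥ c; the consultant's
clinical ABE call is the reference standard.  Per cutoff the confusion
counts and sensitivity, specificity, PPV and NPV (as percentages) are
reported; a metric with a zero denominator is *undefined* and rendered
"N/A", never 0 or 100.  Values are exact internally and displayed to one
decimal, round-half-even.  No ROC smoothing or AUC is attempted and no CIs
are put on the proportions (none exist in the source evaluation).

The packaged cutoff-by-cutoff confusion-count table carries several known
typographical errors in its printed metric columns: sensitivity 90.7 at ≥3
where 48/53 = 90.6, sensitivity 49.6 at ≥9 where 26/53 = 49.1, an abstract
specificity of 97.7 where 274/280 = 97.9, PPV/NPV swapped in the ≥7 row
(37/39 = 94.9, 278/294 = 94.6), and PPV 96.7 at ≥8 where 32/33 = 97.0.
This package always reports the arithmetic of the counts; the
discrepancies are documented in the fixture header rather than reproduced.

## Case-control odds ratios

Odds ratios are crude cross-product ratios `ad/bc` with Woolf logit 95%
CIs `exp(ln OR ± 1.96·√(1/a + 1/b + 1/c + 1/d))`.  For a saturated
single-factor unconditional logistic model the fitted level odds ratios
equal these cross-products, so the closed form replaces iterative fitting;
the published iteratively fitted values (73.94, 25.88, lower bound 5.425)
agree with the closed form (74.0, 25.9, 5.426) within 0.1%, which is the
tolerance the tests use for those entries.  Zero cells receive *no*
continuity correction; they yield explicit flags — `zero_point` (no
exposed cases), `infinite_upper` (no unexposed cases or exposed controls),
`incalculable` (the level was never observed) — and render as
"0.000 (incalculable)" or an upper bound ">999" (display cap 999,
configurable).  A multi-level exposure is analysed level-by-level against
its declared referent; the joint menthol × G6PD exposure uses the "grand
referent" (menthol-unexposed, G6PD-normal) so every combination is
compared against the doubly unexposed group in one family of 2×2s.

Continuous variables (peak bilirubin) are compared with a two-sample t
test; both the pooled-variance and Welch variants are computed, with the
pooled variant shown by default as the conventional default of classical
clinical software.

Woolf CI coverage is verified by simulation: over thousands of 2×2 tables
drawn at a known true OR with adequate cell sizes, the 95% interval covers
the truth 93–97% of the time.

## The synthetic cohort generator

No per-infant records are available for the published evaluation, so the
generator emulates its statistical structure; its defaults are the study
conditions:

* n = 333 infants, latent ABE prevalence 53/333 ≈ 15.9%;
* consultant sub-scores drawn from status-conditional categorical
  profiles.  ABE infants are a two-component mixture: a dominant severe
  component and a 10.5% *mild* component that scores low on every scale
  and carries no eye findings.  The mixture is needed because the study's
  two published anchors — the consultant sub-score margins and the ~90%
  sensitivity / ~98% specificity operating point at cutoff 3 — cannot both
  hold under sub-score independence with a single ABE profile: profiles
  that match the margins are too discriminative (sensitivity ≈ 99%),
  because in real data the sub-scores are correlated and mild ABE cases
  score low across the board.  The default profiles (package constants in
  `synthetic_cohort.DEFAULT_PROFILES`) were chosen once to land the
  operating point (analytic sensitivity 90.3%, specificity 98.5% at
  cutoff 3) while keeping the marginal level frequencies close to the
  published column totals; gaze findings occur only in (severe) ABE
  infants, mirroring the observation that every infant with eye findings
  had an ABE diagnosis;
* resident ratings are the consultant ratings passed through an ordinal
  confusion kernel: stay with probability `p_stay`, otherwise move to an
  adjacent level, spillover split evenly between neighbours and clipped at
  the scale ends (disagreements in the published tables concentrate near
  the diagonal).  Gaze uses a simple flip probability.  Defaults
  `p_stay = 0.8588` and `gaze_flip = 0.0791` are calibrated analytically
  (see below) to expected weighted kappa 0.80 on mental status and simple
  kappa 0.58 on gaze, the agreement levels the study reported;
* risk factors are sampled by inverting the odds-ratio relation: given the
  exposure distribution among controls and a per-level OR, the case
  distribution is `P(level|case) ∝ P(level|control)·OR(level)` — direct
  sampling, no rejection.  Defaults: sepsis (control exposure 24/91,
  OR 8.375) and the 9-level menthol × G6PD grid (control distribution from
  the published 170-control margin; per-level crude ORs from the published
  counts, e.g. 74.0 for exposed/deficient and 25.9 for exposed/unknown.
  The grid's printed unknown/unknown OR of 7.120 is inconsistent with its
  own printed counts, whose crude OR is 1.480; the counts, not the printed
  OR, parameterise the generator);
* peak bilirubin is normal truncated at 0: cases mean 30.71, controls mean
  15.65 mg/dL (the published group means).  The source prints no SDs; the
  defaults (8 and 6 mg/dL) are plausible spreads for peak bilirubin in
  severe jaundice cohorts and are freely configurable;
* one `numpy` Generator seeded from the config drives everything in a
  fixed call order, so a fixed seed reproduces the CSV byte for byte.

**Noise calibration.**  For a sub-score field the exact joint
resident × consultant probability table is the kernel applied to the
consultant marginal, so the *population* weighted kappa is available in
closed form without simulation.  It is strictly increasing in `p_stay`, so
`calibrate_noise` bisects on [0, 1].  Adjacent-level noise cannot push
agreement below a profile-dependent floor (≈0.06 for the default mental
status profile); targets below the floor raise a calibration error.  The
total score has no single-kernel representation (it is a convolution over
four scales), so calibration is defined per sub-scale; in practice the
mental-status calibration puts the simulated total-score kappa in the same
~0.8 region.

**Parameter recovery.**  The suite checks, over 200 replicates at n = 333,
that the empirical prevalence recovers the configured value within 1%
absolute and that the recovered sepsis OR recovers 8.375 within 10%.
Recovered odds ratios are averaged as a geometric mean (mean log-OR,
exponentiated) — the standard aggregation for ratio estimators, whose
arithmetic mean is markedly right-skew-biased at these cell sizes (the
exposed-case cell averages ≈13).  Rater-noise calibration is checked by
simulating 50 replicates at the calibrated `p_stay` and requiring the mean
weighted kappa within ±0.02 of the 0.80 target.

**What the generator does not model.**  Gestational age, birth weight,
feto-maternal blood-group serology and exam-age effects are omitted (the
source study found no significant group differences on them).  Sub-scores
are conditionally independent given the three-way status, so fine joint
structure among sub-scales — beyond what the mild/severe mixture induces —
is not reproduced; passing tests demonstrate that the *estimators* behave
correctly under the configured structure, not that real exam data follow
it.

## The reconstructed total-score table

The published 13 × 13 total-score cross-tabulation is typographically
garbled in the available text (all digits run together).  The packaged
`table1.csv` is a reconstruction by exhaustive constrained segmentation of
the digit string: row labels must run 0–12 in order, each row's trailing
total must equal its row sum, the column totals must equal the printed
margin row (248, 23, 8, 4, 2, 6, 3, 6, 7, 9, 6, 9, 2) and the grand total
must be 333.  The search admits exactly one solution, and its weighted
kappa, 0.7969 (95% CI 0.7426, 0.8512), matches the printed values to all
four decimals — strong corroboration, since the kappa was not a search
constraint.

## Numerical and design notes

* All printed-value comparisons use round-half-even at the printed
  precision (4 decimals for kappas, 1 for percentages, 3 for ORs).
* Wald kappa CIs are clipped to [−1, 1] after computation.
* Cross-tabulation requires exactly one resident and one consultant record
  per infant and fails loudly on unpaired or duplicated records.
* Degenerate inputs fail with typed exceptions (`DomainError`,
  `PairingError`, `UndefinedKappaError`, `ConfigError`) or, for odds
  ratios, explicit result flags — never silent coercion.
* Model-style entry points (`InterRaterAgreement`, `ThresholdAnalysis`,
  `CaseControlAnalysis`) wrap the functional core for users who prefer the
  construct → `fit()` → results idiom; the rubric and the generator are
  plain functions and dataclasses since nothing is estimated there.
* Problem sizes in the test suite (200 replicate cohorts of n = 333 for
  recovery, 2000 resampled tables for the SE check, 1500–2000 tables for
  CI coverage, single cohorts of n = 4000–8000 for distributional checks)
  were chosen as the smallest runs at which the Monte-Carlo error is
  comfortably inside the asserted bands.
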