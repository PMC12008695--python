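# Methods

This note documents the models, conventions and numerical choices behind
`reliance_lab`, in the package's own terms: what each stage computes, what the
synthetic-cohort generator does and does not emulate, and where genuinely open
design questions were settled.

## Task and measurement model

The package targets two-step judge–advisor experiments: a participant rates a
case on a continuous 0–100 slider (benign … malignant), sees an AI
recommendation on the same scale, and may revise. One study dataset is two
tables:

* **trials long table** — `participant_id, trial, truth, advice,
  advice_correct, response_1, response_2`; sliders in [0, 100], `truth` ∈
  {benign, malignant}.
* **participants wide table** — `participant_id, experience_years`, item
  columns `<scale>_<i>` per questionnaire, attention-check flags.

### Weight of advice

`WoA = (response₂ − response₁)/(advice − response₁)`, clipped to [−1, 1].
When `advice == response₁` the ratio is undefined; the value is stored as
missing and excluded from participant means (zero-filling would conflate "no
opportunity to move" with "chose not to move"). WoA is invariant to a common
positive affine rescaling of all three inputs, a property the suite checks.

### Correctness, confidence, patterns

Correctness uses truth-specific slider intervals, inclusive at both ends:
malignant [61, 100], benign [1, 40]. The 41–60 band is incorrect for both
truths by construction — the rule defines correct regions only. The printed
benign interval starts at 1, so a response of exactly 0 is (literally)
incorrect; `CutoffRule(benign_correct=(0, 40))` widens it for sensitivity
analyses. Confidence is a binary proxy from the *initial* slider placement:
high (1) in [0, 20] ∪ [80, 100], low (0) otherwise.

Each trial's triple (initial correct, advice correct, final correct) maps
bijectively onto eight reliance patterns. Pooled **RAIR** =
`n(0,1,1)/[n(0,1,1)+n(0,1,0)]` and **RSR** = `n(1,0,1)/[n(1,0,1)+n(1,0,0)]`
are computed case-wise across all participants (summing numerators and
denominators), not as means of per-participant ratios; the per-participant
ratios are also reported, with a missing value when a participant had no
qualifying case (never imputed — such participants drop listwise from any
regression using that variable).

## Psychometrics

All five scales use mean scoring after reflecting reverse-keyed items
(`min + max − x`), keeping scores on the response metric. Reverse-key lists
default to empty and are configuration-editable. A respondent missing ≤ 20%
of a scale's items is scored on the answered items; above that the score is
missing (a common psychometric convention; occurrences are logged).
Cronbach's α uses the variance decomposition
`k/(k−1)·(1 − Σ s²ᵢ / s²_total)` with n−1 variances, and requires ≥ 3
complete respondents, ≥ 2 items and nonzero total variance.

## Inference

* **Advice-correctness contrast** — paired t on each participant's mean WoA
  under correct vs incorrect advice (a within-participant design, df = n−1),
  with Cohen's d_z = mean(diff)/sd(diff).
* **Trust → reliance** — OLS with unstandardised coefficients, run in
  parallel for three reliance outcomes: mean WoA (primary), participant RAIR
  and participant RSR.
* **Confidence moderation** — OLS with a mean-centred focal predictor, the
  moderator (left uncentred when binary), and their product; ΔR² against the
  product-free model; percentile bootstrap CI on the interaction
  coefficient. The moderator default is the participant's mean of the binary
  trial-level confidence proxy.
* **Mediations** — for each of propensity to trust, years of experience,
  technology affinity, control beliefs and need for cognition: simple
  mediation through trust with paths a (M on X), b and c′ (Y on X + M), c
  (Y on X), all OLS; indirect effect a·b; `c = c′ + a·b` holds to machine
  precision and is asserted at 1e−10. CIs use a nonparametric
  case-resampling **percentile** bootstrap, 5000 resamples by default
  (bias-corrected variants were deliberately not made the default; the
  percentile method is the simplest member of the family and its calibration
  is verified by simulation). Significance = CI excludes zero. Bootstrap
  replicates are computed by closed-form batched least squares, chunked so
  the replicate × n workspace stays near 2·10⁶ elements.
* **Experience subgroup contrast** — accuracy improvement (final − first)
  compared between participants ≤ 5 and > 5 years of experience by a
  classical pooled-variance two-sample t with pooled-SD Cohen's d.
* **Sample size** — smallest integer N reaching target power, by bisection
  over the noncentral-t (paired design, noncentrality d·√N) or noncentral-F
  (regression omnibus, λ = f²·N, df1 = k, df2 = N−k−1) power function.
  For d = 0.2, α = .05 two-sided, the paired design needs N = 199 at power
  0.80 and N = 265 at power 0.90 — the published figure of 199 corresponds
  to power 0.80 despite being described alongside 0.9, so both values are
  surfaced here. For R² = 0.13 (f² = 0.149), k = 6, power 0.90, the omnibus
  design gives N = 124.
* No multiple-testing correction is applied across the hypothesis family by
  default, matching the original analysis style; every test's α, seed and
  n are recorded in the report.

Randomness: a single master seed; each bootstrap analysis receives a
deterministic sub-seed (`master·10007 + index mod 2³¹−1`), so reports are
byte-identical under a fixed seed and configuration.

## Synthetic-cohort generator

The generator emulates the design of a web-based dermatologist study:
223 participants × 24 trials, advice wrong on exactly 5 trials per
participant with positions shuffled per participant, advice placed uniformly
15–25 slider units from the extreme it points to (so [15, 25] when pointing
benign, [75, 85] when pointing malignant — never in the dead zones), and
responses continuous in [0, 100] (integer rounding available by flag).

Behavioural equations (defaults in `BehaviorConfig`):

* latent traits: standardised normals; **experience**: truncated normal on
  [0, 50] years whose *truncated* mean is the configured 15.5 y (SD 11.2);
  the location parameter is solved by bisection so the cohort mean matches
  the configured value despite truncation.
* **trust** = 3.0 + 0.30·propensity − 0.02·experience + N(0, 0.40), clipped
  to the 1–5 response metric. The two nonzero slopes encode the qualitative
  path structure under study (propensity raises trust; experience lowers
  it); affinity, control beliefs and need for cognition carry no paths, so
  their mediations are true nulls.
* per-trial **adherence weight** w = −0.30 + 0.15·trust − 0.05·confidence +
  N(0, 0.20), clipped to [0, 1] (a flag permits negative weights; movement
  away from advice is rare enough in this paradigm that it is off by
  default). The final response is `response₁ + w·(advice − response₁)`.
  At the default trust level this puts mean WoA near 0.1.
* **initial response**: in the truth's correct region with probability
  `skill` = 0.63 (matching a first-response accuracy near 63%), drawn from a
  truncated normal centred in the chosen region (SD 12).
* **questionnaire items**: scale midpoint + 0.8·latent + N(0, 0.6), rounded
  and clipped to the response range; trust items scatter around the latent
  trust value directly. These defaults put α in the high 0.7s–0.9s,
  the acceptable-to-good range the real instruments show.
* **attention checks**: two independent per-participant Bernoulli checks
  (failure probability 0 by default — the default cohort is the analysed
  sample); failures are flagged, never deleted, so exclusion stays an
  explicit pipeline step. The exclusion rule defaults to "failing either
  check excludes" with a "both" switch.

Seeding: participant p's profile and trial sequence come from sub-streams
`(seed, p, 0)` and `(seed, p, 1)`, so any participant regenerates identically
regardless of cohort size.

### What the generator does and does not emulate

It reproduces the design counts, advice placement, response ranges, the
trait→trust→reliance path signs, realistic scale reliabilities and a
realistic overall adherence level. It does **not** model discrimination
between correct and incorrect advice (w is independent of advice
correctness), case difficulty, response styles, or any experience–skill
correlation (set to zero deliberately, as no such correlation was observed in
the motivating study). Two visible consequences: the simulated
advice-correctness contrast is a true null, and simulated RAIR is far lower
than the ~10% seen in real cohorts — converting an initially wrong decision
requires w large enough to carry the slider across the cut-off, which the
trust-driven adherence model rarely produces. Passing tests therefore
demonstrate that the measurement and inference chain is correct and
calibrated, not that the generator is a behavioural model of clinicians.

## Problem sizes used in the checks

Calibration checks run at the sizes documented here: type-I error of the
paired t and of the mediation CI test over 500 null replications at n = 223
(the mediation null uses a ≠ 0, b = 0 — under the double null the a·b test
is well known to be conservative, so ~5% rejection is only expected against
the single null — with 1000 bootstrap resamples per replication);
indirect-effect consistency at n = 10 000; path-sign recovery over 200
replications of the full default cohort; generator null-faithfulness over
1000 replications of a reduced 60 × 6 cohort (the regression's calibration
does not depend on cohort size). The analysis default of 5000 bootstrap
resamples is unchanged.

## Known limitations

* The percentile bootstrap CI can fail to contain the point estimate in
  pathological resamples; no correction is applied (logged, not hidden).
* Cronbach's α is reported as-is; no factor analysis or measurement-
  invariance testing (out of scope).
* The structural-equation route to the trait hypotheses is intentionally
  absent; independent simple mediations are the supported analysis.
* Real-data quantities that depend on unreleased raw data (specific t values,
  indirect-effect magnitudes, observed α values) are not reproduced; the
  suite verifies the machinery by construction and calibration instead.
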