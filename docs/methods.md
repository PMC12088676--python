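# Methods

## The super-subject model

Single-critical-trial designs give one binary observation per subject, so
sensitivity and bias are defined for a pooled pseudo-observer: the
decision matrix counts, over subjects, yes/no noticing responses on
stimulus-present (N₂) and stimulus-absent (N₁) critical trials. The
analysis then assumes the standard equal-variance Gaussian detection
model *at the group level*: evidence ~ N(0,1) on absent trials and
N(d′, σ) on present trials, with a decision criterion placed on the
common evidence axis. Two assumptions are inherited and deserve note:

1. **A stable criterion across subjects.** Each subject contributes their
   own criterion; the pooled analysis behaves as if there were one. The
   simulator makes the consequence explicit (see *criterion jitter*
   below): between-subject jitter τ attenuates the pooled one-interval
   d′ estimate by exactly 1/√(1+τ²) while leaving 2AFC estimates
   untouched, so pooled one-interval estimates are conservative, never
   inflated.
2. **Equal variance.** The unequal-variance indices d_a and c_a, driven
   by the ROC slope s = 1/σ, quantify the sensitivity of conclusions to
   this assumption; at σ = 1 they reduce exactly to d′ and c.

### Estimators

All rates pass through the log-linear correction — 0.5 added to every
cell, so H = (hits+0.5)/(N₂+1) — applied unconditionally, including to
2AFC matrices; it keeps z-transforms finite at perfect or empty cells and
shrinks rates toward 0.5 by O(1/N). Statistics:

    d′       = z(H) − z(FA)
    d′_2afc  = [z(H) − z(FA)] / √2
    c        = −[z(H) + z(FA)] / 2
    d_a      = √(2/(1+s²)) · [z(H) − s·z(FA)]
    c_a      = −[√2·s/√(1+s²)] · [z(H) + z(FA)] / (1+s)

The 2AFC adjustment is 1/√2 (the factor by which two-interval tasks are
easier than one-interval tasks under the difference rule). σ is the
relative *standard deviation* of the signal distribution; the slope is
s = 1/σ.

Sampling variances come from the delta method applied to the binomial
rates (Gourevitch–Galanter):

    var(z(H))  = H(1−H) / (N₂ φ(H)²),   φ(p) = normal density at z(p)
    var(d′)    = var(z(H)) + var(z(FA))
    var(d′_2afc) = var(d′) / 2
    var(c)     = var(d′) / 4

with symmetric Wald intervals. The variance for c is not commonly printed
alongside the d′ formulas; the ¼ factor follows from c being half the sum
of two independent z-transforms, and is validated in the test suite
against Monte-Carlo spread (2000 replicate matrices, agreement within
5%; observed ≤ 1.4% at N₂ = 841, N₁ = 420). No analytic variance is
attached to d_a/c_a — they are sensitivity-analysis quantities here.

### Inference on proportions

Non-noticer percent-correct is compared with chance three ways:

- **Exact binomial test**, two-sided by the minimum-likelihood rule (sum
  the probabilities of all outcomes no more likely than the observed
  one) — the convention of R's `binom.test`; implemented via
  `scipy.stats.binomtest` and cross-checked against brute-force
  enumeration for every (k, n) with n ≤ 50.
- **Clopper–Pearson interval** by inversion of the binomial tails,
  cross-checked against direct bisection of the tail probabilities.
- **Bayes factor BF₁₀** with H₁ placing a Logistic(logit(p₀), 0.5) prior
  on the log-odds of success — the default prior family and scale of the
  standard Bayesian proportion test. The marginal likelihood is
  integrated by Gauss–Legendre quadrature over ±12 prior scales in log
  space; the node count doubles (401 → …) until successive evaluations
  agree to a relative 1e-8, because the likelihood narrows like 1/√n.
  Truncation at ±12 scales discards < 1e-5 of prior mass. Symmetric
  nodes make BF₁₀(k, n) = BF₁₀(n−k, n) hold to ~1e-12 at p₀ = 0.5.

Families of tests (the eight confidence bins) are corrected with the
Holm–Bonferroni step-down rule; feature tests within an experiment are
deliberately *not* jointly corrected, matching the original analysis
practice for these designs. Bins with fewer than 20 subjects are flagged
`under_powered` but still reported.

## Pipeline conventions

- **Non-noticer** = answered "no" to the noticing question, regardless of
  confidence; confidence ratings only partition bins.
- **2AFC designation**: left-stimulus trials are (arbitrarily) "present"
  and responding "left" is a hit. Swapping the designation together with
  the response coding leaves d′_2afc numerically identical and negates
  c; relabelling only the stimulus designation (fixed response coding,
  `DecisionMatrix.swapped()`) negates d′ instead. Both symmetries are
  tested.
- **One-interval features** (colour, shape): the first design level is
  the "signal" by default; d′ is invariant to that choice, c flips sign.
- **Exclusions** arrive as pre-computed flags with reason codes (primary
  task accuracy, incomplete data, and similar are upstream concerns);
  excluded records never enter any matrix.
- The CSV schema is fixed (14 columns, empty string = not applicable).
  It carries no question-order column, so order-based subsetting is out
  of scope for the report.
- Reports serialise to JSON at full precision; the human-readable table
  rounds for display only.

## The synthetic observer population

`simulate_experiment` draws, per subject: condition (present with the
design's fraction — 2/3 or 3/4 where an absent condition exists),
uniform binary stimulus features, and responses from:

- **Detection**: evidence as in the model above; the subject's criterion
  is N(c̄ + d′/2, τ²) measured from the noise mean, so the generative c̄
  equals the c the analysis estimates (the d′/2 offset centres the
  criterion between the two distributions). With τ = 0, σ = 1 the exact
  mapping is H = Φ(d′/2 − c̄), FA = Φ(−d′/2 − c̄), which the analysis
  inverts; parameter recovery at 10 × 50,000 subjects shows |bias| <
  0.02 for both d′ and c̄.
- **Confidence** (0–3): the number of fixed offsets (default 0.5, 1.0,
  1.5 in evidence units) exceeded by |evidence − criterion|, symmetric
  for yes and no. Single-critical-trial data constrain no confidence
  model; this minimal ordered-criteria scheme is a clearly-labelled
  stand-in.
- **Colour / shape**: independent one-interval Gaussian channels at their
  own d′, with a fixed channel criterion placed so the no-signal
  response probability equals the guess bias. Independence from the
  detection channel is the default (a correlation knob exists, default
  0 — another stand-in, as no joint model is identified by these data).
- **Location**: a criterion-free two-interval difference rule; the
  analysis's d′_2afc recovers `location_dprime` directly.
- **Congruency suppression** (sustained attended-colour designs): one
  parameter scales down detection d′ for attention-incongruent stimulus
  colours and shifts colour guesses toward the unattended colour by the
  same amount on the evidence axis. The second effect is required to
  reproduce the empirical signature — non-noticers are enriched for
  incongruent stimuli, and anti-congruent guessing then inflates their
  apparent colour d′ — and vanishes at suppression 0, preserving channel
  independence.

`STUDY_PARAMS` collects per-design populations whose group statistics
match the reported results of the five studies (detection d′ 1.8–2.0,
criterion 0.31–0.85, feature d′ 0.03–0.51, blue-guess bias 0.78,
suppression 0.55 for the congruent-colour design). What passing
simulation tests show is that the estimators are correct *under the
generative model*; real data may violate channel independence, the
confidence model, and criterion stability in ways the simulator only
probes parametrically.

## Problem sizes and numerical choices

- Simulation-based checks use 50,000 subjects per run (10 replicates for
  recovery), 2000 replicate matrices for variance calibration, and a
  τ grid of {0, 0.25, 0.5, 1, 2} — sizes at which Monte-Carlo error is
  a few times smaller than the tolerances being asserted.
- Normal quantiles/densities: `scipy.stats.norm` (inverse-CDF accurate to
  machine precision). Golden-value tests use ±0.005 on d′/c statistics,
  covering the 2-decimal rounding of printed inputs.
- Degenerate inputs (no present or no absent trials, rates outside (0,1),
  σ ≤ 0, missing variance) raise immediately; nothing is imputed.
- One reproduction sits just outside the golden band by construction: the
  printed corrected rates (72.64%, 45.54%) yield d′_2afc = 0.5049, while
  the value printed alongside them is 0.51 — a 0.0051 gap attributable to
  rounding in the source inputs (the only integer decision matrix
  consistent with those rates, 38/52 vs 25/55, gives the same 0.5049).

## Known limitations

- The super-subject analysis is implemented as specified for binary
  feature levels; multi-level features and rating-scale ROC fitting are
  out of scope.
- d_a/c_a carry no standard errors.
- The simulator does not model the primary task (tracking/counting),
  reaction times, or exclusion processes; exclusion flags pass through.
- The Bayes factor supports only the logistic log-odds prior family.
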