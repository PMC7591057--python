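# Methods

## The model

Metastasis formation is split into three phases: release of tumor cells
from the growing primary tumor into circulation, initiation of a colony
at a secondary site, and outgrowth of the established colony.  The
package models the second phase — the *metastatic bottleneck* — as an
inhomogeneous birth–death process with an Allee effect, and couples it
to primary-tumor kinetics to obtain closed-form, tumor-size-dependent
expressions for clinical outcome.

### Colony initiation (`colony`)

A colony of `i` cells changes by one cell at a time.  Each cell's
proliferation-to-death rate ratio grows with colony size,

    λ_i / μ_i = i / b,

where `b` (cells) is the **bottleneck severity**.  Only the ratio is
identifiable from extinction probabilities, so the chain is simulated as
the embedded jump process with upward probability `p_i = i/(i+b)`; no
absolute time scale is attached.  `p_i` crosses 1/2 at `i = b`, making
`⌈b⌉` the critical colony size.  Survival (never hitting the absorbing
state 0) from `i` cells has the closed form

    s_i(b) = F_Pois(i − 1; b),      s_1(b) = exp(−b),

the Poisson CDF with mean `b`.  At the modal fitted severity `b = 17`
a single seeded cell survives with probability 4.1 × 10⁻⁸.  The
Monte-Carlo simulator exists purely as an independent oracle for these
formulas; survival is declared at a cap of `50⌈b⌉` cells (cap
insensitivity is itself tested).  Non-integer `b` is allowed everywhere;
the chain then never visits `i = b` and the ½-crossing falls between
`⌊b⌋` and `⌈b⌉`.

### Primary-tumor kinetics (`growth`)

The primary tumor is an exponentially growing sphere: diameter `d` (cm)
↔ cell count via `cells = ρ·πd³/6` with density `ρ = 10⁹ cells/cm³`
(1 g ≡ 1 cm³), and time-from-onset `t(d) = ln(cells/initial)/r` with
`r = ln 2 · 365.24 / D` per year for doubling time `D` days.  Cells are
shed from the tumor surface; the shedding rate scales as `V^(2/3)` and
is calibrated so a 1-cm³ tumor sheds 1.5 × 10⁵ cells/day.  Each shed
cell extravasates with probability `p_e = 0.8`; a shed, extravasated
cell is one *seeding attempt*.  The expected attempt count

    N(t) = p_e · k · V₀^(2/3) · (3/2r) · (e^(2rt/3) − 1)

is closed-form, as is its removal-weighted variant
`N(t; a, δ₀) = ∫ rate(u)·w(u) du` over the window
`[max(0, t(d)−δ₀), t]` with

    w(u) = 1 − exp(−(t(d) − u)/a),

the probability that a metastasis seeded at `u` (age `t(d) − u` at
surgery) has already outgrown its Exponential(mean `a`) irremovability
threshold and survives treatment.  Numerical quadrature of these
integrals appears only as a test oracle.  Whether shedding is "per
surface cell" with a geometric prefactor or directly `∝ V^(2/3)` is
unidentifiable given the single calibration point; the two coincide at
1 g by construction.

### Clinical outcome (`outcome`)

Attempts succeed independently with probability `s_1(b)`, so successful
metastases form a Poisson process and

    M(t; b) = 1 − exp(−s_1(b) · N(t))

is the probability of at least one. Post-surgical death probability
conditions on being alive at diagnosis (no success before `t(d) − δ₀`)
and counts only treatment-surviving attempts:
`M(t; a, b, δ₀) = 1 − exp(−s_1(b) N(t; a, δ₀))`.  Detection uses the
same kernel without removal weighting, evaluated δ₁ years before
diagnosis (`δ₁ < δ₀`; screening precedes treatment).  The severity `b`
is a per-patient log-normal frailty with location `μ` and scale `σ`
(median `e^μ`); population curves integrate the per-`b` expressions
against it.

The six free per-cancer parameters, with units and the bounds used in
fitting:

| parameter | meaning | bounds |
|---|---|---|
| δ₀ (y) | initiation → lethal | 0.5–30 |
| δ₁ (y) | initiation → detectable | (0.05–0.995)·δ₀ |
| a (y)  | expected irremovability age | 0.01–1 |
| h (y)  | treatment life prolongation | 0–5 |
| μ (log cells) | severity location | log 2 – log 200 |
| σ (log cells) | severity scale | 0.02–2 |

The upper bound of 1 year on `a` reflects that removal of metastases
older than about a year is clinically implausible; fits frequently park
`a` at this bound, and `OutcomeParams` itself only requires `a > 0` so
that counterfactuals with a boosted `a·c₁ > 1` remain expressible.

**Quantile times to death.**  Among patients who die of cancer, the
death time after diagnosis is `x + δ₀ + h − t(d)` where `x` is the
seeding time of the first non-removed metastasis.  Its conditional CDF
marginalized over the frailty is

    G(x) = E_b[M(x; a, b, δ₀)] / E_b[M(T; a, b, δ₀)],

with `T = t(d)` for all patients and `T = t(d) − δ₁` for the subset
with metastases detectable at diagnosis.  This is the *posterior*
frailty weighting: conditioning on cancer death tilts the severity
distribution toward weak bottlenecks by Bayes' rule, and it is exactly
the distribution a per-patient-frailty generative model produces (the
generator–analytic closure tests certify this).  The alternative
*prior* weighting `G(x) = E_b[M(x)/M(T)]` — taking the conditioning
ratio inside the severity integral, so each severity contributes its
unconditional mass — is retained behind `weighting="prior"`; on
synthetic cohorts it overstates the median time to death severalfold
because it underweights the (rapidly dying) weak-bottleneck patients,
and it is not used by default anywhere.  `q`-quantiles invert `G` by
bisection on the bracket `[max(0, t(d)−δ₀), T]` (absolute tolerance
10⁻⁹ y for public queries, 10⁻⁴ y inside the fitting loop); `G` is
continuous and non-decreasing there, so the root is unique.  As `q→0⁺`
the time tends to `h` (earliest possible seeding) and as `q→1⁻` to
`δ₀ + h`, which the limit tests pin down.  Per-patient survival curves
are `1 − G` on a time grid; a cohort curve averages them.

**Marginalization.**  The frailty integral uses composite Gauss–
Legendre quadrature on the log-`b` axis over `μ ± 8σ` (truncation error
< 10⁻¹⁵ of mass), 4 panels, 256 nodes in total by default.  The
integrand switches sharply near `b ≈ ln N`, which is why a panelled
rule is used: a single 256-node panel converges only to ~10⁻⁵, the
4-panel rule to ~10⁻⁹, and node-doubling stability is asserted in the
tests at 10⁻⁶.  Severities whose death probability underflows (s₁N → 0)
enter conditional ratios through their exact small-s₁ limit
`N(x)/N(T)`, avoiding 0/0.

### Treatment impact (`impact`)

Three counterfactuals are differenced against the status quo, per fixed
`b` and marginally: surgery delay by `δ` (the tumor seeds `δ` years
longer — implemented by advancing the diagnosis to the
growth-equivalent diameter, which shifts the conditioning window and
treatment time coherently); a chemotherapy boost multiplying `a` by
`c₁ > 1`; and bottleneck strengthening multiplying `b` (or the prior
median, i.e. `μ ← μ + ln c₂`) by `c₂ > 1`.  Sign conventions (delay ≥ 0
harms; both boosts help), magnitude monotonicity in the boost factor,
vanishing impact for very small and very large tumors, and unimodality
of fixed-`b` impact-vs-diameter curves are all asserted as tests.

### Synthetic cohorts (`cohort`)

The generator draws, per patient: a diameter from a truncated
log-normal (the diameter law is a free modelling choice — the outcome
model only ever conditions on `d`); one severity `b` from the frailty
prior (one per patient, the frailty reading of the marginal
expressions); successful seed times as an inhomogeneous Poisson process
with rate `s_1(b)·rate(u)` on `[max(0, t(d)−δ₀), t(d)]` — restricting
to this window *is* the alive-at-diagnosis conditioning, because
earlier Poisson increments are independent; a per-seed removal flag
with probability `exp(−(t(d)−u)/a)`; detection iff any seed predates
`t(d) − δ₁`; cancer death at the earliest surviving seed `+ δ₀ + h`;
an independent Exponential other-cause death; administrative censoring
at the follow-up horizon.  Seed times are sampled by exact inversion of
the closed-form `N(u)` (no thinning loop, no discretization bias), and
the per-patient seed draw is capped at 10⁴: conditional seed times are
i.i.d., so the minimum of 10⁴ draws is indistinguishable from the
minimum of more at any scale simulated here, and detection saturates
long before the cap can bind.

What the generator deliberately does *not* emulate about real registry
data: registry filtering (single primary, surgery first), stage- and
age-structured other-cause mortality, diameter measurement error and
digit preference, per-colony (within-patient) severity variation, and
cluster seeding.  Passing tests therefore certify internal consistency
of the model–generator pair and recoverability of parameters under the
model's own assumptions — not correctness of the model for any real
cancer.

### Summaries (`summaries`)

Quarter-cm diameter bins (midpoints 0.125 + 0.25k cm) with at least 20
patients (10 cancer deaths for quantile rows); sparser bins report
missing values.  Per bin: detection frequency; three cancer-death
estimators — upper (all deaths count), lower (other-cause deaths count
as alive), Kaplan–Meier (other-cause deaths censored; computed with
`lifelines`, evaluated at the follow-up horizon) — and empirical
type-7 quantile times among cancer deaths, separately for the detected
subset.  A two-sided Mann–Kendall trend test with tie-corrected normal
approximation screens binned statistics for monotone dependence on
diameter.

### Fitting (`fitting`)

Only the detection curve and the eleven all-patients quantile-time
curves enter the loss; the death estimators and detected-only quantiles
are held out for validation.  The eleven quantiles default to
0.05–0.95 in steps of 0.09 (symmetric, includes the median) and are
configurable.  Residuals are weighted by sampling standard errors —
binomial for frequencies, the asymptotic order-statistic formula
`√(q(1−q)/m) / f̂(x_q)` for quantiles, with the density estimated from
neighbouring quantile spacings and floored at 10⁻³ y — making the
objective an approximate chi-square.  (Standardizing by the per-curve
spread across bins was tried first and discarded: low quantile curves
are nearly flat in diameter, so that normalization amplifies pure
sampling noise by ~100× and the fit chases it.)

The global search is seeded differential evolution over the bounded
box (population 16, Sobol' initialization, relative tolerance 0.01),
followed by a bounded Powell polish.  A purely local multi-start
(Nelder–Mead or Powell from Latin-hypercube starts) was tried first and
found unreliable — the truth basin is narrow relative to the box and
most starts stall on plateaus orders of magnitude above it, while the
evolutionary stage finds the basin reproducibly.  δ₁ is parametrized as
a fraction of δ₀ so the ordering constraint is structural.  The reduced
model replaces (μ, σ) by a point severity b₀ sharing the μ bound.
`a` estimates within ~1% of the 1-year bound are reported as
bound-censored in spirit: the bound itself is part of the model.

Validation compares predicted death probabilities against the
[lower, upper] estimator interval per bin — each edge extended by twice
its binomial standard error, since the band itself is estimated — and
the predicted detected-only median against the observed one.  No
refitting occurs during validation.

## Problem sizes

Simulator–theory agreement uses 5 × 10⁴ colony replicates per (i₀, b)
pair; generator–equation closure 10⁵ patients per (d, b) cell;
parameter recovery three independent cohorts of 2 × 10⁵ patients.
These sizes put Monte-Carlo error well below the asserted tolerances
(3 binomial SEs; 15–20% parameter error) while a full check runs on a
single CPU in minutes.

## Known limitations

* The removal weight `w(u)` is a reconstruction of the
  treatment-removal mechanism from its stated ingredients (exponential
  irremovability age, lower removal probability for older metastases);
  it is isolated in one function so an alternative windowing can be
  swapped in.
* With `other_cause_hazard > 0` the observed quantile times among
  cancer deaths are slightly shortened by competing-risk selection; the
  fitted expressions do not model this, which biases δ₀ a few percent
  low at the default 1%/y hazard.  This is a property of the estimating
  equations, not of the generator.
* `a` is weakly identified away from its bound; `σ` is estimated less
  precisely than the location parameters.
* The generalized exponent law (i/b)^α, truncated-ratio variants,
  cluster seeding, secondary seeding from metastases and metastasis
  size distributions are out of scope.
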