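# Methods

## The problem

A meta-analysis of k randomized trials with a binary outcome observes one
effect estimate θᵢ with sampling variance vᵢ per trial. Heterogeneity
diagnostics ask whether the θᵢ scatter more than sampling error allows.
All of the standard diagnostics are permutation-invariant: they depend
only on the multiset {(θᵢ, vᵢ)}. A clinically real subgroup effect whose
aggregate signature is a *trend* of θᵢ with a trial-level covariate —
here, the proportion pᵢ of trial i's participants belonging to the
subgroup — contributes almost nothing to the between-trial variance when
the pᵢ are spread over a modest range, and is completely invisible to the
ordering-blind statistics. The package implements the diagnostics, a plot
that restores the ordering information, a generator for such scenarios,
and the participant-level analysis that tests the subgroup effect
directly.

## Effect measures (`effects`)

For a trial with a events among n₁ treated and c events among n₀ controls:

| measure | point | variance |
|---|---|---|
| log-RR | ln((a/n₁)/(c/n₀)) | 1/a − 1/n₁ + 1/c − 1/n₀ |
| log-OR | ln(a(n₀−c)/(c(n₁−a))) | 1/a + 1/(n₁−a) + 1/c + 1/(n₀−c) |
| RD | a/n₁ − c/n₀ | p₁(1−p₁)/n₁ + p₀(1−p₀)/n₀ |

Counts may be fractional: expected-count reconstructions of a generative
model are first-class inputs, and every formula is evaluated on real
cells. Ratio measures are computed and pooled on the log scale and
displayed exponentiated; confidence intervals are Wald intervals, with a
zero variance giving the degenerate point interval.

Zero cells: the default policy adds 0.5 to all four cells of an affected
table (per table, only when the requested measure actually needs the zero
cell); `error` and `none` are selectable. RD never needs the correction.

## Heterogeneity and pooling (`heterogeneity`)

Fixed-effect weights wᵢ = 1/vᵢ give θ̂_F = Σwᵢθᵢ/Σwᵢ and
Q = Σwᵢ(θᵢ − θ̂_F)², referred to χ² with df = k − 1 (upper tail via the
regularized incomplete gamma function Γ(df/2, Q/2)/Γ(df/2)).
I² = max(0, (Q − df)/Q), defined as 0 at Q = 0 and truncated at zero; it
is reported as a percentage with at most one decimal. The
DerSimonian–Laird moment estimator is τ² = max(0, (Q − df)/C) with
C = Σwᵢ − Σwᵢ²/Σwᵢ. Random-effects pooling reuses the fixed formulas
with wᵢ* = 1/(vᵢ + τ²). The prediction interval is Higgins-style,
θ̂_R ± t₍ₖ₋₂, (1+γ)/2₎ √(τ² + se_R²), and therefore needs k ≥ 3; k = 2
supports Q, I² and τ² but no prediction interval. No small-k corrections
(Knapp–Hartung) and no alternative τ² estimators (REML, Paule–Mandel) are
provided; meta-regression is deliberately out of scope because weighted
least squares on estimated (θᵢ, pᵢ) ignores their measurement error and
biases the slope.

Numerical choices: double precision throughout; the pooling and Q sums
iterate over the studies in a canonical sort order (label, point,
variance), which makes every statistic bit-identical under permutations of
the input rather than merely equal to rounding error. `compare_measures`
runs the identical tables through all three measures side by side; no
reconciliation is attempted, since homogeneity on one scale generally
implies heterogeneity on another whenever baseline risks differ.

## The modified forest plot (`forest`)

The standard layout places trials on evenly spaced rows (input or
chronological order). The modified layout maps each trial's subgroup
proportion linearly onto a 0–100% vertical axis: vertical *distances*
between trials are proportional to prevalence differences, which is what
distinguishes scaling from mere ordering. Linearity is a choice — any
monotone scaling would preserve the qualitative pattern — and linear is
the least surprising. Ties receive deterministic offsets of up to ±1.5% of
the axis height, assigned in label-lexicographic order. The horizontal
axis is logarithmic for ratio measures (symmetric about 1) and linear for
RD (symmetric about 0), covering all confidence limits with 10% padding;
non-finite or out-of-range limits are clipped and drawn with an arrow
glyph, never dropped. Marker area is proportional to the
inverse-variance weight, capped at five times the smallest. SVG output is
assembled from fixed string templates with two-decimal coordinates and no
timestamps, so re-rendering a layout is byte-identical; a monospace text
renderer serves terminals and tests.

## The scenario generator (`simulate`)

The generative model: trial i randomizes nᵢ participants per arm; a fixed
fraction pᵢ belongs to the subgroup; everyone shares the control-arm risk
r₀; treatment multiplies the risk by RR_in inside the subgroup and RR_out
outside. Because the baseline risk is the same in both strata, the risk
ratio is collapsible and trial i's marginal risk ratio is exactly
pᵢ·RR_in + (1−pᵢ)·RR_out.

The canonical fixture is five trials of 200 subjects (100 per arm),
r₀ = 0.5, RR_in = 0.7, RR_out = 1.0, pᵢ = 0, 0.25, 0.5, 0.75, 1. Its
expected-count tables give per-trial risk ratios 1.00 … 0.70 with
Q ≈ 3.29 (p ≈ 0.51), hence I² = 0 and τ² = 0, while the IPD interaction
is significant — the discordance the package demonstrates. Trial years
(1986, 1989, 1981, 1992, 1984) are an arbitrary fixed assignment chosen so
that chronological order differs from prevalence order, as a realistic
chronological plot would.

Two modes. `expected` emits deterministic fractional expected counts — the
noiseless skeleton, and the mean of the stochastic mode. `binomial` fixes
the subgroup sizes at round(pᵢ·n) (ties to even; compositions are part of
the design, not random) and draws events binomially per arm×stratum cell
from one seeded `numpy` generator per call. IPD output carries one
weighted record per trial×arm×stratum×outcome cell in expected mode
(weight = expected count) and one unit-weight record per participant in
binomial mode; collapsing the IPD by trial and arm reproduces the tables
exactly.

What the generator does *not* emulate: varying baseline risks across
trials or strata (which would break RR collapsibility and is exactly the
situation where measure choice matters), covariate measurement error,
attrition, or non-1:1 allocation. Passing tests on this generator
therefore show correctness of the machinery under the stated design, not
robustness of the qualitative message to those complications.

## IPD analysis (`ipd`)

Stratum treatment effects are reported as Mantel–Haenszel risk ratios
pooled over trials, RR_MH = Σᵢ(aᵢn₀ᵢ/Nᵢ) / Σᵢ(cᵢn₁ᵢ/Nᵢ) on the
stratum-restricted per-trial tables, with the Greenland–Robins variance
for the log-RR. On expected-count fixture data these recover the
generating 0.7 and 1.0 exactly.

The formal subgroup test is a weighted maximum-likelihood logistic
regression of outcome on trial indicators (first trial by label order as
reference), treatment, subgroup and treatment×subgroup. The logit link is
the conventional IPD choice, so the interaction coefficient is a log odds
ratio — on the fixture it equals ln[(0.35/0.65)/(0.5/0.5)] ≈ −0.619 —
while the stratum effects above stay on the ratio scale. Fractional
weights enter the likelihood multiplicatively (a quasi-likelihood for
expected-count data) with standard errors from the weighted information
matrix; records with identical covariates are pooled by summing weights
before fitting, which leaves the likelihood unchanged and keeps fits
O(cells). The fit itself is delegated to statsmodels' GLM (binomial
family, IRLS to tolerance 1e-10, ≤100 iterations); rank deficiency is
detected beforehand and reported with the offending column. Wald
(default) and likelihood-ratio interaction tests are provided; trial
effects are fixed, not random.

## Test-suite problem sizes

Stochastic checks run at sizes chosen to keep Monte-Carlo error well
inside the asserted tolerances: 10⁴ bootstrap replicates for the variance
formulas (10% relative), 2,000 replicates for the expected-vs-sampled
mean check (3 MC standard errors), 1,000 replicates of the null scenario
for the 5% type-I-error window [0.03, 0.07], 200 random meta-analyses for
bit-identical order invariance, and 100 random instances for the τ²
grid-search oracle (|Q − df − Cτ²| minimized over a 10⁻⁴ grid). An
independent cross-check of Q, I², τ² and both pooled models against
`metafor::rma(method = "DL")` runs through Rscript.

## Known limitations

- The modified plot handles one subgroup covariate expressed as a
  proportion; other trial-level covariates (mean age, year) would need a
  different axis scale.
- Exact/conditional odds ratios, continuous and time-to-event outcomes,
  random-effects IPD models and meta-regression are out of scope.
- The continuity correction ("halves") is the classic one; estimates from
  corrected tables are biased for extreme rates, which matters only in
  sparse-data settings the simulator does not generate.
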