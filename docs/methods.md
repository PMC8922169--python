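# Methods

## Exposure model

All tests assume full-shift concentrations within a similar exposure group
(SEG) are lognormal.  For the group tests, ln X ~ N(μ, σ²) with σ² the
*total* log-variance; for the individual test the two-level random-effects
model is used:

    ln X_ij = μ + b_i + e_ij,   b_i ~ N(0, σ²_B),   e_ij ~ N(0, σ²_W),

where i indexes workers and j repeated full-shift samples of the same
worker.  σ²_B captures stable differences between workers' personal mean
exposures (task mix, technique, micro-environment); σ²_W the day-to-day
fluctuation around each personal mean.  Autocorrelation in time, seasonal
structure, and censoring at detection limits are not modelled.

Fits use natural logarithms and the n−1 denominator throughout;
GM = exp(mean log), GSD = exp(SD log).

## Decision rules

**Preliminary screens.** Compliance when every value is strictly below
f(n)·OEL, with f = {1: 0.1, 3: 0.25} for EN689:1995 and
f = {3: 0.1, 4: 0.15, 5: 0.2} for EN689:2018; non-compliance when any
value is strictly above the OEL; otherwise *uncertain* (no decision yet).
Thresholds are strict inequalities because that is how the screens are
stated; a value exactly at the OEL is uncertain, not failing.  Sample
counts outside each standard's set are rejected rather than truncated,
since each threshold is tied to an exact n.

**EN689:1995 statistical test** (n ≥ 6): compliance iff the plug-in
exceedance fraction 1 − Φ((ln OEL − ȳ)/s) is strictly below 0.05.  The
original zoned (green/orange/red) scheme is not implemented; the binary 5%
rule replaces it so the two standards are comparable on one axis.  The
point estimate is used, not a confidence-bounded exceedance — the
confidence margin is exactly what the 2018 test adds, and keeping the 1995
rule plug-in preserves that contrast.

**EN689:2018 statistical test** (n ≥ 6): compliance iff
UTL₉₅,₇₀ = exp(ȳ + k(n)·s) < OEL.  The tolerance factor is computed
exactly from the non-central-t quantile, k(n) = t′₀.₇₀(n−1, z₀.₉₅√n)/√n,
rather than by interpolating printed tables; its defining property — the
limit covers the true 95th percentile with probability 0.70 for every n —
is verified by Monte-Carlo in the acceptance suite.  Because
k(n) > z₀.₉₅, a UTL-compliant SEG always has plug-in exceedance < 5%: the
2018 test dominates the 1995 test, which is the mechanism behind the
higher non-compliance counts it produces.

**Boundary ties** (exceedance exactly 0.05, UTL exactly at the OEL, θ
exactly 0.20) resolve to non-compliance: the compliant reading requires
the strict inequality, and ties are measure-zero on real data.

**BOHS-NVvA test** (n ≥ 6 and at least one worker with repeats).  Variance
components come from the one-way ANOVA moment (method-of-moments)
estimators with the unbalanced-design correction
n₀ = (N − Σnᵢ²/N)/(K−1): σ̂²_W = MSW, σ̂²_B = max(0, (MSB − MSW)/n₀).
Moment estimators rather than REML: they are the estimators of the
guidance's era, are exact closed forms, and make the balanced case
testable against the classical mean squares to machine precision.
Negative between-worker moment estimates are clamped to zero.  When a
single worker holds all repeats (K = 1) the between-worker mean square has
no degrees of freedom; σ̂²_B is reported as 0 and n₀ as NaN, which routes
the SEG to the group test.

Routing: if ρ_B = σ̂²_B/(σ̂²_B + σ̂²_W) ≥ 0.20 the SEG is judged on the
individual criterion θ < 0.20, with

    θ = 1 − Φ((ln OEL − μ̂ − z₀.₉₅·σ̂_W)/σ̂_B),

the model-based fraction of workers whose personal 95th percentile exceeds
the OEL, computed from the point estimates (no uncertainty adjustment).
Below 20% the workers are treated as exchangeable and the pooled
5%-exceedance group test decides; which group-level rule the guidance's
users apply in that branch is genuinely open, and the 5% rule was chosen
because it is the group test the strategy is compared against and the two
coincide exactly in the σ²_B → 0 limit (a property the tests check).  The
sensitivity variant drops SEGs whose repeats come from a single worker,
where σ̂²_B rests on one person's consistency.

z₀.₉₅ is taken at full precision from the normal quantile function
(1.6448…), never rounded.

## Synthetic studies

The generator emulates the structure of a multi-site industrial
dust-monitoring campaign: per SEG, worker means b_i and day effects e_ij
are drawn from the two-level model above and exponentiated; sampling dates
advance one day at a time round-robin over workers, so date-ordered
preliminary subsets mix workers the way progressive campaign sampling
does.  Study defaults are 210 SEGs, 158 with repeated measurements and
1383 measurements in total, each SEG at least 6 measurements (sizes 6 plus
a Poisson(0.6) excess, or extras allocated to hit an exact total); GM
log-uniform on 0.02–0.8 mg m⁻³ and total GSD uniform on 1.5–3.5 against an
OEL of 1 mg m⁻³ — a realistic spread for respirable dust that exercises
all three decision branches; the between-worker share ρ_B is uniform on
0–0.5 so routing straddles the 20% threshold.  SEGs without repeats assign
one worker per measurement.

Randomness flows from a single integer seed through keyed
`numpy.random.SeedSequence` substreams: SEG k's parameters and data come
from streams keyed (seed, k, ·), so in the default sizing mode SEG k is
identical whatever the study size.  Pinning an exact study-wide
measurement total draws the extra-size allocation from a study-level
stream, which trades that invariance for exact totals.

What passing tests on synthetic data do *not* show: behaviour under
autocorrelated exposures, non-detects, mis-specified (non-lognormal)
distributions, or SEGs whose membership violates the similar-exposure
assumption.  The decision *rules* are exact; only their statistical
performance claims are conditional on the generating model.

## Numerical and design notes

* Concentrations must be strictly positive; zero or negative values are
  rejected at parse time rather than imputed (log-scale methods, and
  non-detect handling is out of scope).
* Date ties inside a SEG are broken by stable input order — the selection
  is specified only "per sampling date", and stable order makes reports
  byte-reproducible.
* Degenerate zero-variance fits: exceedance is 0/1/0.5 below/above/at the
  OEL; UTL reduces to the GM; θ reduces to a 0/1 indicator on the group
  95th percentile.
* Displayed percentages round half-up to integers in `count (percent%)`
  cells; the CSV report keeps full precision alongside the counts.
* Problem sizes in the acceptance checks (10⁵ simulated SEGs per coverage
  point, 10⁶ Monte-Carlo draws per grid point, 10⁴ SEGs for the stringency
  sweep, 200 replicates for variance recovery) are chosen so Monte-Carlo
  error is several times smaller than each stated tolerance.

## Limitations

* No distributional diagnostics (e.g. a lognormality check) gate the
  statistical tests; callers are responsible for the lognormal assumption.
* The 1995 statistical test here is the binary 5%-exceedance variant, not
  the original zoned scheme, by design.
* θ uses point estimates of (μ, σ²_B, σ²_W); with few workers or repeats
  its sampling error can be large, and no confidence statement accompanies
  the individual decision.
* Group sizes below 6 measurements are skipped by the pipeline and
  reported, not analysed.
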