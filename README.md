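# ohcompliance

Compliance testing of occupational exposure limits (OELs) for similar
exposure groups (SEGs), for occupational hygienists and exposure
scientists who need to compare the decision rules of three measurement
strategies on the same data:

* **EN689:1995** — preliminary screens (1 sample < 0.1·OEL, or 3 samples
  < 0.25·OEL) and a statistical test requiring the lognormal exceedance
  fraction *P(X > OEL)* to stay below 5%;
* **EN689:2018** — preliminary screens (3/4/5 samples below
  0.1/0.15/0.2·OEL) and a statistical test requiring the upper tolerance
  limit UTL₉₅,₇₀ to stay below the OEL;
* **BOHS-NVvA (2011)** — the individual compliance test: more than 80% of
  SEG members must have at least 95% of their personal exposures below the
  OEL.

## Model

Full-shift concentrations within a SEG are lognormal, ln *X* ~ N(μ, σ²),
with sample statistics ȳ and *s* on the log scale (GM = e^ȳ, GSD = e^s).
The group tests are

* exceedance fraction: *P(X > OEL)* = 1 − Φ((ln OEL − ȳ)/s) < 0.05
  (EN689:1995, the zoned scheme replaced by the conventional 5% rule);
* tolerance limit: UTL₉₅,₇₀ = exp(ȳ + k(n)·s) < OEL, with
  k(n) = t′₀.₇₀(n−1, z₀.₉₅√n)/√n from the non-central *t* distribution
  (EN689:2018).  Since k(n) > z₀.₉₅ for every finite n, the 2018 test is
  strictly more stringent than the 1995 test on the same data.

For the BOHS-NVvA test a one-way random-effects ANOVA on log
concentrations splits variability into between-worker (σ²_B) and
within-worker (σ²_W) components.  Worker *i*'s personal 95th percentile is
exp(b_i + z₀.₉₅·σ_W) with b_i ~ N(μ, σ²_B), so the fraction of overexposed
workers is

θ = 1 − Φ((ln OEL − μ − z₀.₉₅·σ_W)/σ_B).

When the between-worker share ρ_B = σ²_B/(σ²_B+σ²_W) is at least 20% the
SEG is judged on θ < 0.20; more homogeneous SEGs fall back to the group
5%-exceedance test.

A synthetic study generator produces SEG collections with this exact
two-level lognormal structure (defaults: 210 SEGs, 158 with repeated
measurements, 1383 measurements, GM 0.02–0.8 mg m⁻³, total GSD 1.5–3.5,
OEL 1 mg m⁻³ respirable dust), and a pipeline tallies every strategy's
decisions into `count (percent%)` tables.

## Worked example

```python
from ohcompliance import (OELSpec, exceedance_probability, fit_lognormal,
                          statistical_test_1995, statistical_test_2018, utl_95_70)

oel = OELSpec(oel=1.0)
fit = fit_lognormal([0.12, 0.31, 0.18, 0.45, 0.22, 0.58])
print(fit.gm, fit.gsd)
print(exceedance_probability(fit, oel), utl_95_70(fit))
```

prints (see `examples/statistical_tests.py`):

```
n = 6, GM = 0.270 mg m⁻³, GSD = 1.80
exceedance fraction P(X > OEL) = 0.0129
UTL95,70 = 0.975 mg m⁻³
EN689:1995 (exceedance < 5%): compliance
EN689:2018 (UTL < OEL):       compliance
```

The SEG's estimated chance of a shift above the OEL is 1.3%, well under
5%, and the 70%-confidence bound on its 95th percentile (0.975 mg m⁻³)
still sits below the OEL — both group tests pass, the 2018 one only just.
The other scripts in `examples/` demonstrate the preliminary screens, the
BOHS-NVvA test, and the full study comparison; each prints the numbers it
computes and a line on what they mean.

A CLI wraps the same pipeline:

```sh
ohcompliance simulate --n-segs 210 --n-with-repeats 158 --seed 1 --output study.csv
ohcompliance run --input study.csv --oel 1.0 --format markdown
```

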