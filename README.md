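# migtrend

**Does a systematic change in stopover duration bias population trends
estimated from migration counts — and can a detection covariate or
subsampling repair it?**

Daily counts of unmarked migrating birds (and whales, raptors, monarchs,
shorebirds) are widely used as an index of population size: fit a trend to
twenty years of counts and read off the population's trajectory. That
inference assumes each day's count samples a new cohort of individuals and
that a constant fraction of the population is detected. Birds on migratory
stopover violate both: an individual staying several days can be counted
several times, and if stopover duration *changes systematically* over the
years — with climate, habitat succession, or predation risk — counts
inflate (or deflate) for reasons that have nothing to do with population
size.

`migtrend` is a simulation laboratory for this problem, aimed at analysts
of migration-monitoring data. It provides:

* an **individual-based Jolly-Seber simulator** of daily stopover counts:
  yearly totals follow a known trend with lognormal year noise; arrivals
  follow a mid-season-peaked, day-autocorrelated intensity; each bird stays
  with daily survival probability φᵢ (geometric stopover, mean 1/(1−φ)
  days) and is detected each day present with probability p = 0.3. All
  per-individual truth is retained.
* the **hierarchical negative-binomial trend model** used for such counts:

  y(i,j) ~ NegBinom(μ(i,j), φ_NB),
  log μ(i,j) = β₀ + β₁·yearᵢ + β₂·dayⱼ + β₃·dayⱼ² [+ β₄·φᵢ] + εᵢ + η(i,j),

  with iid year effects εᵢ ~ N(0, σ²) and per-year AR(1) day effects
  η(i,j); trends are reported as 100(exp(β₁)−1) %/yr with 95% intervals.
  Fitting is a fast Laplace approximation exploiting the banded AR(1)
  precision (sub-second per 20-year series).
* an **evaluation harness** that runs scenario grids (constant, random,
  cyclic, or linearly increasing φ schedules × declining/stable/increasing
  trends × treatment arms) and reports bias, interval coverage, power, and
  the false-trend ("error") rate, plus OLS meta-regressions of bias on the
  design factors.

## Worked example

`examples/stopover_bias.py` reproduces the core finding at desk scale:
populations declining 1.2 %/yr while daily survival rises linearly from
0.2 to 0.7 (mean stopover ~1.2 → ~3.4 days), analysed three ways on the
same eight datasets:

```
arm                mean bias  coverage   error
untreated              +4.10      0.62    0.25
covariate-only         +2.64      1.00    0.00
covariate+5-day        +2.56      1.00    0.00
```

Read: the untreated model is biased upward by ~4 %/yr — a population losing
20% in 20 years is reported as *growing* ~3 %/yr, and with more replicates
the error rate (confident wrong trends) exceeds 60%. Adding the true annual
φ as a covariate removes only about half the bias, because a linearly
rising φ is exactly collinear with the year trend and the count inflation
log(1/(1−φ)) is nonlinear in it; the treated fits regain interval coverage
by honestly widening. Other capabilities are shown in
`examples/simulate_counts.py` (simulator + truth consistency),
`examples/fit_trend.py` (a single fit: prints e.g. `estimated trend :
-1.41 %/yr`, interval `[-5.00, +2.31]`, covering the simulated −1.2), and
`examples/experiment_grid.py` (a small grid end to end).

A thin CLI wraps the same library calls:

```bash
migtrend simulate --trend -1.2 --pattern linear --phi-lo 0.2 --phi-hi 0.7 --out counts.csv
migtrend fit counts.csv --covariate --subsample every5
migtrend run --seed 1 --replicates 25 --outdir results/
migtrend report results/fits.csv
```

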