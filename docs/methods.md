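# Methods

`migtrend` is a simulation laboratory for a specific inference problem in
migration monitoring: daily counts of *unmarked* migrants are used as an
index of population size, and their long-term trend is read as the
population trend. That reading rests on two assumptions — each day's count
samples a fresh cohort (count independence), and a constant fraction of the
passing population is detected (proportionality). Both fail when birds stop
over for more than a day, and fail *systematically* when stopover duration
changes over the years. The package generates count data in which the truth
is known and the stopover process is controlled, fits the standard
hierarchical trend model to them, and measures what happens.

## 1. Data-generating model

### Annual model

The number of individuals passing the site in year `i` (of `I`, default 20)
is

    n_i ~ Poisson(n_1 (1+beta)^(i-1) * exp(eps_i)),    eps_i ~ N(0, sigma_a^2)

with `beta` the true proportional trend per year (the study grid uses
-0.012, 0, +0.0096, i.e. -20%, 0, +20% over 20 years) and iid lognormal
year-to-year noise around the exponential trend path plus Poisson process
noise. Defaults: `n1 = 3000`, `sigma_a = 0.5`.

Two alternatives are available behind switches: `noise="additive"` places
`eps` additively on the Poisson rate, and `recursion="realized"` recurses
the rate through the *realized* `n_{i-1}` rather than the expected path.
The realized-recursion variant is not the default for a structural reason:
noise then compounds into a random walk in log abundance, and the sampling
SD of a fitted 20-year log-linear slope through a random walk is roughly
three times the SE implied by an iid year-effect model (the walk's drift
masquerades as trend). No iid-year-effect trend model can be
well-calibrated under that process, whereas the documented behaviour of
this class of simulation — near-nominal interval coverage and low power
under constant detection — requires calibration to be attainable. With iid
noise around the trend line, the year-slope sampling SD is
`sigma_a / sqrt(S_tt)` with `S_tt = sum_i (i - ibar)^2 = 665` for 20 years,
about 0.019 on the log scale at `sigma_a = 0.5`.

`sigma_a = 0.5` itself encodes the high among-year variability typical of
single-site songbird migration totals (CV ≈ 50-60%). It implies ~95%
interval coverage, power below ~6% to detect the ±20%-in-20-years trends,
and — combined with the stopover-inflation arithmetic below — a
false-trend (error) rate above 60% under the strongest systematic increase
in stopover duration. These are emergent properties of the chosen
variability, not targets enforced anywhere in the code.

### Seasonal arrival model

Within each year, arrival days are drawn from a normalized daily intensity

    intensity_j = (B_j / ndays) * exp(-(j - mu)^2 / (2 s^2)) * exp(eta_j)
    B_j ~ Binomial(ndays, Pm),     eta_{j+1} = a * eta_j + N(0, tau^2)

i.e. a binomial daily movement fraction (`Pm = 0.85`), a Gaussian
mid-season peak, and day-to-day autocorrelated lognormal noise. Defaults:
`ndays = 60`, `mu = 30`, `s = 9`, `a = 0.5`, `tau = 0.3`. Setting
`tau = 0` gives a fully deterministic season (the movement draw is replaced
by its expectation), which the tests use as a degenerate oracle. The `n_i`
individuals are assigned to arrival days by a single multinomial draw, so
arrivals sum exactly to `n_i`.

The Gaussian kernel makes the log seasonal shape exactly quadratic in day —
deliberately matched to the `day + day^2` fixed effects of the trend model
— and the AR(1) intensity noise is the structure the model's AR(1) day
effects are meant to absorb. Season length is fixed across years by
default.

### Stopover and detection (Jolly-Seber process)

Each individual arriving on day `j0` remains on site with daily "survival"
probability `phi_i` (constant within a year), giving a geometric stopover
of mean `1/(1-phi_i)` days, truncated (censored, not resampled) at the last
season day. On every day present it is counted independently with detection
probability `p = 0.30`. The count `y_ij` is the number of detections on day
`j` — individuals staying several days can be recounted. Expected
detections per individual are `p/(1-phi)` (up to truncation): 0.375 at
`phi = 0.2` and 1.0 at `phi = 0.7`, which is the compounding the study is
about. Simulated mean stopover runs from ~1.2 days (`phi = 0.2`) to ~3.4
days (`phi = 0.7`); truncation at day 60 is why 1.25 and 3.33 shave down
slightly.

Per-individual truth (arrival day, last day, detection days) is retained,
and the count matrix is recomputable exactly from it (`recount()`), which
the property tests assert.

### Stopover schedules and the design grid

`phi_i` over years follows one of four patterns: constant (levels 0, 0.2,
0.5, 0.7 — level 0 is the control in which every bird leaves after one day
and counts are independent), random (iid Uniform(lo, hi) per year), cyclic
(5-year-period sinusoid), or linear (inclusive arithmetic progression lo ->
hi). Ranges: 0.4-0.5, 0.35-0.55, 0.3-0.6, 0.25-0.65, 0.2-0.7. The cyclic
sinusoid starts at the cycle midpoint and is rescaled so the sampled series
spans [lo, hi] exactly (integer-year sampling of an odd period cannot hit
both extremes of a raw sinusoid); with a 5-year period over 20 years the
series ends below its start, which induces the small negative bias the
cyclic scenarios show. The core grid is 3 trends x (4 constant levels + 3
patterns x 5 ranges) = 57 cells; the treatment grid crosses the 5 linear
ranges with {covariate off/on} x {no subset, every 3rd day, every 5th day}
at trend -1.2 %/yr (30 cells).

RNG: each dataset takes one master seed, from which four sub-streams
(annual, arrival, survival, detection) are derived deterministically;
replicate seeds derive from (master seed, data-generating cell, replicate),
so analysis arms share identical datasets and comparisons are paired.

## 2. Trend model and inference

    y_ij ~ NegBinomial(mu_ij, phi_nb)        Var = mu + mu^2/phi_nb
    log mu_ij = b0 + b1 year_i + b2 day_j + b3 day_j^2 [+ b4 phi_i]
                + eps_i + eta_ij
    eps_i ~ N(0, sigma_year^2) iid;  eta_i. ~ AR1(rho, sigma_day) per year

The reported quantity is `100 (exp(b1) - 1)`, the trend in %/yr, with a
central 95% interval. Subsampling (every 3rd/5th day) drops rows before
fitting; the AR(1) chain then runs over the retained, equally spaced days.

Inference is an empirical-Bayes Laplace approximation, built for speed and
reproducibility rather than generality:

* Latent field `u = (eta, eps, b)`; its prior precision is tridiagonal for
  the AR(1) blocks plus a low-dimensional border (year effects and fixed
  effects). Each Newton/Fisher-scoring step factorizes the `eta` block with
  a banded Cholesky (O(n)) and eliminates the ~25-dimensional border with a
  dense Schur complement; posterior variances of fixed effects come from
  the inverse Schur complement.
* Hyperparameters `(phi_nb, sigma_year, sigma_day, rho)` maximise the
  Laplace marginal likelihood by Nelder-Mead (~150 evaluations, warm-started
  inner modes) under weak hyperpriors: log-normal around 3 (x/÷ e^2) for
  `phi_nb`, around 0.3 (x/÷ e^1.5) for both SDs, N(0,1) on atanh(rho). The
  NB dispersion and the AR(1) variance overlap in what day-level
  overdispersion they can absorb; the ridge between them is flat, and trend
  inference is insensitive to where the optimizer settles on it.
* Fixed effects are standardized internally (year, day, day^2, phi all
  z-scored) with independent N(0,1) priors (N(0,10^2) for the intercept);
  `b1` is rescaled to per-year units for reporting. Identified coefficients
  feel essentially no shrinkage from these priors.
* The 95% interval is `b1 ± t_{I-2, 0.975} * sd(b1)`. The t multiplier
  (2.10 at I = 20, vs 1.96) is a small-sample calibration: plug-in
  hyperparameters ignore the uncertainty of `sigma_year`, which is
  estimated from only ~I year-level units and dominates trend uncertainty —
  the same logic as Satterthwaite-type corrections in mixed models.
* Fits that fail the inner Newton iteration or return non-finite variances
  are flagged `converged=False`; evaluation summaries exclude them and
  report the exclusion count.

An oracle anchors the implementation: with the random-effect SDs and
overdispersion pinned to negligible values the model collapses to a
log-linear Poisson regression, and the tests require agreement with an
independent IRLS fit (statsmodels GLM) to 1e-4 on `b1`.

### The covariate arm and collinearity

Under a *linear* phi schedule the annual covariate `phi_i` is an exact
linear function of `year_i`, so the two design columns are perfectly
collinear: the likelihood identifies only `b1 + c b4`, and the split
between them is decided by the priors. Because both columns are z-scored
with equal prior SD, the identified trend direction splits evenly — the
covariate removes about half of the stopover-induced bias — and the
posterior for `b1` widens along the unidentified direction, honestly
reporting that trend and detection-trend are confounded. That widening is
the mechanism by which the treated fits regain nominal interval coverage
(and near-zero power and error).

Two consequences are worth stating plainly. First, even a *perfect*
stopover covariate cannot remove the bias: the inflation of log counts is
`log(1/(1-phi_i))`, convex in the linearly rising `phi_i`, while the model
term `b4 phi_i` is linear — and in the confounded design the posterior mean
retains roughly half the bias. Second, because subsampling removes rows
without changing the retained counts and the collinear split is
data-independent, covariate+subsampling and covariate-only fits have the
same *expected* trend posterior mean here; paired differences between those
two arms are Monte-Carlo noise. A mechanism by which subsampling would
further reduce the posterior-mean bias specifically in combination with
the covariate does not exist under an exactly linear schedule; it would
require year-to-year irregularity in `phi_i` (which random schedules have
and linear ones, by construction, do not).

## 3. Evaluation

Per scenario, over converged replicate fits:

* **bias** = estimated - simulated trend (%/yr); summarized by its mean;
* **coverage** = share of fits whose 95% interval contains the simulated
  trend;
* **power** = share with good coverage *and* an interval excluding zero
  (deliberately stricter than the usual power definition: a significant
  trend that misses the truth does not count);
* **error** = share with poor coverage *and* an interval excluding zero —
  the probability of confidently wrong inference.

By construction power ≤ coverage, error ≤ 1 - coverage, and power + error
equals the share of intervals excluding zero.

Bias meta-regressions are ordinary least squares (statsmodels) on per-fit
bias with treatment-coded factors: design "constant" (trend x constant phi
level; references: no trend, phi 0), "varying" (trend + pattern x range
width; references: no trend, random pattern, narrowest range), "treatment"
(range x subsample x covariate, full three-way; references: narrowest
range, no subset, no covariate).

## 4. Problem sizes and numerical choices

Replicate counts are configurable; the package's desk-scale defaults are
15 replicates per scenario for the constant/linear/treated grids and 10
for the 30 random/cyclic cells (the full-study convention is 100). A fit
of a 20x60 series takes well under a second; the complete acceptance run
is a few hundred fits. Monte-Carlo SEs on pooled proportions at these
sizes are 2-4 percentage points, small against the margins of the
qualitative regime being checked.

Numerical guards: linear predictors are clipped at ±30 before
exponentiation; `log phi_nb` is bounded in [-4, 14], log-SDs in [-7, 2],
|rho| ≤ tanh(3) ≈ 0.995; Newton steps halve on objective decrease (six
times at most); all-zero count series and single-year series are rejected
with explicit errors rather than fitted.

## 5. What the generator does and does not emulate

It emulates: a consistently detected species with a unimodal migration
season, a low proportion of zero-count days (~8% at phi = 0.5), large
within-season and among-year count variability, geometric stopovers with
recounting across days, and constant observer detection. It does not
emulate: weather- or observer-driven detection variation, season length
varying among years (a fixed 60-day window is used), arrival-day
distributions shifting over years, departure probability depending on
arrival date or condition, or any real counts — no field data enter the
package. Passing tests therefore demonstrate the *mechanism* — systematic
stopover change biases trends from unmarked counts, and a covariate alone
cannot repair it — under controlled conditions, not the magnitude of that
bias in any particular monitoring program.

Other limitations: declining linear phi schedules run but are not
validated against any reference behaviour; the meta-regression coefficient
magnitudes depend on the generator's variance scale and are interpreted by
sign/significance pattern only; the Laplace intervals are empirical-Bayes
with a t correction rather than fully Bayesian; and there is no MCMC
backend.
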