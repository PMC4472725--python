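"""Experiment harness: bias / coverage / power / error across scenarios.

For every scenario (a true trend plus a stopover-duration schedule, with
optional analysis arms) the harness simulates replicate datasets, fits the
negative-binomial trend model, and summarizes the replicate fits by

* bias        — estimated minus simulated trend, on the %/year scale;
* coverage    — proportion of fits whose 95% interval contains the
                simulated trend;
* power       — proportion with good coverage AND an interval excluding
                zero (a correctly detected "significant" trend);
* error       — proportion with poor coverage AND an interval excluding
                zero (a confidently wrong trend — the false-inference rate).

It also fits the ordinary-least-squares meta-regressions of bias on the
design factors for the three study designs (constant-phi, varying-phi, and
covariate-by-subsampling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .scenarios import ScenarioSpec, build_design_grid
from .simulator import SeasonConfig, simulate_dataset
from .trend import TrendFit, TrendModelSpec, fit_trend

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationSummary",
    "MetaRegressionTable",
    "evaluate_scenario",
    "bias_meta_regression",
    "replicate_seed",
    "run_scenario",
    "run_experiment",
    "fits_to_frame",
]


@dataclass(frozen=True)
class EvaluationSummary:
    """Replicate-level performance of the trend model in one scenario."""

    scenario_id: str
    simulated_trend_pct: float
    n_fits: int
    n_excluded: int
    bias_values: tuple[float, ...]
    mean_bias: float
    sd_bias: float
    coverage: float
    power: float
    error: float

    def as_dict(self) -> dict:
        d = {
            "scenario_id": self.scenario_id,
            "simulated_trend_pct": self.simulated_trend_pct,
            "n_fits": self.n_fits,
            "n_excluded": self.n_excluded,
            "mean_bias": self.mean_bias,
            "sd_bias": self.sd_bias,
            "coverage": self.coverage,
            "power": self.power,
            "error": self.error,
        }
        return d


@dataclass(frozen=True)
class MetaRegressionTable:
    """OLS coefficient table for bias as a function of design factors."""

    design: str  # constant | varying | treatment
    reference: str
    table: pd.DataFrame  # columns: term, estimate, se, t, p

    def term(self, name: str) -> pd.Series:
        exact = self.table[self.table["term"] == name]
        if len(exact) == 1:
            return exact.iloc[0]
        hit = self.table[self.table["term"].str.contains(name, regex=False)]
        if len(hit) != 1:
            raise KeyError(f"{name!r} matches {len(hit)} terms")
        return hit.iloc[0]


def evaluate_scenario(
    fits: Sequence[TrendFit], simulated_trend_pct: float, scenario_id: str = ""
) -> EvaluationSummary:
    """Apply the bias/coverage/power/error definitions to replicate fits.

    Non-converged fits are excluded (their count is reported), mirroring the
    convention that summaries describe successfully estimated trends.
    """
    kept = [f for f in fits if f.converged]
    n_excluded = len(fits) - len(kept)
    if not kept:
        raise ValueError("no converged fits to evaluate")
    bias = np.array([f.trend_pct - simulated_trend_pct for f in kept])
    covered = np.array([f.covers(simulated_trend_pct) for f in kept])
    excl_zero = np.array([f.interval_excludes_zero for f in kept])
    return EvaluationSummary(
        scenario_id=scenario_id,
        simulated_trend_pct=simulated_trend_pct,
        n_fits=len(kept),
        n_excluded=n_excluded,
        bias_values=tuple(float(b) for b in bias),
        mean_bias=float(bias.mean()),
        sd_bias=float(bias.std(ddof=1)) if len(bias) > 1 else float("nan"),
        coverage=float(covered.mean()),
        power=float((covered & excl_zero).mean()),
        error=float((~covered & excl_zero).mean()),
    )


def replicate_seed(master_seed: int, scenario: ScenarioSpec, replicate: int) -> int:
    """Deterministic per-replicate dataset seed (< 2^31).

    Depends only on the master seed, the scenario's *data-generating* cell
    (trend and phi schedule, not the analysis arms) and the replicate index,
    so treatment arms reuse identical simulated datasets.
    """
    ss = np.random.SeedSequence([int(master_seed), scenario.stable_hash(), int(replicate)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_scenario(
    scenario: ScenarioSpec,
    season: SeasonConfig | None = None,
    n_replicates: int | None = None,
    master_seed: int = 0,
    n1: int = 3000,
    sigma_annual: float = 0.5,
    dataset_cache: dict | None = None,
) -> list[TrendFit]:
    """Simulate replicate datasets for one scenario and fit each one.

    ``dataset_cache`` (optional dict) lets multiple analysis arms of the same
    data-generating cell share simulated datasets, keyed by replicate seed.
    """
    season = season or SeasonConfig()
    n_rep = n_replicates if n_replicates is not None else scenario.n_replicates
    model = TrendModelSpec(
        include_covariate=scenario.covariate_arm, subsample=scenario.subsample_arm
    )
    fits: list[TrendFit] = []
    for rep in range(n_rep):
        seed = replicate_seed(master_seed, scenario, rep)
        if dataset_cache is not None and seed in dataset_cache:
            ds = dataset_cache[seed]
        else:
            ds = simulate_dataset(scenario, season, seed=seed, n1=n1, sigma_annual=sigma_annual)
            if dataset_cache is not None:
                dataset_cache[seed] = ds
        try:
            fit = fit_trend(ds, model)
        except ValueError as exc:  # e.g. an all-zero series; flagged, not fatal
            logger.warning("fit failed for %s rep %d: %s", scenario.scenario_id(), rep, exc)
            fit = _failed_fit(str(exc))
        fits.append(fit)
    return fits


def _failed_fit(msg: str) -> TrendFit:
    nanpair = (float("nan"), float("nan"))
    return TrendFit(
        beta1=float("nan"), beta1_interval=nanpair, trend_pct=float("nan"),
        trend_interval_pct=nanpair, beta2=float("nan"), beta3=float("nan"),
        covariate_coef=None, dispersion=float("nan"), sigma_year=float("nan"),
        sigma_day=float("nan"), ar1_rho=float("nan"), converged=False,
        n_obs=0, n_years=0, marginal_loglik=float("nan"), message=msg,
    )


def fits_to_frame(
    scenario: ScenarioSpec, fits: Sequence[TrendFit], master_seed: int
) -> pd.DataFrame:
    """One-row-per-fit table, including design factors for meta-regression."""
    rows = []
    for rep, f in enumerate(fits):
        rows.append(
            {
                "scenario_id": scenario.scenario_id(),
                "replicate": rep + 1,
                "seed": replicate_seed(master_seed, scenario, rep),
                "trend_pct": scenario.trend_pct,
                "pattern": scenario.phi.pattern,
                "phi_lo": scenario.phi.lo,
                "phi_hi": scenario.phi.hi,
                "phi_range": scenario.phi.label(),
                "covariate": scenario.covariate_arm,
                "subsample": scenario.subsample_arm,
                "beta1": f.beta1,
                "beta1_lo": f.beta1_interval[0],
                "beta1_hi": f.beta1_interval[1],
                "trend_est_pct": f.trend_pct,
                "trend_lo_pct": f.trend_interval_pct[0],
                "trend_hi_pct": f.trend_interval_pct[1],
                "bias_pct": f.trend_pct - scenario.trend_pct,
                "covered": f.covers(scenario.trend_pct) if f.converged else np.nan,
                "excludes_zero": f.interval_excludes_zero if f.converged else np.nan,
                "dispersion": f.dispersion,
                "sigma_year": f.sigma_year,
                "sigma_day": f.sigma_day,
                "ar1_rho": f.ar1_rho,
                "covariate_coef": f.covariate_coef,
                "converged": f.converged,
            }
        )
    return pd.DataFrame(rows)


_DESIGNS = {
    "constant": (
        "bias_pct ~ C(trend_pct, Treatment(0.0)) + C(phi_lo, Treatment(0.0))",
        "no trend (0 %/yr) and no stopovers beyond one day (phi = 0)",
    ),
    "varying": (
        "bias_pct ~ C(trend_pct, Treatment(0.0))"
        " + C(pattern, Treatment('random')) * C(phi_range_width)",
        "no trend, random phi variation, narrowest range (0.4-0.5)",
    ),
    "treatment": (
        "bias_pct ~ C(phi_range_width) * C(subsample, Treatment('none'))"
        " * C(covariate, Treatment(False))",
        "narrowest linear increase (0.4-0.5), no subsampling, no covariate",
    ),
}


def bias_meta_regression(results: pd.DataFrame, design: str) -> MetaRegressionTable:
    """OLS regression of per-fit bias on the design factors of one table design.

    ``design`` is ``constant`` (trend x constant phi level), ``varying``
    (trend + pattern x range) or ``treatment`` (range x subsample x
    covariate, three-way). Reference levels are no-trend / phi 0 / random
    pattern / narrowest range / untreated, as appropriate.
    """
    import statsmodels.formula.api as smf

    if design not in _DESIGNS:
        raise ValueError(f"unknown design: {design!r}")
    formula, reference = _DESIGNS[design]

    df = results[results["converged"] == True].copy()  # noqa: E712
    if df.empty:
        raise ValueError("no converged fits")
    # phi-range width orders category levels from narrowest to widest
    df["phi_range_width"] = (df["phi_hi"] - df["phi_lo"]).round(6)

    # restrict to the rows each table design describes
    if design == "constant":
        df = df[df["pattern"] == "constant"]
    elif design == "varying":
        df = df[df["pattern"].isin(["random", "cyclic", "linear"])]
    else:
        df = df[df["pattern"] == "linear"]

    needed, references = {
        "constant": (["trend_pct", "phi_lo"], [("trend_pct", 0.0), ("phi_lo", 0.0)]),
        "varying": (
            ["trend_pct", "pattern", "phi_range_width"],
            [("trend_pct", 0.0), ("pattern", "random")],
        ),
        "treatment": (
            ["phi_range_width", "subsample", "covariate"],
            [("subsample", "none"), ("covariate", False)],
        ),
    }[design]
    for col in needed:
        if df.empty or df[col].nunique() < 2:
            raise ValueError(f"design factor {col!r} has a single level; rank-deficient design")
    for col, level in references:
        if level not in set(df[col]):
            raise ValueError(f"reference level {level!r} of {col!r} missing from results")

    fit = smf.ols(formula, data=df).fit()
    table = pd.DataFrame(
        {
            "term": fit.params.index,
            "estimate": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "t": fit.tvalues.to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    ).reset_index(drop=True)
    return MetaRegressionTable(design=design, reference=reference, table=table)


def run_experiment(
    config: dict,
    outdir: str | Path,
    season: SeasonConfig | None = None,
    progress: Callable[[str], None] | None = None,
) -> dict[str, Path]:
    """Run a full scenario grid end to end and write CSV outputs.

    ``config`` is a design-grid configuration (see
    :func:`migtrend.scenarios.build_design_grid`) plus optional keys
    ``master_seed`` (default 0), ``n1``, ``sigma_annual``. Writes
    ``fits.csv`` (one row per replicate fit), ``summaries.csv`` (one row per
    scenario) and ``meta_<design>.csv`` for every design whose factors are
    present. Deterministic for a given config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    season = season or SeasonConfig()
    master_seed = int(config.get("master_seed", 0))
    n1 = int(config.get("n1", 3000))
    sigma_annual = float(config.get("sigma_annual", 0.5))

    scenarios = build_design_grid(config)
    all_fits: list[pd.DataFrame] = []
    summaries: list[dict] = []
    cache: dict = {}
    for k, scen in enumerate(scenarios):
        msg = f"[{k + 1}/{len(scenarios)}] {scen.scenario_id()}"
        (progress or logger.info)(msg)
        fits = run_scenario(
            scen, season, master_seed=master_seed, n1=n1,
            sigma_annual=sigma_annual, dataset_cache=cache,
        )
        all_fits.append(fits_to_frame(scen, fits, master_seed))
        summary = evaluate_scenario(fits, scen.trend_pct, scen.scenario_id())
        summaries.append(summary.as_dict())

    fits_df = pd.concat(all_fits, ignore_index=True)
    summaries_df = pd.DataFrame(summaries)
    paths = {
        "fits": outdir / "fits.csv",
        "summaries": outdir / "summaries.csv",
    }
    fits_df.to_csv(paths["fits"], index=False)
    summaries_df.to_csv(paths["summaries"], index=False)

    for design in _DESIGNS:
        try:
            meta = bias_meta_regression(fits_df, design)
        except ValueError:
            continue
        path = outdir / f"meta_{design}.csv"
        meta.table.to_csv(path, index=False)
        paths[f"meta_{design}"] = path
    return paths
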