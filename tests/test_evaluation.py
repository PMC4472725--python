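"""Evaluation definitions, meta-regression oracle, and experiment plumbing."""

import numpy as np
import pandas as pd
import pytest

import migtrend as mt
from migtrend.evaluation import (
    bias_meta_regression,
    evaluate_scenario,
    run_experiment,
)
from migtrend.trend import TrendFit


def _fake_fit(trend_pct, lo, hi, converged=True):
    import math

    def inv(p):
        return math.log(1 + p / 100.0)

    return TrendFit(
        beta1=inv(trend_pct), beta1_interval=(inv(lo), inv(hi)), trend_pct=trend_pct,
        trend_interval_pct=(lo, hi), beta2=0.0, beta3=0.0, covariate_coef=None,
        dispersion=1.0, sigma_year=0.1, sigma_day=0.1, ar1_rho=0.0,
        converged=converged, n_obs=10, n_years=5, marginal_loglik=0.0,
    )


class TestEvaluateScenario:
    def test_all_covering_intervals_containing_zero(self):
        fits = [_fake_fit(0.1, -1.0, 1.0) for _ in range(3)]
        s = evaluate_scenario(fits, simulated_trend_pct=0.5)
        assert s.coverage == 1.0 and s.power == 0.0 and s.error == 0.0

    def test_power_counts_covered_interval_excluding_zero(self):
        s = evaluate_scenario([_fake_fit(1.0, 0.5, 1.5)], 1.0)
        assert s.coverage == 1.0 and s.power == 1.0 and s.error == 0.0

    def test_error_counts_miss_with_interval_excluding_zero(self):
        s = evaluate_scenario([_fake_fit(1.0, 0.5, 1.5)], 0.0)
        assert s.coverage == 0.0 and s.power == 0.0 and s.error == 1.0

    def test_nonconverged_fits_are_excluded_and_counted(self):
        fits = [_fake_fit(0.0, -1.0, 1.0), _fake_fit(0.0, -1.0, 1.0, converged=False)]
        s = evaluate_scenario(fits, 0.0)
        assert s.n_fits == 1 and s.n_excluded == 1

    def test_no_converged_fits_raises(self):
        with pytest.raises(ValueError):
            evaluate_scenario([_fake_fit(0.0, -1.0, 1.0, converged=False)], 0.0)

    def test_invariant_power_plus_error_bounded_by_exclusion_rate(self):
        rng = np.random.default_rng(0)
        fits = [
            _fake_fit(t, t - rng.uniform(0.1, 2), t + rng.uniform(0.1, 2))
            for t in rng.normal(0, 1, 40)
        ]
        s = evaluate_scenario(fits, 0.4)
        excl = np.mean([f.interval_excludes_zero for f in fits])
        assert s.power <= s.coverage
        assert s.error <= 1 - s.coverage
        assert s.power + s.error <= excl + 1e-12


def _synthetic_results(bias_fn):
    rows = []
    for trend in (-1.2, 0.0, 0.96):
        for pattern in ("random", "cyclic", "linear"):
            for lo, hi in mt.PHI_RANGES:
                for rep in range(4):
                    rows.append(
                        {
                            "trend_pct": trend, "pattern": pattern,
                            "phi_lo": lo, "phi_hi": hi,
                            "phi_range": f"{pattern}[{lo}-{hi}]",
                            "covariate": False, "subsample": "none",
                            "bias_pct": bias_fn(trend, pattern, lo, hi),
                            "converged": True,
                        }
                    )
    return pd.DataFrame(rows)


class TestMetaRegression:
    def test_zero_bias_gives_zero_estimates(self):
        res = _synthetic_results(lambda *a: 0.0)
        tab = bias_meta_regression(res, "varying").table
        assert np.allclose(tab["estimate"], 0.0, atol=1e-12)

    def test_constructed_linear_effect_recovered_exactly(self):
        res = _synthetic_results(lambda t, pat, lo, hi: 0.05 if pat == "linear" else 0.0)
        meta = bias_meta_regression(res, "varying")
        lin = meta.term("C(pattern, Treatment('random'))[T.linear]")
        assert lin["estimate"] == pytest.approx(0.05, abs=1e-10)
        others = meta.table[~meta.table["term"].str.contains("linear")]
        assert np.allclose(others["estimate"], 0.0, atol=1e-10)

    def test_missing_levels_raise(self):
        res = _synthetic_results(lambda *a: 0.0)
        res = res[res["pattern"] == "random"]
        with pytest.raises(ValueError, match="single level"):
            bias_meta_regression(res, "varying")

    def test_unknown_design_rejected(self):
        with pytest.raises(ValueError):
            bias_meta_regression(_synthetic_results(lambda *a: 0.0), "bespoke")


TINY_CONFIG = {
    "trends_pct": [0.0, -1.2],
    "constant_levels": [0.0, 0.5],
    "patterns": [],
    "n_replicates": 2,
    "nyears": 6,
    "n1": 400,
    "sigma_annual": 0.3,
    "master_seed": 3,
}


@pytest.fixture(scope="module")
def outputs(tmp_path_factory):
    out = tmp_path_factory.mktemp("exp")
    season = mt.SeasonConfig(ndays=20, peak_day=10.0, spread=4.0)
    return run_experiment(TINY_CONFIG, out, season=season)


class TestRunExperiment:
    def test_bookkeeping_row_counts(self, outputs):
        fits = pd.read_csv(outputs["fits"])
        summaries = pd.read_csv(outputs["summaries"])
        assert len(fits) == 4 * 2  # scenarios x replicates
        assert len(summaries) == 4
        assert set(summaries.columns) >= {"coverage", "power", "error", "mean_bias"}

    def test_deterministic_given_seed(self, outputs, tmp_path):
        season = mt.SeasonConfig(ndays=20, peak_day=10.0, spread=4.0)
        paths2 = run_experiment(TINY_CONFIG, tmp_path, season=season)
        assert paths2["fits"].read_bytes() == outputs["fits"].read_bytes()
        assert paths2["summaries"].read_bytes() == outputs["summaries"].read_bytes()

    def test_meta_regression_written_for_constant_design(self, outputs):
        assert "meta_constant" in outputs
        tab = pd.read_csv(outputs["meta_constant"])
        assert {"term", "estimate", "se", "t", "p"} <= set(tab.columns)
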