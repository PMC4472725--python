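"""Individual-based simulator: closed-form oracles and truth consistency."""

import numpy as np
import pytest

import migtrend as mt
from migtrend.simulator import (
    SeasonConfig,
    simulate_annual_totals,
    simulate_arrival_probabilities,
    simulate_season,
)


class TestAnnualModel:
    def test_zero_trend_zero_noise_mean(self, rng):
        means = [
            np.mean(simulate_annual_totals(1000, 0.0, 0.0, 20, rng).totals)
            for _ in range(200)
        ]
        # Poisson(1000) each year: SE of the grand mean ~ sqrt(1000/4000)
        assert np.mean(means) == pytest.approx(1000.0, abs=3 * 0.5)

    @pytest.mark.parametrize("beta", [-0.012, 0.0096])
    def test_geometric_decay_growth_closed_form(self, beta, rng):
        last = [
            simulate_annual_totals(1000, beta, 0.0, 20, rng).totals[-1]
            for _ in range(400)
        ]
        expected = 1000 * (1 + beta) ** 19
        se = np.sqrt(expected / 400)
        assert np.mean(last) == pytest.approx(expected, abs=3 * se)

    def test_lognormal_noise_expectation(self, rng):
        # E[n_i] = n1 (1+beta)^(i-1) exp(sigma^2/2) under lognormal year noise
        sigma = 0.5
        vals = np.array(
            [simulate_annual_totals(1000, 0.0, sigma, 2, rng).totals[1] for _ in range(4000)],
            dtype=float,
        )
        expected = 1000 * np.exp(sigma**2 / 2)
        assert vals.mean() == pytest.approx(expected, rel=0.05)

    def test_realized_recursion_switch(self):
        rng = np.random.default_rng(3)
        ser = simulate_annual_totals(500, 0.1, 0.0, 5, rng, recursion="realized")
        assert len(ser.totals) == 5 and all(t >= 0 for t in ser.totals)

    def test_invalid_inputs_raise(self, rng):
        with pytest.raises(ValueError):
            simulate_annual_totals(0, 0.0, 0.1, 5, rng)
        with pytest.raises(ValueError):
            simulate_annual_totals(10, -1.5, 0.1, 5, rng)
        with pytest.raises(ValueError):
            simulate_annual_totals(10, 0.0, 0.1, 5, rng, recursion="sideways")


class TestArrivalProbabilities:
    def test_normalization(self, rng):
        b = simulate_arrival_probabilities(1000, SeasonConfig(), rng)
        assert b.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(b >= 0)

    def test_deterministic_season_peaks_at_peak_day(self, rng):
        season = SeasonConfig(noise_sd=0.0, autocorr=0.0)
        b = simulate_arrival_probabilities(1000, season, rng)
        assert int(np.argmax(b)) + 1 == season.peak_day

    def test_mean_arrival_day_near_peak(self, rng):
        season = SeasonConfig()
        days = np.arange(1, season.ndays + 1)
        means = [
            float((simulate_arrival_probabilities(1000, season, rng) * days).sum())
            for _ in range(200)
        ]
        assert np.mean(means) == pytest.approx(season.peak_day, abs=2.0)


class TestSeasonProcess:
    def test_phi_zero_perfect_detection_counts_all_once(self, rng):
        nd = 30
        b = np.full(nd, 1.0 / nd)
        counts, truth = simulate_season(500, b, 0.0, 1.0, nd, rng)
        assert counts.sum() == 500
        assert np.all(truth["last_day"] == truth["arrival_day"])
        assert len(truth["det_day"]) == 500

    def test_detection_rate_binomial_expectation(self, rng):
        nd = 30
        b = np.full(nd, 1.0 / nd)
        counts, _ = simulate_season(10000, b, 0.0, 0.3, nd, rng)
        sd = np.sqrt(10000 * 0.3 * 0.7)
        assert counts.sum() == pytest.approx(3000, abs=3 * sd)

    @pytest.mark.parametrize("phi", [0.2, 0.5, 0.7])
    def test_mean_stay_matches_geometric_oracle(self, phi, rng):
        # early arrivals + long season => truncation negligible; mean stay 1/(1-phi)
        nd = 120
        b = np.zeros(nd)
        b[:10] = 0.1
        stays = []
        for _ in range(20):
            _, truth = simulate_season(2000, b, phi, 0.3, nd, rng)
            stays.append(np.mean(truth["last_day"] - truth["arrival_day"] + 1))
        expected = 1.0 / (1.0 - phi)
        sd_stay = np.sqrt(phi) / (1 - phi)  # geometric SD
        se = sd_stay / np.sqrt(20 * 2000)
        assert np.mean(stays) == pytest.approx(expected, abs=max(4 * se, 0.01))

    def test_detections_per_individual_oracle(self, rng):
        # E[detections] = p * E[stay]; phi = 0.5, p = 0.3, negligible truncation
        nd = 120
        b = np.zeros(nd)
        b[:10] = 0.1
        dets = []
        for _ in range(20):
            _, truth = simulate_season(2000, b, 0.5, 0.3, nd, rng)
            dets.append(len(truth["det_day"]) / 2000)
        assert np.mean(dets) == pytest.approx(0.3 * 2.0, rel=0.03)


class TestDatasets:
    def test_truth_consistency_exact(self):
        for pattern, lo, hi in [("constant", 0.5, 0.5), ("linear", 0.2, 0.7)]:
            scen = mt.ScenarioSpec(trend_pct=-1.2, phi=mt.make_phi_schedule(pattern, lo, hi, 20))
            ds = mt.simulate_dataset(scen, seed=99)
            assert (ds.recount() == ds.counts).all()

    def test_arrivals_sum_to_annual_totals(self, null_dataset):
        per_year = null_dataset.individuals.groupby("year").size()
        assert (per_year.to_numpy() == null_dataset.annual.as_array()).all()

    def test_same_seed_identical_dataset(self):
        scen = mt.ScenarioSpec(trend_pct=0.0, phi=mt.make_phi_schedule("constant", 0.2, 0.2, 20))
        a = mt.simulate_dataset(scen, seed=7)
        b = mt.simulate_dataset(scen, seed=7)
        c = mt.simulate_dataset(scen, seed=8)
        assert (a.counts == b.counts).all()
        assert a.individuals.equals(b.individuals)
        assert not (a.counts == c.counts).all()

    def test_phi_zero_stopover_is_one_day(self):
        scen = mt.ScenarioSpec(trend_pct=0.0, phi=mt.make_phi_schedule("constant", 0.0, 0.0, 20))
        ds = mt.simulate_dataset(scen, seed=5)
        assert mt.mean_stopover_duration(ds, 1) == 1.0
        # single-day presence: mean detections per individual = p
        mean_det = ds.individuals["n_detections"].mean()
        n = len(ds.individuals)
        assert mean_det == pytest.approx(0.3, abs=4 * np.sqrt(0.3 * 0.7 / n))

    def test_detections_per_individual_increase_under_linear_phi(self):
        scen = mt.ScenarioSpec(trend_pct=0.0, phi=mt.make_phi_schedule("linear", 0.2, 0.7, 20))
        ds = mt.simulate_dataset(scen, seed=13)
        det = ds.individuals.groupby("year")["n_detections"].mean()
        assert det.loc[20] > det.loc[1]
        assert mt.mean_stopover_duration(ds, 20) > mt.mean_stopover_duration(ds, 1)

    def test_summary_properties_commonly_detected(self, null_dataset):
        s = mt.summarize_dataset(null_dataset)
        assert s["prop_zero_days"] < 0.25
        assert s["season_length"] == 60.0
        assert s["mean_annual_count"] > 0

    def test_mean_stopover_errors(self, null_dataset):
        with pytest.raises(ValueError):
            mt.mean_stopover_duration(null_dataset, 0)
        with pytest.raises(ValueError):
            mt.mean_stopover_duration(null_dataset, 21)

    def test_individual_history_view(self):
        scen = mt.ScenarioSpec(
            trend_pct=0.0, phi=mt.make_phi_schedule("constant", 0.5, 0.5, 3), nyears=3
        )
        ds = mt.simulate_dataset(scen, seed=2, n1=30, sigma_annual=0.0)
        hists = list(ds.iter_histories())
        assert len(hists) == len(ds.individuals)
        for h in hists[:50]:
            assert h.arrival_day <= h.last_day <= ds.ndays
            assert all(h.arrival_day <= d <= h.last_day for d in h.detection_days)
            assert h.stopover_duration >= 1

    def test_counts_csv_roundtrip(self, tmp_path, null_dataset):
        path = tmp_path / "counts.csv"
        mt.write_counts_csv([null_dataset], path)
        df = mt.read_counts_csv(path)
        assert len(df) == null_dataset.nyears * null_dataset.ndays
        wide = df.pivot_table(index="year", columns="day", values="count").to_numpy()
        assert (wide == null_dataset.counts).all()
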