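import numpy as np
import pandas as pd
import pytest
from scipy import stats

import deepcompete as dc
from deepcompete.simulate import NoHarvestError

from conftest import fit_rates


def ztp_multi_fraction_oracle(lam: float) -> float:
    """Independent closed form: 1 - lam e^-lam / (1 - e^-lam)."""
    return 1.0 - lam * np.exp(-lam) / (1.0 - np.exp(-lam))


class TestTransformation:
    def test_multi_plasmid_fraction_matches_ztp_tail(self):
        lam, n = 0.5, 100_000
        cfg = dc.AssayConfig(lambda_plasmids=lam, n_founders=n, seed=2)
        pool = dc.simulate_transformation(np.array([0.5, 0.5]), cfg)
        expected = ztp_multi_fraction_oracle(lam)  # 0.22925 at lam=0.5
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(pool.multi_plasmid_fraction() - expected) < 3 * se

    def test_multi_fraction_monotone_in_lambda(self):
        fracs = []
        for lam in (0.25, 1.0):
            cfg = dc.AssayConfig(lambda_plasmids=lam, n_founders=50_000, seed=3)
            pool = dc.simulate_transformation(np.array([1.0]), cfg)
            fracs.append(pool.multi_plasmid_fraction())
        assert fracs[1] > fracs[0]

    def test_single_plasmid_limit(self):
        cfg = dc.AssayConfig(force_single_plasmid=True, n_founders=1000, seed=0)
        pool = dc.simulate_transformation(np.array([0.3, 0.7]), cfg)
        assert pool.multi_plasmid_fraction() == 0.0

    def test_founders_start_at_unit_abundance(self):
        cfg = dc.AssayConfig(n_founders=100, seed=0)
        pool = dc.simulate_transformation(np.array([1.0]), cfg)
        assert np.all(pool.abundance == 1.0)
        assert pool[0].abundance == 1.0

    def test_deterministic_given_seed(self):
        cfg = dc.AssayConfig(lambda_plasmids=2.0, n_founders=500, seed=9)
        a = dc.simulate_transformation(np.array([0.5, 0.5]), cfg)
        b = dc.simulate_transformation(np.array([0.5, 0.5]), cfg)
        assert np.array_equal(a.plasmid_idx, b.plasmid_idx)

    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(ValueError):
            dc.simulate_transformation(np.array([0.5, 0.6]), dc.AssayConfig())


class TestCloneGrowthRate:
    def test_max_of_two(self):
        clone = dc.FounderClone({"a": 1, "b": 1})
        assert dc.clone_growth_rate(clone, {"a": 0.05, "b": 0.20}) == 0.20

    def test_single_plasmid_identity(self):
        assert dc.clone_growth_rate(dc.FounderClone({"a": 1}), {"a": 0.13}) == 0.13

    def test_order_invariance(self):
        rates = {"a": 0.1, "b": 0.2, "c": 0.15}
        c1 = dc.FounderClone({"a": 1, "b": 1, "c": 1})
        c2 = dc.FounderClone({"c": 1, "b": 1, "a": 1})
        assert dc.clone_growth_rate(c1, rates) == dc.clone_growth_rate(c2, rates)

    def test_empty_clone_rejected(self):
        with pytest.raises(ValueError):
            dc.FounderClone({})

    def test_missing_rate_raises(self):
        with pytest.raises(KeyError):
            dc.clone_growth_rate(dc.FounderClone({"a": 1}), {})

    def test_multi_penalty_only_hits_multi_clones(self):
        rates = {"a": 0.2, "b": 0.1}
        single = dc.FounderClone({"a": 1})
        double = dc.FounderClone({"a": 1, "b": 1})
        assert dc.clone_growth_rate(single, rates, multi_penalty=0.9) == 0.2
        assert dc.clone_growth_rate(double, rates, multi_penalty=0.9) == pytest.approx(0.18)


def brute_force_harvest_time(a, r, cfg, lo, hi):
    """Two-stage grid-search oracle for the harvest time."""
    target = 2.0**cfg.g_target * np.sum(a)

    def f(T):
        return np.sum(a * 2.0 ** (cfg.r_lag * cfg.t_lag + r * (T - cfg.t_lag)))

    for _ in range(4):
        grid = np.linspace(lo, hi, 1001)
        vals = np.array([f(T) for T in grid])
        i = int(np.argmin(np.abs(vals - target)))
        lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    return grid[i]


class TestHarvestTime:
    def test_single_clone_closed_form(self):
        cfg = dc.AssayConfig(t_lag=0.0, g_target=5.0)
        T = dc.solve_harvest_time(np.array([1.0]), np.array([0.2]), cfg)
        assert T == pytest.approx(5.0 / 0.2, abs=1e-9)

    def test_two_clone_mixture_matches_grid_search(self):
        cfg = dc.AssayConfig(t_lag=0.0, g_target=5.0)
        a = np.array([0.5, 0.5])
        r = np.array([0.1, 0.2])
        T = dc.solve_harvest_time(a, r, cfg)
        T_grid = brute_force_harvest_time(a, r, cfg, 0.0, 60.0)
        assert T == pytest.approx(T_grid, abs=1e-6)
        # and the defining equation holds
        assert np.sum(a * 2 ** (r * T)) == pytest.approx(2**5, abs=1e-8)

    def test_monotone_in_generations(self):
        a = np.array([1.0, 2.0])
        r = np.array([0.05, 0.2])
        times = [
            dc.solve_harvest_time(a, r, dc.AssayConfig(t_lag=2.5, g_target=G))
            for G in (2.0, 3.0, 5.0)
        ]
        assert times[0] < times[1] < times[2]

    def test_harvest_inside_lag(self):
        cfg = dc.AssayConfig(t_lag=10.0, r_lag=0.3, g_target=2.0)  # 3.0 lag doublings > 2
        T = dc.solve_harvest_time(np.array([1.0]), np.array([0.01]), cfg)
        assert T == pytest.approx(2.0 / 0.3)

    def test_no_solution_when_rates_all_zero(self):
        cfg = dc.AssayConfig(t_lag=1.0, r_lag=0.1, g_target=5.0)
        with pytest.raises(NoHarvestError):
            dc.solve_harvest_time(np.array([1.0]), np.array([0.0]), cfg)


class TestCompetition:
    def test_single_clone_exponential(self):
        cfg = dc.AssayConfig(t_lag=0.0, g_target=4.0)
        out, T = dc.simulate_competition(np.array([2.0]), np.array([0.25]), cfg)
        assert out[0] / 2.0 == pytest.approx(2 ** (0.25 * T), rel=1e-12)

    def test_population_total_hits_target_generations(self):
        cfg = dc.AssayConfig(t_lag=2.5, r_lag=0.23, g_target=5.0)
        a = np.array([1.0, 3.0, 0.5])
        r = np.array([0.02, 0.1, 0.23])
        out, _ = dc.simulate_competition(a, r, cfg)
        assert out.sum() / a.sum() == pytest.approx(2.0**5, abs=1e-9)

    def test_degenerate_all_lag(self):
        # harvest falls inside the lag: every clone grows identically
        cfg = dc.AssayConfig(t_lag=50.0, r_lag=0.2, g_target=3.0)
        a = np.array([1.0, 2.0])
        out, T = dc.simulate_competition(a, np.array([0.01, 0.2]), cfg)
        assert np.allclose(out / a, out[0] / a[0])
        assert T == pytest.approx(3.0 / 0.2)


class TestSampleReads:
    def test_expected_mode_proportional(self):
        counts = dc.sample_reads(np.array([3.0, 1.0]), 1000, "expected")
        assert np.allclose(counts, [750.0, 250.0])

    def test_stochastic_counts_sum_to_depth(self):
        rng = np.random.default_rng(0)
        counts = dc.sample_reads(np.array([1.0, 2.0, 3.0]), 5000, "stochastic", rng)
        assert counts.sum() == 5000

    def test_stochastic_mean_matches_expectation(self):
        w = np.array([5.0, 3.0, 2.0])
        depth = 1000
        expected = dc.sample_reads(w, depth, "expected")
        draws = np.array(
            [
                dc.sample_reads(w, depth, "stochastic", np.random.default_rng(s))
                for s in range(1000)
            ]
        )
        p = w / w.sum()
        se = np.sqrt(depth * p * (1 - p) / len(draws))
        assert np.all(np.abs(draws.mean(axis=0) - expected) < 3 * se)

    def test_zero_total_weight_rejected(self):
        with pytest.raises(ValueError):
            dc.sample_reads(np.array([0.0, 0.0]), 100, "expected")


class TestAssayInvariants:
    def test_exact_recovery_in_ideal_regime(self, ideal_assay):
        ghat = fit_rates(ideal_assay)
        assert np.max(np.abs(ghat.values - ideal_assay.truth["true_rate"].values)) < 1e-9

    @pytest.mark.parametrize("lam,t_lag,protocol", [
        (0.05, 0.0, "standard"),
        (0.5, 2.5, "standard"),
        (2.0, 2.5, "pre_incubation"),
    ])
    def test_frequency_conservation_identity(self, balanced_truth, lam, t_lag, protocol):
        """sum_v freqIn_v 2^(ghat_v T) = ODout/ODin on every expected-value run."""
        cfg = dc.AssayConfig(
            lambda_plasmids=lam, n_founders=50_000, mode="expected",
            t_lag=t_lag, protocol=protocol, seed=4,
        )
        assay = dc.simulate_assay(balanced_truth, cfg)
        ghat = fit_rates(assay)
        freq_in = dc.compute_frequencies(assay.counts)["input_rep1"].reindex(ghat.index)
        T = assay.elapsed[1]
        lhs = np.sum(freq_in.values * 2.0 ** (ghat.values * T))
        assert lhs == pytest.approx(cfg.effective_od_out / cfg.od_in, abs=1e-9)

    def test_lag_bias_closed_form(self, balanced_truth):
        cfg = dc.AssayConfig(
            force_single_plasmid=True, mode="expected", t_lag=2.5, r_lag=0.23, seed=1
        )
        assay = dc.simulate_assay(balanced_truth, cfg)
        ghat = fit_rates(assay).values
        T = assay.elapsed[1]
        g = balanced_truth["true_rate"].values
        predicted = (0.23 * 2.5 + g * (T - 2.5)) / T
        assert np.max(np.abs(ghat - predicted)) < 1e-9

    def test_pre_incubation_removes_lag_bias(self, balanced_truth):
        cfg = dc.AssayConfig(
            force_single_plasmid=True, mode="expected", t_lag=2.5, r_lag=0.23,
            protocol="pre_incubation", seed=1,
        )
        ghat = fit_rates(dc.simulate_assay(balanced_truth, cfg)).values
        assert np.max(np.abs(ghat - balanced_truth["true_rate"].values)) < 1e-9

    def test_expected_counts_sum_to_depth(self, ideal_assay):
        sums = ideal_assay.counts.sum(axis=0)
        assert np.allclose(sums["input_rep1"], ideal_assay.config.depth_in, atol=1e-6)
        assert np.allclose(sums["output_rep1"], ideal_assay.config.depth_out, atol=1e-6)

    def test_stochastic_counts_sum_to_depth(self, balanced_truth):
        cfg = dc.AssayConfig(n_founders=10_000, depth_in=5000, depth_out=7000, seed=5)
        assay = dc.simulate_assay(balanced_truth, cfg)
        assert assay.counts["input_rep1"].sum() == 5000
        assert assay.counts["output_rep1"].sum() == 7000

    def test_replicates_differ_but_run_is_reproducible(self, balanced_truth):
        cfg = dc.AssayConfig(n_founders=5000, n_replicates=2, seed=6,
                             depth_in=10_000, depth_out=10_000)
        a = dc.simulate_assay(balanced_truth, cfg)
        b = dc.simulate_assay(balanced_truth, cfg)
        assert a.counts.equals(b.counts)
        assert not a.counts["output_rep1"].equals(a.counts["output_rep2"])

    def test_cotransformation_compresses_rates(self, balanced_truth):
        """Fig. 2-direction property at reduced founder count."""
        iqrs, medians = [], []
        g = balanced_truth["true_rate"]
        bottom = (g <= g.quantile(0.25)).values
        for lam in (0.05, 0.5, 2.0, 10.0):
            cfg = dc.AssayConfig(lambda_plasmids=lam, n_founders=60_000,
                                 mode="expected", t_lag=0.0, seed=7)
            ghat = fit_rates(dc.simulate_assay(balanced_truth, cfg))
            iqrs.append(dc.distribution_summary(ghat)["iqr"])
            medians.append(float(ghat[bottom].median()))
        assert all(a > b for a, b in zip(iqrs, iqrs[1:]))
        assert all(a < b for a, b in zip(medians, medians[1:]))

    def test_plasmid_loss_knob_reduces_multiplicity_effect(self, balanced_truth):
        g = balanced_truth["true_rate"]
        bottom = (g <= g.quantile(0.25)).values
        meds = []
        for loss in (0.0, 0.5):
            cfg = dc.AssayConfig(lambda_plasmids=2.0, n_founders=40_000, mode="expected",
                                 t_lag=0.0, loss_rate=loss, seed=8)
            ghat = fit_rates(dc.simulate_assay(balanced_truth, cfg))
            meds.append(float(ghat[bottom].median()))
        assert meds[1] < meds[0]  # losing extra plasmids weakens the upward bias


class TestPlatingSimulation:
    def test_forced_doubles_recover_25_50_25(self):
        n = 200_000
        plates = dc.simulate_double_transformant_plating(
            lam=0.2, n_cells=n, plating_fractions=1.0, seed=1, force_multiplicity=2
        )
        counts = plates.set_index("plate_class")["colonies"]
        # m=2: P(>=1 ura) = 3/4, P(both) = 1/2
        assert counts["sel_A"] / n == pytest.approx(0.75, abs=0.005)
        assert counts["sel_B"] / n == pytest.approx(0.75, abs=0.005)
        assert counts["sel_AB"] / n == pytest.approx(0.50, abs=0.005)
        # Eq. 1 then reports 100% doubles
        pct = dc.percent_double_posttransform(counts["sel_A"], counts["sel_B"], counts["sel_AB"])
        assert pct == pytest.approx(100.0, abs=1.0)

    def test_small_lambda_has_no_double_colonies(self):
        plates = dc.simulate_double_transformant_plating(
            lam=1e-4, n_cells=20_000, plating_fractions=1.0, seed=2
        )
        counts = plates.set_index("plate_class")["colonies"]
        assert counts["sel_AB"] <= 2

    def test_estimator_matches_exact_ztp_expectation(self):
        """The printed estimator converges to its exact ZTP expectation
        (computed here independently from the Poisson pmf), which exceeds
        the true >= 2-plasmid fraction by the m >= 3 over-count."""
        lam, n = 0.2, 1_000_000
        plates = dc.simulate_double_transformant_plating(lam, n, 1.0, seed=3)
        c = plates.set_index("plate_class")["colonies"]
        est = dc.percent_double_posttransform(c["sel_A"], c["sel_B"], c["sel_AB"]) / 100.0
        m = np.arange(1, 100)
        pmf = stats.poisson.pmf(m, lam) / (1 - np.exp(-lam))
        exact = float(np.sum(pmf * 2 * (1 - 2.0 ** (1 - m))))
        se = np.sqrt(exact * (1 - exact) / n)
        assert abs(est - exact) < 3 * se
        # the package reports the same expectation and a positive m>=3 bias
        assert dc.eq1_expectation(lam) == pytest.approx(exact, abs=1e-12)
        assert exact > ztp_multi_fraction_oracle(lam)

    def test_plating_fraction_thins_counts(self):
        full = dc.simulate_double_transformant_plating(0.5, 50_000, 1.0, seed=4)
        thinned = dc.simulate_double_transformant_plating(
            0.5, 50_000, {"sel_A": [0.1], "sel_B": [0.1], "sel_AB": [0.1]}, seed=4
        )
        f = full.set_index("plate_class")["colonies"]
        t = thinned.set_index("plate_class")["colonies"]
        for cls in ("sel_A", "sel_B", "sel_AB"):
            assert t[cls] == pytest.approx(0.1 * f[cls], rel=0.15)

    def test_invalid_plating_fraction_rejected(self):
        with pytest.raises(ValueError):
            dc.simulate_double_transformant_plating(0.2, 100, {"sel_A": [1.5]}, seed=0)
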