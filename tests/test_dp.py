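"""Laplace mechanism, sensitivity bounds, composition and enforcement."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from covleak import (
    BudgetExhausted,
    DisclosurePolicy,
    Federation,
    FederationSpec,
    InvalidParameter,
    NoisePolicy,
    PrivacyAccountant,
    ProbeMatrix,
    SensitivityModel,
    ServerDataset,
    allowed_iterations,
    attack_budget,
    epsilon_for_query,
    generate_federation,
    generate_probes,
    reconstruct_variable,
    run_dp_attack_experiment,
    run_standard_analysis_budget,
)
from covleak.dp import LN3, attack_iteration_cost


class TestPrimitives:
    def test_epsilon_is_sensitivity_over_scale(self):
        assert epsilon_for_query(1.0, 1.0) == 1.0
        assert epsilon_for_query(0.5, 5.0) == pytest.approx(0.1)
        with pytest.raises(InvalidParameter):
            epsilon_for_query(0.0, 1.0)
        with pytest.raises(InvalidParameter):
            epsilon_for_query(1.0, -1.0)

    def test_attack_budget_composition(self):
        assert attack_budget(0, [], 0.0) == 0.0
        assert attack_budget(3, [0.1, 0.1, 0.1], 0.05) == pytest.approx(0.35)
        with pytest.raises(InvalidParameter):
            attack_budget(2, [0.1], 0.0)

    def test_allowed_iterations(self):
        assert allowed_iterations(LN3, LN3) == 1
        assert allowed_iterations(LN3, 2 * LN3) == 0
        assert allowed_iterations(1.0, 0.1) == 10
        with pytest.raises(InvalidParameter):
            allowed_iterations(1.0, 0.0)


class TestLaplaceMechanism:
    def test_noise_variance_matches_scale(self):
        """Laplace noise at scale b has variance 2 b^2."""
        b = 1.7
        policy = NoisePolicy.laplace_from_scales(b, b)
        rng = np.random.default_rng(0)
        draws = np.array([policy.draw(rng, policy.cov_noise_sd) for _ in range(10**5)])
        assert np.var(draws) == pytest.approx(2 * b**2, rel=0.05)

    def test_noise_distribution_is_laplace(self):
        """Kolmogorov-Smirnov at alpha = 0.01 against Laplace(0, b)."""
        b = 0.8
        policy = NoisePolicy.laplace_from_scales(b, b)
        rng = np.random.default_rng(1)
        draws = np.array([policy.draw(rng, policy.mean_noise_sd) for _ in range(10**5)])
        _, p = stats.kstest(draws, "laplace", args=(0.0, b))
        assert p > 0.01


def _replace_one(x, y, s, u, v):
    x2, y2 = x.copy(), y.copy()
    x2[s], y2[s] = u, v
    return x2, y2


def _cov(a, b):
    return float(np.cov(a, b, ddof=1)[0, 1])


class TestSensitivities:
    """Brute-force cross-validation of the worst-case formulas."""

    def test_mean_sensitivity(self):
        assert SensitivityModel().mean(10, (0.0, 2.0)) == pytest.approx(0.2)

    @pytest.mark.parametrize("n", [3, 8, 25])
    def test_cov_with_public_probe_bound_is_tight(self, n):
        rng = np.random.default_rng(n)
        bounds = (15.0, 50.0)
        probe = rng.standard_normal(n)
        delta = SensitivityModel().cov_with_public(n, bounds, probe)
        worst = 0.0
        for _ in range(500):
            x = rng.uniform(*bounds, n)
            s = rng.integers(n)
            u = rng.uniform(*bounds)
            x2 = x.copy()
            x2[s] = u
            worst = max(worst, abs(_cov(x2, probe) - _cov(x, probe)))
        assert worst <= delta * (1 + 1e-9)
        # the bound is attained: move the record at the most extreme probe
        # position across the full clip width
        s_star = np.argmax(np.abs(probe - probe.mean()))
        x = np.full(n, bounds[0])
        x2 = x.copy()
        x2[s_star] = bounds[1]
        assert abs(_cov(x2, probe) - _cov(x, probe)) == pytest.approx(delta, rel=1e-9)

    @pytest.mark.parametrize("n", [3, 8, 25])
    def test_cov_of_two_data_columns_bound(self, n):
        rng = np.random.default_rng(100 + n)
        bx, by = (15.0, 50.0), (0.0, 1.0)
        delta = SensitivityModel().cov(n, bx, by)
        worst = 0.0
        for _ in range(2000):
            x = rng.uniform(*bx, n)
            y = rng.uniform(*by, n)
            s = rng.integers(n)
            x2, y2 = _replace_one(x, y, s, rng.uniform(*bx), rng.uniform(*by))
            worst = max(worst, abs(_cov(x2, y2) - _cov(x, y)))
        assert worst <= delta * (1 + 1e-9)
        # vertex configurations are realisable datasets; the best of them
        # achieves the enumerated bound exactly
        achieved = 0.0
        import itertools

        for xs, u, mx in itertools.product(bx, repeat=3):
            for ys, v, my in itertools.product(by, repeat=3):
                x = np.full(n, mx)
                y = np.full(n, my)
                x[0], y[0] = xs, ys
                x2, y2 = _replace_one(x, y, 0, u, v)
                achieved = max(achieved, abs(_cov(x2, y2) - _cov(x, y)))
        assert achieved == pytest.approx(delta, rel=1e-12)

    @pytest.mark.parametrize("n", [3, 8, 25])
    def test_variance_bound_with_interior_optimum(self, n):
        rng = np.random.default_rng(200 + n)
        bounds = (15.0, 50.0)
        delta = SensitivityModel().var(n, bounds)
        worst = 0.0
        for _ in range(4000):
            x = rng.uniform(*bounds, n)
            s = rng.integers(n)
            x2 = x.copy()
            x2[s] = rng.uniform(*bounds)
            worst = max(worst, abs(_cov(x2, x2) - _cov(x, x)))
        # random search never exceeds the bound
        assert worst <= delta * (1 + 1e-9)
        # the bound is attained by a constructed dataset: all untouched
        # records at one extreme, the replaced record swept over the box
        achieved = 0.0
        a, b = bounds
        for u in (a, b):
            for m in (a, b):
                for xs in np.linspace(a, b, 801):
                    x = np.full(n, m)
                    x[0] = xs
                    x2 = x.copy()
                    x2[0] = u
                    achieved = max(achieved, abs(_cov(x2, x2) - _cov(x, x)))
        assert achieved <= delta * (1 + 1e-9)
        assert achieved == pytest.approx(delta, rel=1e-3)


class TestAccountant:
    def _metered_fed(self, n=10, budget=1e4, scale=1.0):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.uniform(15, 50, n)})
        acc = PrivacyAccountant(budget, {"x": (15.0, 50.0)}, default_bounds=(-5.0, 5.0))
        fed = Federation(
            [ServerDataset("s", df)],
            policy=DisclosurePolicy(enabled=False),
            noise=NoisePolicy.laplace_from_scales(scale, scale, rng_seed=1),
            accountant=acc,
        )
        return fed, acc

    def test_ledger_total_equals_consumed(self):
        fed, acc = self._metered_fed()
        fed.query_mean("s", "x")
        fed.query_cov("s", "x", "x")
        assert acc.consumed == pytest.approx(sum(e.epsilon for e in acc.ledger))
        assert len(acc.ledger) == 2
        assert all(e.epsilon > 0 for e in acc.ledger)

    def test_budget_enforcement_withholds_answer(self):
        fed, acc = self._metered_fed(budget=0.5, scale=1.0)
        with pytest.raises(BudgetExhausted):
            for _ in range(100):
                fed.query_cov("s", "x", "x")
        assert acc.consumed <= 0.5 + 1e-12

    def test_probe_only_queries_are_free(self):
        fed, acc = self._metered_fed()
        fed.broadcast("s", "p", np.random.default_rng(2).standard_normal((10, 2)))
        fed.query_mean("s", "p[0]")
        fed.query_cov("s", "p[0]", "p[1]")
        assert acc.consumed == 0.0

    def test_uniform_attack_budget_matches_ledger(self):
        """With identity probes every covariance has the same sensitivity,
        so the ledger total equals n*eps_cov + eps_mean exactly."""
        for n in (7, 50):
            fed, acc = self._metered_fed(n=n, budget=1e9, scale=2.0)
            probes = ProbeMatrix(np.eye(n))
            reconstruct_variable(fed, "s", "x", probes=probes, score=False)
            model = SensitivityModel()
            eps_cov = epsilon_for_query(
                model.cov_with_public(n, (15.0, 50.0), np.eye(n)[:, 0]), 2.0
            )
            eps_mean = epsilon_for_query(model.mean(n, (15.0, 50.0)), 2.0)
            closed_form = attack_budget(n, [eps_cov] * n, eps_mean)
            assert acc.consumed == pytest.approx(closed_form, rel=1e-12)

    def test_allowed_iterations_matches_simulated_accountant(self):
        """floor(budget / per-iteration cost) equals the number of full
        attack iterations the live accountant actually admits."""
        n = 8
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"x": rng.uniform(15, 50, n)})
        probes = generate_probes(n, seed=6)
        scale = 300.0
        budget = 0.25
        cost = attack_iteration_cost(probes, n, (15.0, 50.0), scale)
        predicted = allowed_iterations(budget, cost)
        acc = PrivacyAccountant(budget, {"x": (15.0, 50.0)})
        fed = Federation(
            [ServerDataset("s", df)],
            policy=DisclosurePolicy(enabled=False),
            noise=NoisePolicy.laplace_from_scales(scale, scale, rng_seed=2),
            accountant=acc,
        )
        fed.broadcast("s", "p", probes.Y)
        admitted = 0
        try:
            for _ in range(predicted + 2):
                reconstruct_variable(
                    fed, "s", "x", probes=probes, probe_name="p", score=False
                )
                admitted += 1
        except BudgetExhausted:
            pass
        assert admitted == predicted >= 1

    def test_invalid_construction(self):
        with pytest.raises(InvalidParameter):
            PrivacyAccountant(0.0, {})
        with pytest.raises(InvalidParameter):
            PrivacyAccountant(1.0, {"x": (2.0, 1.0)})


@pytest.fixture(scope="module")
def dp_fed():
    servers, _ = generate_federation(FederationSpec(n_per_server=(25,), seed=20))
    return Federation(servers)


class TestDpAttackExperiment:
    def test_tradeoff_directions(self, dp_fed):
        results, summary = run_dp_attack_experiment(
            dp_fed,
            budget_grid=(math.log(1.01), math.log(1.1), LN3),
            noise_scales=(400.0, 3200.0, 25600.0),
            replicates=6,
            seed=7,
        )
        # more noise => at least as many admissible iterations (per replicate)
        for (_, _), grp in results.groupby(["budget", "replicate"]):
            R = grp.sort_values("noise_scale")["allowed_R"].to_numpy()
            assert np.all(np.diff(R) >= 0)
        # more budget => at least as many iterations, error not worse
        for (_, _), grp in results.groupby(["noise_scale", "replicate"]):
            g = grp.sort_values("budget")
            assert np.all(np.diff(g["allowed_R"].to_numpy()) >= 0)
        med = summary.pivot(
            index="budget", columns="noise_scale", values="median_relative_mse"
        ).to_numpy()
        # inf-safe elementwise comparison (inf <= inf holds for cells
        # where no budget level affords an iteration)
        assert np.all(med[1:] <= med[:-1] * (1 + 1e-12))

    def test_zero_iteration_cells_have_no_reconstruction(self, dp_fed):
        results, _ = run_dp_attack_experiment(
            dp_fed,
            budget_grid=(math.log(1.01),),
            noise_scales=(50.0,),
            replicates=2,
            seed=8,
        )
        assert (results["allowed_R"] == 0).all()
        assert results["relative_mse"].isna().all()


class TestStandardAnalysisBudget:
    def test_huge_noise_scale_consumes_almost_nothing(self, dp_fed):
        reports = run_standard_analysis_budget(
            dp_fed, ["bmi", "cholesterol_total"], noise_scales=(1e9,)
        )
        for r in reports:
            assert r.completed
            assert r.consumed < 1e-6

    def test_tight_noise_exhausts_budget_on_pairwise_covariances(self, dp_fed):
        """At analysis-grade noise, the covariances among five metric
        variables cannot all be paid for from a ln(3) budget."""
        metric = ["bmi", "cholesterol_total", "triglycerides", "hdl", "glucose"]
        reports = run_standard_analysis_budget(dp_fed, metric, noise_scales=(2.0,))
        pairwise = [r for r in reports if r.scenario == "pairwise_covariances"]
        assert any(not r.completed for r in pairwise)

    def test_cumulative_equals_ledger_and_is_nondecreasing(self, dp_fed):
        reports = run_standard_analysis_budget(
            dp_fed, ["bmi", "glucose"], noise_scales=(100.0,)
        )
        for r in reports:
            cum = r.cumulative
            assert cum[-1] == pytest.approx(r.consumed)
            assert np.all(np.diff(cum) >= 0)
            assert r.consumed_truncated <= LN3 + 1e-12

    def test_requires_two_variables(self, dp_fed):
        with pytest.raises(InvalidParameter):
            run_standard_analysis_budget(dp_fed, ["bmi"], noise_scales=(1.0,))
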