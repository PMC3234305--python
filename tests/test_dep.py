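"""Beta-binomial pmf, ML fitting, the LRT and BH correction."""

import numpy as np
import pytest
from scipy import integrate, stats

from qfish.dep import (
    CountTable,
    bh_adjust,
    betabinom_logpmf,
    fit_betabinom,
    lrt_test,
    run_dep,
    wald_test,
)
from qfish.synth import SimConfig, emit_counts


def _quadrature_logpmf(x, n, pi, phi):
    """Numerical integration of the binomial-beta mixture integral."""
    a = pi * (1 - phi) / phi
    b = (1 - pi) * (1 - phi) / phi

    def integrand(p):
        return stats.binom.pmf(x, n, p) * stats.beta.pdf(p, a, b)

    val, _ = integrate.quad(integrand, 0, 1, limit=400,
                            epsabs=1e-14, epsrel=1e-12)
    return np.log(val)


class TestLogPmf:
    def test_uniform_marginal_when_alpha_beta_one(self):
        """alpha = beta = 1 (pi = 0.5, phi = 1/3) makes every count equally
        likely: pmf = 1/(n+1)."""
        n = 17
        for x in range(n + 1):
            assert betabinom_logpmf(x, n, 0.5, 1.0 / 3.0) == pytest.approx(
                np.log(1.0 / (n + 1)), abs=1e-10
            )

    def test_binomial_limit(self):
        x, n, pi = 7, 40, 0.21
        bb = betabinom_logpmf(x, n, pi, 1e-8)
        binom = stats.binom.logpmf(x, n, pi)
        assert bb == pytest.approx(binom, rel=1e-6)
        assert betabinom_logpmf(x, n, pi, 0.0) == pytest.approx(binom, abs=1e-12)

    def test_matches_quadrature_oracle(self, rng):
        """Random parameter draws agree with numerical integration of the
        defining mixture integral to 1e-8."""
        for _ in range(25):
            n = int(rng.integers(5, 60))
            x = int(rng.integers(0, n + 1))
            pi = float(rng.uniform(0.05, 0.95))
            phi = float(rng.uniform(0.01, 0.6))
            got = betabinom_logpmf(x, n, pi, phi)
            assert got == pytest.approx(
                _quadrature_logpmf(x, n, pi, phi), abs=1e-8
            )

    def test_matches_scipy_parameterization(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 100))
            x = int(rng.integers(0, n + 1))
            pi = float(rng.uniform(0.01, 0.99))
            phi = float(rng.uniform(1e-4, 0.9))
            a = pi * (1 - phi) / phi
            b = (1 - pi) * (1 - phi) / phi
            assert betabinom_logpmf(x, n, pi, phi) == pytest.approx(
                stats.betabinom.logpmf(x, n, a, b), abs=1e-9
            )

    def test_normalizes_to_one(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 80))
            pi = float(rng.uniform(0.02, 0.98))
            phi = float(rng.uniform(0.0, 0.8))
            total = np.exp(
                betabinom_logpmf(np.arange(n + 1), n, pi, phi)
            ).sum()
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_rejects_invalid_arguments(self):
        with pytest.raises(ValueError):
            betabinom_logpmf(5, 3, 0.5, 0.1)
        with pytest.raises(ValueError):
            betabinom_logpmf(1, 3, 0.0, 0.1)
        with pytest.raises(ValueError):
            betabinom_logpmf(1, 3, 0.5, 1.0)

    def test_moment_identities_on_simulation(self, rng):
        """Sample mean and variance of beta-binomial draws match n*pi and
        n*pi*(1-pi)*[1+(n-1)*phi] within Monte-Carlo error."""
        n, pi, phi, B = 400, 0.1, 0.08, 40000
        a = pi * (1 - phi) / phi
        b = (1 - pi) * (1 - phi) / phi
        x = rng.binomial(n, rng.beta(a, b, B))
        assert x.mean() == pytest.approx(n * pi, rel=0.02)
        expected_var = n * pi * (1 - pi) * (1 + (n - 1) * phi)
        assert x.var() == pytest.approx(expected_var, rel=0.05)


class TestFit:
    def test_recovers_proportion_at_large_n(self, rng):
        n = np.full(6, 50000)
        pi_true = 0.04
        x = rng.binomial(n, pi_true)  # phi ~ 0 data
        fit = fit_betabinom(x, n, np.ones((6, 1)))
        assert fit.converged
        assert fit.pi[0] == pytest.approx(x.sum() / n.sum(), abs=1e-3)

    def test_phi_recovery_median_error(self, rng):
        """500 clusters at (pi=0.01, phi=0.05), n=5000, 6 replicates:
        the ML overdispersion lands near the truth in the median."""
        pi, phi = 0.01, 0.05
        a, b = pi * (1 - phi) / phi, (1 - pi) * (1 - phi) / phi
        n = np.full(6, 5000)
        errs = []
        X = np.ones((6, 1))
        for _ in range(500):
            x = rng.binomial(n, rng.beta(a, b, 6))
            if x.sum() == 0:
                continue
            errs.append(abs(fit_betabinom(x, n, X).phi - phi))
        assert np.median(errs) < 0.05

    def test_all_zero_counts_pinned_at_boundary(self):
        n = np.full(6, 1000)
        fit = fit_betabinom(np.zeros(6), n, np.ones((6, 1)))
        assert fit.pi[0] < 1e-4

    def test_alpha_beta_recoverable(self, rng):
        n = np.full(6, 2000)
        x = rng.binomial(n, 0.05)
        fit = fit_betabinom(x, n, np.ones((6, 1)))
        a, b = fit.alpha_beta
        phi = max(fit.phi, 1e-10)
        assert a[0] / (a[0] + b[0]) == pytest.approx(fit.pi[0], rel=1e-6)
        assert 1.0 / (a[0] + b[0] + 1) == pytest.approx(phi, rel=1e-4)


class TestLrt:
    GROUPS = ["A", "A", "A", "B", "B", "B"]

    def test_identical_proportions_give_null_result(self):
        n = np.full(6, 1000)
        x = np.full(6, 50)
        stat, p, *_ = lrt_test(x, n, self.GROUPS)
        assert stat == pytest.approx(0.0, abs=1e-4)
        assert p > 0.95

    def test_invariant_to_group_label_swap(self, rng):
        n = np.full(6, 2000)
        x = np.array([10, 15, 12, 40, 35, 45])
        stat1, p1, _, fit1 = lrt_test(x, n, self.GROUPS)
        swapped = ["B", "B", "B", "A", "A", "A"]
        stat2, p2, _, fit2 = lrt_test(x, n, swapped)
        assert stat1 == pytest.approx(stat2, abs=1e-4)
        assert p1 == pytest.approx(p2, abs=1e-5)

    def test_large_effect_detected(self):
        n = np.full(6, 5000)
        x = np.array([200, 180, 220, 50, 45, 55])
        stat, p, *_ = lrt_test(x, n, self.GROUPS)
        assert p < 1e-6

    def test_phi_fixed_at_zero_reduces_to_binomial_lrt(self, rng):
        """With the overdispersion held at zero the whole test collapses
        to the binomial LRT, computed here in closed form."""
        from scipy.special import xlogy

        n = np.full(6, 20000)
        x = rng.binomial(n, [0.02, 0.02, 0.02, 0.025, 0.025, 0.025])

        def binom_ll(x_, n_, p_):
            return float(np.sum(xlogy(x_, p_) + xlogy(n_ - x_, 1 - p_)))

        g = np.array([0, 0, 0, 1, 1, 1], dtype=bool)
        p0 = x.sum() / n.sum()
        ll0 = binom_ll(x, n, p0)
        ll1 = binom_ll(x[~g], n[~g], x[~g].sum() / n[~g].sum()) + binom_ll(
            x[g], n[g], x[g].sum() / n[g].sum()
        )
        oracle_stat = 2 * (ll1 - ll0)
        stat, _, *_ = lrt_test(x, n, self.GROUPS, fix_phi=0.0)
        assert stat == pytest.approx(oracle_stat, abs=1e-3)

    def test_wald_agrees_in_order_of_magnitude(self, rng):
        n = np.full(6, 5000)
        x = np.array([200, 180, 220, 100, 90, 110])
        lrt_stat, lrt_p, *_ = lrt_test(x, n, self.GROUPS)
        wald_stat, wald_p = wald_test(x, n, self.GROUPS)
        assert wald_p < 0.01 and lrt_p < 0.01

    def test_power_increases_with_odds_ratio(self):
        """Rejection rates rise strictly over odds ratios 1.5, 2, 4.

        The same seed is reused at every effect size (common random
        numbers) so the comparison is paired rather than drowned in
        between-panel Monte-Carlo noise."""
        rates = []
        for odds_ratio in (1.5, 2.0, 4.0):
            cfg = SimConfig(n_templates=120, dep_fraction=1.0,
                            dep_odds_ratio=odds_ratio, seed=300)
            table, _ = emit_counts(cfg)
            ps = [
                lrt_test(table.x[i], table.n, table.groups)[1]
                for i in range(table.n_clusters)
            ]
            rates.append(np.mean(np.asarray(ps) <= 0.05))
        assert rates[0] < rates[1] < rates[2]


class TestBhAdjust:
    def test_step_up_arithmetic(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_matches_independent_step_up_oracle(self, rng):
        """100 random p vectors agree with a from-scratch step-up."""

        def oracle(p):
            p = np.asarray(p)
            m = p.size
            order = np.argsort(p)
            adj = p[order] * m / np.arange(1, m + 1)
            adj = np.minimum.accumulate(adj[::-1])[::-1]
            out = np.empty(m)
            out[order] = np.minimum(adj, 1.0)
            return out

        for _ in range(100):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), oracle(p), atol=1e-12)

    def test_nan_excluded_from_universe(self):
        q = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], bh_adjust([0.01, 0.04]))

    def test_q_at_least_p_and_monotone(self, rng):
        p = np.sort(rng.uniform(0, 1, 30))
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-12)
        assert np.all(np.diff(q) >= -1e-12)


class TestRunDep:
    def test_empty_input_gives_empty_result(self):
        table = CountTable(
            x=np.zeros((0, 2), dtype=int), n=np.array([5, 5]),
            replicate_keys=[("A", "1"), ("B", "1")], groups=["A", "B"],
            cluster_ids=[], occupancy=[],
        )
        assert len(run_dep(table)) == 0

    def test_exclusive_clusters_not_tested(self, rng):
        table, _ = emit_counts(SimConfig(n_templates=10, seed=1), rng)
        table.occupancy[0] = "HCC-only"
        result = run_dep(table)
        assert "C0" not in set(result.cluster_id)
        assert len(result) == 9

    def test_strong_signal_survives_bh(self):
        rng = np.random.default_rng(5)
        cfg = SimConfig(n_templates=40, dep_fraction=0.1,
                        dep_odds_ratio=8.0, phi=0.01, seed=5)
        table, is_dep = emit_counts(cfg, rng)
        result = run_dep(table, alpha=0.05)
        hit = set(result.loc[result.significant, "cluster_id"])
        truth = {f"C{i}" for i in np.flatnonzero(is_dep)}
        assert truth <= hit  # all four strong DEPs found

    def test_direction_labels_follow_fitted_proportions(self):
        rng = np.random.default_rng(6)
        cfg = SimConfig(n_templates=20, dep_fraction=0.2,
                        dep_odds_ratio=6.0, phi=0.01, seed=6)
        table, is_dep = emit_counts(cfg, rng)
        result = run_dep(table).set_index("cluster_id")
        # the generator boosts the first group's odds for true DEPs
        first = sorted(set(table.groups))[0]
        for i in np.flatnonzero(is_dep):
            row = result.loc[f"C{i}"]
            if row.significant:
                assert row.direction == f"up in {first}"


class TestCountTable:
    def test_tsv_round_trip(self, tmp_path, rng):
        table, _ = emit_counts(SimConfig(n_templates=6, seed=2), rng)
        path = tmp_path / "counts.tsv"
        table.to_tsv(path)
        back = CountTable.from_tsv(path)
        np.testing.assert_array_equal(back.x, table.x)
        np.testing.assert_array_equal(back.n, table.n)
        assert back.replicate_keys == table.replicate_keys
        assert back.occupancy == table.occupancy

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            CountTable(
                x=np.array([[6]]), n=np.array([5]),
                replicate_keys=[("A", "1")], groups=["A"],
                cluster_ids=["c"], occupancy=["shared"],
            )
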