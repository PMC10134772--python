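"""Cost evaluation and simulated-annealing estimation."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

import snapkin as sk
from snapkin.kinetics import ValidationError, propagate_moments
from snapkin.moments import MomentSummary

from conftest import random_conserving_matrix


def _lognormal_moments(p, rng, time=0.0, n=500):
    x = rng.lognormal(mean=np.log(100.0), sigma=0.5, size=(n, p))
    mu = x.mean(axis=0)
    d = x - mu
    return MomentSummary(mu=mu, J=(d.T @ d) / n, n_cells=n, time=time)


@pytest.fixture(scope="module")
def one_slot_problem():
    """p=2 data generated by a single conversion rate k* = 0.37."""
    panel = sk.SpeciesPanel(["X1", "X2"])
    rng = np.random.default_rng(11)
    m1 = _lognormal_moments(2, rng)
    M = sk.build_rate_matrix(sk.KineticRates(off_diagonal={("X1", "X2"): 0.37}), panel)
    m2 = propagate_moments(m1, M, 30.0)
    arch = sk.NetworkArchitecture.from_reactions(panel, [("X1", "X2")])
    return panel, m1, m2, arch


class TestChiSquared:
    def test_exact_zero_at_generating_matrix(self, chain4_closed_form):
        m1, m2, M = chain4_closed_form
        cb = sk.chi_squared(M, m1, m2)
        assert cb.total == 0.0
        assert cb.mean_term == 0.0 and cb.covariance_term == 0.0
        assert cb.conservation_term == 0.0

    def test_conservation_term_zero_for_zero_column_sums(self):
        rng = np.random.default_rng(0)
        panel = sk.SpeciesPanel(["A", "B", "C"])
        M = sk.RateMatrix(random_conserving_matrix(3, rng), panel)
        m1 = _lognormal_moments(3, rng)
        m2 = _lognormal_moments(3, np.random.default_rng(1), time=30.0)
        assert sk.chi_squared(M, m1, m2).conservation_term == 0.0

    def test_half_ratio_mean_term(self):
        # actual mean of X1 doctored to twice the prediction: (1 - 1/2)^2
        panel = sk.SpeciesPanel(["X1", "X2"])
        rng = np.random.default_rng(2)
        m1 = _lognormal_moments(2, rng)
        M = sk.build_rate_matrix(sk.KineticRates(off_diagonal={("X1", "X2"): 0.2}), panel)
        pred = propagate_moments(m1, M, 30.0)
        mu_actual = pred.mu.copy()
        mu_actual[0] = 2.0 * pred.mu[0]
        m2 = MomentSummary(mu=mu_actual, J=pred.J, n_cells=m1.n_cells, time=30.0)
        cb = sk.chi_squared(M, m1, m2)
        assert cb.mean_term == pytest.approx(0.25, rel=1e-12)
        assert cb.covariance_term == 0.0
        assert cb.total == pytest.approx(0.25, rel=1e-12)

    def test_conservation_scale_prefactor(self):
        # lambda = ((t2-t1)/a)^2 multiplies the squared column sums
        panel = sk.SpeciesPanel(["A", "B"])
        M = sk.build_rate_matrix(
            sk.KineticRates(off_diagonal={("A", "B"): 0.5}, self_rates={"A": 0.2}),
            panel,
        )
        rng = np.random.default_rng(3)
        m1 = _lognormal_moments(2, rng)
        m2 = propagate_moments(m1, M, 30.0)
        base = sk.chi_squared(M, m1, m2, conservation_scale=30.0).conservation_term
        assert base == pytest.approx(0.2**2, rel=1e-12)
        halved = sk.chi_squared(M, m1, m2, conservation_scale=60.0).conservation_term
        assert halved == pytest.approx(base / 4.0, rel=1e-12)

    def test_covariance_pairs_counted_twice_by_default(self):
        # off-diagonal residuals appear twice under "all", once under "upper"
        panel = sk.SpeciesPanel(["A", "B"])
        rng = np.random.default_rng(4)
        m1 = _lognormal_moments(2, rng)
        M = sk.build_rate_matrix(sk.KineticRates(off_diagonal={("A", "B"): 0.1}), panel)
        pred = propagate_moments(m1, M, 30.0)
        J_actual = pred.J * np.array([[1.0, 2.0], [2.0, 1.0]])  # doctor off-diagonal
        m2 = MomentSummary(mu=pred.mu, J=J_actual, n_cells=m1.n_cells, time=30.0)
        both = sk.chi_squared(M, m1, m2).covariance_term
        upper = sk.chi_squared(M, m1, m2, pair_mode="upper").covariance_term
        assert both == pytest.approx(2 * 0.25, rel=1e-12)
        assert upper == pytest.approx(0.25, rel=1e-12)

    def test_near_zero_denominators_skipped_and_counted(self):
        panel = sk.SpeciesPanel(["A", "B"])
        rng = np.random.default_rng(5)
        m1 = _lognormal_moments(2, rng)
        M = sk.RateMatrix(np.zeros((2, 2)), panel)
        pred = propagate_moments(m1, M, 30.0)
        mu = pred.mu.copy()
        mu[0] = 0.0  # dead channel at t2
        m2 = MomentSummary(mu=mu, J=pred.J, n_cells=m1.n_cells, time=30.0)
        cb = sk.chi_squared(M, m1, m2)
        assert cb.n_mean_skipped == 1
        assert np.isfinite(cb.total)

    def test_time_ordering_enforced(self, chain4_closed_form):
        m1, m2, M = chain4_closed_form
        with pytest.raises(ValidationError):
            sk.chi_squared(M, m2, m1)


class TestFit:
    def test_single_slot_matches_1d_minimizer(self, one_slot_problem):
        panel, m1, m2, arch = one_slot_problem

        def cost_of(k):
            M = sk.build_rate_matrix(
                sk.KineticRates(off_diagonal={("X1", "X2"): float(k)}), panel
            )
            return sk.chi_squared(M, m1, m2).total

        # brute-force bracket (the basin is narrow), then golden refinement
        grid = np.linspace(0.005, 2.0, 400)
        k0 = grid[int(np.argmin([cost_of(k) for k in grid]))]
        oracle = minimize_scalar(cost_of, bounds=(k0 - 0.01, k0 + 0.01),
                                 method="bounded", options={"xatol": 1e-10})
        res = sk.fit(m1, m2, arch,
                     sk.AnnealingSchedule(n_cooling_steps=300, cooling_rate=0.95,
                                          mc_trials_per_step=20, seed=5))
        fitted = res.M.M[1, 0]
        assert fitted == pytest.approx(oracle.x, abs=1e-3)
        assert fitted == pytest.approx(0.37, abs=1e-3)

    def test_seeded_determinism_bitwise(self, one_slot_problem):
        _, m1, m2, arch = one_slot_problem
        sched = sk.AnnealingSchedule(n_cooling_steps=50, cooling_rate=0.9,
                                     mc_trials_per_step=10, seed=123)
        r1 = sk.fit(m1, m2, arch, sched)
        r2 = sk.fit(m1, m2, arch, sched)
        assert r1.M.M.tobytes() == r2.M.M.tobytes()
        assert r1.trace == r2.trace
        assert r1.cost == r2.cost

    def test_trace_best_cost_monotone_and_below_start(self, chain4_moments):
        m1, m2 = chain4_moments
        arch = sk.chain_architecture(4)
        res = sk.fit(m1, m2, arch,
                     sk.AnnealingSchedule(n_cooling_steps=100, cooling_rate=0.93,
                                          mc_trials_per_step=10, seed=2))
        best = [b for _, _, b in res.trace]
        assert all(b2 <= b1 for b1, b2 in zip(best, best[1:]))
        assert res.cost.total == pytest.approx(best[-1], rel=1e-12)

    def test_masked_slots_stay_exactly_zero(self, chain4_moments):
        m1, m2 = chain4_moments
        arch = sk.chain_architecture(4)
        res = sk.fit(m1, m2, arch,
                     sk.AnnealingSchedule(n_cooling_steps=60, cooling_rate=0.9,
                                          mc_trials_per_step=10, seed=0))
        off = ~np.eye(4, dtype=bool)
        assert np.all(res.M.M[off & ~arch.allowed] == 0.0)

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValidationError):
            sk.AnnealingSchedule(cooling_rate=1.5)
        with pytest.raises(ValidationError):
            sk.AnnealingSchedule(n_cooling_steps=0)

    def test_p40_chain_completes_at_reduced_schedule(self):
        # dimension-scaling smoke test: a 40-species chain fit runs end to end
        rng = np.random.default_rng(8)
        run = sk.simulate_chain(40, n_cells=200, seed=8)
        m1 = sk.compute_moments(run.snapshots[0])
        m2 = sk.compute_moments(run.snapshots[1])
        res = sk.fit(m1, m2, sk.chain_architecture(40),
                     sk.AnnealingSchedule(n_cooling_steps=30, cooling_rate=0.8,
                                          mc_trials_per_step=10, seed=1))
        assert np.isfinite(res.cost.total)


class TestInitialTemperature:
    def test_constant_landscape_returns_common_value(self):
        # a slot fed by an all-zero species cannot move the cost: every
        # probe evaluates to the same value, and the max returns it
        panel = sk.SpeciesPanel(["A", "B"])
        mu1 = np.array([0.0, 50.0])
        J1 = np.diag([0.0, 25.0])
        m1 = MomentSummary(mu=mu1, J=J1, n_cells=100, time=0.0)
        m2 = MomentSummary(mu=np.array([0.0, 100.0]), J=J1, n_cells=100, time=30.0)
        arch = sk.NetworkArchitecture.from_reactions(panel, [("A", "B")])
        t0 = sk.initial_temperature(m1, m2, arch, n_probe=10, seed=0)
        expected = sk.chi_squared(
            sk.build_rate_matrix(sk.KineticRates(off_diagonal={("A", "B"): 0.5}), panel),
            m1, m2,
        ).total
        assert t0 == pytest.approx(expected, rel=1e-12)

    def test_max_contract_and_probe_monotonicity(self, chain4_moments):
        m1, m2 = chain4_moments
        arch = sk.chain_architecture(4)
        t_small = sk.initial_temperature(m1, m2, arch, n_probe=10, seed=0)
        t_big = sk.initial_temperature(m1, m2, arch, n_probe=100, seed=0)
        # same seed: the first 10 probes are a prefix of the 100
        assert t_big >= t_small
        with pytest.raises(ValidationError):
            sk.initial_temperature(m1, m2, arch, n_probe=1, seed=0)
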