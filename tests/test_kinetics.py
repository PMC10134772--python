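"""Rate-matrix construction and closed-form propagation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import snapkin as sk
from snapkin.kinetics import (
    ConfigurationError,
    ValidationError,
    propagate_moments,
)
from snapkin.moments import MomentSummary

from conftest import random_conserving_matrix


def eig_expm(M: np.ndarray, t: float) -> np.ndarray:
    """Independent oracle: exp(Mt) via explicit eigendecomposition."""
    lam, V = np.linalg.eig(M)
    return np.real(V @ np.diag(np.exp(lam * t)) @ np.linalg.inv(V))


class TestBuildRateMatrix:
    def test_single_conversion(self):
        panel = sk.SpeciesPanel(["X1", "X2"])
        rates = sk.KineticRates(off_diagonal={("X1", "X2"): 0.5})
        M = sk.build_rate_matrix(rates, panel)
        np.testing.assert_array_equal(M.M, [[-0.5, 0.0], [0.5, 0.0]])

    def test_empty_rates_give_zero_matrix(self):
        panel = sk.SpeciesPanel(["A", "B", "C"])
        M = sk.build_rate_matrix(sk.KineticRates(), panel)
        np.testing.assert_array_equal(M.M, np.zeros((3, 3)))

    def test_diagonal_absorbs_outflow_and_self_rate(self):
        panel = sk.SpeciesPanel(["X1", "X2", "X3"])
        rates = sk.KineticRates(
            off_diagonal={("X1", "X2"): 0.3, ("X1", "X3"): 0.2},
            self_rates={"X1": 0.1},
        )
        M = sk.build_rate_matrix(rates, panel)
        assert M.M[0, 0] == pytest.approx(0.1 - 0.5)
        assert M.column_sums()[0] == pytest.approx(0.1)

    def test_round_trip_is_lossless(self):
        panel = sk.SpeciesPanel(["A", "B", "C"])
        rates = sk.KineticRates(
            off_diagonal={("A", "B"): 0.25, ("C", "A"): 1.5},
            self_rates={"B": -0.75},
        )
        M = sk.build_rate_matrix(rates, panel)
        back = M.to_rates()
        assert dict(back.off_diagonal) == dict(rates.off_diagonal)
        assert dict(back.self_rates) == dict(rates.self_rates)

    def test_unknown_species_rejected(self):
        panel = sk.SpeciesPanel(["A", "B"])
        with pytest.raises(ConfigurationError, match="Zzz"):
            sk.build_rate_matrix(
                sk.KineticRates(off_diagonal={("A", "Zzz"): 0.1}), panel
            )

    def test_negative_conversion_rate_rejected(self):
        with pytest.raises(ValidationError):
            sk.KineticRates(off_diagonal={("A", "B"): -0.1})

    def test_csv_round_trip(self, tmp_path):
        panel = sk.SpeciesPanel(["A", "B"])
        M = sk.build_rate_matrix(
            sk.KineticRates(off_diagonal={("A", "B"): 0.5}, self_rates={"A": -0.2}),
            panel,
        )
        path = tmp_path / "M.csv"
        M.to_csv(path)
        M2 = sk.RateMatrix.from_csv(path)
        assert M2.panel.names == panel.names
        np.testing.assert_allclose(M2.M, M.M)


class TestMatrixExponential:
    def test_zero_time_gives_identity(self):
        M = sk.RateMatrix(np.array([[-1.0, 0.0], [1.0, 0.0]]), sk.SpeciesPanel(["A", "B"]))
        np.testing.assert_array_equal(sk.matrix_exponential(M, 0.0), np.eye(2))

    def test_diagonal_matrix(self):
        M = np.diag([-1.0, 2.0])
        E = sk.matrix_exponential(M, 1.0)
        np.testing.assert_allclose(E, np.diag([np.exp(-1.0), np.exp(2.0)]), rtol=1e-12)

    def test_matches_eigendecomposition_oracle(self):
        # 100 random diagonalizable matrices up to p = 10
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(100):
            p = int(rng.integers(2, 11))
            M = random_conserving_matrix(p, rng)
            E = sk.matrix_exponential(M, 30.0)
            worst = max(worst, float(np.abs(E - eig_expm(M, 30.0)).max()))
        assert worst < 1e-8

    def test_rejects_nonfinite(self):
        with pytest.raises(ValidationError):
            sk.matrix_exponential(np.array([[np.nan, 0.0], [0.0, 0.0]]), 1.0)

    def test_rejects_negative_dt(self):
        with pytest.raises(ValidationError):
            sk.matrix_exponential(np.zeros((2, 2)), -1.0)


class TestPropagateCells:
    def test_zero_matrix_is_identity(self):
        panel = sk.SpeciesPanel(["A", "B"])
        M = sk.RateMatrix(np.zeros((2, 2)), panel)
        cells = sk.CellStateMatrix(np.array([[1.0, 2.0], [3.0, 4.0]]), time=0.0)
        out = sk.propagate_cells(cells, M, 10.0)
        np.testing.assert_array_equal(out.x, cells.x)
        assert out.time == 10.0

    def test_two_species_half_life(self):
        # X1 -> X2 at k = 0.5; pick dt so that exp(-k dt) = 1/2
        panel = sk.SpeciesPanel(["X1", "X2"])
        M = sk.build_rate_matrix(
            sk.KineticRates(off_diagonal={("X1", "X2"): 0.5}), panel
        )
        dt = np.log(2.0) / 0.5
        out = sk.propagate_cells(sk.CellStateMatrix([[10.0, 0.0]], time=0.0), M, dt)
        np.testing.assert_allclose(out.x, [[5.0, 5.0]], rtol=1e-12)

    def test_mass_conservation_per_cell(self):
        rng = np.random.default_rng(0)
        panel = sk.SpeciesPanel([f"X{i}" for i in range(5)])
        M = sk.RateMatrix(random_conserving_matrix(5, rng), panel)
        cells = sk.CellStateMatrix(rng.lognormal(size=(50, 5)), time=0.0)
        out = sk.propagate_cells(cells, M, 17.0)
        np.testing.assert_allclose(
            out.x.sum(axis=1), cells.x.sum(axis=1), rtol=1e-9
        )

    def test_dimension_mismatch(self):
        panel = sk.SpeciesPanel(["A", "B"])
        M = sk.RateMatrix(np.zeros((2, 2)), panel)
        with pytest.raises(ValidationError):
            sk.propagate_cells(sk.CellStateMatrix(np.ones((3, 3)), time=0.0), M, 1.0)


class TestPropagateMoments:
    def _summary(self, rng, p):
        x = rng.lognormal(size=(200, p))
        mu = x.mean(axis=0)
        d = x - mu
        return MomentSummary(mu=mu, J=(d.T @ d) / len(x), n_cells=len(x), time=0.0)

    def test_zero_matrix_identity(self):
        rng = np.random.default_rng(1)
        panel = sk.SpeciesPanel(["A", "B", "C"])
        M = sk.RateMatrix(np.zeros((3, 3)), panel)
        m1 = self._summary(rng, 3)
        m2 = propagate_moments(m1, M, 5.0)
        np.testing.assert_array_equal(m2.mu, m1.mu)
        np.testing.assert_array_equal(m2.J, m1.J)

    def test_zero_covariance_stays_zero(self):
        rng = np.random.default_rng(2)
        panel = sk.SpeciesPanel(["A", "B", "C"])
        M = sk.RateMatrix(random_conserving_matrix(3, rng), panel)
        m1 = MomentSummary(mu=np.ones(3), J=np.zeros((3, 3)), n_cells=10, time=0.0)
        m2 = propagate_moments(m1, M, 3.0)
        np.testing.assert_array_equal(m2.J, np.zeros((3, 3)))

    def test_commutes_with_cell_propagation(self, chain4_run, chain4_truth_rates):
        # propagating 2,500 cells then summarizing == propagating the summary
        ds0 = chain4_run.snapshots[0]
        M = sk.build_rate_matrix(chain4_truth_rates, chain4_run.measured_panel)
        cells_t2 = sk.propagate_cells(ds0.cells, M, 30.0)
        explicit = sk.compute_moments(
            sk.SnapshotDataset(cells_t2, chain4_run.measured_panel)
        )
        via_moments = propagate_moments(sk.compute_moments(ds0), M, 30.0)
        np.testing.assert_allclose(explicit.mu, via_moments.mu, rtol=1e-9)
        np.testing.assert_allclose(
            explicit.J, via_moments.J, rtol=1e-9, atol=1e-9 * np.abs(explicit.J).max()
        )

    def test_psd_preserved(self):
        rng = np.random.default_rng(3)
        panel = sk.SpeciesPanel([f"X{i}" for i in range(4)])
        M = sk.RateMatrix(random_conserving_matrix(4, rng), panel)
        m1 = self._summary(rng, 4)
        m2 = propagate_moments(m1, M, 30.0)
        assert np.all(np.linalg.eigvalsh(m2.J) > -1e-9 * np.abs(m2.J).max())

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), a=st.floats(0.1, 20.0), b=st.floats(0.1, 20.0))
    def test_semigroup_and_conservation(self, seed, a, b):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(2, 6))
        panel = sk.SpeciesPanel([f"X{i}" for i in range(p)])
        M = sk.RateMatrix(random_conserving_matrix(p, rng), panel)
        m1 = self._summary(rng, p)
        one_hop = propagate_moments(m1, M, a + b)
        two_hop = propagate_moments(propagate_moments(m1, M, a), M, b)
        np.testing.assert_allclose(one_hop.mu, two_hop.mu, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(
            one_hop.J, two_hop.J, rtol=1e-9, atol=1e-9 * max(1.0, np.abs(one_hop.J).max())
        )
        # zero column sums => total mean abundance conserved
        assert one_hop.mu.sum() == pytest.approx(m1.mu.sum(), rel=1e-9)
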