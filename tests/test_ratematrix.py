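import numpy as np
import pytest
import scipy.linalg

import pomopy as pp
from conftest import random_reversible_model
from oracles import bisect_magnitude_for_theta, closed_form_stationary


@pytest.fixture(scope="module")
def rates10(space10, hky_calibrated):
    QM = pp.build_mutation_matrix(space10, hky_calibrated)
    QD = pp.build_drift_matrix(space10)
    return pp.assemble_rate_matrix(QM, QD)


class TestMutationMatrix:
    def test_monomorphic_to_boundary_entries(self, space10, hky):
        QM = pp.build_mutation_matrix(space10, hky)
        iA = space10.monomorphic_index("A")
        j = space10.polymorphic_index("A", "C", 9)  # {9A|1C}
        assert QM[iA, j] == pytest.approx(hky.rate("A", "C"))

    def test_polymorphic_rows_zero(self, space10, hky):
        QM = pp.build_mutation_matrix(space10, hky)
        poly = space10.polymorphic_mask
        assert np.all(QM[poly] == 0.0)

    def test_row_sums_zero(self, space10, hky):
        QM = pp.build_mutation_matrix(space10, hky)
        assert np.allclose(QM.sum(axis=1), 0.0, atol=1e-15)

    def test_alphabet_mismatch(self, space10):
        model = pp.MutationModel.jc(alphabet=pp.Alphabet(("A", "C")))
        with pytest.raises(ValueError):
            pp.build_mutation_matrix(space10, model)


class TestDriftMatrix:
    def test_moran_rates(self, space10):
        QD = pp.build_drift_matrix(space10)
        s = space10.polymorphic_index("A", "C", 5)
        up = space10.polymorphic_index("A", "C", 6)
        down = space10.polymorphic_index("A", "C", 4)
        assert QD[s, up] == pytest.approx(2.5)
        assert QD[s, down] == pytest.approx(2.5)
        edge = space10.polymorphic_index("A", "C", 1)
        assert QD[edge, space10.monomorphic_index("C")] == pytest.approx(0.9)
        assert QD[edge, space10.polymorphic_index("A", "C", 2)] == pytest.approx(0.9)

    def test_monomorphic_rows_zero(self, space10):
        QD = pp.build_drift_matrix(space10)
        assert np.all(QD[:4] == 0.0)

    def test_row_sums_zero(self, space10):
        QD = pp.build_drift_matrix(space10)
        assert np.allclose(QD.sum(axis=1), 0.0, atol=1e-12)


class TestAssembly:
    def test_stationarity(self, rates10):
        assert np.max(np.abs(rates10.stationary @ rates10.Q)) < 1e-10

    def test_jc_symmetry(self, space10):
        QM = pp.build_mutation_matrix(space10, pp.MutationModel.jc(0.01))
        QD = pp.build_drift_matrix(space10)
        rs = pp.assemble_rate_matrix(QM, QD)
        mono = rs.stationary[:4]
        assert np.allclose(mono, mono[0])

    def test_normalization(self, rates10):
        assert -(rates10.stationary * np.diag(rates10.Q)).sum() == pytest.approx(1.0)
        assert np.allclose(rates10.Q, rates10.QM + rates10.QD)

    def test_closed_form_matches_eigenvector(self, space10, hky_calibrated, rates10):
        closed = pp.stationary_closed_form(space10, hky_calibrated)
        assert np.max(np.abs(closed - rates10.stationary)) < 1e-10
        # independently assembled state-by-state from detailed balance
        oracle = closed_form_stationary(space10, hky_calibrated)
        assert np.max(np.abs(closed - oracle)) < 1e-14

    def test_detailed_balance(self, rates10):
        pi = rates10.stationary
        flux = pi[:, None] * rates10.Q
        assert np.max(np.abs(flux - flux.T)) < 1e-10

    @pytest.mark.parametrize("seed", range(20))
    def test_closed_form_random_models(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(2, 12))
        n_sym = int(rng.integers(2, 5))
        alphabet = pp.Alphabet(tuple("ACGT"[:n_sym]))
        space = pp.StateSpace(N, alphabet)
        model = random_reversible_model(rng, alphabet)
        QM = pp.build_mutation_matrix(space, model)
        QD = pp.build_drift_matrix(space)
        rs = pp.assemble_rate_matrix(QM, QD)
        closed = pp.stationary_closed_form(space, model)
        assert np.max(np.abs(closed - rs.stationary)) < 1e-8


class TestCalibration:
    def test_round_trip(self, space10, hky):
        for theta in [0.0025, 0.005, 0.05]:
            cal = pp.calibrate_heterozygosity(hky, space10, theta)
            assert pp.polymorphic_mass(space10, cal) == pytest.approx(theta, abs=1e-8)

    def test_matches_bisection_oracle(self, space10, hky):
        cal = pp.calibrate_heterozygosity(hky, space10, 0.005)
        mu_oracle = bisect_magnitude_for_theta(space10, hky, 0.005)
        assert cal.magnitude == pytest.approx(mu_oracle, rel=1e-6)

    def test_small_theta_linearity(self, space10, hky):
        mu1 = pp.calibrate_heterozygosity(hky, space10, 0.001).magnitude
        mu2 = pp.calibrate_heterozygosity(hky, space10, 0.002).magnitude
        assert mu2 > mu1  # exact monotonicity
        assert mu2 / mu1 == pytest.approx(2.0, rel=0.05)

    def test_validity_warning(self, space10, hky):
        with pytest.warns(UserWarning, match="0.1"):
            pp.calibrate_heterozygosity(hky, space10, 0.2)

    def test_invalid_theta(self, space10, hky):
        for theta in [0.0, 1.0, -0.1]:
            with pytest.raises(ValueError):
                pp.calibrate_heterozygosity(hky, space10, theta)


class TestTransitionProbabilities:
    def test_zero_time_identity(self, rates10):
        assert np.array_equal(
            pp.transition_probabilities(rates10, 0.0), np.eye(rates10.n_states)
        )

    def test_negative_time_rejected(self, rates10):
        with pytest.raises(ValueError):
            pp.transition_probabilities(rates10, -0.1)

    def test_rows_sum_to_one(self, rates10):
        P = pp.transition_probabilities(rates10, 0.37)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert P.min() >= 0.0

    def test_ergodic_limit(self):
        # every row approaches the stationary distribution; N=4 keeps the
        # slowest (substitution-like) relaxation mode fast enough that t=500
        # in normalized event units is deep inside the limit
        space = pp.StateSpace(4)
        model = pp.MutationModel.jc(magnitude=1.0)
        QM = pp.build_mutation_matrix(space, model)
        QD = pp.build_drift_matrix(space)
        rs = pp.assemble_rate_matrix(QM, QD)
        P = pp.transition_probabilities(rs, 500.0)
        assert np.max(np.abs(P - rs.stationary[None, :])) < 1e-6

    def test_matches_pade_exponential(self, rates10):
        P = pp.transition_probabilities(rates10, 0.1)
        Pref = scipy.linalg.expm(rates10.Q * 0.1)
        assert np.max(np.abs(P - Pref)) < 1e-8

    @pytest.mark.parametrize("seed", range(5))
    def test_chapman_kolmogorov(self, rates10, seed):
        rng = np.random.default_rng(seed)
        s, t = rng.uniform(0.01, 1.0, size=2)
        Pst = pp.transition_probabilities(rates10, s + t)
        prod = pp.transition_probabilities(rates10, s) @ pp.transition_probabilities(
            rates10, t
        )
        assert np.max(np.abs(Pst - prod)) < 1e-8


def test_events_per_substitution_identity(space10, hky_calibrated):
    # drift flux is (N-1) times the mutation flux and a single mutant fixes
    # with probability 1/N, so the conversion factor is exactly N^2
    assert pp.events_per_substitution(space10, hky_calibrated) == pytest.approx(100.0)
    space5 = pp.StateSpace(5)
    model = pp.calibrate_heterozygosity(
        pp.MutationModel.jc(), space5, 0.01
    )
    assert pp.events_per_substitution(space5, model) == pytest.approx(25.0)
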