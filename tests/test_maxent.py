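import numpy as np
import pytest
from scipy import optimize

from xsikit import maxent
from xsikit.extraction import InterferencePattern
from xsikit.forward import build_basis_matrix, interference_basis
from xsikit.maxent import DistanceDistribution, chi_squared, fit_amplitude, fit_distribution


@pytest.fixture
def q():
    return np.linspace(0.01, 0.35, 128)


def _pattern(q, curve, sigma):
    return InterferencePattern(q, curve, np.full(q.size, sigma))


class TestChiSquared:
    def test_perfect_model_gives_zero(self, q):
        curve = interference_basis(q, 60.0)
        pat = _pattern(q, 2.0 * curve, 0.1)
        assert chi_squared(pat, curve, 2.0) == pytest.approx(0.0, abs=1e-20)

    def test_one_point_offset_adds_k_squared(self, q):
        curve = interference_basis(q, 60.0)
        values = 2.0 * curve.copy()
        values[10] += 3 * 0.1
        pat = _pattern(q, values, 0.1)
        assert chi_squared(pat, curve, 2.0) == pytest.approx(9.0)

    def test_fitted_amplitude_is_wls_minimizer(self, q):
        rng = np.random.default_rng(0)
        curve = interference_basis(q, 60.0)
        pat = _pattern(q, 2.0 * curve + rng.normal(0, 0.05, q.size), 0.05)
        a_hat = fit_amplitude(pat, curve)
        grid = a_hat + np.linspace(-0.1, 0.1, 11)
        chis = [chi_squared(pat, curve, a) for a in grid]
        assert np.argmin(chis) == 5  # center of the scan


class TestDistributionInvariants:
    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            DistanceDistribution(np.arange(3.0), np.array([0.5, 0.6, -0.1]))

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            DistanceDistribution(np.arange(3.0), np.array([0.5, 0.4, 0.2]))

    def test_nonuniform_grid_rejected(self):
        with pytest.raises(ValueError):
            DistanceDistribution(np.array([1.0, 2.0, 4.0]),
                                 np.array([0.3, 0.3, 0.4]))


class TestFitDistribution:
    def test_single_component_mode_recovered(self, q):
        """A pattern from one basis row inverts to a mode at that distance."""
        basis = build_basis_matrix(q, np.arange(5.0, 151.0, 1.0))
        curve = 100.0 * interference_basis(q, 93.0)
        pat = _pattern(q, curve, 0.5)
        dist = fit_distribution(pat, basis)
        assert abs(dist.mode - 93.0) <= 1.0
        assert dist.weights.min() >= 0.0
        assert dist.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_uninformative_data_returns_prior(self, q):
        basis = build_basis_matrix(q, np.arange(20.0, 120.0, 5.0))
        pat = _pattern(q, interference_basis(q, 60.0), sigma=1e9)
        prior = np.exp(-0.5 * ((basis.d_grid - 70) / 20.0) ** 2)
        prior /= prior.sum()
        dist = fit_distribution(pat, basis, prior=prior)
        np.testing.assert_allclose(dist.weights, prior, atol=1e-6)

    def test_two_component_recovery(self, q):
        """54/89 A mixture at 84/16 with 1% noise: modes +-2 A, split +-0.05."""
        rng = np.random.default_rng(42)
        basis = build_basis_matrix(q, np.arange(5.0, 151.0, 1.0))
        clean = 1000.0 * (0.84 * interference_basis(q, 54.0)
                          + 0.16 * interference_basis(q, 89.0))
        sigma = 0.01 * np.abs(clean).max()
        pat = _pattern(q, clean + rng.normal(0, sigma, q.size), sigma)
        dist = fit_distribution(pat, basis)
        from xsikit import ensemble

        peaks = sorted(ensemble.find_peaks(dist), key=lambda p: p.area,
                       reverse=True)[:2]
        assert abs(peaks[0].mode - 54.0) <= 2.0
        assert abs(peaks[1].mode - 89.0) <= 2.0
        major = peaks[0].area / (peaks[0].area + peaks[1].area)
        assert major == pytest.approx(0.84, abs=0.05)

    def test_mode_invariant_to_denser_q_grid(self):
        for n in (128, 256):
            qi = np.linspace(0.01, 0.35, n)
            basis = build_basis_matrix(qi, np.arange(5.0, 151.0, 1.0))
            curve = 100.0 * interference_basis(qi, 67.0)
            dist = fit_distribution(_pattern(qi, curve, 0.5), basis)
            assert abs(dist.mode - 67.0) <= 1.0

    def test_infeasible_target_flagged(self, q):
        """Data no basis mixture can fit: flag set, least-chi2 returned."""
        rng = np.random.default_rng(3)
        basis = build_basis_matrix(q, np.arange(40.0, 100.0, 5.0))
        values = rng.normal(0, 1, q.size)  # white noise, tiny claimed sigma
        dist = fit_distribution(_pattern(q, values, 1e-4), basis)
        assert dist.infeasible
        assert dist.chi2_per_point > 1.05

    def test_grid_mismatch_rejected(self, q):
        basis = build_basis_matrix(q * 1.001, np.arange(40.0, 100.0, 5.0))
        with pytest.raises(ValueError, match="q-grid"):
            fit_distribution(_pattern(q, np.zeros(q.size), 0.1), basis)


class TestAgainstBruteForceOracle:
    @pytest.mark.parametrize("seed", [5, 11])
    def test_matches_constrained_optimizer_on_small_grid(self, seed):
        """Exponentiated-gradient solution == SLSQP entropy/chi2 optimum.

        Both routes profile the amplitude by weighted least squares and
        solve at the same chi^2 level; agreement to ||dP||_inf < 1e-4 on a
        <= 12-point grid.
        """
        rng = np.random.default_rng(seed)
        q = np.linspace(0.02, 0.3, 40)
        basis = build_basis_matrix(q, np.linspace(40.0, 110.0, 8))
        p_true = np.zeros(8)
        p_true[1], p_true[4] = 0.6, 0.4
        curve = 1200.0 * (p_true @ basis.values)
        sigma = np.full(q.size, 0.02 * np.abs(curve).max())
        obs = curve + rng.normal(0, sigma)
        pat = InterferencePattern(q, obs, sigma)

        dist = fit_distribution(pat, basis, chi2_window=1e-7, inner_tol=1e-13)
        assert not dist.infeasible

        n, m = q.size, np.full(8, 1 / 8)
        w = 1.0 / sigma**2

        def chi2_of(p):
            bp = p @ basis.values
            den = np.sum(w * bp * bp)
            a = np.sum(w * obs * bp) / den if den > 0 else 0.0
            return np.sum(w * (obs - a * bp) ** 2)

        def neg_entropy(p):
            p = np.clip(p, 1e-12, None)
            return float(np.sum(p * np.log(p / m)))

        target = dist.chi2_per_point * n
        cons = [{"type": "eq", "fun": lambda p: p.sum() - 1},
                {"type": "ineq", "fun": lambda p: target - chi2_of(p)}]
        best = None
        for s in range(4):
            x0 = np.random.default_rng(s).dirichlet(np.ones(8))
            res = optimize.minimize(neg_entropy, x0, method="SLSQP",
                                    bounds=[(0, 1)] * 8, constraints=cons,
                                    options={"maxiter": 2000, "ftol": 1e-14})
            if res.success and (best is None or res.fun < best.fun):
                best = res
        assert best is not None
        oracle = best.x / best.x.sum()
        assert np.max(np.abs(oracle - dist.weights)) < 1e-4
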