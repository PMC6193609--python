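"""Mean-field theory: Siegert rates, fixed points, stability analysis."""

import warnings

import mpmath as mp
import numpy as np
import pytest

from mam import meanfield as mf
from mam.fixtures import make_toy_bistable
from mam.model_spec import (
    ConnectivityModel,
    NetworkSpec,
    NeuronParams,
    Population,
    PopulationGrid,
)

P = NeuronParams()


def siegert_oracle(mu, sigma, p=P, dps=40):
    """High-accuracy quadrature of the rate integral (independent of mam)."""
    mp.mp.dps = dps
    mu, sigma = mp.mpf(mu), mp.mpf(sigma)
    shift = mp.fabs(mp.zeta(mp.mpf(1) / 2)) / mp.sqrt(2) * mp.sqrt(mp.mpf(p.tau_s) / p.tau_m)
    a = (mp.mpf(p.V_r - p.E_L) - mu) / sigma + shift
    b = (mp.mpf(p.theta - p.E_L) - mu) / sigma + shift
    # e^{x^2}(1 + erf x) written as e^{x^2} erfc(-x) for numerical stability
    pts = [a, 0, b] if a < 0 < b else [a, b]
    integral = mp.quad(lambda x: mp.exp(x * x) * mp.erfc(-x), pts)
    inv = mp.mpf(p.tau_r) / 1000 + mp.mpf(p.tau_m) / 1000 * mp.sqrt(mp.pi) * integral
    return float(1 / inv)


class TestSiegert:
    def test_subthreshold_limit(self):
        # theta - mu = 50 sigma: astronomically rare threshold crossings
        assert mf.siegert_rate(15.0 - 50.0 * 5.0, 5.0, P) < 1e-10

    def test_refractory_saturation(self):
        assert mf.siegert_rate(1e7, 10.0, P) == pytest.approx(500.0, rel=1e-3)

    def test_matches_quadrature_oracle(self):
        """20-point (mu, sigma) grid against adaptive quadrature, 1e-8 relative."""
        mus = [-20.0, -5.0, 2.0, 8.0, 12.0, 14.0, 15.5, 18.0, 25.0, 60.0]
        sigmas = [1.0, 6.0]
        for mu in mus:
            for sigma in sigmas:
                want = siegert_oracle(mu, sigma)
                if want < 1e-250:
                    continue
                got = mf.siegert_rate(mu, sigma, P)
                assert got == pytest.approx(want, rel=1e-8), (mu, sigma)

    def test_monotone_in_mu(self):
        mus = np.linspace(-30.0, 60.0, 181)
        for sigma in (0.5, 3.0, 12.0):
            rates = mf.siegert_rate(mus, np.full_like(mus, sigma), P)
            assert np.all(np.diff(rates) >= -1e-12)

    def test_deterministic_limit(self):
        # sigma = 0, suprathreshold: exact LIF period
        rate = mf.siegert_rate(30.0, 0.0, P)
        expect = 1.0 / (0.002 + 0.01 * np.log(30.0 / 15.0))
        assert rate == pytest.approx(expect, rel=1e-12)
        assert mf.siegert_rate(10.0, 0.0, P) == 0.0

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            mf.siegert_rate(10.0, -1.0, P)


class TestNetworkInput:
    def test_zero_rates_zero_external(self):
        spec = make_toy_bistable(seed=0, verify=False)
        spec.conn.k_ext[:] = 0.0
        out = mf.network_input(np.zeros(2), spec)
        assert np.all(out.mu == 0) and np.all(out.sigma2 == 0)

    def test_single_source_closed_form(self):
        grid = PopulationGrid([Population("X", "23", "E")], [100])
        K, J = 50.0, 87.8
        conn = ConnectivityModel(
            K=np.array([[K]]), J_mean=np.array([[J]]), d_mean=np.ones((1, 1)),
            k_ext=np.zeros(1),
        )
        spec = NetworkSpec(P, grid, conn)
        nu = np.array([7.0])
        out = mf.network_input(nu, spec)
        j_mv = P.tau_s * J / P.C_m
        assert out.mu[0] == pytest.approx(0.01 * K * j_mv * 7.0, rel=1e-14)
        assert out.sigma2[0] == pytest.approx(0.01 * K * j_mv**2 * 7.0, rel=1e-14)

    def test_matches_naive_summation(self, multiarea_spec):
        """Vectorized input maps equal a brute-force loop to 1e-12."""
        spec = multiarea_spec
        n = len(spec.grid)
        rng = np.random.default_rng(3)
        nu = rng.uniform(0.0, 30.0, n)
        out = mf.network_input(nu, spec)
        tau_m = P.tau_m * 1e-3
        jf = P.tau_s / P.C_m
        for i in range(0, n, 7):
            mu = tau_m * spec.conn.k_ext[i] * spec.conn.nu_bg * spec.conn.J_ext * jf
            s2 = tau_m * spec.conn.k_ext[i] * spec.conn.nu_bg * (spec.conn.J_ext * jf) ** 2
            for j in range(n):
                mu += tau_m * spec.conn.K[i, j] * spec.conn.J_mean[i, j] * jf * nu[j]
                s2 += tau_m * spec.conn.K[i, j] * (spec.conn.J_mean[i, j] * jf) ** 2 * nu[j]
            assert out.mu[i] == pytest.approx(mu, rel=1e-12)
            assert out.sigma2[i] == pytest.approx(s2, rel=1e-12)

    def test_dimension_mismatch(self, multiarea_spec):
        with pytest.raises(ValueError):
            mf.network_input(np.zeros(3), multiarea_spec)


class TestFixedPoints:
    def test_feedforward_unique_fixed_point(self):
        """No recurrence: the fixed point is Phi(external input) directly."""
        grid = PopulationGrid([Population("X", "23", "E")], [100])
        conn = ConnectivityModel(
            K=np.zeros((1, 1)), J_mean=np.array([[87.8]]), d_mean=np.ones((1, 1)),
            k_ext=np.array([850.0]), nu_bg=10.0, J_ext=87.8,
        )
        spec = NetworkSpec(P, grid, conn)
        reports = mf.find_fixed_points(spec, np.array([[0.0], [100.0], [400.0]]))
        conv = [r for r in reports if r.converged]
        assert len(conv) == 1
        mfi = mf.network_input(np.zeros(1), spec)
        direct = mf.siegert_rate(mfi.mu, np.sqrt(mfi.sigma2), P)
        assert conv[0].rates[0] == pytest.approx(float(direct[0]), abs=1e-6)

    def test_bistable_toy_two_fixed_points(self, toy_spec):
        """Both attractors found and both verified by the independent oracle."""
        g1 = np.array([0.0, 50.0, 150.0, 300.0, 480.0])
        ics = np.array([[a, b] for a in g1 for b in g1])
        reports = mf.find_fixed_points(toy_spec, ics, tol=1e-10)
        conv = [r for r in reports if r.converged]
        assert len(conv) == 2
        labels = sorted(r.label for r in conv)
        assert labels == ["HA", "LA"]
        for r in conv:
            mfi = mf.network_input(r.rates, toy_spec)
            oracle = np.array(
                [siegert_oracle(m, np.sqrt(s)) for m, s in zip(mfi.mu, mfi.sigma2)]
            )
            assert np.max(np.abs(oracle - r.rates)) < 1e-6
            assert r.max_eig_real < 1.0  # locally stable

    def test_bimodal_endpoint_histogram(self, toy_spec):
        """Random initial conditions settle into two well-separated rate groups."""
        rng = np.random.default_rng(12)
        ics = rng.uniform(0.0, 200.0, size=(10_000, 2))
        finals, resid, conv = mf._pseudo_time_integrate(
            ics, toy_spec, tol=1e-7, h=0.1, max_steps=20_000
        )
        means = finals[conv].mean(axis=1)
        low, high = (means < 50).sum(), (means > 50).sum()
        assert low > 500 and high > 500
        # nothing between the modes
        assert ((means > 20) & (means < 80)).sum() == 0

    def test_nonconvergence_reported(self, toy_spec):
        reports = mf.find_fixed_points(
            toy_spec, np.array([[150.0, 100.0]]), tol=1e-12, max_steps=3
        )
        assert any(not r.converged for r in reports)


class TestEffectiveConnectivity:
    def test_zero_coupling_zero_jacobian(self):
        grid = PopulationGrid([Population("X", "23", "E")], [10])
        conn = ConnectivityModel(
            K=np.zeros((1, 1)), J_mean=np.ones((1, 1)), d_mean=np.ones((1, 1)),
            k_ext=np.array([850.0]), J_ext=87.8,
        )
        spec = NetworkSpec(P, grid, conn)
        reports = mf.find_fixed_points(spec, np.zeros((1, 1)))
        G, eig = mf.effective_connectivity(spec, reports[0].rates)
        assert np.allclose(G, 0.0)
        assert np.allclose(eig, 0.0)

    def test_matches_finite_differences(self, toy_spec):
        """Analytic Jacobian vs central differences of Phi, step 1e-4 spikes/s."""
        reports = mf.find_fixed_points(toy_spec, np.full((1, 2), 300.0), tol=1e-10)
        nu = reports[0].rates
        G, _ = mf.effective_connectivity(toy_spec, nu)
        eps = 1e-4
        for j in range(2):
            up, dn = nu.copy(), nu.copy()
            up[j] += eps
            dn[j] -= eps
            fd = (mf.transfer(up, toy_spec) - mf.transfer(dn, toy_spec)) / (2 * eps)
            assert np.max(np.abs(G[:, j] - fd)) < 1e-6

    def test_perturbation_decays_at_stable_fixed_point(self, toy_spec):
        reports = mf.find_fixed_points(toy_spec, np.zeros((1, 2)), tol=1e-10)
        r = reports[0]
        assert r.max_eig_real < 1.0
        nu = r.rates + np.array([0.5, 0.3])
        finals, _, conv = mf._pseudo_time_integrate(
            nu[None, :], toy_spec, tol=1e-10, h=0.1, max_steps=20_000
        )
        assert conv[0]
        assert np.max(np.abs(finals[0] - r.rates)) < 1e-6

    def test_warns_away_from_fixed_point(self, toy_spec):
        with pytest.warns(UserWarning, match="away from a fixed point"):
            mf.effective_connectivity(toy_spec, np.array([40.0, 40.0]))

    def test_symmetric_matrix_real_spectrum(self):
        rng = np.random.default_rng(5)
        M = rng.standard_normal((12, 12))
        M = 0.5 * (M + M.T)
        eig = np.linalg.eigvals(M)
        assert np.max(np.abs(eig.imag)) < 1e-10


class TestGlobalStability:
    def test_monostable_fraction_one(self, balanced_spec):
        frac, _ = mf.global_stability(balanced_spec, n_init=60, seed=1)
        assert frac == 1.0

    def test_deterministic_given_seed(self, toy_spec):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1, _ = mf.global_stability(toy_spec, n_init=80, seed=3)
            f2, _ = mf.global_stability(toy_spec, n_init=80, seed=3)
        assert f1 == f2

    def test_fraction_decreases_with_recurrent_excitation(self):
        fracs = []
        for xs in (1.0, 1.15, 1.3):
            spec = make_toy_bistable(seed=0, verify=False)
            spec.conn.J_mean[0, 0] *= xs
            frac, _ = mf.global_stability(spec, n_init=300, seed=3)
            fracs.append(frac)
        assert fracs[0] > fracs[1] > fracs[2]
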