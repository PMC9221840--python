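"""Robustness perturbation families: identities, conservation laws, regimes."""

import numpy as np
import pytest

from cnode import (
    BistableGLVParameters,
    PerturbationSpec,
    add_measurement_noise,
    bistable_steady_state,
    bray_curtis,
    generate_glv_dataset,
    generate_multistable_dataset,
    generate_robustness_suite,
    perturb_interactions,
    rewire_network,
    sample_glv_parameters,
)
from cnode.glv import GLVParameters


@pytest.fixture(scope="module")
def base_params():
    return sample_glv_parameters(10, 0.5, 0.1, seed=42)


def _offdiag(N):
    return ~np.eye(N, dtype=bool)


class TestInteractionNoise:
    def test_zero_eta_is_identity(self, base_params):
        out = perturb_interactions(base_params, 0.0, seed=1)
        np.testing.assert_array_equal(out.A, base_params.A)

    def test_network_topology_preserved(self, base_params):
        out = perturb_interactions(base_params, 0.7, seed=2)
        np.testing.assert_array_equal(out.A != 0, base_params.A != 0)
        np.testing.assert_array_equal(np.diag(out.A), np.diag(base_params.A))

    def test_perturbation_variance_matches_eta_squared(self):
        """Empirical variance of the additive noise over ~10^4 nonzero
        entries agrees with eta^2 within Monte-Carlo error."""
        eta = 0.3
        params = sample_glv_parameters(101, 1.0, 0.1, seed=3)
        out = perturb_interactions(params, eta, seed=4)
        mask = _offdiag(101) & (params.A != 0)
        delta = (out.A - params.A)[mask]
        n = delta.size
        assert n >= 10_000
        se = eta**2 * np.sqrt(2.0 / n)
        assert abs(delta.var() - eta**2) < 3 * se

    def test_relabeling_preserves_zero_pattern_equivariantly(self):
        """Perturbing a relabeled community perturbs exactly the relabeled
        edges: the zero pattern commutes with the permutation."""
        params = sample_glv_parameters(6, 0.5, 0.2, seed=5)
        perm = np.random.default_rng(0).permutation(6)
        permuted = GLVParameters(
            params.A[np.ix_(perm, perm)], params.r[perm]
        )
        out = perturb_interactions(permuted, 0.5, seed=6)
        np.testing.assert_array_equal(
            out.A != 0, params.A[np.ix_(perm, perm)] != 0
        )


class TestRewiring:
    def test_zero_rho_is_identity(self, base_params):
        out = rewire_network(base_params, 0.0, seed=1)
        np.testing.assert_array_equal(out.A, base_params.A)

    @pytest.mark.parametrize("rho", [0.1, 0.5, 1.0])
    def test_edge_count_conserved(self, base_params, rho):
        out = rewire_network(base_params, rho, seed=2)
        N = base_params.N
        assert (out.A[_offdiag(N)] != 0).sum() == (
            base_params.A[_offdiag(N)] != 0
        ).sum()

    def test_full_rewiring_preserves_weight_multiset(self):
        params = sample_glv_parameters(20, 0.15, 0.4, seed=7)
        out = rewire_network(params, 1.0, seed=8)
        w_before = np.sort(params.A[_offdiag(20) & (params.A != 0)])
        w_after = np.sort(out.A[_offdiag(20) & (out.A != 0)])
        np.testing.assert_array_equal(w_before, w_after)
        np.testing.assert_array_equal(np.diag(out.A), np.diag(params.A))

    def test_relabeling_preserves_weight_multiset(self):
        params = sample_glv_parameters(6, 0.4, 0.3, seed=9)
        perm = np.random.default_rng(1).permutation(6)
        permuted = GLVParameters(params.A[np.ix_(perm, perm)], params.r[perm])
        out = rewire_network(permuted, 0.5, seed=10)
        w0 = np.sort(params.A[_offdiag(6) & (params.A != 0)])
        w1 = np.sort(out.A[_offdiag(6) & (out.A != 0)])
        np.testing.assert_allclose(w0, w1)

    def test_complete_network_cannot_rewire(self):
        params = sample_glv_parameters(4, 1.0, 0.2, seed=11)
        with pytest.raises(ValueError, match="empty positions"):
            rewire_network(params, 0.5, seed=0)


class TestMeasurementNoise:
    def test_zero_eps_is_identity(self, rng):
        p = rng.dirichlet(np.ones(8))
        np.testing.assert_array_equal(add_measurement_noise(p, 0.0, seed=1), p)

    @pytest.mark.parametrize("eps", [0.01, 0.05, 0.2])
    def test_output_is_compositional(self, rng, eps):
        p = rng.dirichlet(np.ones(10))
        noisy = add_measurement_noise(p, eps, seed=2)
        assert noisy.sum() == pytest.approx(1.0)
        assert (noisy >= 0).all()

    def test_absent_taxa_can_be_measured_as_present(self):
        p = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
        rng = np.random.default_rng(3)
        appeared = any(
            (add_measurement_noise(p, 0.05, rng)[1:] > 0).any()
            for _ in range(50)
        )
        assert appeared

    def test_mean_corruption_is_stable_across_seeds(self):
        """At the adequate-performance noise level (eps = 0.025, N = 100)
        the mean clean-vs-noisy Bray-Curtis over 10^3 draws is seed-stable
        within 3 standard errors."""
        N, B, eps = 100, 1000, 0.025
        p = np.random.default_rng(4).dirichlet(np.ones(N))
        means, ses = [], []
        for seed in (10, 11):
            rng = np.random.default_rng(seed)
            d = np.array(
                [bray_curtis(p, add_measurement_noise(p, eps, rng)) for _ in range(B)]
            )
            means.append(d.mean())
            ses.append(d.std(ddof=1) / np.sqrt(B))
        combined_se = np.hypot(*ses)
        assert abs(means[0] - means[1]) < 3 * combined_se


@pytest.fixture(scope="module")
def bi_params():
    return BistableGLVParameters(base=sample_glv_parameters(8, 0.5, 0.1, seed=21))


@pytest.fixture(scope="module")
def bi_params_small():
    return BistableGLVParameters(base=sample_glv_parameters(6, 0.5, 0.1, seed=22))


class TestBistable:
    def test_deterministic_given_seed(self, bi_params):
        z = np.ones(8, dtype=np.int8)
        a = bistable_steady_state(bi_params, z, "low", seed=5)
        b = bistable_steady_state(bi_params, z, "low", seed=5)
        np.testing.assert_array_equal(a.x, b.x)

    def test_high_regime_has_more_biomass(self, bi_params):
        z = np.ones(8, dtype=np.int8)
        lo = bistable_steady_state(bi_params, z, "low", seed=6)
        hi = bistable_steady_state(bi_params, z, "high", seed=6)
        assert lo.converged and hi.converged
        assert hi.x.sum() > lo.x.sum()

    def test_equilibrium_residual_below_tolerance(self, bi_params):
        from cnode.glv import SteadyStateSettings
        from cnode.perturb import _bistable_rhs_factory

        settings = SteadyStateSettings()
        z = np.ones(8, dtype=np.int8)
        res = bistable_steady_state(bi_params, z, "high", settings, seed=7)
        assert res.converged
        rate = _bistable_rhs_factory(bi_params)(0.0, res.x)
        alive = res.x > 0
        assert np.abs(rate[alive] / res.x[alive]).max() < settings.convergence_tol

    def test_invalid_regime_rejected(self, bi_params):
        with pytest.raises(ValueError, match="regime"):
            bistable_steady_state(bi_params, np.ones(8), "medium", seed=0)


class TestMultistableDataset:
    @pytest.mark.parametrize("mu, expected_low", [(0.0, 10), (1.0, 0), (0.2, 8)])
    def test_regime_counts(self, bi_params_small, mu, expected_low):
        ds, regimes = generate_multistable_dataset(
            bi_params_small, 10, mu, seed=3, return_regimes=True
        )
        assert ds.S == 10
        assert regimes.count("low") == expected_low
        assert regimes.count("high") == 10 - expected_low

    def test_samples_satisfy_dataset_invariants(self, bi_params_small):
        ds = generate_multistable_dataset(bi_params_small, 8, 0.5, seed=4)
        for s in ds:
            assert abs(s.p.sum() - 1.0) <= 1e-9
            assert not s.p[s.z == 0].any()


class TestRobustnessSuite:
    def test_zero_level_reproduces_clean_generator_bitwise(self, base_params):
        clean = generate_glv_dataset(base_params, 10, seed=17)
        for kind in ("interaction_noise", "measurement_noise"):
            suite = generate_robustness_suite(
                base_params, PerturbationSpec(kind, 0.0, seed=17), 10
            )
            assert np.array_equal(suite.P, clean.P), kind
            assert np.array_equal(suite.Z, clean.Z), kind

    def test_largest_reasonable_eta_level_generates_valid_data(self, base_params):
        """eta = 0.4 (the largest level at which prediction degrades
        gracefully) still yields a fully valid dataset."""
        suite = generate_robustness_suite(
            base_params, PerturbationSpec("interaction_noise", 0.4, seed=18), 15
        )
        assert suite.S == 15
        for s in suite:
            assert abs(s.p.sum() - 1.0) <= 1e-9 and (s.p >= 0).all()

    def test_measurement_noise_flips_presences_both_ways(self, base_params):
        clean = generate_glv_dataset(base_params, 10, seed=19)
        noisy = generate_robustness_suite(
            base_params, PerturbationSpec("measurement_noise", 0.05, seed=19), 10
        )
        # assemblage reflects the measurement: nonzero pattern of noisy p
        np.testing.assert_array_equal(noisy.Z, (noisy.P > 0).astype(np.int8))
        appeared = ((noisy.Z == 1) & (clean.P == 0)).any()
        vanished = ((noisy.Z == 0) & (clean.P > 0)).any()
        assert appeared and vanished

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            PerturbationSpec("gaussian_blur", 0.1)
        with pytest.raises(ValueError, match="level"):
            PerturbationSpec("interaction_noise", -0.1)
        with pytest.raises(ValueError):
            PerturbationSpec("multistability", 1.5)
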