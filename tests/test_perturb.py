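"""Selection indicators, disturbance laws, and the subsampling fits."""

import numpy as np
import pytest

from pertcox import (
    PerturbationScheme,
    SurvivalDataset,
    WeightRealization,
    ZeroEventSubsampleError,
    draw_perturbation,
    draw_selection,
    fit_weighted_cox,
    perturb_subsample_fit,
    repeated_perturb_fit,
)

from conftest import random_dataset


class TestScheme:
    def test_pi_n_and_variance_formulas(self):
        geo = PerturbationScheme("geometric", n=10_000, r=100)
        gam = PerturbationScheme("gamma", n=10_000, r=100)
        assert geo.pi_n == pytest.approx(0.01)
        assert geo.weight_variance == pytest.approx((1 - 0.01) / 0.01**2)
        assert gam.weight_variance == pytest.approx(1 / 0.01)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PerturbationScheme("uniform", n=10, r=1)
        with pytest.raises(ValueError):
            PerturbationScheme("gamma", n=10, r=11)
        with pytest.raises(ValueError):
            draw_selection(10, 0.0, np.random.default_rng(0))


class TestDraws:
    def test_degenerate_bernoulli_selects_all(self):
        delta = draw_selection(50, 1.0, np.random.default_rng(0))
        assert np.all(delta == 1)

    def test_degenerate_geometric_is_all_ones(self):
        scheme = PerturbationScheme("geometric", n=50, r=50)
        eta = draw_perturbation(50, scheme, np.random.default_rng(0))
        np.testing.assert_array_equal(eta, 1.0)

    def test_selected_count_is_binomial(self):
        # E(r*) = r with binomial fluctuations
        n, r, draws = 100_000, 1000, 500
        pi = r / n
        rng = np.random.default_rng(8)
        counts = [draw_selection(n, pi, rng).sum() for _ in range(draws)]
        se = np.sqrt(n * pi * (1 - pi) / draws)
        assert abs(np.mean(counts) - r) < 3 * se

    @pytest.mark.parametrize("family", ["geometric", "gamma"])
    def test_disturbance_mean_is_inverse_pi(self, family):
        n = 1_000_000
        scheme = PerturbationScheme(family, n=n, r=1000)
        eta = draw_perturbation(n, scheme, np.random.default_rng(9))
        se = np.sqrt(scheme.weight_variance / n)
        assert abs(eta.mean() - 1 / scheme.pi_n) < 5 * se
        assert np.all(eta >= 0)

    def test_geometric_variance(self):
        n = 1_000_000
        scheme = PerturbationScheme("geometric", n=n, r=10_000)
        eta = draw_perturbation(n, scheme, np.random.default_rng(10))
        target = scheme.weight_variance
        # relative sampling error of a variance over n draws ~ sqrt(kurt/n)
        assert abs(eta.var() / target - 1) < 0.05

    @pytest.mark.parametrize("family", ["geometric", "gamma"])
    def test_omega_has_unit_mean(self, family):
        n = 1_000_000
        scheme = PerturbationScheme(family, n=n, r=10_000)
        rng = np.random.default_rng(12)
        delta = draw_selection(n, scheme.pi_n, rng)
        eta = draw_perturbation(n, scheme, rng)
        omega = delta * eta
        var_omega = (1 + 1 / scheme.pi_n) - 1  # E w^2 = 1 + 1/pi
        assert abs(omega.mean() - 1.0) < 5 * np.sqrt(var_omega / n)

    def test_fixed_seed_is_bit_identical(self):
        scheme = PerturbationScheme("gamma", n=1000, r=50)
        a = draw_selection(1000, 0.05, np.random.default_rng(77))
        b = draw_selection(1000, 0.05, np.random.default_rng(77))
        np.testing.assert_array_equal(a, b)
        ea = draw_perturbation(1000, scheme, np.random.default_rng(78))
        eb = draw_perturbation(1000, scheme, np.random.default_rng(78))
        np.testing.assert_array_equal(ea, eb)


class TestWeightRealization:
    def test_omega_and_r_star_bookkeeping(self):
        real = WeightRealization(
            delta=np.array([1, 0, 1, 0]), eta=np.array([2.0, 3.0, 0.5, 1.0])
        )
        np.testing.assert_array_equal(real.omega, [2.0, 0.0, 0.5, 0.0])
        assert real.r_star == 2
        assert real.r_star == np.count_nonzero(real.omega > 0)


class TestSingleDrawFit:
    def test_pi_one_geometric_recovers_full_mle(self):
        rng = np.random.default_rng(14)
        data = random_dataset(rng, 300, 3)
        scheme = PerturbationScheme("geometric", n=300, r=300)
        fit, real = perturb_subsample_fit(
            data, scheme, np.random.default_rng(0)
        )
        assert real.r_star == 300
        np.testing.assert_array_equal(real.omega, 1.0)
        full = fit_weighted_cox(data)
        np.testing.assert_allclose(fit.beta, full.beta, atol=1e-12)

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(15)
        data = random_dataset(rng, 2000, 3)
        scheme = PerturbationScheme("gamma", n=2000, r=200)
        f1, r1 = perturb_subsample_fit(data, scheme, np.random.default_rng(5))
        f2, r2 = perturb_subsample_fit(data, scheme, np.random.default_rng(5))
        np.testing.assert_array_equal(f1.beta, f2.beta)
        np.testing.assert_array_equal(r1.omega, r2.omega)

    def test_zero_event_subsample_raises_after_one_redraw(self):
        # single event with tiny inclusion probability: both draws will
        # almost surely miss it
        times = np.linspace(1, 2, 400)
        status = np.zeros(400, dtype=int)
        status[0] = 1
        data = SurvivalDataset(times, status, np.ones((400, 1)))
        scheme = PerturbationScheme("gamma", n=400, r=1)
        with pytest.raises(ZeroEventSubsampleError):
            perturb_subsample_fit(data, scheme, np.random.default_rng(3))

    def test_estimate_tracks_full_mle_as_r_grows(self):
        """||beta_tilde - beta_hat_full|| shrinks with r at fixed n."""
        rng = np.random.default_rng(16)
        data = random_dataset(rng, 20_000, 3, censor=0.2)
        full = fit_weighted_cox(data).beta
        med = {}
        for r in (400, 1000, 4000):
            scheme = PerturbationScheme("gamma", n=20_000, r=r)
            errs = []
            for seed in range(15):
                fit, _ = perturb_subsample_fit(
                    data, scheme, np.random.default_rng(100 + seed)
                )
                errs.append(np.linalg.norm(fit.beta - full))
            med[r] = np.median(errs)
        assert med[400] > med[1000] > med[4000]


class TestRepeatedDrawFit:
    def test_m1_equals_single_run_with_same_stream(self):
        rng = np.random.default_rng(18)
        data = random_dataset(rng, 1000, 2)
        scheme = PerturbationScheme("gamma", n=1000, r=200)
        agg = repeated_perturb_fit(data, scheme, 1, np.random.default_rng(2))
        single, _ = perturb_subsample_fit(
            data, scheme, np.random.default_rng(2)
        )
        np.testing.assert_array_equal(agg.beta_M, single.beta)

    def test_beta_m_is_mean_and_permutation_symmetric(self):
        rng = np.random.default_rng(19)
        data = random_dataset(rng, 1500, 2)
        scheme = PerturbationScheme("gamma", n=1500, r=300)
        agg = repeated_perturb_fit(data, scheme, 5, np.random.default_rng(4))
        betas = np.array([f.beta for f in agg.per_replicate if f.converged])
        np.testing.assert_allclose(agg.beta_M, betas.mean(axis=0))
        perm = np.random.default_rng(0).permutation(len(betas))
        np.testing.assert_allclose(agg.beta_M, betas[perm].mean(axis=0))

    def test_averaging_reduces_variance(self):
        """Across outer seeds, beta_M with M=5 disperses less than M=1."""
        rng = np.random.default_rng(20)
        data = random_dataset(rng, 4000, 2, censor=0.2)
        scheme = PerturbationScheme("gamma", n=4000, r=300)
        singles, aggs = [], []
        for seed in range(25):
            fit, _ = perturb_subsample_fit(
                data, scheme, np.random.default_rng(500 + seed)
            )
            singles.append(fit.beta)
            agg = repeated_perturb_fit(
                data, scheme, 5, np.random.default_rng(900 + seed)
            )
            aggs.append(agg.beta_M)
        var_single = np.var(singles, axis=0).sum()
        var_agg = np.var(aggs, axis=0).sum()
        assert var_agg < var_single

    def test_invalid_m_rejected(self):
        rng = np.random.default_rng(22)
        data = random_dataset(rng, 100, 2)
        scheme = PerturbationScheme("gamma", n=100, r=20)
        with pytest.raises(ValueError):
            repeated_perturb_fit(data, scheme, 0, np.random.default_rng(0))
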