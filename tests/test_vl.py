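"""Variational Laplace engine: hyperpriors, free energy, fitting."""

import warnings

import numpy as np
import pytest
from scipy.stats import wishart

from vrsa import default_hyperprior, fit_vl, free_energy
from vrsa.components import ComponentSet, Contrast, HypothesisMatrix, contrast_to_component
from vrsa.second_order import SecondOrderData, reduce_to_second_order
from vrsa.simulate import SimulationConfig, design_components, simulate_dataset
from vrsa.vl import GaussianDensity, _log_joint, _projected


def make_so(S_bar, upsilon):
    S_bar = np.atleast_2d(S_bar)
    k = S_bar.shape[0]
    return SecondOrderData(S=S_bar * upsilon, Ce=np.eye(k), R=np.eye(k),
                           upsilon=upsilon, n_voxels=int(upsilon))


def single_component_problem(rng, k=6, scale=2.0, noise=1.0, upsilon=200.0):
    c = rng.standard_normal(k)
    c /= np.linalg.norm(c)
    C = np.outer(c, c)
    truth = scale * C + noise * np.eye(k)
    S = wishart.rvs(df=int(upsilon), scale=truth, random_state=rng)
    so = SecondOrderData(S=S, Ce=np.eye(k), R=np.eye(k), upsilon=upsilon,
                         n_voxels=int(upsilon))
    comps = ComponentSet([HypothesisMatrix(C, "effect")]).with_noise(np.eye(k))
    return so, comps


class TestHyperprior:
    def test_defaults(self):
        p = default_hyperprior(4)
        np.testing.assert_array_equal(p.mean, [-16.0] * 4)
        np.testing.assert_array_equal(p.cov, 128.0 * np.eye(4))

    def test_prior_scale_expectation_is_tiny(self):
        # the shrinkage prior puts the expected scale at exp(-16) ~ 1.12e-7
        assert np.exp(default_hyperprior(1).mean[0]) == pytest.approx(1.12e-7,
                                                                      rel=5e-3)

    def test_needs_at_least_one(self):
        with pytest.raises(ValueError):
            default_hyperprior(0)


class TestFreeEnergy:
    def test_prior_coincidence_reduces_to_accuracy(self):
        S_bar = np.array([[2.0, 0.3], [0.3, 1.0]])
        so = make_so(S_bar, 50.0)
        comps = ComponentSet([HypothesisMatrix(np.eye(2), "noise")],
                             includes_noise=True)
        prior = GaussianDensity([0.5], [[4.0]])
        q = GaussianDensity(prior.mean, prior.cov)
        F = free_energy(q, so, comps, prior)
        Sh = np.exp(0.5) * np.eye(2)
        expected = -0.5 * 50.0 * (np.trace(np.linalg.inv(Sh) @ S_bar)
                                  + np.linalg.slogdet(Sh)[1])
        assert F == pytest.approx(expected)

    def test_scalar_mode_at_data_value(self):
        # S_bar = [2] with one free component: the joint objective peaks where
        # exp(lambda) = 2 (up to the weak shrinkage prior pull)
        so = make_so([[2.0]], 200.0)
        comps = ComponentSet([HypothesisMatrix([[1.0]], "c")])
        prior = default_hyperprior(1)
        fit = fit_vl(so, comps, prior)
        Sb, Cs = _projected(so, comps)
        grid = np.arange(-2.0, 3.0, 0.001)
        vals = [_log_joint(np.array([g]), Sb, Cs, 200.0, prior.mean,
                           prior.precision()) for g in grid]
        best = grid[int(np.argmax(vals))]
        assert abs(fit.posterior.mean[0] - best) < 0.01
        assert np.exp(best) == pytest.approx(2.0, rel=0.05)

    def test_sign_of_difference_matches_grid(self):
        so = make_so([[3.0]], 80.0)
        comps = ComponentSet([HypothesisMatrix([[1.0]], "c")])
        prior = default_hyperprior(1)
        q_cov = [[0.1]]
        for a, b in [(-1.0, 1.0), (1.5, 0.9), (0.0, 2.0)]:
            Fa = free_energy(GaussianDensity([a], q_cov), so, comps, prior)
            Fb = free_energy(GaussianDensity([b], q_cov), so, comps, prior)
            Sb_, Cs = _projected(so, comps)
            Ja = _log_joint(np.array([a]), Sb_, Cs, 80.0, prior.mean,
                            prior.precision())
            Jb = _log_joint(np.array([b]), Sb_, Cs, 80.0, prior.mean,
                            prior.precision())
            assert np.sign(Fa - Fb) == np.sign(Ja - Jb)


class TestFit:
    def test_mode_matches_grid_argmax(self, rng):
        so, comps = single_component_problem(rng)
        prior = default_hyperprior(2)
        fit = fit_vl(so, comps, prior)
        # profile the joint over the effect hyperparameter with the noise
        # hyperparameter held at its fitted mode
        Sb, Cs = _projected(so, comps)
        mu_noise = fit.posterior.mean[1]
        grid = np.arange(fit.posterior.mean[0] - 0.5,
                         fit.posterior.mean[0] + 0.5, 0.001)
        vals = [_log_joint(np.array([g, mu_noise]), Sb, Cs, so.upsilon,
                           prior.mean, prior.precision()) for g in grid]
        assert abs(grid[int(np.argmax(vals))] - fit.posterior.mean[0]) < 0.01

    def test_absent_component_shrinks_to_prior(self):
        # second moment carrying no trace of the declared component: its
        # scale collapses to the shrinkage prior's exp(-16) ~ 0
        k = 5
        so = make_so(np.eye(k), 150.0)
        c = np.zeros(k)
        c[0] = 1.0
        comps = ComponentSet([contrast_to_component(Contrast(c, "absent"))]
                             ).with_noise(np.eye(k))
        fit = fit_vl(so, comps, default_hyperprior(2))
        assert np.exp(fit.posterior.mean[0]) < 1e-4
        assert np.exp(fit.posterior.mean[1]) == pytest.approx(1.0, rel=0.05)

    def test_trajectory_nondecreasing_and_convergence(self, rng):
        so, comps = single_component_problem(rng)
        fit = fit_vl(so, comps, default_hyperprior(2))
        assert fit.converged
        assert np.all(np.diff(fit.trajectory) >= -1e-9)

    def test_posterior_no_wider_than_prior(self, rng):
        so, comps = single_component_problem(rng)
        prior = default_hyperprior(2)
        fit = fit_vl(so, comps, prior)
        assert np.trace(fit.posterior.cov) <= np.trace(prior.cov)

    def test_nonconvergence_warns(self, rng):
        so, comps = single_component_problem(rng)
        with pytest.warns(RuntimeWarning, match="converge"):
            fit = fit_vl(so, comps, default_hyperprior(2), max_iter=2, tol=1e-12)
        assert not fit.converged

    def test_dimension_mismatches_rejected(self, rng):
        so, comps = single_component_problem(rng)
        with pytest.raises(ValueError, match="prior dimension"):
            fit_vl(so, comps, default_hyperprior(3))
        bad = ComponentSet([HypothesisMatrix(np.eye(3), "c")])
        with pytest.raises(ValueError, match="dimension"):
            fit_vl(so, bad, default_hyperprior(1))

    def test_two_factor_simulation_recovers_pattern(self, study):
        # both main effects estimated present, interaction near zero
        for fit in study["fits"]:
            v = np.exp(fit.posterior.mean)
            assert v[0] > 0.3 and v[1] > 0.3
            assert v[2] < 0.05


class TestNoiseAndSmoothness:
    def test_noise_doubling_quadruples_noise_scale_only(self):
        # same data, noise sd scaled by two: noise variance ~x4, effect
        # posteriors move by less than half their 90% CI width
        reps = 6
        base_mu, doubled_mu, widths, noise_ratio = [], [], [], []
        for rep in range(reps):
            fits = {}
            for sd in (1.0, 2.0):
                cfg = SimulationConfig(n_subjects=1, noise_sd=sd,
                                       seed=500 + rep)
                d = simulate_dataset(cfg)[0]
                so = reduce_to_second_order(d, centre_rows=True)
                comps = design_components().with_noise(so.Ce)
                fits[sd] = fit_vl(so, comps, default_hyperprior(4))
            lo, hi = fits[1.0].posterior.credible_interval(0.90)
            widths.append((hi - lo)[:2])
            base_mu.append(fits[1.0].posterior.mean[:2])
            doubled_mu.append(fits[2.0].posterior.mean[:2])
            noise_ratio.append(np.exp(fits[2.0].posterior.mean[-1]
                                      - fits[1.0].posterior.mean[-1]))
        shift = np.abs(np.array(doubled_mu) - np.array(base_mu))
        assert np.all(shift.mean(axis=0) < 0.5 * np.array(widths).mean(axis=0))
        assert np.mean(noise_ratio) == pytest.approx(4.0, rel=0.25)

    def test_smoothness_reduces_efficiency(self):
        # one-voxel smoothing vs an eighth of a voxel: posterior variance of
        # the effect hyperparameters strictly increases (paired by seed)
        deltas = []
        for rep in range(8):
            var = {}
            for sd in (0.125, 1.0):
                cfg = SimulationConfig(n_subjects=1, noise_sd=1.0,
                                       smooth_sd_voxels=sd, seed=900 + rep)
                d = simulate_dataset(cfg)[0]
                so = reduce_to_second_order(d, centre_rows=True)
                comps = design_components().with_noise(so.Ce)
                fit = fit_vl(so, comps, default_hyperprior(4))
                var[sd] = np.diag(fit.posterior.cov)[:2].mean()
            deltas.append(var[1.0] - var[0.125])
        assert np.all(np.array(deltas) > 0)
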