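"""Bayesian model reduction, component scoring and exclusive selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vrsa import default_hyperprior, fit_vl
from vrsa.bmr import (bayesian_model_reduction, component_evidence,
                      exclusive_selection, softmax_probabilities)
from vrsa.vl import GaussianDensity
from test_vl import single_component_problem


class TestReduction:
    def test_identity_reduction_is_neutral(self, rng):
        post = GaussianDensity(rng.standard_normal(3),
                               np.diag(rng.uniform(0.1, 1.0, 3)))
        prior = default_hyperprior(3)
        rm = bayesian_model_reduction(post, prior, prior)
        assert rm.delta_F == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(rm.reduced_posterior.mean, post.mean,
                                   atol=1e-10)

    def test_v5_motion_posterior_probability(self):
        # printed marginal LN(-2.09, 0.49) under prior (-16, 128): switching
        # the component off is overwhelmingly rejected
        rm = bayesian_model_reduction(GaussianDensity([-2.09], [[0.49]]),
                                      GaussianDensity([-16.0], [[128.0]]),
                                      GaussianDensity([-16.0], [[1 / 128]]))
        p = softmax_probabilities([rm.delta_F, 0.0])[0]
        assert round(p, 2) == 1.00

    def test_v5_attention_posterior_probability(self):
        # printed marginal LN(-17.89, 128): the data say nothing, p = 0.5
        rm = bayesian_model_reduction(GaussianDensity([-17.89], [[128.0]]),
                                      GaussianDensity([-16.0], [[128.0]]),
                                      GaussianDensity([-16.0], [[1 / 128]]))
        p = softmax_probabilities([rm.delta_F, 0.0])[0]
        assert round(p, 1) == 0.5

    def test_matches_direct_refit(self, rng):
        # the analytic evidence change agrees with refitting under the
        # reduced prior, within the Laplace regime
        so, comps = single_component_problem(rng)
        prior = default_hyperprior(2)
        fit = fit_vl(so, comps, prior)
        for mean, var in [((0.0, -16.0), (8.0, 128.0)),
                          ((-16.0, -16.0), (64.0, 128.0)),
                          ((-14.0, -16.0), (128.0, 128.0))]:
            reduced = GaussianDensity(list(mean), np.diag(list(var)))
            rm = bayesian_model_reduction(fit.posterior, prior, reduced)
            refit = fit.free_energy - fit_vl(so, comps, reduced).free_energy
            assert rm.delta_F == pytest.approx(refit, abs=0.1)

    def test_chained_reductions_compose(self, rng):
        so, comps = single_component_problem(rng)
        prior = default_hyperprior(2)
        fit = fit_vl(so, comps, prior)
        redA = GaussianDensity([-16.0, -16.0], np.diag([1 / 128, 128.0]))
        redAB = GaussianDensity([-16.0, -16.0], np.diag([1 / 128, 1 / 128]))
        rmA = bayesian_model_reduction(fit.posterior, prior, redA)
        rmB = bayesian_model_reduction(rmA.reduced_posterior, redA, redAB)
        rmAB = bayesian_model_reduction(fit.posterior, prior, redAB)
        assert rmA.delta_F + rmB.delta_F == pytest.approx(rmAB.delta_F,
                                                          abs=1e-8)

    def test_inadmissible_reduction_rejected(self):
        post = GaussianDensity([0.0], [[10.0]])  # wider than the prior
        prior = GaussianDensity([0.0], [[1.0]])
        wide = GaussianDensity([0.0], [[1e6]])
        with pytest.raises(ValueError, match="inadmissible|positive definite"):
            bayesian_model_reduction(post, prior, wide)


class TestSoftmax:
    def test_known_triplet(self):
        p = softmax_probabilities([0.0, -5.0, -10.0])
        assert p[0] == pytest.approx(0.9933, abs=1e-4)

    def test_delta_f_three_is_twenty_to_one(self):
        p = softmax_probabilities([3.0, 0.0])
        assert round(p[0] / p[1]) == 20

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=6),
           st.floats(-100, 100))
    def test_shift_invariance(self, les, shift):
        a = softmax_probabilities(les)
        b = softmax_probabilities([x + shift for x in les])
        np.testing.assert_allclose(a, b, atol=1e-12)
        assert a.sum() == pytest.approx(1.0, abs=1e-12)


class TestComponentEvidence:
    def test_uninformative_posterior_gives_half(self):
        prior = default_hyperprior(2)
        from vrsa.vl import FitResult
        fit = FitResult(posterior=GaussianDensity(prior.mean, prior.cov),
                        free_energy=0.0, predicted_S=np.eye(2),
                        n_iterations=1, converged=True, labels=["a", "noise"])
        tab = component_evidence(fit, prior)
        assert tab.kind == "per_component"
        assert tab.probabilities[0] == pytest.approx(0.5, abs=1e-3)

    def test_simulated_study_pattern(self, study):
        # both main effects decisively present, interaction not
        tab = component_evidence(study["fits"][0], study["prior"])
        assert tab.labels == ["parametric", "categorical", "interaction"]
        assert tab.log_evidences[0] > 3 and tab.log_evidences[1] > 3
        assert tab.log_evidences[2] < 3


class TestExclusiveSelection:
    def test_symmetric_components_split_evenly(self, rng):
        # two identical orthogonal effects with identical expression
        from scipy.stats import wishart
        from vrsa.components import ComponentSet, HypothesisMatrix
        from vrsa.second_order import SecondOrderData
        k = 4
        C1 = np.diag([1.0, 0, 0, 0])
        C2 = np.diag([0, 1.0, 0, 0])
        truth = C1 + C2 + np.eye(k)
        S = truth * 300.0  # expected second moment: exactly symmetric roles
        so = SecondOrderData(S=S, Ce=np.eye(k), R=np.eye(k), upsilon=300.0,
                             n_voxels=300)
        comps = ComponentSet([HypothesisMatrix(C1, "a"),
                              HypothesisMatrix(C2, "b")]).with_noise(np.eye(k))
        fit = fit_vl(so, comps, default_hyperprior(3))
        tab = exclusive_selection(fit, default_hyperprior(3))
        np.testing.assert_allclose(tab.probabilities, [0.5, 0.5], atol=1e-6)

    def test_mass_splits_between_true_effects(self, study):
        tab = exclusive_selection(study["fits"][0], study["prior"])
        probs = dict(zip(tab.labels, tab.probabilities))
        assert probs["interaction"] < 0.01
        assert probs["parametric"] + probs["categorical"] > 0.99
        assert abs(tab.probabilities.sum() - 1.0) < 1e-12

    def test_requires_two_effects(self, study):
        from vrsa.vl import FitResult
        fit = FitResult(posterior=GaussianDensity([0.0, 0.0], np.eye(2)),
                        free_energy=0.0, predicted_S=np.eye(2),
                        n_iterations=1, converged=True, labels=["a", "noise"])
        with pytest.raises(ValueError, match="two effect"):
            exclusive_selection(fit, default_hyperprior(2))
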