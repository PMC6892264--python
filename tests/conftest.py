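"""Shared fixtures: a small simulated multi-subject study and its fits."""

import numpy as np
import pytest

from vrsa import default_hyperprior, fit_vl, reduce_to_second_order
from vrsa.simulate import SimulationConfig, design_components, simulate_dataset


@pytest.fixture(scope="session")
def study():
    """Eight subjects from the two-factor design (both main effects present,
    no interaction), with per-subject variational fits."""
    cfg = SimulationConfig(seed=7)
    data = simulate_dataset(cfg)
    prior = default_hyperprior(4)
    fits = []
    for d in data:
        so = reduce_to_second_order(d, centre_rows=True)
        comps = design_components(cfg.n_conditions).with_noise(so.Ce)
        fits.append(fit_vl(so, comps, prior))
    return {"config": cfg, "data": data, "prior": prior, "fits": fits}


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_psd(rng, dim, rank=None):
    """A random symmetric PSD matrix with controllable rank."""
    rank = rank or dim
    A = rng.standard_normal((dim, rank))
    return A @ A.T
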