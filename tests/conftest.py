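import numpy as np
import pandas as pd
import pytest

from veindemog import synthgen as sg


@pytest.fixture(scope="session")
def small_community():
    """20-species community with known parameters and a 5-yr census."""
    hyper = sg.CommunityHyperparams(sigma_obs=0.02)
    params = sg.gen_species_params(20, hyper, seed=101)
    census = sg.gen_census(params, n_per_species=200, interval=5.0, hyper=hyper, seed=101)
    return hyper, params, census


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def brute_force_nearest(mask_from: np.ndarray, mask_to: np.ndarray) -> float:
    """O(N^2) oracle: mean over mask_from pixels of the Euclidean distance
    between pixel centers to the nearest mask_to pixel."""
    src = np.argwhere(mask_from).astype(float)
    dst = np.argwhere(mask_to).astype(float)
    d2 = ((src[:, None, :] - dst[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min(axis=1)).mean())


def brute_force_tau_b(x: np.ndarray, y: np.ndarray) -> float:
    """O(n^2) concordant/discordant count with tie correction."""
    n = len(x)
    s = n1 = n2 = 0
    npairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            npairs += 1
            dx = np.sign(x[i] - x[j])
            dy = np.sign(y[i] - y[j])
            s += dx * dy
            n1 += dx == 0
            n2 += dy == 0
    return s / np.sqrt((npairs - n1) * (npairs - n2))
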