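import numpy as np
import pytest

import modedif as md
from modedif.util import spawn_seeds


@pytest.fixture(scope="session")
def calibrated_1pl():
    """A 1PL bank with its P&P sample and ML calibration (shared, read-only)."""
    seeds = spawn_seeds(0, 3)
    bank = md.generate_bank("1PL", 100, seeds[0])
    sample = md.sample_persons(500, 0.0, seeds[1])
    responses = md.generate_responses(bank, sample, seeds[2])
    calib = md.calibrate(responses, "1PL")
    return bank, sample, responses, calib


@pytest.fixture(scope="session")
def small_mode_data():
    """A small no-DIF P&P / CAT pair with known abilities for sampler tests.

    20 items, 250 persons per mode, both fully observed (so every item has
    high 'usage'), item 7 shifted by +0.63 logits in the CAT mode only.
    """
    rng = np.random.default_rng(99)
    n_items, n_per_mode = 20, 250
    beta = np.linspace(-2.0, 2.0, n_items)
    alpha = np.ones(n_items)
    shift = np.zeros(n_items)
    shift[7] = 0.63
    th_pp = rng.standard_normal(n_per_mode)
    th_cat = rng.standard_normal(n_per_mode)
    p_pp = md.response_prob(th_pp[:, None], alpha, beta)
    p_cat = md.response_prob(th_cat[:, None], alpha, beta + shift)
    pp = md.ResponseMatrix((rng.random(p_pp.shape) < p_pp).astype(np.uint8), mode="PP")
    cat = md.ResponseMatrix((rng.random(p_cat.shape) < p_cat).astype(np.uint8), mode="CAT")
    return dict(
        pp=pp, cat=cat, alpha=alpha, beta=beta, shift=shift,
        theta_true=np.concatenate([th_pp, th_cat]), dif_item=7,
    )
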