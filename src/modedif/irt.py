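"""Dichotomous 1PL/2PL item response model.

The probability that respondent *i* endorses item *j* follows the
two-parameter logistic (2PL) model

    P(Y_ij = 1 | theta_i, alpha_j, beta_j)
        = exp(D * alpha_j * (theta_i - beta_j))
          / (1 + exp(D * alpha_j * (theta_i - beta_j)))

with discrimination ``alpha_j > 0``, difficulty ``beta_j`` (logits), latent
trait ``theta_i`` (logits) and the scaling constant ``D = 1.702`` that makes
the logistic curve nearly coincide with the normal-ogive model.  The 1PL
model is the special case where all discriminations are equal.  The same
``D`` is applied everywhere (data generation, calibration, CAT scoring and
the Bayesian samplers) so that all difficulties live on a single metric.

All functions broadcast over numpy arrays; ``ItemParams`` is a lightweight
record used at module boundaries and can be splatted into the array API
(``response_prob(theta, *item)``).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy.special import expit

#: Logistic-to-normal-ogive scaling constant, fixed in every model evaluation.
D = 1.702

#: Ability estimates are confined to this interval; response patterns with no
#: finite MLE (all endorsed / none endorsed) are clamped to the boundary.
THETA_BOUNDS = (-4.0, 4.0)


class ItemParams(NamedTuple):
    """Discrimination and difficulty of one dichotomous item."""

    alpha: float
    beta: float


class Ability(NamedTuple):
    """Point estimate of the latent trait and its information-based SE."""

    theta: float
    se: float


def _validate(theta, alpha, beta) -> None:
    theta, alpha, beta = np.asarray(theta), np.asarray(alpha), np.asarray(beta)
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta must be finite")
    if not np.all(np.isfinite(alpha)) or not np.all(alpha > 0):
        raise ValueError("alpha must be finite and > 0")


def response_prob(theta, alpha, beta):
    """Endorsement probability under the 2PL model (1PL when alpha == 1).

    Parameters broadcast; returns values strictly inside (0, 1) for finite
    inputs, increasing in ``theta`` and decreasing in ``beta``.
    """
    _validate(theta, alpha, beta)
    return _prob(theta, alpha, beta)


def _prob(theta, alpha, beta):
    # unchecked hot path used by the simulation loops
    return expit(D * np.asarray(alpha) * (np.asarray(theta) - np.asarray(beta)))


def item_information(theta, alpha, beta):
    """Fisher information of one response, ``D^2 alpha^2 P (1 - P)``.

    Maximal at ``theta == beta``; symmetric about the item difficulty.
    """
    _validate(theta, alpha, beta)
    p = _prob(theta, alpha, beta)
    return (D * np.asarray(alpha)) ** 2 * p * (1.0 - p)


def _score_theta(theta, y, alpha, beta, mask=None):
    """d/d theta of the Bernoulli log-likelihood; decreasing in theta."""
    p = _prob(theta[:, None], alpha, beta)
    g = D * alpha * (y - p)
    if mask is not None:
        g = g * mask
    return g.sum(axis=-1)


def ml_theta_batch(y, alpha, beta, mask=None, bounds=THETA_BOUNDS, n_bisect=54):
    """Row-wise ML ability estimates for a response matrix.

    ``y`` is (n_persons, n_items) in {0, 1}; ``alpha``/``beta`` are either
    (n_items,) shared across rows or (n_persons, n_items) per-row (as in CAT
    where each person saw different items).  ``mask`` marks observed cells.

    The log-likelihood is concave in theta, so its derivative is monotone
    decreasing and the root is found by bisection on ``bounds``.  Patterns
    whose score does not change sign on the interval (all / none endorsed,
    or extreme trait levels) are clamped to the nearer boundary.  Returns
    ``(theta, se)`` with ``se = 1 / sqrt(total information at theta)``.
    """
    y = np.asarray(y, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), y.shape)
    beta = np.broadcast_to(np.asarray(beta, dtype=float), y.shape)
    if mask is not None:
        mask = np.broadcast_to(np.asarray(mask, dtype=float), y.shape)
        if not np.all(mask.sum(axis=1) >= 1):
            raise ValueError("every person needs at least one observed response")
    elif y.shape[1] < 1:
        raise ValueError("empty response vector")

    n = y.shape[0]
    lo = np.full(n, bounds[0])
    hi = np.full(n, bounds[1])
    s_lo = _score_theta(lo, y, alpha, beta, mask)
    s_hi = _score_theta(hi, y, alpha, beta, mask)
    at_lo = s_lo <= 0  # likelihood decreasing everywhere -> clamp low
    at_hi = s_hi >= 0  # increasing everywhere -> clamp high
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        s_mid = _score_theta(mid, y, alpha, beta, mask)
        take_hi = s_mid > 0
        lo = np.where(take_hi, mid, lo)
        hi = np.where(take_hi, hi, mid)
    theta = 0.5 * (lo + hi)
    theta[at_lo] = bounds[0]
    theta[at_hi] = bounds[1]

    p = _prob(theta[:, None], alpha, beta)
    info = (D * alpha) ** 2 * p * (1.0 - p)
    if mask is not None:
        info = info * mask
    total = info.sum(axis=1)
    with np.errstate(divide="ignore"):
        se = 1.0 / np.sqrt(total)
    return theta, se


def ml_theta(responses, alpha, beta, bounds=THETA_BOUNDS) -> Ability:
    """ML ability estimate from one response vector.

    ``responses`` in {0, 1}; ``alpha``/``beta`` aligned per item.  All-endorsed
    or none-endorsed patterns have no finite maximum and are clamped to the
    interval boundary (default +/- 4.0, covering the generating range +/- 3
    with margin) so that adaptive testing can proceed from the first item.
    """
    responses = np.atleast_1d(np.asarray(responses, dtype=float))
    if responses.size == 0:
        raise ValueError("empty response vector")
    if not np.all(np.isin(responses, (0.0, 1.0))):
        raise ValueError("responses must be coded 0/1")
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), responses.shape)
    beta = np.broadcast_to(np.asarray(beta, dtype=float), responses.shape)
    _validate(0.0, alpha, beta)
    theta, se = ml_theta_batch(responses[None, :], alpha, beta, bounds=bounds)
    return Ability(float(theta[0]), float(se[0]))
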