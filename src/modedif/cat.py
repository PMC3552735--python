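"""Fixed-length computerized adaptive test (CAT) simulation.

The engine replays a pre-generated complete response matrix through an
adaptive administration: at each step the unused item with maximum Fisher
information at the current ability estimate is selected (ties broken by
lowest item index), the simulee's pre-generated response to that item is
revealed, and the ability is re-estimated by maximum likelihood over the
items administered so far.  Selection and scoring use the *calibrated* P&P
item parameters, while the replayed responses were generated under the
(possibly DIF-perturbed) generating parameters — exactly the situation in
which item-level mode effects corrupt an operational CAT.

Administration stops after a fixed test length (30 items by default).  The
engine also scores every simulee on the full bank, giving the
full-instrument ability benchmark that CAT estimates are correlated
against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .banks import ItemBank, PersonSample, ResponseMatrix, generate_responses
from .irt import D, _prob, item_information, ml_theta_batch
from .util import as_rng

__all__ = [
    "CatConfig",
    "CatResult",
    "select_next",
    "simulate_cat",
    "run_cat",
    "usage_counts",
]


@dataclass(frozen=True)
class CatConfig:
    """Fixed-length CAT settings: 30 items, start at theta = 0, ML scoring."""

    test_length: int = 30
    theta_init: float = 0.0
    bounds: tuple = (-4.0, 4.0)


@dataclass
class CatResult:
    """Batch CAT output: item routes, responses and ability estimates."""

    administered: np.ndarray  # (n_persons, test_length) item indices, in order
    responses: np.ndarray  # (n_persons, test_length) in {0, 1}
    theta: np.ndarray  # final CAT ML ability
    se: np.ndarray  # information-based SE at the final ability
    theta_full: np.ndarray  # ML ability from the complete item bank
    se_full: np.ndarray
    n_items: int  # bank size

    @property
    def n_persons(self) -> int:
        return self.administered.shape[0]

    @property
    def test_length(self) -> int:
        return self.administered.shape[1]

    def to_response_matrix(self) -> ResponseMatrix:
        """Sparse persons x bank matrix with mask marking administered cells."""
        n, j = self.n_persons, self.n_items
        values = np.zeros((n, j), dtype=np.uint8)
        mask = np.zeros((n, j), dtype=bool)
        rows = np.repeat(np.arange(n), self.test_length)
        cols = self.administered.ravel()
        values[rows, cols] = self.responses.ravel()
        mask[rows, cols] = True
        return ResponseMatrix(values=values, mask=mask, mode="CAT")


def select_next(theta: float, alpha, beta, used) -> int:
    """Index of the unused item with maximum Fisher information at theta.

    ``used`` is an iterable of already-administered item indices.  Ties are
    broken deterministically by the lowest index (numpy argmax convention).
    """
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    info = np.asarray(item_information(theta, alpha, beta), dtype=float)
    used = np.asarray(list(used), dtype=int)
    if used.size >= info.size:
        raise ValueError("all items have been used")
    if used.size:
        info[used] = -np.inf
    return int(np.argmax(info))


def simulate_cat(full_responses, est_alpha, est_beta, config: CatConfig = CatConfig()):
    """Run the adaptive test for every row of a complete response matrix.

    ``full_responses`` is an (n_persons, n_items) 0/1 array (or a fully
    observed :class:`ResponseMatrix`) generated beforehand under the
    CAT-mode generating parameters; ``est_alpha``/``est_beta`` are the
    calibrated P&P parameters used for both item selection and ML scoring.
    The simulation is deterministic given its inputs.
    """
    if isinstance(full_responses, ResponseMatrix):
        if not full_responses.fully_observed:
            raise ValueError("simulate_cat needs the complete response matrix")
        y_full = full_responses.values.astype(float)
    else:
        y_full = np.asarray(full_responses, dtype=float)
    n, j = y_full.shape
    a = np.asarray(est_alpha, dtype=float)
    b = np.asarray(est_beta, dtype=float)
    if a.shape != (j,) or b.shape != (j,):
        raise ValueError("item parameter length does not match the bank")
    if not np.all(np.isfinite(a)) or not np.all(np.isfinite(b)):
        raise ValueError("calibrated parameters must be finite")
    length = config.test_length
    if length > j:
        raise ValueError("test_length exceeds the bank size")

    theta = np.full(n, config.theta_init, dtype=float)
    used = np.zeros((n, j), dtype=bool)
    administered = np.zeros((n, length), dtype=int)
    responses = np.zeros((n, length), dtype=np.uint8)
    rows = np.arange(n)
    se = np.full(n, np.inf)

    for t in range(length):
        p = _prob(theta[:, None], a[None, :], b[None, :])
        info = (D * a[None, :]) ** 2 * p * (1.0 - p)
        info[used] = -np.inf
        j_next = np.argmax(info, axis=1)  # first max -> lowest-index tie-break
        administered[:, t] = j_next
        responses[:, t] = y_full[rows, j_next]
        used[rows, j_next] = True
        adm = administered[:, : t + 1]
        theta, se = ml_theta_batch(
            responses[:, : t + 1].astype(float), a[adm], b[adm], bounds=config.bounds
        )

    theta_full, se_full = ml_theta_batch(y_full, a, b, bounds=config.bounds)
    return CatResult(
        administered=administered,
        responses=responses,
        theta=theta,
        se=se,
        theta_full=theta_full,
        se_full=se_full,
        n_items=j,
    )


def run_cat(
    bank: ItemBank,
    truth_theta: float,
    est_alpha,
    est_beta,
    config: CatConfig = CatConfig(),
    seed=None,
):
    """Convenience single-simulee CAT.

    Generates the simulee's complete response vector under the bank's
    DIF-perturbed generating parameters (``beta + dif_shift``, true alpha)
    and replays it through :func:`simulate_cat` using the calibrated
    parameters for selection and scoring.
    """
    rng = as_rng(seed)
    sample = PersonSample(thetas=np.asarray([truth_theta], dtype=float), mu=truth_theta)
    full = generate_responses(bank, sample, rng, use_dif=True)
    return simulate_cat(full, est_alpha, est_beta, config)


def usage_counts(administered, n_items: int) -> np.ndarray:
    """Per-item administration counts; sums to n_persons * test_length.

    ``administered`` is the (n_persons, test_length) index array of a
    :class:`CatResult` (or a list of such rows).
    """
    adm = np.asarray(administered, dtype=int)
    if adm.size == 0:
        return np.zeros(n_items, dtype=int)
    return np.bincount(adm.ravel(), minlength=n_items)
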