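"""Synthetic item banks, person samples and response matrices.

This module generates the study conditions used throughout the package:

* 100-item banks with difficulties drawn uniformly from the 25-point grid
  -3.0, -2.75, ..., +3.0 logits.  Under the 1PL model every discrimination
  is exactly 1.0; under the 2PL model discriminations are drawn from a
  lognormal(log-mean 0, log-SD 0.5) distribution and redrawn until
  they fall in [0.5, 2.5] (rejection rather than clipping, which would pile
  mass on the bounds).
* person samples theta ~ N(mu, 1), with mu = 0 for the paper-and-pencil
  (P&P) validation sample and mu in {0, 1} for the CAT sample.
* complete Bernoulli response matrices under the 2PL response function.
* uniform mode-DIF injection: a chosen percentage of items receives a
  difficulty shift of +/- magnitude (fair-coin sign), emulating items that
  become harder or easier to endorse when administered by CAT.

The conventional DIF magnitudes 0.42 and 0.63 logits correspond to the ETS
"B" (moderate) and "C" (large) DIF classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace, field

import numpy as np
import pandas as pd

from .irt import _prob
from .util import as_rng

#: The difficulty grid: -3.0 to 3.0 logits in 0.25-logit increments.
BETA_GRID = np.round(np.arange(-12, 13) * 0.25, 2)

#: Conventional ETS B/C DIF magnitudes in logits.
DIF_MAGNITUDES = (0.42, 0.63)

ALPHA_RANGE = (0.5, 2.5)
ALPHA_LOG_SD = 0.5


@dataclass
class ItemBank:
    """True generating parameters of an item bank plus DIF annotations."""

    alpha: np.ndarray
    beta: np.ndarray
    model: str  # "1PL" | "2PL"
    dif_flags: np.ndarray = field(default=None)
    dif_shift: np.ndarray = field(default=None)

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.dif_flags is None:
            self.dif_flags = np.zeros(self.n_items, dtype=bool)
        if self.dif_shift is None:
            self.dif_shift = np.zeros(self.n_items, dtype=float)
        self.dif_flags = np.asarray(self.dif_flags, dtype=bool)
        self.dif_shift = np.asarray(self.dif_shift, dtype=float)

    @property
    def n_items(self) -> int:
        return self.alpha.size

    def to_frame(self) -> pd.DataFrame:
        """1-based item table of the generating parameters."""
        return pd.DataFrame(
            {
                "item": np.arange(1, self.n_items + 1),
                "alpha": self.alpha,
                "beta": self.beta,
                "dif_flag": self.dif_flags.astype(int),
                "dif_shift": self.dif_shift,
            }
        )


@dataclass
class PersonSample:
    """Latent-trait sample theta ~ N(mu, 1)."""

    thetas: np.ndarray
    mu: float

    def __post_init__(self):
        self.thetas = np.asarray(self.thetas, dtype=float)

    @property
    def n(self) -> int:
        return self.thetas.size


@dataclass
class ResponseMatrix:
    """Persons x items dichotomous responses with an observedness mask.

    P&P matrices are fully observed; CAT matrices are sparse (exactly
    ``test_length`` observed cells per row).  Values are internally {0, 1};
    the 1 = "no" / 2 = "yes" file coding is converted at I/O.
    """

    values: np.ndarray
    mask: np.ndarray = None
    mode: str = "PP"  # "PP" | "CAT"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask and values must have the same shape")

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def fully_observed(self) -> bool:
        return bool(self.mask.all())


def generate_bank(model: str, n_items: int = 100, seed=None) -> ItemBank:
    """Draw a bank of true item parameters.

    1PL: all discriminations exactly 1.0.  2PL: lognormal(0, 0.5)
    discriminations redrawn until inside [0.5, 2.5].  Difficulties are
    sampled uniformly (with replacement) from the 0.25-logit grid on
    [-3, 3]; with the default 100 items on 25 grid values repeats are
    unavoidable.
    """
    if model not in ("1PL", "2PL"):
        raise ValueError(f"model must be '1PL' or '2PL', got {model!r}")
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    rng = as_rng(seed)
    beta = rng.choice(BETA_GRID, size=n_items, replace=True)
    if model == "1PL":
        alpha = np.ones(n_items)
    else:
        alpha = rng.lognormal(0.0, ALPHA_LOG_SD, size=n_items)
        bad = (alpha < ALPHA_RANGE[0]) | (alpha > ALPHA_RANGE[1])
        while bad.any():
            alpha[bad] = rng.lognormal(0.0, ALPHA_LOG_SD, size=int(bad.sum()))
            bad = (alpha < ALPHA_RANGE[0]) | (alpha > ALPHA_RANGE[1])
    return ItemBank(alpha=alpha, beta=beta, model=model)


def sample_persons(n: int, mu: float = 0.0, seed=None) -> PersonSample:
    """Draw ``n`` latent traits from N(mu, 1)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = as_rng(seed)
    return PersonSample(thetas=mu + rng.standard_normal(n), mu=mu)


def inject_dif(bank: ItemBank, pct: float, magnitude: float, seed=None) -> ItemBank:
    """Return a copy of ``bank`` with mode DIF injected on ``pct``% of items.

    Exactly ``pct * n_items / 100`` items (must be integral) are selected
    uniformly without replacement; each receives a difficulty shift of
    +magnitude (harder to endorse by CAT) or -magnitude (easier), the sign
    drawn as an independent fair coin.  Unselected items keep shift 0.
    """
    n_dif_f = pct * bank.n_items / 100.0
    n_dif = int(round(n_dif_f))
    if abs(n_dif_f - n_dif) > 1e-9:
        raise ValueError(f"pct={pct} of {bank.n_items} items is not integral")
    if magnitude != 0 and magnitude not in DIF_MAGNITUDES:
        warnings.warn(
            f"DIF magnitude {magnitude} is outside the conventional ETS B/C "
            f"values {DIF_MAGNITUDES}",
            stacklevel=2,
        )
    rng = as_rng(seed)
    flags = np.zeros(bank.n_items, dtype=bool)
    shift = np.zeros(bank.n_items, dtype=float)
    if n_dif > 0:
        chosen = rng.choice(bank.n_items, size=n_dif, replace=False)
        signs = rng.choice([1.0, -1.0], size=n_dif)
        flags[chosen] = True
        shift[chosen] = signs * magnitude
    return replace(bank, dif_flags=flags, dif_shift=shift)


def generate_responses(
    bank: ItemBank,
    sample: PersonSample,
    seed=None,
    *,
    alpha=None,
    beta=None,
    use_dif: bool = False,
    mode: str = "PP",
) -> ResponseMatrix:
    """Simulate a complete Bernoulli response matrix.

    By default responses are generated under the bank's true parameters.
    ``alpha``/``beta`` override the generating parameters item-wise — the
    study harness uses this to generate CAT data from the *estimated* P&P
    difficulties while keeping the true discriminations.  With
    ``use_dif=True`` each flagged item's difficulty is shifted by its
    ``dif_shift`` before generation.
    """
    if bank.n_items < 1 or sample.n < 1:
        raise ValueError("bank and sample must be non-empty")
    rng = as_rng(seed)
    a = bank.alpha if alpha is None else np.asarray(alpha, dtype=float)
    b = bank.beta if beta is None else np.asarray(beta, dtype=float)
    if use_dif:
        b = b + bank.dif_shift
    p = _prob(sample.thetas[:, None], a[None, :], b[None, :])
    values = (rng.random(p.shape) < p).astype(np.uint8)
    return ResponseMatrix(values=values, mode=mode)
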