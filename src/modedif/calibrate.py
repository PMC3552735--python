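"""Marginal maximum-likelihood item calibration (Bock-Aitkin EM).

Item parameters are estimated from a fully observed response matrix by
maximizing the marginal likelihood

    L = prod_i  integral  prod_j P_j(t)^y_ij (1 - P_j(t))^(1 - y_ij) phi(t) dt

where the latent trait is integrated against a fixed N(0, 1) density — the
model is identified by fixing the SD of theta at 1.  The integral is
approximated with Gauss-Hermite quadrature (41 nodes by default) and the
likelihood maximized by EM:

* E-step: posterior weights of each quadrature node per person, expected
  node counts ``n_q`` and expected endorsements ``r_jq``.
* M-step: per item, the expected complete-data log-likelihood is exactly a
  weighted logistic regression on the node locations, concave in the slope /
  intercept parameterization ``z = a x + c`` (``a = D alpha``,
  ``c = -a beta``); it is maximized by damped Newton steps.  Under the 1PL
  model a single common slope is estimated jointly with per-item
  intercepts (Newton on the arrow-structured Hessian).

Maximum-likelihood (rather than Bayesian) calibration is deliberate: it
keeps the calibration free of the priors used later in the DIF analysis.
Standard errors come from the empirical cross-products of per-person score
vectors (block-diagonal per item) and are reported only for descriptive use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import roots_hermitenorm
from scipy.stats import pearsonr

from .banks import ItemBank, ResponseMatrix
from .irt import D

__all__ = ["CalibrationResult", "calibrate", "recovery_metrics"]


@dataclass
class CalibrationResult:
    """Estimated item parameters and fit summary from one calibration."""

    alpha: np.ndarray
    beta: np.ndarray
    se_alpha: np.ndarray
    se_beta: np.ndarray
    loglik: float
    n_cycles: int
    converged: bool
    model: str
    excluded: np.ndarray  # items with degenerate (all-0/all-1) responses
    loglik_path: np.ndarray = None

    @property
    def n_items(self) -> int:
        return self.alpha.size


def _quadrature(n_quad: int):
    # probabilists' Hermite nodes integrate against exp(-x^2/2)
    x, w = roots_hermitenorm(n_quad)
    return x, w / w.sum()


def _node_logprobs(a, c, x):
    """log P and log(1-P) at each node; a broadcasts (J,) or scalar."""
    z = np.atleast_1d(a)[:, None] * x[None, :] + np.atleast_1d(c)[:, None]
    log_p = -np.logaddexp(0.0, -z)
    log_q = -np.logaddexp(0.0, z)
    return z, log_p, log_q


def _e_step(y, a, c, x, logw):
    """Posterior node weights; returns (loglik, W, n_q, r_jq)."""
    _, log_p, log_q = _node_logprobs(a, c, x)
    ll = y @ log_p + (1.0 - y) @ log_q + logw[None, :]  # (N, Q)
    m = ll.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(ll - m).sum(axis=1))
    w_post = np.exp(ll - lse[:, None])
    n_q = w_post.sum(axis=0)
    r_jq = y.T @ w_post
    return float(lse.sum()), w_post, n_q, r_jq


def _q_value(a, c, x, n_q, r_jq):
    z, log_p, log_q = _node_logprobs(a, c, x)
    return ((r_jq * log_p) + (n_q[None, :] - r_jq) * log_q).sum(axis=1)


def _m_step_2pl(a, c, x, n_q, r_jq, a_max, n_newton=25, tol=1e-9):
    """Damped Newton per item on the concave expected log-likelihood."""
    a, c = a.copy(), c.copy()
    q_cur = _q_value(a, c, x, n_q, r_jq)
    for _ in range(n_newton):
        z = a[:, None] * x[None, :] + c[:, None]
        p = 1.0 / (1.0 + np.exp(-z))
        res = r_jq - n_q[None, :] * p
        wq = n_q[None, :] * p * (1.0 - p)
        g_a = (res * x[None, :]).sum(axis=1)
        g_c = res.sum(axis=1)
        j_aa = (wq * x[None, :] ** 2).sum(axis=1)
        j_ac = (wq * x[None, :]).sum(axis=1)
        j_cc = wq.sum(axis=1)
        det = j_aa * j_cc - j_ac**2
        det = np.where(det <= 1e-12, 1e-12, det)
        da = (j_cc * g_a - j_ac * g_c) / det
        dc = (j_aa * g_c - j_ac * g_a) / det
        # step-halving keeps each item's objective non-decreasing
        step = np.ones_like(a)
        for _ in range(20):
            a_new = np.clip(a + step * da, 1e-3, a_max)
            c_new = c + step * dc
            q_new = _q_value(a_new, c_new, x, n_q, r_jq)
            worse = q_new < q_cur - 1e-12
            if not worse.any():
                break
            step[worse] *= 0.5
        a, c, q_cur = a_new, c_new, q_new
        if max(np.abs(g_a).max(), np.abs(g_c).max()) < tol * max(1.0, n_q.sum()):
            break
    return a, c


def _m_step_1pl(a, c, x, n_q, r_jq, n_newton=40, tol=1e-9):
    """Joint Newton for a common slope and per-item intercepts."""
    a = float(a)
    c = c.copy()
    for _ in range(n_newton):
        z = a * x[None, :] + c[:, None]
        p = 1.0 / (1.0 + np.exp(-z))
        res = r_jq - n_q[None, :] * p
        wq = n_q[None, :] * p * (1.0 - p)
        g_a = (res * x[None, :]).sum()
        g_c = res.sum(axis=1)
        j_aa = (wq * x[None, :] ** 2).sum()
        j_ac = (wq * x[None, :]).sum(axis=1)  # per item
        j_cc = wq.sum(axis=1)
        # solve the arrow system [[j_aa, j_ac^T], [j_ac, diag(j_cc)]]
        schur = j_aa - (j_ac**2 / j_cc).sum()
        da = (g_a - (j_ac * g_c / j_cc).sum()) / max(schur, 1e-12)
        dc = (g_c - j_ac * da) / j_cc
        q_cur = _q_value(a, c, x, n_q, r_jq).sum()
        step = 1.0
        for _ in range(20):
            a_new = max(a + step * da, 1e-3)
            c_new = c + step * dc
            if _q_value(a_new, c_new, x, n_q, r_jq).sum() >= q_cur - 1e-12:
                break
            step *= 0.5
        a, c = a_new, c_new
        if max(abs(g_a), np.abs(g_c).max()) < tol * max(1.0, n_q.sum()):
            break
    return a, c


def calibrate(
    data,
    model: str = "1PL",
    *,
    n_quad: int = 41,
    max_cycles: int = 500,
    tol: float = 1e-4,
    alpha_max: float = 3.0,
) -> CalibrationResult:
    """Fit item parameters to a fully observed response matrix.

    ``data`` is a :class:`~modedif.banks.ResponseMatrix` or a 0/1 array.
    ``model='1PL'`` constrains discriminations to be equal across items;
    ``model='2PL'`` estimates a free discrimination per item.  EM stops when
    the largest parameter change falls below ``tol`` (on the alpha/beta
    scale) or after ``max_cycles`` cycles.  Items endorsed by everyone or by
    no one carry no information about a finite difficulty; they are excluded
    with a warning and reported as NaN.

    Near-degenerate items (endorsed by almost everyone or almost no one)
    have a weakly identified or divergent ML slope; ``alpha_max`` bounds the
    estimated discrimination (numerical stabilization, the kind of slope
    bound IRT calibration programs apply by default).  The default of 3.0
    comfortably covers the plausible range for health-outcome item banks,
    which rarely field items with discriminations above 2.5.
    """
    if model not in ("1PL", "2PL"):
        raise ValueError(f"model must be '1PL' or '2PL', got {model!r}")
    if isinstance(data, ResponseMatrix):
        if not data.fully_observed:
            raise ValueError("calibration requires a fully observed matrix")
        y_all = data.values.astype(float)
    else:
        y_all = np.asarray(data, dtype=float)
    n, j_all = y_all.shape
    if n < 2:
        raise ValueError("need at least two persons")

    counts = y_all.sum(axis=0)
    excluded = (counts == 0) | (counts == n)
    if excluded.any():
        warnings.warn(
            f"{int(excluded.sum())} degenerate item(s) (all 0s or all 1s) "
            "excluded from calibration",
            stacklevel=2,
        )
    y = y_all[:, ~excluded]
    n_items = y.shape[1]
    if n_items == 0:
        raise ValueError("no non-degenerate items to calibrate")

    x, w = _quadrature(n_quad)
    logw = np.log(w)

    # starting values from marginal endorsement rates
    p_j = y.mean(axis=0).clip(1e-3, 1 - 1e-3)
    c = np.log(p_j / (1.0 - p_j))
    a = np.full(n_items, D) if model == "2PL" else D  # alpha = 1 start

    path = []
    n_cycles = 0
    converged = False
    for n_cycles in range(1, max_cycles + 1):
        loglik, _, n_q, r_jq = _e_step(y, a, c, x, logw)
        path.append(loglik)
        if model == "2PL":
            a_new, c_new = _m_step_2pl(a, c, x, n_q, r_jq, a_max=D * alpha_max)
        else:
            a_new, c_new = _m_step_1pl(a, c, x, n_q, r_jq)
        d_alpha = np.max(np.abs(np.atleast_1d(a_new) - np.atleast_1d(a))) / D
        d_beta = np.max(np.abs(c_new / np.atleast_1d(a_new) - c / np.atleast_1d(a)))
        a, c = a_new, c_new
        if max(d_alpha, d_beta) < tol:
            converged = True
            break
    loglik, w_post, _, _ = _e_step(y, a, c, x, logw)
    path.append(loglik)

    a_vec = np.broadcast_to(np.atleast_1d(a), (n_items,)).astype(float)
    alpha_hat = a_vec / D
    beta_hat = -c / a_vec

    se_a, se_c, cov_ac = _empirical_se(y, a_vec, c, x, w_post, model)
    se_alpha = se_a / D
    # delta method for beta = -c/a
    var_beta = (
        (c / a_vec**2) ** 2 * se_a**2
        + (1.0 / a_vec) ** 2 * se_c**2
        + 2.0 * (c / a_vec**2) * (-1.0 / a_vec) * cov_ac
    )
    se_beta = np.sqrt(np.maximum(var_beta, 0.0))

    def expand(v, fill=np.nan):
        out = np.full(j_all, fill)
        out[~excluded] = v
        return out

    return CalibrationResult(
        alpha=expand(alpha_hat),
        beta=expand(beta_hat),
        se_alpha=expand(se_alpha),
        se_beta=expand(se_beta),
        loglik=loglik,
        n_cycles=n_cycles,
        converged=converged,
        model=model,
        excluded=excluded,
        loglik_path=np.asarray(path),
    )


def _empirical_se(y, a_vec, c, x, w_post, model):
    """Cross-product (outer-product-of-scores) standard errors per item."""
    z = a_vec[:, None] * x[None, :] + c[:, None]
    p = 1.0 / (1.0 + np.exp(-z))  # (J, Q)
    # person-level scores: s_c[i, j] = sum_q W_iq (y_ij - P_jq)
    wp = w_post @ p.T  # (N, J) expected P per person/item
    wpx = w_post @ (p * x[None, :]).T
    wx = w_post @ x  # (N,) posterior mean node per person
    s_c = y - wp
    s_a = y * wx[:, None] - wpx
    i_aa = (s_a**2).sum(axis=0)
    i_cc = (s_c**2).sum(axis=0)
    i_ac = (s_a * s_c).sum(axis=0)
    if model == "1PL":
        # common slope: pool the slope scores across items
        s_a_tot = s_a.sum(axis=1)
        i_aa = np.full_like(i_aa, (s_a_tot**2).sum())
        i_ac = (s_a_tot[:, None] * s_c).sum(axis=0)
    det = np.maximum(i_aa * i_cc - i_ac**2, 1e-12)
    var_a = i_cc / det
    var_c = i_aa / det
    cov_ac = -i_ac / det
    return np.sqrt(var_a), np.sqrt(var_c), cov_ac


def recovery_metrics(truth: ItemBank, est: CalibrationResult) -> dict:
    """Correlations and RMSEs between true and estimated item parameters.

    Computed over items that were not excluded as degenerate.  For a 1PL
    fit the estimated discriminations are constant, so ``corr_alpha`` is
    undefined and reported as NaN.
    """
    if truth.n_items != est.n_items:
        raise ValueError("item count mismatch between truth and estimates")
    keep = ~est.excluded
    ta, tb = truth.alpha[keep], truth.beta[keep]
    ea, eb = est.alpha[keep], est.beta[keep]
    out = {
        "corr_beta": float(pearsonr(tb, eb)[0]),
        "rmse_beta": float(np.sqrt(np.mean((eb - tb) ** 2))),
        "rmse_alpha": float(np.sqrt(np.mean((ea - ta) ** 2))),
    }
    if np.ptp(ea) > 1e-12 and np.ptp(ta) > 1e-12:
        out["corr_alpha"] = float(pearsonr(ta, ea)[0])
    else:
        out["corr_alpha"] = float("nan")
    return out
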