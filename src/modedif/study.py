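"""Monte Carlo study of the mode-DIF detectors.

Orchestrates the fully crossed simulation design — generating model (1PL /
2PL) x DIF magnitude (0.42 / 0.63 logits) x DIF percentage (10 / 30) x
CAT-sample mean shift (0 / 1 logit), 16 conditions — and evaluates the
robust-Z and credible-interval statistics against the injected DIF truth:
per-condition true/false positive percentages, pooled classification
metrics, quadratic-logistic ROC analysis and a correlated-AUC contrast.

Each replication of a condition performs the full pipeline:

    generate bank -> P&P responses (N=500, theta ~ N(0,1))
    -> ML calibration (selection/scoring parameters)
    -> inject DIF -> complete CAT-mode responses
       (N=3000, theta ~ N(mu_cat, 1); estimated difficulties + DIF shift,
        true discriminations)
    -> 30-item adaptive administration -> sparse CAT matrix
    -> three-step Bayesian DIF analysis -> per-item record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .banks import generate_bank, generate_responses, inject_dif, sample_persons
from .bayes import McmcSchedule, Priors, analyze_dif
from .calibrate import calibrate, recovery_metrics
from .cat import CatConfig, simulate_cat, usage_counts
from .util import spawn_seeds

__all__ = [
    "ConditionSpec",
    "StudyResult",
    "default_grid",
    "run_condition",
    "run_study",
    "condition_summary",
    "classification_metrics",
    "roc_auc",
    "auc_difference_test",
    "describe_statistics",
]

logger = logging.getLogger(__name__)

RECORD_COLUMNS = [
    "model", "dif_size", "dif_pct", "mu_cat", "rep", "item", "dif_truth",
    "dif_shift", "usage", "alpha_pp", "beta_pp", "rz", "cri_lo", "cri_hi",
    "delta_cri", "flag_rz", "flag_cri",
]


@dataclass(frozen=True)
class ConditionSpec:
    """One cell of the crossed design plus its sampling sizes."""

    model: str = "1PL"
    dif_size: float = 0.42
    dif_pct: float = 10
    mu_cat: float = 0.0
    n_reps: int = 10
    n_items: int = 100
    n_pp: int = 500
    n_cat: int = 3000
    test_length: int = 30


@dataclass
class StudyResult:
    """Per-item records plus condition-level and pooled summaries."""

    records: pd.DataFrame
    summary: pd.DataFrame = None
    overall: dict = field(default_factory=dict)


def default_grid(**overrides) -> list[ConditionSpec]:
    """The 16-condition fully crossed design (override sizes via kwargs)."""
    grid = []
    for model, size, pct, mu in product(
        ("1PL", "2PL"), (0.42, 0.63), (10, 30), (0.0, 1.0)
    ):
        grid.append(
            ConditionSpec(model=model, dif_size=size, dif_pct=pct, mu_cat=mu, **overrides)
        )
    return grid


def _run_replication(spec: ConditionSpec, rep: int, seed, schedule, min_usage):
    rngs = spawn_seeds(seed, 6)
    bank = generate_bank(spec.model, spec.n_items, rngs[0])
    pp_sample = sample_persons(spec.n_pp, 0.0, rngs[1])
    pp = generate_responses(bank, pp_sample, rngs[2])

    calib = calibrate(pp, spec.model)
    alpha_hat, beta_hat = calib.alpha.copy(), calib.beta.copy()
    if calib.excluded.any():
        # a degenerate item cannot be scaled from the P&P data; pin it at an
        # extreme difficulty so CAT will not select it
        logger.warning(
            "replication %d: %d degenerate item(s) pinned at +/-4 logits",
            rep, int(calib.excluded.sum()),
        )
        all_one = pp.values.mean(axis=0) == 1.0
        beta_hat[calib.excluded] = np.where(all_one[calib.excluded], -4.0, 4.0)
        fill = np.nanmean(alpha_hat) if np.isfinite(np.nanmean(alpha_hat)) else 1.0
        alpha_hat[calib.excluded] = fill

    bank_dif = inject_dif(bank, spec.dif_pct, spec.dif_size, rngs[3])
    cat_sample = sample_persons(spec.n_cat, spec.mu_cat, rngs[4])
    # CAT generating parameters: estimated P&P difficulties (+ DIF shift for
    # flagged items) with the bank's true discriminations
    full_cat = generate_responses(
        bank_dif, cat_sample, rngs[5], alpha=bank.alpha, beta=beta_hat,
        use_dif=True, mode="CAT",
    )
    cat_res = simulate_cat(full_cat, alpha_hat, beta_hat, CatConfig(spec.test_length))
    cat_rm = cat_res.to_response_matrix()
    usage = usage_counts(cat_res.administered, spec.n_items)

    dif = analyze_dif(pp, cat_rm, schedule=schedule, seed=seed.spawn(1)[0],
                      min_usage=min_usage)
    rec = pd.DataFrame(
        {
            "model": spec.model,
            "dif_size": spec.dif_size,
            "dif_pct": spec.dif_pct,
            "mu_cat": spec.mu_cat,
            "rep": rep,
            "item": np.arange(1, spec.n_items + 1),
            "dif_truth": bank_dif.dif_flags.astype(int),
            "dif_shift": bank_dif.dif_shift,
            "usage": usage,
            "alpha_pp": alpha_hat,
            "beta_pp": beta_hat,
            "rz": dif.rz,
            "cri_lo": dif.cri_lo,
            "cri_hi": dif.cri_hi,
            "delta_cri": dif.delta_cri,
            "flag_rz": dif.flag_rz.astype(int),
            "flag_cri": dif.flag_cri.astype(int),
        }
    )
    extras = {
        "recovery": recovery_metrics(bank, calib),
        "mean_se_cat": float(np.mean(cat_res.se[np.isfinite(cat_res.se)])),
        "corr_cat_full": float(np.corrcoef(cat_res.theta, cat_res.theta_full)[0, 1]),
    }
    return rec, extras


def run_condition(
    spec: ConditionSpec,
    master_seed,
    schedule: McmcSchedule = McmcSchedule(),
    min_usage: int = 50,
) -> StudyResult:
    """Run every replication of one condition; failures are logged, skipped."""
    seeds = spawn_seeds(master_seed, spec.n_reps)
    frames, extras, failures = [], [], 0
    for rep, seed in enumerate(seeds):
        try:
            rec, ex = _run_replication(spec, rep, seed, schedule, min_usage)
        except Exception:
            failures += 1
            logger.exception("replication %d of %s failed; skipped", rep, spec)
            continue
        frames.append(rec)
        extras.append(ex)
    if not frames:
        raise RuntimeError(f"all {spec.n_reps} replications failed for {spec}")
    records = pd.concat(frames, ignore_index=True)
    overall = {
        "n_failed_reps": failures,
        "mean_se_cat": float(np.mean([e["mean_se_cat"] for e in extras])),
        "corr_cat_full": float(np.mean([e["corr_cat_full"] for e in extras])),
        "recovery": {
            k: float(np.mean([e["recovery"][k] for e in extras]))
            for k in extras[0]["recovery"]
        },
    }
    return StudyResult(records=records, summary=condition_summary(records), overall=overall)


def run_study(
    conditions,
    master_seed,
    schedule: McmcSchedule = McmcSchedule(),
    min_usage: int = 50,
) -> StudyResult:
    """Run a list of conditions and pool records, summaries and ROC metrics."""
    seeds = spawn_seeds(master_seed, len(conditions))
    parts = []
    for spec, seed in zip(conditions, seeds):
        logger.info("running condition %s", spec)
        parts.append(run_condition(spec, seed, schedule, min_usage).records)
    records = pd.concat(parts, ignore_index=True)
    overall = {}
    for statistic in ("rz", "cri"):
        overall[statistic] = classification_metrics(records, statistic)
        if records["dif_truth"].nunique() == 2:
            overall[statistic]["auc"] = roc_auc(records, statistic)
    if records["dif_truth"].nunique() == 2:
        overall["auc_difference"] = auc_difference_test(records)
    return StudyResult(records=records, summary=condition_summary(records), overall=overall)


def condition_summary(records: pd.DataFrame) -> pd.DataFrame:
    """TP% / FP% per condition for both statistics (one row per cell).

    TP% is the flag rate among DIF-true items only, FP% among DIF-false
    items only; cells without DIF items report TP% as NaN.
    """
    def _agg(g):
        dif = g[g.dif_truth == 1]
        non = g[g.dif_truth == 0]
        return pd.Series(
            {
                "tp_rz": 100.0 * dif.flag_rz.mean() if len(dif) else np.nan,
                "fp_rz": 100.0 * non.flag_rz.mean() if len(non) else np.nan,
                "tp_cri": 100.0 * dif.flag_cri.mean() if len(dif) else np.nan,
                "fp_cri": 100.0 * non.flag_cri.mean() if len(non) else np.nan,
                "n_reps": g.rep.nunique(),
            }
        )

    keys = ["model", "dif_size", "dif_pct", "mu_cat"]
    out = records.groupby(keys, sort=True).apply(_agg, include_groups=False)
    return out.reset_index()


def _flags_and_truth(records: pd.DataFrame, statistic: str):
    statistic = statistic.lower()
    if statistic not in ("rz", "cri"):
        raise ValueError("statistic must be 'rz' or 'cri'")
    return records["dif_truth"].to_numpy(), records[f"flag_{statistic}"].to_numpy()


def classification_metrics(records: pd.DataFrame, statistic: str) -> dict:
    """Pooled sensitivity / specificity / correct classification (percent)."""
    if len(records) == 0:
        raise ValueError("no records")
    truth, flags = _flags_and_truth(records, statistic)
    tp = np.sum((truth == 1) & (flags == 1))
    fn = np.sum((truth == 1) & (flags == 0))
    tn = np.sum((truth == 0) & (flags == 0))
    fp = np.sum((truth == 0) & (flags == 1))
    return {
        "sensitivity": 100.0 * tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": 100.0 * tn / (tn + fp) if tn + fp else float("nan"),
        "correct_classification": 100.0 * (tp + tn) / len(records),
    }


def _quadratic_logit_probs(records: pd.DataFrame, statistic: str):
    """P(DIF) from a logistic fit on the statistic and its square.

    Both statistics signal DIF at either sign, hence the quadratic term.
    Complete separation only saturates the predicted probabilities, which
    still rank records correctly for ROC purposes; a non-converged fit is
    logged.
    """
    from sklearn.exceptions import ConvergenceWarning
    from sklearn.linear_model import LogisticRegression

    statistic = statistic.lower()
    s = records["rz" if statistic == "rz" else "delta_cri"].to_numpy(dtype=float)
    s = np.nan_to_num(s, posinf=1e6, neginf=-1e6)
    x = np.column_stack([s, s**2])
    y = records["dif_truth"].to_numpy(dtype=int)
    model = LogisticRegression(penalty=None, solver="lbfgs", max_iter=2000)
    import warnings as _w

    with _w.catch_warnings(record=True) as caught:
        _w.simplefilter("always", ConvergenceWarning)
        model.fit(x, y)
    if any(issubclass(c.category, ConvergenceWarning) for c in caught):
        logger.warning("quadratic logistic fit for %s did not fully converge", statistic)
    return model.predict_proba(x)[:, 1]


def roc_auc(records: pd.DataFrame, statistic: str) -> float:
    """AUC (Mann-Whitney) of the quadratic-logistic DIF probabilities."""
    from sklearn.metrics import roc_auc_score

    y = records["dif_truth"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both DIF classes must be present for ROC analysis")
    return float(roc_auc_score(y, _quadratic_logit_probs(records, statistic)))


def _midrank(x):
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    t = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n)
    out[order] = t
    return out


def _delong(truth, scores):
    """DeLong AUC and influence components for paired comparison."""
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    m, n = len(pos), len(neg)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n
    v10 = 1.0 - (tz[m:] - ty) / m
    return auc, v01, v10


def auc_difference_test(records: pd.DataFrame, fit_quadratic: bool = True) -> dict:
    """Correlated-AUC contrast between the RZ and CrI score vectors.

    DeLong covariance of the paired AUCs with a 1-df chi-square statistic.
    By default the scores are the fitted quadratic-logistic probabilities of
    each statistic on the same records; ``fit_quadratic=False`` contrasts
    the raw statistics instead (the test is exactly calibrated for scores
    that are not refitted to the outcome, and slightly conservative for
    fitted probabilities).
    """
    truth = records["dif_truth"].to_numpy(dtype=int)
    if len(np.unique(truth)) < 2:
        raise ValueError("both DIF classes must be present")
    if fit_quadratic:
        p_rz = _quadratic_logit_probs(records, "rz")
        p_cri = _quadratic_logit_probs(records, "cri")
    else:
        p_rz = records["rz"].to_numpy(dtype=float)
        p_cri = records["delta_cri"].to_numpy(dtype=float)
    a1, v01_1, v10_1 = _delong(truth, p_rz)
    a2, v01_2, v10_2 = _delong(truth, p_cri)
    m, n = len(v01_1), len(v10_1)
    s01 = np.cov(np.stack([v01_1, v01_2]))
    s10 = np.cov(np.stack([v10_1, v10_2]))
    cov = s01 / m + s10 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var_diff <= 0:
        if a1 == a2:
            return {"auc_rz": a1, "auc_cri": a2, "chi2": 0.0, "df": 1, "p": 1.0}
        raise ValueError("degenerate variance in AUC contrast")
    chi2 = (a1 - a2) ** 2 / var_diff
    return {
        "auc_rz": float(a1),
        "auc_cri": float(a2),
        "chi2": float(chi2),
        "df": 1,
        "p": float(stats.chi2.sf(chi2, 1)),
    }


def describe_statistics(records: pd.DataFrame) -> pd.DataFrame:
    """Distribution summary of RZ and delta-CrI among non-DIF items.

    Kurtosis is reported as *excess* kurtosis (normal = 0); the column name
    states the convention.
    """
    non = records[records.dif_truth == 0]
    if len(non) == 0:
        raise ValueError("no non-DIF records")
    rows = []
    for name, col in (("rz", "rz"), ("delta_cri", "delta_cri")):
        v = non[col].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        rows.append(
            {
                "statistic": name,
                "mean": v.mean(),
                "sd": v.std(ddof=1) if v.size > 1 else 0.0,
                "skewness": float(stats.skew(v)) if v.size > 2 else np.nan,
                "excess_kurtosis": float(stats.kurtosis(v)) if v.size > 3 else np.nan,
                "p2.5": float(np.percentile(v, 2.5)),
                "p97.5": float(np.percentile(v, 97.5)),
            }
        )
    return pd.DataFrame(rows)
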