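"""Global self-performance estimate (SPE) analyses.

The end-of-block task choice is the behavioral readout of a global SPE:
choosing a task signals the belief that performance on it was better.  This
module implements the choice-side analyses: trial exclusions, a-posteriori
labelling of trials by the block's choice, choice-frequency statistics
(overall and split by the realized performance difference between tasks),
logistic regressions of task choice on difficulty/accuracy and on candidate
block-level predictors compared by summed deviance, the scalar SPE
sensitivity (frequency of choosing the objectively easier task), and a
default-prior (JZS) Bayes factor for one-sample t tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import minimize
from scipy.stats import t as t_dist, ttest_1samp, ttest_rel

__all__ = [
    "exclude_trials",
    "label_trials",
    "block_summaries",
    "choice_frequencies",
    "task_choice_logistic",
    "choice_model_deviance",
    "spe_sensitivity",
    "jzs_bayes_factor",
    "SPEBehavior",
    "ChoiceModelFit",
]

_RIDGE = 1e-4
_EPS = 1e-12


# ---------------------------------------------------------------------------
# exclusions and labelling
# ---------------------------------------------------------------------------

def exclude_trials(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop missed trials and log-RT outliers (|z| > 3, per subject).

    The z-score uses the mean/SD of log RT over each subject's responded
    trials, computed once (no re-iteration after removal).  Returns the kept
    trials and a per-subject report of exclusion fractions.
    """
    responded = trials["response"] != "none"
    keep = responded.copy()
    for sid, sub in trials[responded].groupby("subject"):
        log_rt = np.log(sub["rt_ms"].to_numpy(dtype=float))
        sd = log_rt.std(ddof=0)
        if sd > 0:
            z = (log_rt - log_rt.mean()) / sd
            keep.loc[sub.index[np.abs(z) > 3]] = False
    kept = trials[keep]
    rows = []
    for sid, sub in trials.groupby("subject"):
        n = len(sub)
        n_missed = int((sub["response"] == "none").sum())
        n_kept = int(keep.loc[sub.index].sum())
        rows.append({
            "subject": sid, "n_trials": n, "n_missed": n_missed,
            "n_outlier": n - n_missed - n_kept,
            "excluded_fraction": (n - n_kept) / n if n else 0.0,
        })
    report = pd.DataFrame(rows).set_index("subject")
    if len(kept) == 0:
        import warnings
        warnings.warn("all trials excluded", UserWarning)
    return kept, report


def label_trials(trials: pd.DataFrame, blocks: pd.DataFrame) -> pd.DataFrame:
    """Tag each main-session trial by its block's end-of-block choice.

    A trial of the chosen task is a ``higher_SPE`` trial, otherwise
    ``lower_SPE``.  Every block must have a recorded choice.
    """
    choice = blocks.set_index(["subject", "block"])["chosen_task"]
    if choice.isna().any():
        bad = choice[choice.isna()].index.tolist()
        raise ValueError(f"blocks without a recorded choice: {bad}")
    out = trials.copy()
    key = pd.MultiIndex.from_frame(out[["subject", "block"]])
    missing = ~key.isin(choice.index)
    if missing.any():
        raise ValueError(
            f"trials reference blocks without a choice record: "
            f"{sorted(set(key[missing]))[:5]}"
        )
    chosen = choice.loc[key].to_numpy()
    out["spe_label"] = np.where(out["task"] == chosen, "higher_SPE", "lower_SPE")
    return out


# ---------------------------------------------------------------------------
# block summaries
# ---------------------------------------------------------------------------

def block_summaries(trials: pd.DataFrame, blocks: pd.DataFrame) -> pd.DataFrame:
    """Per-block, per-task aggregates feeding the choice analyses.

    For each task in each block: square difference, realized accuracy, mean
    log RT, mean predicted confidence (if a ``predicted_confidence`` column
    is present) and the count of valid trials.  Adds the easy task (larger
    square difference), the accuracy difference (easy - difficult) and its
    sign as the performance class (positive / null / negative).
    """
    has_pconf = "predicted_confidence" in trials.columns
    rows = []
    for (sid, b), binfo in blocks.groupby(["subject", "block"]):
        info = binfo.iloc[0]
        sub = trials[(trials["subject"] == sid) & (trials["block"] == b)]
        row = {"subject": sid, "block": b,
               "easy_task": info["easy_task"],
               "chosen_task": info["chosen_task"],
               "first_task": info["first_task"]}
        for task in ("A", "B"):
            tt = sub[sub["task"] == task]
            row[f"delta_{task}"] = info[f"delta_{task}"]
            row[f"n_{task}"] = len(tt)
            row[f"acc_{task}"] = tt["accuracy"].mean() if len(tt) else np.nan
            row[f"logrt_{task}"] = (
                np.log(tt["rt_ms"]).mean() if len(tt) else np.nan
            )
            if has_pconf:
                row[f"pconf_{task}"] = (
                    tt["predicted_confidence"].mean() if len(tt) else np.nan
                )
        easy, hard = (("A", "B") if row["delta_A"] > row["delta_B"] else ("B", "A"))
        row["accuracy_difference"] = row[f"acc_{easy}"] - row[f"acc_{hard}"]
        diff = row["accuracy_difference"]
        row["perf_class"] = (
            "positive" if diff > 0 else "negative" if diff < 0 else "null"
        )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# choice frequencies
# ---------------------------------------------------------------------------

@dataclass
class SPEBehavior:
    """Choice-frequency summary: per-subject frequencies and group tests."""

    per_subject: pd.DataFrame
    group: dict


def choice_frequencies(summaries: pd.DataFrame) -> SPEBehavior:
    """Frequency of choosing the easy / best-performed task, per subject.

    ``easy_choice_freq`` is the fraction of blocks where the chosen task is
    the easier one; ``best_performed_choice_freq`` uses the realized block
    accuracies instead (accuracy ties removed from its denominator, with
    the tie count reported).  Frequencies of choosing the easy task are
    also split by performance class.  Group-level tests: one-sample t of
    the easy-choice frequency against 0.5, and paired t tests between the
    performance-class splits (subjects lacking a class are excluded from
    that test, with the n reported).
    """
    rows = []
    for sid, sub in summaries.groupby("subject"):
        chose_easy = (sub["chosen_task"] == sub["easy_task"]).to_numpy()
        easy_freq = float(chose_easy.mean())
        nontied = sub[sub["perf_class"] != "null"]
        if len(nontied):
            best = np.where(nontied["accuracy_difference"] > 0,
                            nontied["easy_task"],
                            np.where(nontied["easy_task"] == "A", "B", "A"))
            best_freq = float((nontied["chosen_task"].to_numpy() == best).mean())
        else:
            best_freq = np.nan
        row = {"subject": sid, "n_blocks": len(sub),
               "easy_choice_freq": easy_freq,
               "best_performed_choice_freq": best_freq,
               "n_accuracy_ties": int((sub["perf_class"] == "null").sum())}
        for cls in ("positive", "null", "negative"):
            mask = sub["perf_class"] == cls
            row[f"easy_choice_freq_{cls}"] = (
                float(chose_easy[mask.to_numpy()].mean()) if mask.any() else np.nan
            )
        rows.append(row)
    per = pd.DataFrame(rows).set_index("subject")

    group: dict = {}
    freq = per["easy_choice_freq"].dropna()
    if len(freq) >= 2:
        res = ttest_1samp(freq, 0.5)
        group["easy_vs_half"] = {"mean": float(freq.mean()),
                                 "t": float(res.statistic),
                                 "p": float(res.pvalue), "n": len(freq)}
    null_freq = per["easy_choice_freq_null"].dropna()
    if len(null_freq) >= 2:
        res = ttest_1samp(null_freq, 0.5)
        group["null_class_vs_half"] = {"mean": float(null_freq.mean()),
                                       "t": float(res.statistic),
                                       "p": float(res.pvalue),
                                       "n": len(null_freq)}
    for a, b in (("positive", "negative"), ("positive", "null")):
        pair = per[[f"easy_choice_freq_{a}", f"easy_choice_freq_{b}"]].dropna()
        if len(pair) >= 2:
            res = ttest_rel(pair.iloc[:, 0], pair.iloc[:, 1])
            group[f"{a}_vs_{b}"] = {"t": float(res.statistic),
                                    "p": float(res.pvalue), "n": len(pair)}
    return SPEBehavior(per_subject=per, group=group)


def spe_sensitivity(summaries: pd.DataFrame) -> float:
    """Frequency of choosing the easier task at the end of blocks.

    Identical to the easy-choice frequency; exposed as the scalar
    brain-behavior covariate of global SPE sensitivity.
    """
    if len(summaries) == 0:
        raise ValueError("need >= 1 block")
    return float((summaries["chosen_task"] == summaries["easy_task"]).mean())


# ---------------------------------------------------------------------------
# logistic choice models
# ---------------------------------------------------------------------------

def _logistic_nll(params, X, y, ridge=0.0):
    eta = params[0] + X @ params[1:]
    # log(1+exp(-|eta|)) formulation is stable for large |eta|
    ll = y * eta - np.logaddexp(0.0, eta)
    return -float(np.sum(ll)) + ridge * float(params[1:] @ params[1:])


def logistic_fit(X: np.ndarray, y: np.ndarray) -> dict:
    """Small MLE logistic helper with a ridge fallback under separation.

    Returns intercept, coefficients, deviance (-2 logL at the returned
    point, without penalty) and a ``separation`` flag.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and len(y) != 1:
        X = X.T
    y = np.asarray(y, dtype=float)
    x0 = np.zeros(1 + X.shape[1])
    res = minimize(_logistic_nll, x0, args=(X, y), method="BFGS",
                   options={"maxiter": 1000, "gtol": 1e-8})
    grad_ok = np.max(np.abs(res.jac)) < 1e-3 * max(1.0, 0.01 * len(y))
    separation = not (res.success or grad_ok) or np.any(np.abs(res.x) > 15)
    if separation:
        res = minimize(_logistic_nll, x0, args=(X, y, _RIDGE), method="BFGS",
                       options={"maxiter": 2000})
    se = np.sqrt(np.clip(np.diag(res.hess_inv), 0, None))
    return {
        "intercept": float(res.x[0]),
        "coef": res.x[1:].copy(),
        "se": se[1:].copy(),
        "deviance": 2 * _logistic_nll(res.x, X, y),
        "separation": bool(separation),
        "converged": bool(res.success) and not separation,
    }


@dataclass
class ChoiceModelFit:
    """Per-subject logistic fits of task choice and their summed deviance."""

    model: str
    per_subject: pd.DataFrame
    summed_deviance: float
    group: pd.DataFrame | None = None


def _zscore_safe(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def task_choice_logistic(summaries: pd.DataFrame,
                         min_blocks: int = 10) -> ChoiceModelFit:
    """Logistic regression of task choice on difficulty, accuracy and their
    interaction.

    Outcome: 1 if the first-cued task was chosen.  Predictors: first-minus-
    second differences in square difference and realized accuracy, z-scored
    across blocks within subject, plus their product.  Coefficients are
    tested against zero at the group level with one-sample t tests.
    """
    names = ["difficulty", "accuracy", "interaction"]
    rows = []
    for sid, sub in summaries.groupby("subject"):
        if len(sub) < min_blocks:
            continue
        first = sub["first_task"].to_numpy()
        sgn = np.where(first == "A", 1.0, -1.0)
        d_delta = sgn * (sub["delta_A"] - sub["delta_B"]).to_numpy(dtype=float)
        d_acc = sgn * (sub["acc_A"] - sub["acc_B"]).to_numpy(dtype=float)
        zd, za = _zscore_safe(d_delta), _zscore_safe(d_acc)
        X = np.column_stack((zd, za, zd * za))
        y = (sub["chosen_task"].to_numpy() == first).astype(float)
        fit = logistic_fit(X, y)
        rows.append({"subject": sid,
                     **dict(zip(names, fit["coef"])),
                     "deviance": fit["deviance"],
                     "separation": fit["separation"]})
    per = pd.DataFrame(rows).set_index("subject")
    group_rows = []
    for name in names:
        vals = per[name].dropna()
        res = ttest_1samp(vals, 0.0) if len(vals) >= 2 else None
        group_rows.append({"coefficient": name, "mean": float(vals.mean()),
                           "t": float(res.statistic) if res else np.nan,
                           "p": float(res.pvalue) if res else np.nan,
                           "n": len(vals)})
    group = pd.DataFrame(group_rows).set_index("coefficient")
    return ChoiceModelFit("difficulty+accuracy", per,
                          float(per["deviance"].sum()), group)


_PREDICTOR_COLS = {
    "predicted_confidence": "pconf",
    "accuracy": "acc",
    "log_rt": "logrt",
}


def choice_model_deviance(summaries: pd.DataFrame,
                          predictor: str) -> ChoiceModelFit:
    """Goodness of fit of one block-level predictor of task choice.

    Per subject: a logistic regression of the choice (first-cued task
    chosen) on the first-minus-second difference of the predictor; the
    deviance (-2 logL) is summed across subjects.  Confidence, accuracy and
    RT models fitted this way are comparable on deviance.
    """
    if predictor not in _PREDICTOR_COLS:
        raise ValueError(f"predictor must be one of {list(_PREDICTOR_COLS)}")
    stem = _PREDICTOR_COLS[predictor]
    cols = [f"{stem}_A", f"{stem}_B"]
    if any(c not in summaries.columns for c in cols):
        raise ValueError(f"summaries lack columns {cols} for {predictor!r}")
    rows = []
    for sid, sub in summaries.groupby("subject"):
        sub = sub.dropna(subset=cols)
        first = sub["first_task"].to_numpy()
        sgn = np.where(first == "A", 1.0, -1.0)
        x = sgn * (sub[cols[0]] - sub[cols[1]]).to_numpy(dtype=float)
        y = (sub["chosen_task"].to_numpy() == first).astype(float)
        fit = logistic_fit(x[:, None], y)
        rows.append({"subject": sid, "beta": float(fit["coef"][0]),
                     "deviance": fit["deviance"],
                     "separation": fit["separation"]})
    per = pd.DataFrame(rows).set_index("subject")
    return ChoiceModelFit(predictor, per, float(per["deviance"].sum()))


# ---------------------------------------------------------------------------
# JZS Bayes factor
# ---------------------------------------------------------------------------

def jzs_bayes_factor(t_stat: float, n: int, r: float = np.sqrt(2) / 2) -> float:
    """Default-prior (JZS) Bayes factor BF10 for a one-sample t test.

    Cauchy prior with scale ``r`` on the standardized effect; the marginal
    likelihood under H1 is evaluated by adaptive quadrature over the
    inverse-gamma mixing variable.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    nu = n - 1
    t2 = float(t_stat) ** 2

    def integrand(g: float) -> float:
        a = 1.0 + n * g * r * r
        return (
            a ** -0.5
            * (1.0 + t2 / (a * nu)) ** (-(nu + 1) / 2)
            * (2 * np.pi) ** -0.5
            * g ** -1.5
            * np.exp(-1.0 / (2 * g))
        )

    num, err = quad(integrand, 0, np.inf, limit=200)
    if not np.isfinite(num) or num <= 0 or err > 1e-6 * max(num, 1e-300):
        raise RuntimeError(
            f"JZS integration failed: value={num}, abs err={err}"
        )
    den = (1.0 + t2 / nu) ** (-(nu + 1) / 2)
    return float(num / den)
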