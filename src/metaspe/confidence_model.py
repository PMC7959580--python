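"""Latent-confidence model: ordinal regression and cross-session transfer.

The metacognition session provides, for each subject, trial-wise 6-level
confidence ratings together with the decision features that plausibly drive
them: difficulty (square difference; larger = easier), accuracy, log RT and
the difficulty x accuracy interaction, each z-scored so coefficients are
comparable.  A cumulative-link (proportional-odds) model

    P(rating <= k | x) = F(theta_k - x . beta),   theta_1 < ... < theta_5

is fitted per subject by maximum likelihood (logit link by default, probit
available).  The fitted coefficients are then transferred to the main
session — where no ratings were collected — to produce a predicted
confidence for every trial as the probability-weighted mean rating
``sum_k k P(rating = k | x)``, a continuous value on the 1-6 scale.
Candidate regressor sets are compared by deviance summed across subjects.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import logistic, norm, t as t_dist

__all__ = [
    "FEATURES",
    "DEFAULT_CANDIDATE_SETS",
    "OrdinalFit",
    "ModelComparison",
    "build_features",
    "fit_ordinal",
    "compare_models",
    "predict_confidence",
    "group_coefficient_tests",
]

FEATURES = ["difficulty", "accuracy", "log_rt", "diff_x_acc"]

#: regressor grids compared by summed deviance
DEFAULT_CANDIDATE_SETS: list[tuple[str, ...]] = [
    ("accuracy",),
    ("log_rt",),
    ("difficulty",),
    ("accuracy", "log_rt"),
    ("accuracy", "difficulty"),
    ("log_rt", "difficulty"),
    ("accuracy", "log_rt", "difficulty"),
    ("accuracy", "log_rt", "difficulty", "diff_x_acc"),
]

_RIDGE = 1e-4
_EPS = 1e-12


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=0)


def build_features(trials: pd.DataFrame, min_trials: int = 20) -> pd.DataFrame:
    """Z-scored regressor table for one subject/session slice.

    Z-scoring is computed within the slice passed in (the scoring scope);
    the interaction is the product of the already z-scored difficulty and
    accuracy columns.  Constant columns (e.g. accuracy in an all-correct
    slice) cannot be z-scored: they are dropped with a warning, along with
    any interaction involving them.
    """
    t = trials[trials["response"] != "none"]
    if len(t) < min_trials:
        raise ValueError(f"need >= {min_trials} usable trials, got {len(t)}")
    raw = {
        "difficulty": t["delta"].to_numpy(dtype=float),
        "accuracy": t["accuracy"].to_numpy(dtype=float),
        "log_rt": np.log(t["rt_ms"].to_numpy(dtype=float)),
    }
    cols: dict[str, np.ndarray] = {}
    dropped = []
    for name, x in raw.items():
        if np.ptp(x) == 0:
            dropped.append(name)
        else:
            cols[name] = _zscore(x)
    if "difficulty" in cols and "accuracy" in cols:
        cols["diff_x_acc"] = cols["difficulty"] * cols["accuracy"]
    else:
        dropped.append("diff_x_acc")
    if dropped:
        warnings.warn(f"constant columns dropped: {dropped}", UserWarning)
    return pd.DataFrame(cols, index=t.index)


@dataclass
class OrdinalFit:
    """Proportional-odds MLE for 6-level confidence."""

    cutpoints: np.ndarray              # strictly increasing, length K-1
    betas: dict[str, float]
    beta_se: dict[str, float]
    deviance: float
    n_trials: int
    converged: bool
    link: str = "logit"
    categories: np.ndarray = field(default_factory=lambda: np.arange(1, 7))
    collapsed: bool = False            # True if rating categories were unobserved

    @property
    def feature_names(self) -> list[str]:
        return list(self.betas)


def _link_cdf(link: str):
    return logistic.cdf if link == "logit" else norm.cdf


def _ordinal_negloglik(params, X, y_rank, m, cdf, ridge=0.0):
    theta = np.concatenate((
        [params[0]], params[0] + np.cumsum(np.exp(np.clip(params[1:m - 1], -20, 20)))
    ))
    beta = params[m - 1:]
    eta = X @ beta if X.shape[1] else np.zeros(len(y_rank))
    upper = np.concatenate((theta, [np.inf]))[y_rank]
    lower = np.concatenate(([-np.inf], theta))[y_rank]
    p = cdf(upper - eta) - cdf(lower - eta)
    nll = -float(np.sum(np.log(np.clip(p, _EPS, None))))
    return nll + ridge * float(beta @ beta)


def fit_ordinal(
    features: pd.DataFrame,
    ratings: np.ndarray | pd.Series,
    link: str = "logit",
    n_categories: int = 6,
) -> OrdinalFit:
    """Fit the cumulative-link model by maximum likelihood.

    Cutpoint order is enforced by optimizing over the first cutpoint plus
    positive log-increments; initialization is deterministic, from the
    empirical cumulative link-quantiles with betas at zero.  Rating
    categories never observed in the data are collapsed onto their upper
    neighbour (duplicated cutpoints, flagged).  Complete separation is
    caught by a ridge (1e-4) refit with ``converged=False``.
    """
    y = np.asarray(ratings, dtype=int)
    if y.min() < 1 or y.max() > n_categories:
        raise ValueError("ratings must lie in 1..%d" % n_categories)
    cats = np.unique(y)
    if len(cats) < 2:
        raise ValueError("need >= 2 distinct rating values")
    X = np.asarray(features, dtype=float)
    names = list(features.columns)
    if len(X) != len(y):
        raise ValueError("features and ratings length mismatch")

    # fit on the observed-category rank scale
    y_rank = np.searchsorted(cats, y)
    m = len(cats)
    cdf = _link_cdf(link)
    quantile = logistic.ppf if link == "logit" else norm.ppf
    cum = np.cumsum(np.bincount(y_rank, minlength=m))[:-1] / len(y)
    theta0 = quantile(np.clip(cum, 0.01, 0.99))
    inc0 = np.log(np.clip(np.diff(theta0), 1e-3, None)) if m > 2 else np.array([])
    x0 = np.concatenate(([theta0[0]], inc0, np.zeros(X.shape[1])))

    res = minimize(_ordinal_negloglik, x0, args=(X, y_rank, m, cdf),
                   method="BFGS", options={"maxiter": 1000, "gtol": 1e-7})
    # BFGS can stop on precision loss with the gradient already negligible
    grad_ok = np.max(np.abs(res.jac)) < 1e-3 * max(1.0, 0.01 * len(y))
    converged = (bool(res.success) or grad_ok) and np.all(
        np.abs(res.x[m - 1:]) < 20
    )
    if not converged:
        res = minimize(_ordinal_negloglik, x0, args=(X, y_rank, m, cdf, _RIDGE),
                       method="BFGS", options={"maxiter": 1000})
        converged = False

    theta = np.concatenate((
        [res.x[0]], res.x[0] + np.cumsum(np.exp(np.clip(res.x[1:m - 1], -20, 20)))
    ))
    beta = res.x[m - 1:]
    se = np.sqrt(np.clip(np.diag(res.hess_inv), 0, None))[m - 1:]

    # expand collapsed categories: unobserved rating k gets a zero-mass bin
    # by duplicating the cutpoint of its lower neighbour
    full_theta = np.empty(n_categories - 1)
    collapsed = len(cats) < n_categories
    obs_upper = {c: i for i, c in enumerate(cats)}
    prev = theta[0] - 1.0
    for k in range(1, n_categories):          # cutpoint below category k+1
        # cumulative P(rating <= k) corresponds to the highest observed cat <= k
        below = [c for c in cats if c <= k]
        if below:
            i = obs_upper[below[-1]]
            prev = theta[i] if i < m - 1 else theta[-1]
        full_theta[k - 1] = prev

    deviance = 2 * _ordinal_negloglik(res.x, X, y_rank, m, cdf)
    return OrdinalFit(
        cutpoints=full_theta,
        betas=dict(zip(names, beta)),
        beta_se=dict(zip(names, se)),
        deviance=float(deviance),
        n_trials=len(y),
        converged=converged,
        link=link,
        categories=cats,
        collapsed=collapsed,
    )


def category_probabilities(fit: OrdinalFit, X: np.ndarray) -> np.ndarray:
    """P(rating = k | x) for k = 1..6, rows summing to one.

    Categories the fit never observed get probability zero.
    """
    cdf = _link_cdf(fit.link)
    beta = np.array([fit.betas[n] for n in fit.feature_names])
    eta = X @ beta if X.shape[1] else np.zeros(X.shape[0])
    # cumulative over observed categories, expanded to the 1..6 grid
    m = len(fit.categories)
    theta_obs = []
    # recover observed-scale cutpoints from the expanded vector
    for i, c in enumerate(fit.categories[:-1]):
        theta_obs.append(fit.cutpoints[c - 1])
    theta_obs = np.asarray(theta_obs)
    cum = cdf(theta_obs[None, :] - eta[:, None]) if m > 1 else np.empty((len(eta), 0))
    cum = np.concatenate((np.zeros((len(eta), 1)), cum, np.ones((len(eta), 1))), axis=1)
    p_obs = np.diff(cum, axis=1)
    probs = np.zeros((len(eta), 6))
    for i, c in enumerate(fit.categories):
        probs[:, c - 1] = p_obs[:, i]
    return probs


def predict_confidence(fit: OrdinalFit, features: pd.DataFrame) -> np.ndarray:
    """Expected rating ``sum_k k P(rating=k|x)`` per trial, in [1, 6].

    ``features`` must carry exactly the columns the model was fitted with
    (z-scored within the session being scored).
    """
    missing = [n for n in fit.feature_names if n not in features.columns]
    if missing:
        raise ValueError(f"feature set mismatch: missing {missing}")
    X = features[fit.feature_names].to_numpy(dtype=float)
    probs = category_probabilities(fit, X)
    return probs @ np.arange(1, 7)


@dataclass
class ModelComparison:
    """Per-candidate deviances summed across subjects, ranked ascending."""

    table: pd.DataFrame                 # index: candidate label
    per_subject: dict[str, dict[str, float]]
    skipped: dict[str, str]


def compare_models(
    trials: pd.DataFrame,
    candidate_sets: list[tuple[str, ...]] | None = None,
    link: str = "logit",
) -> ModelComparison:
    """Fit every candidate regressor set per subject; rank by summed deviance.

    Subjects whose features cannot be built (too few trials, degenerate
    columns required by a set) are skipped with a recorded reason.
    """
    candidate_sets = candidate_sets if candidate_sets is not None else DEFAULT_CANDIDATE_SETS
    labels = ["+".join(s) if s else "(intercept)" for s in candidate_sets]
    per_subject: dict[str, dict[str, float]] = {lab: {} for lab in labels}
    skipped: dict[str, str] = {}
    for sid, sub in trials.groupby("subject"):
        try:
            feats = build_features(sub)
            rated = sub.loc[feats.index, "confidence"]
            for lab, cset in zip(labels, candidate_sets):
                use = [c for c in cset if c in feats.columns]
                if len(use) < len(cset):
                    raise ValueError(f"set {cset} needs dropped columns")
                fit = fit_ordinal(feats[list(use)], rated, link=link)
                per_subject[lab][sid] = fit.deviance
        except ValueError as exc:
            skipped[sid] = str(exc)
            for lab in labels:
                per_subject[lab].pop(sid, None)
    rows = []
    for lab in labels:
        devs = per_subject[lab]
        rows.append({"model": lab, "summed_deviance": sum(devs.values()),
                     "n_subjects": len(devs)})
    table = pd.DataFrame(rows).set_index("model").sort_values("summed_deviance")
    table["rank"] = np.arange(1, len(table) + 1)
    return ModelComparison(table=table, per_subject=per_subject, skipped=skipped)


def group_coefficient_tests(fits: list[OrdinalFit]) -> pd.DataFrame:
    """One-sample t tests of each coefficient across subjects."""
    if len(fits) < 3:
        raise ValueError("need >= 3 subjects for group tests")
    names = fits[0].feature_names
    rows = []
    for name in names:
        vals = np.array([f.betas[name] for f in fits if name in f.betas])
        mean = vals.mean()
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        t_stat = mean / se if se > 0 else 0.0
        p = 2 * t_dist.sf(abs(t_stat), len(vals) - 1) if se > 0 else 1.0
        rows.append({"coefficient": name, "mean": mean, "t": t_stat,
                     "p": p, "n": len(vals)})
    return pd.DataFrame(rows).set_index("coefficient")
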