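"""Type-1 and type-2 signal-detection metrics of metacognition.

Confidence ratings from the metacognition session are scored against
accuracy with two complementary indices, computed separately per difficulty
level and then averaged:

* **meta-d′** — the type-1 sensitivity an SDT-ideal observer would need to
  produce the observed confidence-rating data, estimated by maximum
  likelihood from response-conditional rating counts.  Dividing by the
  actual d′ gives metacognitive efficiency (M-ratio), 1 for an observer
  whose confidence uses all the evidence in the decision.
* **AUROC2** — a model-free index: the area under the type-2 ROC built from
  cumulative confidence distributions conditional on correct vs incorrect
  responses.

A 2x2 (Accuracy x Difficulty) ANOVA on trial-level confidence quantifies
the influence of the experimental factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = [
    "RatingCounts",
    "MetaDFit",
    "AUROC2Result",
    "tabulate_ratings",
    "type1_sdt",
    "fit_metad",
    "auroc2",
    "per_condition_metrics",
    "anova_2x2",
]

_EPS = 1e-12


@dataclass(frozen=True)
class RatingCounts:
    """Response x rating counts conditional on stimulus class.

    ``n_s1`` / ``n_s2`` have length 2K, ordered from the highest-confidence
    "left" response down to rating 1, then rating 1 up to the
    highest-confidence "right" response.  ``padded()`` adds the standard
    1/(2K) cell padding so z-scores and log-likelihoods stay finite.
    """

    n_s1: np.ndarray  # stimulus class S1 = more squares on the left
    n_s2: np.ndarray  # stimulus class S2 = more squares on the right
    n_ratings: int

    def padded(self) -> tuple[np.ndarray, np.ndarray]:
        pad = 1.0 / (2 * self.n_ratings)
        return self.n_s1 + pad, self.n_s2 + pad


@dataclass(frozen=True)
class MetaDFit:
    """MLE meta-d′ fit alongside the type-1 summary."""

    d_prime: float
    criterion: float
    meta_d_prime: float
    m_ratio: float
    t2_criteria_s1: np.ndarray  # ascending, below the scaled type-1 criterion
    t2_criteria_s2: np.ndarray  # ascending, above it
    log_likelihood: float
    converged: bool


@dataclass(frozen=True)
class AUROC2Result:
    """Type-2 ROC area with the underlying operating points."""

    area: float
    hit_rates: np.ndarray        # P(rating >= k | correct), with endpoints
    false_alarm_rates: np.ndarray


def tabulate_ratings(trials: pd.DataFrame, n_ratings: int = 6) -> RatingCounts:
    """Count (response, rating) cells conditional on stimulus class.

    Missed trials (response ``"none"``) carry no rating and are dropped;
    a responded trial without a rating is an error.
    """
    t = trials[trials["response"] != "none"]
    missing = t[t["confidence"].isna()]
    if len(missing):
        idx = missing.index.tolist()[:10]
        raise ValueError(f"responded trials missing confidence ratings: rows {idx}")
    for cls in ("left", "right"):
        if not (t["side"] == cls).any():
            raise ValueError(f"no trials with stimulus class side={cls!r}")
    K = n_ratings
    n_s1 = np.zeros(2 * K, dtype=float)
    n_s2 = np.zeros(2 * K, dtype=float)
    rating = t["confidence"].to_numpy(dtype=int)
    # cell index: "left" responses occupy 0..K-1 (rating K first),
    # "right" responses occupy K..2K-1 (rating 1 first)
    cell = np.where(t["response"] == "left", K - rating, K - 1 + rating)
    for arr, cls in ((n_s1, "left"), (n_s2, "right")):
        sel = (t["side"] == cls).to_numpy()
        np.add.at(arr, cell[sel], 1.0)
    return RatingCounts(n_s1=n_s1, n_s2=n_s2, n_ratings=K)


def type1_sdt(counts: RatingCounts) -> tuple[float, float]:
    """d′ and criterion c from rating counts collapsed over confidence."""
    n_s1, n_s2 = counts.padded()
    K = counts.n_ratings
    far = n_s1[K:].sum() / n_s1.sum()   # "right" response to S1
    hr = n_s2[K:].sum() / n_s2.sum()    # "right" response to S2
    z_hr, z_far = norm.ppf(hr), norm.ppf(far)
    return float(z_hr - z_far), float(-0.5 * (z_hr + z_far))


def _metad_negloglik(
    x: np.ndarray, counts: tuple[np.ndarray, np.ndarray], K: int, c_rel: float
) -> float:
    """Negative log-likelihood of response-conditional rating counts.

    ``x`` = [meta_d, log-increments of the K-1 type-2 criteria below the
    scaled type-1 criterion (outward), log-increments above (outward)].
    """
    meta_d = x[0]
    c_meta = c_rel * meta_d
    inc_lo = np.exp(np.clip(x[1:K], -20, 20))
    inc_hi = np.exp(np.clip(x[K:], -20, 20))
    t2_lo = c_meta - np.cumsum(inc_lo)[::-1]          # ascending, < c_meta
    t2_hi = c_meta + np.cumsum(inc_hi)                # ascending, > c_meta
    bounds = np.concatenate(([-np.inf], t2_lo, [c_meta], t2_hi, [np.inf]))

    nll = 0.0
    n_s1, n_s2 = counts
    for n_obs, mu in ((n_s1, -meta_d / 2), (n_s2, meta_d / 2)):
        cdf = norm.cdf(bounds - mu)
        cell = np.diff(cdf)                            # 2K interval masses
        p_left = max(cdf[K], _EPS)                     # P(x < c_meta)
        p_right = max(1.0 - cdf[K], _EPS)
        cond = np.concatenate((cell[:K] / p_left, cell[K:] / p_right))
        nll -= float(np.sum(n_obs * np.log(np.clip(cond, _EPS, None))))
    return nll


def fit_metad(counts: RatingCounts) -> MetaDFit:
    """Maximum-likelihood meta-d′ from padded rating counts.

    The meta-level observer is Gaussian with sensitivity meta-d′ and its
    type-1 criterion held at the empirically scaled position
    ``c * meta_d′ / d′``; free parameters are meta-d′ and the 2(K-1) type-2
    criteria, kept ordered by optimizing over positive log-increments.
    Deterministic multistart; non-convergence returns the best point with
    ``converged=False``.
    """
    K = counts.n_ratings
    d1, c1 = type1_sdt(counts)
    c_rel = c1 / d1 if abs(d1) > 1e-8 else 0.0
    padded = counts.padded()

    starts = []
    for md0, spacing in ((d1, 0.45), (0.5 * d1 + 0.1, 0.25), (d1, 0.8)):
        starts.append(np.concatenate((
            [md0], np.full(K - 1, np.log(spacing)), np.full(K - 1, np.log(spacing))
        )))
    best = None
    for x0 in starts:
        res = minimize(
            _metad_negloglik, x0, args=(padded, K, c_rel),
            method="L-BFGS-B", options={"maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    meta_d = float(best.x[0])
    c_meta = c_rel * meta_d
    inc_lo = np.exp(np.clip(best.x[1:K], -20, 20))
    inc_hi = np.exp(np.clip(best.x[K:], -20, 20))
    return MetaDFit(
        d_prime=d1,
        criterion=c1,
        meta_d_prime=meta_d,
        m_ratio=float(meta_d / d1) if abs(d1) > 1e-8 else float("nan"),
        t2_criteria_s1=c_meta - np.cumsum(inc_lo)[::-1],
        t2_criteria_s2=c_meta + np.cumsum(inc_hi),
        log_likelihood=-float(best.fun),
        converged=bool(best.success),
    )


def auroc2(correct: np.ndarray, ratings: np.ndarray,
           n_ratings: int = 6) -> AUROC2Result:
    """Area under the type-2 ROC.

    Sweeps the K-1 confidence thresholds: a type-2 "hit" is a high-confidence
    correct trial, a type-2 "false alarm" a high-confidence error.  Endpoints
    (0,0) and (1,1) are appended and the area integrated by trapezoid; ties
    are handled by the cumulative distributions themselves.  All-correct or
    all-error input has no type-2 ROC: returns NaN area.
    """
    correct = np.asarray(correct, dtype=bool)
    ratings = np.asarray(ratings, dtype=float)
    if correct.all() or not correct.any():
        empty = np.array([])
        return AUROC2Result(float("nan"), empty, empty)
    thresholds = np.arange(n_ratings, 1, -1)  # K, K-1, ..., 2
    h = [(ratings[correct] >= k).mean() for k in thresholds]
    f = [(ratings[~correct] >= k).mean() for k in thresholds]
    hits = np.concatenate(([0.0], h, [1.0]))
    fas = np.concatenate(([0.0], f, [1.0]))
    area = float(np.trapezoid(hits, fas))
    return AUROC2Result(area, hits, fas)


def per_condition_metrics(trials: pd.DataFrame) -> dict:
    """M-ratio and AUROC2 per difficulty level, plus their across-level mean.

    Difficulty levels are the distinct square differences present (the
    larger difference is the easier condition).  A condition in which
    AUROC2 is undefined propagates NaN into the average.
    """
    levels = np.sort(trials["delta"].unique())[::-1]
    out: dict = {"per_level": {}}
    for name, delta in zip(("easy", "hard"), levels):
        sub = trials[(trials["delta"] == delta) & (trials["response"] != "none")]
        fit = fit_metad(tabulate_ratings(sub))
        roc = auroc2(sub["accuracy"].to_numpy(), sub["confidence"].to_numpy())
        out["per_level"][name] = {
            "delta": int(delta),
            "d_prime": fit.d_prime,
            "meta_d_prime": fit.meta_d_prime,
            "m_ratio": fit.m_ratio,
            "auroc2": roc.area,
        }
    per = out["per_level"]
    out["m_ratio_avg"] = float(np.mean([per[k]["m_ratio"] for k in per]))
    out["auroc2_avg"] = float(np.mean([per[k]["auroc2"] for k in per]))
    return out


def anova_2x2(trials: pd.DataFrame) -> pd.DataFrame:
    """Two-way ANOVA (Accuracy x Difficulty, with interaction) on confidence.

    Regression-formulated so unbalanced cells are handled; returns a frame
    indexed by effect with columns F and p.  Requires all four cells
    populated.  Zero-variance confidence yields F = 0, p = 1 for every
    effect (no variance to attribute).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    t = trials[trials["response"] != "none"].copy()
    levels = np.sort(t["delta"].unique())[::-1]
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 difficulty levels, got {len(levels)}")
    t["difficulty"] = np.where(t["delta"] == levels[0], "easy", "hard")
    for acc in (0, 1):
        for diff in ("easy", "hard"):
            if not ((t["accuracy"] == acc) & (t["difficulty"] == diff)).any():
                raise ValueError(f"empty cell: accuracy={acc}, difficulty={diff}")
    effects = ["C(accuracy)", "C(difficulty)", "C(accuracy):C(difficulty)"]
    if t["confidence"].nunique() <= 1:
        return pd.DataFrame({"F": 0.0, "p": 1.0}, index=effects)
    model = smf.ols("confidence ~ C(accuracy) * C(difficulty)", data=t).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return pd.DataFrame(
        {"F": table.loc[effects, "F"], "p": table.loc[effects, "PR(>F)"]}
    )
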