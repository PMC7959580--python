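"""Psychometric calibration: cumulative-normal fit and difficulty extraction.

The calibration session presents ten square-difference levels; accuracy as a
function of the square difference ``delta`` is modelled as

    P(correct | delta) = lapse/2 + (1 - lapse) * Phi(delta / sigma_f)

a cumulative normal through 0.5 at delta = 0 (the 2AFC guess rate), with an
optional lapse flattening the upper asymptote.  Inverting the fitted curve
at the two target accuracies (70% and 85% by default) yields the per-subject
easy and difficult stimulus levels used in the main and metacognition
sessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = [
    "PsychometricFit",
    "fit_psychometric",
    "invert_psychometric",
    "extract_difficulty_levels",
]

_SIGMA_BOUNDS = (1e-2, 1e4)
_MAX_LAPSE = 0.1


@dataclass(frozen=True)
class PsychometricFit:
    """Maximum-likelihood cumulative-normal psychometric fit."""

    sigma_f: float
    lapse_hat: float
    log_likelihood: float
    converged: bool
    n_trials: int

    def predict(self, delta: np.ndarray | float) -> np.ndarray | float:
        """P(correct) at square difference ``delta``."""
        return self.lapse_hat / 2 + (1 - self.lapse_hat) * norm.cdf(
            np.asarray(delta, dtype=float) / self.sigma_f
        )


def _negloglik(sigma: float, lapse: float, delta: np.ndarray,
               correct: np.ndarray) -> float:
    p = lapse / 2 + (1 - lapse) * norm.cdf(delta / sigma)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -float(np.sum(np.where(correct, np.log(p), np.log1p(-p))))


def fit_psychometric(trials: pd.DataFrame, fix_lapse: bool = True) -> PsychometricFit:
    """Fit the psychometric function to calibration trials by MLE.

    ``trials`` needs columns ``delta``, ``accuracy`` and ``response``;
    missed trials (response ``"none"``) are ignored.  A multistart over a
    log-spaced ``sigma_f`` grid guards against local optima.  Data with no
    information about the slope (all correct or all error) are returned as a
    non-identifiable fit with ``sigma_f`` at a bound and ``converged=False``
    rather than raising.
    """
    responded = trials[trials["response"] != "none"]
    delta = responded["delta"].to_numpy(dtype=float)
    correct = responded["accuracy"].to_numpy(dtype=int).astype(bool)
    if len(np.unique(delta)) < 2:
        raise ValueError("need >= 2 distinct delta levels to fit")
    n = len(delta)

    if correct.all() or not correct.any():
        # degenerate: likelihood is monotone in sigma, pin at a bound
        sigma = _SIGMA_BOUNDS[0] if correct.all() else _SIGMA_BOUNDS[1]
        ll = -_negloglik(sigma, 0.0, delta, correct)
        return PsychometricFit(sigma, 0.0, ll, converged=False, n_trials=n)

    starts = np.geomspace(delta.min(), delta.max() * 3, num=6)
    best = None
    for s0 in starts:
        if fix_lapse:
            x0 = [np.log(s0)]

            def nll(x):
                return _negloglik(np.exp(x[0]), 0.0, delta, correct)
        else:
            x0 = [np.log(s0), -4.0]  # logit-ish lapse start near 0

            def nll(x):
                lapse = _MAX_LAPSE / (1 + np.exp(-x[1]))
                return _negloglik(np.exp(x[0]), lapse, delta, correct)

        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    sigma_f = float(np.exp(best.x[0]))
    lapse_hat = 0.0 if fix_lapse else float(_MAX_LAPSE / (1 + np.exp(-best.x[1])))
    converged = bool(best.success) and _SIGMA_BOUNDS[0] < sigma_f < _SIGMA_BOUNDS[1]
    if not converged:
        warnings.warn("psychometric fit did not converge cleanly", RuntimeWarning)
    return PsychometricFit(sigma_f, lapse_hat, -float(best.fun),
                           converged=converged, n_trials=n)


def invert_psychometric(fit: PsychometricFit, p_target: float) -> tuple[int, float]:
    """Stimulus level at which the fitted curve reaches ``p_target``.

    Closed form: ``delta = sigma_f * Phi^-1((p - lapse/2) / (1 - lapse))``.
    Returns ``(rounded integer level, unrounded level)``; the integer is the
    discrete square-count difference actually presentable.
    """
    lo, hi = fit.lapse_hat / 2, 1 - fit.lapse_hat / 2
    if not lo < p_target < hi:
        raise ValueError(
            f"p_target={p_target} outside attainable range ({lo}, {hi})"
        )
    exact = fit.sigma_f * norm.ppf((p_target - lo) / (1 - fit.lapse_hat))
    return int(round(exact)), float(exact)


def extract_difficulty_levels(
    fit: PsychometricFit, targets: tuple[float, float] = (0.70, 0.85)
) -> tuple[int, int]:
    """Integer (easy, hard) square differences for the two accuracy targets.

    The higher target defines the easy level.  Integer levels are forced to
    be >= 1 and strictly ordered (a rounding collision bumps the easy level
    up by one).
    """
    lo_t, hi_t = sorted(targets)
    hard, _ = invert_psychometric(fit, lo_t)
    easy, _ = invert_psychometric(fit, hi_t)
    hard = max(1, hard)
    easy = max(1, easy)
    if easy <= hard:
        easy = hard + 1
    return easy, hard
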