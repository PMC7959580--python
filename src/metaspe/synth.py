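"""Synthetic metacognitive-observer simulator.

Generates complete behavioral datasets for a two-alternative "which box has
more squares" discrimination study in three sessions:

* a **calibration** session (200 trials over ten square-difference levels,
  no confidence ratings) used to fit a psychometric function,
* a **main** session of short blocks in which two tasks (one easy, one
  difficult) alternate pseudorandomly and the subject chooses the task they
  believe they performed best at the end of every block (the behavioral
  proxy for a global self-performance estimate, SPE),
* a **metacognition** session (200 trials at the two calibrated difficulty
  levels) with a 6-point confidence rating on every trial.

The generative agent is a Gaussian signal-detection observer: on a trial
with square difference ``delta`` and correct side ``s`` (+1 right, -1 left)
it draws decision evidence ``e ~ Normal(s * delta / sigma_p, 1)`` and
responds with the sign of ``e``.  Confidence arises from meta-level evidence
``m = |e| + Normal(0, sigma_m)`` cut by five fixed criteria into ratings
1-6, so ``sigma_m = 0`` yields an SDT-ideal metacognitive observer
(M-ratio = 1) and larger ``sigma_m`` degrades metacognitive efficiency
without touching type-1 accuracy.  End-of-block task choices follow a
softmax on the within-block mean confidence difference with temperature
``tau`` — each local confidence sample contributes evidence toward the
global estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ObserverParams",
    "DesignParams",
    "TrialRecord",
    "BlockRecord",
    "StimulusSpec",
    "TRIAL_COLUMNS",
    "simulate_trial",
    "simulate_trials",
    "generate_block_sequence",
    "simulate_calibration_session",
    "simulate_main_session",
    "simulate_metacog_session",
    "simulate_subject",
    "simulate_cohort",
    "write_sidecar",
]

# Canonical tidy trial-table header shared by synthetic and deposited-style data.
TRIAL_COLUMNS = [
    "subject", "session", "block", "trial", "task", "delta", "side",
    "response", "accuracy", "rt_ms", "confidence", "chosen_task",
]

#: columns carrying generative ground truth, kept only for recovery tests
INTERNAL_COLUMNS = ["evidence", "meta_evidence", "conf_true"]

RT_FLOOR_MS = 200.0  # keeps log RT finite and sub-deadline RTs physiological


class ParameterError(ValueError):
    """Invalid observer or stimulus parameter."""


class DesignError(ValueError):
    """Unsatisfiable or inconsistent experimental-design parameters."""


@dataclass(frozen=True)
class ObserverParams:
    """Generative SDT agent.

    Parameters
    ----------
    sigma_p
        Perceptual noise in square-difference units (> 0).  Accuracy at
        square difference ``delta`` is ``Phi(delta / sigma_p)`` (lapse-free).
    lapse
        Probability of a stimulus-independent uniform guess, in [0, 0.1].
    sigma_m
        Metacognitive noise: SD of additive Gaussian noise on the absolute
        decision evidence before it is cut into confidence ratings (>= 0).
    criteria
        Five strictly increasing nonnegative thresholds on meta-evidence
        mapping to ratings 1-6.
    rt_intercept, rt_slope, rt_sd
        Log-RT model: ``log rt = rt_intercept - rt_slope * |e| + noise``.
    miss_rate
        Probability of no response on a trial, in [0, 0.05].
    tau
        Task-choice softmax temperature (> 0); small tau makes the
        end-of-block choice an argmax over mean confidence.
    """

    sigma_p: float = 12.0
    lapse: float = 0.0
    sigma_m: float = 0.5
    criteria: tuple[float, ...] = (0.4, 0.8, 1.2, 1.7, 2.3)
    rt_intercept: float = 6.94
    rt_slope: float = 0.22
    rt_sd: float = 0.25
    miss_rate: float = 0.02
    tau: float = 0.5

    def __post_init__(self) -> None:
        if not self.sigma_p > 0:
            raise ParameterError(f"sigma_p must be > 0, got {self.sigma_p}")
        if not 0 <= self.lapse <= 0.1:
            raise ParameterError(f"lapse must be in [0, 0.1], got {self.lapse}")
        if not self.sigma_m >= 0:
            raise ParameterError(f"sigma_m must be >= 0, got {self.sigma_m}")
        crit = np.asarray(self.criteria, dtype=float)
        if crit.ndim != 1 or len(crit) != 5:
            raise ParameterError("criteria must be 5 thresholds (ratings 1-6)")
        if np.any(crit < 0) or np.any(np.diff(crit) <= 0):
            raise ParameterError("criteria must be nonnegative and strictly increasing")
        if not self.rt_sd >= 0:
            raise ParameterError(f"rt_sd must be >= 0, got {self.rt_sd}")
        if not 0 <= self.miss_rate <= 0.05:
            raise ParameterError(f"miss_rate must be in [0, 0.05], got {self.miss_rate}")
        if not self.tau > 0:
            raise ParameterError(f"tau must be > 0, got {self.tau}")


@dataclass(frozen=True)
class DesignParams:
    """Experimental design constants of the three-session paradigm."""

    n_blocks: int = 32
    trials_per_block: int = 12
    trials_per_task: int = 6
    max_run: int = 3
    calib_levels: tuple[int, ...] = (2, 5, 7, 9, 10, 12, 14, 18, 34, 70)
    n_calib_trials: int = 200
    n_metacog_trials: int = 200
    target_accuracies: tuple[float, float] = (0.70, 0.85)
    n_rating_levels: int = 6
    deadline_ms: float = 1500.0

    def __post_init__(self) -> None:
        if self.trials_per_block != 2 * self.trials_per_task:
            raise DesignError("trials_per_block must equal 2 * trials_per_task")
        if any(not (0.5 < t < 1.0) for t in self.target_accuracies):
            raise DesignError("target accuracies must be strictly within (0.5, 1)")
        if any((int(v) != v or v <= 0) for v in self.calib_levels):
            raise DesignError("calib_levels must be positive integers")
        if self.max_run < 1:
            raise DesignError("max_run must be >= 1")


@dataclass(frozen=True)
class StimulusSpec:
    """Numeric specification of one stimulus pair (no rendering).

    The reference grid is always half filled; the comparison grid holds
    ``reference + delta`` squares and cannot exceed grid capacity.
    """

    delta: int
    reference: int = 200
    capacity: int = 400

    def __post_init__(self) -> None:
        if not self.reference <= self.comparison <= self.capacity:
            raise ParameterError(
                f"comparison count {self.comparison} outside "
                f"[{self.reference}, {self.capacity}]"
            )

    @property
    def comparison(self) -> int:
        return self.reference + self.delta


@dataclass
class TrialRecord:
    """One perceptual decision."""

    subject: str
    session: str
    block: int
    trial: int
    task: str | None
    delta: int
    side: str
    response: str
    accuracy: int
    rt_ms: float
    confidence: int | None
    # generative ground truth, for recovery tests only
    evidence: float = np.nan
    meta_evidence: float = np.nan
    conf_true: int | None = None


@dataclass
class BlockRecord:
    """One main-session block: task->difficulty assignment and end choice."""

    block: int
    easy_task: str
    delta_A: int
    delta_B: int
    sequence: tuple[str, ...]
    chosen_task: str
    first_task: str = field(init=False)

    def __post_init__(self) -> None:
        self.first_task = self.sequence[0]


# ---------------------------------------------------------------------------
# trial-level simulation
# ---------------------------------------------------------------------------

def simulate_trials(
    deltas: np.ndarray,
    sides: np.ndarray,
    params: ObserverParams,
    rng: np.random.Generator,
    deadline_ms: float = 1500.0,
) -> pd.DataFrame:
    """Vectorized core: simulate one decision per (delta, side) pair.

    Returns a frame with columns delta, side, response, accuracy, rt_ms,
    confidence (rating 1-6) plus the internal evidence columns.  Missed
    trials have response "none", accuracy 0 and NaN rt/confidence.
    """
    deltas = np.asarray(deltas, dtype=float)
    sides = np.asarray(sides)
    if np.any(deltas <= 0):
        raise ParameterError("square difference delta must be > 0")
    if not np.all(np.isin(sides, ["left", "right"])):
        raise ParameterError("side must be 'left' or 'right'")
    n = len(deltas)
    sign = np.where(sides == "right", 1.0, -1.0)

    evidence = rng.normal(sign * deltas / params.sigma_p, 1.0)
    response = np.where(evidence > 0, "right", "left")
    # stimulus-independent lapses: uniform guess
    lapse_mask = rng.random(n) < params.lapse
    if lapse_mask.any():
        guesses = rng.choice(["left", "right"], size=int(lapse_mask.sum()))
        response[lapse_mask] = guesses
    miss_mask = rng.random(n) < params.miss_rate

    meta_evidence = np.abs(evidence) + rng.normal(0.0, params.sigma_m, size=n)
    crit = np.asarray(params.criteria, dtype=float)
    rating = 1 + (meta_evidence[:, None] > crit[None, :]).sum(axis=1)

    log_rt = (
        params.rt_intercept
        - params.rt_slope * np.abs(evidence)
        + rng.normal(0.0, params.rt_sd, size=n)
    )
    rt_ms = np.clip(np.exp(log_rt), RT_FLOOR_MS, deadline_ms)

    accuracy = (response == sides).astype(int)
    out = pd.DataFrame(
        {
            "delta": deltas.astype(int),
            "side": sides,
            "response": response,
            "accuracy": accuracy,
            "rt_ms": rt_ms,
            "confidence": rating,
            "evidence": evidence,
            "meta_evidence": meta_evidence,
            "conf_true": rating,
        }
    )
    if miss_mask.any():
        out.loc[miss_mask, "response"] = "none"
        out.loc[miss_mask, "accuracy"] = 0
        out.loc[miss_mask, ["rt_ms", "confidence", "conf_true"]] = np.nan
    return out


def simulate_trial(
    delta: float,
    side: str,
    params: ObserverParams,
    rng: np.random.Generator,
    deadline_ms: float = 1500.0,
) -> TrialRecord:
    """Simulate a single decision; see :func:`simulate_trials`."""
    row = simulate_trials(np.array([delta]), np.array([side]), params, rng,
                          deadline_ms).iloc[0]
    conf = None if pd.isna(row["confidence"]) else int(row["confidence"])
    return TrialRecord(
        subject="sim", session="single", block=0, trial=0, task=None,
        delta=int(row["delta"]), side=row["side"], response=row["response"],
        accuracy=int(row["accuracy"]),
        rt_ms=float(row["rt_ms"]) if not pd.isna(row["rt_ms"]) else np.nan,
        confidence=conf, evidence=float(row["evidence"]),
        meta_evidence=float(row["meta_evidence"]), conf_true=conf,
    )


# ---------------------------------------------------------------------------
# block sequence
# ---------------------------------------------------------------------------

def generate_block_sequence(
    design: DesignParams, rng: np.random.Generator, max_tries: int = 10_000
) -> list[str]:
    """Pseudorandom task sequence for one block.

    Exactly ``trials_per_task`` trials of each task with no run of the same
    task longer than ``max_run``; rejection sampling with a retry cap.
    """
    base = np.array(["A"] * design.trials_per_task + ["B"] * design.trials_per_task)
    for _ in range(max_tries):
        seq = rng.permutation(base)
        if _max_run_length(seq) <= design.max_run:
            return list(seq)
    raise DesignError(
        f"could not satisfy max_run={design.max_run} in {max_tries} tries"
    )


def _max_run_length(seq: Sequence[str]) -> int:
    longest = run = 1
    for a, b in zip(seq, list(seq)[1:]):
        run = run + 1 if a == b else 1
        longest = max(longest, run)
    return longest


# ---------------------------------------------------------------------------
# sessions
# ---------------------------------------------------------------------------

def _balanced_sides(n: int, rng: np.random.Generator) -> np.ndarray:
    """Left/right labels with counts differing by at most one, shuffled."""
    half = n // 2
    sides = np.array(["left"] * half + ["right"] * (n - half))
    if n % 2:  # random parity of the odd side
        sides[-1] = rng.choice(["left", "right"])
    return rng.permutation(sides)


def simulate_calibration_session(
    params: ObserverParams,
    design: DesignParams,
    rng: np.random.Generator,
    subject: str = "s01",
) -> pd.DataFrame:
    """Calibration phase: equal trial counts at each square-difference level,
    balanced sides, randomized order, no confidence ratings."""
    levels = design.calib_levels
    n_levels = len(levels)
    if design.n_calib_trials % n_levels:
        raise DesignError(
            f"n_calib_trials={design.n_calib_trials} not divisible by "
            f"{n_levels} levels"
        )
    per_level = design.n_calib_trials // n_levels
    deltas = np.repeat(levels, per_level)
    sides = np.concatenate([_balanced_sides(per_level, rng) for _ in levels])
    order = rng.permutation(len(deltas))
    frame = simulate_trials(deltas[order], sides[order], params, rng,
                            design.deadline_ms)
    frame[["confidence", "conf_true", "meta_evidence"]] = np.nan
    frame.insert(0, "subject", subject)
    frame.insert(1, "session", "calibration")
    frame.insert(2, "block", 0)
    frame.insert(3, "trial", np.arange(len(frame)))
    frame.insert(4, "task", None)
    frame["chosen_task"] = None
    return frame[TRIAL_COLUMNS + INTERNAL_COLUMNS]


def simulate_main_session(
    params: ObserverParams,
    design: DesignParams,
    easy_delta: int,
    hard_delta: int,
    rng: np.random.Generator,
    subject: str = "s01",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Main (in-scanner analog) session: blocks of two interleaved tasks.

    Within each block one task is randomly assigned the easy level and the
    other the difficult level.  The end-of-block task choice is sampled from
    ``P(choose A) = logistic((mean_conf_A - mean_conf_B) / tau)`` where the
    means are over the block's simulated confidence ratings (1-6 scale).
    Confidence is never reported in this session; the ratings used for the
    choice are retained only in the internal ``conf_true`` column.

    Returns (trials, blocks) frames.
    """
    if not easy_delta > hard_delta > 0:
        raise ParameterError(
            f"need easy_delta > hard_delta > 0, got {easy_delta}, {hard_delta}"
        )
    trial_frames = []
    block_rows = []
    for b in range(design.n_blocks):
        easy_task = rng.choice(["A", "B"])
        delta_by_task = {
            "A": easy_delta if easy_task == "A" else hard_delta,
            "B": easy_delta if easy_task == "B" else hard_delta,
        }
        seq = np.array(generate_block_sequence(design, rng))
        deltas = np.array([delta_by_task[t] for t in seq], dtype=float)
        # sides pseudorandomized per task within block
        sides = np.empty(len(seq), dtype=object)
        for t in ("A", "B"):
            idx = np.flatnonzero(seq == t)
            sides[idx] = _balanced_sides(len(idx), rng)
        frame = simulate_trials(deltas, sides.astype(str), params, rng,
                                design.deadline_ms)
        frame.insert(0, "subject", subject)
        frame.insert(1, "session", "main")
        frame.insert(2, "block", b)
        frame.insert(3, "trial", np.arange(len(frame)))
        frame.insert(4, "task", seq)

        conf = frame.groupby("task")["conf_true"].mean()
        # a fully-missed task contributes the scale midpoint (no information)
        mid = (1 + design.n_rating_levels) / 2
        mean_a = conf.get("A", np.nan)
        mean_b = conf.get("B", np.nan)
        mean_a = mid if pd.isna(mean_a) else mean_a
        mean_b = mid if pd.isna(mean_b) else mean_b
        from scipy.special import expit

        p_choose_a = expit((mean_a - mean_b) / params.tau)
        chosen = "A" if rng.random() < p_choose_a else "B"
        frame["chosen_task"] = chosen
        frame["confidence"] = np.nan  # not reported in this session
        trial_frames.append(frame[TRIAL_COLUMNS + INTERNAL_COLUMNS])
        block_rows.append(
            BlockRecord(block=b, easy_task=easy_task,
                        delta_A=delta_by_task["A"], delta_B=delta_by_task["B"],
                        sequence=tuple(seq), chosen_task=chosen)
        )
    trials = pd.concat(trial_frames, ignore_index=True)
    blocks = pd.DataFrame(
        {
            "subject": subject,
            "block": [r.block for r in block_rows],
            "easy_task": [r.easy_task for r in block_rows],
            "delta_A": [r.delta_A for r in block_rows],
            "delta_B": [r.delta_B for r in block_rows],
            "first_task": [r.first_task for r in block_rows],
            "chosen_task": [r.chosen_task for r in block_rows],
        }
    )
    return trials, blocks


def simulate_metacog_session(
    params: ObserverParams,
    design: DesignParams,
    easy_delta: int,
    hard_delta: int,
    rng: np.random.Generator,
    subject: str = "s01",
) -> pd.DataFrame:
    """Metacognition session: the two calibrated levels randomly interleaved
    in equal proportion, every responded trial rated 1-6."""
    if not easy_delta > hard_delta > 0:
        raise ParameterError(
            f"need easy_delta > hard_delta > 0, got {easy_delta}, {hard_delta}"
        )
    n = design.n_metacog_trials
    half = n // 2
    deltas = np.array([easy_delta] * half + [hard_delta] * (n - half), dtype=float)
    sides = np.concatenate(
        [_balanced_sides(half, rng), _balanced_sides(n - half, rng)]
    )
    order = rng.permutation(n)
    frame = simulate_trials(deltas[order], sides[order], params, rng,
                            design.deadline_ms)
    frame.insert(0, "subject", subject)
    frame.insert(1, "session", "metacog")
    frame.insert(2, "block", 0)
    frame.insert(3, "trial", np.arange(n))
    frame.insert(4, "task", None)
    frame["chosen_task"] = None
    return frame[TRIAL_COLUMNS + INTERNAL_COLUMNS]


# ---------------------------------------------------------------------------
# subject / cohort convenience
# ---------------------------------------------------------------------------

def simulate_subject(
    params: ObserverParams,
    design: DesignParams,
    rng: np.random.Generator,
    subject: str = "s01",
    easy_delta: int | None = None,
    hard_delta: int | None = None,
) -> dict:
    """Simulate all three sessions of one subject.

    If difficulty levels are not supplied they are the observer's true
    levels, ``sigma_p * Phi^-1(target)`` rounded to integers (>= 1), so the
    simulated paradigm is calibrated the way the real one was.
    """
    from scipy.stats import norm

    if easy_delta is None or hard_delta is None:
        lo, hi = sorted(design.target_accuracies)
        hard_delta = max(1, round(params.sigma_p * norm.ppf(lo)))
        easy_delta = max(hard_delta + 1, round(params.sigma_p * norm.ppf(hi)))
    calib = simulate_calibration_session(params, design, rng, subject)
    main, blocks = simulate_main_session(
        params, design, easy_delta, hard_delta, rng, subject
    )
    metacog = simulate_metacog_session(
        params, design, easy_delta, hard_delta, rng, subject
    )
    return {
        "trials": pd.concat([calib, main, metacog], ignore_index=True),
        "blocks": blocks,
        "easy_delta": easy_delta,
        "hard_delta": hard_delta,
        "params": params,
    }


def sample_observer(rng: np.random.Generator) -> ObserverParams:
    """Draw one subject's observer parameters from realistic cohort ranges."""
    return ObserverParams(
        sigma_p=float(rng.uniform(9.0, 16.0)),
        lapse=float(rng.uniform(0.0, 0.02)),
        sigma_m=float(rng.uniform(0.2, 0.8)),
        criteria=tuple(np.cumsum(rng.uniform(0.25, 0.6, size=5))),
        rt_intercept=float(rng.uniform(6.8, 7.1)),
        rt_slope=float(rng.uniform(0.15, 0.3)),
        rt_sd=float(rng.uniform(0.2, 0.3)),
        miss_rate=float(rng.uniform(0.0, 0.04)),
        tau=float(rng.uniform(0.3, 0.8)),
    )


def simulate_cohort(
    n_subjects: int,
    seed: int,
    design: DesignParams | None = None,
    params: ObserverParams | None = None,
) -> dict:
    """Simulate a cohort; per-subject generators derived by fixed offsets.

    If ``params`` is None each subject's observer is drawn from
    :func:`sample_observer` (between-subject variability); otherwise every
    subject shares ``params``.
    """
    design = design or DesignParams()
    subjects = {}
    for i in range(n_subjects):
        sid = f"s{i + 1:02d}"
        rng = np.random.default_rng([seed, i])
        p = params or sample_observer(rng)
        subjects[sid] = simulate_subject(p, design, rng, subject=sid)
    trials = pd.concat([s["trials"] for s in subjects.values()], ignore_index=True)
    blocks = pd.concat([s["blocks"] for s in subjects.values()], ignore_index=True)
    return {"trials": trials, "blocks": blocks, "subjects": subjects,
            "design": design, "seed": seed}


def write_sidecar(path: str | Path, params: ObserverParams,
                  design: DesignParams, seed: int) -> None:
    """JSON sidecar recording the generating parameters and seed."""
    payload = {
        "observer": asdict(params),
        "design": asdict(design),
        "seed": seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=list) + "\n")
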