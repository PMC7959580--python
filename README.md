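# metaspe

Simulation and analysis of **local confidence** and **global
self-performance estimates (SPEs)** in perceptual decision making.

People do not only feel more or less confident about single decisions —
they also form broader beliefs about how good they are at a task. This
package implements the behavioral machinery for studying how the second is
built from the first, in a three-session psychophysics paradigm:

1. **Calibration** — 200 two-alternative "which box has more squares"
   trials over ten square-difference levels. A cumulative-normal
   psychometric function `P(correct | Δ) = λ/2 + (1−λ)·Φ(Δ/σ)` is fitted
   per subject and inverted to find the stimulus levels producing 70% and
   85% correct.
2. **Main task** — 32 blocks of 12 trials; in each block two tasks (one at
   the easy level, one at the difficult level) alternate pseudorandomly
   with at most three consecutive trials of the same task and no feedback.
   At the end of every block the subject chooses the task they think they
   performed best — the behavioral proxy for a global SPE.
3. **Metacognition task** — 200 trials at the two calibrated levels with a
   1–6 confidence rating on every trial.

Because no human dataset ships with the package, a parameterized
signal-detection observer generates all three sessions: decision evidence
`e ~ N(±Δ/σ_p, 1)`, responses by the sign of `e`, confidence from
`|e| + N(0, σ_m)` cut by fixed criteria into six ratings, log-normal
response times decreasing in `|e|`, and end-of-block choices from a softmax
over the within-block mean confidence difference with temperature `τ`.

On top of that the package provides the full analysis pipeline:

- **Psychometric calibration** (`psychometric`): maximum-likelihood
  cumulative-normal fit, closed-form inversion, integer difficulty levels.
- **Metacognition metrics** (`metacog`): type-1 d′ and criterion,
  maximum-likelihood **meta-d′** and metacognitive efficiency
  (M-ratio = meta-d′/d′), the model-free **AUROC2**, each per difficulty
  level and averaged, plus a 2×2 Accuracy × Difficulty ANOVA on confidence.
- **Latent confidence model** (`confidence_model`): per-subject
  proportional-odds ordinal regression of ratings on z-scored difficulty,
  accuracy, log RT and the difficulty × accuracy interaction; deviance-based
  comparison of candidate regressor sets; transfer of fitted coefficients
  to the unrated main session to produce a predicted confidence
  `Σ_k k·P(rating = k | x)` per trial.
- **Global-SPE analyses** (`spe_analysis`): trial exclusions (missed and
  |z(log RT)| > 3), a-posteriori labelling of trials by the block's choice,
  easy-task and best-performed choice frequencies with performance-class
  splits, logistic regressions of task choice, deviance comparison of
  confidence/accuracy/RT choice models, the scalar SPE sensitivity, and a
  JZS Bayes factor for one-sample t tests.
- **Pipeline and CLI** (`io_cli`): a shared tidy trial-table CSV schema,
  validated I/O, a reproducible end-to-end pipeline, and the `metaspe`
  command-line interface (`simulate`, `calibrate`, `fit-metad`,
  `fit-confidence`, `analyze-spe`, `run`, `report`).

## Worked example

Simulate and analyze an eight-subject cohort, then print the summary:

```bash
$ metaspe run --seed 7 --n-subjects 8 --out demo
pipeline complete: 8 subjects -> demo/report.json
$ metaspe report --in demo
report 0f752756628d (seed 7), 8 subjects
easy-task choice frequency: 0.711 (t=6.24, p=0.00043, n=8)
predicted confidence higher/lower SPE: 3.324 vs 2.960 (t=4.23, p=0.0039)
choice-model deviances: accuracy=297.9, log_rt=311.0, predicted_confidence=294.8
```

Reading the output: the cohort chooses the objectively easier task in 71%
of blocks (significantly above the 50% chance level), so end-of-block
choices track difficulty; predicted local confidence — inferred by the
ordinal model fitted on the rated metacognition session and transferred to
the unrated main session — is higher on trials of the chosen
("higher-SPE") task than the unchosen one; and among single-predictor
logistic models of the block choice, the predicted-confidence model fits
better (lower summed deviance) than accuracy or RT alone, the signature
that local confidence carries information about global SPEs beyond raw
performance.

The same stages are available as library functions:

```python
import numpy as np
from metaspe import (ObserverParams, DesignParams,
                     simulate_calibration_session, fit_psychometric,
                     extract_difficulty_levels)

rng = np.random.default_rng(0)
calib = simulate_calibration_session(ObserverParams(), DesignParams(), rng)
fit = fit_psychometric(calib)
easy, hard = extract_difficulty_levels(fit)   # e.g. (17, 8)
```

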