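"""Exclusions, SPE labelling, choice frequencies, choice models, Bayes factor."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from metaspe import (
    DesignParams,
    ObserverParams,
    block_summaries,
    choice_frequencies,
    choice_model_deviance,
    exclude_trials,
    jzs_bayes_factor,
    label_trials,
    simulate_main_session,
    spe_sensitivity,
    task_choice_logistic,
)
from metaspe.spe_analysis import logistic_fit


def _main_session(seed=0, tau=0.5, n_blocks=32, miss_rate=0.0):
    params = ObserverParams(tau=tau, miss_rate=miss_rate)
    design = DesignParams(n_blocks=n_blocks)
    rng = np.random.default_rng(seed)
    return simulate_main_session(params, design, 14, 6, rng)


class TestExcludeTrials:
    def _trials(self, rts, responses=None, subject="s01"):
        n = len(rts)
        return pd.DataFrame({
            "subject": subject,
            "response": responses or ["left"] * n,
            "rt_ms": rts,
        })

    def test_single_outlier_dropped(self):
        # 100 near-identical RTs and one at 10x: only the outlier exceeds 3 SD
        rng = np.random.default_rng(0)
        rts = list(500 + rng.normal(0, 5, 100)) + [5000.0]
        kept, report = exclude_trials(self._trials(rts))
        assert len(kept) == 100
        assert 5000.0 not in kept["rt_ms"].to_numpy()
        assert report.loc["s01", "n_outlier"] == 1

    def test_clean_data_identity(self):
        rng = np.random.default_rng(1)
        t = self._trials(list(rng.uniform(400, 900, 50)))
        kept, report = exclude_trials(t)
        pd.testing.assert_frame_equal(kept, t)
        assert report.loc["s01", "excluded_fraction"] == 0.0

    def test_all_missed_warns_and_returns_empty(self):
        t = self._trials([np.nan] * 5, responses=["none"] * 5)
        with pytest.warns(UserWarning, match="all trials excluded"):
            kept, report = exclude_trials(t)
        assert len(kept) == 0
        assert report.loc["s01", "excluded_fraction"] == 1.0

    def test_zscore_computed_once_not_iterated(self):
        # after dropping the huge outlier, the remaining spread would flag
        # more trials if the z-score were recomputed; it must not be
        rts = [500.0] * 20 + [650.0] * 2 + [60000.0]
        kept, _ = exclude_trials(self._trials(rts))
        assert len(kept) == 22

    def test_exclusion_is_per_subject(self):
        a = self._trials([500.0] * 30 + [5000.0], subject="a")
        b = self._trials([5000.0] * 30 + [500.0], subject="b")
        kept, report = exclude_trials(pd.concat([a, b], ignore_index=True))
        assert report.loc["a", "n_outlier"] == 1
        assert report.loc["b", "n_outlier"] == 1
        assert kept[kept["subject"] == "b"]["rt_ms"].eq(5000.0).all()


class TestLabelTrials:
    def test_labels_follow_choice(self):
        trials, blocks = _main_session(seed=2, n_blocks=4)
        labelled = label_trials(trials, blocks)
        for _, b in blocks.iterrows():
            sub = labelled[labelled["block"] == b["block"]]
            chosen = sub[sub["task"] == b["chosen_task"]]
            other = sub[sub["task"] != b["chosen_task"]]
            assert (chosen["spe_label"] == "higher_SPE").all()
            assert (other["spe_label"] == "lower_SPE").all()
            assert len(chosen) == len(other) == 6

    def test_flipping_choices_swaps_labels(self):
        trials, blocks = _main_session(seed=3, n_blocks=4)
        flipped = blocks.copy()
        flipped["chosen_task"] = np.where(blocks["chosen_task"] == "A",
                                          "B", "A")
        l1 = label_trials(trials, blocks)["spe_label"]
        l2 = label_trials(trials, flipped)["spe_label"]
        assert (l1 != l2).all()

    def test_missing_choice_raises_with_block(self):
        trials, blocks = _main_session(seed=4, n_blocks=4)
        blocks.loc[2, "chosen_task"] = np.nan
        with pytest.raises(ValueError, match="without a recorded choice"):
            label_trials(trials, blocks)


def _toy_summaries(chosen, easy="A", acc_a=None, acc_b=None):
    n = len(chosen)
    return pd.DataFrame({
        "subject": "s01", "block": range(n),
        "easy_task": easy, "chosen_task": chosen, "first_task": "A",
        "delta_A": 14, "delta_B": 6,
        "acc_A": acc_a if acc_a is not None else [0.9] * n,
        "acc_B": acc_b if acc_b is not None else [0.6] * n,
        "logrt_A": 6.6, "logrt_B": 6.8,
        "n_A": 6, "n_B": 6,
    }).assign(
        accuracy_difference=lambda d: d["acc_A"] - d["acc_B"],
        perf_class=lambda d: np.select(
            [d["accuracy_difference"] > 0, d["accuracy_difference"] < 0],
            ["positive", "negative"], "null"),
    )


class TestChoiceFrequencies:
    def test_hand_built_six_block_fixture(self):
        s = _toy_summaries(
            chosen=["A", "A", "B", "A", "B", "A"],
            acc_a=[0.9, 0.9, 0.9, 0.5, 0.5, 0.7],
            acc_b=[0.6, 0.6, 0.6, 0.7, 0.7, 0.7],
        )
        out = choice_frequencies(s)
        row = out.per_subject.loc["s01"]
        assert row["easy_choice_freq"] == pytest.approx(4 / 6)
        # best-performed: blocks 0-2 best=A, 3-4 best=B, 5 tie (excluded)
        # chosen: A A B A B A -> correct on 0,1,4 of 5 non-tied
        assert row["best_performed_choice_freq"] == pytest.approx(3 / 5)
        assert row["n_accuracy_ties"] == 1
        assert row["easy_choice_freq_positive"] == pytest.approx(2 / 3)
        assert row["easy_choice_freq_negative"] == pytest.approx(1 / 2)
        assert row["easy_choice_freq_null"] == pytest.approx(1.0)

    def test_random_choices_near_half(self):
        rng = np.random.default_rng(5)
        s = _toy_summaries(chosen=list(rng.choice(["A", "B"], 1000)))
        out = choice_frequencies(s)
        freq = out.per_subject.loc["s01", "easy_choice_freq"]
        assert abs(freq - 0.5) < 3 * np.sqrt(0.25 / 1000)

    def test_greedy_simulator_always_chooses_easy(self):
        # tau -> 0 with far-separated difficulties: easy nearly always wins
        params = ObserverParams(tau=1e-6, miss_rate=0.0, sigma_m=0.0)
        design = DesignParams(n_blocks=100)
        rng = np.random.default_rng(6)
        trials, blocks = simulate_main_session(params, design, 70, 2, rng)
        s = block_summaries(trials, blocks)
        assert spe_sensitivity(s) > 0.95


class TestSpeSensitivity:
    def test_extremes(self):
        assert spe_sensitivity(_toy_summaries(["A"] * 10)) == 1.0
        assert spe_sensitivity(_toy_summaries(["A"] * 5 + ["B"] * 5)) == 0.5

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            spe_sensitivity(_toy_summaries([]))

    def test_monotone_decreasing_in_temperature(self):
        """Higher choice temperature dilutes SPE sensitivity."""
        sens = []
        for j, tau in enumerate((0.1, 0.5, 2.0, 10.0)):
            trials, blocks = _main_session(seed=[7, j], tau=tau,
                                           n_blocks=1000)
            sens.append(spe_sensitivity(block_summaries(trials, blocks)))
        assert all(a > b for a, b in zip(sens, sens[1:]))


class TestTaskChoiceLogistic:
    def test_generative_recovery(self):
        # choices driven only by the z-scored accuracy difference (beta=1)
        rng = np.random.default_rng(8)
        n = 10_000
        acc_a = rng.uniform(0.4, 1.0, n)
        acc_b = rng.uniform(0.4, 1.0, n)
        d_acc = acc_a - acc_b
        z = (d_acc - d_acc.mean()) / d_acc.std()
        chosen = np.where(rng.random(n) < expit(1.0 * z), "A", "B")
        s = _toy_summaries(chosen=list(chosen), acc_a=acc_a, acc_b=acc_b)
        # randomize easy assignment so difficulty is informative-free noise
        s["delta_A"] = rng.choice([6, 14], n)
        s["delta_B"] = np.where(s["delta_A"] == 6, 14, 6)
        fit = task_choice_logistic(s)
        row = fit.per_subject.loc["s01"]
        # per-subject SEs from the logistic information matrix
        assert abs(row["accuracy"] - 1.0) < 0.1
        assert abs(row["difficulty"]) < 0.1

    def test_null_predictors_small_coefficients(self):
        rng = np.random.default_rng(9)
        tvals = []
        for i in range(100):
            rng_i = np.random.default_rng([9, i])
            chosen = list(rng_i.choice(["A", "B"], 40))
            acc_a = rng_i.uniform(0.5, 1.0, 40)
            acc_b = rng_i.uniform(0.5, 1.0, 40)
            s = _toy_summaries(chosen=chosen, acc_a=acc_a, acc_b=acc_b)
            fit = task_choice_logistic(s)
            tvals.append(fit.per_subject.loc["s01", "accuracy"])
        # across replicates the coefficient is centred on zero
        mean = np.mean(tvals)
        se = np.std(tvals, ddof=1) / np.sqrt(len(tvals))
        assert abs(mean) < 3 * se + 0.05

    def test_deterministic_choices_flag_separation(self):
        rng = np.random.default_rng(10)
        delta_a = rng.choice([6, 14], 40)
        s = _toy_summaries(chosen=["x"] * 40)
        s["delta_A"] = delta_a
        s["delta_B"] = np.where(delta_a == 6, 14, 6)
        s["chosen_task"] = np.where(delta_a == 14, "A", "B")
        s["easy_task"] = s["chosen_task"]
        fit = task_choice_logistic(s)
        row = fit.per_subject.loc["s01"]
        assert row["separation"]
        assert row["difficulty"] > 0


class TestChoiceModelDeviance:
    def _summaries_with_pconf(self, seed=11, n=500, driver="pconf"):
        rng = np.random.default_rng(seed)
        pconf_a = rng.normal(3.5, 0.6, n)
        pconf_b = rng.normal(3.5, 0.6, n)
        acc_a = np.clip(pconf_a / 6 + rng.normal(0, 0.15, n), 0, 1)
        acc_b = np.clip(pconf_b / 6 + rng.normal(0, 0.15, n), 0, 1)
        chosen = np.where(
            rng.random(n) < expit(2.0 * (pconf_a - pconf_b)), "A", "B")
        s = _toy_summaries(chosen=list(chosen), acc_a=acc_a, acc_b=acc_b)
        s["pconf_A"], s["pconf_B"] = pconf_a, pconf_b
        return s

    def test_confidence_driver_wins_deviance_race(self):
        wins = 0
        for i in range(50):
            s = self._summaries_with_pconf(seed=[12, i], n=120)
            devs = {
                name: choice_model_deviance(s, name).summed_deviance
                for name in ("predicted_confidence", "accuracy", "log_rt")
            }
            wins += min(devs, key=devs.get) == "predicted_confidence"
        assert wins >= 45

    def test_constant_predictor_gives_null_deviance(self):
        s = self._summaries_with_pconf(seed=13, n=200)
        s["pconf_A"] = 3.5
        s["pconf_B"] = 3.5
        fit = choice_model_deviance(s, "predicted_confidence")
        y = (s["chosen_task"] == s["first_task"]).mean()
        n = len(s)
        null_dev = -2 * n * (y * np.log(y) + (1 - y) * np.log(1 - y))
        assert fit.summed_deviance == pytest.approx(null_dev, abs=1e-6)

    def test_deviance_matches_brute_force(self):
        s = self._summaries_with_pconf(seed=14, n=300)
        fit = choice_model_deviance(s, "predicted_confidence")
        row = fit.per_subject.loc["s01"]
        sgn = np.where(s["first_task"] == "A", 1.0, -1.0)
        x = sgn * (s["pconf_A"] - s["pconf_B"]).to_numpy()
        y = (s["chosen_task"] == s["first_task"]).to_numpy().astype(float)
        # refit intercept via the returned parameters
        eta = fit.per_subject.loc["s01", "beta"] * x
        intercept_fit = logistic_fit(x[:, None], y)
        eta = intercept_fit["intercept"] + intercept_fit["coef"][0] * x
        p = expit(eta)
        direct = -2 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert row["deviance"] == pytest.approx(direct, abs=1e-6)

    def test_unknown_predictor_raises(self):
        s = self._summaries_with_pconf(seed=15)
        with pytest.raises(ValueError):
            choice_model_deviance(s, "confidence")


class TestOrderInvariance:
    def test_frequencies_and_deviances_invariant_to_trial_order(self):
        trials, blocks = _main_session(seed=16, n_blocks=16)
        rng = np.random.default_rng(17)
        shuffled = (trials.sample(frac=1.0, random_state=1)
                    .reset_index(drop=True))
        s1 = block_summaries(trials, blocks)
        s2 = block_summaries(shuffled, blocks)
        assert spe_sensitivity(s1) == spe_sensitivity(s2)
        f1 = choice_frequencies(s1).per_subject
        f2 = choice_frequencies(s2).per_subject
        pd.testing.assert_frame_equal(f1, f2)


class TestJZSBayesFactor:
    def test_zero_t_supports_null(self):
        assert jzs_bayes_factor(0.0, 40) < 1.0

    def test_monotone_in_t(self):
        bfs = [jzs_bayes_factor(t, 30) for t in (0.0, 0.5, 1.0, 2.0, 4.0)]
        assert all(a < b for a, b in zip(bfs, bfs[1:]))

    def test_large_t_supports_alternative(self):
        assert jzs_bayes_factor(5.0, 40) > 100.0

    @pytest.mark.parametrize("t", [0.0, 1.0, 2.5, 5.0])
    @pytest.mark.parametrize("n", [20, 40])
    def test_fine_grid_quadrature_oracle(self, t, n):
        """Adaptive quadrature agrees with a dense fixed-grid integral."""
        r = np.sqrt(2) / 2
        nu = n - 1
        g = np.geomspace(1e-8, 1e6, 400_000)
        a = 1.0 + n * g * r * r
        integrand = (a ** -0.5 * (1 + t * t / (a * nu)) ** (-(nu + 1) / 2)
                     * (2 * np.pi) ** -0.5 * g ** -1.5
                     * np.exp(-1.0 / (2 * g)))
        num = np.trapezoid(integrand, g)
        expected = num / (1 + t * t / nu) ** (-(nu + 1) / 2)
        assert jzs_bayes_factor(t, n) == pytest.approx(expected, rel=0.01)

    def test_small_n_raises(self):
        with pytest.raises(ValueError):
            jzs_bayes_factor(1.0, 1)


class TestEndToEndCohorts:
    def test_qualitative_choice_and_confidence_patterns(self):
        """Synthetic cohorts show the expected global-SPE signatures:
        easy tasks chosen above chance, more so when the realized
        performance difference favours the easy task, and higher predicted
        confidence on higher-SPE trials."""
        from metaspe import (build_features, fit_ordinal, predict_confidence,
                             simulate_subject)
        from scipy.stats import ttest_rel

        for cohort in range(3):
            summaries, conf_diffs = [], []
            for i in range(10):
                rng = np.random.default_rng([18, cohort, i])
                data = simulate_subject(
                    ObserverParams(miss_rate=0.0), DesignParams(), rng,
                    subject=f"s{i:02d}")
                t = data["trials"]
                meta = t[t["session"] == "metacog"]
                main = t[t["session"] == "main"].copy()
                mf = build_features(meta)
                fit = fit_ordinal(mf, meta.loc[mf.index, "confidence"])
                ff = build_features(main)
                main = main.loc[ff.index]
                main["predicted_confidence"] = predict_confidence(
                    fit, ff[fit.feature_names])
                labelled = label_trials(main, data["blocks"])
                summaries.append(block_summaries(labelled, data["blocks"]))
                by = labelled.groupby("spe_label")["predicted_confidence"].mean()
                conf_diffs.append(by["higher_SPE"] - by["lower_SPE"])
            s = pd.concat(summaries, ignore_index=True)
            out = choice_frequencies(s)
            assert out.group["easy_vs_half"]["mean"] > 0.5
            assert out.group["easy_vs_half"]["p"] < 0.05
            pos = out.per_subject["easy_choice_freq_positive"].dropna()
            neg = out.per_subject["easy_choice_freq_negative"].dropna()
            assert pos.mean() > neg.mean()
            res = ttest_rel(conf_diffs, np.zeros(len(conf_diffs)))
            assert np.mean(conf_diffs) > 0 and res.pvalue < 0.05
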