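"""Response scoring, signed-rank test, GLMMs and model selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from bluetitsong import (
    CallEvent,
    SimResponseConfig,
    aicc,
    fit_habituation_model,
    fit_preference_model,
    habituation_design,
    inverse_logit,
    model_average,
    score_responses,
    simulate_responses,
    treatment_comparison,
    vif,
)


# ---------------------------------------------------------------------------
# scoring


def toy_cue_table():
    rows = []
    for b in range(4):
        for pos in range(1, 4):
            rows.append(
                {
                    "bout_index": b,
                    "song_type": "A" if b % 2 == 0 else "B",
                    "preceded_by": "silence_gap" if b % 2 == 0 else "type_switch",
                    "position": pos,
                    "onset_s": 100.0 * b + 10.0 * (pos - 1),
                }
            )
    return pd.DataFrame(rows)


class TestScoreResponses:
    def test_call_inside_bout_credits_that_position(self):
        cues = toy_cue_table()
        events = [CallEvent(312.0, "copulation")]  # bout 3, position 2 window
        res = score_responses(events, cues, [(0.0, 1000.0)], bout_duration=30.0)
        by_idx = {r.bout_index: r for r in res}
        assert by_idx[3].any_response == 1
        assert by_idx[3].per_position == (0, 1, 0)
        assert all(by_idx[b].any_response == 0 for b in (0, 1, 2))

    def test_non_solicitation_calls_ignored(self):
        cues = toy_cue_table()
        events = [CallEvent(5.0, "churring"), CallEvent(105.0, "screaming"),
                  CallEvent(205.0, "unclassified")]
        res = score_responses(events, cues, [(0.0, 1000.0)], bout_duration=30.0)
        assert all(r.any_response == 0 for r in res)

    def test_twittering_and_chattering_count(self):
        cues = toy_cue_table()
        events = [CallEvent(1.0, "twittering"), CallEvent(101.0, "chattering")]
        res = score_responses(events, cues, [(0.0, 1000.0)], bout_duration=30.0)
        assert res[0].any_response == 1 and res[1].any_response == 1

    def test_call_between_bouts_not_credited(self):
        cues = toy_cue_table()
        events = [CallEvent(50.0, "copulation")]  # after bout 0 ends (30 s)
        res = score_responses(events, cues, [(0.0, 1000.0)], bout_duration=30.0)
        assert all(r.any_response == 0 for r in res)

    def test_absent_female_bouts_removed(self):
        cues = toy_cue_table()
        res = score_responses([], cues, [(0.0, 150.0)], bout_duration=30.0)
        assert sorted(r.bout_index for r in res) == [0, 1]

    def test_any_response_is_or_of_positions(self):
        cues = toy_cue_table()
        events = [CallEvent(0.5, "copulation"), CallEvent(21.0, "copulation")]
        res = score_responses(events, cues, [(0.0, 1000.0)], bout_duration=30.0)
        assert res[0].per_position == (1, 0, 1)
        assert res[0].any_response == int(any(res[0].per_position))


# ---------------------------------------------------------------------------
# inverse logit


class TestInverseLogit:
    @pytest.mark.parametrize(
        "x, p",
        [(-1.406, 0.197), (0.0, 0.5), (0.532, 0.630)],
    )
    def test_reference_values(self, x, p):
        assert inverse_logit(x) == pytest.approx(p, abs=5e-4)

    @given(st.floats(-30, 30))
    @settings(max_examples=50, deadline=None)
    def test_symmetry(self, x):
        assert inverse_logit(-x) == pytest.approx(1 - inverse_logit(x), abs=1e-12)


# ---------------------------------------------------------------------------
# paired signed-rank


def enumerate_signed_rank_p(d, observed_v, alternative):
    """Exhaustive 2^n sign-flip null distribution of V (sum of positive ranks)."""
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    n = len(d)
    vs = []
    for signs in itertools.product([0, 1], repeat=n):
        vs.append(sum(r for r, s in zip(ranks, signs) if s))
    vs = np.array(vs)
    if alternative == "greater":
        return np.mean(vs >= observed_v)
    if alternative == "less":
        return np.mean(vs <= observed_v)
    return min(1.0, 2 * min(np.mean(vs >= observed_v), np.mean(vs <= observed_v)))


class TestTreatmentComparison:
    def test_all_positive_differences_n6(self):
        """All second > first with distinct magnitudes: the lesser-rank side
        is 0 and the exact one-sided p is 1/64."""
        first = [0.10, 0.20, 0.15, 0.30, 0.25, 0.05]
        second = [0.21, 0.35, 0.27, 0.50, 0.44, 0.11]
        res = treatment_comparison(first, second, alternative="greater")
        total = 6 * 7 // 2
        assert total - res.v == 0  # lesser-rank side
        assert res.p_value == pytest.approx(1 / 64)
        assert res.method == "exact"

    def test_identical_vectors_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            treatment_comparison([0.3, 0.1], [0.3, 0.1])

    def test_single_pair(self):
        res = treatment_comparison([0.3], [0.1], alternative="less")
        assert res.p_value == pytest.approx(0.5)

    @pytest.mark.parametrize("n", [4, 6, 8, 10])
    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_matches_exhaustive_enumeration(self, n, alternative):
        """Exact p-values equal the 2^n sign-enumeration oracle for n <= 10."""
        rng = np.random.default_rng(n * 13 + 1)
        d = rng.normal(0.2, 1.0, n)
        while np.unique(np.abs(d)).size < n or np.any(d == 0):
            d = rng.normal(0.2, 1.0, n)
        res = treatment_comparison(np.zeros(n), d, alternative=alternative)
        expected = enumerate_signed_rank_p(d, res.v, alternative)
        assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_approx_ci_close_to_exact(self):
        """At n=20 (exact still available) the normal-approximation CI for
        the median difference nearly matches the exact-quantile CI."""
        rng = np.random.default_rng(8)
        first = rng.uniform(0, 1, 20)
        d = rng.normal(0.15, 0.2, 20)
        second = first + d
        exact = treatment_comparison(first, second)
        assert exact.method == "exact"
        # force the approximation by introducing one tied magnitude pair
        second2 = np.append(second[:-1], first[-1] + np.sign(d[-2]) * abs(d[-2]))
        approx = treatment_comparison(first, second2)
        assert approx.method == "approx"
        assert approx.ci_low == pytest.approx(exact.ci_low, abs=0.1)
        assert approx.ci_high == pytest.approx(exact.ci_high, abs=0.1)

    def test_hl_ci_brackets_estimate(self):
        rng = np.random.default_rng(5)
        first = rng.uniform(0, 1, 15)
        second = first + rng.normal(0.2, 0.1, 15)
        res = treatment_comparison(first, second)
        assert res.ci_low <= res.median_difference <= res.ci_high
        assert res.ci_low > 0  # clear positive shift


# ---------------------------------------------------------------------------
# habituation GLMM


TRUTH = {
    "intercept": 0.052,
    "switch": -0.813,
    "log_position": -1.039,
    "log_position:switch": 0.532,
}


class TestHabituationModel:
    def test_back_transform_consistency(self):
        data = simulate_responses(SimResponseConfig(n_females=40, bouts_per_female=6), seed=1)
        fit = fit_habituation_model(data)
        for name in fit.coefficients.index:
            assert fit.back_transformed[name] == pytest.approx(
                float(inverse_logit(fit.coefficients[name])), abs=1e-12
            )
        assert np.all((fit.back_transformed > 0) & (fit.back_transformed < 1))

    def test_habituation_monotone_in_position(self):
        data = simulate_responses(SimResponseConfig(n_females=40, bouts_per_female=6), seed=2)
        fit = fit_habituation_model(data)
        assert fit.coefficients["log_position"] < 0
        probs = [fit.predicted_probability(p, switch=0) for p in range(1, 16)]
        assert all(a > b for a, b in zip(probs, probs[1:]))

    def test_dishabituation_is_partial_recovery(self):
        """With the reference coefficients, the response to the first song
        after a switch sits below position 1 after silence but above position
        15 of the preceding bout (plug-in computation)."""
        c = TRUTH
        eta = lambda pos, s: (
            c["intercept"] + c["switch"] * s + c["log_position"] * np.log(pos)
            + c["log_position:switch"] * s * np.log(pos)
        )
        p_silence_1 = expit(eta(1, 0))
        p_switch_1 = expit(eta(1, 1))
        p_prev_15 = expit(eta(15, 0))
        assert p_prev_15 < p_switch_1 < p_silence_1

    def test_all_ones_flags_separation(self):
        rows = [
            {"female_id": f"f{f}", "switch": s, "position": p, "response": 1}
            for f in range(5)
            for s in (0, 1)
            for p in range(1, 6)
        ]
        with pytest.warns(UserWarning, match="separation"):
            fit = fit_habituation_model(pd.DataFrame(rows))
        assert fit.glmm.separation_flag

    def test_single_preceded_by_level_drops_switch(self):
        data = simulate_responses(SimResponseConfig(n_females=20, bouts_per_female=4,
                                                    switch_fraction=0.0), seed=3)
        with pytest.warns(UserWarning, match="switch"):
            fit = fit_habituation_model(data)
        assert list(fit.coefficients.index) == ["intercept", "log_position"]


class TestPreferenceModel:
    @staticmethod
    def simulate(n_females, bouts, betas=(0.489, 0.0, 0.06), intercept=-1.406,
                 re_sd=0.68, seed=0):
        """Successes per song type per trial under the preference process;
        the linear predictor uses z-scored covariates, the same convention
        the fitter applies."""
        rng = np.random.default_rng(seed)
        n_rows = 2 * n_females
        cov = rng.normal(size=(n_rows, 3))
        cov = (cov - cov.mean(0)) / cov.std(0)
        b = np.repeat(rng.normal(0, re_sd, n_females), 2)
        eta = intercept + cov @ np.array(betas) + b
        y = rng.binomial(bouts, expit(eta))
        return pd.DataFrame(
            {
                "female_id": np.repeat([f"f{i}" for i in range(n_females)], 2),
                "vocal_consistency": cov[:, 0],
                "song_rate": cov[:, 1],
                "trill_length": cov[:, 2],
                "successes": y,
                "failures": bouts - y,
            }
        )

    def test_recovers_consistency_coefficient(self):
        """95% CI covers the injected consistency effect (0.489, female SD
        0.68, 200 females x 30 bouts) in >= 90% of seeded replicates."""
        R, covered = 25, 0
        for rep in range(R):
            data = self.simulate(200, 30, seed=60_000 + rep)
            fit = fit_preference_model(data)
            lo, hi = fit.conf_int.loc["vocal_consistency"]
            covered += lo <= 0.489 <= hi
        assert covered / R >= 0.90

    def test_null_type_one_error_controlled(self):
        """With all effects 0, the CI-excludes-zero rate stays <= 7.5% at a
        nominal 5% level over 200 replicates."""
        R, rejections = 200, 0
        for rep in range(R):
            data = self.simulate(60, 16, betas=(0.0, 0.0, 0.0), seed=70_000 + rep)
            fit = fit_preference_model(data, predictors=("vocal_consistency",))
            lo, hi = fit.conf_int.loc["vocal_consistency"]
            rejections += not (lo <= 0.0 <= hi)
        assert rejections / R <= 0.075

    def test_zero_variance_predictor_named(self):
        data = self.simulate(20, 10, seed=1)
        data["trill_length"] = 5.0
        with pytest.raises(ValueError, match="trill_length"):
            fit_preference_model(data)


class TestGlmerCrossCheck:
    def test_matches_lme4_glmer(self, tmp_path):
        """The adaptive-quadrature fitter agrees with lme4::glmer (nAGQ=9)
        on a small simulated habituation dataset."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        data = simulate_responses(SimResponseConfig(n_females=30, bouts_per_female=6,
                                                    positions_per_bout=10), seed=9)
        csv = tmp_path / "d.csv"
        data.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv('{csv}')
            d$logp <- log(d$position)
            m <- glmer(response ~ switch*logp + (1|female_id), data=d,
                       family=binomial, nAGQ=9)
            cat(fixef(m), sqrt(unlist(VarCorr(m))), sep='\\n')
            """
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        vals = [float(v) for v in out.stdout.strip().split("\n")]
        r_coefs = dict(zip(["intercept", "switch", "log_position", "log_position:switch"],
                           vals[:4]))
        r_sd = vals[4]
        fit = fit_habituation_model(data)
        for name, r_val in r_coefs.items():
            assert fit.coefficients[name] == pytest.approx(r_val, abs=0.02)
        assert fit.female_sd == pytest.approx(r_sd, abs=0.03)


# ---------------------------------------------------------------------------
# AICc / model averaging / VIF


class TestAicc:
    def test_closed_form(self):
        assert aicc(-10, 2, 100) == pytest.approx(24 + 12 / 97)

    def test_limits(self):
        assert aicc(-10, 2, 10**9) == pytest.approx(24.0, abs=1e-6)
        assert aicc(-7.5, 0, 50) == pytest.approx(15.0)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="AICc"):
            aicc(-10, 5, 6)


class TestModelAverage:
    def test_single_candidate(self):
        rep = model_average({"m": (10.0, pd.Series({"a": 1.5}))})
        assert rep.table.weight.iloc[0] == pytest.approx(1.0)
        assert rep.averaged["a"] == pytest.approx(1.5)
        assert rep.importance["a"] == pytest.approx(1.0)

    def test_equal_aicc_half_weights(self):
        rep = model_average(
            {"m1": (10.0, pd.Series({"a": 1.0})), "m2": (10.0, pd.Series({"a": 3.0}))}
        )
        assert np.allclose(rep.table.weight, 0.5)
        assert rep.averaged["a"] == pytest.approx(2.0)

    def test_delta_threshold_and_weight_formula(self):
        # deltas (0, 1, 4): third excluded; weights proportional to (1, e^-0.5)
        rep = model_average(
            {
                "m1": (100.0, pd.Series({"a": 1.0})),
                "m2": (101.0, pd.Series({"a": 1.0, "b": 2.0})),
                "m3": (104.0, pd.Series({"b": 1.0})),
            }
        )
        w1 = 1 / (1 + np.exp(-0.5))
        w2 = np.exp(-0.5) / (1 + np.exp(-0.5))
        tab = rep.table.set_index("model")
        assert tab.loc["m1", "weight"] == pytest.approx(w1)
        assert tab.loc["m2", "weight"] == pytest.approx(w2)
        assert not tab.loc["m3", "in_average_set"]
        # full averaging substitutes 0 for b in m1
        assert rep.averaged["b"] == pytest.approx(w2 * 2.0)
        assert rep.importance["b"] == pytest.approx(w2)
        assert rep.importance["a"] == pytest.approx(1.0)

    def test_weights_sum_to_one_and_importance_bounded(self):
        rng = np.random.default_rng(0)
        cands = {
            f"m{i}": (float(100 + rng.uniform(0, 6)), pd.Series({"a": 1.0}))
            for i in range(8)
        }
        rep = model_average(cands)
        assert rep.table.weight.sum() == pytest.approx(1.0)
        assert ((rep.importance >= 0) & (rep.importance <= 1)).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            model_average({})


class TestVif:
    def test_orthogonal_columns_unity(self):
        n = 64
        t = np.arange(n)
        X = pd.DataFrame(
            {"a": np.cos(2 * np.pi * t / n), "b": np.sin(2 * np.pi * t / n)}
        )
        assert np.allclose(vif(X), 1.0, atol=1e-8)

    def test_duplicated_column_flagged_infinite(self):
        x = np.random.default_rng(1).normal(size=50)
        res = vif(pd.DataFrame({"a": x, "b": x}))
        assert np.isinf(res).all()
        assert set(res.attrs["flagged"]) == {"a", "b"}

    def test_known_correlation_closed_form(self):
        # exact sample correlation 0.8 by Gram-Schmidt construction
        rng = np.random.default_rng(2)
        u = rng.normal(size=200)
        v = rng.normal(size=200)
        u = (u - u.mean()) / u.std()
        v = v - v.mean()
        v -= (v @ u) / (u @ u) * u  # orthogonal to u
        v /= v.std()
        x2 = 0.8 * u + np.sqrt(1 - 0.64) * v
        res = vif(pd.DataFrame({"x1": u, "x2": x2}))
        assert np.allclose(res, 1 / (1 - 0.64), atol=1e-8)


class TestHabituationDesign:
    def test_intercept_is_first_position_after_silence(self):
        X = habituation_design(np.array([1, 2, 15]), np.array([0, 0, 1]))
        assert X.iloc[0].tolist() == [1.0, 0.0, 0.0, 0.0]
        assert X["log_position"].iloc[2] == pytest.approx(np.log(15))
        assert X["log_position:switch"].iloc[2] == pytest.approx(np.log(15))

    def test_positions_one_based(self):
        with pytest.raises(ValueError, match="1-based"):
            habituation_design(np.array([0, 1]), np.array([0, 0]))
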