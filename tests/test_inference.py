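"""Mixed model, baseline correctness, bootstrap and binomial intervals."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit, logit

import guessability as g
from guessability.errors import ContractError, ValidationError
from guessability.synthetic_data import _predictors_for_responses, study_config


def _small_cohort(language="turkish", n=40, seed=5, **cfg_kw):
    cfg = study_config(language, n_participants=n, master_seed=seed, **cfg_kw)
    lex = g.generate_lexicon(cfg, seed=seed)
    responses = g.simulate_study(lex, cfg, seed=seed)
    frame = _predictors_for_responses(responses, lex)
    resp = g.responses_frame(responses)
    return resp, frame


class TestFitMixedLogistic:
    def test_zero_variance_matches_plain_glm(self):
        """With no participant heterogeneity the GLMM is an ordinary GLM.

        The scale MLE sits at the boundary; at small n sampling noise can
        push it off zero, so the cohort is large enough for the estimate to
        collapse and the fixed effects to agree tightly.
        """
        import statsmodels.api as sm

        cfg_kw = dict(random_effect_sds={"intercept": 0.0})
        resp, frame = _small_cohort(n=250, seed=8, **cfg_kw)
        terms = ("length_agreement", "edit_phon_similarity", "inverse_trial")
        std, _ = g.standardize_predictors(frame, columns=terms)
        fit = g.fit_mixed_logistic(
            resp, std,
            g.GlmmSpec(fixed_terms=terms, random_terms=terms),
        )
        X = np.column_stack([np.ones(len(std))] +
                            [std[t].to_numpy() for t in terms])
        oracle = sm.GLM(resp["correct"].to_numpy(), X,
                        family=sm.families.Binomial()).fit()
        ours = np.array([fit.coefficients[t].estimate
                         for t in ("intercept",) + terms])
        assert np.allclose(ours, oracle.params, atol=1e-3)
        # the GLM is nested at zero scales, so the marginal likelihood of
        # the mixed fit can never fall below it
        assert fit.loglik >= oracle.llf - 1e-6

    def test_matches_lme4_random_intercept(self, tmp_path):
        """Independent oracle: lme4's Laplace glmer on the same data."""
        resp, frame = _small_cohort(n=40, seed=21)
        terms = ("length_agreement", "inverse_trial")
        std, _ = g.standardize_predictors(frame, columns=terms)
        fit = g.fit_mixed_logistic(
            resp, std,
            g.GlmmSpec(fixed_terms=terms, random_terms=(), random_intercept=True),
        )
        data = pd.DataFrame({
            "correct": resp["correct"].to_numpy(),
            "pid": resp["participant_id"].to_numpy(),
            "la": std["length_agreement"].to_numpy(),
            "inv": std["inverse_trial"].to_numpy(),
        })
        csv = tmp_path / "d.csv"
        data.to_csv(csv, index=False)
        rscript = tmp_path / "fit.R"
        rscript.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(correct ~ la + inv + (1 | pid), data = d,
                       family = binomial, nAGQ = 1)
            cat(fixef(m), sep = "\\n")
        """))
        out = subprocess.run(["Rscript", str(rscript)], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        lme4 = np.array([float(x) for x in out.stdout.split()])
        ours = np.array([fit.coefficients[t].estimate
                         for t in ("intercept",) + terms])
        assert np.allclose(ours, lme4, atol=0.02)

    def test_intercept_only_balanced_data(self):
        rng = np.random.default_rng(0)
        n_part, n_trials = 50, 34
        resp = pd.DataFrame({
            "participant_id": np.repeat([f"p{i}" for i in range(n_part)], n_trials),
            "correct": rng.integers(0, 2, n_part * n_trials),
        })
        frame = pd.DataFrame(index=range(len(resp)))
        fit = g.fit_mixed_logistic(
            resp, frame, g.GlmmSpec(fixed_terms=(), random_intercept=True))
        se = 2 / np.sqrt(len(resp))  # logit-scale binomial SE at p=0.5
        assert abs(fit.coefficients["intercept"].estimate) < 3 * se

    def test_reparameterization_invariance(self):
        """Standardized and raw fits describe the same fitted probabilities."""
        resp, frame = _small_cohort(n=40, seed=31)
        terms = ("length_agreement", "inverse_trial")
        raw_fit = g.fit_mixed_logistic(
            resp, frame,
            g.GlmmSpec(fixed_terms=terms, random_terms=(), standardized=False,
                       random_intercept=False))
        std, scaling = g.standardize_predictors(frame, columns=terms)
        std_fit = g.fit_mixed_logistic(
            resp, std,
            g.GlmmSpec(fixed_terms=terms, random_terms=(), random_intercept=False))
        X = frame[list(terms)].to_numpy(float)
        eta_raw = raw_fit.intercept + X @ np.array(
            [raw_fit.coefficients[t].estimate for t in terms])
        Z = std[list(terms)].to_numpy(float)
        eta_std = std_fit.intercept + Z @ np.array(
            [std_fit.coefficients[t].estimate for t in terms])
        assert np.allclose(expit(eta_raw), expit(eta_std), atol=1e-4)

    def test_misaligned_inputs_rejected(self):
        resp, frame = _small_cohort(n=4, seed=2)
        with pytest.raises(ValidationError):
            g.fit_mixed_logistic(resp.iloc[:-1], frame,
                                 g.GlmmSpec(fixed_terms=()))

    def test_participant_level_terms_cannot_be_random(self):
        with pytest.raises(Exception):
            g.GlmmSpec(fixed_terms=("age",), random_terms=("age",))

    def test_ci_contains_estimate(self):
        resp, frame = _small_cohort(n=30, seed=3)
        terms = ("inverse_trial",)
        std, _ = g.standardize_predictors(frame, columns=terms)
        fit = g.fit_mixed_logistic(resp, std, g.GlmmSpec(fixed_terms=terms))
        for c in fit.coefficients.values():
            assert c.ci_lo <= c.estimate <= c.ci_hi


class TestBaselineCorrectness:
    def _raw_fit(self, intercept, standardized=False):
        return g.GlmmFit(
            coefficients={"intercept": g.CoefEstimate(intercept, intercept - 0.1,
                                                      intercept + 0.1, 0.01)},
            intercept=intercept, random_variances={}, converged=True,
            n_obs=100, n_participants=10, standardized=standardized, loglik=0.0,
        )

    def test_zero_intercept_is_chance(self):
        prob, _ = g.baseline_correctness(self._raw_fit(0.0))
        assert prob == pytest.approx(0.5)

    def test_closed_form_value(self):
        prob, _ = g.baseline_correctness(self._raw_fit(0.1243))
        assert prob == pytest.approx(0.531, abs=5e-4)

    def test_monotone_in_intercept(self):
        p1, _ = g.baseline_correctness(self._raw_fit(0.2))
        p2, _ = g.baseline_correctness(self._raw_fit(0.8))
        assert p2 > p1

    def test_standardized_fit_rejected(self):
        with pytest.raises(ContractError):
            g.baseline_correctness(self._raw_fit(0.1, standardized=True))


class TestParticipantBootstrap:
    def _frame(self, correct_per_participant):
        rows = []
        for i, arr in enumerate(correct_per_participant):
            for c in arr:
                rows.append({"participant_id": f"p{i}", "correct": c})
        return pd.DataFrame(rows)

    def test_degenerate_all_correct(self):
        df = self._frame([[1] * 10] * 5)
        mean, (lo, hi) = g.participant_bootstrap_ci(df, B=200, seed=1)
        assert (mean, lo, hi) == (1.0, 1.0, 1.0)

    def test_identical_participants_zero_width(self):
        df = self._frame([[1, 0, 1, 0]] * 6)
        mean, (lo, hi) = g.participant_bootstrap_ci(df, B=200, seed=1)
        assert lo == hi == pytest.approx(mean)

    def test_reproducible_and_contains_mean(self):
        rng = np.random.default_rng(4)
        df = self._frame([rng.integers(0, 2, 34) for _ in range(30)])
        a = g.participant_bootstrap_ci(df, B=500, seed=7)
        b = g.participant_bootstrap_ci(df, B=500, seed=7)
        assert a == b
        mean, (lo, hi) = a
        assert lo <= mean <= hi

    def test_small_B_warns(self):
        df = self._frame([[1, 0]] * 4)
        with pytest.warns(UserWarning):
            g.participant_bootstrap_ci(df, B=50, seed=0)


class TestBinomialCI:
    def test_boundary_cases(self):
        _, (lo, _) = g.per_item_binomial_ci(0, 20)
        assert lo == 0.0
        _, (_, hi) = g.per_item_binomial_ci(20, 20)
        assert hi == 1.0

    def test_exact_beta_quantiles(self):
        prop, (lo, hi) = g.per_item_binomial_ci(9, 10)
        assert prop == pytest.approx(0.9)
        assert lo == pytest.approx(stats.beta.ppf(0.025, 9, 2))
        assert hi == pytest.approx(stats.beta.ppf(0.975, 10, 1))
        assert (lo, hi) == (pytest.approx(0.555, abs=5e-4),
                            pytest.approx(0.997, abs=5e-4))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            g.per_item_binomial_ci(5, 4)


class TestCorrectnessSummary:
    def test_flags_and_pooling(self, latvian_fixture):
        cfg = study_config("latvian", n_participants=30, master_seed=9)
        responses = g.simulate_study(latvian_fixture, cfg, seed=9)
        summary = g.correctness_summary(responses, latvian_fixture,
                                        bootstrap_B=300, seed=2)
        per = summary.per_item
        assert len(per) == 68
        assert (per["n"] == 30).all()  # every concept in every session
        assert ((per["accuracy"] < 0.5) == per["below_chance"]).all()
        assert ((per["ci_lo"] > 0.5) == per["significantly_above"]).all()
        lo, hi = summary.pooled_ci
        assert lo <= summary.pooled <= hi

    def test_unknown_concept_rejected(self, latvian_fixture, toy_lexicon):
        cfg = study_config("latvian", n_participants=2, master_seed=9)
        responses = g.simulate_study(latvian_fixture, cfg, seed=9)
        with pytest.raises(ValidationError):
            g.correctness_summary(responses, toy_lexicon, bootstrap_B=200)
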