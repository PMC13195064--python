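"""Mixed-effects logistic modelling and uncertainty quantification.

The per-language analysis model is a logistic mixed model: trial correctness
is Bernoulli with logit equal to a fixed linear predictor plus
participant-level random components (an intercept and independent random
slopes, diagonal covariance — identifiable with 34 trials per participant).
Estimation maximises the Laplace-approximated marginal likelihood: for
candidate random-effect scales, fixed effects and participant modes are
found by penalised iteratively reweighted least squares exploiting the
participant-block structure of the Hessian, and the log-determinant
correction is accumulated block by block.  Wald intervals for the fixed
effects condition on the estimated scales, as is conventional.

Also here: participant-wise bootstrap intervals for pooled correctness,
exact (Clopper-Pearson) per-translation binomial intervals, and baseline
(residual) correctness -- the inverse-logit of the intercept of a re-fit on
raw-scale cue covariates, i.e. predicted accuracy when every cue is absent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .errors import ConfigError, ContractError, ValidationError
from .lexicon_io import ResponseRecord, StudyLexicon

__all__ = [
    "GlmmSpec",
    "GlmmFit",
    "CoefEstimate",
    "fit_mixed_logistic",
    "baseline_correctness",
    "participant_bootstrap_ci",
    "per_item_binomial_ci",
    "correctness_summary",
    "responses_frame",
    "BASELINE_TERMS",
]

#: Cue covariates entering the un-normalised baseline re-fit (raw scale,
#: only log-frequency agreement centered; no demographic or design terms).
BASELINE_TERMS = (
    "cognate",
    "semantic_distance",
    "edit_phon_similarity",
    "vector_phon_similarity",
    "length_agreement",
    "logfreq_agreement",
)

_SEPARATION_THRESHOLD = 10.0


@dataclass(frozen=True)
class GlmmSpec:
    """Model specification.

    ``fixed_terms`` and ``random_terms`` name predictor columns;
    participant-level covariates (age, gender) may appear only among the
    fixed terms.  ``random_intercept`` adds a participant intercept
    component.  The link is logit.
    """

    fixed_terms: tuple[str, ...]
    random_terms: tuple[str, ...] = ()
    standardized: bool = True
    random_intercept: bool = True

    def __post_init__(self):
        bad = {"age", "gender"} & set(self.random_terms)
        if bad:
            raise ConfigError(
                f"participant-level covariates cannot vary within participant: {sorted(bad)}"
            )


@dataclass(frozen=True)
class CoefEstimate:
    estimate: float
    ci_lo: float
    ci_hi: float
    p_value: float

    def __post_init__(self):
        if not self.ci_lo <= self.estimate <= self.ci_hi:
            raise ValidationError("confidence interval does not contain estimate")


@dataclass(frozen=True)
class GlmmFit:
    """Fitted model: fixed coefficients with Wald 95% intervals, random-term
    variances, convergence diagnostics."""

    coefficients: dict[str, CoefEstimate]
    intercept: float
    random_variances: dict[str, float]
    converged: bool
    n_obs: int
    n_participants: int
    standardized: bool
    loglik: float
    warnings: tuple[str, ...] = ()

    @property
    def intercept_ci(self) -> tuple[float, float]:
        c = self.coefficients["intercept"]
        return (c.ci_lo, c.ci_hi)


def responses_frame(responses: Iterable[ResponseRecord]) -> pd.DataFrame:
    """Flatten response records to a DataFrame."""
    rows = []
    for r in responses:
        rows.append({
            "participant_id": r.participant_id,
            "session_trial_index": r.session_trial_index,
            "concept_id_1": r.trial.czech_pair[0].concept_id,
            "concept_id_2": r.trial.czech_pair[1].concept_id,
            "inverse": r.trial.inverse,
            "correct": r.correct,
            "age": r.age,
            "gender": r.gender,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Laplace-approximated mixed logistic regression
# ---------------------------------------------------------------------------

def _group_index(participants: np.ndarray) -> tuple[np.ndarray, int]:
    uniq, idx = np.unique(participants, return_inverse=True)
    return idx, len(uniq)


def _penalized_irls(y, X, Z, g, P, sd, beta0=None, tol=1e-6, max_iter=200):
    """Joint penalised Newton over fixed effects and participant modes.

    Returns (beta, u, laplace_loglik, converged).  ``Z`` holds the random
    design row per observation (q columns), ``g`` the participant index,
    ``sd`` the random-effect scales.
    """
    n, p = X.shape
    q = Z.shape[1]
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    u = np.zeros((P, q))
    d_inv = 1.0 / np.maximum(sd, 1e-8) ** 2

    def penalized_ll(beta, u):
        eta = X @ beta + np.sum(Z * u[g], axis=1)
        ll = np.sum(y * eta - np.logaddexp(0.0, eta))
        return ll - 0.5 * np.sum(u ** 2 * d_inv)

    ll_old = penalized_ll(beta, u)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta + np.sum(Z * u[g], axis=1)
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        r = y - mu
        grad_b = X.T @ r
        gu = np.zeros((P, q))
        np.add.at(gu, g, Z * r[:, None])
        gu -= u * d_inv
        # Hessian blocks
        A = X.T @ (X * w[:, None])
        B = np.zeros((P, p, q))
        np.add.at(B, g, w[:, None, None] * X[:, :, None] * Z[:, None, :])
        C = np.zeros((P, q, q))
        np.add.at(C, g, w[:, None, None] * Z[:, :, None] * Z[:, None, :])
        C[:, np.arange(q), np.arange(q)] += d_inv
        Cinv = np.linalg.inv(C)
        # Schur complement on the fixed block
        S = A - np.einsum("pij,pjk,plk->il", B, Cinv, B)
        rhs = grad_b - np.einsum("pij,pjk,pk->i", B, Cinv, gu)
        try:
            db = np.linalg.solve(S, rhs)
        except np.linalg.LinAlgError:
            db = np.linalg.lstsq(S, rhs, rcond=None)[0]
        du = np.einsum("pjk,pk->pj", Cinv, gu - np.einsum("pij,i->pj", B, db))
        # step halving on the penalised objective
        step = 1.0
        for _half in range(30):
            ll_new = penalized_ll(beta + step * db, u + step * du)
            if ll_new >= ll_old - 1e-12:
                break
            step *= 0.5
        beta = beta + step * db
        u = u + step * du
        gnorm = max(np.abs(grad_b).max(), np.abs(gu).max())
        if gnorm < tol and abs(ll_new - ll_old) < tol:
            ll_old = ll_new
            converged = True
            break
        ll_old = ll_new
    # Laplace correction at the mode
    eta = X @ beta + np.sum(Z * u[g], axis=1)
    mu = expit(eta)
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    C = np.zeros((P, q, q))
    np.add.at(C, g, w[:, None, None] * Z[:, :, None] * Z[:, None, :])
    C[:, np.arange(q), np.arange(q)] += d_inv
    sign, logdet_C = np.linalg.slogdet(C)
    logdet_D = P * np.sum(2.0 * np.log(np.maximum(sd, 1e-8)))
    la = penalized_ll(beta, u) - 0.5 * logdet_D - 0.5 * np.sum(logdet_C)
    return beta, u, float(la), converged


def _fixed_covariance(y, X, Z, g, P, sd, beta, u):
    """Wald covariance of the fixed effects, conditional on the scales."""
    eta = X @ beta + np.sum(Z * u[g], axis=1)
    mu = expit(eta)
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    d_inv = 1.0 / np.maximum(sd, 1e-8) ** 2
    q = Z.shape[1]
    A = X.T @ (X * w[:, None])
    B = np.zeros((P, X.shape[1], q))
    np.add.at(B, g, w[:, None, None] * X[:, :, None] * Z[:, None, :])
    C = np.zeros((P, q, q))
    np.add.at(C, g, w[:, None, None] * Z[:, :, None] * Z[:, None, :])
    C[:, np.arange(q), np.arange(q)] += d_inv
    Cinv = np.linalg.inv(C)
    S = A - np.einsum("pij,pjk,plk->il", B, Cinv, B)
    return np.linalg.inv(S)


def fit_mixed_logistic(
    responses: Iterable[ResponseRecord] | pd.DataFrame,
    predictors: pd.DataFrame,
    spec: GlmmSpec,
) -> GlmmFit:
    """Fit the logistic mixed model.

    ``responses`` (records or a frame with ``participant_id`` and
    ``correct``) must align row-for-row with ``predictors``.  Returns a
    ``GlmmFit``; non-convergence is flagged, never silent.
    """
    resp = responses if isinstance(responses, pd.DataFrame) else responses_frame(responses)
    if len(resp) != len(predictors):
        raise ValidationError(
            f"{len(resp)} responses but {len(predictors)} predictor rows"
        )
    y = resp["correct"].to_numpy(float)
    g, P = _group_index(resp["participant_id"].to_numpy())
    if P < 2:
        raise ValidationError("need at least two participants")

    cols = {}
    for term in spec.fixed_terms:
        if term == "gender":
            raw = resp["gender"].astype(str).to_numpy()
            cols[term] = (raw == "F").astype(float)
        elif term == "age":
            cols[term] = resp["age"].to_numpy(float)
        else:
            if term not in predictors.columns:
                raise ConfigError(f"unknown fixed term {term!r}")
            cols[term] = predictors[term].to_numpy(float)
    X = np.column_stack([np.ones(len(y))] + [cols[t] for t in spec.fixed_terms])
    names = ["intercept"] + list(spec.fixed_terms)

    rand_names = (["intercept"] if spec.random_intercept else []) + list(spec.random_terms)
    fit_warnings: list[str] = []
    if rand_names:
        Zcols = []
        for term in rand_names:
            if term == "intercept":
                Zcols.append(np.ones(len(y)))
            else:
                if term not in predictors.columns:
                    raise ConfigError(f"unknown random term {term!r}")
                Zcols.append(predictors[term].to_numpy(float))
        Z = np.column_stack(Zcols)

        state = {"beta": None}

        def neg_laplace(log_sd):
            sd = np.exp(np.clip(log_sd, -12.0, 3.0))
            beta, u, la, conv = _penalized_irls(
                y, X, Z, g, P, sd, beta0=state["beta"], tol=1e-6, max_iter=200
            )
            state["beta"] = beta
            return -la

        # scale-aware start: a slope scale of 0.3 per SD of its covariate
        col_sd = np.maximum(Z.std(axis=0), 1e-3)
        if rand_names and rand_names[0] == "intercept":
            col_sd[0] = 1.0
        x0 = np.log(0.3 / col_sd)
        res = optimize.minimize(
            neg_laplace, x0, method="Nelder-Mead",
            options={"maxiter": 200 * len(rand_names), "xatol": 1e-3, "fatol": 1e-5},
        )
        sd_hat = np.exp(np.clip(res.x, -12.0, 3.0))
        beta, u, la, inner_conv = _penalized_irls(
            y, X, Z, g, P, sd_hat, beta0=state["beta"], tol=1e-6, max_iter=200
        )
        cov = _fixed_covariance(y, X, Z, g, P, sd_hat, beta, u)
        converged = bool(res.success and inner_conv)
        loglik = float(la)
        random_variances = {n: float(s ** 2) for n, s in zip(rand_names, sd_hat)}
    else:
        import statsmodels.api as sm

        glm = sm.GLM(y, X, family=sm.families.Binomial())
        glm_res = glm.fit()
        beta = np.asarray(glm_res.params)
        cov = np.asarray(glm_res.cov_params())
        converged = bool(glm_res.converged)
        loglik = float(glm_res.llf)
        random_variances = {}

    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    coefficients = {
        n: CoefEstimate(
            estimate=float(b),
            ci_lo=float(b - 1.959963984540054 * s),
            ci_hi=float(b + 1.959963984540054 * s),
            p_value=float(pv),
        )
        for n, b, s, pv in zip(names, beta, se, pvals)
    }
    big = [n for n, b in zip(names, beta) if abs(b) > _SEPARATION_THRESHOLD]
    if big:
        fit_warnings.append(f"possible separation: |coefficient| > "
                            f"{_SEPARATION_THRESHOLD} for {big}")
    if not converged:
        fit_warnings.append("optimizer did not converge")
    return GlmmFit(
        coefficients=coefficients,
        intercept=float(beta[0]),
        random_variances=random_variances,
        converged=converged,
        n_obs=int(len(y)),
        n_participants=int(P),
        standardized=spec.standardized,
        loglik=loglik,
        warnings=tuple(fit_warnings),
    )


# ---------------------------------------------------------------------------
# Baseline correctness and uncertainty
# ---------------------------------------------------------------------------

def baseline_correctness(fit_unstandardized: GlmmFit) -> tuple[float, tuple[float, float]]:
    """Inverse-logit of the intercept (and its CI) of a raw-covariate re-fit.

    The fit must use un-normalised cue covariates so that the intercept is
    the log-odds of a correct answer when every cue is at zero.
    """
    if fit_unstandardized.standardized:
        raise ContractError("baseline correctness needs an un-standardized fit")
    lo, hi = fit_unstandardized.intercept_ci
    return float(expit(fit_unstandardized.intercept)), (float(expit(lo)), float(expit(hi)))


def participant_bootstrap_ci(
    responses: Iterable[ResponseRecord] | pd.DataFrame,
    B: int = 10_000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Pooled correctness with a participant-wise bootstrap 95% interval.

    Participants are resampled with replacement ``B`` times; the pooled
    proportion is recomputed per replicate; percentile bounds are returned.
    """
    if B < 100:
        warnings.warn(f"B={B} bootstrap replicates is small; intervals will be noisy")
    resp = responses if isinstance(responses, pd.DataFrame) else responses_frame(responses)
    per = resp.groupby("participant_id")["correct"].agg(["sum", "count"])
    k = per["sum"].to_numpy(float)
    n = per["count"].to_numpy(float)
    if len(k) < 2:
        raise ValidationError("need at least two participants")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(k), size=(B, len(k)))
    boots = k[idx].sum(axis=1) / n[idx].sum(axis=1)
    mean = float(k.sum() / n.sum())
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return mean, (float(lo), float(hi))


def per_item_binomial_ci(
    successes: int, trials: int, level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Exact (Clopper-Pearson) two-sided binomial interval."""
    if not 0 <= successes <= trials or trials < 1:
        raise ValidationError("need 0 <= successes <= trials, trials >= 1")
    alpha = 1.0 - level
    lo = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha / 2, successes, trials - successes + 1)
    )
    hi = 1.0 if successes == trials else float(
        stats.beta.ppf(1 - alpha / 2, successes + 1, trials - successes)
    )
    return successes / trials, (lo, hi)


@dataclass(frozen=True)
class CorrectnessSummary:
    """Per-translation accuracies and the pooled language-level rate."""

    per_item: pd.DataFrame = field(repr=False)
    pooled: float = 0.0
    pooled_ci: tuple[float, float] = (0.0, 1.0)
    n_below_chance: int = 0
    n_significantly_above: int = 0


def correctness_summary(
    responses: Iterable[ResponseRecord] | pd.DataFrame,
    lexicon: StudyLexicon,
    bootstrap_B: int = 10_000,
    seed: int = 0,
) -> CorrectnessSummary:
    """Accuracy per translation (each response counts for both words shown)
    with exact binomial intervals, plus pooled correctness with a
    participant-wise bootstrap interval."""
    resp = responses if isinstance(responses, pd.DataFrame) else responses_frame(responses)
    known = {r.concept_id for r in lexicon.records}
    used = set(resp["concept_id_1"]) | set(resp["concept_id_2"])
    unknown = used - known
    if unknown:
        raise ValidationError(f"responses reference unknown concepts: {sorted(unknown)[:5]}")
    long = pd.concat([
        resp[["concept_id_1", "correct"]].rename(columns={"concept_id_1": "concept_id"}),
        resp[["concept_id_2", "correct"]].rename(columns={"concept_id_2": "concept_id"}),
    ])
    rows = []
    for cid, grp in long.groupby("concept_id", sort=False):
        k, n = int(grp["correct"].sum()), int(len(grp))
        prop, (lo, hi) = per_item_binomial_ci(k, n)
        rows.append({
            "concept_id": cid, "n": n, "correct": k, "accuracy": prop,
            "ci_lo": lo, "ci_hi": hi,
            "below_chance": prop < 0.5,
            "significantly_above": lo > 0.5,
        })
    per_item = pd.DataFrame(rows).set_index("concept_id")
    pooled, ci = participant_bootstrap_ci(resp, B=bootstrap_B, seed=seed)
    return CorrectnessSummary(
        per_item=per_item,
        pooled=pooled,
        pooled_ci=ci,
        n_below_chance=int(per_item["below_chance"].sum()),
        n_significantly_above=int(per_item["significantly_above"].sum()),
    )
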