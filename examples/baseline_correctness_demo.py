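"""Baseline (residual) correctness from the un-standardized re-fit.

How well would participants do with *no* usable cues — no cognates, no
length or frequency agreement, no phonological similarity?  The answer is
the inverse-logit of the intercept of a re-fit on raw-scale cue covariates
(only log-frequency agreement centered).  Here the cohort is generated with
a known baseline of 56%, which the re-fit should recover within a couple of
percentage points.
"""

from scipy.special import logit

import guessability as g
from guessability.synthetic_data import _predictors_for_responses, study_config

true_baseline = 0.56
cfg = study_config(
    "latvian", n_participants=300, master_seed=3, coefficients_scale="raw",
    true_coefficients={
        "intercept": float(logit(true_baseline)),
        "cognate": 0.40, "edit_phon_similarity": 0.008,
        "vector_phon_similarity": 0.10, "length_agreement": 0.06,
        "logfreq_agreement": 0.02, "semantic_distance": 0.01,
    },
    random_effect_sds={"intercept": 0.2},
)
lexicon = g.generate_lexicon(cfg, seed=3)
responses = g.simulate_study(lexicon, cfg, seed=3)

resp = g.responses_frame(responses)
frame = _predictors_for_responses(responses, lexicon)
frame["logfreq_agreement"] -= frame["logfreq_agreement"].mean()
fit = g.fit_mixed_logistic(
    resp, frame,
    g.GlmmSpec(fixed_terms=g.BASELINE_TERMS, random_terms=(),
               standardized=False, random_intercept=True),
)
prob, (lo, hi) = g.baseline_correctness(fit)
print(f"generating baseline: {true_baseline:.1%}")
print(f"recovered baseline:  {prob:.1%}  (95% CI [{lo:.1%}, {hi:.1%}])")
print("\nA baseline above 50% means cues in the model do not exhaust "
      "whatever lets participants beat chance.")
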