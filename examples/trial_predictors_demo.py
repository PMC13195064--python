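"""Predictors of one forced-choice trial.

Builds one session from the packaged synthetic Latvian lexicon and prints
the covariate vector of its first trial: positive length agreement means
the longer Czech word also has the longer translation (a usable cue);
positive phonological similarity means the true mapping is phonologically
closer than the crossed one.
"""

import guessability as g

lexicon = g.load_synthetic_lexicon("latvian")
(session,) = g.build_sessions(lexicon, n_participants=1, seed=7)
trial = session.trials[0]

w1, w2 = trial.czech_pair
print(f"Czech pair:   {w1.czech_form} / {w2.czech_form}")
print(f"foreign pair: {w1.foreign_form} / {w2.foreign_form}"
      f"  (shown {'inverted' if trial.inverse else 'in order'})")

tp = g.trial_predictors(trial)
for name in g.PREDICTOR_NAMES:
    print(f"  {name:<24} {getattr(tp, name):+.3f}")
print("\nA random guesser is right 50% of the time; positive cue values "
      "raise the odds of a correct match.")
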