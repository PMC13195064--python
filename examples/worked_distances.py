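"""Phonological distances between a Czech word and its foreign translations.

Computes the feature-weighted edit distance and the 12-feature vector
distance for the word pairs with published worked values: a small edit
distance (den-din 0.5, one vowel-height feature) signals a cognate; large
edit distances (>10) are typical even for correct translations, while the
vector metric, built on phonological-class proportions, stays near 1.
"""

import guessability as g

table = g.load_default_table()
pairs = [
    ("den", "din", "Hindi 'day'"),
    ("den", "djena", "Latvian 'day'"),
    ("den", "hi", "Japanese 'day'"),
    ("směr", "hókó", "Japanese 'direction'"),
]

print(f"{'pair':<16} {'edit':>8} {'vector':>8}")
for cz, fo, gloss in pairs:
    ipa_cz, ipa_fo = g.czech_to_ipa(cz), g.czech_to_ipa(fo)
    edit = g.feature_edit_distance(ipa_cz, ipa_fo, table)
    vec = g.vector_distance(
        g.word_feature_vector(ipa_cz, table),
        g.word_feature_vector(ipa_fo, table),
    )
    print(f"{cz+'-'+fo:<16} {edit:>8.4g} {vec:>8.4f}   [{ipa_cz} / {ipa_fo}] {gloss}")

print("\nSmaller numbers = more similar; the edit metric counts weighted "
      "feature changes, the vector metric compares class profiles.")
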