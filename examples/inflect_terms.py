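"""Medical plural/singular exchange.

An OOV token that is merely the plural (or singular) of a vocabulary word
is mapped back by a first-match-wins scan of the medical suffix rule table
(vertebra→vertebrae, diagnosis→diagnoses, bacterium→bacteria, ...).
"""

import medterm as mt

rules = mt.fixture_lexicon().inflection_rules

for word in ["vertebra", "diagnosis", "bacterium", "appendix", "phalanx", "fungus"]:
    plural = mt.pluralize(word, rules)
    print(f"{word:12s} -> {plural:12s} -> back: {mt.singularize(plural, rules)}")

print("candidates for 'vertebrae':", mt.inflection_candidates("vertebrae", rules))
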