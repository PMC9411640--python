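"""Decompose compound medical terms into word parts and meanings.

Each term is split into prefix/root/suffix components over the built-in
fixture lexicon; the printed meaning words are what the encoder averages
when the term is missing from an embedding vocabulary.
"""

import medterm as mt

lexicon = mt.fixture_lexicon()

for term in [
    "choledocholithiasis",
    "dyspnea",
    "mastodynia",
    "dermatitis",
    "arteriosclerosis",
    "prostatism",
]:
    dec = mt.decompose(term, lexicon)
    parts = " + ".join(f"{s}({role})" for s, _, role in dec.components)
    print(f"{term:22s} -> {parts}")
    print(f"{'':22s}    meanings: {', '.join(dec.meaning_words)}")
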