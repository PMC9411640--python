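"""Encode out-of-vocabulary tokens through the four-stage chain.

A toy embedding knows only a handful of plain English words; each OOV
token below is resolved by the first stage that can produce a vector, and
the provenance tag says which stage that was.  The vector of e.g.
"dyspnea" is the mean of the vectors of "painful" and "breathing".
"""

import numpy as np

import medterm as mt

lexicon = mt.fixture_lexicon()
cfg = mt.SynthConfig(n_terms=1, seed=0, embedding_dim=8)
emb = mt.generate_embedding(
    mt.meaning_vocabulary(lexicon) + ["heart", "vertebra", "sea", "sick"], cfg
)
seg = mt.train_segmenter([("sea", 5), ("sick", 5)])

for token in ["heart", "Heart.", "vertebrae", "dyspnea", "seasickness", "qqqq"]:
    enc = mt.encode_token(token, emb, lexicon, seg)
    norm = "-" if enc.vector is None else f"{np.linalg.norm(enc.vector):.3f}"
    print(f"{token:14s} stage={enc.provenance:10s} |v|={norm}   {enc.trace[-1]}")
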