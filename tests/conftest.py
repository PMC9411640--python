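import itertools

import numpy as np
import pytest
from hypothesis import settings

import medterm as mt

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def lexicon():
    return mt.fixture_lexicon()


@pytest.fixture(scope="session")
def rules(lexicon):
    return lexicon.inflection_rules


@pytest.fixture(scope="session")
def seg_model(lexicon):
    return mt.train_segmenter([(w, 1) for w in mt.meaning_vocabulary(lexicon)])


@pytest.fixture(scope="session")
def meaning_embedding(lexicon):
    """Toy embedding covering every meaning word of the fixture lexicon."""
    cfg = mt.SynthConfig(n_terms=1, seed=123, embedding_dim=16)
    return mt.generate_embedding(mt.meaning_vocabulary(lexicon), cfg)


def brute_force_spearman(x, y):
    """Independent Spearman oracle: explicit average ranks + Pearson."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def avg_ranks(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), float)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def brute_force_segment(term, model, tol=1e-9):
    """Enumerate all 2^(n-1) cut masks and rank like the Viterbi decoder:
    best score first (scores within ``tol`` are tied), then fewer units,
    then leftmost-longest units."""
    n = len(term)
    scored = []
    for mask in itertools.product([0, 1], repeat=n - 1):
        cuts = [0] + [i + 1 for i, m in enumerate(mask) if m] + [n]
        units = [term[a:b] for a, b in zip(cuts, cuts[1:])]
        score = sum(
            model.unit_log_prob.get(u, -model.unknown_penalty * len(u)) for u in units
        )
        scored.append((score, units))
    top = max(s for s, _ in scored)
    tied = [(len(u), tuple(-len(x) for x in u), u) for s, u in scored if s >= top - tol]
    return min(tied)[2]
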