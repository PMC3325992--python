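import numpy as np
import pytest

from atcpred import build_label_table, build_score_table


@pytest.fixture
def small_labels():
    """Three training drugs: a:{1}, b:{1}, c:{2}."""
    return build_label_table([("a", ["A"]), ("b", ["A"]), ("c", ["B"])])


@pytest.fixture
def small_q_table():
    return build_score_table(
        "interaction", [("q", "a", 300), ("q", "b", 500), ("q", "c", 200)]
    )


def random_instance(rng: np.random.Generator, n_drugs=None, with_similarity=False):
    """A random tiny labelled instance plus a score table and a query id.

    Used by the brute-force oracle tests: drugs get 1-3 random classes,
    random sparse symmetric scores connect the query and the drugs.
    """
    if n_drugs is None:
        n_drugs = int(rng.integers(1, 31))
    ids = [f"d{i}" for i in range(n_drugs)]
    pairs = []
    for d in ids:
        k = int(rng.integers(1, 4))
        classes = rng.choice(14, size=k, replace=False) + 1
        letters = "ABCDGHJLMNPRSV"
        pairs.append((d, [letters[j - 1] for j in classes]))
    labels = build_label_table(pairs)
    edges = []
    everyone = ids + ["q"]
    for i, a in enumerate(everyone):
        for b in everyone[i + 1:]:
            if rng.random() < 0.4:
                if with_similarity:
                    edges.append((a, b, float(rng.uniform(0.01, 1.0))))
                else:
                    edges.append((a, b, int(rng.integers(1, 1001))))
    kind = "similarity" if with_similarity else "interaction"
    return labels, build_score_table(kind, edges), "q"


def brute_force_likelihoods(query, labels, table):
    """Independent oracle for the per-class likelihoods: an explicit double
    loop over (class, training drug) pairs using only ScoreTable.score."""
    values = []
    for j in range(1, 15):
        best = 0
        for drug_id in labels:
            if j in labels[drug_id].classes and drug_id != query:
                best = max(best, table.score(query, drug_id))
        values.append(best)
    return tuple(values)
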