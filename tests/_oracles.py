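"""Independent oracles shared across tests.

These deliberately avoid the code paths they check: Moran's I is evaluated
as a literal double loop over the dense weight matrix, and topic-recovery
error is a brute-force best-permutation total variation distance.
"""

from __future__ import annotations

import itertools

import numpy as np

import crowdwatch as cw


def moran_bruteforce(values, dense_w) -> float:
    """Literal double-sum evaluation of global Moran's I."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    m = x.mean()
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += dense_w[i, j] * (x[i] - m) * (x[j] - m)
            s0 += dense_w[i, j]
    den = sum((xi - m) ** 2 for xi in x)
    return n * num / (s0 * den)


def best_permutation_tv(true_phi: np.ndarray, est_phi: np.ndarray) -> float:
    """Mean total-variation distance between matched topic rows, minimized
    over topic permutations."""
    k = true_phi.shape[0]
    best = np.inf
    for perm in itertools.permutations(range(k)):
        tv = np.mean(
            [0.5 * np.abs(true_phi[i] - est_phi[perm[i]]).sum() for i in range(k)]
        )
        best = min(best, tv)
    return float(best)


def two_topic_corpus(n_docs: int, seed: int, doc_len: int = 50):
    """Two-topic disjoint-vocabulary corpus drawn from the generative
    process; returns (corpus, true_phi)."""
    rng = np.random.default_rng(seed)
    n_vocab = 40
    phi = np.zeros((2, n_vocab))
    phi[0, :20] = 1.0 / 20
    phi[1, 20:] = 1.0 / 20
    tokens = tuple(f"w{i}" for i in range(n_vocab))
    vocab = cw.Vocabulary(tokens)
    docs = []
    for _ in range(n_docs):
        theta = rng.dirichlet((1.0, 1.0))
        docs.append(cw.generate_document(theta, phi, doc_len, rng))
    from crowdwatch.topics import corpus_from_documents

    return corpus_from_documents(docs, vocab), phi
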