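"""Collapsed Gibbs sampler kernel for latent Dirichlet allocation.

The sampler integrates out the topic-word distributions phi and the
document-topic distributions theta and resamples each word's topic
assignment z from its full conditional

    p(z = k | rest) ∝ (n_dk + alpha) * (n_kw + beta) / (n_k + V*beta)

where the counts exclude the word being resampled. Randomness comes from an
internal xorshift64* generator so that a given (corpus, seed) pair yields an
identical chain on every platform and run.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MULT = np.uint64(2685821657736338717)
_TWO53 = 9007199254740992.0


@njit(cache=False)
def _uniform(state):
    """Advance the xorshift64* state in place; return a double in [0, 1)."""
    s = state[0]
    s ^= s >> np.uint64(12)
    s ^= s << np.uint64(25)
    s ^= s >> np.uint64(27)
    state[0] = s
    return np.float64((s * _MULT) >> np.uint64(11)) / _TWO53


@njit(cache=False)
def _run_chain(doc_ids, word_ids, n_docs, n_topics, n_vocab, alpha, beta, n_iter, seed):
    n_tokens = doc_ids.shape[0]
    z = np.zeros(n_tokens, dtype=np.int64)
    n_dk = np.zeros((n_docs, n_topics), dtype=np.float64)
    n_kv = np.zeros((n_topics, n_vocab), dtype=np.float64)
    n_k = np.zeros(n_topics, dtype=np.float64)

    state = np.empty(1, dtype=np.uint64)
    # splitmix-style scramble of the seed so nearby seeds decorrelate
    s = (np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)) * np.uint64(
        0xBF58476D1CE4E5B9
    )
    state[0] = s if s != np.uint64(0) else np.uint64(0x106689D45497FDB5)

    for t in range(n_tokens):
        k = int(_uniform(state) * n_topics)
        if k >= n_topics:
            k = n_topics - 1
        z[t] = k
        n_dk[doc_ids[t], k] += 1.0
        n_kv[k, word_ids[t]] += 1.0
        n_k[k] += 1.0

    p = np.empty(n_topics, dtype=np.float64)
    vbeta = n_vocab * beta
    for _ in range(n_iter):
        for t in range(n_tokens):
            d = doc_ids[t]
            w = word_ids[t]
            k = z[t]
            n_dk[d, k] -= 1.0
            n_kv[k, w] -= 1.0
            n_k[k] -= 1.0
            total = 0.0
            for kk in range(n_topics):
                total += (n_dk[d, kk] + alpha) * (n_kv[kk, w] + beta) / (
                    n_k[kk] + vbeta
                )
                p[kk] = total
            u = _uniform(state) * total
            k = 0
            while p[k] < u and k < n_topics - 1:
                k += 1
            z[t] = k
            n_dk[d, k] += 1.0
            n_kv[k, w] += 1.0
            n_k[k] += 1.0
    return z, n_dk, n_kv, n_k


def run_gibbs(
    doc_ids: np.ndarray,
    word_ids: np.ndarray,
    n_docs: int,
    n_topics: int,
    n_vocab: int,
    alpha: float,
    beta: float,
    n_iter: int,
    seed: int,
):
    """Run the collapsed Gibbs chain; returns (z, n_dk, n_kv, n_k)."""
    return _run_chain(
        np.ascontiguousarray(doc_ids, dtype=np.int64),
        np.ascontiguousarray(word_ids, dtype=np.int64),
        np.int64(n_docs),
        np.int64(n_topics),
        np.int64(n_vocab),
        np.float64(alpha),
        np.float64(beta),
        np.int64(n_iter),
        np.uint64(seed & 0x7FFFFFFF),
    )
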