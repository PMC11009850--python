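"""Numba kernels for collapsed Gibbs sampling.

The token stream is flattened into parallel ``doc_ids``/``word_ids`` arrays;
the kernels mutate the assignment vector and count matrices in place.
Numba's legacy per-thread RNG is seeded inside the kernel, which makes a
sweep deterministic for a given seed on a single thread.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def gibbs_train(doc_ids, word_ids, z, n_dk, n_kw, n_k, alpha, beta, n_iter, seed):
    """Standard collapsed Gibbs updates for LDA.

    Each token's topic is resampled proportional to
    (n_dk - i + alpha) * (n_kw - i + beta) / (n_k - i + V*beta)
    with the token's own count removed.
    """
    np.random.seed(seed)
    K = n_k.shape[0]
    V = n_kw.shape[1]
    n_tokens = doc_ids.shape[0]
    p = np.empty(K)
    for _ in range(n_iter):
        for i in range(n_tokens):
            d = doc_ids[i]
            w = word_ids[i]
            k = z[i]
            n_dk[d, k] -= 1
            n_kw[k, w] -= 1
            n_k[k] -= 1
            total = 0.0
            for kk in range(K):
                p[kk] = (
                    (n_dk[d, kk] + alpha)
                    * (n_kw[kk, w] + beta)
                    / (n_k[kk] + V * beta)
                )
                total += p[kk]
            u = np.random.random() * total
            acc = 0.0
            knew = K - 1
            for kk in range(K):
                acc += p[kk]
                if u < acc:
                    knew = kk
                    break
            z[i] = knew
            n_dk[d, knew] += 1
            n_kw[knew, w] += 1
            n_k[knew] += 1


@njit(cache=False)
def gibbs_foldin(doc_ids, word_ids, z, n_dk, phi, alpha, n_iter, seed):
    """Fold-in sampling for held-out documents with the topic-word
    distributions frozen: p(z=k) ∝ phi[k, w] * (n_dk - i + alpha)."""
    np.random.seed(seed)
    K = phi.shape[0]
    n_tokens = doc_ids.shape[0]
    p = np.empty(K)
    for _ in range(n_iter):
        for i in range(n_tokens):
            d = doc_ids[i]
            w = word_ids[i]
            k = z[i]
            n_dk[d, k] -= 1
            total = 0.0
            for kk in range(K):
                p[kk] = phi[kk, w] * (n_dk[d, kk] + alpha)
                total += p[kk]
            u = np.random.random() * total
            acc = 0.0
            knew = K - 1
            for kk in range(K):
                acc += p[kk]
                if u < acc:
                    knew = kk
                    break
            z[i] = knew
            n_dk[d, knew] += 1
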