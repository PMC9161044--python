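"""Independent reference computations used to check the implementation.

The LDA oracle works by explicit enumeration of the collapsed
Dirichlet-multinomial joint over all K^N topic-assignment vectors of a tiny
corpus, using nothing from the package's sampler: plain Python loops and
``math.lgamma``.  The Cochran-Armitage oracle enumerates the exact
permutation distribution of the trend statistic.
"""

from __future__ import annotations

import itertools
from math import comb, lgamma

import numpy as np


def exact_log_joint(z, doc_of, word_of, K, V, alpha, eta):
    """log p(z, w) under symmetric Dirichlet priors, by direct evaluation of

    prod_d [Γ(Kα)/Γ(n_d+Kα) · prod_k Γ(n_dk+α)/Γ(α)]
      · prod_k [Γ(Vη)/Γ(n_k+Vη) · prod_w Γ(n_kw+η)/Γ(η)]
    """
    docs = sorted(set(doc_of))
    total = 0.0
    for d in docs:
        n_d = 0
        n_dk = [0] * K
        for i, dd in enumerate(doc_of):
            if dd == d:
                n_d += 1
                n_dk[z[i]] += 1
        total += lgamma(K * alpha) - lgamma(n_d + K * alpha)
        for k in range(K):
            total += lgamma(n_dk[k] + alpha) - lgamma(alpha)
    for k in range(K):
        n_k = 0
        n_kw = [0] * V
        for i in range(len(z)):
            if z[i] == k:
                n_k += 1
                n_kw[word_of[i]] += 1
        total += lgamma(V * eta) - lgamma(n_k + V * eta)
        for w in range(V):
            total += lgamma(n_kw[w] + eta) - lgamma(eta)
    return total


def exact_posterior(doc_of, word_of, K, V, alpha, eta):
    """p(z | w) over all K^N assignment vectors, by enumeration."""
    n = len(doc_of)
    log_p = {}
    for z in itertools.product(range(K), repeat=n):
        log_p[z] = exact_log_joint(z, doc_of, word_of, K, V, alpha, eta)
    mx = max(log_p.values())
    weights = {z: np.exp(lp - mx) for z, lp in log_p.items()}
    total = sum(weights.values())
    return {z: w / total for z, w in weights.items()}


def exact_conditional(z, i, doc_of, word_of, K, V, alpha, eta):
    """p(z_i = k | z_-i, w) as a ratio of enumerated joints."""
    logs = []
    for k in range(K):
        zz = list(z)
        zz[i] = k
        logs.append(exact_log_joint(tuple(zz), doc_of, word_of, K, V, alpha, eta))
    mx = max(logs)
    weights = [np.exp(l - mx) for l in logs]
    s = sum(weights)
    return np.array([w / s for w in weights])


def iter_small_corpora(max_tokens=6, V=3, max_docs=2):
    """All corpora (as per-token doc and word index tuples) with up to
    ``max_docs`` documents, each a nonempty word multiset, totalling at most
    ``max_tokens`` tokens over a ``V``-word vocabulary."""
    def multisets(size):
        return itertools.combinations_with_replacement(range(V), size)

    for n_docs in range(1, max_docs + 1):
        for sizes in itertools.product(range(1, max_tokens + 1), repeat=n_docs):
            if sum(sizes) > max_tokens:
                continue
            for docs_words in itertools.product(*(multisets(s) for s in sizes)):
                doc_of, word_of = [], []
                for d, words in enumerate(docs_words):
                    for w in words:
                        doc_of.append(d)
                        word_of.append(w)
                yield tuple(doc_of), tuple(word_of)


def permutation_trend_distribution(x, n, scores):
    """Exact permutation distribution of T = Σ s_y (x_y − n_y p̄) when the
    Σx successes are dropped uniformly into the Σn slots (two groups only).

    Returns (values, probabilities) over all C(n_total, x_total) arrangements,
    computed from the (multivariate) hypergeometric law by enumeration.
    """
    x = list(x)
    n = list(n)
    total_x, total_n = sum(x), sum(n)
    p_bar = total_x / total_n
    vals, probs = [], []
    ranges = [range(0, min(total_x, ni) + 1) for ni in n]
    denom = comb(total_n, total_x)
    for combo in itertools.product(*ranges):
        if sum(combo) != total_x:
            continue
        weight = 1
        for ci, ni in zip(combo, n):
            weight *= comb(ni, ci)
        t = sum(s * (c - ni * p_bar) for s, c, ni in zip(scores, combo, n))
        vals.append(t)
        probs.append(weight / denom)
    return np.array(vals), np.array(probs)
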