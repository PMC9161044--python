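"""Latent Dirichlet allocation fitted by collapsed Gibbs sampling.

The sampler integrates out the document-topic mixtures θ and topic-word
distributions φ and resamples each token's topic assignment z from the
collapsed conditional

    p(z = k | z₋, w)  ∝  (n_dk⁻ + α) · (n_kw⁻ + η) / (n_k⁻ + V·η)

where the superscript ⁻ means the current token's contribution has been
removed from the count aggregates.  Point estimates are read off the final
state (optionally averaged over thinned post-burn-in states):

    φ̂_kw = (n_kw + η) / (n_k + V·η)        θ̂_dk = (n_dk + α) / (n_d + K·α)

Sweeps visit tokens in a fixed document-then-position order and all
randomness flows from one seeded generator, so a run is exactly
reproducible.  The inner loop is JIT-compiled with numba when available; a
pure-Python loop with identical semantics is the fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator

import numpy as np
from scipy.special import gammaln

__all__ = [
    "LdaConfig",
    "LdaState",
    "TopicModel",
    "init_state",
    "conditional",
    "fit",
    "sample_posterior",
    "log_joint",
    "top_words",
]


@dataclass(frozen=True)
class LdaConfig:
    """Hyperparameters and run settings for a collapsed Gibbs fit.

    Defaults follow common literature-mining practice for large corpora:
    20 topics, symmetric Dirichlet concentrations alpha = eta = 0.02, and
    5000 sweeps.  ``burn_in`` only matters when ``average_states`` is on;
    left at 0 it is then taken as ``n_iter // 2``.
    """

    n_topics: int = 20
    alpha: float = 0.02
    eta: float = 0.02
    n_iter: int = 5000
    burn_in: int = 0
    average_states: bool = False
    thin: int = 10
    seed: int = 0
    log_every: int = 0

    def __post_init__(self) -> None:
        if self.n_topics < 1:
            raise ValueError(f"n_topics must be >= 1, got {self.n_topics}")
        if self.alpha <= 0 or self.eta <= 0:
            raise ValueError("alpha and eta must be > 0")
        if not (self.n_iter > self.burn_in >= 0):
            raise ValueError("need n_iter > burn_in >= 0")

    @property
    def effective_burn_in(self) -> int:
        if self.average_states and self.burn_in == 0:
            return self.n_iter // 2
        return self.burn_in


@dataclass
class LdaState:
    """Collapsed sufficient statistics of the sampler.

    ``z[i]`` is the topic of token occurrence ``i``; ``doc_of`` / ``word_of``
    give its document and vocabulary indices.  Invariants (checked by
    :meth:`check`): rows of ``n_dk`` sum to ``n_d``, rows of ``n_kw`` sum to
    ``n_k``, and ``n_k`` sums to the token total.
    """

    z: np.ndarray
    doc_of: np.ndarray
    word_of: np.ndarray
    n_dk: np.ndarray
    n_kw: np.ndarray
    n_k: np.ndarray
    n_d: np.ndarray

    @property
    def n_tokens(self) -> int:
        return self.z.shape[0]

    @property
    def n_topics(self) -> int:
        return self.n_kw.shape[0]

    @property
    def n_vocab(self) -> int:
        return self.n_kw.shape[1]

    def check(self) -> None:
        assert (self.n_dk >= 0).all() and (self.n_kw >= 0).all()
        assert (self.n_dk.sum(axis=1) == self.n_d).all()
        assert (self.n_kw.sum(axis=1) == self.n_k).all()
        assert self.n_k.sum() == self.n_tokens


@dataclass
class TopicModel:
    """Smoothed point estimates: phi (K × V) and theta (D × K)."""

    phi: np.ndarray
    theta: np.ndarray
    config: LdaConfig
    log_joint_trace: list[tuple[int, float]] = field(default_factory=list)

    @property
    def n_topics(self) -> int:
        return self.phi.shape[0]


def _expand_tokens(dtm) -> tuple[np.ndarray, np.ndarray]:
    """Flatten a DTM into per-token (doc, word) arrays, document-major,
    positions in vocabulary-column order within each document."""
    coo = dtm.counts.tocoo()
    order = np.lexsort((coo.col, coo.row))
    rows = np.repeat(coo.row[order], coo.data[order])
    cols = np.repeat(coo.col[order], coo.data[order])
    return rows.astype(np.int64), cols.astype(np.int64)


def init_state(dtm, config: LdaConfig, rng: np.random.Generator | None = None) -> LdaState:
    """Assign every token a uniformly random topic and build the count
    aggregates; deterministic under ``config.seed``."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    doc_of, word_of = _expand_tokens(dtm)
    n = doc_of.shape[0]
    if n == 0:
        raise ValueError("document-term matrix has no tokens")
    K, D, V = config.n_topics, dtm.counts.shape[0], dtm.counts.shape[1]
    z = rng.integers(0, K, size=n, dtype=np.int64)
    n_dk = np.zeros((D, K), dtype=np.int64)
    n_kw = np.zeros((K, V), dtype=np.int64)
    np.add.at(n_dk, (doc_of, z), 1)
    np.add.at(n_kw, (z, word_of), 1)
    return LdaState(
        z=z,
        doc_of=doc_of,
        word_of=word_of,
        n_dk=n_dk,
        n_kw=n_kw,
        n_k=n_kw.sum(axis=1),
        n_d=n_dk.sum(axis=1),
    )


def conditional(state: LdaState, d: int, w: int, z_current: int,
                config: LdaConfig) -> np.ndarray:
    """Normalised collapsed conditional for a token in document ``d`` with
    word ``w`` whose current assignment ``z_current`` is decremented."""
    K, V = config.n_topics, state.n_vocab
    n_dk = state.n_dk[d].astype(np.float64).copy()
    n_kw = state.n_kw[:, w].astype(np.float64).copy()
    n_k = state.n_k.astype(np.float64).copy()
    n_dk[z_current] -= 1
    n_kw[z_current] -= 1
    n_k[z_current] -= 1
    p = (n_dk + config.alpha) * (n_kw + config.eta) / (n_k + V * config.eta)
    return p / p.sum()


# ---------------------------------------------------------------------------
# Sweep kernel — numba-compiled when available, pure Python otherwise
# ---------------------------------------------------------------------------

def _sweep_impl(doc_of, word_of, z, n_dk, n_kw, n_k, alpha, eta, uniforms):
    K = n_kw.shape[0]
    V = n_kw.shape[1]
    probs = np.empty(K, dtype=np.float64)
    for i in range(doc_of.shape[0]):
        d = doc_of[i]
        w = word_of[i]
        k_old = z[i]
        n_dk[d, k_old] -= 1
        n_kw[k_old, w] -= 1
        n_k[k_old] -= 1
        total = 0.0
        for k in range(K):
            p = (n_dk[d, k] + alpha) * (n_kw[k, w] + eta) / (n_k[k] + V * eta)
            probs[k] = p
            total += p
        r = uniforms[i] * total
        acc = 0.0
        k_new = K - 1
        for k in range(K):
            acc += probs[k]
            if r < acc:
                k_new = k
                break
        z[i] = k_new
        n_dk[d, k_new] += 1
        n_kw[k_new, w] += 1
        n_k[k_new] += 1


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _sweep: Callable = njit(cache=False)(_sweep_impl)
except ImportError:  # pragma: no cover
    _sweep = _sweep_impl


def _estimates(state: LdaState, config: LdaConfig) -> tuple[np.ndarray, np.ndarray]:
    V, K = state.n_vocab, config.n_topics
    phi = (state.n_kw + config.eta) / (state.n_k + V * config.eta)[:, None]
    theta = (state.n_dk + config.alpha) / (state.n_d + K * config.alpha)[:, None]
    return phi, theta


def log_joint(state: LdaState, config: LdaConfig) -> float:
    """Log of the collapsed joint p(z, w) under symmetric Dirichlet priors."""
    a, e = config.alpha, config.eta
    K, V, D = config.n_topics, state.n_vocab, state.n_dk.shape[0]
    doc_part = (
        D * (gammaln(K * a) - K * gammaln(a))
        + gammaln(state.n_dk + a).sum()
        - gammaln(state.n_d + K * a).sum()
    )
    topic_part = (
        K * (gammaln(V * e) - V * gammaln(e))
        + gammaln(state.n_kw + e).sum()
        - gammaln(state.n_k + V * e).sum()
    )
    return float(doc_part + topic_part)


def _run_sweeps(state: LdaState, config: LdaConfig, rng: np.random.Generator,
                n_sweeps: int, callback: Callable[[int, LdaState], None] | None = None) -> None:
    doc_of, word_of = state.doc_of, state.word_of
    n_dk_f = state.n_dk.astype(np.float64)
    n_kw_f = state.n_kw.astype(np.float64)
    n_k_f = state.n_k.astype(np.float64)
    for sweep in range(n_sweeps):
        uniforms = rng.random(state.n_tokens)
        _sweep(doc_of, word_of, state.z, n_dk_f, n_kw_f, n_k_f,
               config.alpha, config.eta, uniforms)
        if callback is not None:
            state.n_dk = n_dk_f.astype(np.int64)
            state.n_kw = n_kw_f.astype(np.int64)
            state.n_k = n_k_f.astype(np.int64)
            callback(sweep, state)
    state.n_dk = n_dk_f.astype(np.int64)
    state.n_kw = n_kw_f.astype(np.int64)
    state.n_k = n_k_f.astype(np.int64)


def fit(dtm, config: LdaConfig) -> tuple[TopicModel, LdaState]:
    """Run ``config.n_iter`` full Gibbs sweeps over the corpus.

    Estimation uses the final state by default; with
    ``config.average_states`` the smoothed estimates are averaged over every
    ``thin``-th post-burn-in state.  The collapsed log-joint is recorded
    every ``log_every`` sweeps (0 disables the trace).  Identical ``dtm`` and
    ``config`` give bitwise-identical results.
    """
    rng = np.random.default_rng(config.seed)
    state = init_state(dtm, config, rng)
    burn = config.effective_burn_in

    trace: list[tuple[int, float]] = []
    phi_acc = np.zeros((config.n_topics, state.n_vocab))
    theta_acc = np.zeros((state.n_dk.shape[0], config.n_topics))
    n_acc = 0

    def callback(sweep: int, st: LdaState) -> None:
        nonlocal phi_acc, theta_acc, n_acc
        if config.log_every and (sweep + 1) % config.log_every == 0:
            trace.append((sweep + 1, log_joint(st, config)))
        if (
            config.average_states
            and sweep + 1 > burn
            and (sweep + 1 - burn) % config.thin == 0
        ):
            p, t = _estimates(st, config)
            phi_acc += p
            theta_acc += t
            n_acc += 1

    need_cb = config.log_every > 0 or config.average_states
    _run_sweeps(state, config, rng, config.n_iter, callback if need_cb else None)

    if config.average_states and n_acc > 0:
        phi, theta = phi_acc / n_acc, theta_acc / n_acc
    else:
        phi, theta = _estimates(state, config)
    return TopicModel(phi=phi, theta=theta, config=config, log_joint_trace=trace), state


def sample_posterior(dtm, config: LdaConfig, n_samples: int,
                     thin: int = 1) -> Iterator[np.ndarray]:
    """Yield ``n_samples`` copies of the assignment vector z, one every
    ``thin`` sweeps after ``config.burn_in`` burn-in sweeps.

    Intended for posterior diagnostics on small corpora (e.g. comparing the
    sampler's empirical distribution with an exact enumeration).
    """
    rng = np.random.default_rng(config.seed)
    state = init_state(dtm, config, rng)
    _run_sweeps(state, config, rng, config.burn_in)
    for _ in range(n_samples):
        _run_sweeps(state, config, rng, thin)
        yield state.z.copy()


def top_words(model: TopicModel, vocabulary, n: int = 15) -> list[list[tuple[str, float]]]:
    """Per topic, the ``n`` highest-probability terms with their
    probabilities, ties broken by vocabulary order."""
    V = model.phi.shape[1]
    if not 1 <= n <= V:
        raise ValueError(f"n must be in [1, {V}], got {n}")
    out = []
    for k in range(model.n_topics):
        row = model.phi[k]
        order = np.argsort(-row, kind="stable")[:n]
        out.append([(vocabulary[j], float(row[j])) for j in order])
    return out
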