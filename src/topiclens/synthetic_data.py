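"""Synthetic time-stamped corpora from a known LDA generative process.

The generator emulates the structure a century-scale literature-mining run
assumes: K latent topics with sparse Dirichlet topic-word distributions,
document mixtures drawn from a Dirichlet whose mean follows year-dependent
topic prevalence (injected rising/falling linear trends), Poisson document
lengths, and a controlled rate of valence-lexicon words substituted into the
token stream so sentiment recovery has exact ground truth.  Everything a
downstream stage estimates — φ, yearly prevalence, dominant topics,
injected valence counts — is recorded in :class:`GroundTruth`.

Synthetic vocabulary words are ``w`` plus letters from a vowel-free
consonant alphabet, so they pass the alphabetic tokenizer unchanged and are
fixed points of the Porter stemmer; the embedded valence word set is real
English and disjoint from the synthetic vocabulary, making injected
sentiment unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus_io import ArticleRecord, Corpus, ValenceLexicon

__all__ = [
    "GeneratorSpec",
    "GroundTruth",
    "generate_corpus",
    "match_topics",
    "align_phi",
    "default_valence_lexicon",
    "lexicon_tsv",
    "POSITIVE_WORDS",
    "NEGATIVE_WORDS",
]

# Ordered by intended corpus frequency (Zipf-like weights below), echoing
# the valence words most common in biomedical abstracts.
POSITIVE_WORDS = (
    "healthy", "effective", "positive", "survive", "improved",
    "benefit", "success", "gain", "recovery", "safe",
)
NEGATIVE_WORDS = (
    "risk", "chronic", "syndrome", "failure", "severe",
    "adverse", "death", "pain", "loss", "harm",
)

_CODE_ALPHABET = "bcdfghjklmnpqrtvwxz"  # no vowels, no s, no y


def _synth_word(i: int) -> str:
    n = len(_CODE_ALPHABET)
    code = []
    for _ in range(3):
        code.append(_CODE_ALPHABET[i % n])
        i //= n
    return "w" + "".join(reversed(code))


def default_valence_lexicon() -> ValenceLexicon:
    """The embedded valence word set as a loaded lexicon."""
    entries = {w: "positive" for w in POSITIVE_WORDS}
    entries.update({w: "negative" for w in NEGATIVE_WORDS})
    return ValenceLexicon(entries)


def lexicon_tsv() -> str:
    """The embedded valence word set in NRC-style TSV form."""
    lines = [f"{w}\tpositive\t1" for w in POSITIVE_WORDS]
    lines += [f"{w}\tnegative\t1" for w in NEGATIVE_WORDS]
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for a synthetic corpus.

    Defaults give 20 years × 50 documents of ~60 tokens over a
    500-word vocabulary and 5 topics, one rising at +0.01 prevalence/year
    and one falling at −0.01/year, with negative valence words injected at
    three times the positive rate.
    """

    K_true: int = 5
    V: int = 500
    D_per_year: int = 50
    year_start: int = 1990
    year_end: int = 2009
    doc_length: float = 60.0
    beta_conc: float = 0.05
    trend_profiles: tuple[tuple[str, float], ...] | None = None
    mixture_conc: float = 5.0
    pos_rate: float = 0.02
    neg_rate: float = 0.06
    seed: int = 0

    def resolved_profiles(self) -> tuple[tuple[str, float], ...]:
        if self.trend_profiles is not None:
            return self.trend_profiles
        profiles = [("flat", 0.0)] * self.K_true
        if self.K_true >= 1:
            profiles[0] = ("rising", 0.01)
        if self.K_true >= 2:
            profiles[1] = ("falling", 0.01)
        return tuple(profiles)

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    def validate(self) -> None:
        if self.K_true < 1 or self.V < self.K_true:
            raise ValueError("need K_true >= 1 and V >= K_true")
        if self.year_end < self.year_start:
            raise ValueError("empty year range")
        if self.pos_rate < 0 or self.neg_rate < 0 or self.pos_rate + self.neg_rate > 1:
            raise ValueError("valence rates must be nonnegative with sum <= 1")
        profiles = self.resolved_profiles()
        if len(profiles) != self.K_true:
            raise ValueError("need one trend profile per topic")
        raw = self._raw_prevalence()
        if np.any(raw <= 0) or (self.K_true > 1 and np.any(raw >= 1)):
            raise ValueError(
                "trend slopes overshoot: prevalence leaves (0, 1); reduce the slope"
            )

    def _raw_prevalence(self) -> np.ndarray:
        years = self.years
        offsets = years - years.mean()
        base = np.full(self.K_true, 1.0 / self.K_true)
        prev = np.tile(base, (len(years), 1))
        for k, (kind, slope) in enumerate(self.resolved_profiles()):
            if kind == "rising":
                prev[:, k] += slope * offsets
            elif kind == "falling":
                prev[:, k] -= slope * offsets
            elif kind != "flat":
                raise ValueError(f"unknown trend kind {kind!r}")
        return prev

    def prevalence_matrix(self) -> np.ndarray:
        """Year × topic prevalence targets (rows sum to 1)."""
        prev = np.clip(self._raw_prevalence(), 0.001, 0.999)
        return prev / prev.sum(axis=1, keepdims=True)


@dataclass
class GroundTruth:
    """Everything the generator knows about the corpus it emitted."""

    spec: GeneratorSpec
    phi_true: np.ndarray           # K_true × V
    prevalence: np.ndarray         # Y × K_true
    years: np.ndarray              # (Y,)
    doc_year: np.ndarray           # (D,)
    doc_dominant: np.ndarray       # (D,) arg-max of the drawn mixture
    doc_theta: np.ndarray          # D × K_true drawn mixtures
    doc_length: np.ndarray         # (D,) token counts actually emitted
    doc_pos_injected: np.ndarray   # (D,)
    doc_neg_injected: np.ndarray   # (D,)
    vocabulary: list[str] = field(default_factory=list)
    lexicon: ValenceLexicon = field(default_factory=default_valence_lexicon)


def _zipf_weights(n: int) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1)
    return w / w.sum()


def generate_corpus(spec: GeneratorSpec) -> tuple[Corpus, GroundTruth]:
    """Sample a corpus and its ground truth; identical spec → identical output.

    Per document: topic mixture ~ Dirichlet(mixture_conc × year prevalence),
    length ~ Poisson(doc_length) (floored at 1), each token drawn
    topic-then-word from φ, then independently replaced by a positive
    (probability ``pos_rate``) or negative (``neg_rate``) lexicon word drawn
    with Zipf-like weights.  The first five tokens form the title, the rest
    the abstract.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    vocab = [_synth_word(i) for i in range(spec.V)]
    phi_true = rng.dirichlet(np.full(spec.V, spec.beta_conc), size=spec.K_true)
    prevalence = spec.prevalence_matrix()
    years = spec.years

    pos_w = _zipf_weights(len(POSITIVE_WORDS))
    neg_w = _zipf_weights(len(NEGATIVE_WORDS))

    records: list[ArticleRecord] = []
    doc_year, doc_dom, doc_len, doc_pos, doc_neg = [], [], [], [], []
    thetas = []
    d = 0
    for yi, year in enumerate(years):
        conc = spec.mixture_conc * prevalence[yi]
        for _ in range(spec.D_per_year):
            theta = rng.dirichlet(conc)
            length = max(1, int(rng.poisson(spec.doc_length)))
            z = rng.choice(spec.K_true, size=length, p=theta)
            words = [vocab[w] for w in
                     (rng.random((length, 1)) < phi_true[z].cumsum(axis=1)).argmax(axis=1)]
            u = rng.random(length)
            n_pos = n_neg = 0
            for i in range(length):
                if u[i] < spec.pos_rate:
                    words[i] = str(rng.choice(POSITIVE_WORDS, p=pos_w))
                    n_pos += 1
                elif u[i] < spec.pos_rate + spec.neg_rate:
                    words[i] = str(rng.choice(NEGATIVE_WORDS, p=neg_w))
                    n_neg += 1
            title = " ".join(words[:5])
            abstract = " ".join(words[5:])
            records.append(ArticleRecord(id=f"d{d:06d}", year=int(year),
                                         title=title, abstract=abstract))
            doc_year.append(int(year))
            doc_dom.append(int(np.argmax(theta)))
            doc_len.append(length)
            doc_pos.append(n_pos)
            doc_neg.append(n_neg)
            thetas.append(theta)
            d += 1

    truth = GroundTruth(
        spec=spec,
        phi_true=phi_true,
        prevalence=prevalence,
        years=years,
        doc_year=np.asarray(doc_year),
        doc_dominant=np.asarray(doc_dom),
        doc_theta=np.asarray(thetas),
        doc_length=np.asarray(doc_len),
        doc_pos_injected=np.asarray(doc_pos),
        doc_neg_injected=np.asarray(doc_neg),
        vocabulary=vocab,
    )
    return Corpus(records=records), truth


def align_phi(phi_est: np.ndarray, vocab_index: dict[str, int],
              truth_vocabulary: list[str]) -> np.ndarray:
    """Re-express an estimated φ on the generator's vocabulary axis.

    Columns for synthetic words pruned from the fitted vocabulary (e.g. by a
    document-frequency floor) are zero, which only lowers cosine similarity
    — the comparison stays conservative.
    """
    phi_est = np.asarray(phi_est)
    out = np.zeros((phi_est.shape[0], len(truth_vocabulary)))
    for j, word in enumerate(truth_vocabulary):
        jj = vocab_index.get(word)
        if jj is not None:
            out[:, j] = phi_est[:, jj]
    return out


def match_topics(phi_est: np.ndarray, phi_true: np.ndarray) -> list[tuple[int, int, float]]:
    """Greedy one-to-one matching of estimated to true topics by cosine
    similarity (largest similarity first).

    Returns (estimated index, true index, cosine) triples.  Requires equal
    topic counts.
    """
    phi_est = np.asarray(phi_est, dtype=np.float64)
    phi_true = np.asarray(phi_true, dtype=np.float64)
    if phi_est.shape[0] != phi_true.shape[0]:
        raise ValueError(
            f"topic counts differ: {phi_est.shape[0]} vs {phi_true.shape[0]}"
        )
    a = phi_est / np.linalg.norm(phi_est, axis=1, keepdims=True)
    b = phi_true / np.linalg.norm(phi_true, axis=1, keepdims=True)
    cos = a @ b.T
    K = cos.shape[0]
    free_est, free_true = set(range(K)), set(range(K))
    pairs: list[tuple[int, int, float]] = []
    work = cos.copy()
    for _ in range(K):
        i, j = np.unravel_index(np.argmax(work), work.shape)
        pairs.append((int(i), int(j), float(cos[i, j])))
        free_est.discard(int(i))
        free_true.discard(int(j))
        work[i, :] = -np.inf
        work[:, j] = -np.inf
    pairs.sort()
    return pairs
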