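"""Text normalisation: tokenisation, Porter stemming, and the document-term matrix.

The cleaning rules follow standard bibliometric practice: lowercase, split
hyphenated compounds, keep purely alphabetic tokens, drop stopwords
(prepositions, articles, pronouns and other function words carried by an
input word list) and tokens below a minimum length, then reduce inflected
forms with the classic Porter stemmer (``compression``, ``compressed`` and
``compressing`` all map to ``compress``).  Raw stem counts feed the topic
model; the per-year 1-100 frequency rank scale is descriptive output only.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import scipy.sparse as sp

from .corpus_io import Corpus

__all__ = [
    "Vocabulary",
    "DocumentTermMatrix",
    "tokenize",
    "porter_stem",
    "build_dtm",
    "yearly_term_rank",
    "default_stopwords",
    "EmptyCorpusError",
]


class EmptyCorpusError(ValueError):
    """No documents (or no vocabulary) survive filtering."""


def default_stopwords() -> set[str]:
    """The standard English function-word list shipped with the package."""
    text = resources.files("topiclens.data").joinpath("stopwords.txt").read_text("utf-8")
    return {w for w in text.split() if w}


# ---------------------------------------------------------------------------
# Tokenisation
# ---------------------------------------------------------------------------

_ALPHA_RE = re.compile(r"[a-z]+")


def tokenize(text: str, stopwords: set[str] | frozenset[str] = frozenset(),
             min_len: int = 2) -> list[str]:
    """Split free text into lowercase alphabetic tokens.

    Hyphenated compounds are split at the hyphen; digits and punctuation
    never appear in a token (``p<0.05`` and ``140/90`` yield nothing).
    Tokens in ``stopwords`` or shorter than ``min_len`` are removed.  The
    result is the *nonstop* token stream: stopword-free but unstemmed, which
    is also what valence scoring consumes.
    """
    tokens = _ALPHA_RE.findall(text.lower())
    return [t for t in tokens if len(t) >= min_len and t not in stopwords]


# ---------------------------------------------------------------------------
# Porter stemmer (classic 1980 algorithm)
# ---------------------------------------------------------------------------

_VOWELS = frozenset("aeiou")


def _is_cons(word: str, i: int) -> bool:
    ch = word[i]
    if ch in _VOWELS:
        return False
    if ch == "y":
        return i == 0 or not _is_cons(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of vowel→consonant transitions ([C](VC)^m[V] form)."""
    m = 0
    prev_cons: bool | None = None
    for i in range(len(stem)):
        cons = _is_cons(stem, i)
        if prev_cons is False and cons:
            m += 1
        prev_cons = cons
    return m


def _has_vowel(stem: str) -> bool:
    return any(not _is_cons(stem, i) for i in range(len(stem)))


def _ends_double_cons(stem: str) -> bool:
    return (
        len(stem) >= 2
        and stem[-1] == stem[-2]
        and _is_cons(stem, len(stem) - 1)
    )


def _ends_cvc(stem: str) -> bool:
    # consonant-vowel-consonant, final consonant not w, x or y
    if len(stem) < 3:
        return False
    return (
        _is_cons(stem, len(stem) - 3)
        and not _is_cons(stem, len(stem) - 2)
        and _is_cons(stem, len(stem) - 1)
        and stem[-1] not in "wxy"
    )


_STEP2 = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
]
_STEP3 = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]
_STEP4 = [
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]
_STEP2.sort(key=lambda p: -len(p[0]))
_STEP3.sort(key=lambda p: -len(p[0]))
_STEP4.sort(key=len, reverse=True)


@lru_cache(maxsize=200_000)
def porter_stem(token: str) -> str:
    """Porter-stem a lowercase alphabetic token.

    Idempotent on its own output for practical vocabulary (tested as an
    invariant); tokens of length <= 2 are returned unchanged.
    """
    w = token
    if len(w) <= 2:
        return w

    # Step 1a — plurals
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif not w.endswith("ss") and w.endswith("s"):
        w = w[:-1]

    # Step 1b — -ed / -ing
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            w = w[:-1]
    else:
        stripped = None
        if w.endswith("ed") and _has_vowel(w[:-2]):
            stripped = w[:-2]
        elif w.endswith("ing") and _has_vowel(w[:-3]):
            stripped = w[:-3]
        if stripped is not None:
            w = stripped
            if w.endswith(("at", "bl", "iz")):
                w += "e"
            elif _ends_double_cons(w) and w[-1] not in "lsz":
                w = w[:-1]
            elif _measure(w) == 1 and _ends_cvc(w):
                w += "e"

    # Step 1c — terminal y
    if w.endswith("y") and _has_vowel(w[:-1]):
        w = w[:-1] + "i"

    # Step 2
    for suffix, repl in _STEP2:
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            if _measure(stem) > 0:
                w = stem + repl
            break

    # Step 3
    for suffix, repl in _STEP3:
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            if _measure(stem) > 0:
                w = stem + repl
            break

    # Step 4
    for suffix in _STEP4:
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            if _measure(stem) > 1 and (suffix != "ion" or stem.endswith(("s", "t"))):
                w = stem
            break

    # Step 5a — terminal e
    if w.endswith("e"):
        stem = w[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            w = stem

    # Step 5b — -ll
    if _measure(w) > 1 and _ends_double_cons(w) and w.endswith("l"):
        w = w[:-1]

    return w


# ---------------------------------------------------------------------------
# Document-term matrix
# ---------------------------------------------------------------------------

@dataclass
class Vocabulary:
    """Ordered stemmed vocabulary with a term → column index map."""

    terms: list[str]
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {t: j for j, t in enumerate(self.terms)}

    def __len__(self) -> int:
        return len(self.terms)

    def __getitem__(self, j: int) -> str:
        return self.terms[j]


@dataclass
class DocumentTermMatrix:
    """Documents × stemmed-vocabulary counts plus per-document metadata.

    ``counts`` is a CSR sparse matrix of nonnegative integers; row ``d`` sums
    to the number of retained tokens of document ``d``.  Documents with zero
    retained tokens are excluded at construction and tallied in
    ``n_empty_docs``.
    """

    counts: sp.csr_matrix
    doc_years: np.ndarray
    doc_ids: list[str]
    vocabulary: Vocabulary
    n_empty_docs: int = 0

    @property
    def n_docs(self) -> int:
        return self.counts.shape[0]

    @property
    def n_terms(self) -> int:
        return self.counts.shape[1]

    @property
    def n_tokens(self) -> int:
        return int(self.counts.sum())


def build_dtm(corpus: Corpus, stopwords: set[str] | frozenset[str],
              min_doc_freq: int = 5, min_token_len: int = 2) -> DocumentTermMatrix:
    """Tokenise, stem and count each document's combined title+abstract.

    The vocabulary is restricted to stems occurring in at least
    ``min_doc_freq`` documents, columns ordered by first appearance in the
    corpus.  Documents left with no in-vocabulary token are dropped and
    tallied.

    Raises
    ------
    EmptyCorpusError
        If the corpus is empty or no term survives the frequency filter.
    """
    if len(corpus) == 0:
        raise EmptyCorpusError("corpus is empty")

    doc_stems: list[list[str]] = []
    for rec in corpus:
        toks = tokenize(rec.text, stopwords, min_len=min_token_len)
        doc_stems.append([porter_stem(t) for t in toks])

    doc_freq: dict[str, int] = {}
    order: list[str] = []
    for stems in doc_stems:
        for s in dict.fromkeys(stems):  # unique, first-appearance order
            if s not in doc_freq:
                order.append(s)
            doc_freq[s] = doc_freq.get(s, 0) + 1

    terms = [t for t in order if doc_freq[t] >= min_doc_freq]
    if not terms:
        raise EmptyCorpusError(
            f"no term occurs in >= {min_doc_freq} documents; vocabulary is empty"
        )
    vocab = Vocabulary(terms)

    rows: list[int] = []
    cols: list[int] = []
    vals: list[int] = []
    years: list[int] = []
    ids: list[str] = []
    n_empty = 0
    for rec, stems in zip(corpus, doc_stems):
        counts: dict[int, int] = {}
        for s in stems:
            j = vocab.index.get(s)
            if j is not None:
                counts[j] = counts.get(j, 0) + 1
        if not counts:
            n_empty += 1
            continue
        d = len(ids)
        for j, c in sorted(counts.items()):
            rows.append(d)
            cols.append(j)
            vals.append(c)
        years.append(rec.year)
        ids.append(rec.id)

    if not ids:
        raise EmptyCorpusError("all documents empty after filtering")

    counts_mat = sp.csr_matrix(
        (np.asarray(vals, dtype=np.int64), (rows, cols)),
        shape=(len(ids), len(terms)),
    )
    return DocumentTermMatrix(
        counts=counts_mat,
        doc_years=np.asarray(years, dtype=np.int64),
        doc_ids=ids,
        vocabulary=vocab,
        n_empty_docs=n_empty,
    )


def yearly_term_rank(dtm: DocumentTermMatrix) -> dict[int, dict[str, int]]:
    """Per-year 1-100 frequency rank scale (1 = most frequent term that year).

    Within each year, terms present that year are ranked by descending total
    count; tied terms share the better (smaller) score.  With ``n`` ranked
    terms the term at 1-based position ``p`` scores
    ``max(1, ceil(100 * (p - 1) / (n - 1)))`` (a single term scores 1), so
    the most frequent term scores 1 and the least frequent scores 100.
    Descriptive output only — raw counts, not these scores, feed the sampler.
    """
    if dtm.n_docs == 0:
        raise EmptyCorpusError("empty document-term matrix")
    out: dict[int, dict[str, int]] = {}
    counts = dtm.counts
    for year in sorted(set(dtm.doc_years.tolist())):
        mask = dtm.doc_years == year
        totals = np.asarray(counts[mask].sum(axis=0)).ravel()
        present = np.nonzero(totals)[0]
        # sort by descending count, ties by column index for determinism
        order = present[np.lexsort((present, -totals[present]))]
        n = len(order)
        scores: dict[str, int] = {}
        pos = 0
        prev_count = None
        for rank_i, j in enumerate(order, start=1):
            if totals[j] != prev_count:
                pos = rank_i  # tied terms share the position of the first
                prev_count = totals[j]
            if n == 1:
                score = 1
            else:
                score = max(1, math.ceil(100 * (pos - 1) / (n - 1)))
            scores[dtm.vocabulary[j]] = min(score, 100)
        out[year] = scores
    return out
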