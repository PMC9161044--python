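"""Lexicon-based valence scoring of articles and yearly sentiment trends.

Each article's stopword-free token stream is matched against a valence
lexicon of positive/negative lemmas.  The positive (negative) ratio is the
count of positive (negative) tokens divided by the article's nonstop token
count, so both ratios live in [0, 1] and sum to at most 1; an article is
labelled by whichever polarity has the larger ratio, *neutral* on ties
(including no hits at all).  Matching is on unstemmed lowercase tokens —
the lexicon indexes dictionary lemmas, and stemmed forms (``effective`` →
``effect``) would miss them.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus_io import ValenceLexicon

__all__ = [
    "ValenceScore",
    "score_article",
    "yearly_sentiment",
    "top_valence_words",
    "LABELS",
]

LABELS = ("positive", "negative", "neutral")


@dataclass(frozen=True)
class ValenceScore:
    """Valence tallies and ratios for one article."""

    pos_count: int
    neg_count: int
    nonstop_count: int
    pos_ratio: float
    neg_ratio: float
    label: str


def score_article(tokens: list[str], lexicon: ValenceLexicon) -> ValenceScore:
    """Score one article's nonstop token stream against the lexicon.

    An empty stream (or equal ratios) is neutral; ratios range from 0
    (no valence words) to 1 (every nonstop word carries that polarity).
    """
    pos = neg = 0
    for t in tokens:
        polarity = lexicon.polarity(t)
        if polarity == "positive":
            pos += 1
        elif polarity == "negative":
            neg += 1
    n = len(tokens)
    if n == 0:
        return ValenceScore(0, 0, 0, 0.0, 0.0, "neutral")
    pos_ratio, neg_ratio = pos / n, neg / n
    if pos_ratio > neg_ratio:
        label = "positive"
    elif neg_ratio > pos_ratio:
        label = "negative"
    else:
        label = "neutral"
    return ValenceScore(pos, neg, n, pos_ratio, neg_ratio, label)


def yearly_sentiment(scores: list[ValenceScore], doc_years) -> pd.DataFrame:
    """Per-year fractions of positive / negative / neutral articles.

    Returns a frame indexed by year with columns ``positive``, ``negative``,
    ``neutral`` summing to 1 per row, plus the year's article count ``n``.
    """
    years = np.asarray(doc_years)
    frame = pd.DataFrame({"year": years, "label": [s.label for s in scores]})
    counts = (
        frame.pivot_table(index="year", columns="label", aggfunc="size", fill_value=0)
        .reindex(columns=list(LABELS), fill_value=0)
    )
    counts.columns.name = None
    n = counts.sum(axis=1)
    out = counts.div(n, axis=0)
    out["n"] = n
    return out


def top_valence_words(token_lists: list[list[str]], lexicon: ValenceLexicon,
                      n: int = 20) -> tuple[list[tuple[str, int]], list[tuple[str, int]]]:
    """Most frequent lexicon-flagged words across the corpus, per polarity.

    Returns (top positive, top negative) as (word, count) lists ranked by
    descending corpus frequency, ties broken alphabetically.
    """
    pos_counts: Counter[str] = Counter()
    neg_counts: Counter[str] = Counter()
    for tokens in token_lists:
        for t in tokens:
            polarity = lexicon.polarity(t)
            if polarity == "positive":
                pos_counts[t] += 1
            elif polarity == "negative":
                neg_counts[t] += 1

    def rank(c: Counter[str]) -> list[tuple[str, int]]:
        return sorted(c.items(), key=lambda kv: (-kv[1], kv[0]))[:n]

    return rank(pos_counts), rank(neg_counts)
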