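"""Readers and writers for every external format the pipeline touches.

Article corpora arrive either as MEDLINE flat files (the export format of a
PubMed query: ``PMID``/``TI``/``AB``/``DP`` tags with space-indented
continuation lines) or as JSON lines with ``id``/``year``/``title``/
``abstract`` keys.  The valence lexicon is the NRC-style tab-separated
``word<TAB>category<TAB>flag`` format, of which only the *positive* and
*negative* categories are retained (emotion categories such as anger or joy
are ignored).  Stopword lists are plain text, one word per line.  All result
tables elsewhere in the package are TSV with a header row.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Union

__all__ = [
    "ArticleRecord",
    "Corpus",
    "ValenceLexicon",
    "CorpusParseError",
    "LexiconError",
    "parse_medline",
    "parse_jsonl",
    "write_corpus_jsonl",
    "load_lexicon",
    "load_stopwords",
]


class CorpusParseError(ValueError):
    """Raised for structurally malformed corpus input; carries a line number."""


class LexiconError(ValueError):
    """Raised when the valence lexicon is internally inconsistent."""


@dataclass(frozen=True)
class ArticleRecord:
    """One article: identifier, publication year, title and abstract.

    The abstract may be empty (title alone is analysed); records where both
    title and abstract are empty are dropped at parse time.
    """

    id: str
    year: int
    title: str
    abstract: str = ""

    @property
    def text(self) -> str:
        """Title and abstract combined into a single string for analysis."""
        if self.title and self.abstract:
            return self.title + " " + self.abstract
        return self.title or self.abstract


@dataclass
class Corpus:
    """Ordered collection of article records plus a tally of skipped input.

    ``n_skipped`` counts source records dropped for a missing/unparseable
    year or for having neither title nor abstract.
    """

    records: list[ArticleRecord] = field(default_factory=list)
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ArticleRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> ArticleRecord:
        return self.records[i]

    @property
    def years(self) -> list[int]:
        return [r.year for r in self.records]

    def validate(self, min_year: int | None = None, max_year: int | None = None) -> None:
        """Check id uniqueness and (optionally) the year window."""
        seen: set[str] = set()
        for r in self.records:
            if not r.id:
                raise CorpusParseError("empty article id")
            if r.id in seen:
                raise CorpusParseError(f"duplicate article id {r.id!r}")
            seen.add(r.id)
            if min_year is not None and r.year < min_year:
                raise CorpusParseError(f"article {r.id}: year {r.year} < {min_year}")
            if max_year is not None and r.year > max_year:
                raise CorpusParseError(f"article {r.id}: year {r.year} > {max_year}")


@dataclass
class ValenceLexicon:
    """Map from lowercase lemma to valence polarity (``positive``/``negative``)."""

    entries: dict[str, str] = field(default_factory=dict)

    def polarity(self, word: str) -> str | None:
        return self.entries.get(word)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, word: str) -> bool:
        return word in self.entries

    def swapped(self) -> "ValenceLexicon":
        """Polarity-swapped copy (used for symmetry checks)."""
        flip = {"positive": "negative", "negative": "positive"}
        return ValenceLexicon({w: flip[p] for w, p in self.entries.items()})


def _as_lines(stream: Union[str, IO[str], Iterable[str]]) -> Iterator[str]:
    if isinstance(stream, str):
        return iter(stream.splitlines())
    return iter(l.rstrip("\n") for l in stream)


_YEAR_RE = re.compile(r"\b(\d{4})\b")


def _parse_year(dp: str) -> int | None:
    """First 4-digit token of a MEDLINE DP field (fields carry month/season suffixes)."""
    m = _YEAR_RE.search(dp)
    return int(m.group(1)) if m else None


def parse_medline(stream: Union[str, IO[str], Iterable[str]]) -> Corpus:
    """Parse MEDLINE flat-file text into a corpus.

    Each record is a block of ``TAG - value`` lines starting at ``PMID``;
    continuation lines begin with spaces and are appended to the previous
    field.  Records with no parseable year, or with neither title nor
    abstract, are dropped and counted in ``Corpus.n_skipped``.

    Raises
    ------
    CorpusParseError
        If a field line appears before any PMID block has opened.
    """
    corpus = Corpus()
    fields: dict[str, str] | None = None
    current_tag: str | None = None

    def flush() -> None:
        nonlocal fields
        if fields is None:
            return
        year = _parse_year(fields.get("DP", ""))
        title = fields.get("TI", "").strip()
        abstract = fields.get("AB", "").strip()
        if year is None or (not title and not abstract):
            corpus.n_skipped += 1
        else:
            corpus.records.append(
                ArticleRecord(id=fields["PMID"].strip(), year=year, title=title, abstract=abstract)
            )
        fields = None

    for lineno, line in enumerate(_as_lines(stream), start=1):
        if not line.strip():
            continue
        if line.startswith(" "):
            if fields is None or current_tag is None:
                raise CorpusParseError(f"line {lineno}: continuation line outside a record")
            fields[current_tag] += " " + line.strip()
            continue
        m = re.match(r"^([A-Z]{1,4})\s*- ?(.*)$", line)
        if m is None:
            raise CorpusParseError(f"line {lineno}: unrecognized MEDLINE line {line!r}")
        tag, value = m.group(1), m.group(2)
        if tag == "PMID":
            flush()
            fields = {"PMID": value}
        elif fields is None:
            raise CorpusParseError(f"line {lineno}: field {tag} before any PMID")
        elif tag in fields:
            fields[tag] += " " + value
        else:
            fields[tag] = value
        current_tag = tag
    flush()
    return corpus


def parse_jsonl(stream: Union[str, IO[str], Iterable[str]]) -> Corpus:
    """Parse a JSON-lines corpus (keys ``id``, ``year``, ``title``, ``abstract``).

    Records are kept in file order.  A record whose year is missing or not an
    integer, or which has neither title nor abstract, is skipped and tallied;
    a line that is not valid JSON raises :class:`CorpusParseError` with its
    line number.
    """
    corpus = Corpus()
    for lineno, line in enumerate(_as_lines(stream), start=1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise CorpusParseError(f"line {lineno}: invalid JSON ({exc.msg})") from exc
        year = obj.get("year")
        if isinstance(year, str) and year.isdigit():
            year = int(year)
        title = str(obj.get("title") or "")
        abstract = str(obj.get("abstract") or "")
        if not isinstance(year, int) or isinstance(year, bool) or (not title and not abstract):
            corpus.n_skipped += 1
            continue
        corpus.records.append(
            ArticleRecord(id=str(obj.get("id", "")), year=year, title=title, abstract=abstract)
        )
    return corpus


def write_corpus_jsonl(corpus: Corpus, stream: IO[str]) -> None:
    """Write a corpus as JSON lines; ``parse_jsonl`` round-trips it exactly."""
    for r in corpus:
        stream.write(
            json.dumps(
                {"id": r.id, "year": r.year, "title": r.title, "abstract": r.abstract},
                ensure_ascii=False,
            )
            + "\n"
        )


def load_lexicon(stream: Union[str, IO[str], Iterable[str]]) -> ValenceLexicon:
    """Load an NRC-style TSV valence lexicon.

    Only rows with category ``positive`` or ``negative`` and flag ``1`` are
    retained (lowercased).  A word flagged 1 for both polarities is an error:
    the downstream valence-ratio arithmetic needs an unambiguous polarity per
    lemma.
    """
    entries: dict[str, str] = {}
    for lineno, line in enumerate(_as_lines(stream), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise LexiconError(f"line {lineno}: expected 3 tab-separated fields, got {len(parts)}")
        word, category, flag = parts[0].strip().lower(), parts[1].strip().lower(), parts[2].strip()
        if category not in ("positive", "negative") or flag != "1":
            continue
        prev = entries.get(word)
        if prev is not None and prev != category:
            raise LexiconError(f"word {word!r} flagged both positive and negative")
        entries[word] = category
    return ValenceLexicon(entries)


def load_stopwords(stream: Union[str, IO[str], Iterable[str]]) -> set[str]:
    """Load a plain-text stopword list (one lowercase word per line)."""
    return {line.strip().lower() for line in _as_lines(stream) if line.strip()}
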