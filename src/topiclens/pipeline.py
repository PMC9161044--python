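"""End-to-end orchestration: preprocess → fit → trends → clustering → sentiment.

Every stage reads and writes plain-text artifacts (TSV tables, MatrixMarket
matrices, a key=value model config), so each can be re-run standalone on the
previous stage's persisted outputs with results identical to the end-to-end
run.  A run directory collects all outputs plus a JSON manifest (config
echo, seed, package versions, skip tallies, runtime).  Identical config and
seed reproduce identical result tables byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml
from scipy.io import mmread, mmwrite

from . import __version__
from .corpus_io import Corpus, ValenceLexicon, load_lexicon, load_stopwords, parse_jsonl, parse_medline
from .lda_gibbs import LdaConfig, TopicModel, fit, top_words
from .preprocess import DocumentTermMatrix, Vocabulary, build_dtm, default_stopwords, tokenize, yearly_term_rank
from .sentiment import score_article, top_valence_words, yearly_sentiment
from .topic_clustering import build_graph, dendrogram_table, topic_similarity
from .topic_dynamics import dominant_topic, trend_table, yearly_share

logger = logging.getLogger("topiclens")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_corpus",
           "save_dtm", "load_dtm", "save_model", "load_model", "yearly_counts"]

_FLOAT_FMT = "%.12g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths, preprocessing parameters, model settings and thresholds."""

    corpus: str
    lexicon: str
    out_dir: str
    stopwords: str | None = None          # None → packaged English list
    corpus_format: str = "auto"           # jsonl | medline | auto (by suffix)
    min_doc_freq: int = 5
    min_token_len: int = 2
    lda: LdaConfig = field(default_factory=LdaConfig)
    infrequent_threshold: float = 0.04
    trend_alpha: float = 0.05
    bonferroni: bool = False
    cluster_threshold: float = 0.2
    similarity_method: str = "pearson"
    top_n_words: int = 15
    top_n_valence: int = 20
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text("utf-8")) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        lda_raw = raw.pop("lda", {})
        cfg = cls(**raw)
        if lda_raw:
            cfg.lda = LdaConfig(**{**dataclasses.asdict(cfg.lda), **lda_raw})
        return cfg

    def validate(self) -> None:
        for name in ("corpus", "lexicon"):
            p = getattr(self, name)
            if not Path(p).is_file():
                raise PipelineError("validate", f"{name} path does not exist: {p}")
        if self.stopwords is not None and not Path(self.stopwords).is_file():
            raise PipelineError("validate", f"stopwords path does not exist: {self.stopwords}")
        out = Path(self.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if not out.is_dir():
            raise PipelineError("validate", f"output directory not writable: {out}")


# ---------------------------------------------------------------------------
# Persistence helpers
# ---------------------------------------------------------------------------

def load_corpus(path: str | Path, corpus_format: str = "auto") -> Corpus:
    path = Path(path)
    fmt = corpus_format
    if fmt == "auto":
        fmt = "medline" if path.suffix.lower() in (".medline", ".nbib", ".txt") else "jsonl"
    text = path.read_text("utf-8", errors="replace")
    return parse_medline(text) if fmt == "medline" else parse_jsonl(text)


def save_dtm(dtm: DocumentTermMatrix, out_dir: str | Path) -> None:
    out = Path(out_dir)
    mmwrite(str(out / "dtm.mtx"), dtm.counts)
    pd.DataFrame({"term": dtm.vocabulary.terms}).to_csv(out / "vocabulary.tsv", sep="\t", index=False)
    pd.DataFrame({"id": dtm.doc_ids, "year": dtm.doc_years}).to_csv(
        out / "documents.tsv", sep="\t", index=False)


def load_dtm(out_dir: str | Path) -> DocumentTermMatrix:
    out = Path(out_dir)
    counts = sp.csr_matrix(mmread(str(out / "dtm.mtx")), dtype=np.int64)
    vocab = Vocabulary(pd.read_csv(out / "vocabulary.tsv", sep="\t")["term"].tolist())
    docs = pd.read_csv(out / "documents.tsv", sep="\t")
    return DocumentTermMatrix(counts=counts, doc_years=docs["year"].to_numpy(),
                              doc_ids=docs["id"].astype(str).tolist(), vocabulary=vocab)


def save_model(model: TopicModel, out_dir: str | Path) -> None:
    out = Path(out_dir)
    mmwrite(str(out / "phi.mtx"), model.phi)
    mmwrite(str(out / "theta.mtx"), model.theta)
    with open(out / "lda_config.txt", "w") as fh:
        for key, value in dataclasses.asdict(model.config).items():
            fh.write(f"{key}={value}\n")


def load_model(out_dir: str | Path) -> TopicModel:
    out = Path(out_dir)
    raw: dict[str, str] = {}
    for line in (out / "lda_config.txt").read_text().splitlines():
        if line.strip():
            key, _, value = line.partition("=")
            raw[key] = value
    config = LdaConfig(
        n_topics=int(raw["n_topics"]), alpha=float(raw["alpha"]), eta=float(raw["eta"]),
        n_iter=int(raw["n_iter"]), burn_in=int(raw["burn_in"]),
        average_states=raw["average_states"] == "True", thin=int(raw["thin"]),
        seed=int(raw["seed"]), log_every=int(raw["log_every"]),
    )
    return TopicModel(phi=np.asarray(mmread(str(out / "phi.mtx"))),
                      theta=np.asarray(mmread(str(out / "theta.mtx"))), config=config)


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def yearly_counts(corpus: Corpus) -> pd.DataFrame:
    """Articles per publication year (the corpus growth curve)."""
    counts = pd.Series(corpus.years).value_counts().sort_index()
    return pd.DataFrame({"year": counts.index, "n_articles": counts.to_numpy()})


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_preprocess(config: PipelineConfig, corpus: Corpus) -> DocumentTermMatrix:
    stopwords = (load_stopwords(Path(config.stopwords).read_text("utf-8"))
                 if config.stopwords else default_stopwords())
    dtm = build_dtm(corpus, stopwords, min_doc_freq=config.min_doc_freq,
                    min_token_len=config.min_token_len)
    logger.info("preprocess: %d docs, %d terms, %d tokens (%d empty docs dropped)",
                dtm.n_docs, dtm.n_terms, dtm.n_tokens, dtm.n_empty_docs)
    return dtm


def stage_trends(config: PipelineConfig, theta: np.ndarray,
                 doc_years: np.ndarray) -> tuple[pd.DataFrame, pd.DataFrame]:
    dom = dominant_topic(theta)
    series = yearly_share(dom, doc_years, n_topics=theta.shape[1])
    share_frame = pd.DataFrame(series.share, columns=[f"topic_{k}" for k in range(series.n_topics)])
    share_frame.insert(0, "year", series.years)
    trends = trend_table(series, infrequent_threshold=config.infrequent_threshold,
                         alpha=config.trend_alpha, bonferroni=config.bonferroni)
    return share_frame, trends


def stage_sentiment(config: PipelineConfig, corpus: Corpus, lexicon: ValenceLexicon,
                    stopwords: set[str]) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    token_lists = [tokenize(r.text, stopwords, min_len=config.min_token_len) for r in corpus]
    scores = [score_article(toks, lexicon) for toks in token_lists]
    per_article = pd.DataFrame({
        "id": [r.id for r in corpus],
        "year": [r.year for r in corpus],
        "pos_ratio": [s.pos_ratio for s in scores],
        "neg_ratio": [s.neg_ratio for s in scores],
        "label": [s.label for s in scores],
    })
    yearly = yearly_sentiment(scores, [r.year for r in corpus]).reset_index()
    top_pos, top_neg = top_valence_words(token_lists, lexicon, n=config.top_n_valence)
    top = pd.DataFrame(
        [("positive", r + 1, w, c) for r, (w, c) in enumerate(top_pos)]
        + [("negative", r + 1, w, c) for r, (w, c) in enumerate(top_neg)],
        columns=["polarity", "rank", "word", "count"],
    )
    return per_article, yearly, top


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and write the full result bundle under
    ``config.out_dir``; returns the run directory."""
    t0 = time.time()
    config.validate()
    out = Path(config.out_dir)

    def attempt(stage, fn, *args):
        try:
            return fn(*args)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    corpus = attempt("load", load_corpus, config.corpus, config.corpus_format)
    if len(corpus) == 0:
        raise PipelineError("load", "corpus contains no usable records")
    lexicon = attempt("load", load_lexicon, Path(config.lexicon).read_text("utf-8"))
    stopwords = (load_stopwords(Path(config.stopwords).read_text("utf-8"))
                 if config.stopwords else default_stopwords())
    logger.info("load: %d records (%d skipped), %d lexicon entries",
                len(corpus), corpus.n_skipped, len(lexicon))

    dtm = attempt("preprocess", stage_preprocess, config, corpus)
    save_dtm(dtm, out)
    ranks = yearly_term_rank(dtm)
    _write_tsv(pd.DataFrame(
        [(y, t, s) for y, scores in ranks.items() for t, s in sorted(scores.items())],
        columns=["year", "term", "rank_score"]), out / "yearly_term_rank.tsv")

    lda_config = dataclasses.replace(config.lda, seed=config.seed)
    model, _state = attempt("fit", fit, dtm, lda_config)
    save_model(model, out)
    summaries = top_words(model, dtm.vocabulary, n=min(config.top_n_words, dtm.n_terms))
    _write_tsv(pd.DataFrame(
        [(k, r + 1, term, prob) for k, rows in enumerate(summaries)
         for r, (term, prob) in enumerate(rows)],
        columns=["topic", "rank", "term", "probability"]), out / "topic_top_words.tsv")
    logger.info("fit: K=%d, %d sweeps", lda_config.n_topics, lda_config.n_iter)

    share_frame, trends = attempt("trends", stage_trends, config, model.theta, dtm.doc_years)
    _write_tsv(share_frame, out / "yearly_share.tsv")
    _write_tsv(trends, out / "topic_trends.tsv")
    logger.info("trends: %s", trends["label"].value_counts().to_dict())

    simmat = attempt("cluster", topic_similarity, model.theta, config.similarity_method)
    graph = build_graph(simmat, threshold=config.cluster_threshold)
    _write_tsv(pd.DataFrame(graph.edges, columns=["topic_i", "topic_j", "similarity"]),
               out / "topic_edges.tsv")
    _write_tsv(pd.DataFrame({"topic": np.arange(graph.n_topics),
                             "component": graph.components}), out / "topic_components.tsv")
    _write_tsv(dendrogram_table(simmat), out / "topic_dendrogram.tsv")

    per_article, yearly, top = attempt("sentiment", stage_sentiment, config, corpus,
                                       lexicon, stopwords)
    _write_tsv(per_article, out / "article_sentiment.tsv")
    _write_tsv(yearly, out / "yearly_sentiment.tsv")
    _write_tsv(top, out / "top_valence_words.tsv")

    _write_tsv(yearly_counts(corpus), out / "yearly_counts.tsv")

    manifest = {
        "config": {**dataclasses.asdict(config), "lda": dataclasses.asdict(lda_config)},
        "seed": config.seed,
        "versions": {"topiclens": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "tallies": {"records": len(corpus), "skipped_records": corpus.n_skipped,
                    "empty_docs_dropped": dtm.n_empty_docs,
                    "docs_modeled": dtm.n_docs, "terms": dtm.n_terms,
                    "tokens": dtm.n_tokens},
        "runtime_seconds": round(time.time() - t0, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    logger.info("done in %.1fs → %s", manifest["runtime_seconds"], out)
    return out
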