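import numpy as np
import pytest

import topiclens as tl

RECOVERY_SEEDS = (1, 2, 3, 4, 5)


def recovery_spec(seed: int) -> tl.GeneratorSpec:
    """The reference synthetic study: 5 topics, 500 words, 20 years x 50
    documents of ~60 tokens, one rising and one falling topic."""
    return tl.GeneratorSpec(seed=seed)


@pytest.fixture(scope="session")
def stopwords():
    return tl.default_stopwords()


@pytest.fixture(scope="session")
def lexicon():
    return tl.default_valence_lexicon()


@pytest.fixture(scope="session")
def recovery_runs(stopwords):
    """Generate + fit the reference synthetic corpus for each seed.

    Fits use the generator's true topic count with alpha = eta = 0.02 and
    500 sweeps.  Shared session-wide because the fits dominate suite runtime.
    """
    runs = []
    for seed in RECOVERY_SEEDS:
        corpus, truth = tl.generate_corpus(recovery_spec(seed))
        dtm = tl.build_dtm(corpus, stopwords, min_doc_freq=5)
        config = tl.LdaConfig(n_topics=truth.spec.K_true, alpha=0.02, eta=0.02,
                              n_iter=500, seed=seed)
        model, state = tl.fit(dtm, config)
        phi_aligned = tl.align_phi(model.phi, dtm.vocabulary.index, truth.vocabulary)
        matches = tl.match_topics(phi_aligned, truth.phi_true)
        runs.append({
            "seed": seed, "corpus": corpus, "truth": truth, "dtm": dtm,
            "model": model, "state": state, "matches": matches,
        })
    return runs


@pytest.fixture()
def small_pipeline_inputs(tmp_path):
    """A 200-document synthetic corpus with lexicon on disk, plus a config."""
    spec = tl.GeneratorSpec(K_true=4, V=120, D_per_year=50, year_start=2000,
                            year_end=2003, doc_length=30.0, seed=7)
    corpus, truth = tl.generate_corpus(spec)
    corpus_path = tmp_path / "corpus.jsonl"
    with open(corpus_path, "w") as fh:
        tl.write_corpus_jsonl(corpus, fh)
    lexicon_path = tmp_path / "lexicon.tsv"
    lexicon_path.write_text(tl.lexicon_tsv())
    config = tl.PipelineConfig(
        corpus=str(corpus_path), lexicon=str(lexicon_path),
        out_dir=str(tmp_path / "run"), min_doc_freq=2,
        lda=tl.LdaConfig(n_topics=4, n_iter=120, seed=7), seed=7,
    )
    return config, corpus, truth
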