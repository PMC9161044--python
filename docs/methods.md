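# Methods

This note records the modelling choices behind `topiclens`, the parameters
that matter, what the synthetic generator does and does not emulate, and
the numerical conventions a user re-implementing or auditing the pipeline
would need.

## Preprocessing

Each article's title and abstract are combined into one string.  Tokens
are lowercase alphabetic runs; hyphenated compounds split at the hyphen,
so digits and punctuation never enter a token (`p<0.05` contributes
nothing).  Stopwords come from an input word list — the shipped default
covers articles, prepositions, pronouns, conjunctions and auxiliaries —
because the categories of "words with no analytical significance" admit
many concrete lists and the choice should be visible and replaceable.
Tokens shorter than `min_token_len` (default 2) are dropped.

Stemming uses the classic Porter algorithm, implemented in
`topiclens.preprocess` and verified against the standard vectors
(*compression/compressed/compressing → compress*, *ponies → poni*,
*generalization → gener*, …).  Porter is not strictly idempotent
(*hypertension → hypertens → hyperten*); the pipeline stems exactly once,
so this is a documentation point, not a correctness issue — the
idempotence tests cover representative domain vocabulary and the synthetic
vocabulary, whose words are stemmer fixed points by construction.

The document-term matrix keeps stems occurring in at least `min_doc_freq`
documents (default 5, to bound the vocabulary on large corpora), columns
in first-appearance order.  Documents left empty are dropped and tallied.
The per-year 1–100 term rank scale (1 = most frequent term of the year;
tied counts share the better score; with *n* ranked terms, position *p*
scores `max(1, ceil(100(p−1)/(n−1)))`) is descriptive output only: LDA
consumes raw integer counts, and no downstream computation reads the
scale.

## Collapsed Gibbs LDA

Symmetric Dirichlet priors, α on document-topic mixtures and η on
topic-word distributions, both defaulting to 0.02 — sparse enough that
documents concentrate on few topics and topics on few words, which is what
makes century-scale corpora interpretable.  Default K = 20 and 5000
sweeps suit the reporting scale the package targets; both are ordinary
config fields (a 50-topic run is just `n_topics: 50`).

Initialization assigns every token a uniform random topic.  Sweeps visit
tokens in a fixed document-major, vocabulary-column order; all randomness
flows from one `numpy` generator seeded per run, so identical config and
seed reproduce results bitwise.  Estimates are read off the final state by
default; optional state averaging (every `thin` sweeps after burn-in,
burn-in defaulting to half the run when averaging is on) reduces Monte
Carlo noise but averages over topic-label permutations if the chain ever
switches modes, so it is off by default.  The collapsed log-joint can be
traced every `log_every` sweeps for convergence monitoring.

The inner loop is JIT-compiled with numba; a pure-Python loop with
identical arithmetic is the fallback, so results do not depend on which
path runs.  Correctness rests on an enumeration oracle: on every corpus of
at most 6 tokens over a 3-word vocabulary, the implemented conditional
matches ratios of the exactly enumerated Dirichlet-multinomial joint to
1e-10 relative error, and long thinned runs of the sampler match the
enumerated posterior in total variation.  Thinning matters in that check:
at α = η = 0.02 the single-site chain is strongly autocorrelated, so
consecutive samples understate the effective sample size without biasing
the stationary distribution.

## Topic dynamics

Prevalence is counted from dominant topics — each article contributes to
exactly one topic, matching how per-topic article counts are reported in
bibliometric tables — with a mean-θ alternative (`mean_theta_share`) for
users preferring soft mass.  Years with no documents are omitted, not
imputed.

The Cochran-Armitage statistic uses calendar years as scores (the test is
invariant to affine score changes, so any linear recoding of years gives
the same z).  A table with no successes or all successes is degenerate and
returns z = 0, p = 1 with no rejection.  Classification thresholds: mean
share below 0.04 → *infrequent*; otherwise Cochran-Armitage p < 0.05 with
positive (negative) OLS slope → *hot* (*cold*); else *stable*.  The 0.04
floor and 0.05 level are package conventions, exposed as config.  No
multiple-testing correction is applied across the K tests by default —
the labels are descriptive screening, not confirmatory inference — with
Bonferroni available by flag.

One behaviour worth knowing: dominant-topic shares are compositional, so
injecting a *falling* topic mechanically lifts the dominance share of flat
topics (and vice versa); small significant trends on topics generated as
flat are therefore expected whenever other topics trend, and are real
features of the share series, not false positives of the test (its type-I
error under a true constant-proportion null is verified to sit at the
nominal 5%).

## Topic clustering

Similarity between topics is the Pearson correlation of their θ columns
across documents.  Correlation (rather than cosine on raw θ) is used
because θ rows sum to 1: closure alone makes all columns positively
aligned in raw space, while correlation exposes which topics co-occur
*more than the closure forces* (with K = 2 the closure forces exactly −1).
Cosine is available by flag.  Zero-variance columns have undefined
correlation; they are flagged and given similarity 0.  Edges connect pairs
with similarity at or above the threshold (default 0.2, an artifact
convention for readable graphs); connected components are reported, and an
average-linkage merge table over distance 1 − similarity is emitted for
users wanting a hierarchy.

## Sentiment

Valence matching is on **unstemmed** lowercase nonstop tokens: the lexicon
indexes dictionary lemmas, and stemmed forms (*effective → effect*) would
miss them.  Ratios divide polarity counts by the article's nonstop word
count, so `pos_ratio + neg_ratio ≤ 1`; an article with no nonstop words,
or with equal ratios, is neutral.  This majority-polarity rule is the
simplest classification consistent with ratios "from 0 (neutral) to 1";
threshold-based variants would need a justified cutoff the package does
not presume.  A known interpretive limitation of any general-purpose
valence lexicon on scientific text: words like *risk* or *inhibition* are
methodological vocabulary, not authorial sentiment, so sentiment shares
describe framing vocabulary rather than attitude.

## Synthetic generator

`GeneratorSpec` defaults define the reference study: 5 topics over a
500-word vocabulary, 20 years (1990–2009) × 50 documents, mean length 60
tokens (Poisson, floored at 1), topic-word Dirichlet concentration 0.05
(sparse, well-separated topics), one topic rising at +0.01 prevalence/year
and one falling at −0.01, valence injection rates 0.02 positive / 0.06
negative per token.  Year dependence enters through the mean of the
document-mixture Dirichlet (concentration fixed at 5 × the year's
prevalence vector), keeping the within-year model exactly LDA.  Raw
trajectories leaving (0, 1) are rejected before sampling; otherwise they
are clipped to [0.001, 0.999] and renormalized.

Synthetic words are `w` + three letters from a vowel-free, s-free
consonant alphabet: they pass the tokenizer unchanged and are Porter fixed
points, so the pipeline round-trips the generated corpus exactly.  The
embedded valence word set is real English, disjoint from the synthetic
vocabulary, drawn with Zipf-like weights so frequency ranks are
predictable; every injected token is recorded, and ground truth reconciles
exactly with the emitted text.

What the generator does *not* emulate: real MeSH vocabulary, prose
structure, citation or journal effects, vocabulary growth over time, and
corpus growth (documents per year is constant).  Passing recovery tests
therefore demonstrates correctness of the inference machinery under the
model's own assumptions, not robustness to real-literature misspecification.

## Problem sizes and verification

The validation suite works at sizes chosen to make the checks exact or
statistically sharp: enumeration oracles on ≤ 6-token corpora (where the
posterior has at most 64 atoms), recovery and trend detection on the
reference 1,000-document corpus with 500 sweeps across 5 seeds (mean
matched-topic cosine ≥ 0.9; rising topic hot and falling topic cold), the
trend test's type-I error on 2,000 simulated null datasets, and bitwise
comparison of full pipeline reruns.  `scripts/acceptance.py` recomputes
all of these from scratch under a caller-supplied seed.

## Known limitations

* Single-chain MCMC with no convergence diagnostics beyond the log-joint
  trace; label switching makes cross-run topic identities arbitrary
  (matching to a reference φ is provided for evaluation).
* The MEDLINE parser handles the PMID/TI/AB/DP tag subset with
  continuation lines, not the full NLM field zoo; publication-type
  filtering is not implemented.
* Trend labels are descriptive: no multiple-testing correction by
  default, no changepoint or nonlinear trend modelling.
* Dominant-topic prevalence discards within-document topic mixing; the
  mean-θ variant is provided but untested against reported tables.
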