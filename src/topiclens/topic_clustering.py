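"""Topic co-occurrence structure from the document-topic matrix.

Topics that tend to appear in the same articles have correlated θ columns;
thresholding the pairwise correlation gives a topic graph whose connected
components are the clusters of jointly-discussed themes (an isolated node is
a topic never discussed alongside others).  Because θ rows are compositional
(they sum to 1), Pearson correlation of columns is the default similarity;
cosine similarity is available as an alternative.  An average-linkage
dendrogram over 1 − similarity is also provided for users wanting a
hierarchy rather than a graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

__all__ = [
    "TopicSimilarityMatrix",
    "TopicGraph",
    "topic_similarity",
    "build_graph",
    "dendrogram_table",
]


@dataclass
class TopicSimilarityMatrix:
    """Symmetric K × K topic-similarity matrix with unit diagonal.

    ``degenerate`` lists topics whose θ column had zero variance; their
    off-diagonal similarities are set to 0.
    """

    sim: np.ndarray
    degenerate: list[int] = field(default_factory=list)

    @property
    def n_topics(self) -> int:
        return self.sim.shape[0]


@dataclass
class TopicGraph:
    """Thresholded similarity graph: edge list, components, isolated nodes."""

    n_topics: int
    threshold: float
    edges: list[tuple[int, int, float]]
    components: np.ndarray  # component id per topic

    @property
    def isolated(self) -> list[int]:
        comp_sizes = np.bincount(self.components)
        return [k for k in range(self.n_topics) if comp_sizes[self.components[k]] == 1]


def topic_similarity(theta: np.ndarray, method: str = "pearson") -> TopicSimilarityMatrix:
    """Pairwise similarity of topic columns of θ across documents.

    ``method`` is ``"pearson"`` (default) or ``"cosine"``.  Needs at least
    two documents.  Zero-variance columns (Pearson undefined) get similarity
    0 to every other topic and are flagged.
    """
    theta = np.asarray(theta, dtype=np.float64)
    if theta.shape[0] < 2:
        raise ValueError("need at least 2 documents")
    K = theta.shape[1]
    degenerate: list[int] = []
    if method == "pearson":
        sd = theta.std(axis=0)
        degenerate = [int(k) for k in np.nonzero(sd == 0)[0]]
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = np.corrcoef(theta, rowvar=False)
        sim = np.atleast_2d(sim)
        for k in degenerate:
            sim[k, :] = 0.0
            sim[:, k] = 0.0
    elif method == "cosine":
        norms = np.linalg.norm(theta, axis=0)
        degenerate = [int(k) for k in np.nonzero(norms == 0)[0]]
        safe = np.where(norms == 0, 1.0, norms)
        unit = theta / safe
        sim = unit.T @ unit
        for k in degenerate:
            sim[k, :] = 0.0
            sim[:, k] = 0.0
    else:
        raise ValueError(f"unknown method {method!r}")
    np.fill_diagonal(sim, 1.0)
    sim = np.clip((sim + sim.T) / 2, -1.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return TopicSimilarityMatrix(sim=sim, degenerate=degenerate)


def build_graph(simmat: TopicSimilarityMatrix, threshold: float = 0.2) -> TopicGraph:
    """Edges where off-diagonal similarity >= threshold; components by
    breadth-first traversal.  Raising the threshold never merges components."""
    if not -1 < threshold < 1:
        raise ValueError(f"threshold must be in (-1, 1), got {threshold}")
    K = simmat.n_topics
    sim = simmat.sim
    edges = [
        (i, j, float(sim[i, j]))
        for i in range(K)
        for j in range(i + 1, K)
        if sim[i, j] >= threshold
    ]
    adj: list[list[int]] = [[] for _ in range(K)]
    for i, j, _ in edges:
        adj[i].append(j)
        adj[j].append(i)
    components = np.full(K, -1, dtype=np.int64)
    cid = 0
    for start in range(K):
        if components[start] >= 0:
            continue
        stack = [start]
        components[start] = cid
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if components[v] < 0:
                    components[v] = cid
                    stack.append(v)
        cid += 1
    return TopicGraph(n_topics=K, threshold=threshold, edges=edges, components=components)


def dendrogram_table(simmat: TopicSimilarityMatrix) -> pd.DataFrame:
    """Average-linkage hierarchical clustering over distance 1 − similarity.

    Returns the merge table (left, right, distance, size) in scipy linkage
    convention: node ids >= K denote previously formed merges.
    """
    dist = 1.0 - simmat.sim
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(np.maximum(dist, 0.0), checks=False)
    merges = linkage(condensed, method="average")
    return pd.DataFrame(merges, columns=["left", "right", "distance", "size"]).astype(
        {"left": int, "right": int, "size": int}
    )
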