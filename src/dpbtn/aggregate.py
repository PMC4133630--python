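"""Aggregation of posterior network samples into interpretable outputs.

Posterior draws are grouped by density-based clustering of the flattened
(W, w0) vectors (DBSCAN with a median k-nearest-neighbour radius heuristic),
each cluster summarized by its elementwise-median representative network,
a probability (member fraction of *all* samples, so noise points dilute
every cluster), and per-edge support fractions.  Edge scores are the
elementwise medians over all samples; a threshold delta turns them into a
discrete signed network (|median| >= delta keeps the edge; a relative mode
uses delta = c * max|median|).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import SignalingNetwork
from .sampler import PosteriorSampleSet

#: Fig-style support classes for rendering: fraction of samples with the edge.
SUPPORT_CLASSES = ((0.8, "thick"), (0.6, "thin"), (0.4, "dashed"))


@dataclass
class NetworkCluster:
    """One cluster of similar sampled networks."""

    member_ids: np.ndarray
    probability: float
    representative: SignalingNetwork
    edge_support: np.ndarray  # (N, N) fraction of members with |w_ij| > eps

    @property
    def n_members(self) -> int:
        return self.member_ids.size


@dataclass
class ClusterSettings:
    min_samples: int = 5
    eps: float | None = None          # None -> median k-NN distance heuristic
    support_epsilon: float | None = None  # None -> 0.1 * prior scale s
    prior_scale: float = 1.0


def _support_epsilon(settings: ClusterSettings) -> float:
    if settings.support_epsilon is not None:
        return settings.support_epsilon
    return 0.1 * settings.prior_scale


def _make_cluster(samples: PosteriorSampleSet, ids: np.ndarray,
                  total: int, eps_support: float, gamma: float) -> NetworkCluster:
    w_med = np.median(samples.weights[ids], axis=0)
    w0_med = np.median(samples.basal[ids], axis=0)
    np.fill_diagonal(w_med, 0.0)
    support = (np.abs(samples.weights[ids]) > eps_support).mean(axis=0)
    np.fill_diagonal(support, 0.0)
    rep = SignalingNetwork(w_med, np.minimum(w0_med, 0.0), gamma,
                           list(samples.node_names) or None)
    return NetworkCluster(
        member_ids=ids, probability=ids.size / total,
        representative=rep, edge_support=support,
    )


def cluster_samples(samples: PosteriorSampleSet,
                    settings: ClusterSettings | None = None,
                    gamma: float = 1.8) -> list[NetworkCluster]:
    """Density-based clustering of sampled networks, sorted by probability.

    Samples labelled as noise by DBSCAN belong to no cluster but stay in the
    probability denominator.  Degenerate inputs (a single sample, or all
    samples identical) yield one cluster with probability 1.
    """
    from sklearn.cluster import DBSCAN
    from sklearn.neighbors import NearestNeighbors

    settings = settings or ClusterSettings()
    X = samples.flattened(include_basal=True)
    total = X.shape[0]
    eps_support = _support_epsilon(settings)
    if total == 1 or np.allclose(X, X[0]):
        ids = np.arange(total)
        return [_make_cluster(samples, ids, total, eps_support, gamma)]

    k = min(settings.min_samples, total - 1)
    if settings.eps is None:
        # median k-NN distance sets the density scale; the factor 2 keeps
        # distribution tails attached to their cluster instead of labelling
        # them noise
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
        dists, _ = nn.kneighbors(X)
        eps = 2.0 * float(np.median(dists[:, -1]))
        if eps <= 0.0:
            eps = max(float(dists.max()), 1e-12)
    else:
        eps = settings.eps
    labels = DBSCAN(eps=eps, min_samples=min(settings.min_samples, total)).fit_predict(X)

    clusters = []
    for lab in sorted(set(labels) - {-1}):
        ids = np.flatnonzero(labels == lab)
        clusters.append(_make_cluster(samples, ids, total, eps_support, gamma))
    if not clusters:  # everything flagged noise: fall back to one cluster
        ids = np.arange(total)
        clusters = [_make_cluster(samples, ids, total, eps_support, gamma)]
    clusters.sort(key=lambda c: -c.probability)
    return clusters


@dataclass
class EdgeScoreMatrix:
    """Per-edge posterior medians (the edge 'scores' for evaluation)."""

    scores: np.ndarray  # (N, N), diagonal zero
    node_names: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.scores.shape[0]

    def magnitudes(self) -> np.ndarray:
        return np.abs(self.scores)


def edge_scores(samples: PosteriorSampleSet) -> EdgeScoreMatrix:
    """Elementwise median of the sampled weight matrices."""
    med = np.median(samples.weights, axis=0)
    np.fill_diagonal(med, 0.0)
    return EdgeScoreMatrix(scores=med, node_names=list(samples.node_names))


def discretize_network(scores: EdgeScoreMatrix, delta: float,
                       relative: bool = False) -> np.ndarray:
    """Binary (N, N) edge set: |score| >= delta (or delta = c * max|score|).

    The sign of a kept edge is the sign of its median score and is reported
    separately by callers; exact-zero scores never produce edges.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    mag = scores.magnitudes()
    thr = delta * mag.max() if relative else delta
    edges = (mag >= thr) & (mag > 0.0)
    np.fill_diagonal(edges, False)
    return edges.astype(int)


def to_dot(representative: SignalingNetwork, edge_support: np.ndarray,
           min_support: float = 0.4) -> str:
    """Graphviz DOT rendering with support-dependent edge styles.

    Activations are black, inhibitions red; style follows the support
    classes (> 0.8 thick solid, > 0.6 thin solid, > 0.4 dashed).
    """
    lines = ["digraph network {"]
    for name in representative.node_names:
        lines.append(f'  "{name}";')
    n = representative.n_nodes
    for i in range(n):
        for j in range(n):
            w = representative.weights[i, j]
            sup = edge_support[i, j]
            if w == 0.0 or sup <= min_support:
                continue
            if sup > 0.8:
                style = "solid", 3
            elif sup > 0.6:
                style = "solid", 1
            else:
                style = "dashed", 1
            color = "black" if w > 0 else "red"
            arrow = "normal" if w > 0 else "tee"
            lines.append(
                f'  "{representative.node_names[i]}" -> '
                f'"{representative.node_names[j]}" '
                f'[color={color}, style={style[0]}, penwidth={style[1]}, '
                f'arrowhead={arrow}, label="{w:.2f}"];'
            )
    lines.append("}")
    return "\n".join(lines) + "\n"
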