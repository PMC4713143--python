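"""Graph-theoretic network metrics over proportionally thresholded
connectivity matrices, with phase-randomized surrogate normalization.

A dwPLI matrix is thresholded to keep a fixed fraction of its strongest
weights (connection density), swept from 10% to 50% in 2.5% steps.  At each
density four weighted metrics are computed: Onnela clustering coefficient
(micro scale), characteristic path length on inverse-weight distances
(macro scale), Louvain modularity Q averaged over repetitions and the
standard deviation of participation coefficients (meso scale).  Each metric
is normalized by its mean over phase-randomized surrogates of the original
time-frequency coefficients, and small-worldness is the ratio of normalized
clustering to normalized path length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from networkx.algorithms.community import louvain_communities, modularity
from scipy.sparse.csgraph import shortest_path

from .spectral import (
    ConnectivityResult,
    TFDecomposition,
    band_connectivity,
    dwpli,
)

#: 17 connection densities: 10% to 50% in steps of 2.5%.
DEFAULT_DENSITIES: np.ndarray = np.round(np.arange(0.10, 0.50 + 1e-9, 0.025), 4)

METRIC_NAMES = ("clustering", "path_length", "modularity", "participation_sd")


@dataclass
class ThresholdedGraph:
    adjacency: np.ndarray
    density: float

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, k=1)))


@dataclass
class GraphMetrics:
    """Raw, surrogate-mean and normalized metrics per connection density."""

    densities: np.ndarray
    raw: dict[str, np.ndarray]
    surrogate_mean: dict[str, np.ndarray] | None = None
    normalized: dict[str, np.ndarray] | None = None
    small_worldness: np.ndarray | None = None
    partitions: list[np.ndarray] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def summary(self) -> dict[str, float]:
        """Unweighted mean of each metric across densities."""
        out = {k: float(np.nanmean(v)) for k, v in self.raw.items()}
        if self.normalized is not None:
            out.update(
                {f"norm_{k}": float(np.nanmean(v)) for k, v in self.normalized.items()}
            )
        if self.small_worldness is not None:
            out["small_worldness"] = float(np.nanmean(self.small_worldness))
        return out


def threshold_proportional(matrix: np.ndarray, density: float) -> ThresholdedGraph:
    """Keep the ``round(density * C(N,2))`` largest upper-triangle weights.

    Round-half-up edge counts; ties between equal weights broken by
    lexicographic pair order for determinism.  Weights are preserved (not
    binarized); negative retained values are floored at zero since the
    downstream metrics assume non-negative weights.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(m, m.T):
        raise ValueError("matrix must be symmetric")
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    n = m.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    weights = m[iu, ju]
    n_keep = int(np.floor(density * weights.size + 0.5))
    order = np.lexsort((ju, iu, -weights))  # weight desc, then (i, j) asc
    keep = order[:n_keep]
    adj = np.zeros_like(m)
    adj[iu[keep], ju[keep]] = np.maximum(weights[keep], 0.0)
    adj = adj + adj.T
    return ThresholdedGraph(adjacency=adj, density=float(density))


def clustering_coefficient(graph: ThresholdedGraph) -> tuple[np.ndarray, float]:
    """Onnela weighted clustering, weights rescaled by the maximum.

    c_i = (1 / (k_i (k_i - 1))) * sum_{j,h} (w_ij w_ih w_jh)^(1/3) with
    w normalized by max weight; nodes of degree < 2 get 0.
    """
    w = graph.adjacency
    wmax = w.max()
    if wmax <= 0:
        return np.zeros(w.shape[0]), 0.0
    w_hat = (w / wmax) ** (1.0 / 3.0)
    k = (w > 0).sum(axis=1)
    cyc = np.diagonal(w_hat @ w_hat @ w_hat)
    denom = k * (k - 1)
    c = np.where(denom > 0, cyc / np.where(denom > 0, denom, 1), 0.0)
    return c, float(c.mean())


def characteristic_path_length(graph: ThresholdedGraph) -> tuple[float, int]:
    """Mean shortest-path distance (edge length 1/weight) over reachable
    ordered pairs; returns (L, number of unreachable ordered pairs)."""
    w = graph.adjacency
    n = w.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    dist = shortest_path(lengths, method="D", directed=False)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    n_unreachable = int((off & ~np.isfinite(dist)).sum())
    if not finite.any():
        raise ValueError("graph has no connected pairs")
    return float(dist[finite].mean()), n_unreachable


def _to_nx(adjacency: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    n = adjacency.shape[0]
    g.add_nodes_from(range(n))
    iu, ju = np.nonzero(np.triu(adjacency, k=1))
    g.add_weighted_edges_from(
        (int(i), int(j), float(adjacency[i, j])) for i, j in zip(iu, ju)
    )
    return g


def louvain_partition(
    graph: ThresholdedGraph, reps: int = 50, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Weighted-modularity Louvain, averaged over shuffled repetitions.

    Runs the heuristic ``reps`` times with distinct seeds (randomizing its
    node visit order), reports Q as the mean over repetitions and the
    partition from the best-Q repetition as integer labels.
    """
    adj = graph.adjacency
    if not np.count_nonzero(np.triu(adj, k=1)):
        raise ValueError("edgeless graph")
    g = _to_nx(adj)
    rng = np.random.default_rng(seed)
    best_q, best_parts = -np.inf, None
    qs = []
    for _ in range(reps):
        parts = louvain_communities(
            g, weight="weight", seed=int(rng.integers(2**31 - 1))
        )
        q = modularity(g, parts, weight="weight")
        qs.append(q)
        if q > best_q:
            best_q, best_parts = q, parts
    labels = np.empty(adj.shape[0], dtype=int)
    for m, nodes in enumerate(best_parts):
        for node in nodes:
            labels[node] = m
    return labels, float(np.mean(qs))


def participation_coefficients(
    graph: ThresholdedGraph, partition: np.ndarray
) -> tuple[np.ndarray, float]:
    """P_i = 1 - sum_m (k_im / k_i)^2 on weighted strengths.

    Isolated nodes get 0.  Also returns the population standard deviation
    across nodes.
    """
    w = graph.adjacency
    labels = np.asarray(partition)
    if labels.shape[0] != w.shape[0]:
        raise ValueError("partition must cover all nodes")
    strength = w.sum(axis=1)
    p = np.zeros(w.shape[0])
    for m in np.unique(labels):
        k_im = w[:, labels == m].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p += np.where(strength > 0, (k_im / np.where(strength > 0, strength, 1)) ** 2, 0.0)
    p = np.where(strength > 0, 1.0 - p, 0.0)
    return p, float(p.std())


def small_worldness(norm_clustering: float, norm_path_length: float) -> float:
    """Ratio of normalized clustering to normalized path length."""
    if norm_clustering <= 0 or norm_path_length <= 0:
        return float("nan")
    return norm_clustering / norm_path_length


def metrics_at_density(
    matrix: np.ndarray,
    density: float,
    louvain_reps: int = 50,
    seed: int = 0,
) -> tuple[dict[str, float], np.ndarray, list[str]]:
    """All four raw metrics of one thresholded graph, plus warnings."""
    g = threshold_proportional(matrix, density)
    warnings: list[str] = []
    n = g.adjacency.shape[0]
    avg_degree = 2 * g.n_edges / n
    if avg_degree < 2 * np.log(n):
        warnings.append(
            f"density {density:.3f}: average degree {avg_degree:.2f} below "
            f"estimability floor 2 ln(N) = {2 * np.log(n):.2f}"
        )
    _, clust = clustering_coefficient(g)
    path, n_unreach = characteristic_path_length(g)
    if n_unreach:
        warnings.append(
            f"density {density:.3f}: fragmented graph, "
            f"{n_unreach} unreachable ordered pairs excluded"
        )
    labels, q = louvain_partition(g, reps=louvain_reps, seed=seed)
    _, part_sd = participation_coefficients(g, labels)
    metrics = {
        "clustering": clust,
        "path_length": path,
        "modularity": q,
        "participation_sd": part_sd,
    }
    return metrics, labels, warnings


def density_sweep(
    matrix: np.ndarray,
    densities: np.ndarray = DEFAULT_DENSITIES,
    louvain_reps: int = 50,
    seed: int = 0,
) -> GraphMetrics:
    """Raw metrics at every connection density."""
    raw = {k: [] for k in METRIC_NAMES}
    partitions, warns = [], []
    for d_i, d in enumerate(densities):
        metrics, labels, w = metrics_at_density(
            matrix, float(d), louvain_reps=louvain_reps, seed=seed + d_i
        )
        for k in METRIC_NAMES:
            raw[k].append(metrics[k])
        partitions.append(labels)
        warns.extend(w)
    return GraphMetrics(
        densities=np.asarray(densities, dtype=float),
        raw={k: np.asarray(v) for k, v in raw.items()},
        partitions=partitions,
        warnings=warns,
    )


def phase_randomize(
    tf: TFDecomposition, rng: np.random.Generator
) -> TFDecomposition:
    """Add an independent uniform phase per channel x epoch to all
    coefficients, destroying cross-channel phase relations while preserving
    amplitude spectra."""
    theta = rng.uniform(0.0, 2 * np.pi, size=(tf.n_epochs, tf.n_channels))
    rot = np.exp(1j * theta).astype(np.complex64)
    return TFDecomposition(
        coeffs=tf.coeffs * rot[:, :, None, None],
        freqs=tf.freqs,
        times=tf.times,
        fs=tf.fs,
        window=tf.window,
        labels=list(tf.labels),
    )


def surrogate_normalize(
    tf: TFDecomposition,
    band: tuple[float, float],
    densities: np.ndarray = DEFAULT_DENSITIES,
    n_surrogates: int = 50,
    louvain_reps: int = 50,
    seed: int = 0,
    conn: ConnectivityResult | None = None,
) -> GraphMetrics:
    """Observed metrics normalized by phase-randomized surrogate nulls.

    For each surrogate the time-frequency coefficients are phase-randomized
    per channel and epoch, dwPLI recomputed, thresholded, and the metric
    sweep repeated; the normalized metric is observed / mean(surrogates),
    and small-worldness is formed from the normalized clustering and path
    length at each density.
    """
    if n_surrogates < 2:
        raise ValueError("need at least 2 surrogates")
    rng = np.random.default_rng(seed)
    if conn is None:
        conn = dwpli(tf)
    obs_mat, _ = band_connectivity(conn, band)
    observed = density_sweep(
        obs_mat, densities, louvain_reps=louvain_reps, seed=seed
    )

    surr = {k: np.zeros((n_surrogates, len(densities))) for k in METRIC_NAMES}
    for s in range(n_surrogates):
        tf_s = phase_randomize(tf, rng)
        conn_s = dwpli(tf_s)
        mat_s, _ = band_connectivity(conn_s, band)
        gm_s = density_sweep(
            mat_s, densities, louvain_reps=louvain_reps, seed=seed + 1000 + s
        )
        for k in METRIC_NAMES:
            surr[k][s] = gm_s.raw[k]

    surrogate_mean = {k: surr[k].mean(axis=0) for k in METRIC_NAMES}
    normalized = {}
    for k in METRIC_NAMES:
        with np.errstate(invalid="ignore", divide="ignore"):
            normalized[k] = np.where(
                surrogate_mean[k] != 0,
                observed.raw[k] / np.where(surrogate_mean[k] != 0, surrogate_mean[k], 1),
                np.nan,
            )
        if np.any(surrogate_mean[k] == 0):
            observed.warnings.append(
                f"{k}: zero surrogate mean at some density; normalized value missing"
            )
    sw = np.array(
        [
            small_worldness(c, l)
            for c, l in zip(normalized["clustering"], normalized["path_length"])
        ]
    )
    observed.surrogate_mean = surrogate_mean
    observed.normalized = normalized
    observed.small_worldness = sw
    return observed
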