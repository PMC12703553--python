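"""Network-level summaries compared between conditions.

Edge subsets follow the seven-network scheme: for each network N,
``within:N`` holds the edges among N's regions and ``between:N`` all edges
with exactly one endpoint in N, pooled over the other networks.  Every
undirected edge therefore lands in exactly one within subset or in exactly
two between subsets.

The primary dissimilarity is the cosine distance between two FC edge
vectors, d(a, b) = 1 - <a, b> / (||a|| ||b||): 0 for proportional patterns,
1 for orthogonal ones, 2 for antipodal ones, and invariant to positive
rescaling of either input.  Euclidean distance and Pearson similarity are
provided as robustness variants, as are weighted-graph modularity and global
efficiency of the FC graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .connectivity import FCMatrix
from .io_config import NETWORKS, ParcelTable

log = logging.getLogger("fcx")


@dataclass(frozen=True)
class EdgeSubset:
    """A named set of undirected edges, pairs (i, j) with i < j in fixed
    lexicographic order."""

    name: str
    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError(f"duplicate pairs in subset {self.name}")
        for i, j in self.pairs:
            if not i < j:
                raise ValueError(f"subset {self.name}: pairs must have i < j")
        object.__setattr__(self, "pairs", tuple(sorted(self.pairs)))

    def __len__(self) -> int:
        return len(self.pairs)


def whole_brain_subset(n_regions: int) -> EdgeSubset:
    pairs = tuple((i, j) for i in range(n_regions) for j in range(i + 1, n_regions))
    return EdgeSubset("whole-brain", pairs)


def network_subsets(parcels: ParcelTable) -> dict[str, EdgeSubset]:
    """The 7 within-network and 7 pooled between-network edge subsets.

    Networks with fewer than 2 member regions would make the within subset
    empty; the parcel table invariant (R >= 2 per network) is checked here
    for the networks actually present.
    """
    nets = parcels.networks
    out: dict[str, EdgeSubset] = {}
    for net in NETWORKS:
        members = set(np.flatnonzero(nets == net))
        if not members:
            continue
        within = tuple(
            (i, j) for i in sorted(members) for j in range(i + 1, parcels.n_regions)
            if j in members
        )
        between = tuple(
            (i, j)
            for i in range(parcels.n_regions)
            for j in range(i + 1, parcels.n_regions)
            if (i in members) != (j in members)
        )
        out[f"within:{net}"] = EdgeSubset(f"within:{net}", within)
        out[f"between:{net}"] = EdgeSubset(f"between:{net}", between)
    return out


def edge_vector(fc: FCMatrix, subset: EdgeSubset) -> np.ndarray:
    """The subset's edge values in fixed (i, j) lexicographic order.

    Missing edges are returned as NaN; the distance functions drop them
    pairwise-consistently across their two inputs.
    """
    if len(subset) == 0:
        raise ValueError(f"empty edge subset {subset.name}")
    idx = np.array(subset.pairs)
    if idx.max() >= fc.n_regions:
        raise ValueError(f"subset {subset.name} indexes beyond R={fc.n_regions}")
    return fc.values[idx[:, 0], idx[:, 1]]


def _pairwise_complete(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    if keep.sum() < a.size:
        log.info("pairwise-complete distance: %d/%d edges used", keep.sum(), a.size)
    return a[keep], b[keep]


def cosine_distance(a, b) -> float:
    """1 - cos(angle between a and b); zero-norm inputs are an error."""
    a, b = _pairwise_complete(a, b)
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine distance undefined for a zero-norm vector")
    return float(1.0 - np.dot(a, b) / (na * nb))


def distance_variants(a, b, which: str) -> float:
    """Robustness variants: ``euclidean`` = ||a - b||; ``pearson_similarity``
    = sample correlation of the two edge vectors."""
    a, b = _pairwise_complete(a, b)
    if which == "euclidean":
        return float(np.linalg.norm(a - b))
    if which == "pearson_similarity":
        if a.std() == 0.0 or b.std() == 0.0:
            raise ValueError("Pearson similarity undefined for a constant vector")
        return float(np.corrcoef(a, b)[0, 1])
    raise ValueError(f"unknown distance variant {which!r}")


def mean_network_fc(fc: FCMatrix, subset: EdgeSubset, absolute: bool = True) -> float:
    """Mean (absolute) Fisher-z connectivity over an edge subset."""
    v = edge_vector(fc, subset)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError(f"all edges missing in subset {subset.name}")
    return float(np.mean(np.abs(v)) if absolute else np.mean(v))


# ---------------------------------------------------------------------------
# Graph metrics
# ---------------------------------------------------------------------------


def fc_graph(fc: FCMatrix, mode: str = "absolute") -> nx.Graph:
    """Weighted graph from an FC matrix.

    ``absolute`` (default): weights are |z| normalized by the matrix maximum
    to [0, 1], so negative correlations enter by magnitude.  ``positive``
    keeps only positive edges, likewise normalized.  Missing edges are
    absent from the graph.
    """
    v = fc.values.copy()
    np.fill_diagonal(v, np.nan)
    if mode == "absolute":
        w = np.abs(v)
    elif mode == "positive":
        w = np.where(v > 0, v, np.nan)
    else:
        raise ValueError(f"unknown graph mode {mode!r}")
    finite = w[np.isfinite(w)]
    if finite.size and finite.max() > 0:
        w = w / finite.max()
    G = nx.Graph()
    G.add_nodes_from(range(fc.n_regions))
    ii, jj = np.triu_indices(fc.n_regions, k=1)
    for i, j in zip(ii, jj):
        if np.isfinite(w[i, j]) and w[i, j] > 0:
            G.add_edge(int(i), int(j), weight=float(w[i, j]))
    return G


def modularity(fc: FCMatrix, partition, mode: str = "absolute") -> float:
    """Newman weighted modularity Q of the given node partition.

    ``partition`` is either per-node community labels (length R) or an
    iterable of node sets.  Defaults to magnitude weights; the partition is
    typically the a priori 7-network assignment rather than a data-driven
    one.
    """
    G = fc_graph(fc, mode)
    if G.size(weight="weight") == 0:
        raise ValueError("modularity undefined for total weight 0")
    communities = _as_communities(partition, fc.n_regions)
    return float(nx.community.modularity(G, communities, weight="weight"))


def louvain_partition(fc: FCMatrix, mode: str = "absolute", seed: int = 0) -> list[set]:
    """Data-driven alternative partition (Louvain); not the default."""
    G = fc_graph(fc, mode)
    return [set(c) for c in nx.community.louvain_communities(G, weight="weight", seed=seed)]


def _as_communities(partition, n: int) -> list[set]:
    if isinstance(partition, (list, tuple)) and partition and isinstance(partition[0], (set, frozenset)):
        return [set(c) for c in partition]
    labels = np.asarray(partition)
    if labels.shape != (n,):
        raise ValueError("partition must be per-node labels or a list of sets")
    return [set(np.flatnonzero(labels == lab)) for lab in _stable_unique(labels)]


def _stable_unique(x: np.ndarray) -> np.ndarray:
    _, idx = np.unique(x, return_index=True)
    return x[np.sort(idx)]


def global_efficiency(fc: FCMatrix, mode: str = "absolute") -> float:
    """Mean inverse shortest-path length over node pairs.

    Path lengths sum 1/weight over traversed edges; disconnected pairs
    contribute 0.  With weights normalized to [0, 1] the result lies in
    [0, 1] (1 for a complete unit-weight graph).
    """
    G = fc_graph(fc, mode)
    n = G.number_of_nodes()
    if n < 2:
        raise ValueError("global efficiency undefined for fewer than 2 nodes")
    for _u, _v, d in G.edges(data=True):
        d["distance"] = 1.0 / d["weight"]
    total = 0.0
    for _source, lengths in nx.all_pairs_dijkstra_path_length(G, weight="distance"):
        for target, dist in lengths.items():
            if target != _source and dist > 0:
                total += 1.0 / dist
    return float(total / (n * (n - 1)))


# ---------------------------------------------------------------------------
# Pairing dissimilarity
# ---------------------------------------------------------------------------


def pairing_dissimilarity(
    fc_a: FCMatrix,
    fc_b: FCMatrix,
    subsets: dict[str, EdgeSubset],
    statistic: str = "cosine_distance",
) -> dict[str, float]:
    """Dissimilarity between two FC matrices per edge subset.

    Supports both designs used downstream: comparing the two single tasks of
    a pairing (e.g. d(VM, AV) vs d(VV, AM)) and comparing conditions across
    task type (d(compatible, incompatible) within single and within dual),
    by passing the appropriate matrices.
    """
    if fc_a.n_regions != fc_b.n_regions:
        raise ValueError("FC matrices differ in size")
    out = {}
    for name, subset in subsets.items():
        a = edge_vector(fc_a, subset)
        b = edge_vector(fc_b, subset)
        usable = np.isfinite(a) & np.isfinite(b)
        if usable.sum() < 2:
            raise ValueError(f"subset {name}: fewer than 2 usable edges")
        if statistic == "cosine_distance":
            out[name] = cosine_distance(a, b)
        elif statistic in ("euclidean", "pearson_similarity"):
            out[name] = distance_variants(a, b, statistic)
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
    return out
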