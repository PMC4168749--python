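"""Network integration: per-network weights, composite network, display edges.

The composite network is a weighted sum of symmetric-normalized source
networks, ``W* = Σ_k α_k · W̄_k``.  Three weighting methods are provided:

``equal``
    every selected network gets ``1/m``;
``group``
    each evidence group (co-expression, physical interaction, ...) gets an
    equal share, split equally within the group, so a category with many
    redundant networks cannot swamp the rest;
``query-adaptive``
    non-negative least squares with an intercept and a small ridge penalty,
    regressing a co-membership target over gene pairs touching the query
    (+1 for query–query pairs, 0 for query–non-query pairs) on the
    normalized edge weights of each network.  Networks whose edges track the
    query's internal structure receive large weights; uninformative ones are
    driven to zero.  If every coefficient is clipped to zero the method falls
    back to equal weights with a warning.

Every nonzero composite entry carries provenance: which source networks
contributed, at what original (raw) weight, and under which α.  For display,
multi-edges are collapsed to at most one edge per evidence group whose weight
is the within-group sum of α-scaled normalized weights, annotated with every
contributing source network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import nnls

from .network import SparseNetwork, normalize_symmetric

DEFAULT_RIDGE = 1e-3


@dataclass
class NetworkWeights:
    """Per-network combination coefficients α_k (non-negative, not all zero)."""

    weights: dict[str, float]
    method: str  # "equal" | "group" | "query-adaptive"

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError("weights must cover at least one network")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")
        if all(w == 0 for w in self.weights.values()):
            raise ValueError("at least one weight must be positive")


@dataclass
class ProvenanceRecord:
    """One source network's contribution to one composite edge."""

    network: str
    group: str
    raw_weight: float  # weight as given in the source data
    normalized_weight: float  # after symmetric degree normalization
    alpha: float  # the network's combination coefficient
    publication: str = ""

    @property
    def contribution(self) -> float:
        return self.alpha * self.normalized_weight


@dataclass
class CompositeNetwork:
    """``W* = Σ_k α_k W̄_k`` plus per-pair provenance.

    ``provenance`` maps each undirected pair ``(i, j)`` with ``i < j`` to the
    list of contributing source networks.  Networks with α=0 contribute
    nothing and never appear in provenance.
    """

    adjacency: sp.csr_matrix
    provenance: dict[tuple[int, int], list[ProvenanceRecord]]
    weights: NetworkWeights

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    def entry(self, i: int, j: int) -> float:
        return float(self.adjacency[i, j])


@dataclass
class DisplayEdge:
    """The single edge shown for one gene pair within one evidence group."""

    gene_i: int
    gene_j: int
    group: str
    weight: float  # within-group sum of alpha-scaled normalized weights
    sources: list[tuple[str, float, str]]  # (network name, raw weight, publication)


def weight_equal(networks: Sequence[SparseNetwork]) -> NetworkWeights:
    """α_k = 1/m for all m networks."""
    if not networks:
        raise ValueError("no networks to weight")
    m = len(networks)
    return NetworkWeights({net.meta.name: 1.0 / m for net in networks}, "equal")


def weight_by_group(networks: Sequence[SparseNetwork]) -> NetworkWeights:
    """Each group receives 1/(number of groups), split equally within group."""
    if not networks:
        raise ValueError("no networks to weight")
    group_sizes: dict[str, int] = {}
    for net in networks:
        group_sizes[net.meta.group] = group_sizes.get(net.meta.group, 0) + 1
    n_groups = len(group_sizes)
    return NetworkWeights(
        {
            net.meta.name: 1.0 / (n_groups * group_sizes[net.meta.group])
            for net in networks
        },
        "group",
    )


def _query_pair_design(
    normalized: Sequence[sp.csr_matrix], query_indices: Sequence[int], n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix over pairs touching the query, and the 0/1 target.

    Rows are unordered gene pairs: all query–query pairs (target +1) followed
    by all query–non-query pairs (target 0); columns are the normalized edge
    weights of each network at that pair.
    """
    q = np.asarray(sorted(set(int(i) for i in query_indices)), dtype=np.int64)
    others = np.setdiff1d(np.arange(n, dtype=np.int64), q, assume_unique=True)
    qi, qj = np.triu_indices(len(q), k=1)
    n_qq = qi.size
    n_cross = len(q) * len(others)
    t = np.concatenate([np.ones(n_qq), np.zeros(n_cross)])
    X = np.empty((n_qq + n_cross, len(normalized)))
    for k, w in enumerate(normalized):
        sub = np.asarray(w[q].todense())  # (|q|, n)
        X[:n_qq, k] = sub[qi, q[qj]]
        X[n_qq:, k] = sub[:, others].ravel()
    return X, t


def weight_query_adaptive(
    networks: Sequence[SparseNetwork],
    query_indices: Sequence[int],
    ridge: float = DEFAULT_RIDGE,
    normalized: Sequence[SparseNetwork] | None = None,
) -> NetworkWeights:
    """Query-adaptive network weights by ridge-regularized NNLS.

    Solves ``min_{β≥0, b} ||Xβ + b·1 − t||² + ridge·||β||²`` where rows of
    ``X`` are gene pairs with at least one query endpoint, the target ``t``
    is 1 for query–query pairs and 0 for query–non-query pairs, and the
    columns are normalized source-network edge weights.  Coefficients are
    rescaled to sum to 1.

    Parameters
    ----------
    networks
        Raw source networks; they are symmetric-normalized internally unless
        pre-normalized copies are supplied via ``normalized``.
    query_indices
        Universe indices of the query genes (at least 2).
    ridge
        Non-negative penalty on the network coefficients (not the intercept);
        stabilizes collinear networks.
    """
    if not networks:
        raise ValueError("no networks to weight")
    if len(set(int(i) for i in query_indices)) < 2:
        raise ValueError(
            "query-adaptive weighting needs at least 2 query genes; "
            "use weight_equal for single-gene queries"
        )
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    if normalized is None:
        normalized = [normalize_symmetric(net) for net in networks]
    n = networks[0].n
    X, t = _query_pair_design([nn.adjacency for nn in normalized], query_indices, n)
    m = len(networks)
    # intercept is unconstrained: represent it as the difference of two
    # non-negative columns so plain NNLS can solve the whole system
    ones = np.ones((X.shape[0], 1))
    A = np.hstack([X, ones, -ones])
    b = t
    if ridge > 0:
        pen = np.zeros((m, m + 2))
        pen[:, :m] = np.sqrt(ridge) * np.eye(m)
        A = np.vstack([A, pen])
        b = np.concatenate([t, np.zeros(m)])
    sol, _ = nnls(A, b)
    coeffs = sol[:m]
    total = coeffs.sum()
    if total <= 1e-12:
        warnings.warn(
            "all query-adaptive network weights are zero; "
            "falling back to equal weights",
            stacklevel=2,
        )
        return weight_equal(networks)
    coeffs = coeffs / total
    return NetworkWeights(
        {net.meta.name: float(c) for net, c in zip(networks, coeffs)},
        "query-adaptive",
    )


def combine(
    networks: Sequence[SparseNetwork],
    weights: NetworkWeights,
    normalized: Sequence[SparseNetwork] | None = None,
) -> CompositeNetwork:
    """Build the composite ``W* = Σ_k α_k W̄_k`` with per-pair provenance.

    ``networks`` are the raw source networks; each is symmetric-normalized
    before scaling so that the composite keeps a spectral radius bounded by
    Σα (the provenance still records the original raw edge weight alongside
    the normalized one).  Networks with α_k = 0 contribute no edges and no
    provenance records.

    Raises
    ------
    ValueError
        If a network is missing from ``weights`` or dimensions disagree.
    """
    if not networks:
        raise ValueError("no networks to combine")
    n = networks[0].n
    for net in networks:
        if net.n != n:
            raise ValueError(
                f"dimension mismatch: {net.meta.name!r} has {net.n} genes, expected {n}"
            )
        if net.meta.name not in weights.weights:
            raise ValueError(f"no weight for network {net.meta.name!r}")
    if normalized is None:
        normalized = [normalize_symmetric(net) for net in networks]
    total = sp.csr_matrix((n, n))
    provenance: dict[tuple[int, int], list[ProvenanceRecord]] = {}
    for net, norm in zip(networks, normalized):
        alpha = weights.weights[net.meta.name]
        if alpha == 0:
            continue
        total = total + alpha * norm.adjacency
        raw_upper = sp.triu(net.adjacency, k=1).tocoo()
        norm_upper = sp.triu(norm.adjacency, k=1).tocoo()
        # normalization preserves the sparsity pattern, so the two upper
        # triangles align entry for entry once both are sorted
        raw_map = {
            (int(i), int(j)): float(v)
            for i, j, v in zip(raw_upper.row, raw_upper.col, raw_upper.data)
        }
        for i, j, v in zip(norm_upper.row, norm_upper.col, norm_upper.data):
            key = (int(i), int(j))
            provenance.setdefault(key, []).append(
                ProvenanceRecord(
                    network=net.meta.name,
                    group=net.meta.group,
                    raw_weight=raw_map[key],
                    normalized_weight=float(v),
                    alpha=float(alpha),
                    publication=net.meta.publication,
                )
            )
    return CompositeNetwork(adjacency=total.tocsr(), provenance=provenance, weights=weights)


def collapse_for_display(
    composite: CompositeNetwork, gene_subset: Iterable[int]
) -> list[DisplayEdge]:
    """Collapse multi-edges to at most one display edge per (pair, group).

    Only pairs with both endpoints inside ``gene_subset`` are emitted.  Each
    display edge's weight is the within-group sum of α-scaled normalized
    weights, and its sources list every contributing network with its raw
    weight and publication text.  Summed over groups, the display weights of
    a pair reconstruct the composite adjacency entry exactly.
    """
    subset = set(int(g) for g in gene_subset)
    edges: list[DisplayEdge] = []
    for (i, j) in sorted(composite.provenance):
        if i not in subset or j not in subset:
            continue
        by_group: dict[str, list[ProvenanceRecord]] = {}
        for rec in composite.provenance[(i, j)]:
            by_group.setdefault(rec.group, []).append(rec)
        for group in sorted(by_group):
            recs = by_group[group]
            edges.append(
                DisplayEdge(
                    gene_i=i,
                    gene_j=j,
                    group=group,
                    weight=float(sum(r.contribution for r in recs)),
                    sources=[(r.network, r.raw_weight, r.publication) for r in recs],
                )
            )
    return edges
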