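"""End-to-end query pipeline: resolve → filter → weight → combine → propagate → rank.

This is the layer both the command-line interface and library users call to
reproduce the interactive workflow: given a gene list and a network database,
produce the ranked related genes, ranked attributes, display edges with
provenance, and (optionally) a functional enrichment table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .database import NetworkDatabase, filter_database
from .evaluation import AnnotationSet, hypergeom_enrich
from .integration import (
    CompositeNetwork,
    DisplayEdge,
    NetworkWeights,
    collapse_for_display,
    combine,
    weight_by_group,
    weight_equal,
    weight_query_adaptive,
)
from .identifiers import resolve_gene_list
from .network import normalize_symmetric
from .propagation import (
    DEFAULT_LAMBDA,
    ScoreVector,
    build_labels,
    propagate,
    rank_related,
    score_attributes,
)

DEFAULT_RELATED = 20
DEFAULT_ATTRIBUTES = 20


@dataclass
class QueryResult:
    """Everything one query produces."""

    query_indices: list[int]
    unresolved: list[str]
    related: list[tuple[int, float]]  # (universe index, score), best first
    attributes: list[tuple[str, float]]
    display_edges: list[DisplayEdge]
    weights: NetworkWeights
    scores: ScoreVector
    composite: CompositeNetwork
    enrichment: pd.DataFrame | None = None
    result_gene_set: list[int] = field(default_factory=list)

    @property
    def related_indices(self) -> list[int]:
        return [i for i, _ in self.related]


def run_query(
    db: NetworkDatabase,
    query_names: list[str],
    *,
    weighting: str = "adaptive",
    lam: float = DEFAULT_LAMBDA,
    n_related: int = DEFAULT_RELATED,
    n_attributes: int = DEFAULT_ATTRIBUTES,
    ridge: float = 1e-3,
    core_only: bool = False,
    open_license_only: bool = False,
    annotation_sets: list[AnnotationSet] | None = None,
) -> QueryResult:
    """Run the full prediction pipeline for one gene list.

    Parameters
    ----------
    db
        Loaded network database.
    query_names
        Gene names/synonyms; unresolved names are reported, not fatal
        (unless none resolve).
    weighting
        ``equal``, ``group``, or ``adaptive``.  Adaptive falls back to equal
        for single-gene queries, which carry no co-membership signal.
    lam
        Propagation smoothing strength λ.
    n_related, n_attributes
        How many related genes / attributes to return (0 allowed: connect the
        query genes only, without extending the list).
    annotation_sets
        Optional functional terms; when given, the result genes (query +
        related) are tested for hypergeometric enrichment.
    """
    if core_only or open_license_only:
        db = filter_database(db, core_only=core_only, open_license_only=open_license_only)
    query, unresolved = resolve_gene_list(query_names, db.universe)
    normalized = [normalize_symmetric(net) for net in db.networks]
    if weighting == "equal":
        weights = weight_equal(db.networks)
    elif weighting == "group":
        weights = weight_by_group(db.networks)
    elif weighting in ("adaptive", "query-adaptive"):
        if len(query) < 2:
            weights = weight_equal(db.networks)
        else:
            weights = weight_query_adaptive(db.networks, query, ridge=ridge, normalized=normalized)
    else:
        raise ValueError(f"unknown weighting method {weighting!r}")
    composite = combine(db.networks, weights, normalized=normalized)
    labels = build_labels(query, len(db.universe))
    scores = propagate(composite, labels, lam=lam)
    related = rank_related(scores, query, n_related)
    result_genes = sorted(set(query) | {i for i, _ in related})
    attrs = score_attributes(
        db.attributes, scores, result_genes, n_attributes, db.attribute_names
    )
    edges = collapse_for_display(composite, result_genes)
    enrichment = None
    if annotation_sets:
        enrichment = hypergeom_enrich(result_genes, annotation_sets, len(db.universe))
    return QueryResult(
        query_indices=query,
        unresolved=unresolved,
        related=related,
        attributes=attrs,
        display_edges=edges,
        weights=weights,
        scores=scores,
        composite=composite,
        enrichment=enrichment,
        result_gene_set=result_genes,
    )
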