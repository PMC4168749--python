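"""Benchmarking and annotation: cross-validated function prediction, enrichment.

Guilt-by-association evaluation: hold out part of a functional term's member
genes, query with the rest, and measure how highly the held-out members rank
among all genes outside the term (AUROC with midrank tie handling, and
precision at k where k is the number held out).  Held-out genes are removed
from the query but stay in the network — the transductive setting label
propagation operates in.

Enrichment of a result gene set against annotation sets uses the one-sided
hypergeometric upper tail with Benjamini–Hochberg FDR across tested terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, rankdata
from statsmodels.stats.multitest import multipletests

from .database import NetworkDatabase
from .errors import DatabaseError
from .identifiers import GeneUniverse, NOT_FOUND
from .integration import combine, weight_by_group, weight_equal, weight_query_adaptive
from .network import normalize_symmetric
from .propagation import build_labels, propagate, DEFAULT_LAMBDA


@dataclass(frozen=True)
class AnnotationSet:
    """A functional term (e.g. a Gene Ontology term) and its member genes."""

    term: str
    members: frozenset[int]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"annotation set {self.term!r} has no members")


@dataclass
class CVReport:
    """Per-fold cross-validation metrics for one term."""

    term: str
    folds: int
    seed: int
    weighting: str
    auroc: list[float] = field(default_factory=list)
    precision_at_k: list[float] = field(default_factory=list)

    @property
    def auroc_mean(self) -> float:
        return float(np.mean(self.auroc))

    @property
    def auroc_std(self) -> float:
        return float(np.std(self.auroc))

    @property
    def precision_mean(self) -> float:
        return float(np.mean(self.precision_at_k))


def auroc_rank(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """AUROC by the Mann–Whitney rank statistic; ties contribute 1/2."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one negative score")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))


def _weights_for(db: NetworkDatabase, method: str, query, normalized):
    if method == "equal":
        return weight_equal(db.networks)
    if method == "group":
        return weight_by_group(db.networks)
    if method in ("adaptive", "query-adaptive"):
        if len(set(query)) < 2:
            return weight_equal(db.networks)
        return weight_query_adaptive(db.networks, query, normalized=normalized)
    raise ValueError(f"unknown weighting method {method!r}")


def kfold_crossval(
    db: NetworkDatabase,
    term: AnnotationSet,
    folds: int = 5,
    weighting: str = "adaptive",
    seed: int = 0,
    lam: float = DEFAULT_LAMBDA,
) -> CVReport:
    """k-fold cross-validation of function prediction for one term.

    The term's member genes are shuffled (seeded) and split into ``folds``
    parts.  For each fold the retained members form the query; every gene is
    scored by propagation; the held-out members are then ranked against all
    genes outside the term.  Reports AUROC and precision@k (k = held-out
    count) per fold.

    Raises
    ------
    ValueError
        If the term has fewer members than folds, or ``folds < 2``.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    members = np.array(sorted(term.members), dtype=np.int64)
    if members.size < folds:
        raise ValueError(
            f"term {term.term!r} has {members.size} members, fewer than {folds} folds"
        )
    if not db.networks:
        raise DatabaseError("database has no networks")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(members)
    fold_parts = np.array_split(perm, folds)
    n = len(db.universe)
    normalized = [normalize_symmetric(net) for net in db.networks]
    non_members = np.setdiff1d(np.arange(n), members, assume_unique=False)
    report = CVReport(term=term.term, folds=folds, seed=seed, weighting=weighting)
    for held_out in fold_parts:
        query = np.setdiff1d(members, held_out, assume_unique=False)
        weights = _weights_for(db, weighting, query, normalized)
        composite = combine(db.networks, weights, normalized=normalized)
        labels = build_labels(query, n)
        scores = propagate(composite, labels, lam=lam)
        pos = scores.f[held_out]
        neg = scores.f[non_members]
        report.auroc.append(auroc_rank(pos, neg))
        # precision@k over the evaluation set (held-out positives vs non-members)
        k = held_out.size
        eval_idx = np.concatenate([held_out, non_members])
        eval_scores = scores.f[eval_idx]
        order = np.lexsort((eval_idx, -eval_scores))
        topk = set(eval_idx[order[:k]].tolist())
        report.precision_at_k.append(len(topk & set(held_out.tolist())) / k)
    return report


def hypergeom_enrich(
    result_genes,
    annotation_sets: list[AnnotationSet],
    universe_size: int,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each term in a result gene set.

    For a term with K members in a universe of M genes and a result set of
    N genes overlapping it in x, the p-value is the one-sided upper tail
    ``P[X >= x]`` with ``X ~ Hypergeom(M, K, N)``.  q-values are
    Benjamini–Hochberg across the tested terms.

    Returns a DataFrame (term, overlap, term_size, p, q) sorted by p
    ascending (ties by term name).
    """
    genes = set(int(g) for g in result_genes)
    if not genes:
        raise ValueError("result gene set is empty")
    rows = []
    for aset in annotation_sets:
        overlap = len(genes & aset.members)
        p = float(hypergeom.sf(overlap - 1, universe_size, len(aset.members), len(genes)))
        rows.append((aset.term, overlap, len(aset.members), min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p"])
    if len(df):
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    else:
        df["q"] = []
    return df.sort_values(["p", "term"], kind="stable").reset_index(drop=True)


def read_annotations(path: str | Path, universe: GeneUniverse) -> list[AnnotationSet]:
    """Read annotation sets from long-format TSV (``term<TAB>gene``) or GMT.

    GMT rows are ``term<TAB>description<TAB>gene1<TAB>gene2...`` and are
    detected by the ``.gmt`` extension.  Unresolvable genes are dropped;
    terms left empty are omitted.
    """
    path = Path(path)
    members: dict[str, set[int]] = {}
    order: list[str] = []
    gmt = path.suffix.lower() == ".gmt"
    for line in path.read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if gmt:
            term, genes = cols[0], cols[2:]
        else:
            term, genes = cols[0], cols[1:2]
        for g in genes:
            idx = universe.resolve(g.strip())
            if idx == NOT_FOUND:
                continue
            if term not in members:
                members[term] = set()
                order.append(term)
            members[term].add(idx)
    return [AnnotationSet(t, frozenset(members[t])) for t in order if members.get(t)]


def write_annotations(sets: list[AnnotationSet], universe: GeneUniverse, path: str | Path) -> None:
    """Write annotation sets in long-format TSV using primary gene IDs."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for aset in sets:
            for idx in sorted(aset.members):
                fh.write(f"{aset.term}\t{universe.primary_ids[idx]}\n")
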