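"""Build sparse co-expression networks from expression profiles.

Edges are Pearson correlations between gene expression rows.  Only positive
correlations are kept (negative co-expression is a different kind of evidence
and would violate the non-negative adjacency contract), each gene retains its
``k`` strongest partners, and a pair survives if *either* endpoint selects it
(union symmetrization).  The default ``k=50`` keeps genome-scale networks
sparse while preserving module structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ProfileError
from .identifiers import GeneUniverse, NOT_FOUND
from .network import NetworkMeta, SparseNetwork

DEFAULT_TOP_K = 50


@dataclass
class ExpressionProfile:
    """Genes-by-samples expression matrix aligned to a universe.

    ``gene_indices[i]`` is the universe index of row ``i`` of ``values``.
    """

    gene_indices: np.ndarray  # (g,) universe indices, unique
    values: np.ndarray  # (g, s) float
    sample_names: list[str]

    def __post_init__(self) -> None:
        self.gene_indices = np.asarray(self.gene_indices, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] < 2:
            raise ProfileError("expression profile needs at least 2 samples")
        if len(np.unique(self.gene_indices)) != len(self.gene_indices):
            raise ProfileError("gene indices must be unique")
        if self.values.shape[0] != len(self.gene_indices):
            raise ProfileError("values/gene_indices length mismatch")


@dataclass
class ProfileReport:
    n_genes: int = 0
    skipped_unresolved: list[str] = field(default_factory=list)
    n_duplicates_averaged: int = 0


def read_profile(
    path: str | Path, universe: GeneUniverse
) -> tuple[ExpressionProfile, ProfileReport]:
    """Read a tab-delimited expression profile.

    Format: header row of sample names, column 1 the gene name, remaining
    columns numeric.  Genes that do not resolve against the universe are
    skipped (reported); duplicate rows for the same gene are averaged.
    Missing values are not supported.

    Raises
    ------
    ProfileError
        With fewer than 2 samples, or on a non-numeric/missing cell (the
        error names the row and column).
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", header=0, dtype=str, index_col=0)
    if raw.shape[1] < 2:
        raise ProfileError(f"{path}: profiles need at least 2 samples")
    sample_names = [str(c) for c in raw.columns]
    report = ProfileReport()
    sums: dict[int, np.ndarray] = {}
    counts: dict[int, int] = {}
    order: list[int] = []
    for rowno, (gene, row) in enumerate(raw.iterrows(), start=2):
        idx = universe.resolve(str(gene))
        if idx == NOT_FOUND:
            if str(gene) not in report.skipped_unresolved:
                report.skipped_unresolved.append(str(gene))
            continue
        try:
            vals = row.astype(float).to_numpy()
        except (TypeError, ValueError):
            bad = next(
                c for c, v in row.items() if _not_numeric(v)
            )
            raise ProfileError(
                f"{path}: non-numeric value in row {rowno} (gene {gene!r}), "
                f"sample {bad!r}"
            ) from None
        if np.isnan(vals).any():
            bad = sample_names[int(np.isnan(vals).argmax())]
            raise ProfileError(
                f"{path}: missing value in row {rowno} (gene {gene!r}), sample {bad!r}"
            )
        if idx in sums:
            sums[idx] += vals
            counts[idx] += 1
            report.n_duplicates_averaged += 1
        else:
            sums[idx] = vals.copy()
            counts[idx] = 1
            order.append(idx)
    if not order:
        raise ProfileError(f"{path}: no gene rows resolved against the universe")
    values = np.vstack([sums[i] / counts[i] for i in order])
    report.n_genes = len(order)
    profile = ExpressionProfile(np.array(order), values, sample_names)
    return profile, report


def _not_numeric(v: object) -> bool:
    try:
        float(v)  # type: ignore[arg-type]
        return False
    except (TypeError, ValueError):
        return True


def profile_to_network(
    profile: ExpressionProfile,
    universe: GeneUniverse,
    k: int = DEFAULT_TOP_K,
    meta: NetworkMeta | None = None,
) -> SparseNetwork:
    """Convert an expression profile into a sparse co-expression network.

    Pairwise Pearson correlation between gene rows; zero-variance genes get
    no edges; correlations <= 0 are dropped; each gene keeps its ``k``
    largest-correlation partners and a pair is kept if either endpoint
    selects it.  Edge weight is the correlation itself, so all weights lie
    in (0, 1].

    Raises
    ------
    ProfileError
        If fewer than 2 genes have non-zero variance, or ``k < 1``.
    """
    if k < 1:
        raise ProfileError("k must be >= 1")
    if meta is None:
        meta = NetworkMeta(name="co-expression", group="co-expression")
    variable = profile.values.std(axis=1) > 0
    usable = np.flatnonzero(variable)
    if usable.size < 2:
        raise ProfileError("fewer than 2 genes with non-zero variance")
    vals = profile.values[usable]
    corr = np.corrcoef(vals)
    np.fill_diagonal(corr, 0.0)
    corr[corr <= 0] = 0.0
    corr = np.nan_to_num(corr, nan=0.0)
    np.clip(corr, 0.0, 1.0, out=corr)  # guard float round-off above 1
    g = corr.shape[0]
    keep = np.zeros_like(corr, dtype=bool)
    kk = min(k, g - 1)
    # top-k per row, deterministic tie-break by column index (stable argsort
    # of (-corr, col) via mergesort on negated values)
    part = np.argsort(-corr, axis=1, kind="stable")[:, :kk]
    rows = np.repeat(np.arange(g), kk)
    keep[rows, part.ravel()] = True
    keep &= corr > 0  # never keep zero entries pulled in by argsort
    keep |= keep.T  # union symmetrization
    iu, ju = np.nonzero(np.triu(keep, k=1))
    gi = profile.gene_indices[usable]
    n = len(universe)
    upper = sp.coo_matrix((corr[iu, ju], (gi[iu], gi[ju])), shape=(n, n)).tocsr()
    net = SparseNetwork(upper + upper.T, meta)
    net.validate()
    return net
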