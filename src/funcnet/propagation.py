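"""Label propagation: score genome-wide relevance to a query gene list.

Query genes carry label 1, every other gene label 0, and the labels are
smoothed over the composite network by solving the Gaussian-field system

    (I + λ·L̄) f = y,        L̄ = D̄ − W*,

where ``W*`` is the composite adjacency, ``D̄`` its diagonal of row sums and
λ > 0 the smoothing strength.  The system is symmetric positive definite, so
it is solved by conjugate gradients; with a 0/1 right-hand side the maximum
principle guarantees 0 ≤ f_i ≤ 1.  At λ=0 the scores reduce to the labels
themselves, and isolated genes always keep their label exactly.  The score
``f_i`` is saved per gene ("score attribute in the node table") and measures
how strongly gene *i* is connected to the query through the selected
evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import cg

from .errors import ConvergenceError, QueryError
from .integration import CompositeNetwork

DEFAULT_LAMBDA = 1.0
DEFAULT_TOL = 1e-10


@dataclass
class LabelVector:
    """0/1 labels: 1 on the query genes, 0 elsewhere."""

    y: np.ndarray
    query_indices: frozenset[int]


@dataclass
class ScoreVector:
    """Propagation solution with solver diagnostics."""

    f: np.ndarray
    lam: float
    iterations: int
    residual: float  # ||(I+λL)f − y||₂ / ||y||₂


def build_labels(query_indices, n: int) -> LabelVector:
    """Label vector of length ``n``: exactly the query entries are 1."""
    qs = frozenset(int(i) for i in query_indices)
    if not qs:
        raise QueryError("empty query")
    if any(i < 0 or i >= n for i in qs):
        raise QueryError("query index out of range")
    y = np.zeros(n)
    y[list(qs)] = 1.0
    return LabelVector(y=y, query_indices=qs)


def propagate(
    composite: CompositeNetwork | sp.spmatrix,
    y: np.ndarray | LabelVector,
    lam: float = DEFAULT_LAMBDA,
    tol: float = DEFAULT_TOL,
    max_iter: int | None = None,
) -> ScoreVector:
    """Solve ``(I + λ(D̄ − W*)) f = y`` by conjugate gradients.

    Parameters
    ----------
    composite
        The composite network (or a bare symmetric sparse adjacency).
    y
        Label vector (1 on query genes, 0 elsewhere).
    lam
        Smoothing strength λ ≥ 0; 0 returns the labels unchanged.
    tol
        Relative residual target ``||Af − y|| ≤ tol·||y||``.
    max_iter
        Iteration budget, default ``10·n``.

    Raises
    ------
    ConvergenceError
        If the residual target is not met within ``max_iter`` iterations.
    """
    w = composite.adjacency if isinstance(composite, CompositeNetwork) else sp.csr_matrix(composite)
    if isinstance(y, LabelVector):
        y = y.y
    y = np.asarray(y, dtype=np.float64)
    n = w.shape[0]
    if y.shape != (n,):
        raise ValueError(f"label vector has shape {y.shape}, expected ({n},)")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if lam == 0:
        return ScoreVector(f=y.copy(), lam=0.0, iterations=0, residual=0.0)
    deg = np.asarray(w.sum(axis=1)).ravel()
    A = sp.eye(n, format="csr") + lam * (sp.diags(deg) - w)
    if max_iter is None:
        max_iter = 10 * n
    n_iter = 0

    def _count(_):
        nonlocal n_iter
        n_iter += 1

    f, info = cg(A, y, rtol=tol, atol=0.0, maxiter=max_iter, callback=_count)
    ynorm = float(np.linalg.norm(y))
    residual = float(np.linalg.norm(A @ f - y)) / ynorm if ynorm else 0.0
    if info != 0 or residual > tol * 10:
        raise ConvergenceError(
            f"propagation did not converge in {max_iter} iterations "
            f"(relative residual {residual:.3e}, target {tol:.1e})"
        )
    # genes with no edges satisfy f_i = y_i exactly; enforce against round-off
    isolated = deg == 0
    f[isolated] = y[isolated]
    return ScoreVector(f=f, lam=float(lam), iterations=n_iter, residual=residual)


def rank_related(
    scores: ScoreVector | np.ndarray, query_indices, n_top: int
) -> list[tuple[int, float]]:
    """Rank non-query genes with positive score, best first.

    Ties are broken by ascending universe index so output is deterministic.
    ``n_top`` may be 0 (visualize the query alone) or exceed the number of
    scored genes (return all).
    """
    if n_top < 0:
        raise ValueError("n_top must be >= 0")
    f = scores.f if isinstance(scores, ScoreVector) else np.asarray(scores)
    qs = set(int(i) for i in query_indices)
    candidates = [(i, float(f[i])) for i in range(len(f)) if i not in qs and f[i] > 0]
    candidates.sort(key=lambda t: (-t[1], t[0]))
    return candidates[:n_top]


def score_attributes(
    attribute_incidence: sp.spmatrix,
    scores: ScoreVector | np.ndarray,
    result_gene_set,
    n_top: int,
    attribute_names: list[str],
) -> list[tuple[str, float]]:
    """Rank attributes (e.g. protein domains) attached to the result genes.

    An attribute's score is the sum of propagation scores of the result genes
    that carry it, so attributes shared by many high-scoring genes rise to the
    top.  Attributes with zero score are excluded; ties break by name.
    """
    if n_top < 0:
        raise ValueError("n_top must be >= 0")
    f = scores.f if isinstance(scores, ScoreVector) else np.asarray(scores)
    genes = sorted(set(int(g) for g in result_gene_set))
    if not genes or attribute_incidence.shape[1] == 0:
        return []
    inc = sp.csr_matrix(attribute_incidence)[genes]
    vals = np.asarray(inc.T @ f[genes]).ravel()
    ranked = [
        (attribute_names[a], float(v)) for a, v in enumerate(vals) if v > 0
    ]
    ranked.sort(key=lambda t: (-t[1], t[0]))
    return ranked[:n_top]
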