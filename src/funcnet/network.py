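"""Sparse symmetric networks: parsing, validation, normalization, binary IO.

A source network is an undirected weighted graph over the gene universe,
stored as a symmetric non-negative scipy CSR matrix with a zero diagonal.
Networks are persisted in a compact self-describing binary format (magic
``GMNW``) holding only the upper triangle in CSR layout, so the on-disk size
is half the in-memory symmetric matrix and round trips are bit-exact.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .errors import BinaryFormatError, EdgeListError
from .identifiers import GeneUniverse, NOT_FOUND

_MAGIC = b"GMNW"
_VERSION = 1
_SYMMETRY_TOL = 1e-12


@dataclass
class NetworkMeta:
    """Descriptive metadata attached to one source network."""

    name: str
    group: str
    source_description: str = ""
    publication: str = ""
    open_license: bool = True
    default_selected: bool = True

    def __post_init__(self) -> None:
        if not self.group:
            raise ValueError("network group must be non-empty")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkMeta":
        return cls(**d)


@dataclass
class ImportReport:
    """Per-import accounting: what was kept, skipped, merged."""

    n_edges: int = 0
    n_lines: int = 0
    n_unresolved_lines: int = 0
    unresolved_names: list[str] = field(default_factory=list)
    n_self_edges_dropped: int = 0
    n_duplicate_pairs_merged: int = 0


class SparseNetwork:
    """Symmetric non-negative weighted adjacency over a gene universe.

    Invariants (checked by :meth:`validate`): symmetry within 1e-12, zero
    diagonal, strictly positive stored weights, dimension equal to the
    universe size.
    """

    def __init__(self, adjacency: sp.spmatrix, meta: NetworkMeta):
        self.adjacency = sp.csr_matrix(adjacency)
        self.adjacency.eliminate_zeros()
        self.meta = meta

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def nnz_pairs(self) -> int:
        """Number of undirected edges (upper-triangle nonzeros)."""
        return sp.triu(self.adjacency, k=1).nnz

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    def validate(self) -> None:
        a = self.adjacency
        if a.shape[0] != a.shape[1]:
            raise ValueError(f"adjacency not square: {a.shape}")
        if a.nnz:
            if a.data.min() <= 0:
                raise ValueError("stored weights must be > 0")
            asym = abs(a - a.T)
            if asym.nnz and asym.data.max() > _SYMMETRY_TOL:
                raise ValueError("adjacency not symmetric within tolerance")
            if np.abs(a.diagonal()).max() > 0:
                raise ValueError("diagonal must be zero")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SparseNetwork):
            return NotImplemented
        return (
            self.meta == other.meta
            and self.adjacency.shape == other.adjacency.shape
            and (self.adjacency != other.adjacency).nnz == 0
        )


def read_edge_list(
    path: str | Path, universe: GeneUniverse, meta: NetworkMeta
) -> tuple[SparseNetwork, ImportReport]:
    """Parse a tab-delimited edge list into a symmetric network.

    Rows are ``geneA<TAB>geneB[<TAB>weight]``; a missing weight defaults to
    1.0.  Duplicate pairs are summed, self-edges dropped, and lines naming
    unresolvable genes skipped — all counted in the returned report.  Blank
    lines and ``#`` comments are ignored.

    Raises
    ------
    EdgeListError
        On a negative or non-numeric weight (with line number), or when no
        resolvable edge remains.
    """
    path = Path(path)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    report = ImportReport()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise EdgeListError(f"{path}:{lineno}: expected at least 2 columns")
            report.n_lines += 1
            a, b = parts[0].strip(), parts[1].strip()
            if len(parts) >= 3 and parts[2].strip():
                try:
                    w = float(parts[2])
                except ValueError:
                    raise EdgeListError(
                        f"{path}:{lineno}: non-numeric weight {parts[2]!r}"
                    ) from None
                if not np.isfinite(w):
                    raise EdgeListError(f"{path}:{lineno}: non-finite weight {w!r}")
            else:
                w = 1.0
            if w < 0:
                raise EdgeListError(f"{path}:{lineno}: negative weight {w}")
            ia, ib = universe.resolve(a), universe.resolve(b)
            if ia == NOT_FOUND or ib == NOT_FOUND:
                report.n_unresolved_lines += 1
                for name, idx in ((a, ia), (b, ib)):
                    if idx == NOT_FOUND and name not in report.unresolved_names:
                        report.unresolved_names.append(name)
                continue
            if ia == ib:
                report.n_self_edges_dropped += 1
                continue
            if w == 0:
                continue
            lo, hi = (ia, ib) if ia < ib else (ib, ia)
            rows.append(lo)
            cols.append(hi)
            vals.append(w)
    if not rows:
        raise EdgeListError(f"{path}: no resolvable edges")
    n = len(universe)
    upper = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()  # dups summed
    report.n_duplicate_pairs_merged = len(rows) - upper.nnz
    report.n_edges = upper.nnz
    net = SparseNetwork(upper + upper.T, meta)
    net.validate()
    return net, report


def network_from_edges(
    n: int,
    edges: "list[tuple[int, int, float]]",
    meta: NetworkMeta,
) -> SparseNetwork:
    """Build a network directly from (i, j, weight) triples (duplicates summed)."""
    if edges:
        i, j, w = zip(*((min(a, b), max(a, b), float(v)) for a, b, v in edges if a != b))
        upper = sp.coo_matrix((w, (i, j)), shape=(n, n)).tocsr()
    else:
        upper = sp.csr_matrix((n, n))
    net = SparseNetwork(upper + upper.T, meta)
    net.validate()
    return net


def normalize_symmetric(net: SparseNetwork) -> SparseNetwork:
    """Symmetric degree normalization: ``W̄ = D^(-1/2) W D^(-1/2)``.

    ``D`` is the diagonal of row sums (weighted degrees).  Rows and columns of
    isolated genes stay zero; the output is symmetric and its spectral radius
    is at most 1, which keeps downstream label propagation well conditioned
    and stops dense high-weight networks from dominating the composite.
    """
    d = net.degrees()
    with np.errstate(divide="ignore"):
        dinv = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    dhalf = sp.diags(dinv)
    w = (dhalf @ net.adjacency @ dhalf).tocsr()
    # enforce exact symmetry against float round-off
    w = (w + w.T) * 0.5
    return SparseNetwork(w, net.meta)


# ---------------------------------------------------------------------------
# Binary format ("GMNW", little-endian):
#   magic[4]  version:u32  n:u64  nnz:u64
#   indptr[(n+1) x i8]  indices[nnz x i8]  data[nnz x f8]   (upper triangle CSR)
#   meta_len:u64  meta_json[meta_len]
# ---------------------------------------------------------------------------

_HEADER = struct.Struct("<4sIQQ")


def write_binary(net: SparseNetwork, path: str | Path) -> None:
    """Serialize a network losslessly (8-byte float weights, upper triangle)."""
    upper = sp.triu(net.adjacency, k=1).tocsr()
    upper.sort_indices()
    meta_blob = json.dumps(net.meta.to_dict(), sort_keys=True).encode("utf-8")
    with Path(path).open("wb") as fh:
        fh.write(_HEADER.pack(_MAGIC, _VERSION, upper.shape[0], upper.nnz))
        fh.write(upper.indptr.astype("<i8").tobytes())
        fh.write(upper.indices.astype("<i8").tobytes())
        fh.write(upper.data.astype("<f8").tobytes())
        fh.write(struct.pack("<Q", len(meta_blob)))
        fh.write(meta_blob)


def read_binary(path: str | Path, universe: GeneUniverse | None = None) -> SparseNetwork:
    """Load a ``GMNW`` file, reconstructing the full symmetric adjacency.

    Raises
    ------
    BinaryFormatError
        On bad magic/version, truncation, or a dimension mismatch with the
        universe (when one is given).
    """
    buf = Path(path).read_bytes()
    if len(buf) < _HEADER.size:
        raise BinaryFormatError(f"{path}: truncated header")
    magic, version, n, nnz = _HEADER.unpack_from(buf, 0)
    if magic != _MAGIC:
        raise BinaryFormatError(f"{path}: bad magic {magic!r}")
    if version != _VERSION:
        raise BinaryFormatError(f"{path}: unsupported version {version}")
    if universe is not None and n != len(universe):
        raise BinaryFormatError(
            f"{path}: network has {n} genes but universe has {len(universe)}"
        )
    off = _HEADER.size
    need = (n + 1) * 8 + nnz * 8 + nnz * 8 + 8
    if len(buf) < off + need:
        raise BinaryFormatError(f"{path}: truncated body")
    indptr = np.frombuffer(buf, dtype="<i8", count=n + 1, offset=off)
    off += (n + 1) * 8
    indices = np.frombuffer(buf, dtype="<i8", count=nnz, offset=off)
    off += nnz * 8
    data = np.frombuffer(buf, dtype="<f8", count=nnz, offset=off)
    off += nnz * 8
    (meta_len,) = struct.unpack_from("<Q", buf, off)
    off += 8
    if len(buf) < off + meta_len:
        raise BinaryFormatError(f"{path}: truncated metadata")
    meta = NetworkMeta.from_dict(json.loads(buf[off : off + meta_len].decode("utf-8")))
    upper = sp.csr_matrix(
        (data.copy(), indices.astype(np.int64), indptr.astype(np.int64)), shape=(n, n)
    )
    net = SparseNetwork(upper + upper.T, meta)
    net.validate()
    return net


def random_network(
    n: int,
    density: float,
    rng: np.random.Generator,
    meta: NetworkMeta | None = None,
) -> SparseNetwork:
    """Erdős–Rényi-style random weighted network (testing/benchmark helper)."""
    if meta is None:
        meta = NetworkMeta(name=f"random-{n}", group="random")
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(iu.size) < density
    if not keep.any():  # guarantee at least one edge on tiny instances
        keep[rng.integers(iu.size)] = True
    w = rng.uniform(0.1, 1.0, size=int(keep.sum()))
    upper = sp.coo_matrix((w, (iu[keep], ju[keep])), shape=(n, n)).tocsr()
    return SparseNetwork(upper + upper.T, meta)
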