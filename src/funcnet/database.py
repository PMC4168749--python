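"""On-disk network database: manifest, universe, binary networks, attributes.

A database directory holds everything one organism needs for queries:

    genome.tsv        primary ID + synonyms, one gene per row
    manifest.tsv      one row per network: file, name, group, flags, provenance
    networks/*.gmnw   binary sparse matrices (see :mod:`funcnet.network`)
    attributes.tsv    optional gene<TAB>attribute incidence (e.g. protein domains)

Metadata lives in the manifest and is loaded into a plain in-memory index;
two subsets are expressible through per-network flags: the *core* subset
(``default_selected``) and the *open license* subset (``open_license``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .errors import DatabaseError
from .identifiers import GeneUniverse, read_genome_table, write_genome_table, NOT_FOUND
from .network import NetworkMeta, SparseNetwork, read_binary, write_binary

_MANIFEST_COLS = [
    "file",
    "name",
    "group",
    "default_selected",
    "open_license",
    "source_description",
    "publication",
]


@dataclass
class NetworkDatabase:
    """An organism's universe, source networks and attribute incidence."""

    universe: GeneUniverse
    networks: list[SparseNetwork] = field(default_factory=list)
    attributes: sp.csr_matrix | None = None  # genes x attributes, binary
    attribute_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.attributes is None:
            self.attributes = sp.csr_matrix((len(self.universe), 0))
        names = [net.meta.name for net in self.networks]
        if len(set(names)) != len(names):
            raise DatabaseError("network names must be unique within a database")
        if len(set(self.attribute_names)) != len(self.attribute_names):
            raise DatabaseError("attribute names must be unique")
        for net in self.networks:
            if net.n != len(self.universe):
                raise DatabaseError(
                    f"network {net.meta.name!r} has {net.n} genes, "
                    f"universe has {len(self.universe)}"
                )

    def get_network(self, name: str) -> SparseNetwork:
        for net in self.networks:
            if net.meta.name == name:
                return net
        raise KeyError(name)

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for net in self.networks:
            if net.meta.group not in seen:
                seen.append(net.meta.group)
        return seen


def filter_database(
    db: NetworkDatabase, core_only: bool = False, open_license_only: bool = False
) -> NetworkDatabase:
    """Restrict to the *core* and/or *open license* network subsets.

    The universe and attributes are unchanged; only the network list is
    filtered by its ``default_selected`` / ``open_license`` flags.

    Raises
    ------
    DatabaseError
        If no network satisfies the requested flags.
    """
    nets = [
        net
        for net in db.networks
        if (not core_only or net.meta.default_selected)
        and (not open_license_only or net.meta.open_license)
    ]
    if not nets:
        raise DatabaseError("no networks left after subset filtering")
    return NetworkDatabase(
        universe=db.universe,
        networks=nets,
        attributes=db.attributes,
        attribute_names=db.attribute_names,
    )


def _clean(text: str) -> str:
    """Make free text safe for one TSV cell."""
    return text.replace("\t", " ").replace("\n", " ").replace("\r", " ")


def save_database(db: NetworkDatabase, db_dir: str | Path) -> None:
    """Write a database directory (genome, manifest, binary networks, attributes)."""
    db_dir = Path(db_dir)
    (db_dir / "networks").mkdir(parents=True, exist_ok=True)
    write_genome_table(db.universe, db_dir / "genome.tsv")
    with (db_dir / "manifest.tsv").open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_MANIFEST_COLS) + "\n")
        for k, net in enumerate(db.networks):
            fname = f"networks/net{k:04d}.gmnw"
            write_binary(net, db_dir / fname)
            m = net.meta
            fh.write(
                "\t".join(
                    [
                        fname,
                        _clean(m.name),
                        _clean(m.group),
                        "1" if m.default_selected else "0",
                        "1" if m.open_license else "0",
                        _clean(m.source_description),
                        _clean(m.publication),
                    ]
                )
                + "\n"
            )
    if db.attribute_names:
        with (db_dir / "attributes.tsv").open("w", encoding="utf-8") as fh:
            inc = db.attributes.tocoo()
            order = np.lexsort((inc.col, inc.row))
            for r, c in zip(inc.row[order], inc.col[order]):
                fh.write(f"{db.universe.primary_ids[r]}\t{db.attribute_names[c]}\n")


def read_attribute_table(
    path: str | Path, universe: GeneUniverse
) -> tuple[sp.csr_matrix, list[str], list[str]]:
    """Read a long-format ``gene<TAB>attribute`` table.

    Returns (incidence matrix genes x attributes, attribute names in
    first-seen order, unresolved gene names).
    """
    rows: list[int] = []
    cols: list[int] = []
    names: list[str] = []
    name_index: dict[str, int] = {}
    unresolved: list[str] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        gene, attr = line.split("\t")[:2]
        idx = universe.resolve(gene.strip())
        if idx == NOT_FOUND:
            if gene not in unresolved:
                unresolved.append(gene)
            continue
        attr = attr.strip()
        if attr not in name_index:
            name_index[attr] = len(names)
            names.append(attr)
        rows.append(idx)
        cols.append(name_index[attr])
    inc = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(universe), len(names))
    ).tocsr()
    inc.data[:] = 1.0  # collapse duplicate rows to binary incidence
    return inc, names, unresolved


def load_database(db_dir: str | Path) -> NetworkDatabase:
    """Load a database directory written by :func:`save_database`."""
    db_dir = Path(db_dir)
    manifest = db_dir / "manifest.tsv"
    if not manifest.is_file():
        raise DatabaseError(f"{db_dir}: not a network database (no manifest.tsv)")
    universe = read_genome_table(db_dir / "genome.tsv")
    networks: list[SparseNetwork] = []
    lines = manifest.read_text(encoding="utf-8").splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != len(_MANIFEST_COLS):
            raise DatabaseError(f"{manifest}: malformed row {line!r}")
        meta = NetworkMeta(
            name=cols[1],
            group=cols[2],
            default_selected=cols[3] == "1",
            open_license=cols[4] == "1",
            source_description=cols[5],
            publication=cols[6],
        )
        net = read_binary(db_dir / cols[0], universe)
        net.meta = meta  # manifest is authoritative for metadata
        networks.append(net)
    attributes = None
    attribute_names: list[str] = []
    attr_path = db_dir / "attributes.tsv"
    if attr_path.is_file():
        attributes, attribute_names, _ = read_attribute_table(attr_path, universe)
    return NetworkDatabase(
        universe=universe,
        networks=networks,
        attributes=attributes,
        attribute_names=attribute_names,
    )
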