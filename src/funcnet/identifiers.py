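"""Gene identifier universe: genome tables, name resolution and autocompletion.

Every matrix in the package is indexed against a :class:`GeneUniverse`, the
ordered set of an organism's primary gene identifiers together with a synonym
map.  Matching is case-insensitive throughout: gene symbols are capitalised
inconsistently across sources, and a case-sensitive index would silently split
one gene into two.  Synonym collisions between different genes are hard errors
rather than first-wins, because a silently misassigned synonym corrupts every
downstream matrix built on the universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import GenomeFormatError, QueryError

NOT_FOUND = -1


@dataclass
class GeneUniverse:
    """An organism's gene set with primary IDs and a synonym index.

    Parameters
    ----------
    primary_ids
        Unique primary identifiers, one per gene, in file order.  The position
        of a gene in this list is its universe index (dense ``0..n-1``).
    synonyms
        Extra identifiers per gene (same length as ``primary_ids``), original
        spelling, deduplicated within each gene.
    organism_name
        Free-text label for the organism.
    """

    primary_ids: list[str]
    synonyms: list[list[str]] = field(default_factory=list)
    organism_name: str = ""
    # lowercase name -> universe index (primaries and synonyms)
    synonym_map: dict[str, int] = field(default_factory=dict)
    # lowercase name -> original spelling, for autocompletion display
    _display: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.synonyms:
            self.synonyms = [[] for _ in self.primary_ids]
        if not self.synonym_map:
            self._build_index()

    def _build_index(self) -> None:
        self.synonym_map = {}
        self._display = {}
        seen_primary: dict[str, str] = {}
        for idx, pid in enumerate(self.primary_ids):
            key = pid.lower()
            if key in seen_primary:
                raise GenomeFormatError(f"duplicate primary ID {pid!r}")
            seen_primary[key] = pid
            self.synonym_map[key] = idx
            self._display[key] = pid
        for idx, extras in enumerate(self.synonyms):
            deduped: list[str] = []
            for name in extras:
                key = name.lower()
                if key in self.synonym_map:
                    other = self.synonym_map[key]
                    if other != idx:
                        raise GenomeFormatError(
                            f"synonym {name!r} maps to both "
                            f"{self.primary_ids[other]!r} and {self.primary_ids[idx]!r}"
                        )
                    continue  # same gene's own entry; deduplicate
                self.synonym_map[key] = idx
                self._display[key] = name
                deduped.append(name)
            self.synonyms[idx] = deduped

    def __len__(self) -> int:
        return len(self.primary_ids)

    @property
    def n(self) -> int:
        return len(self.primary_ids)

    def resolve(self, name: str) -> int:
        """Case-insensitive exact lookup; returns ``NOT_FOUND`` (-1) on a miss."""
        return self.synonym_map.get(name.lower(), NOT_FOUND)

    def autocomplete(self, prefix: str, limit: int = 10) -> list[str]:
        """Names (primary IDs and synonyms) starting with ``prefix``.

        Matching is case-insensitive; results are sorted lexicographically
        (case-insensitively, with the spelled name as tie-break) and truncated
        to ``limit``.
        """
        if limit < 1:
            raise ValueError("limit must be >= 1")
        p = prefix.lower()
        hits = [disp for key, disp in self._display.items() if key.startswith(p)]
        hits.sort(key=lambda s: (s.lower(), s))
        return hits[:limit]


def resolve(name: str, universe: GeneUniverse) -> int:
    """Functional form of :meth:`GeneUniverse.resolve`."""
    return universe.resolve(name)


def autocomplete(prefix: str, universe: GeneUniverse, limit: int = 10) -> list[str]:
    """Functional form of :meth:`GeneUniverse.autocomplete`."""
    return universe.autocomplete(prefix, limit)


def read_genome_table(
    path: str | Path, organism_name: str = "", skip_header: bool = False
) -> GeneUniverse:
    """Load a tab-delimited genome table into a :class:`GeneUniverse`.

    One gene per row: column 1 is the primary identifier, columns 2+ are
    alternate identifiers and synonyms.  Blank lines and lines starting with
    ``#`` are skipped.  There is no header unless ``skip_header`` is set.

    Raises
    ------
    GenomeFormatError
        On duplicate primary IDs or on a synonym shared by two genes.
    """
    path = Path(path)
    primary_ids: list[str] = []
    synonyms: list[list[str]] = []
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if skip_header and lines:
        lines = lines[1:]
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = [c.strip() for c in line.split("\t")]
        if not cols[0]:
            raise GenomeFormatError(f"line {lineno}: empty primary identifier")
        primary_ids.append(cols[0])
        synonyms.append([c for c in cols[1:] if c])
    if not primary_ids:
        raise GenomeFormatError(f"{path}: no genes found")
    return GeneUniverse(primary_ids, synonyms, organism_name=organism_name or path.stem)


def resolve_gene_list(
    names: Iterable[str], universe: GeneUniverse
) -> tuple[list[int], list[str]]:
    """Resolve a list of names to deduplicated universe indices.

    Returns ``(indices, unresolved)`` where indices are in first-seen order and
    unresolved names are reported rather than silently dropped.

    Raises
    ------
    QueryError
        If no name resolves at all.
    """
    indices: list[int] = []
    seen: set[int] = set()
    unresolved: list[str] = []
    for name in names:
        idx = universe.resolve(name)
        if idx == NOT_FOUND:
            unresolved.append(name)
        elif idx not in seen:
            seen.add(idx)
            indices.append(idx)
    if not indices:
        raise QueryError("no query genes resolved")
    return indices, unresolved


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text query gene list (one name per line, '#' comments)."""
    names: list[str] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        name = line.strip()
        if name and not name.startswith("#"):
            names.append(name)
    return names


def write_genome_table(universe: GeneUniverse, path: str | Path) -> None:
    """Write a universe back to the tab-delimited genome format (round trip)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for pid, extras in zip(universe.primary_ids, universe.synonyms):
            fh.write("\t".join([pid, *extras]) + "\n")


def _as_index_set(genes: Sequence[int] | Iterable[int]) -> list[int]:
    """Deduplicate indices preserving first-seen order."""
    out: list[int] = []
    seen: set[int] = set()
    for g in genes:
        g = int(g)
        if g not in seen:
            seen.add(g)
            out.append(g)
    return out
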