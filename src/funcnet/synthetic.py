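"""Deterministic synthetic organisms, networks and profiles for benchmarking.

The generator plants a module (community) structure and emits every input the
pipeline consumes — genome table, weighted networks in several evidence
groups, an expression profile whose module genes co-vary, per-module
annotation sets, and per-module attribute incidence — all driven by a single
seeded random stream, so any run is reproducible bit for bit.

Networks follow a planted-partition model: a pair of genes inside the same
module is connected with probability ``within_module_edge_prob`` and weight
Uniform(0.5, 1); any other pair with probability ``background_edge_prob`` and
weight Uniform(0, 0.3).  The expression profile gives each module a latent
per-sample factor; member genes load on it with Gaussian noise on top, so
correlation-based network construction can recover module co-membership.

This emulates the modular co-functionality structure that real functional
genomics networks exhibit; it does not emulate heavy-tailed degree
distributions, batch effects, or missing data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .coexpression import ExpressionProfile
from .database import NetworkDatabase, save_database
from .evaluation import AnnotationSet, write_annotations
from .identifiers import GeneUniverse
from .network import NetworkMeta, SparseNetwork

DEFAULT_GROUPS = {
    "co-expression": 1,
    "physical-interaction": 1,
    "shared-protein-domains": 1,
}


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study.

    Defaults describe a benchmark of 200 genes carrying 4 planted modules of
    30 genes each, three evidence networks (one per group) with
    within-module edge probability 0.4 against a 0.02 background, and a
    20-sample expression profile with unit module effect and noise sd 0.5.
    """

    n_genes: int = 200
    n_modules: int = 4
    module_size: int = 30
    within_module_edge_prob: float = 0.4
    background_edge_prob: float = 0.02
    networks_per_group: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUPS)
    )
    n_samples: int = 20
    module_effect: float = 1.0
    noise_sd: float = 0.5
    attribute_within_prob: float = 0.8
    attribute_background_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.within_module_edge_prob,
            self.background_edge_prob,
            self.attribute_within_prob,
            self.attribute_background_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.within_module_edge_prob <= self.background_edge_prob:
            raise ValueError("within-module probability must exceed background")
        if self.module_size * self.n_modules > self.n_genes:
            raise ValueError("module_size * n_modules exceeds n_genes")
        if self.n_samples < 2:
            raise ValueError("profiles need at least 2 samples")

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureSpec":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n", encoding="utf-8")


@dataclass
class Fixture:
    """Everything :func:`generate_fixture` produces."""

    spec: FixtureSpec
    universe: GeneUniverse
    database: NetworkDatabase
    annotations: list[AnnotationSet]
    profile: ExpressionProfile
    module_of: np.ndarray  # (n_genes,), module id or -1 for background genes


def _module_assignment(spec: FixtureSpec) -> np.ndarray:
    module_of = np.full(spec.n_genes, -1, dtype=np.int64)
    for m in range(spec.n_modules):
        module_of[m * spec.module_size : (m + 1) * spec.module_size] = m
    return module_of


def _planted_network(
    spec: FixtureSpec, module_of: np.ndarray, meta: NetworkMeta, rng: np.random.Generator
) -> SparseNetwork:
    n = spec.n_genes
    iu, ju = np.triu_indices(n, k=1)
    same = (module_of[iu] >= 0) & (module_of[iu] == module_of[ju])
    u = rng.random(iu.size)
    present = np.where(same, u < spec.within_module_edge_prob, u < spec.background_edge_prob)
    w = np.zeros(iu.size)
    n_within = int((present & same).sum())
    n_back = int((present & ~same).sum())
    w[present & same] = rng.uniform(0.5, 1.0, n_within)
    w[present & ~same] = rng.uniform(0.0, 0.3, n_back)
    keep = present & (w > 0)
    upper = sp.coo_matrix((w[keep], (iu[keep], ju[keep])), shape=(n, n)).tocsr()
    return SparseNetwork(upper + upper.T, meta)


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Generate a complete synthetic study from one seeded random stream."""
    rng = np.random.default_rng(spec.seed)
    module_of = _module_assignment(spec)
    primary = [f"G{i:04d}" for i in range(spec.n_genes)]
    synonyms = [[f"g{i}"] for i in range(spec.n_genes)]
    universe = GeneUniverse(primary, synonyms, organism_name=f"synthetic-{spec.seed}")

    networks: list[SparseNetwork] = []
    for group, count in spec.networks_per_group.items():
        for rep in range(count):
            meta = NetworkMeta(
                name=f"{group}-{rep + 1}",
                group=group,
                source_description=f"planted-partition fixture seed={spec.seed}",
                publication=f"synthetic fixture network ({group} #{rep + 1})",
            )
            networks.append(_planted_network(spec, module_of, meta, rng))

    # expression profile: module genes load on a shared per-module factor
    factors = rng.normal(size=(spec.n_modules, spec.n_samples))
    values = rng.normal(scale=spec.noise_sd, size=(spec.n_genes, spec.n_samples))
    in_module = module_of >= 0
    values[in_module] += spec.module_effect * factors[module_of[in_module]]
    profile = ExpressionProfile(
        gene_indices=np.arange(spec.n_genes),
        values=values,
        sample_names=[f"S{j + 1}" for j in range(spec.n_samples)],
    )

    # per-module attributes (protein-domain-like incidence)
    rows: list[int] = []
    cols: list[int] = []
    attribute_names = [f"DOMAIN_M{m + 1}" for m in range(spec.n_modules)]
    for m in range(spec.n_modules):
        p = np.where(module_of == m, spec.attribute_within_prob, spec.attribute_background_prob)
        carriers = np.flatnonzero(rng.random(spec.n_genes) < p)
        rows.extend(carriers.tolist())
        cols.extend([m] * carriers.size)
    attributes = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(spec.n_genes, spec.n_modules)
    ).tocsr()

    annotations = [
        AnnotationSet(f"module_{m + 1}", frozenset(np.flatnonzero(module_of == m).tolist()))
        for m in range(spec.n_modules)
    ]
    database = NetworkDatabase(
        universe=universe,
        networks=networks,
        attributes=attributes,
        attribute_names=attribute_names,
    )
    return Fixture(
        spec=spec,
        universe=universe,
        database=database,
        annotations=annotations,
        profile=profile,
        module_of=module_of,
    )


def write_fixture(fixture: Fixture, out_dir: str | Path) -> None:
    """Write a fixture as import-ready text files plus a loadable database.

    Produces ``genome.tsv``, per-network edge lists under ``edgelists/``,
    ``profile.tsv``, ``annotations.tsv``, ``attributes.tsv``, the generating
    ``spec.json``, and a binary database directory under ``db/``.
    """
    out = Path(out_dir)
    (out / "edgelists").mkdir(parents=True, exist_ok=True)
    fixture.spec.to_json(out / "spec.json")
    universe = fixture.universe
    with (out / "genome.tsv").open("w", encoding="utf-8") as fh:
        for pid, extras in zip(universe.primary_ids, universe.synonyms):
            fh.write("\t".join([pid, *extras]) + "\n")
    for net in fixture.database.networks:
        path = out / "edgelists" / f"{net.meta.name}.tsv"
        upper = sp.triu(net.adjacency, k=1).tocoo()
        order = np.lexsort((upper.col, upper.row))
        with path.open("w", encoding="utf-8") as fh:
            for i, j, w in zip(upper.row[order], upper.col[order], upper.data[order]):
                fh.write(f"{universe.primary_ids[i]}\t{universe.primary_ids[j]}\t{w:.17g}\n")
    with (out / "profile.tsv").open("w", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(fixture.profile.sample_names) + "\n")
        for gi, row in zip(fixture.profile.gene_indices, fixture.profile.values):
            cells = "\t".join(f"{v:.17g}" for v in row)
            fh.write(f"{universe.primary_ids[gi]}\t{cells}\n")
    write_annotations(fixture.annotations, universe, out / "annotations.tsv")
    inc = fixture.database.attributes.tocoo()
    order = np.lexsort((inc.col, inc.row))
    with (out / "attributes.tsv").open("w", encoding="utf-8") as fh:
        for r, c in zip(inc.row[order], inc.col[order]):
            fh.write(f"{universe.primary_ids[r]}\t{fixture.database.attribute_names[c]}\n")
    save_database(fixture.database, out / "db")
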