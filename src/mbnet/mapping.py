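"""Map biomarker metabolites to disease-related protein seed sets.

Two complementary sources feed the seed sets: direct metabolite-protein
associations (an HMDB-style pairwise table) and enzymes extracted from
metabolic maps. For the latter, an enzyme qualifies when it labels a
compound-compound edge whose nearer endpoint lies within ``max_len - 1``
hops of the biomarker, i.e. the enzyme sits "up to path length
``max_len``" from the metabolite when hops are counted compound to
compound. Per-disease unions of both sources form the seed sets that
anchor the disease interaction network.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from . import io
from .errors import MbnetError, ParseError

VALID_LABELS = {"SCZ": frozenset({"SCZ"}), "BD": frozenset({"BD"}), "BOTH": frozenset({"SCZ", "BD"})}


@dataclass(frozen=True)
class Biomarker:
    name: str
    diseases: frozenset[str]

    def __post_init__(self):
        if not self.name.strip():
            raise ValueError("biomarker name must be non-empty")
        if not self.diseases or not self.diseases <= {"SCZ", "BD"}:
            raise ValueError("diseases must be a non-empty subset of {SCZ, BD}")


@dataclass(frozen=True)
class SeedSets:
    """Per-disease protein seed sets with their union and intersection."""

    scz: frozenset[str]
    bd: frozenset[str]

    @property
    def union(self) -> frozenset[str]:
        return self.scz | self.bd

    @property
    def intersection(self) -> frozenset[str]:
        return self.scz & self.bd

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein": sorted(self.union),
                "in_SCZ": [int(p in self.scz) for p in sorted(self.union)],
                "in_BD": [int(p in self.bd) for p in sorted(self.union)],
            }
        )


def _norm(name: str) -> str:
    return name.strip().casefold()


def load_biomarkers(path: os.PathLike | str) -> list[Biomarker]:
    """Load a two-column (metabolite, disease-label) table.

    Accepts tab- or comma-separated rows; labels are SCZ, BD or BOTH.
    Duplicate metabolite names (case-insensitive) merge by unioning
    their disease labels; the result is sorted by name.
    """
    records: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split(",")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected metabolite and disease label")
            # Metabolite names may themselves contain commas; the label
            # is always the last field.
            name = fields[0] if "\t" in line else ",".join(fields[:-1])
            name, label = name.strip(), fields[-1].strip().upper()
            if label not in VALID_LABELS:
                raise ParseError(f"{path}:{lineno}: unknown disease label {fields[-1].strip()!r}")
            if not name:
                raise ParseError(f"{path}:{lineno}: empty metabolite name")
            key = _norm(name)
            if key in records:
                records[key] = (records[key][0], records[key][1] | set(VALID_LABELS[label]))
            else:
                records[key] = (name, set(VALID_LABELS[label]))
    return [
        Biomarker(name=orig, diseases=frozenset(d))
        for _, (orig, d) in sorted(records.items())
    ]


def load_associations(path: os.PathLike | str) -> pd.DataFrame:
    return io.read_tsv(path, ["metabolite", "protein"])


class MetabolicGraph:
    """Undirected compound graph with one or more enzyme labels per edge."""

    def __init__(self) -> None:
        self.graph = nx.Graph()

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MetabolicGraph":
        g = cls()
        for row in df.itertuples(index=False):
            a, b, enzyme = str(row[0]), str(row[1]), str(row[2])
            if a == b:
                raise ParseError(f"self-loop compound edge on {a!r}")
            if g.graph.has_edge(a, b):
                g.graph.edges[a, b]["enzymes"].add(enzyme)
            else:
                g.graph.add_edge(a, b, enzymes={enzyme})
        return g

    @classmethod
    def from_file(cls, path: os.PathLike | str) -> "MetabolicGraph":
        return cls.from_frame(io.read_tsv(path, ["compound_a", "compound_b", "enzyme_label"]))

    def resolve(self, compound: str) -> str | None:
        """Resolve a compound name case-insensitively to its node id."""
        if compound in self.graph:
            return compound
        index = {_norm(n): n for n in self.graph.nodes}
        return index.get(_norm(compound))

    def __contains__(self, compound: str) -> bool:
        return self.resolve(compound) is not None

    @property
    def compounds(self) -> set[str]:
        return set(self.graph.nodes)


def associated_proteins(biomarker: Biomarker | str, associations: pd.DataFrame) -> frozenset[str]:
    """Exact-name lookup (case-folded, trimmed); empty set when absent."""
    name = _norm(biomarker.name if isinstance(biomarker, Biomarker) else biomarker)
    if associations.empty:
        return frozenset()
    hits = associations.loc[
        associations["metabolite"].astype(str).map(_norm) == name, "protein"
    ]
    return frozenset(hits.astype(str))


def enzymes_within_path_length(
    graph: MetabolicGraph, metabolite: str, max_len: int = 2
) -> frozenset[str]:
    """Enzymes on edges whose nearer endpoint is within ``max_len - 1`` hops.

    Raises LookupError naming the compound when the metabolite is not a
    node of the graph.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    g = graph.graph
    node = graph.resolve(metabolite)
    if node is None:
        raise LookupError(f"compound {metabolite!r} not present in the metabolic graph")
    dist = nx.single_source_shortest_path_length(g, node, cutoff=max_len - 1)
    enzymes: set[str] = set()
    for u in dist:
        for v in g.neighbors(u):
            enzymes |= g.edges[u, v]["enzymes"]
    return frozenset(enzymes)


def build_seed_sets(
    biomarkers: list[Biomarker],
    associations: pd.DataFrame,
    graph: MetabolicGraph | None = None,
    max_len: int = 2,
) -> SeedSets:
    """Union associations and path-limited enzymes into per-disease seed sets.

    A biomarker absent from the metabolic graph simply contributes no
    enzymes; a biomarker labelled for both diseases contributes to both
    sets.
    """
    scz: set[str] = set()
    bd: set[str] = set()
    for bm in biomarkers:
        contrib = set(associated_proteins(bm, associations))
        if graph is not None and bm.name in graph:
            contrib |= enzymes_within_path_length(graph, bm.name, max_len=max_len)
        if "SCZ" in bm.diseases:
            scz |= contrib
        if "BD" in bm.diseases:
            bd |= contrib
    seeds = SeedSets(scz=frozenset(scz), bd=frozenset(bd))
    if seeds.union != seeds.scz | seeds.bd:  # pragma: no cover - identity guard
        raise MbnetError("seed-set union bookkeeping is inconsistent")
    return seeds
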