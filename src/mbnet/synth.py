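"""Synthetic inputs with planted structure for the whole pipeline.

Real runs of this analysis consume six external resources (a curated
biomarker list, metabolite-protein associations, metabolic maps, a
scored interactome, a reference disease-gene list and pathway gene
sets), none of which ship with the package. This module generates all
six as flat files with *known* planted structure so that every
downstream stage - seed mapping, network construction, overlapping
clustering, enrichment, ROC density selection and pathway ranking - can
be tested end to end without any download.

The planted world:

* ``n_modules`` dense protein modules (consecutive modules share
  ``overlap_nodes`` proteins, giving ground truth for overlapping
  clusters) sit inside a larger protein universe. Within-module pairs
  interact with probability ``p_in``; background pairs with ``p_out``.
* Interaction confidence scores are Beta-distributed: high-shifted for
  within-module edges, low-shifted for background edges, so a >0.7
  confidence cutoff filters background contacts meaningfully.
* Each module protein additionally gains ~``periphery_rate``
  high-confidence partners outside every module, mimicking a real
  interactome where disease-linked proteins also have confident
  partners that are not themselves biomarker-linked.
* ``n_background_seeds`` background proteins are biomarker-associated
  without belonging to any module; each carries ~``background_halo``
  high-confidence partners. These distractor neighbourhoods are
  admitted to the disease network by the score cutoff but carry no
  planted disease signal, and their non-seed partners supply the
  negative class for the ROC stage.
* The first ``n_disease_modules`` modules are disease modules: their
  proteins enter the reference disease-gene list with odds
  ``disease_odds`` times the background odds.
* A fraction ``pathway_module_alignment`` of pathway gene sets are
  supersets-with-noise of planted modules (disease modules are aligned
  first); the rest are random gene sets.
* Metabolite biomarkers connect to module proteins through an
  association table and through small metabolic-map fragments whose
  enzyme labels sit within a path length of two of the biomarker; one
  decoy enzyme per fragment sits beyond that horizon and must *not* be
  picked up by the mapping stage.

All randomness flows from ``SynthConfig.seed`` through per-output
``numpy`` generators; identical config yields byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .errors import ConfigError

_DISEASE_CYCLE = ("SCZ", "BD", "BOTH")


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the planted world (defaults are the demo scenario)."""

    n_proteins: int = 800
    n_modules: int = 5
    module_size_range: tuple[int, int] = (48, 60)
    overlap_nodes: int = 3
    p_in: float = 0.13
    p_out: float = 0.002
    score_in_params: tuple[float, float] = (8.0, 2.0)
    score_out_params: tuple[float, float] = (2.0, 8.0)
    periphery_rate: float = 0.0
    n_background_seeds: int = 40
    background_halo: float = 6.0
    disease_odds: float = 10.0
    disease_background_rate: float = 0.10
    n_disease_modules: int = 4
    n_pathways: int = 12
    pathway_module_alignment: float = 0.5
    pathway_noise_genes: int = 8
    n_metabolites: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be >= 1")
        if self.n_modules < 1:
            raise ConfigError("n_modules must be >= 1")
        lo, hi = self.module_size_range
        if lo < 3 or hi < lo:
            raise ConfigError("module_size_range must satisfy 3 <= min <= max")
        if self.overlap_nodes < 0 or self.overlap_nodes >= lo:
            raise ConfigError("overlap_nodes must be >= 0 and smaller than the minimum module size")
        for name in ("p_in", "p_out"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        for name in ("score_in_params", "score_out_params"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ConfigError(f"{name} must be positive Beta parameters")
        if self.periphery_rate < 0:
            raise ConfigError("periphery_rate must be >= 0")
        if self.n_background_seeds < 0:
            raise ConfigError("n_background_seeds must be >= 0")
        if self.background_halo < 0:
            raise ConfigError("background_halo must be >= 0")
        if not self.disease_odds > 0:
            raise ConfigError("disease_odds must be > 0")
        if not 0.0 < self.disease_background_rate < 1.0:
            raise ConfigError("disease_background_rate must lie in (0, 1)")
        if not 0 <= self.n_disease_modules <= self.n_modules:
            raise ConfigError("n_disease_modules must lie in [0, n_modules]")
        if self.n_pathways < 1:
            raise ConfigError("n_pathways must be >= 1")
        if not 0.0 <= self.pathway_module_alignment <= 1.0:
            raise ConfigError("pathway_module_alignment must lie in [0, 1]")
        if self.pathway_noise_genes < 0:
            raise ConfigError("pathway_noise_genes must be >= 0")
        if self.n_metabolites < 1:
            raise ConfigError("n_metabolites must be >= 1")
        # A rough capacity check: modules must fit inside the universe.
        need = self.n_modules * hi
        if need > self.n_proteins:
            raise ConfigError("n_proteins too small for n_modules modules of the requested size")


@dataclass
class GroundTruth:
    """Everything the generators planted, for closed-loop verification."""

    proteins: tuple[str, ...]
    modules: list[frozenset[str]]
    module_assignments: dict[str, set[int]]
    disease_module_ids: tuple[int, ...]
    background_seed_pool: tuple[str, ...] = ()
    disease_genes: frozenset[str] = frozenset()
    planted_pathways: dict[str, frozenset[str]] = field(default_factory=dict)
    pathway_module: dict[str, int] = field(default_factory=dict)
    metabolite_protein_truth: dict[str, frozenset[str]] = field(default_factory=dict)
    metabolite_diseases: dict[str, frozenset[str]] = field(default_factory=dict)
    seed_scz: frozenset[str] = frozenset()
    seed_bd: frozenset[str] = frozenset()

    @property
    def module_nodes(self) -> frozenset[str]:
        return frozenset().union(*self.modules) if self.modules else frozenset()

    @property
    def disease_module_nodes(self) -> frozenset[str]:
        return frozenset().union(
            *(self.modules[i] for i in self.disease_module_ids)
        ) if self.disease_module_ids else frozenset()

    @property
    def seed_all(self) -> frozenset[str]:
        return self.seed_scz | self.seed_bd

    @property
    def disease_aligned_pathways(self) -> frozenset[str]:
        return frozenset(
            p for p, m in self.pathway_module.items() if m in self.disease_module_ids
        )


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def generate_ppi(config: SynthConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Plant overlapping dense modules in a scored interaction list.

    Returns the edge table (protein_a, protein_b, score; canonical pair
    order, no self-loops, no duplicates) and the ground truth recording
    module membership.
    """
    config.validate()
    rng = _rng(config, 1)
    width = max(4, len(str(config.n_proteins)))
    proteins = tuple(f"P{i:0{width}d}" for i in range(1, config.n_proteins + 1))
    perm = [proteins[i] for i in rng.permutation(config.n_proteins)]

    lo, hi = config.module_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_modules)
    modules: list[frozenset[str]] = []
    cursor = 0
    prev_tail: list[str] = []
    for i in range(config.n_modules):
        fresh_n = int(sizes[i]) - (len(prev_tail) if i > 0 else 0)
        fresh = perm[cursor:cursor + fresh_n]
        cursor += fresh_n
        nodes = list(prev_tail) + fresh
        modules.append(frozenset(nodes))
        prev_tail = nodes[-config.overlap_nodes:] if config.overlap_nodes else []

    assignments: dict[str, set[int]] = {}
    for mid, mod in enumerate(modules):
        for n in mod:
            assignments.setdefault(n, set()).add(mid)
    module_nodes = frozenset(assignments)
    background = [p for p in proteins if p not in module_nodes]

    within_pairs: set[tuple[str, str]] = set()
    for mod in modules:
        members = sorted(mod)
        for i, u in enumerate(members):
            for v in members[i + 1:]:
                within_pairs.add((u, v))

    edges: dict[tuple[str, str], float] = {}
    a_in, b_in = config.score_in_params
    a_out, b_out = config.score_out_params
    for u, v in sorted(within_pairs):
        if rng.random() < config.p_in:
            edges[(u, v)] = float(rng.beta(a_in, b_in))
    # Background pairs: everything not inside a common module. The
    # reserved background-seed hubs (below) are kept out of the noise
    # process: their neighbourhoods consist solely of their planted
    # high-confidence partners, so the distractor structures stay
    # separated from the disease modules.
    pool_set = frozenset(background[: config.n_background_seeds])
    n = len(proteins)
    for i in range(n):
        u = proteins[i]
        draws = rng.random(n - i - 1)
        for j, r in enumerate(draws, start=i + 1):
            if r < config.p_out:
                v = proteins[j]
                pair = (u, v)
                if pair not in within_pairs and u not in pool_set and v not in pool_set:
                    edges.setdefault(pair, float(rng.beta(a_out, b_out)))
    # Background proteins reserved for biomarker association without
    # module membership; they anchor distractor neighbourhoods.
    pool = tuple(background[: config.n_background_seeds])
    halo_targets = background[config.n_background_seeds:] or background

    # High-confidence periphery: module proteins interact with a few
    # partners outside every module, scored like true interactions.
    if background and config.periphery_rate > 0:
        for u in sorted(module_nodes):
            k = min(int(rng.poisson(config.periphery_rate)), len(halo_targets))
            if k == 0:
                continue
            partners = rng.choice(len(halo_targets), size=k, replace=False)
            for idx in sorted(int(x) for x in partners):
                v = halo_targets[idx]
                pair = (u, v) if u < v else (v, u)
                score = float(rng.beta(a_in, b_in))
                edges[pair] = max(edges.get(pair, 0.0), score)
    # Distractor neighbourhoods: each background seed anchors a star of
    # exactly `background_halo` non-seed partners, with the partner sets
    # disjoint across hubs. These emulate curated complexes around
    # well-studied hub proteins, so their interactions are uniformly
    # high-confidence (scores in (0.7, 1]) and survive the score
    # cutoff; the uniform, non-overlapping shape keeps the distractor
    # clusters statistically exchangeable.
    halo_k = int(round(config.background_halo))
    if background and halo_k > 0 and pool:
        perm_targets = [halo_targets[int(i)] for i in rng.permutation(len(halo_targets))]
        for i, u in enumerate(pool):
            partners = perm_targets[i * halo_k:(i + 1) * halo_k]
            for v in sorted(partners):
                pair = (u, v) if u < v else (v, u)
                score = 0.7 + 0.3 * float(rng.beta(2.0, 2.0))
                edges[pair] = max(edges.get(pair, 0.0), score)

    table = pd.DataFrame(
        [(u, v, s) for (u, v), s in sorted(edges.items())],
        columns=["protein_a", "protein_b", "score"],
    )
    truth = GroundTruth(
        proteins=proteins,
        modules=modules,
        module_assignments=assignments,
        disease_module_ids=tuple(range(config.n_disease_modules)),
        background_seed_pool=pool,
    )
    return table, truth


def generate_disease_reference(truth: GroundTruth, config: SynthConfig) -> pd.DataFrame:
    """Sample a reference disease-gene list over the protein universe.

    Membership odds inside disease modules are ``disease_odds`` times
    the background odds implied by ``disease_background_rate``. An
    infinite ``disease_odds`` saturates to membership probability 1
    inside disease modules and 0 outside.
    """
    config.validate()
    rng = _rng(config, 2)
    if math.isinf(config.disease_odds):
        p_inside, p_outside = 1.0, 0.0
    else:
        q = config.disease_background_rate
        odds_in = config.disease_odds * q / (1.0 - q)
        p_inside = odds_in / (1.0 + odds_in)
        p_outside = q
    inside = truth.disease_module_nodes
    genes = []
    for p in truth.proteins:
        prob = p_inside if p in inside else p_outside
        if rng.random() < prob:
            genes.append(p)
    truth.disease_genes = frozenset(genes)
    return pd.DataFrame({"gene": sorted(genes)})


def generate_pathways(truth: GroundTruth, config: SynthConfig) -> dict[str, tuple[str, frozenset[str]]]:
    """Build pathway gene sets; a configurable fraction align with modules.

    Aligned pathways are supersets of a planted module plus
    ``pathway_noise_genes`` random extra genes; alignment cycles over
    disease modules first so that the planted disease signal reaches the
    pathway stage. The remaining pathways are random gene sets.
    """
    config.validate()
    rng = _rng(config, 3)
    n_aligned = round(config.pathway_module_alignment * config.n_pathways)
    order = list(truth.disease_module_ids) + [
        i for i in range(len(truth.modules)) if i not in truth.disease_module_ids
    ]
    width = max(2, len(str(config.n_pathways)))
    lo, hi = config.module_size_range
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    truth.planted_pathways = {}
    truth.pathway_module = {}
    for j in range(config.n_pathways):
        name = f"PW{j + 1:0{width}d}"
        if j < n_aligned and truth.modules:
            mid = order[j % len(order)]
            module = set(truth.modules[mid])
            outside = [p for p in truth.proteins if p not in module]
            k = min(config.pathway_noise_genes, len(outside))
            noise = {outside[int(i)] for i in rng.choice(len(outside), size=k, replace=False)} if k else set()
            genes = frozenset(module | noise)
            sets[name] = (f"planted module {mid}", genes)
            truth.planted_pathways[name] = genes
            truth.pathway_module[name] = mid
        else:
            size = int(rng.integers(lo, hi + 1))
            idx = rng.choice(len(truth.proteins), size=size, replace=False)
            genes = frozenset(truth.proteins[int(i)] for i in idx)
            sets[name] = ("random gene set", genes)
    return sets


def generate_metabolic_inputs(
    truth: GroundTruth, config: SynthConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate biomarkers, metabolite-protein associations and map fragments.

    Each metabolite is tied to one module: part of that module's
    proteins appear as direct associations, part as enzyme labels on a
    short metabolic chain within path length two of the metabolite. A
    decoy enzyme on each chain sits at path length three and must not be
    reachable; it is drawn from proteins outside every planted
    contribution. The union of planted contributions per metabolite is
    recorded in ``truth.metabolite_protein_truth`` and the per-disease
    unions in ``truth.seed_scz`` / ``truth.seed_bd``.
    """
    config.validate()
    rng = _rng(config, 4)
    width = max(2, len(str(config.n_metabolites)))
    mets = [f"M{i + 1:0{width}d}" for i in range(config.n_metabolites)]
    labels = {m: _DISEASE_CYCLE[i % 3] for i, m in enumerate(mets)}

    n_mod = len(truth.modules)
    mets_of_module: dict[int, list[str]] = {i: [] for i in range(n_mod)}
    for i, m in enumerate(mets):
        mets_of_module[i % n_mod].append(m)

    assoc_part: dict[str, list[str]] = {m: [] for m in mets}
    enzyme_part: dict[str, list[str]] = {m: [] for m in mets}
    for mid in range(n_mod):
        owners = mets_of_module[mid]
        if not owners:
            continue
        nodes = sorted(truth.modules[mid])
        nodes = [nodes[int(i)] for i in rng.permutation(len(nodes))]
        split = max(1, int(round(0.6 * len(nodes))))
        for j, p in enumerate(nodes[:split]):
            assoc_part[owners[j % len(owners)]].append(p)
        for j, p in enumerate(nodes[split:]):
            enzyme_part[owners[j % len(owners)]].append(p)

    module_nodes = truth.module_nodes
    pool = set(truth.background_seed_pool)
    extra_by_met: dict[str, list[str]] = {m: [] for m in mets}
    for j, p in enumerate(truth.background_seed_pool):
        extra_by_met[mets[j % len(mets)]].append(p)
    decoy_pool = [p for p in truth.proteins if p not in module_nodes and p not in pool]
    decoy_idx = list(rng.permutation(len(decoy_pool)))
    decoys = [decoy_pool[decoy_idx.pop()] if decoy_idx else None for _ in mets]

    assoc_rows: list[tuple[str, str]] = []
    graph_rows: list[tuple[str, str, str]] = []
    truth.metabolite_protein_truth = {}
    truth.metabolite_diseases = {}
    for i, m in enumerate(mets):
        contributions = set(assoc_part[m]) | set(enzyme_part[m])
        for extra in extra_by_met[m]:
            assoc_part[m].append(extra)
            contributions.add(extra)
        for p in sorted(set(assoc_part[m])):
            assoc_rows.append((m, p))
        enz = sorted(set(enzyme_part[m]))
        if enz:
            shell1, shell2 = enz[0::2], enz[1::2]
            c1, c2, c3 = f"{m}_C1", f"{m}_C2", f"{m}_C3"
            for e in shell1:
                graph_rows.append((m, c1, e))
            for e in shell2 or shell1[:1]:
                graph_rows.append((c1, c2, e))
            decoy = decoys[i]
            if decoy is not None and decoy not in contributions:
                graph_rows.append((c2, c3, decoy))
        truth.metabolite_protein_truth[m] = frozenset(contributions)
        lab = labels[m]
        truth.metabolite_diseases[m] = (
            frozenset({"SCZ", "BD"}) if lab == "BOTH" else frozenset({lab})
        )

    scz, bd = set(), set()
    for m, prots in truth.metabolite_protein_truth.items():
        if "SCZ" in truth.metabolite_diseases[m]:
            scz |= prots
        if "BD" in truth.metabolite_diseases[m]:
            bd |= prots
    truth.seed_scz, truth.seed_bd = frozenset(scz), frozenset(bd)

    biomarkers = pd.DataFrame({"metabolite": mets, "disease": [labels[m] for m in mets]})
    associations = pd.DataFrame(sorted(assoc_rows), columns=["metabolite", "protein"])
    metabolic_graph = pd.DataFrame(
        sorted(graph_rows), columns=["compound_a", "compound_b", "enzyme_label"]
    )
    return biomarkers, associations, metabolic_graph


@dataclass
class SynthData:
    """All six generated inputs plus the ground truth behind them."""

    config: SynthConfig
    interactions: pd.DataFrame
    disease_genes: pd.DataFrame
    pathways: dict[str, tuple[str, frozenset[str]]]
    biomarkers: pd.DataFrame
    associations: pd.DataFrame
    metabolic_graph: pd.DataFrame
    truth: GroundTruth


def generate_all(config: SynthConfig) -> SynthData:
    """Run all generators in their canonical order."""
    interactions, truth = generate_ppi(config)
    disease = generate_disease_reference(truth, config)
    pathways = generate_pathways(truth, config)
    biomarkers, associations, metabolic_graph = generate_metabolic_inputs(truth, config)
    return SynthData(
        config=config,
        interactions=interactions,
        disease_genes=disease,
        pathways=pathways,
        biomarkers=biomarkers,
        associations=associations,
        metabolic_graph=metabolic_graph,
        truth=truth,
    )


def write_inputs(data: SynthData, outdir: Path | str) -> dict[str, Path]:
    """Write the six pipeline input files; returns their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "interactions": outdir / "interactions.tsv",
        "disease_genes": outdir / "disease_genes.tsv",
        "pathways": outdir / "pathways.gmt",
        "biomarkers": outdir / "biomarkers.tsv",
        "associations": outdir / "associations.tsv",
        "metabolic_graph": outdir / "metabolic_graph.tsv",
    }
    io.write_tsv(paths["interactions"], data.interactions)
    io.write_gene_list(paths["disease_genes"], data.disease_genes["gene"])
    io.write_gmt(paths["pathways"], data.pathways)
    io.write_tsv(paths["biomarkers"], data.biomarkers)
    io.write_tsv(paths["associations"], data.associations)
    io.write_tsv(paths["metabolic_graph"], data.metabolic_graph)
    return paths
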