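"""End-to-end orchestration: map -> network -> cluster sweep -> significance
-> ROC density selection -> pathway ranking.

The pipeline consumes the six flat-file inputs (or generates them from a
synthetic-world config), writes every intermediate artifact into the
output directory and returns a machine-readable run report. Disease
enrichment of clusters uses the reference disease-gene list restricted
to the network (the two diseases are analysed together); the ROC truth
set is the union of that reference with the biomarker-derived seed
proteins.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import dpcluso as dp
from . import enrichment, io, mapping, network, pathways, prioritize, synth
from .errors import ConfigError, PipelineError

log = logging.getLogger("mbnet")


@dataclass
class PipelineConfig:
    # Either the six input paths ...
    biomarkers: str | None = None
    associations: str | None = None
    metabolic_graph: str | None = None
    interactions: str | None = None
    disease_genes: str | None = None
    pathways: str | None = None
    # ... or a synthetic world generated under `seed`.
    synth: synth.SynthConfig | None = None

    score_threshold: float = 0.7
    densities: tuple[float, ...] = dp.DEFAULT_DENSITIES
    cp_in: float = 0.5
    min_report_size: int = 2
    fdr_cutoff: float = 0.05
    count_min: int = 2
    ease_max: float = 0.1
    fdr_max: float = 0.05
    top_k: int = 3
    min_degree: int = 3
    fdr_floor: float = 1e-16
    max_path_length: int = 2
    per_disease: bool = False
    seed: int = 0
    outdir: str = "mbnet_out"

    def validate(self) -> None:
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ConfigError("score_threshold must lie in [0, 1]")
        if not self.densities:
            raise ConfigError("densities must be non-empty")
        ds = list(self.densities)
        if ds != sorted(set(ds)) or not all(0.0 < d <= 1.0 for d in ds):
            raise ConfigError("densities must be unique, ascending and in (0, 1]")
        for name in ("fdr_cutoff", "ease_max", "fdr_max"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigError(f"{name} must lie in (0, 1]")
        if self.top_k < 1:
            raise ConfigError("top_k must be >= 1")
        if self.min_degree < 1:
            raise ConfigError("min_degree must be >= 1")
        if self.count_min < 0:
            raise ConfigError("count_min must be >= 0")


_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a flat key=value config file.

    Keys prefixed ``synth.`` populate the synthetic-world config (their
    presence switches the pipeline to synthetic inputs). Pair- and
    list-valued fields use comma separation.
    """
    cfg_fields = {f.name: f for f in dataclasses.fields(PipelineConfig)}
    synth_fields = {f.name: f for f in dataclasses.fields(synth.SynthConfig)}
    kwargs: dict = {}
    synth_kwargs: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected key=value")
            key, value = (s.strip() for s in line.split("=", 1))
            if key.startswith("synth."):
                name = key[len("synth."):]
                if name not in synth_fields:
                    raise ConfigError(f"{path}:{lineno}: unknown synth field {name!r}")
                synth_kwargs[name] = _coerce(value, getattr(synth.SynthConfig, name, None))
            else:
                if key not in cfg_fields:
                    raise ConfigError(f"{path}:{lineno}: unknown config key {key!r}")
                kwargs[key] = _coerce(value, cfg_fields[key].default)
    if synth_kwargs:
        kwargs["synth"] = synth.SynthConfig(**synth_kwargs)
    return PipelineConfig(**kwargs)


def _coerce(value: str, default):
    if isinstance(default, bool):
        return _BOOL[value.lower()]
    if isinstance(default, int):
        return int(value)
    if isinstance(default, float):
        return float(value)
    if isinstance(default, tuple):
        parts = [p for p in value.replace(",", " ").split() if p]
        elem = default[0] if default else 0.0
        cast = int if isinstance(elem, int) else float
        return tuple(cast(p) for p in parts)
    return value


@dataclass
class RunReport:
    config: dict
    counts: dict = field(default_factory=dict)
    sweep: list = field(default_factory=list)
    auc_by_density: dict = field(default_factory=dict)
    selected_density: float | None = None
    selected_pathways: list = field(default_factory=list)
    version: str = ""
    started: str = ""
    finished: str = ""

    def to_json(self, path: Path | str) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the five analysis steps in order, writing all artifacts."""
    from . import __version__

    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_echo = dataclasses.asdict(config)
    report = RunReport(config=cfg_echo, version=__version__,
                       started=time.strftime("%Y-%m-%dT%H:%M:%S"))

    # Stage 0: inputs (synthetic world if requested).
    if config.synth is not None:
        sc = dataclasses.replace(config.synth, seed=config.seed)
        data = synth.generate_all(sc)
        paths = synth.write_inputs(data, outdir / "inputs")
        in_paths = {k: str(v) for k, v in paths.items()}
    else:
        needed = ("biomarkers", "associations", "metabolic_graph",
                  "interactions", "disease_genes", "pathways")
        missing = [k for k in needed if getattr(config, k) is None]
        if missing:
            raise PipelineError("inputs", f"missing input paths: {', '.join(missing)}")
        in_paths = {k: getattr(config, k) for k in needed}

    # Stage 1: biomarker -> protein seed mapping.
    try:
        biomarkers = mapping.load_biomarkers(in_paths["biomarkers"])
        if not biomarkers:
            raise ValueError("biomarker list is empty")
        associations = mapping.load_associations(in_paths["associations"])
        metgraph = mapping.MetabolicGraph.from_file(in_paths["metabolic_graph"])
        seeds = mapping.build_seed_sets(
            biomarkers, associations, metgraph, max_len=config.max_path_length
        )
        io.write_tsv(outdir / "seeds.tsv", seeds.to_frame())
    except Exception as exc:
        raise PipelineError("mapping", str(exc)) from exc
    report.counts["biomarkers"] = len(biomarkers)
    report.counts["seed_SCZ"] = len(seeds.scz)
    report.counts["seed_BD"] = len(seeds.bd)
    report.counts["seed_common"] = len(seeds.intersection)
    report.counts["seed_total"] = len(seeds.union)
    log.info("mapping: %d biomarkers -> %d seed proteins (SCZ %d, BD %d, common %d)",
             len(biomarkers), len(seeds.union), len(seeds.scz), len(seeds.bd),
             len(seeds.intersection))

    # Stage 2: disease network and its topology.
    try:
        interactions = io.read_interactions(in_paths["interactions"])
        net = network.build_network(interactions, seeds, threshold=config.score_threshold)
        if net.number_of_nodes() == 0:
            raise ValueError("no interactions survive the seed/score rules")
        network.write_network(net, outdir / "network.tsv")
        topo = network.topology_stats(net)
        topo.to_json(outdir / "topology.json")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("network", str(exc)) from exc
    report.counts["network_nodes"] = topo.n_nodes
    report.counts["network_edges"] = topo.n_edges
    report.counts["network_edges_SCZ"] = net.graph["n_edges_SCZ"]
    report.counts["network_edges_BD"] = net.graph["n_edges_BD"]
    report.counts["network_edges_common"] = net.graph["n_edges_common"]
    log.info("network: %d nodes, %d edges (clustering %.3f, cpl %.3f, diameter %d)",
             topo.n_nodes, topo.n_edges, topo.clustering_coefficient,
             topo.characteristic_path_length, topo.diameter)

    # Stage 3: DPClusO sweep + per-density disease enrichment.
    try:
        runs = dp.density_sweep(net, config.densities, cp_in=config.cp_in,
                                min_report_size=config.min_report_size)
        reference = io.read_gene_list(in_paths["disease_genes"])
        nodes = sorted(net.nodes)
        disease_in_net = reference & set(nodes)
        # Clusters are scored for enrichment of the biomarker-derived
        # disease proteins S (both diseases pooled unless per_disease);
        # the reference gene list serves as ROC truth in the next stage.
        if config.per_disease:
            disease_sets = {
                "SCZ": seeds.scz & set(nodes),
                "BD": seeds.bd & set(nodes),
            }
        else:
            disease_sets = {"union": seeds.union & set(nodes)}
        enrich_set = frozenset().union(*disease_sets.values())
        sig_by_density: dict[float, list[enrichment.ClusterSignificance]] = {}
        for run in runs:
            sigs = enrichment.score_clusters(
                run, enrich_set, nodes, alpha=config.fdr_cutoff
            )
            run.n_significant = sum(s.significant for s in sigs)
            sig_by_density[run.params.d_in] = sigs
            io.write_tsv(
                outdir / f"clusters_d{run.params.d_in:g}.tsv", dp.clusters_to_frame(run)
            )
            io.write_tsv(
                outdir / f"cluster_significance_d{run.params.d_in:g}.tsv",
                _significance_frame(sigs),
            )
        sweep = dp.summary_table(runs)
        io.write_tsv(outdir / "summary.tsv", sweep)
    except Exception as exc:
        raise PipelineError("cluster", str(exc)) from exc
    report.sweep = sweep.to_dict(orient="records")
    report.counts["reference_genes"] = len(reference)
    report.counts["reference_genes_in_network"] = len(disease_in_net)

    # Stage 4: SScores, ROC per density, density selection.
    try:
        labels = prioritize.truth_labels(nodes, disease_in_net, seeds.union)
        rocs = []
        for run in runs:
            table = prioritize.assign_sscores(
                run, sig_by_density[run.params.d_in], fdr_floor=config.fdr_floor
            )
            io.write_tsv(outdir / f"sscores_d{run.params.d_in:g}.tsv", table.to_frame())
            roc = prioritize.roc_auc(table, labels, density=run.params.d_in)
            io.write_tsv(outdir / f"roc_d{run.params.d_in:g}.tsv",
                         prioritize.roc_to_frame(roc))
            rocs.append(roc)
        selected = prioritize.select_density(rocs)
        io.write_tsv(
            outdir / "auc_summary.tsv",
            _auc_frame(rocs),
        )
    except Exception as exc:
        raise PipelineError("roc", str(exc)) from exc
    report.auc_by_density = {f"{r.density:g}": r.auc for r in rocs}
    report.selected_density = selected
    log.info("roc: selected density %g (AUC %.4f)", selected,
             max(r.auc for r in rocs))

    # Stage 5: pathway enrichment of significant clusters, bipartite ranking.
    try:
        gmt = io.read_gmt(in_paths["pathways"])
        pathway_sets = {name: genes for name, (_, genes) in gmt.items()}
        bg = frozenset().union(*pathway_sets.values()) | set(nodes)
        chosen_run = next(r for r in runs if r.params.d_in == selected)
        chosen_sigs = sig_by_density[selected]
        significant_ids = {s.cluster_id for s in chosen_sigs if s.significant}
        cluster_by_id = {c.id: c for c in chosen_run.clusters}
        all_results = []
        per_cluster = []
        for cid in sorted(significant_ids):
            results = enrichment.enrich_pathways(
                cid, cluster_by_id[cid].nodes, pathway_sets, bg,
                count_min=config.count_min, ease_max=config.ease_max,
                fdr_max=config.fdr_max,
            )
            all_results.extend(results)
            per_cluster.append(pathways.top_k(results, k=config.top_k))
        bipartite = pathways.build_bipartite(per_cluster)
        selected_pathways = pathways.select_pathways(bipartite, min_degree=config.min_degree)
        io.write_tsv(outdir / "pathway_enrichment.tsv", _enrichment_frame(all_results))
        io.write_tsv(outdir / "bipartite_edges.tsv", bipartite.to_frame())
        io.write_tsv(outdir / "pathway_ranking.tsv",
                     pathways.ranking_frame(bipartite, min_degree=config.min_degree))
    except Exception as exc:
        raise PipelineError("pathways", str(exc)) from exc
    report.counts["significant_clusters"] = len(significant_ids)
    report.selected_pathways = [
        {"pathway": p, "degree": d} for p, d in selected_pathways
    ]
    log.info("pathways: %d significant clusters -> %d selected pathways",
             len(significant_ids), len(selected_pathways))

    report.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    report.to_json(outdir / "report.json")
    return report


def summarize_sweep(runs, significances=None):
    """Sweep summary with significant-cluster counts filled in."""
    if significances is not None:
        for run in runs:
            sigs = significances.get(run.params.d_in, [])
            run.n_significant = sum(s.significant for s in sigs)
    return dp.summary_table(runs)


def _significance_frame(sigs):
    import pandas as pd

    return pd.DataFrame(
        [
            (s.cluster_id, s.size, s.k, s.p, s.p_bonferroni, s.fdr, int(s.significant))
            for s in sigs
        ],
        columns=["cluster_id", "size", "k", "p", "bonferroni", "fdr", "significant"],
    )


def _enrichment_frame(results):
    import pandas as pd

    return pd.DataFrame(
        [(r.cluster_id, r.pathway_id, r.count, r.ease_p, r.fdr) for r in results],
        columns=["cluster_id", "pathway", "count", "ease_p", "fdr"],
    )


def _auc_frame(rocs: Sequence[prioritize.RocResult]):
    import pandas as pd

    return pd.DataFrame(
        [(r.density, r.auc, r.n_pos, r.n_neg) for r in rocs],
        columns=["density", "auc", "n_pos", "n_neg"],
    )
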