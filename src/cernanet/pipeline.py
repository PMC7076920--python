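"""End-to-end orchestration: DE screen -> consensus pairs -> network ->
centrality/hubs -> enrichment, from one config with one seed.

The run writes every stage artifact to ``output_dir`` (DE table, consensus
pairs, SIF/GraphML network, centrality and hub tables, enrichment tables)
plus a deterministic ``summary.json`` and a ``run.log``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

from . import diffexpr, enrichment, interactions, network, simulate
from .errors import ContractError, EmptyNetworkError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One full analysis: either file inputs or a simulation, plus thresholds.

    Exactly one of ``input_paths`` / ``simulate`` must be set.  input_paths
    keys: expression, groups, biotype, lnc_mi, mi_mrna_1..3, annotation
    (annotation optional).
    """

    input_paths: dict | None = None
    simulate: simulate.SimulationParams | None = None
    fc_threshold: float = 1.0
    adj_threshold: float = 0.05
    strict_thresholds: bool = True
    enrich_p: float = 0.05
    top_k: int = 40
    closeness_mode: str = "component"
    correlation_filter: bool = False
    n_terms: int = 50
    term_size_range: tuple = (10, 60)
    output_dir: str = "cernanet_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_paths is None) == (self.simulate is None):
            raise ContractError(
                "exactly one of input_paths / simulate must be provided"
            )
        if self.fc_threshold < 0 or not (0 < self.adj_threshold <= 1):
            raise ContractError("invalid DE thresholds")
        if not (0 < self.enrich_p <= 1):
            raise ContractError("enrich_p must lie in (0, 1]")
        if self.top_k < 1:
            raise ContractError("top_k must be >= 1")


@dataclass
class RunSummary:
    """Counts and statistics mirrored from every stage of one run."""

    seed: int = 0
    n_genes: int = 0
    n_samples: int = 0
    de_lnc_up: int = 0
    de_lnc_down: int = 0
    de_mrna_up: int = 0
    de_mrna_down: int = 0
    consensus_pairs: int = 0
    lnc_mi_de_pairs: int = 0
    mi_mrna_de_pairs: int = 0
    network_lnc: int = 0
    network_mirna: int = 0
    network_mrna: int = 0
    network_edges: int = 0
    kruskal_wallis: dict = field(default_factory=dict)
    hubs: list = field(default_factory=list)
    hub_lnc: list = field(default_factory=list)
    hub_mirna: list = field(default_factory=list)
    enriched_terms: int = 0
    stopped_at: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _load_inputs(config: PipelineConfig, outdir: str):
    if config.simulate is not None:
        params = dataclasses.replace(config.simulate, seed=config.seed)
        matrix, _ = simulate.generate_expression(params)
        lnc_mi, cats, _ = simulate.generate_interactions(params)
        annotation = simulate.generate_annotation(
            simulate.mrna_ids(params), config.n_terms,
            tuple(config.term_size_range), params.seed,
        )
        return matrix, lnc_mi, cats, {"annotation": annotation}
    paths = config.input_paths
    matrix = diffexpr.load_expression(
        paths["expression"], paths["groups"], paths["biotype"]
    )
    lnc_mi = interactions.load_interaction_table(paths["lnc_mi"], kind="lnc_mi")
    cats = tuple(
        interactions.load_interaction_table(paths[f"mi_mrna_{i}"], kind="mi_mrna")
        for i in (1, 2, 3)
    )
    annotations = {}
    if paths.get("annotation"):
        annotations["annotation"] = enrichment.load_annotation(paths["annotation"])
    return matrix, lnc_mi, cats, annotations


def run(config: PipelineConfig) -> RunSummary:
    """Execute the five-stage analysis; deterministic given config + seed."""
    outdir = config.output_dir
    os.makedirs(outdir, exist_ok=True)
    log_path = os.path.join(outdir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("cernanet")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary = RunSummary(seed=config.seed)
    try:
        return _run_stages(config, outdir, summary)
    finally:
        _write_summary(summary, outdir)
        root.removeHandler(handler)
        handler.close()


def _run_stages(config: PipelineConfig, outdir: str, summary: RunSummary) -> RunSummary:
    matrix, lnc_mi, cats, annotations = _load_inputs(config, outdir)
    summary.n_genes = len(matrix.gene_ids)
    summary.n_samples = len(matrix.sample_ids)
    logger.info(
        "loaded %d genes x %d samples; %d lnc-mi pairs; catalogues %s",
        summary.n_genes, summary.n_samples, len(lnc_mi),
        [len(c) for c in cats],
    )

    # stage 1: differential expression
    de_table = diffexpr.differential_expression(
        matrix,
        fc_threshold=config.fc_threshold,
        adj_threshold=config.adj_threshold,
        strict=config.strict_thresholds,
    )
    diffexpr.write_de_table(de_table, os.path.join(outdir, "de_table.tsv"))
    de_sets = diffexpr.select_de(
        de_table, config.fc_threshold, config.adj_threshold,
        strict=config.strict_thresholds,
    )
    summary.de_lnc_up = len(de_sets.de_lnc_up)
    summary.de_lnc_down = len(de_sets.de_lnc_down)
    summary.de_mrna_up = len(de_sets.de_mrna_up)
    summary.de_mrna_down = len(de_sets.de_mrna_down)
    logger.info(
        "DE: lncRNA %d up / %d down; mRNA %d up / %d down",
        summary.de_lnc_up, summary.de_lnc_down,
        summary.de_mrna_up, summary.de_mrna_down,
    )

    # stage 2: consensus interactions restricted to DE genes
    consensus = interactions.intersect_catalogues(cats)
    summary.consensus_pairs = len(consensus)
    lnc_mi_de, mi_mrna_de = interactions.restrict_to_de(lnc_mi, consensus, de_sets)
    summary.lnc_mi_de_pairs = len(lnc_mi_de)
    summary.mi_mrna_de_pairs = len(mi_mrna_de)
    simulate.write_interactions(
        consensus, os.path.join(outdir, "consensus_pairs.tsv")
    )
    logger.info(
        "consensus %d pairs; after DE restriction: %d lnc-mi, %d mi-mrna",
        summary.consensus_pairs, summary.lnc_mi_de_pairs, summary.mi_mrna_de_pairs,
    )

    # stage 3: network assembly
    try:
        net = network.assemble(lnc_mi_de, mi_mrna_de)
    except EmptyNetworkError as exc:
        summary.stopped_at = f"empty network: {exc}"
        logger.warning("pipeline stopped: %s", exc)
        return summary
    summary.network_lnc = len(net.lnc_nodes)
    summary.network_mirna = len(net.mi_nodes)
    summary.network_mrna = len(net.mrna_nodes)
    summary.network_edges = net.n_edges
    network.write_sif(net, os.path.join(outdir, "network.sif"))
    network.write_graphml(net, os.path.join(outdir, "network.graphml"))
    logger.info(
        "network: %d lncRNA / %d miRNA / %d mRNA nodes, %d edges",
        summary.network_lnc, summary.network_mirna,
        summary.network_mrna, summary.network_edges,
    )

    # stage 4: topology and hubs
    records = network.centrality_table(net, closeness_mode=config.closeness_mode)
    network.write_centrality_table(records, os.path.join(outdir, "centrality.tsv"))
    kw = network.compare_centrality_by_class(records)
    summary.kruskal_wallis = {
        metric: {"H": h, "p": p} for metric, (h, p) in kw.items()
    }
    hubset = network.consensus_hubs(records, k=config.top_k)
    summary.hubs = sorted(hubset.hubs)
    summary.hub_lnc = sorted(h for h in hubset.hubs if h in net.lnc_nodes)
    summary.hub_mirna = sorted(h for h in hubset.hubs if h in net.mi_nodes)
    network.write_hubs(hubset, records, os.path.join(outdir, "hubs.tsv"))
    logger.info("hubs (top-%d consensus): %s", config.top_k, summary.hubs)

    # stage 5: enrichment of the network's mRNAs
    universe = set(matrix.gene_ids)
    for name, annotation in annotations.items():
        result = enrichment.enrich(
            net.mrna_nodes, annotation, universe, p_threshold=config.enrich_p
        )
        enrichment.write_enrichment(
            result, os.path.join(outdir, f"enrichment_{name}.tsv")
        )
        summary.enriched_terms += len(result)
        logger.info("enrichment '%s': %d terms below p=%g",
                    name, len(result), config.enrich_p)
    return summary


def _write_summary(summary: RunSummary, outdir: str) -> None:
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        fh.write(summary.to_json())
        fh.write("\n")
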