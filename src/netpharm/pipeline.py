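"""End-to-end orchestration: screen -> targets -> PPI -> enrichment -> H-C-T-P.

The pipeline consumes either a file-based input set (see :mod:`netpharm.io`)
or an in-memory :class:`~netpharm.synth.StudyBundle`, applies every stage
with its documented threshold, and emits a run report with the per-stage
record counts (the "funnel"), all artifacts, and a JSON summary. Reruns with
identical inputs and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import pandas as pd

from . import io as npio
from .admet import screen_compounds
from .enrich import enrich, top_k
from .hctp import build_hctp, class_counts, rank_by_degree
from .ppi import KeyTargetCriteria, build_graph, centralities, induced_subgraph_recompute, select_key_targets
from .synth import StudyBundle
from .targets import intersect_targets, select_potential_targets

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "run_on_bundle", "export_network"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage thresholds in one place, defaulting to the documented cut-offs."""

    input_dir: str = "."
    output_dir: str = "out"
    qed_min: float = 0.3
    require_veber: bool = True
    min_probability: float = 0.0
    relevance_cutoff: object = "mean"  # "mean" or float
    ppi_min_score: float = 0.7
    min_degree: int = 10
    min_betweenness: float = 0.001
    min_closeness: float = 0.430
    top_k_pathways: int = 20
    background: int = 20000
    mass_tol_ppm: float = 10.0
    selection: str = "max-tie"
    seed: int = 0

    def criteria(self) -> KeyTargetCriteria:
        return KeyTargetCriteria(self.min_degree, self.min_betweenness, self.min_closeness)


@dataclass
class RunReport:
    """Per-stage record counts and run metadata."""

    counts: dict = field(default_factory=dict)
    key_components: list = field(default_factory=list)
    key_targets: list = field(default_factory=list)
    top_pathways: list = field(default_factory=list)
    cutoffs: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True) + "\n"


@dataclass
class PipelineResult:
    """Full in-memory stage outputs (the report plus every intermediate table)."""

    report: RunReport
    screen: pd.DataFrame
    potential_targets: pd.DataFrame
    centrality_table: pd.DataFrame
    subnetwork: nx.Graph
    subnetwork_centralities: pd.DataFrame
    enrichment: pd.DataFrame
    hctp: nx.Graph
    ranking: pd.DataFrame


def run_on_bundle(bundle: StudyBundle, config: PipelineConfig | None = None) -> PipelineResult:
    """Execute all analysis stages on an in-memory bundle."""
    cfg = config or PipelineConfig()

    # 1. ADMET screen
    verdicts = screen_compounds(bundle.compounds, qed_min=cfg.qed_min)
    if not cfg.require_veber:
        verdicts = verdicts.assign(is_eac=verdicts["qed"] >= cfg.qed_min)
    eac_ids = set(verdicts.loc[verdicts["is_eac"], "compound_id"])
    logger.info("screen: %d/%d compounds are EAC", len(eac_ids), len(verdicts))

    # 2. target intersection + relevance cutoff
    eac_targets = bundle.compound_targets[bundle.compound_targets["compound_id"].isin(eac_ids)]
    intersected = intersect_targets(eac_targets, bundle.disease_genes, min_probability=cfg.min_probability)
    potential = select_potential_targets(intersected, cutoff=cfg.relevance_cutoff)
    logger.info(
        "targets: %d intersected, %d potential (cutoff %.4g)",
        len(intersected), len(potential.members), potential.cutoff_used,
    )

    # 3. PPI topology on the potential-target network
    g_all = build_graph(bundle.ppi_edges, min_score=cfg.ppi_min_score)
    keep = [s for s in potential.symbols if s in g_all]
    g_pot = nx.Graph(g_all.subgraph(keep))
    cent = centralities(g_pot)
    key_targets = select_key_targets(cent, cfg.criteria())
    sub, sub_cent = (
        induced_subgraph_recompute(g_pot, key_targets)
        if key_targets
        else (nx.Graph(), centralities(nx.Graph()))
    )
    logger.info("ppi: %d potential-target nodes, %d key targets", g_pot.number_of_nodes(), len(key_targets))

    # 4. pathway enrichment of the key targets
    if key_targets:
        enr = enrich(key_targets, bundle.pathways, background=cfg.background)
    else:
        enr = pd.DataFrame(
            columns=["pathway_id", "name", "k", "K", "n", "N", "p_value", "fdr", "gene_ratio", "hit_genes"]
        )
    top = top_k(enr, cfg.top_k_pathways)

    # 5. integrated H-C-T-P network
    key_set = set(key_targets)
    ct_edges = [
        (r.compound_id, r.gene_symbol)
        for r in eac_targets.itertuples()
        if r.gene_symbol in key_set and r.probability > cfg.min_probability
    ]
    linked_compounds = {c for c, _ in ct_edges}  # EAC without key-target links are dropped
    herb_map = bundle.compounds.set_index("compound_id")["herbs"]
    hc_edges = []
    for cid in sorted(linked_compounds):
        for h in str(herb_map.loc[cid]).split(";"):
            if h:
                hc_edges.append((h, cid))
    pw_members = {s.pathway_id: set(s.genes) for s in bundle.pathways}
    tp_edges = [
        (t, pid) for pid in top["pathway_id"] for t in sorted(key_set & pw_members[pid])
    ]
    net = build_hctp(hc_edges, ct_edges, tp_edges)
    if linked_compounds:
        ranking = rank_by_degree(net, "compound", top=cfg.selection)
        key_components = ranking.key_components
        rank_df = ranking.ranking
    else:
        key_components, rank_df = [], pd.DataFrame(columns=["node_id", "degree"])

    counts = {
        "collected": int(len(verdicts)),
        "eac": int(len(eac_ids)),
        "intersected": int(len(intersected)),
        "potential_targets": int(len(potential.members)),
        "ppi_nodes": int(g_pot.number_of_nodes()),
        "ppi_edges": int(g_pot.number_of_edges()),
        "key_targets": int(len(key_targets)),
        "pathways_tested": int(len(enr)),
        "pathways_retained": int(len(top)),
        "hctp_nodes": int(net.number_of_nodes()),
        "hctp_edges": int(net.number_of_edges()),
        "hctp_class_counts": class_counts(net),
        "key_components": int(len(key_components)),
    }
    report = RunReport(
        counts=counts,
        key_components=list(key_components),
        key_targets=list(key_targets),
        top_pathways=top["pathway_id"].tolist(),
        cutoffs={
            "qed_min": cfg.qed_min,
            "relevance_cutoff_used": potential.cutoff_used,
            "ppi_min_score": cfg.ppi_min_score,
            "key_target_criteria": [cfg.min_degree, cfg.min_betweenness, cfg.min_closeness],
            "top_k_pathways": cfg.top_k_pathways,
            "background": cfg.background,
        },
        seed=cfg.seed,
    )
    return PipelineResult(
        report=report,
        screen=verdicts,
        potential_targets=potential.members,
        centrality_table=cent,
        subnetwork=sub,
        subnetwork_centralities=sub_cent,
        enrichment=enr,
        hctp=net,
        ranking=rank_df,
    )


def run_pipeline(config: PipelineConfig) -> RunReport:
    """File-based pipeline run: read inputs, execute stages, write all artifacts."""
    indir = Path(config.input_dir)
    for fname in ("compounds.tsv", "compound_targets.tsv", "disease_genes.tsv", "ppi_edges.tsv", "pathways.gmt"):
        if not (indir / fname).exists():
            raise FileNotFoundError(f"pipeline input missing: {indir / fname}")
    bundle = npio.read_bundle(indir) if (indir / "dose_response.csv").exists() else StudyBundle(
        compounds=npio.read_compounds(indir / "compounds.tsv"),
        compound_targets=npio.read_compound_targets(indir / "compound_targets.tsv"),
        disease_genes=npio.read_disease_genes(indir / "disease_genes.tsv"),
        ppi_edges=npio.read_string_edges(indir / "ppi_edges.tsv"),
        pathways=npio.read_gmt(indir / "pathways.gmt"),
        dose_response={},
    )
    res = run_on_bundle(bundle, config)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    res.screen.to_csv(out / "screen.tsv", sep="\t", index=False, float_format="%.6g")
    res.potential_targets.to_csv(out / "potential_targets.tsv", sep="\t", index=False, float_format="%.6g")
    res.centrality_table.to_csv(out / "centralities.tsv", sep="\t", index=False, float_format="%.6g")
    (out / "key_targets.txt").write_text("".join(s + "\n" for s in res.report.key_targets))
    res.enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
    top_k(res.enrichment, config.top_k_pathways)[["pathway_id", "gene_ratio", "k", "p_value"]].to_csv(
        out / "bubble_data.csv", index=False, float_format="%.6g"
    )
    res.ranking.to_csv(out / "ranking.tsv", sep="\t", index=False)
    export_network(res.subnetwork, out / "key_target_subnetwork.sif", "sif")
    export_network(res.hctp, out / "hctp.sif", "sif")
    export_network(res.hctp, out / "hctp.graphml", "graphml")
    (out / "run_report.json").write_text(res.report.to_json())
    return res.report


def export_network(net: nx.Graph, path, format: str) -> None:
    """Write a network as SIF or GraphML (Cytoscape interchange)."""
    if format == "sif":
        npio.export_sif(net, path)
    elif format == "graphml":
        npio.export_graphml(net, path)
    else:
        raise ValueError(f"unknown network format {format!r}")
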