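"""Readers and writers for the pipeline's tabular and network interchange formats.

Tables are TSV/CSV with headers; pathway collections are GMT; networks are
exported as SIF (node TAB interaction TAB node) and GraphML. STRING-style
edge lists may carry combined scores on either the 0-1000 integer or the
0-1 float scale; the dialect is auto-detected and logged.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .doseresponse import DoseResponseSeries
from .enrich import GeneSetCollection
from .synth import StudyBundle, GroundTruth

__all__ = [
    "read_compounds",
    "read_compound_targets",
    "read_disease_genes",
    "read_string_edges",
    "read_gmt",
    "write_gmt",
    "read_dose_response",
    "write_bundle",
    "read_bundle",
    "export_sif",
    "export_graphml",
    "import_sif",
]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


def read_compounds(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_compound_targets(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_disease_genes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_string_edges(path) -> pd.DataFrame:
    """STRING-like edge list; scores normalised to the 0-1 scale."""
    df = pd.read_csv(path, sep="\t")
    need = {"protein1", "protein2", "combined_score"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}, got {list(df.columns)}")
    smax = df["combined_score"].max()
    if smax > 1.0:
        logger.info("%s: combined_score on 0-1000 scale, rescaling to 0-1", path)
        df = df.assign(combined_score=df["combined_score"] / 1000.0)
    else:
        logger.info("%s: combined_score on 0-1 scale", path)
    return df


def read_gmt(path) -> GeneSetCollection:
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{i + 1}: GMT line needs id, description and >= 1 gene")
            records.append((parts[0], parts[1], parts[2:]))
    return GeneSetCollection.from_records(records)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.pathway_id, s.name, *s.genes]) + "\n")


def read_dose_response(path) -> dict[str, DoseResponseSeries]:
    df = pd.read_csv(path)
    out: dict[str, DoseResponseSeries] = {}
    for cid, grp in df.groupby("compound_id", sort=True):
        out[cid] = DoseResponseSeries(
            compound_id=cid,
            concentrations=grp["conc_uM"].to_numpy(float),
            responses=grp["aggregation_pct"].to_numpy(float),
            agonist=grp["agonist"].iloc[0] if "agonist" in grp else "collagen",
        )
    return out


def write_bundle(bundle: StudyBundle, outdir, truth: GroundTruth | None = None) -> dict[str, Path]:
    """Serialize a study bundle as the standard file set; byte-stable for a fixed bundle."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["compounds"] = out / "compounds.tsv"
    bundle.compounds.to_csv(paths["compounds"], sep="\t", index=False, float_format=_FLOAT_FMT)

    paths["compound_targets"] = out / "compound_targets.tsv"
    bundle.compound_targets.to_csv(paths["compound_targets"], sep="\t", index=False, float_format=_FLOAT_FMT)

    paths["disease_genes"] = out / "disease_genes.tsv"
    bundle.disease_genes.to_csv(paths["disease_genes"], sep="\t", index=False, float_format=_FLOAT_FMT)

    paths["ppi_edges"] = out / "ppi_edges.tsv"
    string_like = bundle.ppi_edges.assign(
        combined_score=(bundle.ppi_edges["combined_score"] * 1000).round().astype(int)
    )
    string_like.to_csv(paths["ppi_edges"], sep="\t", index=False)

    paths["pathways"] = out / "pathways.gmt"
    write_gmt(bundle.pathways, paths["pathways"])

    paths["dose_response"] = out / "dose_response.csv"
    rows = []
    for cid in sorted(bundle.dose_response):
        s = bundle.dose_response[cid]
        rep_counter: dict[float, int] = {}
        for c, y in zip(s.concentrations, s.responses):
            rep_counter[c] = rep_counter.get(c, 0) + 1
            rows.append(
                {"compound_id": cid, "agonist": s.agonist, "conc_uM": c,
                 "replicate": rep_counter[c], "aggregation_pct": round(float(y), 4)}
            )
    pd.DataFrame(rows, columns=["compound_id", "agonist", "conc_uM", "replicate", "aggregation_pct"]).to_csv(
        paths["dose_response"], index=False, float_format=_FLOAT_FMT
    )

    if truth is not None:
        paths["ground_truth"] = out / "ground_truth.json"
        with open(paths["ground_truth"], "w") as fh:
            json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")
    return paths


def read_bundle(indir) -> StudyBundle:
    d = Path(indir)
    return StudyBundle(
        compounds=read_compounds(d / "compounds.tsv"),
        compound_targets=read_compound_targets(d / "compound_targets.tsv"),
        disease_genes=read_disease_genes(d / "disease_genes.tsv"),
        ppi_edges=read_string_edges(d / "ppi_edges.tsv"),
        pathways=read_gmt(d / "pathways.gmt"),
        dose_response=read_dose_response(d / "dose_response.csv"),
    )


def export_sif(g: nx.Graph, path, interaction: str = "pp") -> None:
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(map(str, e))) for e in g.edges):
            fh.write(f"{u}\t{interaction}\t{v}\n")


def import_sif(path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                g.add_edge(parts[0], parts[2])
    return g


def export_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)
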