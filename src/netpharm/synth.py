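"""Seeded synthetic study-bundle generator with planted ground truth.

Emulates every input of the network-pharmacology workflow — compound
descriptor tables, compound-target predictions, disease-gene relevance
lists, confidence-scored PPI edge lists, pathway gene sets and replicate
dose-response curves — with known planted signal so every pipeline stage can
be tested end-to-end without any database access:

* *planted key compounds* pass the ADMET screen and are wired to all planted
  hub targets plus the highest-degree interaction partners, so the
  multipartite ranking should recover exactly them as the max-degree tie
  class;
* *planted hub targets* receive extra attachment in the
  preferential-attachment PPI graph, occupy the top of the degree
  distribution, and carry inflated disease relevance scores so they survive
  the mean-relevance cutoff;
* one *planted enriched pathway* contains every planted hub plus the other
  likely key targets, so over-representation analysis should rank it first;
* dose-response series are generated from known 4PL parameters plus
  truncated Gaussian noise.

All randomness flows from a single root seed through named substreams, one
per generated table, so regenerating with the same config is byte-identical
and changing one table leaves the others untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .admet import qed_score, veber_pass
from .doseresponse import DoseResponseSeries, four_pl
from .enrich import GeneSetCollection

__all__ = ["StudyConfig", "GroundTruth", "StudyBundle", "generate_study", "generate_dose_response"]

# fixed substream registry: table name -> child index of the root SeedSequence
_SUBSTREAMS = {
    "herb_assignment": 0,
    "descriptors": 1,
    "relevance": 2,
    "ppi": 3,
    "targets": 4,
    "pathways": 5,
    "dose": 6,
}


def _rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), _SUBSTREAMS[name])))


@dataclass(frozen=True)
class StudyConfig:
    """Sizes, planted-signal counts and noise settings of a synthetic study.

    Defaults mirror the motivating study design: 9 herbs, 119 compounds,
    110 pathways, 4 planted key compounds, n = 4 dose-response replicates.
    """

    n_herbs: int = 9
    n_compounds: int = 119
    n_genes: int = 400  # background gene universe
    n_disease_genes: int = 300
    n_pathways: int = 110
    pathway_size_range: tuple[int, int] = (10, 40)
    n_planted_key_compounds: int = 4
    n_planted_hub_targets: int = 5
    frac_fail_qed: float = 0.1
    frac_fail_veber: float = 0.1
    relevance_score_distribution: tuple[str, dict] = ("lognormal", {"mu": 0.0, "sigma": 1.0})
    ppi_model: tuple[str, dict] = ("preferential_attachment", {"m": 3, "hub_extra_frac": 0.3})
    seed: int = 0

    def __post_init__(self):
        for name in ("n_herbs", "n_compounds", "n_genes", "n_disease_genes", "n_pathways"):
            if getattr(self, name) < 1:
                raise ValueError(f"config field {name} must be >= 1, got {getattr(self, name)}")
        for name in ("n_planted_key_compounds", "n_planted_hub_targets"):
            if getattr(self, name) < 0:
                raise ValueError(f"config field {name} must be >= 0")
        for name in ("frac_fail_qed", "frac_fail_veber"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"config field {name} must lie in [0, 1], got {v}")
        if self.n_planted_key_compounds > self.n_compounds:
            raise ValueError("config field n_planted_key_compounds exceeds n_compounds")
        if self.n_planted_hub_targets > self.n_disease_genes:
            raise ValueError("config field n_planted_hub_targets exceeds n_disease_genes")
        if self.n_disease_genes > self.n_genes:
            raise ValueError("config field n_disease_genes exceeds n_genes")
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi <= self.n_genes):
            raise ValueError("config field pathway_size_range must satisfy 1 <= lo <= hi <= n_genes")
        n_fail = int(self.frac_fail_qed * self.n_compounds) + int(self.frac_fail_veber * self.n_compounds)
        if self.n_planted_key_compounds + n_fail > self.n_compounds:
            raise ValueError("config field frac_fail_*: fail fractions plus planted compounds exceed n_compounds")


@dataclass
class GroundTruth:
    planted_key_compound_ids: list[str]
    planted_hub_target_symbols: list[str]
    planted_enriched_pathway_id: str
    true_ic50_per_compound: dict[str, float]
    true_hill_params: dict[str, tuple[float, float, float]]  # bottom %, top %, slope

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class StudyBundle:
    """All generated study tables, in-memory (see io module for the file forms)."""

    compounds: pd.DataFrame  # compound_id, name, herbs, smiles, 8 descriptors
    compound_targets: pd.DataFrame  # compound_id, gene_symbol, probability
    disease_genes: pd.DataFrame  # gene_symbol, relevance_score
    ppi_edges: pd.DataFrame  # protein1, protein2, combined_score (0-1)
    pathways: GeneSetCollection
    dose_response: dict[str, DoseResponseSeries]


def generate_dose_response(
    params: tuple[float, float, float, float],
    concentrations,
    n_reps: int,
    noise_sd: float,
    seed: int,
    compound_id: str = "CMP",
) -> DoseResponseSeries:
    """Replicate 4PL measurements with additive Gaussian noise, truncated to [0, 100].

    ``params`` is (bottom %, top %, ic50 uM, slope).
    """
    bottom, top, ic50, slope = params
    conc = np.asarray(concentrations, dtype=float)
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    c_rep = np.repeat(conc, n_reps)
    y = four_pl(c_rep, bottom, top, ic50, slope)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    y = np.clip(y, 0.0, 100.0)
    return DoseResponseSeries(compound_id=compound_id, concentrations=c_rep, responses=y)


def _sample_pass_descriptors(rng: np.random.Generator) -> dict:
    """Descriptors comfortably inside drug-like space (QED >= 0.3, Veber TRUE)."""
    while True:
        d = {
            "MW": round(float(rng.uniform(220, 420)), 2),
            "ALOGP": round(float(rng.uniform(0.5, 3.5)), 2),
            "HBA": int(rng.integers(2, 8)),
            "HBD": int(rng.integers(0, 4)),
            "PSA": round(float(rng.uniform(40, 100)), 2),
            "ROTB": int(rng.integers(1, 8)),
            "AROM": int(rng.integers(1, 4)),
            "ALERT": 0,
        }
        if qed_score(d) >= 0.32 and veber_pass(d):
            return d


def _sample_fail_qed_descriptors(rng: np.random.Generator) -> dict:
    """Grossly non-drug-like (huge MW/ALOGP, many alerts) yet Veber-passing."""
    while True:
        d = {
            "MW": round(float(rng.uniform(900, 1200)), 2),
            "ALOGP": round(float(rng.uniform(7, 9)), 2),
            "HBA": int(rng.integers(2, 7)),
            "HBD": int(rng.integers(0, 4)),
            "PSA": round(float(rng.uniform(40, 100)), 2),
            "ROTB": int(rng.integers(1, 8)),
            "AROM": int(rng.integers(5, 8)),
            "ALERT": int(rng.integers(6, 11)),
        }
        if qed_score(d) < 0.3 and veber_pass(d):
            return d


def _sample_fail_veber_descriptors(rng: np.random.Generator) -> dict:
    d = _sample_pass_descriptors(rng)
    mode = rng.integers(0, 3)
    if mode == 0:
        d["ROTB"] = int(rng.integers(11, 17))
    elif mode == 1:
        d["PSA"] = round(float(rng.uniform(150, 220)), 2)
    else:
        d["HBA"], d["HBD"] = 9, 5
    return d


def generate_study(config: StudyConfig) -> tuple[StudyBundle, GroundTruth]:
    """Generate a complete synthetic study bundle with recorded ground truth."""
    cfg = config
    seed = cfg.seed

    herbs = [f"HERB{i + 1:02d}" for i in range(cfg.n_herbs)]
    compound_ids = [f"CMP{i + 1:03d}" for i in range(cfg.n_compounds)]
    genes = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]

    # --- partition compounds into planted / fail-QED / fail-Veber / plain pass
    rng_h = _rng(seed, "herb_assignment")
    order = rng_h.permutation(cfg.n_compounds)
    n_p = cfg.n_planted_key_compounds
    n_fq = int(cfg.frac_fail_qed * cfg.n_compounds)
    n_fv = int(cfg.frac_fail_veber * cfg.n_compounds)
    planted_idx = set(order[:n_p].tolist())
    fail_qed_idx = set(order[n_p : n_p + n_fq].tolist())
    fail_veber_idx = set(order[n_p + n_fq : n_p + n_fq + n_fv].tolist())
    planted_compounds = sorted(compound_ids[i] for i in planted_idx)

    rng_d = _rng(seed, "descriptors")
    comp_rows = []
    for i, cid in enumerate(compound_ids):
        if i in fail_qed_idx:
            desc = _sample_fail_qed_descriptors(rng_d)
        elif i in fail_veber_idx:
            desc = _sample_fail_veber_descriptors(rng_d)
        else:
            desc = _sample_pass_descriptors(rng_d)
        herb = herbs[int(rng_h.integers(0, cfg.n_herbs))]
        comp_rows.append({"compound_id": cid, "name": cid.lower(), "herbs": herb, "smiles": "", **desc})
    compounds = pd.DataFrame(comp_rows)

    # --- disease genes with lognormal relevance scores
    rng_r = _rng(seed, "relevance")
    disease_symbols = sorted(rng_r.choice(genes, size=cfg.n_disease_genes, replace=False).tolist())
    dist_name, dist_params = cfg.relevance_score_distribution
    if dist_name == "lognormal":
        scores = rng_r.lognormal(dist_params.get("mu", 0.0), dist_params.get("sigma", 1.0), cfg.n_disease_genes)
    elif dist_name == "uniform":
        scores = rng_r.uniform(dist_params.get("low", 0.0), dist_params.get("high", 10.0), cfg.n_disease_genes)
    else:
        raise ValueError(f"unknown relevance_score_distribution {dist_name!r}")
    scores = np.round(scores, 4)

    # --- PPI over the disease genes: preferential attachment + planted hubs
    model_name, model_params = cfg.ppi_model
    if model_name != "preferential_attachment":
        raise ValueError(f"unknown ppi_model {model_name!r}")
    rng_p = _rng(seed, "ppi")
    D = cfg.n_disease_genes
    m = min(model_params.get("m", 3), max(D - 1, 1))
    g = nx.barabasi_albert_graph(D, m, seed=int(rng_p.integers(0, 2**31 - 1)))
    hub_nodes = sorted(rng_p.choice(D, size=cfg.n_planted_hub_targets, replace=False).tolist())
    extra = int(np.ceil(model_params.get("hub_extra_frac", 0.3) * D))
    for h in hub_nodes:
        others = [x for x in range(D) if x != h]
        for t in rng_p.choice(others, size=min(extra, len(others)), replace=False):
            g.add_edge(h, int(t))
    ppi_rows = []
    for u, v in sorted(tuple(sorted(e)) for e in g.edges):
        score = round(float(rng_p.uniform(0.70, 0.999)), 3)
        ppi_rows.append({"protein1": disease_symbols[u], "protein2": disease_symbols[v], "combined_score": score})
    ppi_edges = pd.DataFrame(ppi_rows)

    hub_symbols = sorted(disease_symbols[h] for h in hub_nodes)

    # likely key targets: planted hubs plus the highest-degree attachment nodes
    deg = dict(g.degree)
    non_hub_by_degree = sorted((n for n in g.nodes if n not in hub_nodes), key=lambda n: (-deg[n], n))
    n_extra_signal = max(0, 12 - cfg.n_planted_hub_targets)
    signal_nodes = hub_nodes + non_hub_by_degree[:n_extra_signal]
    signal_symbols = [disease_symbols[n] for n in signal_nodes]

    # inflate signal-gene relevance so the mean cutoff always retains them
    q90 = float(np.quantile(scores, 0.9))
    sym_to_idx = {s: i for i, s in enumerate(disease_symbols)}
    for s in signal_symbols:
        scores[sym_to_idx[s]] = round(q90 * float(rng_r.uniform(1.5, 3.0)), 4)
    disease_genes = pd.DataFrame({"gene_symbol": disease_symbols, "relevance_score": scores})

    # --- compound -> target predictions
    rng_t = _rng(seed, "targets")
    tgt_rows = []
    for i, cid in enumerate(compound_ids):
        if i in planted_idx:
            chosen = list(signal_symbols)
            extra_n = int(rng_t.integers(1, 4))
            chosen += rng_t.choice(genes, size=extra_n, replace=False).tolist()
            probs = rng_t.uniform(0.7, 1.0, len(chosen))
        else:
            n_t = int(rng_t.integers(2, 7))
            chosen = rng_t.choice(genes, size=n_t, replace=False).tolist()
            probs = rng_t.uniform(0.05, 0.95, len(chosen))
        for sym, pr in zip(chosen, probs):
            tgt_rows.append({"compound_id": cid, "gene_symbol": sym, "probability": round(float(pr), 4)})
    compound_targets = pd.DataFrame(tgt_rows).drop_duplicates(subset=["compound_id", "gene_symbol"])

    # --- pathways: one planted enriched set containing the signal genes
    rng_w = _rng(seed, "pathways")
    lo, hi = cfg.pathway_size_range
    planted_pw_idx = int(rng_w.integers(0, cfg.n_pathways))
    records = []
    for j in range(cfg.n_pathways):
        pid = f"PW{j + 1:03d}"
        size = int(rng_w.integers(lo, hi + 1))
        if j == planted_pw_idx:
            members = list(signal_symbols)
            n_fill = max(size, len(members) + 3) - len(members)
            pool = [x for x in genes if x not in set(members)]
            members += rng_w.choice(pool, size=min(n_fill, len(pool)), replace=False).tolist()
        else:
            members = rng_w.choice(genes, size=size, replace=False).tolist()
        records.append((pid, f"pathway {j + 1}", members))
    pathways = GeneSetCollection.from_records(records)
    planted_pw_id = f"PW{planted_pw_idx + 1:03d}"

    # --- dose-response for the planted key compounds
    rng_dose = _rng(seed, "dose")
    conc_grid = np.round(np.geomspace(1.0, 100.0, 6), 3)
    dose: dict[str, DoseResponseSeries] = {}
    true_ic50: dict[str, float] = {}
    true_hill: dict[str, tuple[float, float, float]] = {}
    for cid in planted_compounds:
        bottom = round(float(rng_dose.uniform(0, 8)), 2)
        top = round(float(rng_dose.uniform(75, 92)), 2)
        ic50 = round(float(rng_dose.lognormal(np.log(30.0), 0.4)), 2)
        slope = round(float(rng_dose.uniform(1.0, 2.2)), 2)
        sub_seed = int(rng_dose.integers(0, 2**31 - 1))
        dose[cid] = generate_dose_response(
            (bottom, top, ic50, slope), conc_grid, n_reps=4, noise_sd=2.0, seed=sub_seed, compound_id=cid
        )
        true_ic50[cid] = ic50
        true_hill[cid] = (bottom, top, slope)

    bundle = StudyBundle(
        compounds=compounds,
        compound_targets=compound_targets.reset_index(drop=True),
        disease_genes=disease_genes,
        ppi_edges=ppi_edges,
        pathways=pathways,
        dose_response=dose,
    )
    truth = GroundTruth(
        planted_key_compound_ids=planted_compounds,
        planted_hub_target_symbols=hub_symbols,
        planted_enriched_pathway_id=planted_pw_id,
        true_ic50_per_compound=true_ic50,
        true_hill_params=true_hill,
    )
    return bundle, truth
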