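"""Pathway over-representation analysis with BH-FDR control.

For a query gene set (the key targets) and a collection of pathway gene
sets, each pathway's overlap is scored with the one-sided hypergeometric
tail P[X >= k] (Fisher's exact over-representation test); the EASE variant
(tail evaluated at k-1) is available by flag. Raw p-values are corrected
with Benjamini-Hochberg step-up FDR, and results are ranked by ascending p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["GeneSet", "GeneSetCollection", "hypergeom_p", "bh_fdr", "enrich", "top_k"]


@dataclass(frozen=True)
class GeneSet:
    pathway_id: str
    name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"pathway {self.pathway_id} has no members")


@dataclass
class GeneSetCollection:
    """Ordered collection of pathway gene sets (GMT-style)."""

    sets: list[GeneSet] = field(default_factory=list)

    @classmethod
    def from_records(cls, records) -> "GeneSetCollection":
        """records: iterable of (pathway_id, name, member iterable); members deduplicated."""
        sets = []
        for pid, name, genes in records:
            dedup = tuple(dict.fromkeys(genes))
            sets.append(GeneSet(pid, name, dedup))
        return cls(sets)

    def __iter__(self):
        return iter(self.sets)

    def __len__(self):
        return len(self.sets)

    @property
    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets:
            out.update(s.genes)
        return out


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """One-sided over-representation tail P[X >= k], X ~ Hypergeometric(N, K, n).

    ``k`` overlap, ``K`` pathway size, ``n`` query size, ``N`` background size.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N and K >= 0 and n >= 0):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(query, collection: GeneSetCollection, background=20000, ease: bool = False) -> pd.DataFrame:
    """Over-representation of ``query`` genes in each pathway of ``collection``.

    Parameters
    ----------
    query
        Gene symbols (order and duplicates irrelevant).
    background
        Either an integer background size N, or an explicit background symbol
        list (query and pathways are then restricted to it).
    ease
        Use the conservative EASE score (tail at k-1) instead of the plain
        hypergeometric tail.

    Returns
    -------
    pandas.DataFrame
        One row per pathway with k >= 1; columns ``pathway_id, name, k, K, n,
        N, p_value, fdr, gene_ratio, hit_genes``; ranked by ascending p,
        ties broken by descending k then pathway_id.
    """
    qset = set(dict.fromkeys(query))
    if not qset:
        raise ValueError("query gene set is empty")
    if isinstance(background, (int, np.integer)):
        N = int(background)
        restrict = None
    else:
        restrict = set(background)
        N = len(restrict)
        qset &= restrict
        if not qset:
            raise ValueError("query has no genes in the background")
    pathway_genes = collection.all_genes if restrict is None else collection.all_genes & restrict
    universe_needed = len(pathway_genes | qset)
    if N < universe_needed:
        raise ValueError(f"background N={N} smaller than observed universe ({universe_needed})")
    n = len(qset)
    rows = []
    for s in collection:
        members = set(s.genes) if restrict is None else set(s.genes) & restrict
        K = len(members)
        hits = sorted(qset & members)
        k = len(hits)
        if k == 0:
            continue
        p = hypergeom_p(max(k - 1, 0) if ease else k, K, n, N)
        rows.append(
            {
                "pathway_id": s.pathway_id,
                "name": s.name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": p,
                "gene_ratio": k / n,
                "hit_genes": ";".join(hits),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["pathway_id", "name", "k", "K", "n", "N", "p_value", "fdr", "gene_ratio", "hit_genes"]
        )
    df = pd.DataFrame(rows)
    df["fdr"] = bh_fdr(df["p_value"].to_numpy())
    df["_negk"] = -df["k"]
    df = df.sort_values(["p_value", "_negk", "pathway_id"], kind="mergesort").drop(columns="_negk")
    cols = ["pathway_id", "name", "k", "K", "n", "N", "p_value", "fdr", "gene_ratio", "hit_genes"]
    return df[cols].reset_index(drop=True)


def top_k(results: pd.DataFrame, k: int = 20) -> pd.DataFrame:
    """First ``k`` ranked enrichment results (or all, if fewer)."""
    return results.head(k).reset_index(drop=True)
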