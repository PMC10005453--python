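"""Target intersection and potential-target selection.

Predicted compound targets (gene symbols with prediction probabilities) are
intersected with a disease gene list carrying relevance scores; genes at or
above a relevance cutoff — either explicit or the arithmetic mean of the
intersected scores — are retained as potential targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "normalize_symbols",
    "intersect_targets",
    "select_potential_targets",
    "PotentialTargetSet",
]

logger = logging.getLogger(__name__)


def normalize_symbols(symbols) -> list[str]:
    """Uppercase and trim gene symbols, dropping duplicates (first occurrence wins).

    Symbols that are empty after trimming are dropped with a logged warning.
    """
    out: list[str] = []
    seen: set[str] = set()
    for s in symbols:
        t = str(s).strip().upper()
        if not t:
            logger.warning("dropping empty gene symbol %r", s)
            continue
        if t not in seen:
            seen.add(t)
            out.append(t)
    return out


@dataclass
class PotentialTargetSet:
    """Retained disease genes with the cutoff that produced them."""

    members: pd.DataFrame  # columns: gene_symbol, relevance_score
    cutoff_used: float

    @property
    def symbols(self) -> list[str]:
        return self.members["gene_symbol"].tolist()


def intersect_targets(
    predicted: pd.DataFrame,
    disease: pd.DataFrame,
    min_probability: float = 0.0,
) -> pd.DataFrame:
    """Genes predicted as compound targets that are also disease-related.

    Parameters
    ----------
    predicted
        Columns ``compound_id, gene_symbol, probability``. Rows with
        probability <= ``min_probability`` are excluded first (the
        "false-positive" filter; default keeps everything with probability > 0).
    disease
        Columns ``gene_symbol, relevance_score``.

    Returns
    -------
    pandas.DataFrame
        One row per intersected gene, carrying the disease relevance score,
        in disease-list order.
    """
    kept = predicted.loc[predicted["probability"] > min_probability, "gene_symbol"]
    pred_symbols = set(normalize_symbols(kept))
    dis = disease.copy()
    dis["gene_symbol"] = dis["gene_symbol"].astype(str).str.strip().str.upper()
    dis = dis.drop_duplicates(subset="gene_symbol", keep="first")
    out = dis[dis["gene_symbol"].isin(pred_symbols)].reset_index(drop=True)
    return out[["gene_symbol", "relevance_score"]]


def select_potential_targets(scored: pd.DataFrame, cutoff="mean") -> PotentialTargetSet:
    """Retain genes with relevance score >= cutoff (inclusive).

    ``cutoff="mean"`` uses the arithmetic mean of the input scores, mirroring
    the common practice of thresholding at the average relevance.
    """
    if cutoff == "mean":
        if len(scored) == 0:
            raise ValueError("cannot take mean cutoff of an empty gene list")
        cut = float(scored["relevance_score"].mean())
    else:
        cut = float(cutoff)
    members = scored[scored["relevance_score"] >= cut].reset_index(drop=True)
    return PotentialTargetSet(members=members, cutoff_used=cut)
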