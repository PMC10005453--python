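"""Drug-likeness (QED) and oral-bioavailability (Veber) screening.

The quantitative estimate of drug-likeness (QED) maps eight physicochemical
descriptors — molecular weight (MW), octanol-water partition coefficient
(ALOGP), hydrogen-bond acceptor and donor counts (HBA, HBD), polar surface
area (PSA), rotatable-bond count (ROTB), aromatic-ring count (AROM) and
structural-alert count (ALERT) — through asymmetric double-sigmoid
desirability functions fitted to the property distributions of approved oral
drugs, and combines them as a (optionally weighted) geometric mean in (0, 1].

Veber's rule is a hard oral-bioavailability filter: ROTB <= 10,
HBA + HBD <= 12 and PSA <= 140 A^2, all boundaries inclusive.

A compound passing both (QED >= 0.3 and Veber TRUE by default) is an
Expected Active Compound (EAC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "QED_PROPERTIES",
    "QED_WEIGHTS_MEAN",
    "ads_desirability",
    "qed_score",
    "veber_pass",
    "screen_compounds",
]

#: The eight QED descriptors, in canonical order.
QED_PROPERTIES = ("MW", "ALOGP", "HBA", "HBD", "PSA", "ROTB", "AROM", "ALERT")


@dataclass(frozen=True)
class _ADSParams:
    """Asymmetric double-sigmoid parameters: a + b * s1(x) * (1 - s2(x)), max-normalised by dmax."""

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float
    dmax: float


# Published ADS parameter table for the eight descriptors (versioned constants;
# no fitting is performed at runtime).
ADS_PARAMS: dict[str, _ADSParams] = {
    "MW": _ADSParams(2.817065973, 392.5754953, 290.7489764, 2.419764353, 49.22325677, 65.37051707, 104.9805561),
    "ALOGP": _ADSParams(3.172690585, 137.8624751, 2.534937431, 4.581497897, 0.822739154, 0.576295591, 131.3186604),
    "HBA": _ADSParams(2.948620388, 160.4605972, 3.615294657, 4.435986202, 0.290141953, 1.300669958, 148.7763046),
    "HBD": _ADSParams(1.618662227, 1010.051101, 0.985094388, 1e-09, 0.713820843, 0.920922555, 258.1632616),
    "PSA": _ADSParams(1.876861559, 125.2232657, 62.90773554, 87.83366614, 12.01999824, 28.51324732, 104.5686167),
    "ROTB": _ADSParams(0.01, 272.4121427, 2.55837997, 1.565547684, 1.271567166, 2.758063707, 105.4420403),
    "AROM": _ADSParams(3.21778897, 957.7374108, 2.274627939, 1e-09, 1.317690384, 0.375760881, 312.337261),
    "ALERT": _ADSParams(0.01, 1199.094025, -0.09002883, 1e-09, 0.185904477, 0.875193782, 417.725314),
}

#: Published mean-optimal QED weights (selectable alternative to the
#: unweighted geometric mean).
QED_WEIGHTS_MEAN: dict[str, float] = {
    "MW": 0.66,
    "ALOGP": 0.46,
    "HBA": 0.05,
    "HBD": 0.61,
    "PSA": 0.06,
    "ROTB": 0.65,
    "AROM": 0.48,
    "ALERT": 0.95,
}


def ads_desirability(property_name: str, x: float) -> float:
    """Max-normalised asymmetric double-sigmoid desirability of descriptor value ``x``.

    Parameters
    ----------
    property_name
        One of :data:`QED_PROPERTIES`.
    x
        Finite descriptor value.

    Returns
    -------
    float
        Desirability in (0, 1]; 1 at the function's mode.
    """
    try:
        p = ADS_PARAMS[property_name]
    except KeyError:
        raise ValueError(
            f"unknown descriptor {property_name!r}; expected one of {QED_PROPERTIES}"
        ) from None
    if not math.isfinite(x):
        raise ValueError(f"descriptor {property_name} must be finite, got {x!r}")
    s1 = 1.0 / (1.0 + math.exp(-(x - p.c + p.d / 2.0) / p.e))
    s2 = 1.0 / (1.0 + math.exp(-(x - p.c - p.d / 2.0) / p.f))
    val = (p.a + p.b * s1 * (1.0 - s2)) / p.dmax
    # a > 0 for every property keeps the desirability strictly positive, but
    # guard against underflow so log() downstream is always defined
    return max(val, 1e-300)


def _as_descriptor_mapping(desc) -> Mapping[str, float]:
    if isinstance(desc, Mapping):
        return desc
    if isinstance(desc, pd.Series):
        return desc.to_dict()
    raise TypeError("descriptors must be a mapping or pandas Series with the 8 QED keys")


def qed_score(desc: Mapping[str, float], weights="unweighted") -> float:
    """QED of a descriptor vector: exp(sum w_i ln d_i / sum w_i).

    ``weights`` may be ``"unweighted"`` (geometric mean), ``"mean"`` (the
    published mean-optimal weight set) or a mapping property -> non-negative
    weight, not all zero.
    """
    desc = _as_descriptor_mapping(desc)
    missing = [p for p in QED_PROPERTIES if p not in desc]
    if missing:
        raise ValueError(f"descriptor vector missing {missing}")
    if weights == "unweighted":
        w = {p: 1.0 for p in QED_PROPERTIES}
    elif weights == "mean":
        w = QED_WEIGHTS_MEAN
    else:
        w = dict(weights)
        if any(v < 0 for v in w.values()) or sum(w.values()) <= 0:
            raise ValueError("weights must be non-negative and not all zero")
    total = sum(w.get(p, 0.0) for p in QED_PROPERTIES)
    acc = 0.0
    for p in QED_PROPERTIES:
        x = float(desc[p])
        if not math.isfinite(x):
            raise ValueError(f"descriptor {p} must be finite, got {x!r}")
        acc += w.get(p, 0.0) * math.log(ads_desirability(p, x))
    return math.exp(acc / total)


def veber_pass(desc: Mapping[str, float]) -> bool:
    """Veber oral-bioavailability verdict: ROTB <= 10, HBA + HBD <= 12, PSA <= 140.

    All three boundaries are inclusive.
    """
    desc = _as_descriptor_mapping(desc)
    return (
        float(desc["ROTB"]) <= 10
        and float(desc["HBA"]) + float(desc["HBD"]) <= 12
        and float(desc["PSA"]) <= 140
    )


def screen_compounds(
    compounds: pd.DataFrame,
    qed_min: float = 0.3,
    weights="unweighted",
) -> pd.DataFrame:
    """Score every compound and flag Expected Active Compounds.

    Parameters
    ----------
    compounds
        One row per compound with a unique ``compound_id`` column and the
        eight descriptor columns of :data:`QED_PROPERTIES`.
    qed_min
        QED cutoff (inclusive) for the EAC verdict; default 0.3.

    Returns
    -------
    pandas.DataFrame
        Columns ``compound_id, qed, veber_ok, is_eac`` in input order.
    """
    if compounds["compound_id"].duplicated().any():
        dupes = compounds.loc[compounds["compound_id"].duplicated(), "compound_id"].tolist()
        raise ValueError(f"duplicate compound ids: {dupes}")
    rows = []
    for _, rec in compounds.iterrows():
        q = qed_score(rec, weights=weights)
        v = veber_pass(rec)
        rows.append(
            {
                "compound_id": rec["compound_id"],
                "qed": q,
                "veber_ok": v,
                "is_eac": bool(q >= qed_min and v),
            }
        )
    out = pd.DataFrame(rows, columns=["compound_id", "qed", "veber_ok", "is_eac"])
    return out
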