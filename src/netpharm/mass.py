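"""Monoisotopic mass, adduct m/z and ppm-error peak matching.

Implements the arithmetic behind "Find by Formula" style identification in
negative-mode ESI: the calculated m/z of the deprotonated molecular ion
[M-H]- is the monoisotopic mass minus one *neutral* hydrogen atom
(1.0078250319 Da); the electron-mass correction (+m_e for an anion) is off
by default, matching the convention of most instrument software, and can be
enabled per call.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "MONOISOTOPIC_MASS",
    "parse_formula",
    "formula_to_string",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "match_peaks",
]

#: Monoisotopic (most-abundant-isotope) atomic masses, Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
    "F": 18.99840322,
    "Cl": 34.96885271,
    "Br": 78.9183376,
    "I": 126.904468,
    "Na": 22.98976928,
    "K": 38.9637069,
}

ELECTRON_MASS = 0.00054857990907  # Da

_H_ATOM = MONOISOTOPIC_MASS["H"]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse a Hill-notation molecular formula into an element -> count map.

    >>> parse_formula("C15H10O5")
    {'C': 15, 'H': 10, 'O': 5}
    """
    s = text.strip()
    if not s:
        raise ValueError("empty formula")
    pos = 0
    counts: dict[str, int] = {}
    for m in _TOKEN.finditer(s):
        if m.start() != pos:
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        el, num = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element {el!r} in formula {text!r}")
        n = int(num) if num else 1
        if n <= 0:
            raise ValueError(f"non-positive count for {el} in {text!r}")
        counts[el] = counts.get(el, 0) + n
        pos = m.end()
    if pos != len(s):
        raise ValueError(f"malformed formula {text!r} at position {pos}")
    return counts


def formula_to_string(f: dict[str, int]) -> str:
    """Serialize in Hill order: C, H, then remaining elements alphabetically."""
    order = [el for el in ("C", "H") if el in f] + sorted(k for k in f if k not in ("C", "H"))
    return "".join(f"{el}{f[el] if f[el] != 1 else ''}" for el in order)


def monoisotopic_mass(f: dict[str, int] | str) -> float:
    """Sum of most-abundant-isotope masses; accepts a formula string or map."""
    if isinstance(f, str):
        f = parse_formula(f)
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in f.items())


def adduct_mz(f: dict[str, int] | str, adduct: str = "[M-H]-", electron_correction: bool = False) -> float:
    """Calculated m/z of an adduct ion of formula ``f``.

    Only the deprotonated ion ``[M-H]-`` is registered: monoisotopic mass
    minus one neutral hydrogen atom; with ``electron_correction`` the mass
    of the extra electron is added.
    """
    if isinstance(f, str):
        f = parse_formula(f)
    if adduct != "[M-H]-":
        raise ValueError(f"unsupported adduct {adduct!r}")
    if f.get("H", 0) < 1:
        raise ValueError("[M-H]- requires at least one hydrogen")
    mz = monoisotopic_mass(f) - _H_ATOM
    if electron_correction:
        mz += ELECTRON_MASS
    return mz


def ppm_error(observed: float, calculated: float) -> float:
    """Signed mass error in parts per million: (obs - calc)/calc * 1e6."""
    if calculated <= 0:
        raise ValueError("calculated m/z must be positive")
    return (observed - calculated) / calculated * 1e6


def match_peaks(peaks, candidates, tol_ppm: float, adduct: str = "[M-H]-") -> pd.DataFrame:
    """Match observed peaks to candidate formulas within a ppm tolerance.

    Parameters
    ----------
    peaks
        Iterable of ``(rt_min, observed_mz)``.
    candidates
        Iterable of ``(name, formula)`` with formula as string or element map.
    tol_ppm
        Symmetric tolerance, > 0.

    Returns
    -------
    pandas.DataFrame
        One row per (peak, candidate) pair within tolerance, plus one row
        with name NaN for each unmatched peak. Columns: ``rt_min,
        observed_mz, name, formula, calculated_mz, error_ppm``.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    cand = []
    for name, f in candidates:
        fmap = parse_formula(f) if isinstance(f, str) else dict(f)
        cand.append((name, formula_to_string(fmap), adduct_mz(fmap, adduct)))
    rows = []
    for rt, mz in peaks:
        hit = False
        for name, fstr, calc in cand:
            err = ppm_error(mz, calc)
            if abs(err) <= tol_ppm:
                rows.append(
                    {"rt_min": rt, "observed_mz": mz, "name": name,
                     "formula": fstr, "calculated_mz": calc, "error_ppm": err}
                )
                hit = True
        if not hit:
            rows.append(
                {"rt_min": rt, "observed_mz": mz, "name": None,
                 "formula": None, "calculated_mz": None, "error_ppm": None}
            )
    return pd.DataFrame(rows, columns=["rt_min", "observed_mz", "name", "formula", "calculated_mz", "error_ppm"])
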