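"""Elemental formulas and natural-abundance isotopologue arithmetic.

Nominal-mass bookkeeping only: each element contributes a per-atom
distribution over integer mass shifts (0 for the lightest isotope, +1 for
one extra neutron, ...). Molecular distributions are convolution powers of
the per-atom distributions. This is the standard model behind natural
abundance correction of GC-MS mass isotopomer data.
"""

from __future__ import annotations

import re

import numpy as np

__all__ = [
    "NATURAL_ABUNDANCE",
    "parse_formula",
    "formula_to_string",
    "carbon_count",
    "atom_shift_distribution",
    "natural_shift_distribution",
    "convolve_power",
]

# Per-atom probability of each nominal mass shift (index = shift in Da).
# Editable in one place; values are IUPAC representative isotopic
# compositions, with 13C kept at 0.0107.
NATURAL_ABUNDANCE: dict[str, tuple[float, ...]] = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
    "Si": (0.92223, 0.04685, 0.03092),
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str | dict[str, int]) -> dict[str, int]:
    """Parse a Hill-style formula string ("C16H34O2") into element counts.

    Dicts pass through (after validation). Counts must be non-negative.
    """
    if isinstance(formula, dict):
        counts = dict(formula)
    else:
        counts = {}
        pos = 0
        for match in _FORMULA_RE.finditer(formula):
            if match.start() != pos:
                raise ValueError(f"unparsable formula {formula!r} at position {pos}")
            if not match.group(0):
                break
            element, digits = match.groups()
            counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
            pos = match.end()
        if pos != len(formula):
            raise ValueError(f"unparsable formula {formula!r} at position {pos}")
    for element, n in counts.items():
        if n < 0:
            raise ValueError(f"negative atom count for {element}")
    return {e: n for e, n in counts.items() if n > 0}


def formula_to_string(counts: dict[str, int]) -> str:
    return "".join(f"{e}{n if n != 1 else ''}" for e, n in sorted(counts.items()))


def carbon_count(formula: str | dict[str, int]) -> int:
    return parse_formula(formula).get("C", 0)


def atom_shift_distribution(element: str) -> np.ndarray:
    try:
        return np.asarray(NATURAL_ABUNDANCE[element], dtype=float)
    except KeyError:
        raise ValueError(
            f"no natural-abundance data for element {element!r}; "
            f"supported: {sorted(NATURAL_ABUNDANCE)}"
        ) from None


def convolve_power(dist: np.ndarray, n: int) -> np.ndarray:
    """n-fold self-convolution of a mass-shift distribution (n >= 0)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    result = np.array([1.0])
    base = np.asarray(dist, dtype=float)
    while n:
        if n & 1:
            result = np.convolve(result, base)
        n >>= 1
        if n:
            base = np.convolve(base, base)
    return result


def natural_shift_distribution(formula: str | dict[str, int]) -> np.ndarray:
    """Mass-shift distribution of a molecule with all atoms at natural abundance."""
    counts = parse_formula(formula)
    dist = np.array([1.0])
    for element, n in sorted(counts.items()):
        dist = np.convolve(dist, convolve_power(atom_shift_distribution(element), n))
    return dist
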