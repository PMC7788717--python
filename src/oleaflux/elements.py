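"""Elemental formula parsing and molecular weights.

Atomic masses follow the IUPAC 2021 standard atomic weights rounded to four
decimal places.  Molecular weights are expressed in g/mmol throughout the
package (numerically g/mol divided by 1000), matching the convention used to
standardize the biomass pseudo-reaction to 1 g/mmol.
"""

from __future__ import annotations

import re

# IUPAC 2021 standard atomic weights (g/mol), 4 decimals.
ATOMIC_MASS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.9738,
    "S": 32.06,
    "Cl": 35.45,
    "Na": 22.9898,
    "K": 39.0983,
    "Mg": 24.305,
    "Ca": 40.078,
    "Fe": 55.845,
    "Zn": 65.38,
    "Cu": 63.546,
    "Mn": 54.938,
    "Se": 78.971,
    "Co": 58.9332,
    "Mo": 95.95,
    "I": 126.9045,
    "F": 18.9984,
    "Br": 79.904,
    "B": 10.81,
    "Si": 28.085,
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised when an elemental formula cannot be parsed."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula like ``C6H12O6`` into element counts.

    Only flat formulas over standard element symbols with non-negative
    integer counts are supported (no parentheses, charges or isotopes).
    """
    if not isinstance(formula, str) or not formula:
        raise FormulaError(f"empty or non-string formula: {formula!r}")
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(formula):
        if m.start() != pos:
            raise FormulaError(f"cannot parse formula {formula!r} at {pos}")
        pos = m.end()
        sym, num = m.group(1), m.group(2)
        if sym not in ATOMIC_MASS:
            raise FormulaError(f"unknown element {sym!r} in {formula!r}")
        counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
    if pos != len(formula):
        raise FormulaError(f"cannot parse formula {formula!r} at {pos}")
    return counts


def molecular_weight(formula: str) -> float:
    """Molecular weight of ``formula`` in g/mmol.

    Numerically equal to the conventional g/mol value divided by 1000, e.g.
    ``molecular_weight("C3H8O3") * 1000 == 92.094`` for glycerol.
    """
    counts = parse_formula(formula)
    return sum(n * ATOMIC_MASS[el] for el, n in counts.items()) / 1000.0


def molecular_weight_gmol(formula: str) -> float:
    """Molecular weight in g/mol (convenience for reporting)."""
    return molecular_weight(formula) * 1000.0
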