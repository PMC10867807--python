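"""Periodic-table lookup: element symbol <-> nuclear charge and atomic mass.

Masses are conventional standard atomic weights in Da (IUPAC 2021 abridged).
Covers H–Kr plus a few heavier elements common in organic/inorganic work;
extend the table if an element is missing.
"""

from __future__ import annotations

_TABLE: list[tuple[str, int, float]] = [
    ("H", 1, 1.008), ("He", 2, 4.0026),
    ("Li", 3, 6.94), ("Be", 4, 9.0122), ("B", 5, 10.81), ("C", 6, 12.011),
    ("N", 7, 14.007), ("O", 8, 15.999), ("F", 9, 18.998), ("Ne", 10, 20.180),
    ("Na", 11, 22.990), ("Mg", 12, 24.305), ("Al", 13, 26.982),
    ("Si", 14, 28.085), ("P", 15, 30.974), ("S", 16, 32.06),
    ("Cl", 17, 35.45), ("Ar", 18, 39.95),
    ("K", 19, 39.098), ("Ca", 20, 40.078), ("Sc", 21, 44.956),
    ("Ti", 22, 47.867), ("V", 23, 50.942), ("Cr", 24, 51.996),
    ("Mn", 25, 54.938), ("Fe", 26, 55.845), ("Co", 27, 58.933),
    ("Ni", 28, 58.693), ("Cu", 29, 63.546), ("Zn", 30, 65.38),
    ("Ga", 31, 69.723), ("Ge", 32, 72.630), ("As", 33, 74.922),
    ("Se", 34, 78.971), ("Br", 35, 79.904), ("Kr", 36, 83.798),
    ("I", 53, 126.904), ("Xe", 54, 131.293),
]

SYMBOL_TO_Z: dict[str, int] = {s: z for s, z, _ in _TABLE}
SYMBOL_TO_MASS: dict[str, float] = {s: m for s, _, m in _TABLE}
Z_TO_SYMBOL: dict[int, str] = {z: s for s, z, _ in _TABLE}

_LOWER_TO_SYMBOL: dict[str, str] = {s.lower(): s for s, _, _ in _TABLE}


def normalize_symbol(symbol: str) -> str:
    """Resolve an element symbol case-insensitively to its canonical form."""
    try:
        return _LOWER_TO_SYMBOL[symbol.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown element symbol: {symbol!r}") from None


def nuclear_charge(symbol: str) -> int:
    return SYMBOL_TO_Z[normalize_symbol(symbol)]


def atomic_mass(symbol: str) -> float:
    return SYMBOL_TO_MASS[normalize_symbol(symbol)]
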