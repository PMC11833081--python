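"""Standard atomic weights and element inference for PDB records.

Masses are IUPAC 2021 standard atomic weights (conventional values), in
unified atomic mass units.  Hydrogen-mass-repartitioned masses used by some
MD engines are deliberately not reproduced; analyses here are engine
independent.
"""

from __future__ import annotations

from .errors import FormatError

# Conventional standard atomic weights (u) for elements that occur in
# protein/ligand PDB files.  Extend as needed.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "NA": 22.990,
    "MG": 24.305,
    "P": 30.974,
    "S": 32.06,
    "CL": 35.45,
    "K": 39.098,
    "CA": 40.078,
    "MN": 54.938,
    "FE": 55.845,
    "CO": 58.933,
    "NI": 58.693,
    "CU": 63.546,
    "ZN": 65.38,
    "SE": 78.971,
    "BR": 79.904,
    "I": 126.904,
}

_TWO_LETTER = {sym for sym in ATOMIC_MASSES if len(sym) == 2}


def mass_of(element: str) -> float:
    """Return the standard atomic weight of ``element`` (case-insensitive)."""
    try:
        return ATOMIC_MASSES[element.upper()]
    except KeyError:
        raise FormatError(f"unknown element {element!r}") from None


def is_hydrogen(element: str) -> bool:
    return element.upper() in ("H", "D")


def element_from_atom_name(atom_name: str) -> str:
    """Infer the element from a PDB atom name.

    Fallback for files without an element column.  Follows the PDB
    convention that the element occupies columns 13-14 of the atom-name
    field: a name starting in column 13 with a recognised two-letter symbol
    (``FE``, ``ZN`` ...) is that element; otherwise the first alphabetic
    character wins, so ``1HB`` is hydrogen and `` CA `` is a carbon alpha.
    """
    raw = atom_name  # 4-char field, possibly space padded
    field = raw.ljust(4)[:4]
    two = field[:2].strip().upper()
    if len(field[:2].strip()) == 2 and two in _TWO_LETTER and field[0] != " ":
        return two
    for ch in raw:
        if ch.isalpha():
            return ch.upper()
    raise FormatError(f"cannot infer element from atom name {atom_name!r}")
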