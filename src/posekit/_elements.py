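"""Element tables: covalent radii, AutoDock atom types, metals."""

from __future__ import annotations

# Single-bond covalent radii in Å (Cordero et al. values, rounded).
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "D": 0.31, "He": 0.28,
    "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "Ne": 0.58, "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11,
    "P": 1.07, "S": 1.05, "Cl": 1.02, "Ar": 1.06, "K": 2.03, "Ca": 1.76,
    "Mn": 1.39, "Fe": 1.32, "Co": 1.26, "Ni": 1.24, "Cu": 1.32, "Zn": 1.22,
    "Ga": 1.22, "Ge": 1.20, "As": 1.19, "Se": 1.20, "Br": 1.20, "Kr": 1.16,
    "Rb": 2.20, "Sr": 1.95, "Mo": 1.54, "Ru": 1.46, "Pd": 1.39, "Ag": 1.45,
    "Cd": 1.44, "Sn": 1.39, "Sb": 1.39, "Te": 1.38, "I": 1.39, "Xe": 1.40,
    "Cs": 2.44, "Ba": 2.15, "W": 1.62, "Pt": 1.36, "Au": 1.36, "Hg": 1.32,
    "Pb": 1.46,
}

#: Slack added to the radius sum when perceiving bonds from distances.
BOND_TOLERANCE = 0.45

#: Metals recognised by the interaction detector (coordination centres).
METALS = frozenset({
    "Li", "Na", "K", "Rb", "Cs", "Mg", "Ca", "Sr", "Ba",
    "Mn", "Fe", "Co", "Ni", "Cu", "Zn", "Cd", "Hg", "Al",
})

# AutoDock/PDBQT atom types → element.  Types not listed fall back to the
# leading alphabetic characters of the type, title-cased.
AUTODOCK_TYPES: dict[str, str] = {
    "A": "C",      # aromatic carbon
    "C": "C",
    "N": "N", "NA": "N", "NS": "N",
    "O": "O", "OA": "O", "OS": "O",
    "S": "S", "SA": "S",
    "H": "H", "HD": "H", "HS": "H",
    "F": "F", "CL": "Cl", "BR": "Br", "I": "I", "P": "P",
    "MG": "Mg", "MN": "Mn", "ZN": "Zn", "CA": "Ca", "FE": "Fe",
    "W": "O",      # hydrated-docking water
    "G": "C", "GA": "C", "J": "C", "Q": "C",   # Vina branch/macrocycle carbons
}

# Typical valence caps used by the synthetic generator's legality check.
MAX_VALENCE: dict[str, int] = {
    "H": 1, "C": 4, "N": 3, "O": 2, "S": 2, "P": 5,
    "F": 1, "Cl": 1, "Br": 1, "I": 1,
}


def element_from_autodock(ad_type: str) -> str:
    t = ad_type.strip()
    if not t:
        return ""
    hit = AUTODOCK_TYPES.get(t.upper())
    if hit:
        return hit
    alpha = "".join(ch for ch in t if ch.isalpha())
    return alpha[:2].capitalize() if len(alpha) >= 2 else alpha.upper()


def normalise_element(raw: str) -> str:
    """Normalise a raw symbol ('CL', 'cl', ' C') to periodic-table form."""
    s = raw.strip()
    if not s:
        return ""
    if len(s) == 1:
        return s.upper()
    return s[0].upper() + s[1:].lower()
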