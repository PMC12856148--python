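"""Residue-level constants: monoisotopic masses, biochemical categories, hydropathy.

All downstream mass-shift arithmetic (SAAV theoretical shifts, fragment ions)
goes through this module so there is exactly one source of truth for the
amino-acid mass table.
"""

from __future__ import annotations

from typing import Mapping

STANDARD_AA: str = "ACDEFGHIKLMNPQRSTVWY"

#: Symbol for the isobaric Leu/Ile class: leucine and isoleucine share a
#: monoisotopic residue mass and cannot be distinguished by a mass shift.
IL_CLASS: str = "X"

#: Monoisotopic residue (amino-acid minus water) masses in Da, rounded to
#: 5 decimals. Values follow the standard IUPAC/unimod monoisotopic table
#: (identical, at this precision, to pyteomics' ``std_aa_mass``).
MONO_MASS: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00918,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04048,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

PROTON: float = 1.00728
WATER: float = 18.01056

#: Five-class biochemical partition of the 20 residues. The scheme is chosen
#: to agree with the canonical pairings reported for translational errors:
#: Val/Ile and Met/Leu are nonpolar, Tyr/Phe aromatic.
BIOCHEM_CATEGORIES: dict[str, str] = {
    **{aa: "nonpolar" for aa in "GAVLIPM"},
    **{aa: "aromatic" for aa in "FWY"},
    **{aa: "polar" for aa in "STCNQ"},
    **{aa: "positive" for aa in "KRH"},
    **{aa: "negative" for aa in "DE"},
}

#: Kyte-Doolittle hydropathy indices; used by the simulator's linear
#: retention-time device, not as a chromatographic claim.
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


def residue_mass(aa: str, table: Mapping[str, float] | None = None) -> float:
    """Monoisotopic residue mass; ``X`` resolves to the shared Leu/Ile mass."""
    table = MONO_MASS if table is None else table
    if aa == IL_CLASS:
        return table["L"]
    try:
        return table[aa]
    except KeyError:
        raise KeyError(f"unknown residue {aa!r}") from None


def residue_category(aa: str, categories: Mapping[str, str] | None = None) -> str:
    """Biochemical category of a residue; ``X`` maps to the Leu/Ile category."""
    categories = BIOCHEM_CATEGORIES if categories is None else categories
    if aa == IL_CLASS:
        aa = "L"
    try:
        return categories[aa]
    except KeyError:
        raise KeyError(f"residue {aa!r} has no biochemical category") from None


def same_category(a: str, b: str, categories: Mapping[str, str] | None = None) -> bool:
    return residue_category(a, categories) == residue_category(b, categories)
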