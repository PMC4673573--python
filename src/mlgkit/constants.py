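"""Centralized mass table for glucan and fragment arithmetic.

All masses in the package come from the elemental compositions below,
evaluated against one shared atomic-mass table, so that monoisotopic and
average conventions stay consistent everywhere.  Nothing here is fitted to
observed spectra.
"""

from __future__ import annotations

from typing import Dict, Mapping

# Atomic masses (Da).  Monoisotopic values are CODATA/IUPAC; average values
# are standard atomic weights.
ATOMIC_MONO: Dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "O": 15.9949146196,
    "Na": 22.9897692809,
}
ATOMIC_AVG: Dict[str, float] = {
    "C": 12.011,
    "H": 1.008,
    "O": 15.999,
    "Na": 22.98977,
}

Composition = Mapping[str, int]


def composition_mass(comp: Composition, *, average: bool = False) -> float:
    """Mass of an elemental composition under one mass convention.

    Negative element counts are allowed: fragment compositions are written
    as residue multiples plus a (possibly negative) correction term.
    """
    table = ATOMIC_AVG if average else ATOMIC_MONO
    return sum(table[el] * n for el, n in comp.items())


def combine(*comps: Composition, scale: Mapping[str, int] | None = None) -> Dict[str, int]:
    """Elementwise sum of compositions (helper for fragment tables)."""
    out: Dict[str, int] = {}
    for comp in comps:
        for el, n in comp.items():
            out[el] = out.get(el, 0) + n
    if scale:
        for el, n in scale.items():
            out[el] = out.get(el, 0) + n
    return {el: n for el, n in out.items() if n != 0}


def scaled(comp: Composition, k: int) -> Dict[str, int]:
    return {el: n * k for el, n in comp.items() if n * k != 0}


# Building-block compositions.
WATER: Composition = {"H": 2, "O": 1}
METHYLENE: Composition = {"C": 1, "H": 2}          # one CH2 = one O-methyl vs O-H
METHANE: Composition = {"C": 1, "H": 4}
FORMALDEHYDE: Composition = {"C": 1, "H": 2, "O": 1}
METHANOL: Composition = {"C": 1, "H": 4, "O": 1}
H2: Composition = {"H": 2}

# Anhydroglucose residue (glucose minus water) and its permethylated
# counterpart (three O-methyls per internal residue).
ANHYDROGLUCOSE: Composition = {"C": 6, "H": 10, "O": 5}
PERMETHYL_RESIDUE: Composition = {"C": 9, "H": 16, "O": 5}

# Frequently used scalar masses (monoisotopic / average).
RESIDUE_MONO = composition_mass(ANHYDROGLUCOSE)                  # 162.0528
RESIDUE_AVG = composition_mass(ANHYDROGLUCOSE, average=True)
PERMETHYL_RESIDUE_MONO = composition_mass(PERMETHYL_RESIDUE)     # 204.0998
PERMETHYL_RESIDUE_AVG = composition_mass(PERMETHYL_RESIDUE, average=True)
WATER_MONO = composition_mass(WATER)
METHYLENE_MONO = composition_mass(METHYLENE)

# Adduct masses.  The sodium constant is the atomic mass (electron mass is
# below every tolerance used in this package); the proton constant includes
# the electron correction as is conventional.
ADDUCT_MASS = {
    "none": (0.0, 0.0),
    "proton": (1.00727646688, 1.00728),
    "sodium": (ATOMIC_MONO["Na"], 22.99),
}
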