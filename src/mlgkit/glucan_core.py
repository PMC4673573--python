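"""Data model, notation grammar, and mass arithmetic for linear mixed-linkage glucans.

A chain is a linear run of beta-D-glucopyranosyl residues written
nonreducing -> reducing (residue 1 is the nonreducing terminus).  Residue i
donates its anomeric carbon (C1) to O3 or O4 of residue i+1, so a chain of
n residues carries n-1 linkages, each 1->3 or 1->4.  The compact notation
``G3G4G...G`` mirrors the shorthand used throughout the mixed-linkage
glucan literature: ``G3G`` is laminaribiose, ``G4G4G4G4G`` cellopentaose,
``G3G4G3G4G`` the pentasaccharide carrying a cellobiosyl unit.

Only beta anomeric configuration and 1->3 / 1->4 linkages are
representable; branched glycans and 1->6 bonds (laminarin side chains) are
deliberately outside the model.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, List, Sequence, Tuple

from . import constants as C


class Linkage(enum.IntEnum):
    """Glycosidic linkage donated by a residue's C1."""

    L3 = 3
    L4 = 4

    def __str__(self) -> str:  # "3" / "4" for notation
        return str(int(self))


class ChainParseError(ValueError):
    """Raised for malformed compact chain notation; carries the position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


@dataclass(frozen=True)
class GlucanChain:
    """Linear beta-glucan chain, defined by its linkage vector.

    ``linkages[i]`` is the bond donated by residue i+1 to residue i+2
    (0-based storage; the public bond numbering used by the digestion and
    fragmentation modules is 1-based: bond b joins residues b and b+1).
    """

    linkages: Tuple[Linkage, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "linkages", tuple(Linkage(l) for l in self.linkages)
        )

    @property
    def n_residues(self) -> int:
        return len(self.linkages) + 1

    # DP is the field's name for chain length
    @property
    def dp(self) -> int:
        return self.n_residues

    def bond(self, b: int) -> Linkage:
        """Linkage of bond b (1-based, joining residues b and b+1)."""
        if not 1 <= b <= len(self.linkages):
            raise IndexError(f"bond {b} out of range for DP {self.dp}")
        return self.linkages[b - 1]

    def __len__(self) -> int:
        return self.n_residues

    def __str__(self) -> str:
        return to_notation(self)

    def __repr__(self) -> str:
        return f"GlucanChain({to_notation(self)!r})"


class Derivatization(enum.Enum):
    """Chemical state of the chain for mass computation.

    ``reduced`` converts the reducing end to an alditol (NaBH4 reduction,
    as done before methylation analysis); ``permethylated`` methylates
    every free hydroxyl (the state analyzed by MALDI-CID).
    """

    NATIVE = "native"
    REDUCED = "reduced"
    PERMETHYLATED = "permethylated"
    PERMETHYLATED_REDUCED = "permethylated_reduced"


@dataclass(frozen=True)
class MassSpec:
    """Mass convention and adduct for m/z computation (singly charged)."""

    mass_convention: str = "monoisotopic"  # or "average"
    adduct: str = "sodium"                 # "none", "proton", "sodium"
    charge: int = 1

    def __post_init__(self) -> None:
        if self.mass_convention not in ("monoisotopic", "average"):
            raise ValueError(f"unknown mass convention {self.mass_convention!r}")
        if self.adduct not in C.ADDUCT_MASS:
            raise ValueError(f"unknown adduct {self.adduct!r}")
        if self.charge != 1:
            raise ValueError("only singly charged species are modeled")

    @property
    def average(self) -> bool:
        return self.mass_convention == "average"

    @property
    def adduct_mass(self) -> float:
        mono, avg = C.ADDUCT_MASS[self.adduct]
        return avg if self.average else mono


_NOTATION_RE = re.compile(r"G((3|4)G)*$")


def parse_chain(notation: str) -> GlucanChain:
    """Parse compact notation (``G((3|4)G)*``) into a chain.

    The string is read nonreducing -> reducing; the digit between the i-th
    and (i+1)-th ``G`` is linkage i.  Raises :class:`ChainParseError`
    naming the first offending position.
    """
    s = notation.strip()
    if not s:
        raise ChainParseError("empty chain notation", 0)
    linkages: List[Linkage] = []
    i = 0
    expect_residue = True
    while i < len(s):
        ch = s[i]
        if expect_residue:
            if ch != "G":
                raise ChainParseError(f"expected 'G', found {ch!r}", i)
            expect_residue = False
        else:
            if ch not in "34":
                raise ChainParseError(f"expected linkage digit '3' or '4', found {ch!r}", i)
            linkages.append(Linkage(int(ch)))
            expect_residue = True
        i += 1
    if expect_residue:
        raise ChainParseError("notation ends with a dangling linkage digit", len(s) - 1)
    return GlucanChain(tuple(linkages))


def to_notation(chain: GlucanChain) -> str:
    """Serialize a chain back to compact notation (inverse of parse_chain)."""
    return "G" + "".join(f"{int(l)}G" for l in chain.linkages)


def free_hydroxyl_count(chain: GlucanChain, derivatization: Derivatization = Derivatization.NATIVE) -> int:
    """Number of free hydroxyls available for methylation.

    A linear native chain has 3n+2: the nonreducing terminus exposes four
    (O2, O3, O4, O6), each internal residue three, and the reducing
    terminus four (O1 anomeric, O2, O6, plus whichever of O3/O4 is not
    glycosylated).  Ring opening on reduction frees O5, adding one.
    """
    n = chain.n_residues
    base = 3 * n + 2
    if derivatization in (Derivatization.REDUCED, Derivatization.PERMETHYLATED_REDUCED):
        base += 1
    return base


def chain_mass(
    chain: GlucanChain,
    derivatization: Derivatization = Derivatization.NATIVE,
    spec: MassSpec = MassSpec(mass_convention="monoisotopic", adduct="none"),
) -> float:
    """Mass (Da) of a chain under a derivatization state and adduct.

    Native mass is n residues plus one water; reduction adds H2;
    permethylation adds one methylene equivalent per free hydroxyl.
    """
    n = chain.n_residues
    comp = C.combine(C.scaled(C.ANHYDROGLUCOSE, n), C.WATER)
    if derivatization in (Derivatization.REDUCED, Derivatization.PERMETHYLATED_REDUCED):
        comp = C.combine(comp, C.H2)
    if derivatization in (Derivatization.PERMETHYLATED, Derivatization.PERMETHYLATED_REDUCED):
        n_oh = free_hydroxyl_count(chain, derivatization)
        comp = C.combine(comp, C.scaled(C.METHYLENE, n_oh))
    return C.composition_mass(comp, average=spec.average) + spec.adduct_mass


# ---------------------------------------------------------------------------
# Chain files: one compact-notation chain per line, '#' comments, optional
# FASTA-like '>id' headers (the header only names the following chain).
# ---------------------------------------------------------------------------

def iter_chain_lines(lines: Iterable[str]) -> Iterator[Tuple[str, GlucanChain]]:
    pending_id = ""
    for lineno, raw in enumerate(lines, 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith(">"):
            pending_id = line[1:].strip()
            continue
        try:
            chain = parse_chain(line)
        except ChainParseError as exc:
            raise ChainParseError(f"line {lineno}: {exc}", exc.position) from exc
        yield (pending_id or f"chain{lineno}", chain)
        pending_id = ""


def read_chains(path: str | Path) -> List[GlucanChain]:
    """Read chains from a plain-text chain file."""
    with open(path) as fh:
        return [chain for _, chain in iter_chain_lines(fh)]


def write_chains(path: str | Path, chains: Sequence[GlucanChain], header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for chain in chains:
            fh.write(to_notation(chain) + "\n")
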