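"""Theoretical lipid species: PG / PE / CL backbones, optional aminoacylation.

Species are modeled at total-acyl-composition level — "(32:0)" means 32 acyl
carbons and 0 desaturations summed over all chains, the granularity at which
a unit-resolution precursor scan reads out.  sn-positional isomers, and the
mass-identical distinction between a monounsaturated and a cyclopropane
chain, are deliberately not represented.

The amino-acid table covers the 20 proteinogenic residues as free amino
acids; ester attachment to the head-group glycerol costs one water, so the
aminoacylation mass shift is (free amino acid - H2O), e.g. +128.0950 for
lysine and +71.0371 for alanine.  D- and L-stereoisomers are mass-identical
and share a formula; stereochemistry is carried as an optional label only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .chem import (
    ADDUCTS,
    Adduct,
    Formula,
    GLYCEROL,
    MassTolerance,
    M_MINUS_H,
    PHOSPHORIC_ACID,
    ETHANOLAMINE,
    WATER,
)

#: free (unbound) formulas of the 20 proteinogenic amino acids, 3-letter codes
AMINO_ACIDS: dict[str, Formula] = {
    "Gly": Formula.parse("C2H5NO2"),
    "Ala": Formula.parse("C3H7NO2"),
    "Ser": Formula.parse("C3H7NO3"),
    "Pro": Formula.parse("C5H9NO2"),
    "Val": Formula.parse("C5H11NO2"),
    "Thr": Formula.parse("C4H9NO3"),
    "Cys": Formula.parse("C3H7NO2S"),
    "Leu": Formula.parse("C6H13NO2"),
    "Ile": Formula.parse("C6H13NO2"),
    "Asn": Formula.parse("C4H8N2O3"),
    "Asp": Formula.parse("C4H7NO4"),
    "Gln": Formula.parse("C5H10N2O3"),
    "Lys": Formula.parse("C6H14N2O2"),
    "Glu": Formula.parse("C5H9NO4"),
    "Met": Formula.parse("C5H11NO2S"),
    "His": Formula.parse("C6H9N3O2"),
    "Phe": Formula.parse("C9H11NO2"),
    "Arg": Formula.parse("C6H14N4O2"),
    "Tyr": Formula.parse("C9H11NO3"),
    "Trp": Formula.parse("C11H12N2O2"),
}

#: amino acids whose screen behavior needs a caution flag: the aminoacyl-anion
#: precursor scan is unreliable for cysteine (thiol side chain)
UNRELIABLE_SCREEN_AA = frozenset({"Cys"})

#: adjective stems for species names ("lysyl-PG", "alanyl-PG", ...)
AA_ADJECTIVES: dict[str, str] = {
    "Gly": "glycyl", "Ala": "alanyl", "Ser": "seryl", "Pro": "prolyl",
    "Val": "valyl", "Thr": "threonyl", "Cys": "cysteinyl", "Leu": "leucyl",
    "Ile": "isoleucyl", "Asn": "asparaginyl", "Asp": "aspartyl",
    "Gln": "glutaminyl", "Lys": "lysyl", "Glu": "glutamyl",
    "Met": "methionyl", "His": "histidyl", "Phe": "phenylalanyl",
    "Arg": "arginyl", "Tyr": "tyrosyl", "Trp": "tryptophyl",
}

BACKBONES = ("PG", "PE", "CL")
_CHAINS = {"PG": 2, "PE": 2, "CL": 4}


def amino_acid_formula(code: str) -> Formula:
    try:
        return AMINO_ACIDS[code]
    except KeyError:
        raise KeyError(f"unknown amino-acid code {code!r}") from None


def residue_formula(code: str) -> Formula:
    """Ester-linked residue formula: free amino acid minus one water."""
    return amino_acid_formula(code) - WATER


@dataclass(frozen=True, order=True)
class AcylComposition:
    """Total fatty-acyl composition "(carbons:unsaturations)"."""

    carbons: int
    unsaturations: int = 0

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError("need at least 2 acyl carbons")
        if not 0 <= self.unsaturations <= self.carbons:
            raise ValueError("unsaturation count out of range")

    @property
    def notation(self) -> str:
        return f"({self.carbons}:{self.unsaturations})"

    def fatty_acid_formula(self, chains: int) -> Formula:
        """Summed formula of ``chains`` free fatty acids with this total
        composition: C(nc) H(2nc-2nd) O(2*chains)."""
        h = 2 * self.carbons - 2 * self.unsaturations
        return Formula(C=self.carbons, H=h, O=2 * chains)

    def __str__(self) -> str:
        return self.notation


def parse_acyl(text: str) -> AcylComposition:
    """Parse "(32:0)" or "32:0" into an :class:`AcylComposition`."""
    t = text.strip().strip("()")
    nc, _, nd = t.partition(":")
    return AcylComposition(int(nc), int(nd or 0))


@dataclass(frozen=True)
class LipidSpecies:
    """A glycerophospholipid species, optionally aminoacylated.

    backbone: "PG", "PE" or "CL"; ``amino_acid`` is a 3-letter code or None;
    ``stereo`` ("D"/"L") labels the aminoacyl stereocenter without affecting
    mass.
    """

    backbone: str
    acyl: AcylComposition
    amino_acid: str | None = None
    stereo: str | None = None

    def __post_init__(self) -> None:
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.amino_acid is not None and self.amino_acid not in AMINO_ACIDS:
            raise ValueError(f"unknown amino acid {self.amino_acid!r}")
        if self.stereo not in (None, "D", "L"):
            raise ValueError("stereo label must be 'D', 'L' or None")

    @property
    def chain_count(self) -> int:
        return _CHAINS[self.backbone]

    @property
    def name(self) -> str:
        mod = f"{AA_ADJECTIVES[self.amino_acid]}-" if self.amino_acid else ""
        st = f"{self.stereo}-" if self.stereo else ""
        return f"{self.acyl.notation} {st}{mod}{self.backbone}"

    def formula(self) -> Formula:
        return species_formula(self)

    def mz(self, adduct: Adduct | str) -> float:
        if isinstance(adduct, str):
            adduct = ADDUCTS[adduct]
        return adduct.mz(self.formula())

    def __str__(self) -> str:
        return self.name


def _backbone_core(backbone: str) -> Formula:
    """Fully condensed head+glycerol core, before acylation.

    PG core: glycerophosphoglycerol (2 glycerols + phosphate - 2 H2O);
    PE core: glycerophosphoethanolamine; CL core: 3 glycerols + 2 phosphates
    - 4 H2O (each phosphate forms two phosphodiester bonds).
    """
    if backbone == "PG":
        return GLYCEROL * 2 + PHOSPHORIC_ACID - WATER * 2
    if backbone == "PE":
        return GLYCEROL + ETHANOLAMINE + PHOSPHORIC_ACID - WATER * 2
    if backbone == "CL":
        return GLYCEROL * 3 + PHOSPHORIC_ACID * 2 - WATER * 4
    raise ValueError(backbone)


def species_formula(s: LipidSpecies) -> Formula:
    """Neutral elemental formula of a species.

    The formula is assembled as core + summed fatty acids - one water per
    ester bond + optional aminoacyl residue.  For PG(nc:nd) this reduces to
    C(nc+6) H(2nc-2nd+11) O10 P, for PE(nc:nd) to C(nc+5) H(2nc-2nd+10) N O8 P.
    """
    chains = s.chain_count
    f = (
        _backbone_core(s.backbone)
        + s.acyl.fatty_acid_formula(chains)
        - WATER * chains
    )
    if s.amino_acid:
        f = f + residue_formula(s.amino_acid)
    return f


def enumerate_library(
    backbones: Iterable[str] = ("PG",),
    amino_acids: Iterable[str] | None = None,
    carbon_range: tuple[int, int] = (26, 36),
    unsat_range: tuple[int, int] = (0, 2),
) -> list[LipidSpecies]:
    """Cartesian species library: each backbone, unmodified + each amino acid,
    over the acyl-composition grid.  ``amino_acids=None`` means all 20.

    Sorted by (backbone, modification, carbons, unsaturations); deduplicated.
    """
    if amino_acids is None:
        amino_acids = list(AMINO_ACIDS)
    mods: list[str | None] = [None, *amino_acids]
    seen: set[tuple] = set()
    out: list[LipidSpecies] = []
    for bb, aa, nc, nd in itertools.product(
        backbones,
        mods,
        range(carbon_range[0], carbon_range[1] + 1),
        range(unsat_range[0], unsat_range[1] + 1),
    ):
        key = (bb, aa, nc, nd)
        if key in seen:
            continue
        seen.add(key)
        out.append(LipidSpecies(bb, AcylComposition(nc, nd), aa))
    out.sort(key=lambda s: (s.backbone, s.amino_acid or "", s.acyl))
    return out


def isobaric_groups(
    library: Sequence[LipidSpecies],
    tol: MassTolerance,
    adduct: Adduct | str = M_MINUS_H,
) -> list[list[LipidSpecies]]:
    """Partition a library into groups indistinguishable at the tolerance.

    Species are sorted by ion m/z and chained: neighbours closer than the
    window merge into one group.  At 0.3 amu lysyl and glutaminyl species
    merge (delta 0.0365) as do leucyl/isoleucyl (identical formula); at a few
    ppm only the identical-formula pairs remain merged.
    """
    if not library:
        raise ValueError("empty library")
    if isinstance(adduct, str):
        adduct = ADDUCTS[adduct]
    ranked = sorted(library, key=lambda s: s.mz(adduct))
    groups: list[list[LipidSpecies]] = [[ranked[0]]]
    for sp in ranked[1:]:
        prev = groups[-1][-1]
        if sp.mz(adduct) - prev.mz(adduct) <= tol.window(sp.mz(adduct)):
            groups[-1].append(sp)
        else:
            groups.append([sp])
    return groups
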