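"""Rule-based in-silico fragmentation of (aminoacyl-)PG and PE species.

Collision-induced dissociation of these lipids produces a finite, named
vocabulary of fragments — fatty-acyl anions, the aminoacyl anion, the
cyclo-glycerophosphate backbone anion in negative mode; dehydroxylated
diacylglycerol and a ladder of head-group ions (cyclo-aminoacyl,
(cyclo-)aminoacyl-glycerol, (cyclo-)aminoacyl-glycerolphosphate, phosphate,
glycerolphosphate, and the neutral-loss survivors PA and PG) from sodiated
cations.  The engine is therefore a declarative rule table — each rule names
a sub-structure, gives a recipe for its elemental formula and carries the
scissile-bond label(s) used in the source spectra — rather than a generic
bond-graph cleaver.  "cyclo-" always means the dehydrated (intramolecular
ester/lactam) form: one water lighter than the open compound.

Every fragment keeps its complementary neutral, so fragment ion + lost
neutral always reassembles the precursor ion formula exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import pandas as pd

from .chem import (
    Adduct,
    ADDUCTS,
    Formula,
    FormulaError,
    GLYCEROL,
    HYDROGEN,
    HYDROXYL,
    M_MINUS_H,
    M_PLUS_H,
    M_PLUS_NA,
    PHOSPHORIC_ACID,
    ETHANOLAMINE,
    SODIUM,
    WATER,
)
from .lipids import (
    AA_ADJECTIVES as _AA_ADJECTIVES,
    AcylComposition,
    LipidSpecies,
    amino_acid_formula,
    residue_formula,
    species_formula,
)

GRO_PHO = GLYCEROL + PHOSPHORIC_ACID - WATER          # glycerolphosphate
PETN = ETHANOLAMINE + PHOSPHORIC_ACID - WATER          # phosphoethanolamine


class UnsupportedFragmentation(ValueError):
    """Raised for precursors the rule table does not cover (e.g. CL)."""


@dataclass(frozen=True)
class FragmentIon:
    """One theoretical product ion of a given precursor.

    ``ion_formula`` is the formula of the charged fragment (including any
    sodium it retains); ``complement`` is the lost neutral, so
    ion_formula + complement == precursor ion formula, exactly.
    """

    name: str
    cleavage: str | None
    ion_formula: Formula
    polarity: int
    complement: Formula

    @property
    def mz(self) -> float:
        return self.ion_formula.mass

    @property
    def nominal(self) -> int:
        return self.ion_formula.nominal_mass


@dataclass(frozen=True)
class FragmentTable:
    species: LipidSpecies
    adduct: Adduct
    ions: tuple[FragmentIon, ...]
    low_informative: bool = False  # protonated aminoacyl-PG: weak fragments

    def __post_init__(self) -> None:
        names = [(i.name, i.polarity) for i in self.ions]
        if len(names) != len(set(names)):
            dupes = {n for n in names if names.count(n) > 1}
            raise ValueError(f"duplicate fragment names: {dupes}")

    def find(self, name: str) -> FragmentIon:
        for ion in self.ions:
            if ion.name == name:
                return ion
        raise KeyError(f"no fragment named {name!r} in table for {self.species}")

    def mz_values(self) -> list[float]:
        return [i.mz for i in self.ions]

    @property
    def precursor_mz(self) -> float:
        return self.adduct.mz(species_formula(self.species))

    def to_dataframe(self) -> pd.DataFrame:
        """Export in the layout of an assignment table: observed (blank),
        calculated, cleavage, description."""
        return pd.DataFrame(
            {
                "observed_mz": ["" for _ in self.ions],
                "calculated_mz": [round(i.mz, 4) for i in self.ions],
                "cleavage": [i.cleavage or "" for i in self.ions],
                "description": [i.name for i in self.ions],
                "formula": [i.ion_formula.hill() for i in self.ions],
            }
        )


def _aa_label(code: str) -> str:
    return code


def enumerate_chain_splits(
    acyl: AcylComposition, per_chain_range: tuple[int, int] = (12, 20)
) -> list[AcylComposition]:
    """All distinct single-chain compositions from splitting a two-chain
    total, each chain within ``per_chain_range`` carbons and unsaturation
    distributed in every possible way."""
    lo, hi = per_chain_range
    seen: set[tuple[int, int]] = set()
    out: list[AcylComposition] = []
    for a in range(lo, hi + 1):
        b = acyl.carbons - a
        if not lo <= b <= hi:
            continue
        for x in range(acyl.unsaturations + 1):
            for c, d in ((a, x), (b, acyl.unsaturations - x)):
                if d > c:
                    continue
                if (c, d) not in seen:
                    seen.add((c, d))
                    out.append(AcylComposition(c, d))
    out.sort()
    return out


def _make_ion(
    name: str,
    cleavage: str | None,
    ion_formula: Formula,
    precursor_ion: Formula,
    polarity: int,
) -> FragmentIon:
    complement = precursor_ion - ion_formula  # FormulaError if not a sub-formula
    return FragmentIon(name, cleavage, ion_formula, polarity, complement)


@lru_cache(maxsize=4096)
def fragment_table(
    s: LipidSpecies,
    adduct: Adduct | str,
    per_chain_range: tuple[int, int] = (12, 20),
    include_acyl_losses: bool = False,
) -> FragmentTable:
    """Theoretical fragment table of a (PG or PE) species under one adduct.

    Negative mode gives per-chain fatty-acyl anions, the aminoacyl anion (if
    modified) and the cyclo-glycerophosphate anion for PG backbones.  The
    sodiated cation gives the full head-group ladder plus DAG/PA/PG survivor
    ions; the protonated cation gives DAG - OH and head-group neutral-loss
    ions only and is flagged ``low_informative`` for aminoacylated species.

    ``include_acyl_losses`` adds the minor fatty-acid / ketene neutral losses
    from sodiated precursors (ordinarily below the counting threshold).
    """
    if isinstance(adduct, str):
        adduct = ADDUCTS[adduct]
    if s.backbone == "CL" and adduct is not M_MINUS_H:
        raise UnsupportedFragmentation(
            "positive-mode cardiolipin MS/MS is not modeled; deprotonated CL "
            "is covered minimally (aminoacyl and cyclo-glycerophosphate anions)"
        )

    neutral = species_formula(s)
    precursor_ion = adduct.ion_formula(neutral)
    aa = s.amino_acid
    ions: list[FragmentIon] = []

    def add(name: str, cleavage: str | None, formula: Formula) -> None:
        ions.append(_make_ion(name, cleavage, formula, precursor_ion, adduct.polarity))

    dag = GLYCEROL + s.acyl.fatty_acid_formula(2) - WATER * 2
    pa = dag + PHOSPHORIC_ACID - WATER

    if s.backbone == "CL":  # negative mode only: screen-level diagnostics
        if aa:
            add(f"[{aa}-H]-", None, amino_acid_formula(aa) - HYDROGEN)
        add("cGP-", None, GRO_PHO - WATER - HYDROGEN)
        return FragmentTable(s, adduct, tuple(ions))

    if adduct is M_MINUS_H:
        for chain in enumerate_chain_splits(s.acyl, per_chain_range):
            fa = chain.fatty_acid_formula(1)
            add(f"[FA{chain.notation}-H]-", None, fa - HYDROGEN)
        if aa and s.backbone == "PG":
            # ester-linked aminoacyl releases the free aminoacyl anion; the
            # amide-linked PE counterpart does not
            add(f"[{_aa_label(aa)}-H]-", None, amino_acid_formula(aa) - HYDROGEN)
        if s.backbone == "PG":
            # diagnostic backbone anion, nominal 153
            add("cGP-", None, GRO_PHO - WATER - HYDROGEN)
        return FragmentTable(s, adduct, tuple(ions))

    if adduct is M_PLUS_NA:
        head_gro = GLYCEROL if s.backbone == "PG" else ETHANOLAMINE
        head_name = "Gro" if s.backbone == "PG" else "Etn"
        gro_pho = head_gro + PHOSPHORIC_ACID - WATER
        add("Pho + Na+", "c & f", PHOSPHORIC_ACID + SODIUM)
        add(f"cyclo-{head_name}-Pho + Na+", "c & g", gro_pho - WATER + SODIUM)
        add(f"{head_name}-Pho + Na+", "c & h", gro_pho + SODIUM)
        if aa:
            aa_f = amino_acid_formula(aa)
            aa_gro = aa_f + head_gro - WATER
            aa_gro_pho = aa_gro + PHOSPHORIC_ACID - WATER
            add(f"cyclo-{aa} + Na+", "h", aa_f - WATER + SODIUM)
            add(f"cyclo-{aa}-{head_name} - OH", "f & i", aa_gro - WATER - HYDROXYL)
            add(f"cyclo-{aa}-{head_name} + Na+", "f", aa_gro - WATER + SODIUM)
            add(f"cyclo-{aa}-{head_name}-Pho + Na+", "d", aa_gro_pho - WATER + SODIUM)
            add(f"{aa}-{head_name}-Pho + Na+", "c", aa_gro_pho + SODIUM)
            # neutral-loss survivors: losing cyclo-aa leaves the sodiated
            # unmodified backbone; losing cyclo-aa-head leaves sodiated PA
            add(f"{s.backbone} + Na+", "h", precursor_ion - (aa_f - WATER))
        add("DAG - OH", "c", dag - HYDROXYL)
        add("DAG - H2O + Na+", "c", dag - WATER + SODIUM)
        add("DAG + Na+", "d", dag + SODIUM)
        add("PA + Na+", "f", pa + SODIUM)
        if include_acyl_losses:
            for chain in enumerate_chain_splits(s.acyl, per_chain_range):
                fa = chain.fatty_acid_formula(1)
                add(f"[M+Na-FA{chain.notation}]+", None, precursor_ion - fa)
                add(
                    f"[M+Na-ketene{chain.notation}]+",
                    None,
                    precursor_ion - (fa - WATER),
                )
        return FragmentTable(s, adduct, tuple(ions))

    if adduct is M_PLUS_H:
        # head-group neutral loss dominates; DAG - OH is the survivor cation
        add("DAG - OH", "c", dag - HYDROXYL)
        if aa:
            aa_gro = amino_acid_formula(aa) + (
                GLYCEROL if s.backbone == "PG" else ETHANOLAMINE
            ) - WATER
            head_name = "Gro" if s.backbone == "PG" else "Etn"
            add(f"cyclo-{aa}-{head_name} - OH", "f & i", aa_gro - WATER - HYDROXYL)
        return FragmentTable(
            s, adduct, tuple(ions), low_informative=bool(aa)
        )

    raise UnsupportedFragmentation(f"no fragmentation rules for adduct {adduct}")


# ---------------------------------------------------------------------------
# named neutral losses and diagnostic scan fragments

_AA_NOUNS = {
    "Gly": "glycine", "Ala": "alanine", "Ser": "serine", "Pro": "proline",
    "Val": "valine", "Thr": "threonine", "Cys": "cysteine", "Leu": "leucine",
    "Ile": "isoleucine", "Asn": "asparagine", "Asp": "aspartate",
    "Gln": "glutamine", "Lys": "lysine", "Glu": "glutamate",
    "Met": "methionine", "His": "histidine", "Phe": "phenylalanine",
    "Arg": "arginine", "Tyr": "tyrosine", "Trp": "tryptophan",
}
_NAME_TO_CODE = {v: k for k, v in _AA_ADJECTIVES.items()}
_NAME_TO_CODE.update({v: k for k, v in _AA_NOUNS.items()})
_NAME_TO_CODE.update({k.lower(): k for k in _AA_ADJECTIVES})


def _resolve_aa(token: str) -> str:
    code = _NAME_TO_CODE.get(token.lower())
    if code is None:
        raise KeyError(f"unknown amino-acid name {token!r}")
    return code


def neutral_loss_mass(head: str) -> float:
    """Monoisotopic mass of a named head-group (or amino-acid) neutral.

    Recognized descriptors (amino acids by 3-letter code, adjective or noun):
    "phosphoethanolamine", "<aa>-phosphoethanolamine", "cyclo-<aa>",
    "cyclo-<aa>-glycerol", "<aa>-glycerolphosphate".  Nominal values match
    the classic scan settings: 141 (PEtn), 269 (lysyl-PEtn), 212
    (alanyl-PEtn), 128 (cyclo-lysine), 202 (cyclo-lysyl-glycerol).
    """
    return neutral_loss_formula(head).mass


def neutral_loss_formula(head: str) -> Formula:
    h = head.strip().lower()
    if h == "phosphoethanolamine":
        return PETN
    if h.startswith("cyclo-"):
        rest = h[len("cyclo-"):]
        if rest.endswith("-glycerol"):
            aa = _resolve_aa(rest[: -len("-glycerol")])
            return amino_acid_formula(aa) + GLYCEROL - WATER * 2
        aa = _resolve_aa(rest)
        return amino_acid_formula(aa) - WATER
    if h.endswith("-phosphoethanolamine"):
        aa = _resolve_aa(h[: -len("-phosphoethanolamine")])
        return PETN + residue_formula(aa)
    if h.endswith("-glycerolphosphate"):
        aa = _resolve_aa(h[: -len("-glycerolphosphate")])
        return GRO_PHO + residue_formula(aa)
    raise KeyError(f"unknown head-group descriptor {head!r}")


DIAGNOSTIC_MODES = (
    "negative-aminoacyl-anion",
    "positive-sodiated-head",
)


def diagnostic_fragment(aa: str, backbone: str = "PG",
                        mode: str = "negative-aminoacyl-anion") -> float:
    """The single scan-defining m/z for one amino acid.

    * negative-aminoacyl-anion: [aa-H]- (backbone-independent), the most
      sensitive screen channel;
    * positive-sodiated-head: sodiated aa-glycerolphosphate for PG (e.g.
      323.10 for Lys, 266.04 for Ala) or sodiated aa-phosphoethanolamine for
      PE (nominal 292 for Lys, 235 for Ala).
    """
    aa_code = aa if aa in _AA_ADJECTIVES else _resolve_aa(aa)
    if mode == "negative-aminoacyl-anion":
        return (amino_acid_formula(aa_code) - HYDROGEN).mass
    if mode == "positive-sodiated-head":
        if backbone == "PG":
            head = GRO_PHO + residue_formula(aa_code)
        elif backbone == "PE":
            head = PETN + residue_formula(aa_code)
        else:
            raise KeyError(f"no sodiated-head diagnostic for backbone {backbone!r}")
        return (head + SODIUM).mass
    raise KeyError(f"unknown diagnostic mode {mode!r}")
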