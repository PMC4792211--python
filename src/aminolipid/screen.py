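"""Multi-step screen for aminoacylated phospholipids.

The screen runs one precursor-ion scan per distinct deprotonated amino-acid
anion m/z over a negative-mode MS/MS collection, maps responding precursors
back onto a theoretical species library, and summarizes per-amino-acid
responses into a semi-quantitative relative-abundance profile (the scan
ordinate reflects both abundance and ionization/dissociation efficiency, so
ratios between amino acids are indicative, not absolute).

Candidates are then confirmed against high-accuracy MS/MS spectra: a species
counts as confirmed only when enough head-group-informative fragments match
(the aminoacyl anion, cyclo-aminoacyl, (cyclo-)aminoacyl-glycerol and
(cyclo-)aminoacyl-glycerolphosphate ions).  DAG-type ions are shared by all
glycerophospholipids and never confirm aminoacylation by themselves.
Aminoacyl-PE candidates always carry an artifact-caution flag: ester
aminolysis during sample drying can generate them from PE and aminoacyl-PG,
so they are never auto-confirmed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .chem import HYDROGEN, MassTolerance, M_MINUS_H, ADDUCTS, Adduct
from .fragments import fragment_table
from .lipids import (
    AMINO_ACIDS,
    LipidSpecies,
    UNRELIABLE_SCREEN_AA,
    amino_acid_formula,
)
from .scans import Annotation, MsMsRecord, ScanHit, ScanResult, annotate_msms, precursor_ion_scan

#: precursor m/z range where cardiolipin-sized species fall
CL_REGION = (1400.0, 1600.0)


@dataclass(frozen=True)
class CandidateMatch:
    species: LipidSpecies
    hit: ScanHit
    delta_amu: float


@dataclass(frozen=True)
class AminoAcidGroupResult:
    """Result of one aminoacyl-anion precursor scan (one isobaric group)."""

    amino_acids: tuple[str, ...]
    query_mz: float
    scan: ScanResult
    candidates: tuple[CandidateMatch, ...]
    unexplained: tuple[ScanHit, ...]
    cl_region_hits: tuple[ScanHit, ...]
    flags: tuple[str, ...]

    @property
    def label(self) -> str:
        return "/".join(self.amino_acids)

    @property
    def total_intensity(self) -> float:
        return self.scan.total_intensity

    @property
    def detected(self) -> bool:
        return bool(self.scan.hits)

    def best_candidate(self) -> CandidateMatch | None:
        return max(self.candidates, key=lambda c: c.hit.intensity, default=None)


@dataclass(frozen=True)
class ScreenReport:
    groups: tuple[AminoAcidGroupResult, ...]
    tolerance: MassTolerance
    n_records: int

    def group(self, aa: str) -> AminoAcidGroupResult:
        for g in self.groups:
            if aa in g.amino_acids:
                return g
        raise KeyError(f"amino acid {aa!r} not screened")

    def detected_groups(self) -> list[AminoAcidGroupResult]:
        return [g for g in self.groups if g.detected]


def _isobaric_aa_groups(
    amino_acids: Iterable[str], tol: MassTolerance
) -> list[tuple[str, ...]]:
    """Chain amino acids whose [aa-H]- anions are indistinguishable at tol."""
    anion = {aa: (amino_acid_formula(aa) - HYDROGEN).mass for aa in amino_acids}
    ranked = sorted(anion, key=anion.get)
    groups: list[list[str]] = [[ranked[0]]] if ranked else []
    for aa in ranked[1:]:
        prev = groups[-1][-1]
        if anion[aa] - anion[prev] <= tol.window(anion[aa]):
            groups[-1].append(aa)
        else:
            groups.append([aa])
    return [tuple(g) for g in groups]


def screen_aminoacyl_lipids(
    records: Sequence[MsMsRecord],
    library: Sequence[LipidSpecies],
    tol: MassTolerance = MassTolerance(0.3, "amu"),
) -> ScreenReport:
    """Screen a negative-mode MS/MS collection for every aminoacyl lipid in
    the library via deprotonated-aminoacyl precursor scans.

    Amino acids indistinguishable at the tolerance (Lys/Gln at unit
    resolution, Leu/Ile always) are scanned and reported as one group.
    Responding precursors are matched back to library species within the
    tolerance; unmatched hits are retained as unexplained (discovery mode),
    and hits in the cardiolipin-sized region (1400-1600) are reported
    separately.
    """
    if not library:
        raise ValueError("empty species library")
    records = [r for r in records if r.polarity == -1]
    lib_aas = sorted(
        {s.amino_acid for s in library if s.amino_acid}
    )
    if not lib_aas:
        raise ValueError("library contains no aminoacylated species")
    groups_out: list[AminoAcidGroupResult] = []
    for aa_group in _isobaric_aa_groups(lib_aas, tol):
        anion_mzs = [(amino_acid_formula(aa) - HYDROGEN).mass for aa in aa_group]
        query = sum(anion_mzs) / len(anion_mzs)
        scan = precursor_ion_scan(records, query, tol)
        members = [
            s for s in library if s.amino_acid in aa_group
        ]
        candidates: list[CandidateMatch] = []
        unexplained: list[ScanHit] = []
        for hit in scan.hits:
            best: tuple[float, LipidSpecies] | None = None
            for sp in members:
                d = abs(hit.precursor_mz - sp.mz(M_MINUS_H))
                if d <= tol.window(hit.precursor_mz) and (
                    best is None or d < best[0]
                ):
                    best = (d, sp)
            if best is None:
                unexplained.append(hit)
            else:
                candidates.append(
                    CandidateMatch(best[1], hit, hit.precursor_mz - best[1].mz(M_MINUS_H))
                )
        cl_hits = tuple(
            h for h in scan.hits if CL_REGION[0] <= h.precursor_mz <= CL_REGION[1]
        )
        flags: list[str] = []
        if len(aa_group) > 1:
            flags.append("isobaric-ambiguity")
        if any(aa in UNRELIABLE_SCREEN_AA for aa in aa_group):
            flags.append("cysteine-unreliable")
        if any(c.species.backbone == "PE" for c in candidates):
            flags.append("aminoacyl-PE-artifact-caution")
        groups_out.append(
            AminoAcidGroupResult(
                amino_acids=aa_group,
                query_mz=query,
                scan=scan,
                candidates=tuple(candidates),
                unexplained=tuple(unexplained),
                cl_region_hits=cl_hits,
                flags=tuple(flags),
            )
        )
    return ScreenReport(tuple(groups_out), tol, len(records))


#: fragment names that carry head-group aminoacylation evidence contain the
#: amino-acid code; DAG/PA/Pho/Gro-Pho ions do not and never confirm.
def _is_diagnostic(ion_name: str, aa: str) -> bool:
    return aa in ion_name


@dataclass(frozen=True)
class Identification:
    species: LipidSpecies
    adduct: Adduct
    evidence: Annotation
    n_diagnostic_matched: int
    status: str  # "confirmed" | "tentative" | "rejected"
    flags: tuple[str, ...] = ()


def confirm_species(
    candidate: LipidSpecies,
    record: MsMsRecord,
    tol: MassTolerance = MassTolerance(5.0, "ppm"),
    adduct: Adduct | str = "[M+Na]+",
    min_diagnostic: int = 3,
    precursor_tol: float = 1.0,
) -> Identification:
    """Confirm (or reject) an aminoacyl-lipid candidate from a high-accuracy
    MS/MS record.

    The record is annotated against the candidate's theoretical fragment
    table; the species is confirmed when at least ``min_diagnostic``
    aminoacyl-bearing head-group ions match within tolerance.  With matches
    but fewer diagnostics the call is tentative; with none it is rejected.
    Aminoacyl-PE candidates are capped at tentative (drying-artifact caution).
    """
    if isinstance(adduct, str):
        adduct = ADDUCTS[adduct]
    table = fragment_table(candidate, adduct)
    ann = annotate_msms(record, table, tol)
    if abs(record.precursor_mz - table.precursor_mz) > precursor_tol:
        # the spectrum is not even of the candidate's molecular ion
        return Identification(
            candidate, adduct, ann, 0, "rejected", ("precursor-mismatch",)
        )
    aa = candidate.amino_acid
    n_diag = (
        sum(1 for name in ann.assigned_names() if _is_diagnostic(name, aa))
        if aa
        else 0
    )
    flags: list[str] = []
    if candidate.backbone == "PE" and aa:
        flags.append("aminoacyl-PE-artifact-caution")
    if aa is None:
        status = "confirmed" if ann.n_assigned >= min_diagnostic else "tentative"
    elif n_diag >= min_diagnostic and "aminoacyl-PE-artifact-caution" not in flags:
        status = "confirmed"
    elif n_diag > 0 or ann.n_assigned > 0:
        status = "tentative"
    else:
        status = "rejected"
    return Identification(candidate, adduct, ann, n_diag, status, tuple(flags))


@dataclass(frozen=True)
class AbundanceEntry:
    label: str
    amino_acids: tuple[str, ...]
    intensity: float
    fraction: float


def abundance_profile(report: ScreenReport) -> list[AbundanceEntry]:
    """Relative-abundance ranking of detected aminoacyl groups.

    Groups are sorted by summed responding intensity; fractions are over
    detected groups and sum to 1.  This is a semi-quantitative readout of
    aminoacyl-PG synthase specificity, not absolute quantification.
    """
    detected = report.detected_groups()
    if not detected:
        return []
    total = sum(g.total_intensity for g in detected)
    ranked = sorted(detected, key=lambda g: g.total_intensity, reverse=True)
    return [
        AbundanceEntry(g.label, g.amino_acids, g.total_intensity,
                       g.total_intensity / total)
        for g in ranked
    ]
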