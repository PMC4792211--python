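"""Triple-quadrupole acquisition-mode emulation over MS/MS record collections.

A precursor-ion scan reports every precursor whose product spectrum contains
a peak at a fixed m/z; a neutral-loss scan reports every precursor showing a
fixed precursor-minus-product difference.  Both are modeled as queries over
already-acquired product spectra: a record "responds" with the intensity of
the matching product peak (the scan ordinate is ion counts of the detected
product, not the MS1 precursor intensity), and responding precursors are
aggregated into m/z bins of the query tolerance's width, summing intensity
over repeat acquisitions of the same precursor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .chem import MassTolerance, delta_ppm
from .fragments import FragmentIon, FragmentTable


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("peak m/z must be positive")
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")


@dataclass(frozen=True)
class MsMsRecord:
    """One centroided product-ion spectrum with its precursor m/z."""

    precursor_mz: float
    polarity: int  # +1 / -1
    peaks: tuple[Peak, ...]
    source_id: str = ""
    collision_energy: float | None = None

    def __post_init__(self) -> None:
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")
        object.__setattr__(
            self, "peaks", tuple(sorted(self.peaks, key=lambda p: p.mz))
        )

    def base_peak(self) -> Peak | None:
        return max(self.peaks, key=lambda p: p.intensity, default=None)


@dataclass(frozen=True)
class ScanHit:
    precursor_mz: float
    intensity: float
    n_records: int = 1


@dataclass(frozen=True)
class ScanResult:
    """Hits of one precursor-ion or neutral-loss query, sorted by precursor."""

    query_mz: float  # fragment m/z or neutral-loss mass
    tolerance: MassTolerance
    mode: str  # "precursor" | "neutral_loss"
    hits: tuple[ScanHit, ...]

    @property
    def total_intensity(self) -> float:
        return sum(h.intensity for h in self.hits)

    def best_hit(self) -> ScanHit | None:
        return max(self.hits, key=lambda h: h.intensity, default=None)


def _bin_hits(
    raw: list[tuple[float, float]], bin_width: float
) -> tuple[ScanHit, ...]:
    """Aggregate (precursor_mz, intensity) pairs into bins of bin_width,
    chaining neighbours: repeat acquisitions of one precursor sum up."""
    if not raw:
        return ()
    raw.sort()
    groups: list[list[tuple[float, float]]] = [[raw[0]]]
    for pmz, inten in raw[1:]:
        if pmz - groups[-1][-1][0] <= bin_width:
            groups[-1].append((pmz, inten))
        else:
            groups.append([(pmz, inten)])
    hits = []
    for g in groups:
        total = sum(i for _, i in g)
        centroid = sum(p * i for p, i in g) / total if total > 0 else g[0][0]
        hits.append(ScanHit(centroid, total, len(g)))
    return tuple(hits)


def precursor_ion_scan(
    records: Iterable[MsMsRecord],
    fragment_mz: float,
    tol: MassTolerance,
) -> ScanResult:
    """Scan for precursors of a fixed product ion.

    All records must share one polarity.  A record responds with the
    intensity of its product peak nearest ``fragment_mz`` within the window
    (the maximum if several fall inside).
    """
    records = list(records)
    polarities = {r.polarity for r in records}
    if len(polarities) > 1:
        raise ValueError("records mix polarities; scan one polarity at a time")
    window = tol.window(fragment_mz)
    raw: list[tuple[float, float]] = []
    for rec in records:
        matched = [
            p.intensity for p in rec.peaks if abs(p.mz - fragment_mz) <= window
        ]
        if matched:
            raw.append((rec.precursor_mz, max(matched)))
    return ScanResult(fragment_mz, tol, "precursor", _bin_hits(raw, window))


def neutral_loss_scan(
    records: Iterable[MsMsRecord],
    loss_mass: float,
    tol: MassTolerance,
) -> ScanResult:
    """Scan for a fixed precursor-minus-product mass difference (singly
    charged convention: the difference in m/z equals the neutral mass)."""
    if loss_mass <= 0:
        raise ValueError("neutral-loss mass must be positive")
    raw: list[tuple[float, float]] = []
    window = tol.window(loss_mass)
    for rec in records:
        matched = [
            p.intensity
            for p in rec.peaks
            if abs((rec.precursor_mz - p.mz) - loss_mass) <= window
        ]
        if matched:
            raw.append((rec.precursor_mz, max(matched)))
    return ScanResult(loss_mass, tol, "neutral_loss", _bin_hits(raw, window))


@dataclass(frozen=True)
class Assignment:
    peak: Peak
    ion: FragmentIon
    delta_amu: float
    delta_ppm: float


@dataclass(frozen=True)
class Annotation:
    """Peak-to-fragment assignment of one spectrum against one theory table."""

    record: MsMsRecord
    table: FragmentTable
    tolerance: MassTolerance
    assignments: tuple[Assignment, ...]
    unassigned: tuple[Peak, ...]

    @property
    def n_assigned(self) -> int:
        return len(self.assignments)

    def assigned_names(self) -> set[str]:
        return {a.ion.name for a in self.assignments}


def annotate_msms(
    record: MsMsRecord, table: FragmentTable, tol: MassTolerance
) -> Annotation:
    """Greedy nearest-match annotation of observed peaks against a fragment
    table: candidate (peak, ion) pairs within tolerance are taken in order of
    increasing |delta m| (ties broken by table order), each peak and each ion
    used at most once.  The result is invariant to input peak order.
    """
    if record.polarity != table.adduct.polarity:
        raise ValueError(
            f"record polarity {record.polarity:+d} does not match "
            f"table adduct {table.adduct}"
        )
    candidates: list[tuple[float, int, int]] = []
    for ion_idx, ion in enumerate(table.ions):
        window = tol.window(ion.mz)
        for peak_idx, peak in enumerate(record.peaks):
            if abs(peak.mz - ion.mz) <= window:
                candidates.append((abs(peak.mz - ion.mz), ion_idx, peak_idx))
    candidates.sort()
    used_peaks: set[int] = set()
    used_ions: set[int] = set()
    assignments: list[Assignment] = []
    for _, ion_idx, peak_idx in candidates:
        if ion_idx in used_ions or peak_idx in used_peaks:
            continue
        used_ions.add(ion_idx)
        used_peaks.add(peak_idx)
        ion = table.ions[ion_idx]
        peak = record.peaks[peak_idx]
        assignments.append(
            Assignment(peak, ion, peak.mz - ion.mz, delta_ppm(peak.mz, ion.mz))
        )
    assignments.sort(key=lambda a: a.ion.mz)
    unassigned = tuple(
        p for i, p in enumerate(record.peaks) if i not in used_peaks
    )
    return Annotation(record, table, tol, tuple(assignments), unassigned)
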