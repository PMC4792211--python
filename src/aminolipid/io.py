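"""Readers/writers and screen configuration.

MGF is the working text format for MS/MS collections (PEPMASS carries the
precursor m/z and the CHARGE sign the polarity); mzML is supported read-only.
Both go through pyteomics.  Tabular exports (libraries, fragment tables,
scan results, screen reports) are pandas DataFrames written as CSV with m/z
printed to 4 decimals.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import base64
import struct
import zlib

import numpy as np
import pandas as pd
import yaml
from lxml import etree
from pyteomics import mgf as _mgf

from .chem import ADDUCTS, MassTolerance
from .fragments import FragmentTable
from .lipids import AMINO_ACIDS, LipidSpecies, enumerate_library
from .marfey import Chromatogram
from .scans import MsMsRecord, Peak, ScanResult
from .screen import ScreenReport

log = logging.getLogger("aminolipid")


# ---------------------------------------------------------------------------
# MS/MS collections

def write_mgf(records: Iterable[MsMsRecord], path: str | Path) -> None:
    spectra = []
    for i, rec in enumerate(records):
        spectra.append(
            {
                "m/z array": np.array([p.mz for p in rec.peaks]),
                "intensity array": np.array([p.intensity for p in rec.peaks]),
                "params": {
                    "title": rec.source_id or f"record_{i}",
                    "pepmass": (rec.precursor_mz, None),
                    "charge": "1-" if rec.polarity < 0 else "1+",
                },
            }
        )
    _mgf.write(spectra, str(path), file_mode="w")


def _polarity_from_charge(charge) -> int:
    # pyteomics parses "1-" into ChargeList([-1])
    try:
        first = charge[0]
    except (TypeError, IndexError):
        first = charge
    return -1 if int(first) < 0 else 1


def read_mgf(path: str | Path) -> list[MsMsRecord]:
    records: list[MsMsRecord] = []
    skipped = 0
    with _mgf.MGF(str(path)) as reader:
        for spec in reader:
            params = spec.get("params", {})
            pepmass = params.get("pepmass")
            if not pepmass or pepmass[0] is None:
                skipped += 1
                continue
            polarity = _polarity_from_charge(params.get("charge", [1]))
            peaks = tuple(
                Peak(float(mz), float(inten))
                for mz, inten in zip(spec["m/z array"], spec["intensity array"])
            )
            records.append(
                MsMsRecord(
                    precursor_mz=float(pepmass[0]),
                    polarity=polarity,
                    peaks=peaks,
                    source_id=str(params.get("title", "")),
                )
            )
    if skipped:
        log.warning("skipped %d MGF records lacking a precursor m/z", skipped)
    return records


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"


def _decode_binary_array(array_el) -> np.ndarray | None:
    """Decode one mzML <binaryDataArray> (64/32-bit float, zlib or none)."""
    accessions = {
        cv.get("accession") for cv in array_el.iter(f"{_MZML_NS}cvParam")
    }
    binary = array_el.find(f"{_MZML_NS}binary")
    if binary is None or not (binary.text or "").strip():
        return np.array([])
    raw = base64.b64decode(binary.text)
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    values = np.frombuffer(raw, dtype=dtype).astype(float)
    if "MS:1000514" in accessions:
        return ("mz", values)  # type: ignore[return-value]
    if "MS:1000515" in accessions:
        return ("intensity", values)  # type: ignore[return-value]
    return None


def read_mzml(path: str | Path) -> list[MsMsRecord]:
    """Read centroided MS2 spectra from an mzML file.

    This is a minimal reader for the subset this package consumes (ms level,
    scan polarity, selected-ion m/z, float peak arrays, optional zlib).
    """
    records: list[MsMsRecord] = []
    skipped = 0
    for _, spec in etree.iterparse(str(path), tag=f"{_MZML_NS}spectrum"):
        params = {
            cv.get("accession"): cv.get("value")
            for cv in spec.iter(f"{_MZML_NS}cvParam")
        }
        if params.get("MS:1000511") != "2":  # ms level
            spec.clear()
            continue
        precursor = params.get("MS:1000744")  # selected ion m/z
        if precursor is None:
            skipped += 1
            spec.clear()
            continue
        polarity = -1 if "MS:1000129" in params else 1  # negative scan
        arrays: dict[str, np.ndarray] = {}
        for array_el in spec.iter(f"{_MZML_NS}binaryDataArray"):
            decoded = _decode_binary_array(array_el)
            if isinstance(decoded, tuple):
                arrays[decoded[0]] = decoded[1]
        peaks = tuple(
            Peak(float(mz), float(inten))
            for mz, inten in zip(
                arrays.get("mz", ()), arrays.get("intensity", ())
            )
            if inten > 0
        )
        records.append(
            MsMsRecord(
                precursor_mz=float(precursor),
                polarity=polarity,
                peaks=peaks,
                source_id=str(spec.get("id", "")),
            )
        )
        spec.clear()
    if skipped:
        log.warning("skipped %d mzML MS2 spectra lacking a precursor m/z", skipped)
    return records


def read_msms_collection(path: str | Path, format: str | None = None) -> list[MsMsRecord]:
    """Read an MS/MS collection from MGF or mzML (format inferred from the
    extension when not given)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "mgf":
        return read_mgf(path)
    if fmt == "mzml":
        return read_mzml(path)
    raise ValueError(f"unsupported MS/MS format {fmt!r}")


# ---------------------------------------------------------------------------
# tabular exports

def library_to_dataframe(library: Sequence[LipidSpecies]) -> pd.DataFrame:
    rows = []
    for s in library:
        f = s.formula()
        rows.append(
            {
                "backbone": s.backbone,
                "modification": s.amino_acid or "",
                "acyl": s.acyl.notation,
                "formula": f.hill(),
                "neutral_mass": round(f.mass, 4),
                "mz[M-H]-": round(s.mz("[M-H]-"), 4),
                "mz[M+H]+": round(s.mz("[M+H]+"), 4),
                "mz[M+Na]+": round(s.mz("[M+Na]+"), 4),
            }
        )
    return pd.DataFrame(rows)


def scan_result_to_dataframe(result: ScanResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "precursor_mz": [round(h.precursor_mz, 4) for h in result.hits],
            "intensity": [h.intensity for h in result.hits],
            "n_records": [h.n_records for h in result.hits],
        }
    )


def screen_report_to_dataframe(report: ScreenReport) -> pd.DataFrame:
    rows = []
    for g in report.groups:
        best = g.best_candidate()
        rows.append(
            {
                "group": g.label,
                "query_mz": round(g.query_mz, 4),
                "n_hits": len(g.scan.hits),
                "total_intensity": g.total_intensity,
                "best_candidate": best.species.name if best else "",
                "n_unexplained": len(g.unexplained),
                "n_cl_region": len(g.cl_region_hits),
                "flags": ";".join(g.flags),
            }
        )
    return pd.DataFrame(rows)


def screen_report_summary(report: ScreenReport) -> str:
    """Human-readable narrative summary of a screen report."""
    from .screen import abundance_profile

    lines = [
        f"Aminoacyl-lipid screen over {report.n_records} negative-mode records "
        f"(tolerance {report.tolerance})",
    ]
    profile = abundance_profile(report)
    if not profile:
        lines.append("No aminoacyl-lipid precursors detected.")
    else:
        lines.append("Detected aminoacyl groups, ranked by summed response:")
        for e in profile:
            g = report.group(e.amino_acids[0])
            best = g.best_candidate()
            cand = f"; best candidate {best.species.name}" if best else ""
            flags = f" [{', '.join(g.flags)}]" if g.flags else ""
            lines.append(
                f"  {e.label:>9}: {e.intensity:.3g} counts "
                f"({100 * e.fraction:.2g}%){cand}{flags}"
            )
    n_cl = sum(len(g.cl_region_hits) for g in report.groups)
    lines.append(
        f"Cardiolipin-sized region (1400-1600): {n_cl} hit(s)."
        if n_cl
        else "No hits in the cardiolipin-sized region (1400-1600)."
    )
    n_unexpl = sum(len(g.unexplained) for g in report.groups)
    if n_unexpl:
        lines.append(f"{n_unexpl} responding precursor(s) without a library match.")
    return "\n".join(lines)


def write_chromatogram_csv(c: Chromatogram, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# monitored_mz={c.monitored_mz}\n")
        pd.DataFrame({"minutes": c.times, "intensity": c.intensities}).to_csv(
            fh, index=False
        )


def read_chromatogram_csv(path: str | Path) -> Chromatogram:
    monitored = float("nan")
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "monitored_mz=" in first:
                monitored = float(first.split("monitored_mz=")[1])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    return Chromatogram(
        monitored_mz=monitored,
        times=df.iloc[:, 0].to_numpy(float),
        intensities=df.iloc[:, 1].to_numpy(float),
    )


# ---------------------------------------------------------------------------
# configuration

@dataclasses.dataclass
class ScreenConfig:
    """Serializable configuration of a full screen run."""

    amino_acids: list[str] = dataclasses.field(
        default_factory=lambda: sorted(AMINO_ACIDS)
    )
    backbones: list[str] = dataclasses.field(default_factory=lambda: ["PG"])
    carbon_range: tuple[int, int] = (26, 36)
    unsat_range: tuple[int, int] = (0, 2)
    per_chain_range: tuple[int, int] = (12, 20)
    unit_tolerance_amu: float = 0.3
    accurate_tolerance_ppm: float = 5.0
    min_diagnostic: int = 3
    instrument: str = "qtrap"  # "qtrap" | "qtof" | "noiseless"
    seed: int = 0
    output_dir: str = "screen_output"

    def __post_init__(self) -> None:
        unknown = set(self.amino_acids) - set(AMINO_ACIDS)
        if unknown:
            raise ValueError(f"unknown amino acids in config: {sorted(unknown)}")
        self.carbon_range = tuple(self.carbon_range)  # type: ignore[assignment]
        self.unsat_range = tuple(self.unsat_range)  # type: ignore[assignment]
        self.per_chain_range = tuple(self.per_chain_range)  # type: ignore[assignment]

    def library(self) -> list[LipidSpecies]:
        return enumerate_library(
            self.backbones, self.amino_acids, self.carbon_range, self.unsat_range
        )

    def unit_tolerance(self) -> MassTolerance:
        return MassTolerance(self.unit_tolerance_amu, "amu")

    def accurate_tolerance(self) -> MassTolerance:
        return MassTolerance(self.accurate_tolerance_ppm, "ppm")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["carbon_range"] = list(self.carbon_range)
        d["unsat_range"] = list(self.unsat_range)
        d["per_chain_range"] = list(self.per_chain_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)
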