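"""Elemental-formula arithmetic, monoisotopic masses and ion m/z conventions.

All species handled by this package are singly charged, and calculated ion
masses follow plain atom-mass arithmetic: the electron mass is ignored, so
[M-H]- is the neutral monoisotopic mass minus one hydrogen *atom* and [M+Na]+
adds one sodium *atom*.  This convention matches how unit-resolution lipid
MS/MS assignments are conventionally tabulated (calculated fragment masses
such as 145.0978 for the deprotonated lysine anion arise from atom-mass sums).

Atomic masses are pinned in ``data/atomic_masses.csv`` (CODATA/NIST
monoisotopic values, >=9 decimals) so every calculated m/z in the package is
a pure function of an elemental formula.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterator, Mapping


def _load_atomic_masses() -> tuple[dict[str, float], dict[str, int]]:
    masses: dict[str, float] = {}
    nucleons: dict[str, int] = {}
    with resources.files("aminolipid.data").joinpath("atomic_masses.csv").open() as fh:
        for row in csv.DictReader(fh):
            masses[row["element"]] = float(row["monoisotopic_mass"])
            nucleons[row["element"]] = int(row["mass_number"])
    return masses, nucleons


ATOMIC_MASSES, MASS_NUMBERS = _load_atomic_masses()

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed formula text or an operation that would break invariants."""


@dataclass(frozen=True)
class Formula:
    """An elemental formula: non-negative integer counts per element symbol.

    Formulas are immutable and support addition, subtraction (rejected if any
    count would go negative) and integer scaling, so lipid compositions can be
    assembled from building blocks (glycerol + phosphate + acyl chains -
    condensation waters) with exact bookkeeping.
    """

    counts: tuple[tuple[str, int], ...]

    def __init__(self, counts: Mapping[str, int] | None = None, **kw: int):
        merged: dict[str, int] = {}
        for src in (counts or {}), kw:
            for el, n in src.items():
                if el not in ATOMIC_MASSES:
                    raise FormulaError(f"unknown element symbol: {el!r}")
                if n < 0:
                    raise FormulaError(f"negative count for {el}: {n}")
                merged[el] = merged.get(el, 0) + n
        clean = tuple(sorted((el, n) for el, n in merged.items() if n > 0))
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse a Hill-notation formula string such as ``"C6H14N2O2"``.

        The empty string parses to the empty formula (mass 0).
        """
        text = text.strip()
        if not text:
            return cls({})
        pos = 0
        counts: dict[str, int] = {}
        for m in _FORMULA_TOKEN.finditer(text):
            if m.start() != pos:
                raise FormulaError(f"malformed formula {text!r} at position {pos}")
            el, num = m.group(1), m.group(2)
            if el not in ATOMIC_MASSES:
                raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
            pos = m.end()
        if pos != len(text):
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        return cls(counts)

    def __getitem__(self, element: str) -> int:
        return dict(self.counts).get(element, 0)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.counts)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __add__(self, other: "Formula") -> "Formula":
        out = dict(self.counts)
        for el, n in other.counts:
            out[el] = out.get(el, 0) + n
        return Formula(out)

    def __sub__(self, other: "Formula") -> "Formula":
        out = dict(self.counts)
        for el, n in other.counts:
            out[el] = out.get(el, 0) - n
            if out[el] < 0:
                raise FormulaError(
                    f"subtraction leaves negative {el} count: {self} - {other}"
                )
        return Formula(out)

    def __mul__(self, k: int) -> "Formula":
        if not isinstance(k, int) or k < 0:
            raise FormulaError(f"formula scaling requires a non-negative int, got {k!r}")
        return Formula({el: n * k for el, n in self.counts})

    __rmul__ = __mul__

    @property
    def mass(self) -> float:
        """Monoisotopic mass in Da (sum of pinned atomic masses)."""
        return sum(ATOMIC_MASSES[el] * n for el, n in self.counts)

    @property
    def nominal_mass(self) -> int:
        """Nucleon-count nominal mass (sum of integer mass numbers).

        This is the unit-resolution label mass spectrometrists quote for an
        ion: 153 for the cyclo-glycerophosphate anion (monoisotopic 152.9953),
        873 for sodiated (32:0) lysyl-PG (monoisotopic 873.5945).
        """
        return sum(MASS_NUMBERS[el] * n for el, n in self.counts)

    def hill(self) -> str:
        """Hill-notation string: C first, then H, then other elements A-Z."""
        d = dict(self.counts)
        order: list[str] = []
        for el in ("C", "H"):
            if el in d:
                order.append(el)
        order.extend(sorted(el for el in d if el not in ("C", "H")))
        return "".join(f"{el}{d[el] if d[el] != 1 else ''}" for el in order)

    def __str__(self) -> str:
        return self.hill() or "(empty)"

    def __repr__(self) -> str:
        return f"Formula({self.hill()!r})"


def parse_formula(text: str) -> Formula:
    """Alias for :meth:`Formula.parse`."""
    return Formula.parse(text)


def monoisotopic_mass(f: Formula | str) -> float:
    """Monoisotopic mass in Da of a formula (or Hill-notation string)."""
    if isinstance(f, str):
        f = Formula.parse(f)
    return f.mass


# common building blocks
WATER = Formula(H=2, O=1)
HYDROGEN = Formula(H=1)
SODIUM = Formula(Na=1)
HYDROXYL = Formula(H=1, O=1)
AMMONIA = Formula(N=1, H=3)
GLYCEROL = Formula(C=3, H=8, O=3)
PHOSPHORIC_ACID = Formula(H=3, P=1, O=4)
ETHANOLAMINE = Formula(C=2, H=7, N=1, O=1)
METHYLENE = Formula(C=1, H=2)


@dataclass(frozen=True)
class Adduct:
    """A singly charged ionization mode: which atoms are gained or lost.

    All ions in this package carry exactly one charge; ``polarity`` is +1 or
    -1 and ``gain``/``loss`` are the atoms added to / removed from the neutral.
    """

    name: str
    polarity: int
    gain: Formula = Formula()
    loss: Formula = Formula()

    def __post_init__(self) -> None:
        if self.polarity not in (-1, 1):
            raise ValueError("only singly charged ions are modeled")

    def ion_formula(self, neutral: Formula) -> Formula:
        return neutral + self.gain - self.loss

    def mz(self, neutral: Formula) -> float:
        return self.ion_formula(neutral).mass

    def __str__(self) -> str:
        return self.name


M_MINUS_H = Adduct("[M-H]-", -1, loss=HYDROGEN)
M_PLUS_H = Adduct("[M+H]+", +1, gain=HYDROGEN)
M_PLUS_NA = Adduct("[M+Na]+", +1, gain=SODIUM)

ADDUCTS: dict[str, Adduct] = {a.name: a for a in (M_MINUS_H, M_PLUS_H, M_PLUS_NA)}
# convenient aliases for CLI / config use
ADDUCTS.update({"-H": M_MINUS_H, "+H": M_PLUS_H, "+Na": M_PLUS_NA})


def ion_mz(neutral: Formula | str, adduct: Adduct | str) -> float:
    """m/z of a singly charged ion: neutral mass +/- adduct atom masses.

    Deprotonating a formula with no hydrogen raises :class:`FormulaError`.
    """
    if isinstance(neutral, str):
        neutral = Formula.parse(neutral)
    if isinstance(adduct, str):
        adduct = ADDUCTS[adduct]
    return adduct.mz(neutral)


def nominal_mz(mz: float) -> int:
    """Integer part of an m/z value (truncation toward zero)."""
    if mz <= 0:
        raise ValueError(f"m/z must be positive, got {mz}")
    return math.trunc(mz)


@dataclass(frozen=True)
class MassTolerance:
    """An m/z matching window, absolute (amu) or relative (ppm)."""

    value: float
    mode: str = "amu"  # "amu" | "ppm"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("tolerance must be positive")
        if self.mode not in ("amu", "ppm"):
            raise ValueError(f"unknown tolerance mode {self.mode!r}")

    def window(self, mz: float) -> float:
        """Half-width of the window in amu at the given m/z."""
        return self.value if self.mode == "amu" else abs(mz) * self.value * 1e-6

    def matches(self, observed: float, theoretical: float) -> bool:
        return abs(observed - theoretical) <= self.window(theoretical)

    def __str__(self) -> str:
        return f"{self.value:g} {self.mode}"


#: unit-resolution window typical of a triple-quadrupole instrument
UNIT_TOL = MassTolerance(0.3, "amu")
#: high-accuracy window typical of a Q-TOF
PPM_TOL = MassTolerance(5.0, "ppm")


def delta_ppm(observed: float, theoretical: float) -> float:
    return (observed - theoretical) / theoretical * 1e6
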