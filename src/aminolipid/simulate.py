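"""Ground-truth simulators: MS/MS spectra, mixtures and LC chromatograms.

The spectrum simulator places one centroid peak at each theoretical fragment
m/z of a species, perturbed by Gaussian mass error in one of two instrument
regimes — "qtrap" (unit resolution, sigma = 0.2 amu) and "qtof"
(high accuracy, sigma = 2 ppm) — with multiplicative log-normal intensity
noise and a Poisson number of uniform chemical-noise peaks with
exponentially distributed intensity.  Fragment intensity templates follow
the qualitative pattern of real aminoacyl-PG spectra: fatty-acyl and
aminoacyl anions dominate in negative mode; DAG and head-group ions dominate
the sodiated cation spectra.

The chromatogram simulator emulates an extracted-ion trace of a Marfey
(FDAA) amino-acid conjugate anion: Gaussian peaks for the L- (7.55 min) and
D- (9.16 min) conjugates, plus an optional near-isobaric background peak at
8.05 min that only appears when the extraction window is wide enough to
admit the neighbouring nominal mass.

Everything is deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .chem import Adduct, ADDUCTS, MassTolerance
from .fragments import FragmentTable, fragment_table
from .lipids import LipidSpecies
from .marfey import Chromatogram
from .scans import MsMsRecord, Peak

#: default template intensities by fragment-name pattern (relative units).
#: Matched in order; first hit wins; unmatched names get DEFAULT_TEMPLATE.
NEGATIVE_TEMPLATES: tuple[tuple[str, float], ...] = (
    ("[FA", 1.0),
    ("-H]-", 0.8),   # aminoacyl anion
    ("cGP-", 0.15),
)
POSITIVE_TEMPLATES: tuple[tuple[str, float], ...] = (
    ("DAG - OH", 1.0),
    ("DAG - H2O + Na+", 0.6),
    ("DAG + Na+", 0.3),
    ("-Pho + Na+", 0.5),   # (cyclo-)aa-Gro-Pho, Gro-Pho ladder
    ("cyclo-", 0.35),
    ("PA + Na+", 0.25),
    ("PG + Na+", 0.2),
    ("PE + Na+", 0.2),
    ("Pho + Na+", 0.1),
)
DEFAULT_TEMPLATE = 0.2


@dataclass(frozen=True)
class InstrumentModel:
    """Stochastic acquisition model.

    mass_error: Gaussian sigma of m/z error (absolute amu or relative ppm);
    intensity_cv: sigma of the log-normal multiplicative intensity noise;
    noise_peak_rate: expected chemical-noise peaks per spectrum;
    noise_intensity_scale: mean intensity (counts) of a noise peak.
    """

    mass_error: MassTolerance = MassTolerance(0.2, "amu")
    intensity_cv: float = 0.2
    noise_peak_rate: float = 5.0
    noise_intensity_scale: float = 50.0
    seed: int = 0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def mz_sigma(self, mz: float) -> float:
        return self.mass_error.window(mz)


def qtrap_model(seed: int = 0, **kw) -> InstrumentModel:
    """Unit-resolution triple-quadrupole regime (sigma = 0.2 amu)."""
    return InstrumentModel(MassTolerance(0.2, "amu"), seed=seed, **kw)


def qtof_model(seed: int = 0, **kw) -> InstrumentModel:
    """High-accuracy Q-TOF regime (sigma = 2 ppm)."""
    return InstrumentModel(MassTolerance(2.0, "ppm"), seed=seed, **kw)


def noiseless_model(seed: int = 0) -> InstrumentModel:
    """Degenerate model: exact m/z, exact template intensities, no noise."""
    return InstrumentModel(
        MassTolerance(1e-12, "amu"),
        intensity_cv=0.0,
        noise_peak_rate=0.0,
        seed=seed,
    )


def template_intensity(name: str, polarity: int) -> float:
    patterns = NEGATIVE_TEMPLATES if polarity < 0 else POSITIVE_TEMPLATES
    for pat, value in patterns:
        if pat in name:
            return value
    return DEFAULT_TEMPLATE


@dataclass(frozen=True)
class MixtureEntry:
    species: LipidSpecies
    adduct: str  # adduct name, e.g. "[M-H]-"
    abundance: float

    def __post_init__(self) -> None:
        if self.abundance <= 0:
            raise ValueError("abundance must be positive")


@dataclass(frozen=True)
class MixtureTruth:
    """Ground truth of a simulated lipid extract."""

    entries: tuple[MixtureEntry, ...]

    @classmethod
    def build(
        cls, triples: Iterable[tuple[LipidSpecies, str, float]]
    ) -> "MixtureTruth":
        return cls(tuple(MixtureEntry(s, a, ab) for s, a, ab in triples))

    def species_set(self) -> set[LipidSpecies]:
        return {e.species for e in self.entries}


def simulate_msms(
    species: LipidSpecies,
    adduct: Adduct | str,
    model: InstrumentModel,
    abundance: float = 1e5,
    rng: np.random.Generator | None = None,
    templates: dict[str, float] | None = None,
) -> MsMsRecord:
    """Simulate one centroided MS/MS record of a species.

    With the degenerate (noiseless) model, peaks sit exactly at the
    theoretical fragment m/z values with intensity = template * abundance.
    """
    if isinstance(adduct, str):
        adduct = ADDUCTS[adduct]
    if rng is None:
        rng = model.rng()
    table = fragment_table(species, adduct)
    peaks: list[Peak] = []
    for ion in table.ions:
        base = (
            templates[ion.name]
            if templates and ion.name in templates
            else template_intensity(ion.name, adduct.polarity)
        )
        mz = ion.mz + rng.normal(0.0, model.mz_sigma(ion.mz))
        inten = base * abundance
        if model.intensity_cv > 0:
            inten *= rng.lognormal(0.0, model.intensity_cv)
        peaks.append(Peak(mz, inten))
    precursor = table.precursor_mz + rng.normal(
        0.0, model.mz_sigma(table.precursor_mz)
    )
    n_noise = rng.poisson(model.noise_peak_rate) if model.noise_peak_rate > 0 else 0
    for _ in range(n_noise):
        peaks.append(
            Peak(
                rng.uniform(50.0, max(51.0, precursor)),
                rng.exponential(model.noise_intensity_scale),
            )
        )
    return MsMsRecord(
        precursor_mz=precursor,
        polarity=adduct.polarity,
        peaks=tuple(peaks),
        source_id=f"sim:{species.name}:{adduct.name}",
    )


def simulate_mixture(
    truth: MixtureTruth,
    model: InstrumentModel,
    replicates: int = 1,
) -> list[MsMsRecord]:
    """One MS/MS record per truth entry (times ``replicates`` for
    multi-channel-accumulation emulation), deterministically shuffled."""
    if not truth.entries:
        raise ValueError("empty mixture truth")
    rng = model.rng()
    records = [
        simulate_msms(e.species, e.adduct, model, e.abundance, rng=rng)
        for e in truth.entries
        for _ in range(replicates)
    ]
    order = rng.permutation(len(records))
    return [records[i] for i in order]


def paper_like_truth(
    acyl: str = "32:0",
    ladder: dict[str, float] | None = None,
) -> MixtureTruth:
    """The reference screen condition: four aminoacyl-PGs whose aminoacyl-
    anion responses span three orders of magnitude (Lys 6e6, Ala 9e5,
    Leu 4e4, Asp 7e3 counts)."""
    from .lipids import parse_acyl

    if ladder is None:
        ladder = {"Lys": 6e6, "Ala": 9e5, "Leu": 4e4, "Asp": 7e3}
    comp = parse_acyl(acyl)
    return MixtureTruth.build(
        (LipidSpecies("PG", comp, aa), "[M-H]-", ab) for aa, ab in ladder.items()
    )


def simulate_marfey_chromatogram(
    d_fraction: float,
    total_area: float = 1e6,
    model: InstrumentModel | None = None,
    rt_L: float = 7.55,
    rt_D: float = 9.16,
    sigma: float = 0.08,
    interference: bool = True,
    mz_window: float = 0.5,
    monitored_mz: float = 340.0,
    t_span: tuple[float, float] = (5.0, 12.0),
    dt: float = 0.01,
) -> Chromatogram:
    """Extracted-ion chromatogram of an amino acid's Marfey conjugate anion.

    Gaussian peaks with areas (1-d)*A at ``rt_L`` and d*A at ``rt_D``.  A
    background ion one nominal mass below (the "339" interferent at 8.05
    min) leaks into the trace only when ``mz_window`` >= 0.5 amu, exercising
    extraction-window discipline.  When a stochastic model is given, the
    whole trace gets one log-normal injection-scale factor (``intensity_cv``)
    and an additive counting-noise floor (``noise_intensity_scale`` counts,
    clipped at zero); peak shapes stay smooth, as in a real extracted-ion
    trace, so area ratios are preserved.
    """
    if not 0.0 <= d_fraction <= 1.0:
        raise ValueError("d_fraction must lie in [0, 1]")
    t = np.arange(t_span[0], t_span[1] + dt / 2, dt)
    y = np.zeros_like(t)

    def gauss(area: float, mu: float) -> np.ndarray:
        return area / (sigma * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((t - mu) / sigma) ** 2
        )

    y += gauss((1.0 - d_fraction) * total_area, rt_L)
    y += gauss(d_fraction * total_area, rt_D)
    if interference and mz_window >= 0.5:
        # near-isobaric background anion, one nominal mass below
        y += gauss(0.2 * max(total_area, 1.0), 8.05)
    if model is not None and (model.intensity_cv > 0 or model.noise_intensity_scale > 0):
        rng = model.rng()
        if model.intensity_cv > 0:
            y *= rng.lognormal(0.0, model.intensity_cv)
        if model.noise_intensity_scale > 0:
            y = np.clip(
                y + rng.normal(0.0, model.noise_intensity_scale, size=y.shape),
                0.0,
                None,
            )
    return Chromatogram(monitored_mz=monitored_mz, times=t, intensities=y)
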