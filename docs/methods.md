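# Methods

## Mass calculus and ion conventions

All masses are monoisotopic, computed from a pinned atomic-mass table
(`aminolipid/data/atomic_masses.csv`; CODATA/NIST values for H, C, N, O, F,
Na, P, S to ≥9 decimals) so every m/z in the package is a pure, exactly
additive function of an elemental formula. Every species handled here is
singly charged, and ion m/z follows plain atom-mass arithmetic — [M−H]⁻
removes one hydrogen atom, [M+Na]⁺ adds one sodium atom, the electron mass
is ignored. This is the convention under which published calculated fragment
masses for these lipids are tabulated (e.g. 145.0978 for the deprotonated
lysine anion); including the electron would shift every value by ~0.0005 Da
in opposite directions per polarity and systematically miss those tables.
Different atomic-mass tables in circulation differ by a few 0.0001 Da once
summed over a lipid-sized formula, so agreement with printed calculated
values is asserted at ±0.0015 Da throughout rather than at face precision.

Two integer "nominal" conventions coexist in practice and both are exposed:

- `nominal_mz(x)` truncates an m/z toward zero (873.5945 → 873), which is
  how high-mass unit-resolution labels usually arise;
- `Formula.nominal_mass` sums integer nucleon numbers over the ion formula.

The nucleon count is what the package uses to label ions, because it is the
only convention that reproduces *all* customary labels at once: the
cyclo-glycerophosphate anion (monoisotopic 152.9953) is universally called
"153", which truncation gets wrong, while for lipid-sized ions accumulated
mass defect makes the nucleon count coincide with truncation (873 for
m/z 873.5945).

## Lipid model

Species are modeled at total-acyl-composition level, "(nc:nd)" — the
granularity a unit-resolution precursor scan can read. sn-positional
isomers are not represented, and monounsaturated vs cyclopropane chains,
being mass-identical, are not distinguished. Neutral formulas are assembled
by condensation bookkeeping (backbone core + summed fatty acids − one water
per ester + aminoacyl residue), which reduces to closed forms
PG(nc:nd) = C(nc+6)H(2nc−2nd+11)O10P and PE(nc:nd) = C(nc+5)H(2nc−2nd+10)NO8P.
Cardiolipin is two phosphatidyl units on a central glycerol (4 chains);
aminoacylation is placed on the remaining central hydroxyl, where only the
mass matters. The amino-acid set defaults to all 20 proteinogenic residues;
ester attachment costs one water (+128.0950 for Lys, +71.0371 for Ala).
Cysteine stays in the library but is flagged screen-unreliable. D/L
stereochemistry is a mass-silent label.

## Fragmentation rules

The fragment generator is a declarative rule table, not a generic bond-graph
cleaver: collision-induced dissociation of these lipids yields a small,
named vocabulary of ions, and reproducing that vocabulary exactly — masses
and scissile-bond labels — is the contract. Negative mode gives per-chain
fatty-acyl anions (every split of the total composition with per-chain
carbons in a configurable range, default 12–20, unsaturations distributed
both ways), the aminoacyl anion for ester-linked (PG) species, and the
cyclo-glycerophosphate anion for glycerophosphate backbones. The sodiated
cation gives the head-group ladder (phosphate, (cyclo-)glycerolphosphate,
cyclo-aminoacyl, (cyclo-)aminoacyl-glycerol(-phosphate)) plus DAG − OH,
DAG − H2O + Na, DAG + Na, PA + Na and the PG + Na survivor of cyclo-aminoacyl
loss; "cyclo-" always means one water lighter than the open form. Protonated
aminoacyl species return only DAG − OH and the head-group loss ions and are
flagged low-informative. Amide-linked aminoacyl-PE does not release a free
aminoacyl anion; its screen channels are the head-group neutral losses and
sodiated head fragments instead. Minor fatty-acid/ketene losses from
sodiated precursors sit behind an off-by-default flag. Deprotonated
cardiolipin gets a minimal table (aminoacyl anion if modified, plus the
backbone anion) — enough for precursor-level screening; positive-mode CL
fragmentation is deliberately unsupported. Every fragment records its
complementary neutral, and fragment + complement reassembles the precursor
ion formula exactly; this identity is enforced at construction and asserted
property-style in tests.

## Scan emulation

Precursor-ion and neutral-loss scans are queries over already-simulated (or
loaded) product spectra. A record responds with the intensity of the
matching product peak — the scan ordinate is ion counts of the detected
product, not MS1 precursor intensity — and responding precursors are
aggregated into bins one query-window wide, summing over repeat
acquisitions; this summation is also how multi-cycle (MCA) accumulation is
emulated. The product-matching window defaults to ±0.3 amu for
unit-resolution work and is fully configurable. Spectrum annotation is
greedy nearest-match: candidate (peak, ion) pairs within tolerance are taken
in order of increasing |Δm| (ties by table order), each peak and ion used at
most once, with Δm reported in both amu and ppm; the assignment is invariant
to input peak order.

## Screen and confirmation

The screen runs one precursor-ion scan per distinct deprotonated amino-acid
anion m/z. Amino acids whose anions are indistinguishable at the working
tolerance are scanned and reported as one group — Lys/Gln (Δ = 0.0365) merge
at 0.3 amu and split only under high-accuracy evidence; Leu/Ile share a
formula and never split. Responding precursors are matched back to library
species within tolerance; unmatched hits are retained as unexplained
(discovery mode), and the cardiolipin-sized region (1400–1600) is reported
separately. Confirmation annotates a high-accuracy record against the
candidate's fragment table and requires at least `min_diagnostic` (default
3) aminoacyl-bearing head-group ions; DAG-type ions are common to all
glycerophospholipids and never confirm by themselves. A record whose
precursor is not within 1 amu of the candidate's molecular ion is rejected
outright. Aminoacyl-PE candidates are capped at "tentative" with an
artifact-caution flag: drying lipid films can generate them chemically from
PE and aminoacyl-PG, so instrument evidence alone cannot establish them as
biological. The abundance profile ranks detected groups by summed responding
intensity with fractions over detected groups; because ionization and
dissociation efficiency differ between amino acids, it is a semi-quantitative
specificity readout, not absolute quantification.

## Synthetic data

The spectrum simulator places one centroid peak per theoretical fragment,
with Gaussian m/z error in one of two named regimes — "qtrap" (σ = 0.2 amu,
the practical accuracy of a unit-resolution triple quadrupole) and "qtof"
(σ = 2 ppm) — log-normal multiplicative intensity noise (CV default 0.2),
and a Poisson number (mean 5) of uniform-m/z chemical-noise peaks with
exponential intensity (mean 50 counts). Fragment intensity templates follow
the qualitative pattern of real spectra (fatty-acyl and aminoacyl anions
dominant in negative mode; DAG and head-group ions dominant sodiated); exact
intensity prediction is out of scope. The reference mixture condition is
four aminoacyl-PGs with anion responses 6×10⁶ / 9×10⁵ / 4×10⁴ / 7×10³
counts (Lys / Ala / Leu / Asp). With σ = 0.2 amu against a ±0.3 amu window a
single acquisition misses a diagnostic peak ~13% of the time; the screen's
acquisition protocol therefore accumulates 30 cycles (`replicates=30`),
mirroring how unit-resolution precursor scans are actually acquired, and
under that protocol the truth ranking is recovered in ≥95% of seeded
replicates. The chromatogram simulator produces Gaussian L- and D-conjugate
peaks (σ = 0.08 min at 7.55 and 9.16 min), an optional near-isobaric
background peak at 8.05 min that leaks in only when the extraction window
is ≥0.5 amu wide, one log-normal injection-scale factor and an additive
counting-noise floor. All generators are bit-deterministic under a seed.

What the simulator does **not** emulate — isotopic envelopes, detector
saturation, chromatographic MS1 features, collision-energy-dependent
intensities, co-eluting isomers — bounds what green tests mean: they
demonstrate the calculus, the scan logic and the inference rules, not
instrument-grade robustness on real extracts.

## Chromatographic peak handling

Peaks are local maxima (scipy.signal.find_peaks) above a caller-supplied
height threshold; the reported area is the trapezoidal integral between the
points where the trace falls below 1% of the apex (or a saddle toward a
neighbouring peak), which recovers an isolated Gaussian's area to well under
1% at a 0.01-min grid. The full width at half maximum is reported alongside.
An integration bounded at half height was considered and rejected: it
captures only ~76% of a Gaussian's area and cannot meet the 2% area-recovery
contract. D/L classification assigns peaks to ±0.3-min windows around the
reference retention times (apex values are all the references available),
takes D-fraction = area(D)/(area(D)+area(L)), and is scale-invariant by
construction; both height- and area-based single-point quantification
against a standard are supported, with area the default.

## Numerical and interface choices

Tolerances are explicit objects (absolute amu or relative ppm). Annotation
ties break by smallest |Δm| then table order. Empty libraries, mixed-polarity
scans, non-positive neutral losses, deprotonation without hydrogen and
negative formula counts raise errors rather than degrade. MGF is the working
text format (precursor in PEPMASS, polarity from the CHARGE sign); mzML is
read-only through a minimal lxml-based MS2 reader covering centroided
spectra, selected-ion m/z, scan polarity and float peak arrays (zlib or
uncompressed). Reports print m/z to 4 decimals. The fragment-table builder
is memoized, which the replicate-heavy screen benchmarks rely on.

## Problem sizes

Default test and acceptance runs use the 11-carbon × 3-unsaturation PG
library (693 species with all 20 amino acids), 100 seeded screen replicates
at 30 accumulated cycles each, and 0.01-min chromatogram grids — sizes
chosen so the full suite exercises every stage in seconds on one core while
keeping Monte-Carlo margins (e.g. ≥95% rank recovery) statistically
meaningful.

## Known limitations

Cysteine's screen channel is flagged but not chemically modeled (thiol side
reactions). The "17 aminoacyl-PGs" scale of a real extract is represented
only through the library mechanics, not a curated roster. Ionization
efficiency is assumed equal across amino acids within the profile's
semi-quantitative caveat. Retention times are inputs, not predictions.
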