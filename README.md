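# aminolipid

In-silico screening of aminoacylated phospholipids by tandem mass
spectrometry, built as a tested, reusable Python library.

Gram-positive bacteria such as *Bacillus subtilis* modulate their negatively
charged membrane surface by esterifying phosphatidylglycerol (PG) head
groups with amino acids — most prominently lysyl-PG and alanyl-PG — which
raises resistance to cationic antimicrobial peptides. These minor lipids are
found by *substructure scans* on a triple quadrupole: a **precursor-ion
scan** reports every lipid whose collision-induced dissociation yields a
chosen fragment (e.g. the deprotonated lysine anion, m/z 145.0978), and a
**neutral-loss scan** reports every precursor losing a chosen neutral (e.g.
the 269-amu lysyl-phosphoethanolamine head group). Candidates are then
confirmed by high-accuracy MS/MS against a theoretical fragment table, and
the stereochemistry of membrane alanylation is read out by LC/MS of Marfey
(FDAA) amino-acid conjugates, whose D-derivative elutes later on reverse
phase.

This package implements the desk-side half of that workflow end to end, with
a synthetic-data generator standing in for the instrument so every stage is
testable without any raw data:

- `aminolipid.chem` — elemental-formula arithmetic on a pinned monoisotopic
  atomic-mass table; singly charged ion m/z by atom-mass arithmetic
  ([M−H]⁻, [M+H]⁺, [M+Na]⁺); nucleon-count nominal masses for
  unit-resolution labels.
- `aminolipid.lipids` — PG / PE / cardiolipin species at total acyl
  composition "(nc:nd)", optional aminoacylation by any of the 20
  proteinogenic amino acids, library enumeration, isobaric grouping
  (Lys/Gln at unit resolution; Leu/Ile always).
- `aminolipid.fragments` — a declarative fragmentation rule engine producing
  the full named fragment vocabulary of (aminoacyl-)PG/PE ions: fatty-acyl
  and aminoacyl anions, the cyclo-glycerophosphate backbone anion (nominal
  153), the sodiated head-group ladder, DAG/PA/PG survivor ions — each with
  its scissile-bond label and exact complementary neutral.
- `aminolipid.scans` — precursor-ion and neutral-loss scan emulation plus
  greedy nearest-match spectrum annotation.
- `aminolipid.screen` — the 20-channel aminoacyl screen, high-accuracy
  confirmation (head-group-diagnostic ions only; DAG ions never confirm) and
  relative-abundance profiling.
- `aminolipid.marfey` — Marfey-conjugate masses, chromatographic peak
  detection and integration, D-fraction classification, enrichment
  arithmetic.
- `aminolipid.simulate` — seeded generators for MS/MS records ("qtrap"
  σ = 0.2 amu and "qtof" σ = 2 ppm error regimes) and extracted-ion
  chromatograms.
- `aminolipid.io` / `aminolipid.cli` — MGF (read/write) and mzML (read)
  collections, CSV/JSON/YAML exports, and a thin `aminolipid` command-line
  wrapper.

## Worked example

Fragment calculus for sodiated (32:0) lysyl-PG (`examples/01_fragment_calculus.py`):

```
(32:0) lysyl-PG: C44H87N2O11P (neutral monoisotopic 850.6047 Da)
precursor [M+Na]+ m/z 873.5945 (nominal 873)

  calc m/z  cleavage  description
  120.9667  c & f     Pho + Na+
  151.0847  h         cyclo-Lys + Na+
  176.9929  c & g     cyclo-Gro-Pho + Na+
  185.1290  f & i     cyclo-Lys-Gro - OH
  195.0034  c & h     Gro-Pho + Na+
  225.1215  f         cyclo-Lys-Gro + Na+
  305.0878  d         cyclo-Lys-Gro-Pho + Na+
  323.0984  c         Lys-Gro-Pho + Na+
  551.5039  c         DAG - OH
  573.4859  c         DAG - H2O + Na+
  591.4964  d         DAG + Na+
  671.4628  f         PA + Na+
  745.4996  h         PG + Na+
```

Each row is a named sub-structure of the sodiated precursor ("cyclo-" means
the dehydrated form, one water lighter): the 151/225/305/323 ladder walks
the lysyl-glycerolphosphate head group, 551–591 are diacylglycerol ions, and
671/745 are the survivors of head-group neutral losses. The screen itself
(`examples/03_screen_profile.py`) simulates a four-species extract whose
aminoacyl-anion responses span three orders of magnitude and recovers the
ranking Lys/Gln > Ala > Leu/Ile > Asp with fractions ≈ 85 / 14 / 0.6 / 0.1 %.
The chiral analysis (`examples/04_marfey_dl.py`) prints:

```
whole-cell hydrolysate: D-fraction 0.900 (truth 0.90)
            L peak at  7.55 min, area 106,983
   background peak at  8.05 min, area 214,038
            D peak at  9.16 min, area 961,767
lipid hydrolysate: D-fraction 1.000 (truth 1.00)
   background peak at  8.05 min, area 207,137
            D peak at  9.16 min, area 1,035,693

surface-vs-membrane D-alanine enrichment: 1,000-fold
```

The D-fraction is the D-window peak area over the summed D+L areas; the
8.05-min peak is a near-isobaric background ion excluded by retention time;
and the enrichment line combines measured concentrations (0.05 vs 0.005 mM)
with the ~100-fold difference in cell equivalents between the two lysates.

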