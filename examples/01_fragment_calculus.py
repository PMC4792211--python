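"""Exact-mass calculus: species formulas, ion m/z and a fragment table.

Builds sodiated (32:0) lysyl-phosphatidylglycerol and prints its theoretical
fragment table — the calculated m/z of every named head-group, DAG and
neutral-loss-survivor ion, with its scissile-bond label.
"""

from aminolipid import (
    AMINO_ACIDS,
    LipidSpecies,
    M_MINUS_H,
    M_PLUS_NA,
    fragment_table,
    ion_mz,
    parse_acyl,
    species_formula,
)

# the three reference anions that anchor the screen's diagnostic channels
for aa in ("Lys", "Gln", "Ala"):
    mz = ion_mz(AMINO_ACIDS[aa], M_MINUS_H)
    print(f"[{aa}-H]-  m/z {mz:.4f}")
print()

species = LipidSpecies("PG", parse_acyl("32:0"), "Lys")
formula = species_formula(species)
print(f"{species}: {formula} (neutral monoisotopic {formula.mass:.4f} Da)")

table = fragment_table(species, M_PLUS_NA)
print(f"precursor [M+Na]+ m/z {table.precursor_mz:.4f} "
      f"(nominal {M_PLUS_NA.ion_formula(formula).nominal_mass})\n")
print(f"{'calc m/z':>10}  {'cleavage':8}  description")
for ion in sorted(table.ions, key=lambda i: i.mz):
    print(f"{ion.mz:10.4f}  {ion.cleavage or '':8}  {ion.name}")

# Each row is a sub-structure of the sodiated precursor; fragment + lost
# neutral always reassemble the precursor formula exactly.
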