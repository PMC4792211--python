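"""Precursor-ion and neutral-loss scan emulation on synthetic spectra.

Simulates negative-mode MS/MS records of two lysyl-PG species, scans for
precursors of the deprotonated lysine anion (145.1), then shows a
neutral-loss scan picking out a lysyl-PE record by its 269-amu head group.
"""

from aminolipid import (
    LipidSpecies,
    MassTolerance,
    MixtureTruth,
    neutral_loss_mass,
    neutral_loss_scan,
    parse_acyl,
    precursor_ion_scan,
    qtrap_model,
    simulate_mixture,
    simulate_msms,
)

unit = MassTolerance(0.3, "amu")

truth = MixtureTruth.build(
    [
        (LipidSpecies("PG", parse_acyl("30:0"), "Lys"), "[M-H]-", 3e6),
        (LipidSpecies("PG", parse_acyl("32:0"), "Lys"), "[M-H]-", 6e6),
    ]
)
records = simulate_mixture(truth, qtrap_model(seed=1), replicates=30)

result = precursor_ion_scan(records, 145.1, unit)
print("precursors of the 145.1 anion (lysyl channel):")
for hit in result.hits:
    print(f"  precursor m/z {hit.precursor_mz:8.2f}  "
          f"summed counts {hit.intensity:,.0f} over {hit.n_records} acquisitions")
# the two hits are the (30:0) and (32:0) lysyl-PG molecular anions

# the neutral-loss channel needs better mass accuracy than a 0.3 amu window
# on noisy unit-resolution data affords reliably, so use the 2 ppm regime
from aminolipid import qtof_model

loss = neutral_loss_mass("lysyl-phosphoethanolamine")
pe_record = simulate_msms(
    LipidSpecies("PE", parse_acyl("30:0"), "Lys"), "[M+H]+", qtof_model(seed=2)
)
nl = neutral_loss_scan([pe_record], loss, unit)
print(f"\nneutral loss of {loss:.2f} Da (lysyl-phosphoethanolamine head):")
for hit in nl.hits:
    print(f"  responding precursor m/z {hit.precursor_mz:.2f} -> lysyl-PE candidate")
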