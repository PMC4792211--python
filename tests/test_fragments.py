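"""Fragment rule engine vs the published assignment tables."""

import pytest

from aminolipid.chem import ADDUCTS, M_MINUS_H, M_PLUS_H, M_PLUS_NA
from aminolipid.fragments import (
    UnsupportedFragmentation,
    diagnostic_fragment,
    enumerate_chain_splits,
    fragment_table,
    neutral_loss_formula,
    neutral_loss_mass,
)
from aminolipid.lipids import LipidSpecies, parse_acyl

# published calculated masses for the sodiated (32:0) lysyl-PG fragment table
LYSYL_PG_TABLE = [
    (120.9667, "c & f", "Pho + Na+"),
    (151.0848, "h", "cyclo-Lys + Na+"),
    (176.9929, "c & g", "cyclo-Gro-Pho + Na+"),
    (185.1291, "f & i", "cyclo-Lys-Gro - OH"),
    (195.0035, "c & h", "Gro-Pho + Na+"),
    (225.1216, "f", "cyclo-Lys-Gro + Na+"),
    (305.0879, "d", "cyclo-Lys-Gro-Pho + Na+"),
    (323.0985, "c", "Lys-Gro-Pho + Na+"),
    (551.5040, "c", "DAG - OH"),
    (573.4862, "c", "DAG - H2O + Na+"),
    (591.4968, "d", "DAG + Na+"),
    (671.4631, "f", "PA + Na+"),
    (745.4999, "h", "PG + Na+"),
]

# published calculated masses for the sodiated (32:0) alanyl-PG fragment table
ALANYL_PG_TABLE = [
    (168.0640, "f", "cyclo-Ala-Gro + Na+"),
    (248.0300, "d", "cyclo-Ala-Gro-Pho + Na+"),
    (266.0410, "c", "Ala-Gro-Pho + Na+"),
    (551.5040, "c", "DAG - OH"),
    (573.4860, "c", "DAG - H2O + Na+"),
]


class TestSodiatedTables:
    @pytest.mark.parametrize("calc,cleavage,name", LYSYL_PG_TABLE)
    def test_lysyl_pg_entries(self, lysyl_pg_32, calc, cleavage, name):
        ion = fragment_table(lysyl_pg_32, M_PLUS_NA).find(name)
        assert ion.mz == pytest.approx(calc, abs=0.0015)
        assert ion.cleavage == cleavage

    @pytest.mark.parametrize("calc,cleavage,name", ALANYL_PG_TABLE)
    def test_alanyl_pg_entries(self, alanyl_pg_32, calc, cleavage, name):
        ion = fragment_table(alanyl_pg_32, M_PLUS_NA).find(name)
        assert ion.mz == pytest.approx(calc, abs=0.0015)
        assert ion.cleavage == cleavage

    def test_precursor_mz(self, lysyl_pg_32, alanyl_pg_32):
        assert fragment_table(lysyl_pg_32, M_PLUS_NA).precursor_mz == pytest.approx(
            873.5945, abs=0.0015
        )
        assert int(fragment_table(alanyl_pg_32, M_PLUS_NA).precursor_mz) == 816

    def test_unmodified_pg_has_no_aminoacyl_ions(self, pg_32):
        names = {i.name for i in fragment_table(pg_32, M_PLUS_NA).ions}
        assert not any("Lys" in n or "Ala" in n for n in names)
        assert "DAG - OH" in names and "Pho + Na+" in names


class TestNegativeMode:
    def test_lysyl_pg_30_anions(self, lysyl_pg_30):
        table = fragment_table(lysyl_pg_30, M_MINUS_H)
        assert table.find("[FA(15:0)-H]-").mz == pytest.approx(241.2168, abs=0.0015)
        assert table.find("[FA(17:0)-H]-").mz == pytest.approx(269.2481, abs=0.0015)
        assert table.find("[Lys-H]-").mz == pytest.approx(145.0978, abs=0.0015)

    def test_cgp_backbone_anion(self, pg_32):
        ion = fragment_table(pg_32, M_MINUS_H).find("cGP-")
        assert ion.ion_formula.nominal_mass == 153
        assert ion.mz == pytest.approx(152.9953, abs=0.0015)

    def test_aminoacyl_pe_releases_no_aminoacyl_anion(self, lysyl_pe_30):
        # the amide-linked PE derivative cannot shed a free aminoacyl anion
        names = {i.name for i in fragment_table(lysyl_pe_30, M_MINUS_H).ions}
        assert "[Lys-H]-" not in names

    def test_chain_splits_32_0(self):
        splits = enumerate_chain_splits(parse_acyl("32:0"), (14, 18))
        assert {(c.carbons, c.unsaturations) for c in splits} == {
            (14, 0), (15, 0), (16, 0), (17, 0), (18, 0)
        }

    def test_chain_splits_distribute_unsaturation(self):
        splits = enumerate_chain_splits(parse_acyl("32:1"), (16, 16))
        assert {(c.carbons, c.unsaturations) for c in splits} == {(16, 0), (16, 1)}


class TestComplementarity:
    @pytest.mark.parametrize("adduct", [M_MINUS_H, M_PLUS_NA, M_PLUS_H])
    @pytest.mark.parametrize(
        "bb,acyl,aa",
        [("PG", "32:0", "Lys"), ("PG", "30:0", "Ala"), ("PE", "30:0", "Lys"),
         ("PG", "32:1", None)],
    )
    def test_fragment_plus_complement_is_precursor(self, bb, acyl, aa, adduct):
        s = LipidSpecies(bb, parse_acyl(acyl), aa)
        table = fragment_table(s, adduct)
        precursor = table.adduct.ion_formula(s.formula())
        for ion in table.ions:
            assert ion.ion_formula + ion.complement == precursor

    def test_all_mz_positive_and_unique_names(self, lysyl_pg_32):
        table = fragment_table(lysyl_pg_32, M_PLUS_NA)
        assert all(i.mz > 0 for i in table.ions)
        assert len({i.name for i in table.ions}) == len(table.ions)


class TestNeutralLosses:
    @pytest.mark.parametrize(
        "head,nominal",
        [
            ("phosphoethanolamine", 141),
            ("lysyl-phosphoethanolamine", 269),
            ("alanyl-phosphoethanolamine", 212),
            ("cyclo-lysine", 128),
            ("cyclo-lysyl-glycerol", 202),
            ("lysyl-glycerolphosphate", 300),
        ],
    )
    def test_nominal_values(self, head, nominal):
        assert neutral_loss_formula(head).nominal_mass == nominal

    def test_accurate_mass(self):
        assert neutral_loss_mass("lysyl-phosphoethanolamine") == pytest.approx(
            269.1140, abs=0.0015
        )

    def test_three_letter_codes_accepted(self):
        assert neutral_loss_mass("cyclo-Lys") == neutral_loss_mass("cyclo-lysine")

    def test_unknown_head_rejected(self):
        with pytest.raises(KeyError):
            neutral_loss_mass("glycero-nonsense")


class TestDiagnosticFragments:
    def test_negative_anion_channel(self):
        assert diagnostic_fragment("Lys") == pytest.approx(145.0978, abs=0.0015)
        assert diagnostic_fragment("Ala") == pytest.approx(88.0399, abs=0.0015)

    def test_sodiated_pg_head_channel(self):
        assert diagnostic_fragment("Lys", "PG", "positive-sodiated-head") == pytest.approx(
            323.0985, abs=0.0015
        )
        assert diagnostic_fragment("Ala", "PG", "positive-sodiated-head") == pytest.approx(
            266.0410, abs=0.0015
        )

    def test_sodiated_pe_head_channel(self):
        assert int(diagnostic_fragment("Lys", "PE", "positive-sodiated-head")) == 292
        assert int(diagnostic_fragment("Ala", "PE", "positive-sodiated-head")) == 235

    def test_unknown_mode(self):
        with pytest.raises(KeyError):
            diagnostic_fragment("Lys", "PG", "no-such-mode")


class TestEdgeCases:
    def test_positive_cl_unsupported(self):
        with pytest.raises(UnsupportedFragmentation):
            fragment_table(LipidSpecies("CL", parse_acyl("64:0"), "Lys"), M_PLUS_NA)

    def test_negative_cl_minimal_table(self):
        table = fragment_table(LipidSpecies("CL", parse_acyl("64:0"), "Lys"), M_MINUS_H)
        assert {i.name for i in table.ions} == {"[Lys-H]-", "cGP-"}

    def test_protonated_aminoacyl_pg_flagged_low_informative(self, lysyl_pg_32):
        table = fragment_table(lysyl_pg_32, M_PLUS_H)
        assert table.low_informative
        assert "DAG - OH" in {i.name for i in table.ions}

    def test_minor_acyl_losses_behind_flag(self, lysyl_pg_32):
        base = {i.name for i in fragment_table(lysyl_pg_32, M_PLUS_NA).ions}
        full = {
            i.name
            for i in fragment_table(
                lysyl_pg_32, M_PLUS_NA, include_acyl_losses=True
            ).ions
        }
        extras = full - base
        assert extras and all("[M+Na-" in n for n in extras)
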