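"""Library screen, high-accuracy confirmation and abundance profiling."""

import pytest

from aminolipid.chem import MassTolerance
from aminolipid.lipids import LipidSpecies, enumerate_library, parse_acyl
from aminolipid.screen import (
    abundance_profile,
    confirm_species,
    screen_aminoacyl_lipids,
)
from aminolipid.simulate import (
    MixtureTruth,
    noiseless_model,
    paper_like_truth,
    qtof_model,
    qtrap_model,
    simulate_mixture,
    simulate_msms,
)

UNIT = MassTolerance(0.3, "amu")


@pytest.fixture(scope="module")
def pg_library():
    return enumerate_library(["PG"], None, (26, 36), (0, 2))


def _truth(*entries):
    return MixtureTruth.build(
        (LipidSpecies("PG", parse_acyl(acyl), aa), "[M-H]-", ab)
        for aa, acyl, ab in entries
    )


class TestScreen:
    def test_recovers_exact_truth_groups(self, pg_library):
        truth = _truth(("Lys", "32:0", 1e6), ("Ala", "32:0", 1e5))
        records = simulate_mixture(truth, noiseless_model(seed=0))
        report = screen_aminoacyl_lipids(records, pg_library, UNIT)
        detected = {g.label for g in report.detected_groups()}
        assert detected == {"Gln/Lys", "Ala"}
        for g in report.groups:
            if g.label not in detected:
                assert not g.scan.hits

    def test_candidates_match_truth_species(self, pg_library):
        truth = _truth(("Lys", "32:0", 1e6))
        records = simulate_mixture(truth, noiseless_model(seed=0))
        report = screen_aminoacyl_lipids(records, pg_library, UNIT)
        best = report.group("Lys").best_candidate()
        assert best is not None
        assert best.species.acyl.notation == "(32:0)"
        assert best.species.amino_acid in ("Lys", "Gln")  # isobaric at 0.3 amu

    def test_mprf_null_behavior(self, pg_library):
        """Removing lysyl species empties the 145-amu channel but leaves the
        88-amu (alanyl) channel intact."""
        null_truth = _truth(("Ala", "30:0", 9e5))
        records = simulate_mixture(null_truth, noiseless_model(seed=0))
        report = screen_aminoacyl_lipids(records, pg_library, UNIT)
        assert not report.group("Lys").detected
        ala = report.group("Ala")
        assert ala.detected
        assert ala.best_candidate().species.acyl.notation == "(30:0)"

    def test_lysyl_cl_reported_in_cl_region(self):
        library = enumerate_library(["PG", "CL"], ["Lys"], (26, 66), (0, 0))
        truth = MixtureTruth.build(
            [(LipidSpecies("CL", parse_acyl("64:0"), "Lys"), "[M-H]-", 1e4)]
        )
        records = simulate_mixture(truth, noiseless_model(seed=0))
        report = screen_aminoacyl_lipids(records, library, UNIT)
        assert report.group("Lys").cl_region_hits

    def test_cysteine_flagged_unreliable(self, pg_library):
        truth = _truth(("Cys", "32:0", 1e4))
        records = simulate_mixture(truth, noiseless_model(seed=0))
        report = screen_aminoacyl_lipids(records, pg_library, UNIT)
        assert "cysteine-unreliable" in report.group("Cys").flags

    def test_unexplained_hits_retained(self, pg_library):
        # a precursor responding at the lysyl-anion m/z but with no library
        # match is kept for discovery
        from aminolipid.scans import MsMsRecord, Peak

        odd = MsMsRecord(999.999, -1, (Peak(145.098, 500.0),))
        report = screen_aminoacyl_lipids([odd], pg_library, UNIT)
        assert report.group("Lys").unexplained

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            screen_aminoacyl_lipids([], [], UNIT)


class TestConfirm:
    def test_lysyl_pg_confirmed_from_high_accuracy_spectrum(self, lysyl_pg_32):
        rec = simulate_msms(lysyl_pg_32, "[M+Na]+", qtof_model(seed=5))
        ident = confirm_species(lysyl_pg_32, rec, MassTolerance(5, "ppm"))
        assert ident.status == "confirmed"
        assert ident.n_diagnostic_matched >= 4

    def test_unmodified_pg_spectrum_rejected_as_alanyl_candidate(
        self, pg_32, alanyl_pg_32
    ):
        rec = simulate_msms(pg_32, "[M+Na]+", qtof_model(seed=5))
        ident = confirm_species(alanyl_pg_32, rec, MassTolerance(5, "ppm"))
        assert ident.status == "rejected"

    def test_dag_ions_alone_never_confirm(self, alanyl_pg_32):
        from aminolipid.fragments import fragment_table
        from aminolipid.scans import MsMsRecord, Peak

        table = fragment_table(alanyl_pg_32, "[M+Na]+")
        dag_peaks = tuple(
            Peak(i.mz, 1000.0) for i in table.ions if i.name.startswith("DAG")
        )
        rec = MsMsRecord(table.precursor_mz, 1, dag_peaks)
        ident = confirm_species(alanyl_pg_32, rec, MassTolerance(5, "ppm"))
        assert ident.status == "tentative"

    def test_aminoacyl_pe_capped_at_tentative(self, lysyl_pe_30):
        rec = simulate_msms(lysyl_pe_30, "[M+Na]+", qtof_model(seed=5))
        ident = confirm_species(lysyl_pe_30, rec, MassTolerance(5, "ppm"))
        assert ident.status == "tentative"
        assert "aminoacyl-PE-artifact-caution" in ident.flags

    def test_roundtrip_no_false_species(self, pg_library, lysyl_pg_32, alanyl_pg_32):
        """Noiseless screen + confirm recovers exactly the truth set."""
        truth = _truth(("Lys", "32:0", 1e6), ("Ala", "32:0", 1e5))
        neg = simulate_mixture(truth, noiseless_model(seed=0))
        report = screen_aminoacyl_lipids(neg, pg_library, UNIT)
        confirmed = []
        for species in (lysyl_pg_32, alanyl_pg_32):
            rec = simulate_msms(species, "[M+Na]+", noiseless_model(seed=0))
            ident = confirm_species(species, rec, MassTolerance(5, "ppm"))
            if ident.status == "confirmed":
                confirmed.append(ident.species)
        detected_aas = {
            aa for g in report.detected_groups() for aa in g.amino_acids
        }
        assert {"Lys", "Ala"} <= detected_aas
        assert set(confirmed) == {lysyl_pg_32, alanyl_pg_32}


class TestAbundanceProfile:
    def test_reference_ladder_ranking(self, pg_library):
        records = simulate_mixture(paper_like_truth(), noiseless_model(seed=0))
        report = screen_aminoacyl_lipids(records, pg_library, UNIT)
        profile = abundance_profile(report)
        labels = [e.label for e in profile]
        assert labels[0] == "Gln/Lys"
        assert labels[1] == "Ala"
        assert labels[2] == "Ile/Leu"
        assert labels[3] == "Asp"
        # intensity ratios follow the 6000:900:40:7 truth ladder
        ratio = profile[0].intensity / profile[1].intensity
        assert ratio == pytest.approx(6e6 / 9e5, rel=1e-6)

    def test_fractions_sum_to_one(self, pg_library):
        records = simulate_mixture(paper_like_truth(), qtrap_model(seed=2))
        report = screen_aminoacyl_lipids(records, pg_library, UNIT)
        profile = abundance_profile(report)
        assert sum(e.fraction for e in profile) == pytest.approx(1.0)

    def test_single_species_fraction_one(self, pg_library):
        records = simulate_mixture(
            _truth(("Lys", "32:0", 1e6)), noiseless_model(seed=0)
        )
        report = screen_aminoacyl_lipids(records, pg_library, UNIT)
        profile = abundance_profile(report)
        assert len(profile) == 1 and profile[0].fraction == 1.0

    def test_two_equal_species_split_evenly(self, pg_library):
        records = simulate_mixture(
            _truth(("Lys", "32:0", 1e5), ("Ala", "32:0", 1e5)),
            noiseless_model(seed=0),
        )
        report = screen_aminoacyl_lipids(records, pg_library, UNIT)
        profile = abundance_profile(report)
        assert [e.fraction for e in profile] == pytest.approx([0.5, 0.5])

    def test_rank_preserved_under_qtrap_noise(self, pg_library):
        """Truth intensities spanning >=10x gaps keep their order in at
        least 95% of seeded noisy replicates (30-cycle accumulation, the
        acquisition protocol of unit-resolution precursor scans)."""
        ok = 0
        n = 20
        for seed in range(n):
            records = simulate_mixture(
                paper_like_truth(), qtrap_model(seed=seed), replicates=30
            )
            report = screen_aminoacyl_lipids(records, pg_library, UNIT)
            labels = [e.label for e in abundance_profile(report)][:4]
            ok += labels == ["Gln/Lys", "Ala", "Ile/Leu", "Asp"]
        assert ok / n >= 0.95
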