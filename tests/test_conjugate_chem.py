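import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from haptenfit import (
    ConjugationChemistry,
    PeptideDesign,
    ladder_spacing,
    peptide_mass,
    percent_identity,
    predict_species_masses,
    sbap_chemistry,
)
from haptenfit.conjugate_chem import (
    BOVINE_IRIS,
    HUMAN_IRIS,
    MOUSE_IRIS,
    human_iris_design,
    identity_matrix,
    mouse_iris_design,
    observed_ladder_spacing,
    read_designs_fasta,
)
from haptenfit.errors import ChemistryError

AA = "ACDEFGHIKLMNPQRSTVWY"


def bare(seq, **kw):
    return PeptideDesign(seq, linker="", terminal="", n_term_mod="none", **kw)


class TestPeptideMass:
    def test_single_glycine_average(self):
        assert peptide_mass(bare("G")) == pytest.approx(75.07, abs=0.01)

    def test_glycine_additivity(self):
        diff = peptide_mass(bare("GG")) - peptide_mass(bare("G"))
        assert diff == pytest.approx(57.05, abs=0.01)

    def test_mouse_iris1_against_residue_table_oracle(self):
        # frozen independent sums over the published residue-mass table:
        # Ac-VQHTLTPGDLRDLGGC, free acid
        d = mouse_iris_design(1)
        assert peptide_mass(d, "average") == pytest.approx(1723.92, abs=0.02)
        assert peptide_mass(d, "monoisotopic") == pytest.approx(1722.84, abs=0.02)

    def test_mouse_iris2_against_residue_table_oracle(self):
        assert peptide_mass(mouse_iris_design(2)) == pytest.approx(3284.65, abs=0.02)

    def test_human_iris1_against_residue_table_oracle(self):
        assert peptide_mass(human_iris_design(1)) == pytest.approx(1763.99, abs=0.02)

    def test_acetyl_delta(self):
        plain = bare("GASP")
        ac = PeptideDesign("GASP", linker="", terminal="", n_term_mod="acetyl")
        assert peptide_mass(ac) - peptide_mass(plain) == pytest.approx(42.037, abs=0.001)

    def test_amide_delta(self):
        acid = bare("GASP")
        amide = bare("GASP", c_term="amide")
        assert peptide_mass(amide) - peptide_mass(acid) == pytest.approx(-0.985, abs=0.001)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        a=st.text(AA, min_size=1, max_size=10),
        b=st.text(AA, min_size=1, max_size=10),
    )
    def test_concatenation_adds_minus_one_water(self, a, b):
        total = peptide_mass(bare(a)) + peptide_mass(bare(b)) - 18.01528
        assert peptide_mass(bare(a + b)) == pytest.approx(total, abs=1e-9)

    def test_invalid_residue(self):
        with pytest.raises(ChemistryError):
            PeptideDesign("GAXP")

    def test_invalid_repeats(self):
        with pytest.raises(ChemistryError):
            PeptideDesign("GA", repeats=0)


class TestSbapChemistry:
    def test_remnant_from_formula_arithmetic(self):
        # independent sum-formula oracle: C5H5NO2 (acid - H2O - HBr)
        chem = sbap_chemistry()
        assert chem.linker_remnant_mass == pytest.approx(111.10, abs=0.01)

    def test_capping_adduct_from_formula_arithmetic(self):
        chem = sbap_chemistry()
        assert chem.capping_adduct_mass == pytest.approx(232.25, abs=0.01)

    def test_invalid_sites(self):
        with pytest.raises(ChemistryError):
            ConjugationChemistry(linker_remnant_mass=100.0, n_activatable_sites=0)


class TestLadderSpacing:
    def test_zero_remnant_equals_peptide_mass(self):
        d = mouse_iris_design(1)
        chem = ConjugationChemistry(linker_remnant_mass=0.0)
        assert ladder_spacing(d, chem) == pytest.approx(peptide_mass(d))

    def test_one_repeat_block_difference(self):
        chem = sbap_chemistry()
        diff = ladder_spacing(mouse_iris_design(2), chem) - ladder_spacing(
            mouse_iris_design(1), chem
        )
        block = PeptideDesign(
            MOUSE_IRIS + "GG", linker="", terminal="", n_term_mod="none"
        )
        assert diff == pytest.approx(peptide_mass(block) - 18.01528, abs=1e-6)

    def test_sbap_delta_matches_formula_oracle(self):
        # frozen: 1723.92 (peptide) + 111.10 (remnant)
        assert ladder_spacing(mouse_iris_design(1), sbap_chemistry()) == pytest.approx(
            1835.02, abs=0.03
        )


class TestPercentIdentity:
    def test_mouse_vs_bovine_is_92(self):
        pid = percent_identity(MOUSE_IRIS, BOVINE_IRIS)
        assert pid == pytest.approx(92.3, abs=0.05)
        assert round(pid) == 92

    def test_human_vs_bovine_manual_count(self):
        # hand count: 9 of 13 aligned positions identical
        pid = percent_identity(HUMAN_IRIS, BOVINE_IRIS)
        assert pid == pytest.approx(100.0 * 9 / 13, abs=1e-9)

    def test_identical_sequences(self):
        assert percent_identity(MOUSE_IRIS, MOUSE_IRIS) == 100.0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(a=st.text(AA, min_size=1, max_size=20), b=st.text(AA, min_size=1, max_size=20))
    def test_symmetric_and_100_iff_equal(self, a, b):
        if len(a) != len(b):
            with pytest.raises(ChemistryError):
                percent_identity(a, b)
            return
        assert percent_identity(a, b) == percent_identity(b, a)
        assert (percent_identity(a, b) == 100.0) == (a == b)

    def test_length_mismatch(self):
        with pytest.raises(ChemistryError):
            percent_identity("GA", "GAS")


class TestPredictSpeciesMasses:
    def test_no_adducts_simple_ladder(self):
        d = mouse_iris_design(1)
        chem = ConjugationChemistry(
            linker_remnant_mass=0.0, capping_adduct_mass=0.0, capping_policy="none"
        )
        delta = peptide_mass(d)
        out = predict_species_masses(58_408.0, d, chem, (0, 2))
        np.testing.assert_allclose(
            [m for _, m in out], [58_408.0, 58_408.0 + delta, 58_408.0 + 2 * delta]
        )

    def test_telescoping_uncapped(self):
        d = mouse_iris_design(1)
        chem = sbap_chemistry(capping_policy="none")
        masses = np.array([m for _, m in predict_species_masses(58_408.0, d, chem, (0, 8))])
        np.testing.assert_allclose(
            np.diff(masses), ladder_spacing(d, chem), rtol=1e-12
        )

    def test_telescoping_with_cysteine_capping(self):
        # each conjugation displaces one cysteine cap, so the observed
        # spacing is delta minus the capping adduct
        d = mouse_iris_design(1)
        chem = sbap_chemistry(capping_policy="cap_remaining")
        masses = np.array([m for _, m in predict_species_masses(58_408.0, d, chem, (0, 8))])
        np.testing.assert_allclose(
            np.diff(masses), observed_ladder_spacing(d, chem), rtol=1e-12
        )
        assert observed_ladder_spacing(d, chem) == pytest.approx(
            ladder_spacing(d, chem) - chem.capping_adduct_mass
        )

    def test_load_zero_mass_includes_caps(self):
        d = mouse_iris_design(1)
        chem = sbap_chemistry(n_activatable_sites=20)
        (n0, m0), = predict_species_masses(58_408.0, d, chem, (0, 0))
        assert n0 == 0
        assert m0 == pytest.approx(58_408.0 + 20 * chem.capping_adduct_mass)

    def test_exceeding_sites_errors(self):
        d = mouse_iris_design(1)
        chem = sbap_chemistry(n_activatable_sites=5)
        with pytest.raises(ChemistryError):
            predict_species_masses(58_408.0, d, chem, (0, 6))


class TestFastaAndMatrix:
    def test_read_designs_fasta(self, tmp_path):
        p = tmp_path / "iris.fasta"
        p.write_text(f">mIRIS\n{MOUSE_IRIS}\n>bIRIS\n{BOVINE_IRIS}\n")
        designs = read_designs_fasta(p)
        assert [d.name for d in designs] == ["mIRIS", "bIRIS"]
        assert designs[0].epitope_sequence == MOUSE_IRIS

    def test_empty_fasta(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(ChemistryError):
            read_designs_fasta(p)

    def test_identity_matrix(self):
        m = identity_matrix([MOUSE_IRIS, BOVINE_IRIS])
        assert m[0][0] == 100.0
        assert m[0][1] == m[1][0] == pytest.approx(92.3, abs=0.05)
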