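import pytest
from hypothesis import given, settings, strategies as st

from oryzapep.pepchem import (
    GW9662_FORMULA,
    LipinskiThresholds,
    PeptideProperties,
    average_mw,
    count_hba,
    count_hbd,
    estimate_logp,
    lipinski,
    parse_formula,
    peptide_formula,
    peptide_properties,
)

peptides_st = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=20)


class TestFormula:
    def test_free_glycine(self):
        assert str(peptide_formula("G")) == "C2H5NO2"

    def test_tripeptide(self):
        f = peptide_formula("QPY")
        assert (f["C"], f["H"], f["N"], f["O"]) == (19, 26, 4, 6)

    @settings(derandomize=True, max_examples=100)
    @given(a=peptides_st, b=peptides_st)
    def test_additive_over_concatenation_minus_water(self, a, b):
        joined = peptide_formula(a + b)
        parts = peptide_formula(a) + peptide_formula(b)
        water = parse_formula("H2O")
        assert joined + water == parts

    def test_parse_formula_round_trip(self):
        f = parse_formula("C13H9ClN2O3")
        assert f["Cl"] == 1 and f["C"] == 13
        with pytest.raises(ValueError):
            parse_formula("not a formula")


class TestMolecularWeight:
    # published study values, sequence-derived, tolerance ±0.05 g/mol
    @pytest.mark.parametrize(
        "peptide,expected",
        [("QPY", 406.43), ("IVPQH", 592.69), ("PIVF", 474.59),
         ("IIQGR", 585.70), ("QSPVF", 576.64)],
    )
    def test_candidate_masses(self, peptide, expected):
        assert average_mw(peptide_formula(peptide)) == pytest.approx(expected, abs=0.05)

    def test_water(self):
        assert average_mw(parse_formula("H2O")) == pytest.approx(18.02, abs=0.005)

    def test_control_antagonist_from_formula(self):
        assert average_mw(GW9662_FORMULA) == pytest.approx(276.68, abs=0.05)

    @settings(derandomize=True, max_examples=100)
    @given(seq=peptides_st)
    def test_additivity_of_residue_masses(self, seq):
        from oryzapep.pepchem import ATOMIC_MASS

        def exact(formula):  # unrounded dot product with atomic masses
            return sum(ATOMIC_MASS[el] * n for el, n in formula.counts.items())

        water = exact(parse_formula("H2O"))
        residue_sum = sum(exact(peptide_formula(r)) - water for r in seq)
        assert exact(peptide_formula(seq)) == pytest.approx(residue_sum + water, abs=1e-6)


class TestDonorAcceptorCounts:
    @pytest.mark.parametrize("peptide,expected", [("QPY", 5), ("IIQGR", 10), ("QSPVF", 7)])
    def test_donors(self, peptide, expected):
        assert count_hbd(peptide) == expected

    @pytest.mark.parametrize("peptide,expected", [("QPY", 7), ("IVPQH", 9), ("QSPVF", 9), ("PIVF", 6)])
    def test_acceptors(self, peptide, expected):
        assert count_hba(peptide) == expected

    @pytest.mark.parametrize("n", [1, 4, 9])
    def test_polyglycine_closed_forms(self, n):
        assert count_hbd("G" * n) == n + 1
        assert count_hba("G" * n) == n + 2

    @settings(derandomize=True, max_examples=100)
    @given(seq=peptides_st, extra=st.sampled_from("ACDEFGHIKLMNPQRSTVWY"))
    def test_monotone_under_appending(self, seq, extra):
        assert count_hbd(seq + extra) >= count_hbd(seq)
        assert count_hba(seq + extra) >= count_hba(seq)


class TestLogPEstimate:
    def test_hydrophobic_above_acidic(self):
        assert estimate_logp("FFFF") > estimate_logp("DDDD")

    @settings(derandomize=True, max_examples=50)
    @given(a=peptides_st, b=peptides_st)
    def test_additive_up_to_termini_correction(self, a, b):
        # joining two chains removes one set of free termini:
        # logp(a+b) = logp(a) + logp(b) - T, with T recoverable from glycine
        termini = 2 * estimate_logp("G") - estimate_logp("GG")
        assert estimate_logp(a + b) == pytest.approx(
            estimate_logp(a) + estimate_logp(b) - termini, abs=0.03
        )

    def test_external_value_injection(self):
        props = peptide_properties("QPY", logp_override=1.34)
        assert props.logp_estimate == 1.34 and props.logp_source == "external"


class TestLipinski:
    def test_qpy_meets_all_criteria(self):
        props = peptide_properties("QPY", logp_override=1.34)
        verdict = lipinski(props)
        assert verdict.violation_count == 0 and verdict.orally_absorbable

    def test_ivpqh_fails_mw_and_hbd(self):
        props = peptide_properties("IVPQH", logp_override=2.25)
        verdict = lipinski(props)
        assert not verdict.mw_ok and not verdict.hbd_ok
        assert verdict.violation_count >= 2 and not verdict.orally_absorbable

    def test_within_all_thresholds_means_zero_violations(self):
        props = peptide_properties("GA", logp_override=0.5)
        assert lipinski(props).violation_count == 0

    @settings(derandomize=True, max_examples=100)
    @given(
        mw=st.floats(100, 1200), logp=st.floats(-5, 10),
        hbd=st.integers(2, 20), hba=st.integers(3, 25),
        bump=st.sampled_from(["mw", "logp", "hbd", "hba"]),
    )
    def test_monotonicity_in_every_property(self, mw, logp, hbd, hba, bump):
        """Increasing any property value never decreases the violation count."""
        def verdict(mw, logp, hbd, hba):
            props = PeptideProperties(
                sequence="GG", formula=peptide_formula("GG"),
                mw_average=mw, hbd=hbd, hba=hba, logp_estimate=logp,
            )
            return lipinski(props)

        base = verdict(mw, logp, hbd, hba).violation_count
        bumped = {
            "mw": (mw + 200, logp, hbd, hba),
            "logp": (mw, logp + 3, hbd, hba),
            "hbd": (mw, logp, hbd + 5, hba),
            "hba": (mw, logp, hbd, hba + 8),
        }[bump]
        assert verdict(*bumped).violation_count >= base

    def test_configurable_thresholds(self):
        # the printed-source variant of the acceptor cutoff can be restored
        loose = LipinskiThresholds(hba_max=10.6)
        props = peptide_properties("IVPQH", logp_override=2.25)
        assert lipinski(props, loose).hba_ok


class TestRdkitCrossValidation:
    """Independent structure-based check of the contribution tables."""

    candidates = ["IVPQH", "PIVF", "IIQGR", "QPY", "QSPVF"]

    @pytest.mark.parametrize("peptide", candidates)
    def test_mw_and_donors_match_structure_toolkit(self, peptide):
        rdkit = pytest.importorskip("rdkit")
        from rdkit import Chem
        from rdkit.Chem import Descriptors, Lipinski

        mol = Chem.MolFromSequence(peptide)
        assert average_mw(peptide_formula(peptide)) == pytest.approx(
            Descriptors.MolWt(mol), abs=0.05
        )
        assert count_hbd(peptide) == Lipinski.NumHDonors(mol)
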