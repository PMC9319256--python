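"""Sequence arithmetic: masses, fragmentation, random-coil hydrodynamics."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bindlab import peptides as pep

NLS1 = "AKKKSTGSSTWPLDPGVEVTLTMKVAS"
NLS2 = "YKLFQEQQNEGHGEALLFEGIKKKKQQKI"
NLS2_REGION = "LLASPRSC" + NLS2

seq_strategy = st.text(alphabet=sorted(pep.AVERAGE_RESIDUE_MASS), min_size=1, max_size=40)


class TestAverageMass:
    def test_nls1_free_peptide_mass(self):
        """The 27-mer NLS1 peptide weighs 2819.27 Da with free termini."""
        seq = pep.PeptideSequence(NLS1, start_number=58)
        assert pep.average_mass(seq) == pytest.approx(2819.27, abs=0.05)

    def test_single_glycine(self):
        assert pep.average_mass(pep.PeptideSequence("G")) == pytest.approx(75.07, abs=0.01)

    def test_nls2_capped_mass(self):
        """Acetyl + amide caps reproduce the synthesized NLS2 peptide mass."""
        seq = pep.PeptideSequence(NLS2, start_number=498,
                                  n_term_cap="acetyl", c_term_cap="amide")
        assert pep.average_mass(seq) == pytest.approx(3501.98, abs=0.05)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            pep.PeptideSequence("")

    def test_unknown_residue_reports_position(self):
        with pytest.raises(ValueError, match="position 2"):
            pep.PeptideSequence("AKXK")

    @given(a=seq_strategy, b=seq_strategy)
    @settings(max_examples=50, derandomize=True)
    def test_mass_additivity_for_free_termini(self, a, b):
        """mass(a + b) = mass(a) + mass(b) - water (peptide-bond condensation)."""
        m_ab = pep.average_mass(pep.PeptideSequence(a + b))
        m_a = pep.average_mass(pep.PeptideSequence(a))
        m_b = pep.average_mass(pep.PeptideSequence(b))
        assert m_ab == pytest.approx(m_a + m_b - pep.WATER_MASS, abs=1e-9)

    @given(seq=seq_strategy)
    @settings(max_examples=50, derandomize=True)
    def test_mass_matches_independent_oracle(self, seq):
        """Cross-check against Biopython's average-mass table (independent oracle)."""
        Bio = pytest.importorskip("Bio.SeqUtils")
        ours = pep.average_mass(pep.PeptideSequence(seq))
        theirs = Bio.molecular_weight(seq, seq_type="protein", monoisotopic=False)
        assert ours == pytest.approx(theirs, abs=0.05 * max(1, len(seq) / 25))


class TestMakeFragments:
    def test_nls1_tiling(self):
        """27-mer, window 7, step 2 -> 11 fragments, A58..G64 first, L78..S84 last."""
        parent = pep.PeptideSequence(NLS1, start_number=58, c_term_cap="amide")
        frags = pep.make_fragments(parent)
        assert len(frags) == 11
        assert frags[0].residues == "AKKKSTG" and frags[0].start_number == 58
        assert frags[-1].residues == "LTMKVAS" and frags[-1].end_number == 84

    def test_nls2_extended_region_tiling(self):
        """37-mer region 490-526 -> 16 fragments, L490..S496 first, K520..I526 last."""
        parent = pep.PeptideSequence(NLS2_REGION, start_number=490, c_term_cap="amide")
        frags = pep.make_fragments(parent)
        assert len(frags) == 16
        assert frags[0].residues == "LLASPRS" and frags[0].start_number == 490
        assert frags[-1].residues == "KKKQQKI" and frags[-1].end_number == 526

    def test_caps_methyl_except_terminal_fragment(self):
        parent = pep.PeptideSequence(NLS1, start_number=58, c_term_cap="amide")
        frags = pep.make_fragments(parent)
        assert all(f.n_term_cap == "methyl" for f in frags)
        assert all(f.c_term_cap == "methyl" for f in frags[:-1])
        assert frags[-1].c_term_cap == "amide"  # parent C-terminal amide maintained

    def test_window_equal_length_single_fragment(self):
        parent = pep.PeptideSequence("AKKKSTG")
        frags = pep.make_fragments(parent, window=7, step=2)
        assert len(frags) == 1 and frags[0].residues == parent.residues

    def test_window_larger_than_sequence_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            pep.make_fragments(pep.PeptideSequence("AKK"), window=7)

    def test_inexact_tiling_warns_and_keeps_last_full_window(self):
        parent = pep.PeptideSequence("A" * 10)  # (10-7) % 2 != 0
        with pytest.warns(UserWarning, match="tile"):
            frags = pep.make_fragments(parent, window=7, step=2)
        assert len(frags) == 2
        assert frags[-1].end_number == 9  # one short of the C-terminus

    @given(
        length=st.integers(7, 60),
        window=st.integers(2, 10),
        step=st.integers(1, 4),
    )
    @settings(max_examples=100, derandomize=True)
    def test_count_and_coverage_match_brute_force(self, length, window, step):
        if window > length:
            return
        parent = pep.PeptideSequence("A" * length)
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            frags = pep.make_fragments(parent, window=window, step=step)
        # brute-force window enumeration
        expected_starts = list(range(0, length - window + 1, step))
        assert len(frags) == (length - window) // step + 1 == len(expected_starts)
        coverage = [0] * length
        for off in expected_starts:
            for i in range(off, off + window):
                coverage[i] += 1
        got = [0] * length
        for f in frags:
            for r in range(f.start_number - 1, f.end_number):
                got[r] += 1
        assert got == coverage


class TestHydrodynamics:
    def test_random_coil_rh_of_nls1(self):
        """R_h = 0.027 MW^(1/2) nm gives 14.3 Å for the 2819.27 Da peptide."""
        assert pep.random_coil_rh(2819.27) == pytest.approx(14.3, abs=0.05)

    def test_zero_mass(self):
        assert pep.random_coil_rh(0.0) == 0.0
        assert pep.mass_from_rh(0.0) == 0.0

    def test_analytic_inversion_point(self):
        mass = (1.0 / 0.027) ** 2
        assert pep.random_coil_rh(mass) == pytest.approx(10.0, rel=1e-12)
        assert pep.mass_from_rh(14.3) == pytest.approx((1.43 / 0.027) ** 2, rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pep.random_coil_rh(-1.0)
        with pytest.raises(ValueError):
            pep.mass_from_rh(-1.0)

    @given(mass=st.floats(1e-3, 1e7))
    @settings(max_examples=100, derandomize=True)
    def test_rh_mass_mutual_inverses(self, mass):
        back = pep.mass_from_rh(pep.random_coil_rh(mass))
        assert back == pytest.approx(mass, rel=1e-9)


class TestOligomerOrder:
    def test_hexamer_from_apparent_mass(self):
        """16,421.9 / 2819.27 -> ratio 5.83, called a hexamer."""
        ratio, order = pep.oligomer_order(16421.9, 2819.27)
        assert ratio == pytest.approx(5.83, abs=0.01)
        assert order == 6

    def test_monomer(self):
        assert pep.oligomer_order(2819.27, 2819.27) == (1.0, 1)

    def test_half_rounds_up(self):
        _, order = pep.oligomer_order(2.5, 1.0)
        assert order == 3

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            pep.oligomer_order(0.0, 1.0)
        with pytest.raises(ValueError):
            pep.oligomer_order(1.0, -2.0)
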