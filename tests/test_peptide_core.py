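"""Digestion, mass arithmetic, fragment series and phosphosite ambiguity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coipquant.constants import PHOSPHO, PROTON, WATER
from coipquant.errors import InvalidInputError
from coipquant.peptide_core import (
    ModifiedPeptide,
    Peptide,
    ProteinRecord,
    digest,
    digest_segments,
    digest_table,
    find_occurrences,
    fragment_series,
    ion_mz,
    peptide_mass,
    resolve_site_ambiguity,
)

AA = "ACDEFGHIKLMNPQRSTVWY"
peptides_st = st.text(alphabet=AA, min_size=2, max_size=25)
proteins_st = st.text(alphabet=AA, min_size=1, max_size=80)


# ---------------------------------------------------------------------------
# digestion


class TestDigest:
    def test_kr_not_before_proline(self):
        prot = ProteinRecord("toy", "MKRPTK")
        assert [p.sequence for p in digest(prot, 0)] == ["MK", "RPTK"]

    def test_no_cleavage_sites(self):
        prot = ProteinRecord("toy", "AAAA")
        assert [p.sequence for p in digest(prot, 5)] == ["AAAA"]

    def test_empty_sequence_rejected(self):
        with pytest.raises(InvalidInputError):
            ProteinRecord("bad", "")

    @settings(max_examples=150, deadline=None)
    @given(proteins_st)
    def test_segments_reconstruct_sequence(self, seq):
        assert "".join(digest_segments(seq)) == seq

    @settings(max_examples=150, deadline=None)
    @given(proteins_st)
    def test_no_internal_missed_site_at_zero_mc(self, seq):
        prot = ProteinRecord("p", seq)
        for pep in digest(prot, 0):
            body = pep.sequence[:-1]
            for i, aa in enumerate(body):
                if aa in "KR":
                    assert pep.sequence[i + 1] == "P"

    @settings(max_examples=100, deadline=None)
    @given(proteins_st, st.integers(0, 3))
    def test_occurrences_are_exact_substrings(self, seq, mc):
        prot = ProteinRecord("p", seq)
        for pep in digest(prot, mc):
            assert pep.occurrences
            for start in pep.occurrences:
                assert seq[start - 1 : start - 1 + len(pep.sequence)] == pep.sequence

    def test_repeat_peptide_has_all_occurrences(self, nfm):
        peps = {p.sequence: p for p in digest(nfm, 2)}
        repeat = peps["SPVPKSPVEEK"]
        assert repeat.occurrences == (615, 628, 641, 654)
        assert repeat.missed_cleavages == 1

    def test_phospho_blocked_cleavage_only_adds(self, nfm):
        base = {p.sequence for p in digest(nfm, 0)}
        extended = {p.sequence for p in digest(nfm, 0, phospho_blocks_cleavage=True)}
        assert base <= extended
        # the blocked form spanning a K|S junction appears without spending
        # the missed-cleavage budget
        assert "SPVPKSPVEEK" not in base
        assert "SPVPKSPVEEK" in extended

    def test_doubly_phosphorylatable_blocked_forms(self, nfm):
        peps = {p.sequence for p in digest(nfm, 2)}
        assert {"AKSPVPKSPVEEK", "GKSPVPKSPVEEK", "AKSPVPKSPVEEAK"} <= peps

    def test_digest_table_has_mass_and_mz_columns(self, spino):
        table = digest_table(spino, 1, charges=(2, 3))
        assert {"peptide", "starts", "neutral_mass", "mz_z2", "mz_z3"} <= set(table.columns)
        row = table[table["peptide"] == "AAGAPQVNSK"].iloc[0]
        assert row["mz_z2"] == pytest.approx(
            (peptide_mass("AAGAPQVNSK") + 2 * PROTON) / 2, abs=1e-9
        )


# ---------------------------------------------------------------------------
# masses


class TestMass:
    @pytest.mark.parametrize(
        "seq,n_phospho,expected",
        [
            ("G", 0, 75.03203),
            ("AG", 0, 146.06913),
            ("G", 1, 75.03203 + PHOSPHO),
        ],
    )
    def test_reference_masses(self, seq, n_phospho, expected):
        assert peptide_mass(seq, n_phospho) == pytest.approx(expected, abs=2e-5)

    def test_unknown_residue(self):
        with pytest.raises(InvalidInputError):
            peptide_mass("AZB")

    def test_ion_mz_formula(self):
        assert ion_mz(146.06913, 1) == pytest.approx(147.07641, abs=1e-5)
        assert ion_mz(146.06913, 2) == pytest.approx((146.06913 + 2 * PROTON) / 2, abs=1e-9)

    def test_nonpositive_charge(self):
        with pytest.raises(InvalidInputError):
            ion_mz(500.0, 0)

    @settings(max_examples=100, deadline=None)
    @given(peptides_st)
    def test_matches_pyteomics(self, seq):
        """Independent oracle: pyteomics' monoisotopic peptide mass."""
        pyteomics_mass = pytest.importorskip("pyteomics.mass")
        assert peptide_mass(seq) == pytest.approx(
            pyteomics_mass.fast_mass(seq), abs=5e-4
        )


# ---------------------------------------------------------------------------
# fragments


def _mp(seq, phospho=()):
    pep = Peptide(sequence=seq, parent="q", occurrences=(1,))
    return ModifiedPeptide(peptide=pep, phospho_positions=tuple(phospho))


class TestFragments:
    def test_dipeptide_values(self):
        b, y = fragment_series(_mp("AG"))
        assert b[0] == pytest.approx(72.04439, abs=2e-5)
        assert y[0] == pytest.approx(76.03930, abs=2e-5)
        assert b[0] + y[0] == pytest.approx(146.06913 + 2 * PROTON, abs=5e-5)

    def test_series_lengths(self):
        b, y = fragment_series(_mp("PEPTIDE"))
        assert len(b) == len(y) == 6

    @settings(max_examples=100, deadline=None)
    @given(peptides_st, st.data())
    def test_by_complementarity(self, seq, data):
        """b_i + y_(n-i) = M + 2 x proton, with and without a phosphate."""
        sty = [i + 1 for i, aa in enumerate(seq) if aa in "STY"]
        phospho = ()
        if sty and data.draw(st.booleans()):
            phospho = (data.draw(st.sampled_from(sty)),)
        mp = _mp(seq, phospho)
        b, y = fragment_series(mp)
        M = peptide_mass(seq, len(phospho))
        n = len(seq)
        for i in range(1, n):
            assert b[i - 1] + y[n - i - 1] == pytest.approx(M + 2 * PROTON, abs=1e-4)

    def test_phospho_shifts_correct_fragments(self):
        b0, y0 = fragment_series(_mp("ASGK"))
        b1, y1 = fragment_series(_mp("ASGK", (2,)))
        assert b1[0] == pytest.approx(b0[0], abs=1e-9)  # b1 before the site
        for k in (1, 2):
            assert b1[k] == pytest.approx(b0[k] + PHOSPHO, abs=1e-9)
        assert y1[0] == pytest.approx(y0[0], abs=1e-9)
        assert y1[2] == pytest.approx(y0[2] + PHOSPHO, abs=1e-9)

    def test_too_short(self):
        with pytest.raises(InvalidInputError):
            fragment_series(_mp("G"))


# ---------------------------------------------------------------------------
# site ambiguity


class TestSiteAmbiguity:
    def test_toy_repeat(self):
        pep = Peptide("SPA", parent="toy", occurrences=find_occurrences("KSPAKSPA", "SPA"))
        mp = resolve_site_ambiguity(pep, (1,))
        assert mp.ambiguous_site_sets == ((2, 6),)

    def test_ksp_repeat_domain(self, nfm):
        peps = {p.sequence: p for p in digest(nfm, 2)}
        mp = resolve_site_ambiguity(peps["SPVPKSPVEEK"], (6,))
        assert mp.ambiguous_site_sets == ((620, 633, 646, 659),)

    def test_unique_peptide_singleton(self, nfm):
        peps = {p.sequence: p for p in digest(nfm, 0)}
        mp = resolve_site_ambiguity(peps["EQLQGLNDR"], ())
        assert mp.ambiguous_site_sets == ()
        mp2 = resolve_site_ambiguity(
            Peptide("QASHAQLGDAYDQEIR", "nfm", find_occurrences(nfm.sequence, "QASHAQLGDAYDQEIR")),
            (3,),
        )
        assert len(mp2.ambiguous_site_sets[0]) == 1

    def test_non_sty_rejected(self):
        pep = Peptide("APA", parent="toy", occurrences=(1,))
        with pytest.raises(InvalidInputError):
            resolve_site_ambiguity(pep, (2,))

    def test_invariant_under_occurrence_order(self):
        fwd = Peptide("SPA", "toy", occurrences=(2, 6))
        mp = resolve_site_ambiguity(fwd, (1,))
        # sets are sorted ascending regardless of how occurrences were found
        assert mp.ambiguous_site_sets[0] == tuple(sorted(mp.ambiguous_site_sets[0]))

    def test_spinophilin_sites(self, spino):
        assert spino.residue(17) == "S"
        assert spino.residue(100) == "S"
        peps = {p.sequence: p for p in digest(spino, 1)}
        mp17 = resolve_site_ambiguity(peps["LGDAVTPQSGR"], (9,))
        assert mp17.ambiguous_site_sets == ((17,),)
        mp100 = resolve_site_ambiguity(peps["AVDEGHLTASPLLR"], (10,))
        assert mp100.ambiguous_site_sets == ((100,),)
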