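"""PSM parsing, E-value filtering, protein assembly, coverage, decoy FDR."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lfqpipe.identifications import (
    PeptideSpectrumMatch,
    PSMParseError,
    assemble_proteins,
    compute_coverage,
    estimate_fdr,
    filter_psms,
    parse_psm_table,
    read_fasta_database,
    write_psm_table,
)

HEADER = "spectrum_id\treplicate_id\tcondition_id\tscan_number\tprecursor_mz\tpeptide\taccession\te_value\n"


def psm(**kw):
    base = dict(
        spectrum_id="s1", replicate_id="A1", condition_id="A", scan_number=10,
        precursor_mz=500.0, peptide="PEPTIDEK", accession="P1", e_value=0.001,
    )
    base.update(kw)
    return PeptideSpectrumMatch(**base)


class TestParsePSMTable:
    def test_rows_parsed_in_input_order(self, tmp_path):
        p = tmp_path / "psms.tsv"
        rows = [
            "s1\tA1\tA\t10\t500.5\tPEPTIDEK\tP1\t0.01",
            "s2\tA1\tA\t20\t600.5\tACDEFKR\tP2\t0.02",
            "s3\tB1\tB\t30\t700.5\tWYVTSR\tP1\t0.03",
        ]
        p.write_text(HEADER + "\n".join(rows) + "\n")
        psms = parse_psm_table(p)
        assert [m.spectrum_id for m in psms] == ["s1", "s2", "s3"]
        assert psms[1].scan_number == 20
        assert psms[2].e_value == 0.03

    def test_header_only_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text(HEADER)
        assert parse_psm_table(p) == []

    def test_missing_column_names_it(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(HEADER.replace("\te_value", ""))
        with pytest.raises(PSMParseError, match="e_value"):
            parse_psm_table(p)

    def test_unparseable_numeric_reports_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(HEADER + "s1\tA1\tA\tten\t500.5\tPEPTIDEK\tP1\t0.01\n")
        with pytest.raises(PSMParseError, match="line 2"):
            parse_psm_table(p)

    def test_roundtrip_through_writer(self, tmp_path):
        psms = [psm(spectrum_id=f"s{i}", scan_number=i + 1) for i in range(4)]
        p = tmp_path / "out.tsv"
        write_psm_table(psms, p)
        assert parse_psm_table(p) == psms

    def test_record_invariants_enforced(self):
        with pytest.raises(ValueError):
            psm(e_value=-0.1)
        with pytest.raises(ValueError):
            psm(precursor_mz=0.0)
        with pytest.raises(ValueError):
            psm(scan_number=0)
        with pytest.raises(ValueError):
            psm(peptide="PEPT1DE")


class TestFilterPSMs:
    @pytest.mark.parametrize(
        "e_value,kept",
        [(0.06, False), (0.05, True), (0.0, True), (0.049999, True), (5.0, False)],
    )
    def test_strictly_greater_than_threshold_discarded(self, e_value, kept):
        out = filter_psms([psm(e_value=e_value)])
        assert (len(out) == 1) is kept

    def test_order_preserved(self):
        psms = [psm(spectrum_id=f"s{i}", e_value=0.01 * i) for i in range(6)]
        out = filter_psms(psms, 0.03)
        assert [m.spectrum_id for m in out] == ["s0", "s1", "s2", "s3"]

    @given(st.lists(st.floats(0, 0.2), max_size=30), st.floats(0.001, 0.1), st.floats(0.001, 0.1))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_threshold(self, evals, t1, t2):
        lo, hi = sorted([t1, t2])
        psms = [psm(spectrum_id=f"s{i}", e_value=e) for i, e in enumerate(evals)]
        assert set(m.spectrum_id for m in filter_psms(psms, lo)) <= set(
            m.spectrum_id for m in filter_psms(psms, hi)
        )

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_psms([], 0.0)


DB = {
    "P1": ("MKPEPTIDEKAAACDEFKRWYVTSR", "Gossypium hirsutum"),
    "P2": ("ACDEFKRMMMM", "Gossypium arboreum"),
}


class TestAssembleProteins:
    def test_single_distinct_peptide_discarded(self):
        psms = [psm(spectrum_id=f"s{i}", peptide="PEPTIDEK") for i in range(3)]
        assert assemble_proteins(psms, DB) == []

    def test_two_distinct_peptides_retained(self):
        psms = [psm(spectrum_id="s1"), psm(spectrum_id="s2", peptide="ACDEFKR")]
        out = assemble_proteins(psms, DB)
        assert len(out) == 1
        prot = out[0]
        assert prot.accession == "P1"
        assert prot.peptides == {"PEPTIDEK", "ACDEFKR"}
        assert prot.spectra == {"s1", "s2"}
        assert prot.species == "Gossypium hirsutum"
        assert 0 < prot.coverage_percent <= 100

    def test_empty_in_empty_out(self):
        assert assemble_proteins([], DB) == []

    def test_unresolvable_accession_is_hard_error(self):
        with pytest.raises(KeyError, match="P9"):
            assemble_proteins([psm(accession="P9")], DB)

    def test_idempotent_under_reapplication(self):
        psms = filter_psms([psm(spectrum_id="s1"), psm(spectrum_id="s2", peptide="ACDEFKR")])
        once = assemble_proteins(psms, DB)
        twice = assemble_proteins(filter_psms(psms), DB)
        assert [(p.accession, p.peptides, p.spectra) for p in once] == [
            (p.accession, p.peptides, p.spectra) for p in twice
        ]

    def test_decoy_prefix_sets_flag(self):
        db = dict(DB)
        db["DECOY_P1"] = DB["P1"]
        psms = [
            psm(accession="DECOY_P1", spectrum_id="s1"),
            psm(accession="DECOY_P1", spectrum_id="s2", peptide="ACDEFKR"),
        ]
        out = assemble_proteins(psms, db)
        assert out[0].is_decoy


def coverage_oracle(sequence, peptides):
    """Exhaustive position scan: mark every residue of every match window."""
    marked = set()
    for pep in peptides:
        for start in range(len(sequence) - len(pep) + 1):
            if sequence[start : start + len(pep)] == pep:
                marked.update(range(start, start + len(pep)))
    return 100.0 * len(marked) / len(sequence)


class TestComputeCoverage:
    def test_half_covered(self):
        assert compute_coverage("ABCDEFGHIJ", {"ABCDE"}) == 50.0

    def test_overlap_counted_once(self):
        assert compute_coverage("ABCDEFGHIJ", {"ABCD", "CDEF"}) == 60.0

    def test_repeated_occurrence_marks_both(self):
        seq = "AAKGGGAAKTT"
        assert compute_coverage(seq, {"AAK"}) == coverage_oracle(seq, {"AAK"})

    def test_absent_peptide_contributes_nothing(self):
        assert compute_coverage("ABCDEFGHIJ", {"ZZZ"}) == 0.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            compute_coverage("", {"AA"})

    @given(st.data())
    @settings(max_examples=200, deadline=None)
    def test_matches_exhaustive_marking_oracle(self, data):
        seq = data.draw(st.text(alphabet="ACDK", min_size=1, max_size=50))
        peps = data.draw(st.lists(st.text(alphabet="ACDK", min_size=1, max_size=6), max_size=5))
        assert compute_coverage(seq, set(peps)) == pytest.approx(
            coverage_oracle(seq, set(peps))
        )

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_peptide_set(self, data):
        seq = data.draw(st.text(alphabet="ACDK", min_size=1, max_size=40))
        peps = data.draw(st.lists(st.text(alphabet="ACDK", min_size=1, max_size=5), max_size=4))
        extra = data.draw(st.text(alphabet="ACDK", min_size=1, max_size=5))
        assert compute_coverage(seq, set(peps) | {extra}) >= compute_coverage(seq, set(peps))


class TestEstimateFDR:
    def test_no_decoys_is_zero(self):
        assert estimate_fdr([object()] * 100, []) == 0.0

    def test_one_decoy_per_hundred_targets(self):
        assert estimate_fdr([object()] * 100, [object()]) == pytest.approx(0.01)

    def test_no_targets_with_decoys_warns_and_returns_one(self):
        with pytest.warns(UserWarning):
            assert estimate_fdr([], [object()]) == 1.0

    def test_empty_both_is_zero(self):
        assert estimate_fdr([], []) == 0.0


class TestFastaDatabase:
    def test_species_parsed_from_os_token(self, tmp_path):
        p = tmp_path / "db.fasta"
        p.write_text(
            ">P1 some protein OS=Gossypium hirsutum OX=3635\nMKPEPTIDEK\n"
            ">P2 other protein OS=Gossypium arboreum\nACDEFKR\n"
            ">P3 no species here\nWWWW\n"
        )
        db = read_fasta_database(p)
        assert db["P1"] == ("MKPEPTIDEK", "Gossypium hirsutum")
        assert db["P2"][1] == "Gossypium arboreum"
        assert db["P3"][1] == ""


XTANDEM_XML = """<?xml version="1.0"?>
<bioml xmlns:GAML="http://www.bioml.com/gaml/" label="models from 'test'">
<group id="42" mh="1000.50" z="2" expect="0.001" label="test" type="model" sumI="5.0" maxI="100" fI="1">
<protein expect="-5.0" id="42.1" uid="1" label="G0001 synthetic protein OS=Gossypium hirsutum" sumI="5.0">
<note label="description">G0001 synthetic protein OS=Gossypium hirsutum</note>
<file type="peptide" URL="db.fasta"/>
<peptide start="1" end="10">
<domain id="42.1.1" start="1" end="8" expect="0.0015" mh="1000.50" delta="0.01" hyperscore="20" nextscore="10" y_score="1" y_ions="3" b_score="1" b_ions="2" pre="M" post="A" seq="PEPTIDEK" missed_cleavages="0"/>
</peptide>
</protein>
<group label="fragment ion mass spectrum" type="support">
<note label="Description">scan 42</note>
<GAML:trace id="42" label="42.spectrum" type="tandem mass spectrum">
<GAML:attribute type="M+H">1000.50</GAML:attribute>
<GAML:attribute type="charge">2</GAML:attribute>
<GAML:Xdata label="42.spectrum" units="MASSTOCHARGERATIO"><GAML:values byteorder="INTEL" format="ASCII" numvalues="2">100.0 200.0</GAML:values></GAML:Xdata>
<GAML:Ydata label="42.spectrum" units="UNKNOWN"><GAML:values byteorder="INTEL" format="ASCII" numvalues="2">10.0 20.0</GAML:values></GAML:Ydata>
</GAML:trace>
</group>
</group>
</bioml>
"""


class TestXTandemDialect:
    def test_minimal_synthetic_xtandem_file_maps_to_psm_records(self, tmp_path):
        # synthetic stand-in for an X!tandem output file, minimal bioml form
        p = tmp_path / "search.t.xml"
        p.write_text(XTANDEM_XML)
        psms = parse_psm_table(p, dialect="xtandem-xml", replicate_id="A1", condition_id="A")
        assert len(psms) == 1
        m = psms[0]
        assert m.peptide == "PEPTIDEK"
        assert m.accession == "G0001"
        assert m.e_value == 0.0015
        assert m.scan_number == 42
        # precursor m/z reconstructed from the singly-protonated mass M+H
        assert m.precursor_mz == pytest.approx((1000.50 + 1.00727646677) / 2)

    def test_unknown_dialect_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="dialect"):
            parse_psm_table(tmp_path / "x.tsv", dialect="csv")
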