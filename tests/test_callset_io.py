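"""Call-stats and truth-set I/O: round trips, flagging, error handling."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from lbseq.callset_io import (
    CallstatsFormatError,
    CallstatsParseError,
    GenomicLocus,
    Judgement,
    SampleCallSet,
    TruthRecord,
    TruthSet,
    TruthSetError,
    VariantCall,
    read_callstats,
    read_truth,
    write_callstats,
    write_truth,
    CALLSTATS_COLUMNS,
)

HEADER = "\t".join(CALLSTATS_COLUMNS)


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n")


def test_single_row_table(tmp_path):
    p = tmp_path / "one.tsv"
    write_lines(
        p,
        [
            HEADER,
            "S1\tchr1\t100\tA\tT\t95\t5\t0.05\t12.0\tKEEP\t\t\t",
        ],
    )
    cs = read_callstats(p)
    assert cs.sample_id == "S1"
    assert len(cs.calls) == 1
    call = cs.calls[0]
    assert call.tumour_f == 0.05
    assert call.t_lod == 12.0
    assert call.judgement is Judgement.KEEP
    assert call.pop_af is None
    assert call.locus == GenomicLocus("chr1", 100, "A", "T")


def test_empty_table_with_header(tmp_path):
    p = tmp_path / "empty.tsv"
    write_lines(p, ["# a comment", HEADER])
    cs = read_callstats(p, sample_id="S0")
    assert cs.sample_id == "S0"
    assert len(cs.calls) == 0 and not cs.flagged


def test_missing_required_column_names_it(tmp_path):
    p = tmp_path / "bad.tsv"
    cols = [c for c in CALLSTATS_COLUMNS if c != "t_lod_fstar"]
    write_lines(p, ["\t".join(cols)])
    with pytest.raises(CallstatsFormatError, match="t_lod_fstar"):
        read_callstats(p)


def test_non_numeric_count_reports_line_number(tmp_path):
    p = tmp_path / "bad.tsv"
    write_lines(
        p,
        [
            HEADER,
            "S1\tchr1\t100\tA\tT\t95\t5\t0.05\t12.0\tKEEP\t\t\t",
            "S1\tchr1\t101\tA\tT\tninety\t5\t0.05\t12.0\tKEEP\t\t\t",
        ],
    )
    with pytest.raises(CallstatsParseError, match="line 3"):
        read_callstats(p)


def test_indel_and_inconsistent_rows_flagged_not_dropped(tmp_path):
    p = tmp_path / "mixed.tsv"
    write_lines(
        p,
        [
            HEADER,
            "S1\tchr1\t100\tA\tT\t95\t5\t0.05\t12.0\tKEEP\t\t\t",
            "S1\tchr1\t200\tAT\tA\t95\t5\t0.05\t3.0\tKEEP\t\t\t",  # indel
            "S1\tchr1\t300\tG\tC\t95\t5\t0.50\t3.0\tKEEP\t\t\t",  # f vs counts
        ],
    )
    cs = read_callstats(p)
    # conservation: rows in = calls + flagged
    assert len(cs.calls) + len(cs.flagged) == 3
    assert len(cs.calls) == 1
    reasons = {f.reason for f in cs.flagged}
    assert "non-substitution alleles" in reasons


def test_unknown_judgement_maps_to_reject_with_warning(tmp_path):
    p = tmp_path / "j.tsv"
    write_lines(
        p,
        [HEADER, "S1\tchr1\t100\tA\tT\t95\t5\t0.05\t12.0\tUNCOVERED\t\t\t"],
    )
    with pytest.warns(UserWarning, match="UNCOVERED"):
        cs = read_callstats(p)
    assert cs.calls[0].judgement is Judgement.REJECT


@st.composite
def callsets(draw):
    n = draw(st.integers(0, 20))
    bases = "ACGT"
    calls = []
    positions = draw(
        st.lists(st.integers(1, 10**7), min_size=n, max_size=n, unique=True)
    )
    for i in range(n):
        ref = draw(st.sampled_from(bases))
        alt = draw(st.sampled_from([b for b in bases if b != ref]))
        depth = draw(st.integers(1, 10**5))
        alt_count = draw(st.integers(0, depth))
        calls.append(
            VariantCall(
                locus=GenomicLocus("chr2", positions[i], ref, alt),
                t_ref_count=depth - alt_count,
                t_alt_count=alt_count,
                tumour_f=alt_count / depth,
                t_lod=draw(
                    st.floats(-100, 1e6, allow_nan=False, allow_infinity=False)
                ),
                judgement=draw(st.sampled_from(list(Judgement))),
                pop_af=draw(st.one_of(st.none(), st.floats(0, 1))),
            )
        )
    return SampleCallSet(sample_id="HYP", patient_id="P", calls=calls)


@given(callsets())
def test_round_trip_identity(tmp_path_factory, cs):
    """write_callstats then read_callstats preserves every numeric field."""
    p = tmp_path_factory.mktemp("rt") / "cs.tsv"
    write_callstats(cs, p)
    back = read_callstats(p)
    if cs.calls:  # an empty table carries no sample_id to recover
        assert back.sample_id == cs.sample_id
    assert len(back.calls) == len(cs.calls)
    for a, b in zip(cs.calls, back.calls):
        assert a.locus == b.locus
        assert a.t_ref_count == b.t_ref_count
        assert a.t_alt_count == b.t_alt_count
        assert a.tumour_f == b.tumour_f  # byte-identical via shortest repr
        assert a.t_lod == b.t_lod
        assert a.judgement == b.judgement
        assert a.pop_af == b.pop_af


def test_write_empty_callset_is_header_only(tmp_path):
    p = tmp_path / "e.tsv"
    write_callstats(SampleCallSet(sample_id="X"), p)
    assert p.read_text() == HEADER + "\n"


class TestTruth:
    def test_two_row_fixture(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_lines(
            p,
            [
                "patient_id\tcontig\tposition\tref_allele\talt_allele\tbm_af\tsource",
                "P1\tchr1\t100\tA\tT\t0.47\tclinical_panel",
                "P1\tchr1\t101\tC\tG\t0.014\tfive_gene_panel",
            ],
        )
        truth = read_truth(p)
        assert len(truth) == 2
        assert truth.for_patient("P1")[0].bm_allele_fraction == 0.47

    def test_duplicate_key_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        row = "P1\tchr1\t100\tA\tT\t0.4\tclinical_panel"
        write_lines(
            p,
            [
                "patient_id\tcontig\tposition\tref_allele\talt_allele\tbm_af\tsource",
                row,
                row,
            ],
        )
        with pytest.raises(TruthSetError, match="duplicate"):
            read_truth(p)

    def test_out_of_range_bm_af_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_lines(
            p,
            [
                "patient_id\tcontig\tposition\tref_allele\talt_allele\tbm_af\tsource",
                "P1\tchr1\t100\tA\tT\t1.3\tclinical_panel",
            ],
        )
        with pytest.raises(TruthSetError, match="1.3"):
            read_truth(p)

    def test_truth_round_trip(self, tmp_path):
        truth = TruthSet(
            [
                TruthRecord("P1", GenomicLocus("chr1", 5, "A", "G"), 0.25),
                TruthRecord("P2", GenomicLocus("chrX", 9, "T", "C"), 0.0072),
            ]
        )
        p = tmp_path / "t.tsv"
        write_truth(truth, p)
        back = read_truth(p)
        assert {(r.patient_id, r.locus, r.bm_allele_fraction) for r in back} == {
            (r.patient_id, r.locus, r.bm_allele_fraction) for r in truth
        }


def test_locus_validation():
    with pytest.raises(ValueError):
        GenomicLocus("chr1", 0, "A", "T")
    with pytest.raises(ValueError):
        GenomicLocus("chr1", 10, "A", "A")
    with pytest.raises(ValueError):
        GenomicLocus("chr1", 10, "N", "T")
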