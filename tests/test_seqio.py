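"""I/O round-trips, dialect handling and record invariants."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cwgtscreen import seqio
from cwgtscreen.seqio import (
    SENSE_CODONS,
    SYNONYMOUS_FAMILIES,
    CodingRecord,
    CodonUsageTable,
    PeakRecord,
    ProteinRecord,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


# --- ProteinRecord invariants -------------------------------------------------

@pytest.mark.parametrize(
    "kwargs",
    [
        dict(id="", residues="MKV"),
        dict(id="p", residues=""),
        dict(id="p", residues="MKZ"),
        dict(id="p", residues="mkv"),
    ],
)
def test_protein_record_rejects_invalid(kwargs):
    with pytest.raises(ValueError):
        ProteinRecord(**kwargs)


def test_illegal_residue_error_names_position():
    with pytest.raises(ValueError, match="position 3"):
        ProteinRecord(id="p", residues="MKZV")


# --- FASTA --------------------------------------------------------------------

def test_read_fasta_minimal(tmp_path):
    path = tmp_path / "a.fasta"
    path.write_text(">p1\nMKV\n")
    records = seqio.read_fasta(path)
    assert [(r.id, r.residues) for r in records] == [("p1", "MKV")]


def test_read_fasta_concatenates_wrapped_lines(tmp_path):
    lines = ["MKVA" * 15] * 3  # 3 lines of 60 residues
    path = tmp_path / "w.fasta"
    path.write_text(">p1\n" + "\n".join(lines) + "\n")
    (record,) = seqio.read_fasta(path)
    assert record.residues == "".join(lines)
    assert len(record.residues) == 180


def test_read_fasta_duplicate_id_error(tmp_path):
    path = tmp_path / "d.fasta"
    path.write_text(">a\nMK\n>a\nMV\n")
    with pytest.raises(ValueError, match="'a'"):
        seqio.read_fasta(path)


def test_read_fasta_empty_file_error(tmp_path):
    path = tmp_path / "e.fasta"
    path.write_text("\n")
    with pytest.raises(ValueError, match="no records"):
        seqio.read_fasta(path)


def test_read_fasta_metadata_tokens(tmp_path):
    path = tmp_path / "m.fasta"
    path.write_text(">p1 organism=Zea_mays gene=100282614\nMKV\n")
    (record,) = seqio.read_fasta(path)
    assert record.organism == "Zea mays"
    assert record.gene_identifier == "100282614"


@given(
    st.lists(
        st.tuples(
            st.integers(0, 10_000),
            st.text(alphabet=AA20, min_size=1, max_size=150),
        ),
        min_size=1,
        max_size=8,
        unique_by=lambda t: t[0],
    )
)
def test_fasta_round_trip(tmp_path_factory, items):
    records = [ProteinRecord(id=f"p{n}", residues=seq) for n, seq in items]
    path = tmp_path_factory.mktemp("fasta") / "rt.fasta"
    seqio.write_fasta(records, path)
    back = seqio.read_fasta(path)
    assert [(r.id, r.residues) for r in back] == [
        (r.id, r.residues) for r in records
    ]


# --- Hit table ----------------------------------------------------------------

def _hit_table(tmp_path, header, rows):
    path = tmp_path / "hits.tsv"
    body = "\n".join("\t".join(row) for row in rows)
    path.write_text(header + "\n" + body + "\n")
    return path


def test_read_hit_table_order_and_identity(tmp_path):
    path = _hit_table(
        tmp_path,
        "query_id\tsubject_id\tsubject_seq\tidentity_pct",
        [["q1", "s1", "MKV", "40.0"], ["q1", "s2", "MKVA", ""]],
    )
    hits = seqio.read_hit_table(path)
    assert [h.subject.id for h in hits] == ["s1", "s2"]
    assert hits[0].identity == pytest.approx(0.40)
    assert hits[1].identity is None


def test_read_hit_table_missing_column(tmp_path):
    path = _hit_table(tmp_path, "query_id\tsubject_id", [["q1", "s1"]])
    with pytest.raises(ValueError, match="missing column subject_seq"):
        seqio.read_hit_table(path)


def test_read_hit_table_identity_out_of_range(tmp_path):
    path = _hit_table(
        tmp_path,
        "query_id\tsubject_id\tsubject_seq\tidentity_pct",
        [["q1", "s1", "MKV", "140"]],
    )
    with pytest.raises(ValueError, match="outside"):
        seqio.read_hit_table(path)


def test_hits_from_outfmt6(tmp_path):
    fasta = tmp_path / "subjects.fasta"
    fasta.write_text(">s1\nMKV\n>s2\nMKVA\n")
    blast = tmp_path / "hits.tsv"
    blast.write_text("q1\ts1\t95.0\nq1\ts2\t40.0\n")
    hits = seqio.hits_from_outfmt6(blast, fasta)
    assert [h.subject.residues for h in hits] == ["MKV", "MKVA"]
    assert hits[0].identity == pytest.approx(0.95)


# --- Codon usage --------------------------------------------------------------

def test_codon_usage_uniform_counts(tmp_path):
    path = tmp_path / "usage.tsv"
    path.write_text("\n".join(f"{c}\t100" for c in SENSE_CODONS) + "\n")
    table = seqio.read_codon_usage(path)
    for aa, family in SYNONYMOUS_FAMILIES.items():
        for codon in family:
            assert table[codon] == pytest.approx(1.0 / len(family))
    assert table["ATG"] == 1.0  # single-codon family forced to 1
    assert table["TGG"] == 1.0


def test_codon_usage_missing_codon_named(tmp_path):
    path = tmp_path / "usage.tsv"
    rows = [f"{c}\t1" for c in SENSE_CODONS if c != "GGG"]
    path.write_text("\n".join(rows) + "\n")
    with pytest.raises(ValueError, match="GGG"):
        seqio.read_codon_usage(path)


def test_codon_usage_rna_transliterated(tmp_path):
    path = tmp_path / "usage.tsv"
    rows = [f"{c.replace('T', 'U')}\t5" for c in SENSE_CODONS]
    path.write_text("\n".join(rows) + "\n")
    table = seqio.read_codon_usage(path)
    assert table["ATG"] == 1.0
    assert table["UUU"] == table["TTT"]  # lookup transliterates too


# --- Peak table ---------------------------------------------------------------

def test_read_peak_table_multiple_peaks_per_sample(tmp_path):
    path = tmp_path / "peaks.tsv"
    path.write_text(
        "sample_id\tmw_kda\tconc_ug_ml\tpurity_pct\n"
        "s1\t40.0\t10\t50\ns1\t20.0\t5\t10\ns1\t80.0\t2\t5\n"
    )
    peaks = seqio.read_peak_table(path)
    assert len(peaks) == 3
    assert {p.sample_id for p in peaks} == {"s1"}


def test_read_peak_table_header_only_is_empty(tmp_path):
    path = tmp_path / "peaks.tsv"
    path.write_text("sample_id\tmw_kda\tconc_ug_ml\tpurity_pct\n")
    assert seqio.read_peak_table(path) == []


@pytest.mark.parametrize(
    "row", ["s1\t40.0\t10\t101", "s1\t40.0\t-1\t50", "s1\tforty\t10\t50"]
)
def test_read_peak_table_bad_rows(tmp_path, row):
    path = tmp_path / "peaks.tsv"
    path.write_text("sample_id\tmw_kda\tconc_ug_ml\tpurity_pct\n" + row + "\n")
    with pytest.raises(ValueError):
        seqio.read_peak_table(path)


def test_peak_table_round_trip(tmp_path):
    peaks = [
        PeakRecord("s1", 42.0, 111.0, 55.5),
        PeakRecord("s2", 17.25, 0.0, 0.0),
    ]
    path = tmp_path / "rt.tsv"
    seqio.write_peak_table(peaks, path)
    back = seqio.read_peak_table(path)
    assert len(back) == len(peaks)
    for orig, rt in zip(peaks, back):
        assert rt.sample_id == orig.sample_id
        assert rt.observed_mw == pytest.approx(orig.observed_mw, abs=1e-3)
        assert rt.concentration == pytest.approx(orig.concentration, abs=1e-3)
        assert rt.purity == pytest.approx(orig.purity, abs=1e-3)


# --- Packaged screening tables ------------------------------------------------

def test_paper_table_row_counts(paper_tables):
    assert len(paper_tables.library) == 46
    assert len(paper_tables.test_hits) == 19
    assert len(paper_tables.crop_hits) == 17


def test_library_composition(paper_tables):
    arabidopsis = [
        r for r in paper_tables.library if r.organism.startswith("Arabidopsis")
    ]
    assert len(arabidopsis) == 22  # 22 thale-cress genes + 24 from other plants
    assert all(r.gene_identifier for r in paper_tables.library)


def test_test_hit_spot_checks(paper_tables):
    top = max(paper_tables.test_hits, key=lambda h: h.yield_ug_ml)
    assert top.protein == "RGP1"
    assert top.yield_ug_ml == pytest.approx(271.8)
    assert top.chaperones == "GroEL, GroES"


def test_crop_hit_spot_checks(paper_tables):
    best = max(paper_tables.crop_hits, key=lambda h: h.yield_ug_ml)
    assert best.protein == "FvMUCI10"
    assert best.construct == "Δ1–57 and Δ393–457"


# --- CodingRecord -------------------------------------------------------------

def test_coding_record_splits_codons():
    rec = CodingRecord.from_sequence("g", "ATGGGTTAA")
    assert rec.codons == ("ATG", "GGT", "TAA")


@pytest.mark.parametrize("nt", ["ATGC", "ATGNNN"])
def test_coding_record_rejects_bad_sequences(nt):
    with pytest.raises(ValueError):
        CodingRecord.from_sequence("g", nt)
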