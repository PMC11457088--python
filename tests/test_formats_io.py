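"""Reader/writer round-trips, coordinate conventions and error paths."""

import pytest

from hapcull import formats_io as io


# ---------------------------------------------------------------- FASTA

def test_fasta_uppercases_and_preserves_order(tmp_path):
    p = tmp_path / "a.fa"
    p.write_text(">s1 first\nacgt\n>s2\r\nGGcc\r\n")
    recs = io.read_fasta(p)
    assert [(r.id, r.sequence) for r in recs] == [("s1", "ACGT"), ("s2", "GGCC")]
    assert recs[0].description == "first"


def test_fasta_duplicate_id_and_empty_file_error(tmp_path):
    p = tmp_path / "dup.fa"
    p.write_text(">s1\nAC\n>s1\nGT\n")
    with pytest.raises(io.FormatError, match="s1"):
        io.read_fasta(p)
    empty = tmp_path / "empty.fa"
    empty.write_text("")
    with pytest.raises(io.FormatError):
        io.read_fasta(empty)


def test_fasta_round_trip(tmp_path):
    recs = [io.SeqRecord("s1", "ACGTN" * 30), io.SeqRecord("s2", "TTTT", "desc here")]
    p = tmp_path / "rt.fa"
    io.write_fasta(p, recs)
    back = io.read_fasta(p)
    assert [(r.id, r.sequence, r.description) for r in back] == [
        (r.id, r.sequence, r.description) for r in recs
    ]


# ---------------------------------------------------------------- GFF3

def test_gff_parses_attributes_and_keeps_one_based(tmp_path):
    p = tmp_path / "a.gff3"
    p.write_text(
        "##gff-version 3\n"
        "s1\tsrc\tgene\t10\t100\t.\t+\t.\tID=g1\n"
        "s1\tsrc\tmRNA\t10\t100\t.\t+\t.\tID=g1.t1;Parent=g1\n"
        "s1\tsrc\tweird_type\t5\t6\t.\t.\t.\tID=x\n"
    )
    feats = io.read_gff(p)
    assert feats[0].ftype == "gene" and (feats[0].start, feats[0].end) == (10, 100)
    assert feats[1].parent == "g1"
    assert feats[2].ftype == "other" and feats[2].raw_type == "weird_type"
    by_id = {f.feature_id: f for f in feats}
    assert by_id["g1.t1"].parent in by_id  # parent link resolvable


@pytest.mark.parametrize(
    "line,msg",
    [
        ("s1\tsrc\tgene\t10\t100\t.\t+\t.", "9 tab-separated"),
        ("s1\tsrc\tgene\t100\t10\t.\t+\t.\tID=g1", "end 10 < start 100"),
    ],
)
def test_gff_malformed_line_errors_with_line_number(tmp_path, line, msg):
    p = tmp_path / "bad.gff3"
    p.write_text("##gff-version 3\n" + line + "\n")
    with pytest.raises(io.FormatError, match="2"):
        io.read_gff(p)


def test_gff_round_trip(tmp_path):
    feats = [
        io.GffFeature("s1", "src", "gene", 10, 100, "+", {"ID": "g1"}),
        io.GffFeature("s1", "src", "other", 1, 5, ".", {"ID": "x"},
                      raw_type="region"),
    ]
    p = tmp_path / "rt.gff3"
    io.write_gff(p, feats)
    back = io.read_gff(p)
    assert [(f.seqid, f.ftype, f.start, f.end, f.strand, f.attributes) for f in back] == [
        (f.seqid, f.ftype, f.start, f.end, f.strand, f.attributes) for f in feats
    ]
    assert back[1].raw_type == "region"


# ---------------------------------------------------------------- BUSCO

def test_busco_full_table_statuses(tmp_path):
    p = tmp_path / "full_table.tsv"
    p.write_text(
        "# BUSCO version is: 5.3.2\n"
        "b1\tComplete\ts1\t100\t900\t+\t500\t800\n"
        "b2\tDuplicated\ts1\t5\t10\t+\t400\t6\n"
        "b2\tDuplicated\ts2\t5\t10\t-\t390\t6\n"
        "b3\tMissing\n"
    )
    recs = io.read_busco_full_table(p)
    assert recs[0].status == "Complete" and recs[0].seqid == "s1"
    assert [r.busco_id for r in recs if r.status == "Duplicated"] == ["b2", "b2"]
    missing = recs[-1]
    assert missing.status == "Missing" and missing.seqid == "" and missing.start is None


def test_busco_unknown_status_errors(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("b1\tPresent\ts1\t1\t2\n")
    with pytest.raises(io.FormatError, match="Present"):
        io.read_busco_full_table(p)


# ------------------------------------------------------------ alignments

def test_paf_reader_normalizes_strand(tmp_path):
    p = tmp_path / "a.paf"
    p.write_text(
        "q1\t1000\t100\t600\t-\tr1\t2000\t200\t700\t450\t500\t60\n"
    )
    (b,) = io.read_alignments(p, "paf")
    assert b.strand == "antisense"
    assert (b.qry_start, b.qry_end) == (100, 600)
    assert (b.ref_start, b.ref_end) == (200, 700)
    assert b.match_len == 450


def test_coords_reader_shifts_convention(tmp_path):
    p = tmp_path / "a.coords"
    # 1-based inclusive 1..100 must become internal 0..100
    p.write_text("1\t100\t1\t100\t100\t100\t100.0\tr1\tq1\n"
                 "10\t20\t30\t21\t11\t10\t90.0\tr1\tq1\n")
    blocks = io.read_alignments(p, "coords")
    assert (blocks[0].ref_start, blocks[0].ref_end) == (0, 100)
    assert blocks[0].ref_end - blocks[0].ref_start == 100  # implied length
    assert blocks[1].strand == "antisense"
    assert (blocks[1].qry_start, blocks[1].qry_end) == (20, 30)


def test_paf_out_of_range_errors_and_empty_ok(tmp_path):
    p = tmp_path / "bad.paf"
    p.write_text("q1\t100\t0\t200\t+\tr1\t300\t0\t200\t150\t200\t60\n")
    with pytest.raises(io.FormatError, match="beyond declared"):
        io.read_alignments(p, "paf")
    empty = tmp_path / "empty.paf"
    empty.write_text("")
    assert io.read_alignments(empty, "paf") == []


# ----------------------------------------------------------------- hits

def test_hits_reader_and_round_trip(tmp_path):
    p = tmp_path / "h.tsv"
    p.write_text("gA\tgB\t98.5\t500\t5\t0\t1\t500\t1\t500\t1e-100\t500\n")
    (h,) = io.read_hits(p)
    assert h.bitscore == 500.0 and h.aln_len == 500
    out = tmp_path / "rt.tsv"
    io.write_hits(out, [h])
    (h2,) = io.read_hits(out)
    assert (h2.query_id, h2.subject_id, h2.bitscore) == ("gA", "gB", 500.0)


# --------------------------------------------------------------- repeats

def test_rm_class_mapping():
    assert io.map_rm_class("LINE/R1") == ("LINE", "R1")
    assert io.map_rm_class("Low_complexity") == ("Simple", "")
    with pytest.warns(UserWarning, match="Unknown"):
        assert io.map_rm_class("SINE/Alu")[0] == "Unknown"


def test_rmout_and_trf_round_trip(tmp_path):
    annos = [
        io.RepeatAnnotation("s1", 100, 500, "LTR", "Gypsy-1", ""),
        io.RepeatAnnotation("s1", 900, 1200, "LINE", "R1", ""),
    ]
    p = tmp_path / "r.out"
    io.write_rmout(p, annos)
    back = io.read_repeat_table(p, "rmout")
    assert [(a.seqid, a.start, a.end, a.rclass, a.family) for a in back] == [
        (a.seqid, a.start, a.end, a.rclass, a.family) for a in annos
    ]
    tandem = [io.RepeatAnnotation("s2", 10, 110, "Tandem", "TRF_period5", "")]
    q = tmp_path / "r.dat"
    io.write_trf_dat(q, tandem)
    tback = io.read_repeat_table(q, "trf")
    assert [(a.seqid, a.start, a.end, a.rclass) for a in tback] == [
        ("s2", 10, 110, "Tandem")
    ]


def test_all_synthetic_outputs_parse_cleanly(sim_dir):
    """Every emitted file must round through the readers without warnings."""
    import warnings

    outdir, paths = sim_dir
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        asm = io.read_fasta(paths["assembly"])
        feats = io.read_gff(paths["annotation"])
        buscos = io.read_busco_full_table(paths["busco"])
        io.read_fasta(paths["outgroup_assembly"])
        io.read_gff(paths["outgroup_annotation"])
        io.read_repeat_table(paths["rmout"], "rmout")
        io.read_repeat_table(paths["trf"], "trf")
    assert asm and feats and buscos
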