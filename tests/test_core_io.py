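import numpy as np
import pytest

from asmconcord import core_io


# ---------------------------------------------------------------------------
# contig FASTA
# ---------------------------------------------------------------------------


def test_read_contigs_basic_and_normalisation(tmp_path):
    p = tmp_path / "c.fna"
    p.write_text(">c1\nACGT\n>c2\nacgtn\n>c3\nACXGT\n")
    contigs = core_io.read_contigs(p, "A")
    assert [c.id for c in contigs] == ["c1", "c2", "c3"]
    assert contigs[0].length == 4
    assert contigs[1].sequence == "ACGTN"
    assert contigs[2].sequence == "ACNGT"  # non-ACGTN mapped to N


def test_read_contigs_duplicate_id_error(tmp_path):
    p = tmp_path / "c.fna"
    p.write_text(">c1\nACGT\n>c1\nTTTT\n")
    with pytest.raises(ValueError, match="c1"):
        core_io.read_contigs(p, "A")


def test_read_contigs_empty_file_warns(tmp_path, caplog):
    p = tmp_path / "c.fna"
    p.write_text("")
    with caplog.at_level("WARNING", logger="asmconcord"):
        assert core_io.read_contigs(p, "A") == []
    assert "empty" in caplog.text


def test_contigs_round_trip(tmp_path):
    p = tmp_path / "c.fna"
    p.write_text(">c1\nACGTACGT\n>c2\nNNACGT\n")
    contigs = core_io.read_contigs(p, "A")
    q = tmp_path / "c2.fna"
    core_io.write_contigs(contigs, q)
    assert core_io.read_contigs(q, "A") == contigs


# ---------------------------------------------------------------------------
# Prodigal-dialect protein FASTA
# ---------------------------------------------------------------------------


FAA = """\
>c1_1 # 3 # 1736 # 1 # ID=1_1;partial=00;start_type=ATG
MKVA
>c1_2 # 2000 # 2299 # 1 # ID=1_2;partial=10
MSTV
>c2_1 # 10 # 309 # -1 # ID=2_1;partial=10
MKV*
"""


def test_read_prodigal_faa_fields(tmp_path):
    p = tmp_path / "p.faa"
    p.write_text(FAA)
    recs = core_io.read_prodigal_faa(p, "A")
    r1, r2, r3 = recs
    assert (r1.start, r1.end, r1.strand) == (3, 1736, "+")
    assert not r1.is_partial
    assert r1.contig_id == "c1"
    # partial=10 on '+': truncated at the left contig edge = missing 5' end
    assert (r2.partial5, r2.partial3) == (True, False)
    # same digits on '-': left contig edge is the gene's 3' end
    assert (r3.partial5, r3.partial3) == (False, True)
    assert r3.protein_seq == "MKV"  # trailing stop symbol stripped


def test_read_prodigal_faa_missing_partial_warns(tmp_path, caplog):
    p = tmp_path / "p.faa"
    p.write_text(">c1_1 # 1 # 9 # 1 # ID=1\nMKV\n")
    with caplog.at_level("WARNING", logger="asmconcord"):
        recs = core_io.read_prodigal_faa(p, "A")
    assert not recs[0].is_partial
    assert "partial" in caplog.text


def test_read_prodigal_faa_bad_header_reports_line(tmp_path):
    p = tmp_path / "p.faa"
    p.write_text(">c1_1 # 1 # 9 # 1 # partial=00\nMKV\n>broken header\nMKV\n")
    with pytest.raises(ValueError, match=":3"):
        core_io.read_prodigal_faa(p, "A")


def test_internal_stop_symbol_rejected(tmp_path):
    p = tmp_path / "p.faa"
    p.write_text(">c1_1 # 1 # 12 # 1 # partial=00\nMK*V\n")
    with pytest.raises(ValueError, match="stop"):
        core_io.read_prodigal_faa(p, "A")


def test_prodigal_faa_round_trip(tmp_path, bundle):
    asm = bundle.assemblies["SR1"]
    p = tmp_path / "p.faa"
    core_io.write_prodigal_faa(asm.cds, p)
    back = core_io.read_prodigal_faa(p, "SR1")
    assert back == asm.cds


# ---------------------------------------------------------------------------
# GFF3 CDS
# ---------------------------------------------------------------------------


def test_read_cds_gff3_translates_both_strands(tmp_path):
    from Bio.Seq import Seq

    fwd_nt = "ATGAAAGTTTAA"  # MKV + stop
    rc = str(Seq(fwd_nt).reverse_complement())
    contig_seq = fwd_nt + "CCCC" + rc
    contigs = [core_io.Contig("c1", "A", contig_seq)]
    gff = tmp_path / "a.gff"
    gff.write_text(
        "##gff-version 3\n"
        "c1\ttest\tCDS\t1\t12\t.\t+\t0\tID=g1;partial=00\n"
        f"c1\ttest\tCDS\t17\t28\t.\t-\t0\tID=g2;partial=00\n"
    )
    recs = core_io.read_cds_gff3(gff, "A", contigs)
    assert [r.protein_seq for r in recs] == ["MKV", "MKV"]
    assert [r.strand for r in recs] == ["+", "-"]


# ---------------------------------------------------------------------------
# depth tables
# ---------------------------------------------------------------------------


def test_read_depth_table_basic(tmp_path):
    p = tmp_path / "d.tsv"
    p.write_text("c1\t1\t5\nc1\t2\t7\n")
    (track,) = core_io.read_depth_table(p)
    assert track.contig_id == "c1"
    assert list(track.depth) == [5, 7]


def test_read_depth_table_gap_is_error(tmp_path):
    p = tmp_path / "d.tsv"
    p.write_text("c1\t1\t5\nc1\t3\t7\n")
    with pytest.raises(ValueError, match="c1"):
        core_io.read_depth_table(p)


def test_read_depth_table_negative_depth_is_error(tmp_path):
    p = tmp_path / "d.tsv"
    p.write_text("c1\t1\t5\nc1\t2\t-1\n")
    with pytest.raises(ValueError, match="negative"):
        core_io.read_depth_table(p)


def test_read_depth_table_empty_warns(tmp_path, caplog):
    p = tmp_path / "d.tsv"
    p.write_text("")
    with caplog.at_level("WARNING", logger="asmconcord"):
        assert core_io.read_depth_table(p) == []


def test_depth_round_trip(tmp_path):
    tracks = [
        core_io.DepthTrack("c1", np.array([0, 3, 9])),
        core_io.DepthTrack("c2", np.array([1])),
    ]
    p = tmp_path / "d.tsv"
    core_io.write_depth_table(tracks, p)
    assert core_io.read_depth_table(p) == tracks


# ---------------------------------------------------------------------------
# hits tables
# ---------------------------------------------------------------------------

ROW12 = "q1\ts1\t95.5\t100\t4\t1\t1\t100\t1\t100\t1e-50\t200"


def test_read_hits_14col(tmp_path):
    p = tmp_path / "h.tsv"
    p.write_text(ROW12 + "\t120\t110\n")
    (hit,) = core_io.read_hits_table(p)
    assert (hit.qlen, hit.slen) == (120, 110)
    assert hit.pct_identity == 95.5
    assert hit.subject_interval == (1, 100)


def test_read_hits_12col_with_lengths(tmp_path):
    p = tmp_path / "h.tsv"
    p.write_text(ROW12 + "\n")
    (hit,) = core_io.read_hits_table(p, lengths={"q1": 120, "s1": 110})
    assert (hit.qlen, hit.slen) == (120, 110)


def test_read_hits_12col_without_lengths_errors(tmp_path):
    p = tmp_path / "h.tsv"
    p.write_text(ROW12 + "\n")
    with pytest.raises(ValueError, match="length"):
        core_io.read_hits_table(p)
    with pytest.raises(ValueError, match="s1"):
        core_io.read_hits_table(p, lengths={"q1": 120})


def test_read_hits_non_numeric_reports_line(tmp_path):
    p = tmp_path / "h.tsv"
    p.write_text(ROW12 + "\t120\t110\n" + ROW12.replace("100", "xx") + "\t120\t110\n")
    with pytest.raises(ValueError, match=":2"):
        core_io.read_hits_table(p)


def test_hits_round_trip(tmp_path, bundle):
    hits = bundle.assemblies["LR1"].hits
    p = tmp_path / "h.tsv"
    core_io.write_hits_table(hits, p)
    assert core_io.read_hits_table(p) == hits


# ---------------------------------------------------------------------------
# idxstats and peptide evidence
# ---------------------------------------------------------------------------


def test_read_idxstats(tmp_path):
    p = tmp_path / "i.tsv"
    p.write_text("c1\t6000\t70\t0\nc2\t900\t5\t0\n*\t0\t0\t30\n")
    stats, unmapped = core_io.read_idxstats(p)
    assert unmapped == 30
    assert [s.contig_id for s in stats] == ["c1", "c2"]
    assert stats[0].mapped_reads == 70


def test_read_idxstats_malformed_reports_line(tmp_path):
    p = tmp_path / "i.tsv"
    p.write_text("c1\t6000\t70\t0\nc2\t900\n")
    with pytest.raises(ValueError, match=":2"):
        core_io.read_idxstats(p)


def test_idxstats_round_trip(tmp_path):
    stats = [core_io.ContigMapStats("c1", 500, 10), core_io.ContigMapStats("c2", 90, 0)]
    p = tmp_path / "i.tsv"
    core_io.write_idxstats(stats, 7, p)
    assert core_io.read_idxstats(p) == (stats, 7)


def test_peptide_evidence_round_trip(tmp_path):
    ev = [core_io.PeptideEvidence("p1", 3), core_io.PeptideEvidence("p2", 0)]
    p = tmp_path / "pep.tsv"
    core_io.write_peptide_evidence(ev, p)
    assert core_io.read_peptide_evidence(p) == ev
    bad = tmp_path / "bad.tsv"
    bad.write_text("p1\tthree\n")
    with pytest.raises(ValueError, match=":1"):
        core_io.read_peptide_evidence(bad)
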