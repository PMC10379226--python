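"""Format readers/writers and the single internal coordinate convention."""

import json

import pytest

from hervmir import annotation_io as aio
from hervmir.annotation_io import (GenomicInterval, MirnaFeature,
                                   RepeatFeature)
from hervmir.mdte import calls_from_herv_mirna_table


def test_interval_validation():
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 10, 10)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", -1, 5)
    with pytest.raises(ValueError):
        GenomicInterval("", 0, 5)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 0, 5, "x")
    assert GenomicInterval("chr1", 0, 5).length == 5


def test_mature_mirna_length_bounds():
    with pytest.raises(ValueError):
        MirnaFeature(GenomicInterval("chr1", 0, 10), "too-short")
    with pytest.raises(ValueError):
        MirnaFeature(GenomicInterval("chr1", 0, 40), "too-long")


def test_normalize_chrom():
    assert aio.normalize_chrom("4") == "chr4"
    assert aio.normalize_chrom("chr4") == "chr4"
    assert aio.normalize_chrom("MT") == "chrM"


def test_read_rmsk_ucsc_is_already_half_open(tmp_path):
    p = tmp_path / "rmsk.tsv"
    p.write_text("#genoName\tgenoStart\tgenoEnd\tstrand\trepName\trepClass"
                 "\trepFamily\nchr1\t100\t200\t+\tLTR7\tLTR\tERV1\n")
    (feat,) = aio.read_rmsk(p, "ucsc_tsv")
    assert (feat.interval.start, feat.interval.end) == (100, 200)
    assert (feat.rep_name, feat.rep_class, feat.rep_family) == \
        ("LTR7", "LTR", "ERV1")


def test_read_rmsk_out_converts_one_based(tmp_path):
    header = ("   SW   perc perc perc  query     position in query\n"
              "score   div. del. ins.  sequence  begin  end\n"
              "\n")
    row = ("  463   1.3  0.6  1.7  chr1   101   200  (99)  +  "
           "LTR7  LTR/ERV1   1  97  (0)   1\n")
    p = tmp_path / "rm.out"
    p.write_text(header + row)
    (feat,) = aio.read_rmsk(p, "rm_out")
    assert (feat.interval.start, feat.interval.end) == (100, 200)
    assert feat.rep_family == "ERV1"


def test_read_rmsk_skips_corrupt_rows_with_line_number(tmp_path, caplog):
    p = tmp_path / "rmsk.tsv"
    p.write_text(
        "#genoName\tgenoStart\tgenoEnd\tstrand\trepName\trepClass\trepFamily\n"
        "chr1\t100\t200\t+\tLTR7\tLTR\tERV1\n"
        "chr1\tnot_a_number\t300\t+\tLTR7\tLTR\tERV1\n"
        "chr2\t500\t900\t-\tHERV-H-int\tLTR\tERV1\n")
    with caplog.at_level("WARNING"):
        feats = aio.read_rmsk(p, "ucsc_tsv")
    assert len(feats) == 2
    assert any("line 3" in rec.message for rec in caplog.records)


def test_unknown_dialect_fatal(tmp_path):
    p = tmp_path / "x.tsv"
    p.write_text("")
    with pytest.raises(aio.AnnotationError):
        aio.read_rmsk(p, "nope")


def test_read_mirna_gff_mature_only_and_coordinates(tmp_path):
    gff = (
        "##gff-version 3\n"
        "chr4\t.\tmiRNA_primary_transcript\t163093520\t163093650\t.\t+\t.\t"
        "ID=MI0016800;Name=hsa-mir-4454\n"
        "chr4\t.\tmiRNA\t163093607\t163093626\t.\t+\t.\t"
        "ID=MIMAT0018976;Name=hsa-miR-4454\n")
    p = tmp_path / "mirna.gff3"
    p.write_text(gff)
    feats = aio.read_mirna_gff(p)
    assert len(feats) == 1
    m = feats[0]
    # 1-based inclusive 163,093,607..163,093,626 -> [163093606, 163093626)
    assert (m.interval.start, m.interval.end) == (163093606, 163093626)
    assert m.interval.length == 20
    assert m.mirna_id == "hsa-miR-4454"


def test_read_mirna_gff_precursor_only_gives_empty(tmp_path):
    p = tmp_path / "pre.gff3"
    p.write_text("##gff-version 3\n"
                 "chr1\t.\tmiRNA_primary_transcript\t100\t180\t.\t+\t.\t"
                 "ID=MI000;Name=hsa-mir-x\n")
    assert aio.read_mirna_gff(p) == []


def test_read_mirna_gff_mixed_counts_match_manifest(tmp_path):
    lines = ["##gff-version 3"]
    n_mature = 0
    for i in range(6):
        start = 1000 * (i + 1)
        lines.append(f"chr1\t.\tmiRNA_primary_transcript\t{start}\t{start+80}"
                     f"\t.\t+\t.\tID=MI{i};Name=hsa-mir-{i}")
        for j in range(i % 3):
            s = start + 10 + 25 * j
            lines.append(f"chr1\t.\tmiRNA\t{s}\t{s+20}\t.\t+\t.\t"
                         f"ID=MIMAT{i}_{j};Name=hsa-miR-{i}-{j}")
            n_mature += 1
    p = tmp_path / "mixed.gff3"
    p.write_text("\n".join(lines) + "\n")
    assert len(aio.read_mirna_gff(p)) == n_mature


def test_herv_mirna_table_verbatim():
    rows = aio.read_herv_mirna_table()
    assert len(rows) == 29
    by_id = {r.mirna.mirna_id: r for r in rows}
    mir4454 = by_id["hsa-miR-4454"]
    assert mir4454.mirna.interval.chrom == "chr4"
    assert (mir4454.mirna.interval.start, mir4454.mirna.interval.end) == \
        (163093606, 163093626)
    mir7975 = by_id["hsa-miR-7975"]
    assert mir7975.mirna.interval.chrom == "chr19"
    assert mir7975.subfamily == "HERV-H-int"
    assert all(17 <= r.mirna.interval.length <= 24 for r in rows)


def test_rmsk_roundtrip_all_dialects(tmp_path):
    feats = [
        RepeatFeature(GenomicInterval("chr2", 10, 500, "+"), "LTR7", "LTR",
                      "ERV1"),
        RepeatFeature(GenomicInterval("chr1", 0, 63, "-"), "LTR7C", "LTR",
                      "ERV1"),
        RepeatFeature(GenomicInterval("chr1", 100, 450, "."), "THE1B", "LTR",
                      "ERVL-MaLR"),
    ]
    for dialect in ("ucsc_tsv", "bed6"):
        p = tmp_path / f"rt.{dialect}"
        aio.write_rmsk(feats, p, dialect)
        back = aio.read_rmsk(p, dialect)
        assert sorted(back) == sorted(feats)


def test_mirna_gff_roundtrip(tmp_path):
    feats = [MirnaFeature(GenomicInterval("chr1", 100, 120, "+"), "m1"),
             MirnaFeature(GenomicInterval("chr2", 5, 27, "-"), "m2")]
    p = tmp_path / "m.gff3"
    aio.write_mirna_gff(feats, p)
    assert sorted(aio.read_mirna_gff(p)) == sorted(feats)


def test_write_calls_empty_and_sorted_bed(tmp_path):
    p = tmp_path / "empty.tsv"
    aio.write_calls([], p, "tsv")
    assert p.read_text().startswith("#")
    calls = calls_from_herv_mirna_table(aio.read_herv_mirna_table())[:3]
    out = tmp_path / "calls.bed"
    aio.write_calls(calls, out, "bed6")
    lines = out.read_text().strip().split("\n")
    assert len(lines) == 3
    starts = [(l.split("\t")[0], int(l.split("\t")[1])) for l in lines]
    assert starts == sorted(starts)


def test_calls_json_roundtrip(tmp_path):
    calls = calls_from_herv_mirna_table(aio.read_herv_mirna_table())
    p = tmp_path / "calls.json"
    aio.write_calls(calls, p, "json")
    back = aio.read_calls_json(p)
    assert len(back) == 29
    flat = {d["mirna"]["mirna_id"]: d for d in back}
    assert flat["hsa-miR-4454"]["subfamily"] == "HERV-H-int"
    assert flat["hsa-miR-4454"]["mirna"]["interval"]["start"] == 163093606
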