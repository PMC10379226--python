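"""Readers and writers for repeat and miRNA annotation.

All readers normalize coordinates to a single internal convention:
0-based, half-open ``[start, end)`` intervals on "chr"-prefixed chromosome
names. The conversions applied per source format are:

* UCSC rmsk TSV (``genoStart``/``genoEnd``): already 0-based half-open —
  taken verbatim.
* RepeatMasker ``.out`` (``begin``/``end``): 1-based inclusive — ``begin``
  is decremented by one.
* GFF3 (miRBase dialect) and the packaged HERV-miRNA table: 1-based
  inclusive — start decremented by one.
* BED6: already 0-based half-open.

Malformed rows are skipped record-by-record with a logged warning carrying
the line number; only structural problems (missing file, unknown dialect)
are fatal.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

#: sha256 of the packaged HERV-derived-miRNA coordinate table.
_HERV_MIRNA_TABLE_SHA256 = (
    "9fbd53139586df0d5bba2327df0b1a82cdb13a8a4b89903cd14e4e2c7eed6e81"
)


class AnnotationError(ValueError):
    """Fatal problem with an annotation file (missing, wrong dialect...)."""


def normalize_chrom(name: str) -> str:
    """Map bare chromosome names onto the "chr"-prefixed convention.

    ``"4" -> "chr4"``, ``"MT" -> "chrM"``; names already prefixed pass
    through unchanged.
    """
    name = name.strip()
    if not name:
        raise AnnotationError("empty chromosome name")
    if name.startswith("chr"):
        return name
    if name in ("MT", "Mt", "mt"):
        return "chrM"
    return "chr" + name


@dataclasses.dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclasses.dataclass(frozen=True, order=True)
class RepeatFeature:
    """One repeat-annotation record (interval plus RepeatMasker names)."""

    interval: GenomicInterval
    rep_name: str    # subfamily, e.g. HERV-H-int, LTR7, MER52A
    rep_class: str   # e.g. LTR
    rep_family: str  # e.g. ERV1, ERVK, ERVL, ERVL-MaLR, Gypsy

    def __post_init__(self) -> None:
        for field in ("rep_name", "rep_class", "rep_family"):
            if not getattr(self, field):
                raise ValueError(f"{field} must be non-empty")


# Mature-miRNA length bounds (bp) accepted by MirnaFeature.
MATURE_LEN_MIN = 15
MATURE_LEN_MAX = 30


@dataclasses.dataclass(frozen=True, order=True)
class MirnaFeature:
    """One mature-miRNA genomic record."""

    interval: GenomicInterval
    mirna_id: str

    def __post_init__(self) -> None:
        if not self.mirna_id:
            raise ValueError("mirna_id must be non-empty")
        if not (MATURE_LEN_MIN <= self.interval.length <= MATURE_LEN_MAX):
            raise ValueError(
                f"{self.mirna_id}: mature length {self.interval.length} bp "
                f"outside [{MATURE_LEN_MIN}, {MATURE_LEN_MAX}]"
            )


# ---------------------------------------------------------------------------
# repeat annotation
# ---------------------------------------------------------------------------

RMSK_DIALECTS = ("ucsc_tsv", "rm_out", "bed6")

_UCSC_REQUIRED = ("genoName", "genoStart", "genoEnd", "strand",
                  "repName", "repClass", "repFamily")


def _repeat_from_bed_name(name: str) -> tuple[str, str, str]:
    parts = name.split(";")
    if len(parts) != 3:
        raise ValueError(f"BED name {name!r} is not repName;repClass;repFamily")
    return parts[0], parts[1], parts[2]


def read_rmsk(path: str | Path, dialect: str = "ucsc_tsv") -> list[RepeatFeature]:
    """Read repeat annotation into :class:`RepeatFeature` records.

    Parameters
    ----------
    path
        Annotation file.
    dialect
        ``ucsc_tsv`` (UCSC table browser rmsk export, tab-separated with a
        header naming at least genoName/genoStart/genoEnd/strand/repName/
        repClass/repFamily), ``rm_out`` (RepeatMasker .out) or ``bed6``
        (name field encodes ``repName;repClass;repFamily``).
    """
    path = Path(path)
    if not path.exists():
        raise AnnotationError(f"no such annotation file: {path}")
    if dialect not in RMSK_DIALECTS:
        raise AnnotationError(f"unknown rmsk dialect {dialect!r}")
    features: list[RepeatFeature] = []
    with open(path) as fh:
        if dialect == "ucsc_tsv":
            header_line = fh.readline()
            header = header_line.lstrip("#").rstrip("\n").split("\t")
            try:
                idx = {c: header.index(c) for c in _UCSC_REQUIRED}
            except ValueError as exc:
                raise AnnotationError(f"{path}: missing rmsk column ({exc})")
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                try:
                    iv = GenomicInterval(
                        normalize_chrom(fields[idx["genoName"]]),
                        int(fields[idx["genoStart"]]),
                        int(fields[idx["genoEnd"]]),
                        fields[idx["strand"]] or ".",
                    )
                    features.append(RepeatFeature(
                        iv, fields[idx["repName"]],
                        fields[idx["repClass"]], fields[idx["repFamily"]]))
                except (ValueError, IndexError) as exc:
                    logger.warning("%s line %d skipped: %s", path, lineno, exc)
        elif dialect == "rm_out":
            for lineno, line in enumerate(fh, start=1):
                fields = line.split()
                # header lines start with "SW"/"score" or are blank
                if not fields or not fields[0][0].isdigit():
                    continue
                try:
                    chrom = normalize_chrom(fields[4])
                    start = int(fields[5]) - 1   # 1-based inclusive begin
                    end = int(fields[6])
                    strand = "-" if fields[8] == "C" else fields[8]
                    rep_name = fields[9]
                    cls_fam = fields[10].split("/")
                    rep_class = cls_fam[0]
                    rep_family = cls_fam[1] if len(cls_fam) > 1 else cls_fam[0]
                    features.append(RepeatFeature(
                        GenomicInterval(chrom, start, end, strand),
                        rep_name, rep_class, rep_family))
                except (ValueError, IndexError) as exc:
                    logger.warning("%s line %d skipped: %s", path, lineno, exc)
        else:  # bed6
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.rstrip("\n").split("\t")
                try:
                    name, cls, fam = _repeat_from_bed_name(fields[3])
                    features.append(RepeatFeature(
                        GenomicInterval(normalize_chrom(fields[0]),
                                        int(fields[1]), int(fields[2]),
                                        fields[5] if len(fields) > 5 else "."),
                        name, cls, fam))
                except (ValueError, IndexError) as exc:
                    logger.warning("%s line %d skipped: %s", path, lineno, exc)
    return features


def write_rmsk(features: Sequence[RepeatFeature], path: str | Path,
               dialect: str = "ucsc_tsv") -> Path:
    """Write repeats in a dialect :func:`read_rmsk` can read back."""
    path = Path(path)
    if dialect not in ("ucsc_tsv", "bed6"):
        raise AnnotationError(f"unsupported write dialect {dialect!r}")
    rows = sorted(features, key=lambda f: (f.interval.chrom, f.interval.start,
                                           f.rep_name))
    with open(path, "w") as fh:
        if dialect == "ucsc_tsv":
            fh.write("#" + "\t".join(_UCSC_REQUIRED) + "\n")
            for f in rows:
                fh.write("\t".join([
                    f.interval.chrom, str(f.interval.start), str(f.interval.end),
                    f.interval.strand, f.rep_name, f.rep_class, f.rep_family,
                ]) + "\n")
        else:
            for f in rows:
                name = ";".join([f.rep_name, f.rep_class, f.rep_family])
                fh.write("\t".join([
                    f.interval.chrom, str(f.interval.start), str(f.interval.end),
                    name, "0", f.interval.strand]) + "\n")
    return path


# ---------------------------------------------------------------------------
# miRNA annotation
# ---------------------------------------------------------------------------

def read_mirna_gff(path: str | Path) -> list[MirnaFeature]:
    """Read mature miRNAs from a miRBase-dialect GFF3.

    Only rows of feature type ``miRNA`` (the mature records) are retained;
    ``miRNA_primary_transcript`` precursors are ignored. GFF3 1-based
    inclusive coordinates are converted to the internal half-open
    convention. Rows lacking both Name and ID are skipped with a warning.
    """
    import gffutils

    path = Path(path)
    if not path.exists():
        raise AnnotationError(f"no such GFF3 file: {path}")
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", sort_attribute_values=True)
    out: list[MirnaFeature] = []
    for feat in db.features_of_type("miRNA"):
        name = feat.attributes.get("Name", feat.attributes.get("ID", [None]))[0]
        if name is None:
            logger.warning("%s: miRNA row at %s:%d-%d has no Name/ID; skipped",
                           path, feat.seqid, feat.start, feat.end)
            continue
        try:
            out.append(MirnaFeature(
                GenomicInterval(normalize_chrom(feat.seqid),
                                feat.start - 1, feat.end,
                                feat.strand if feat.strand in STRANDS else "."),
                name))
        except ValueError as exc:
            logger.warning("%s: miRNA row %s skipped: %s", path, name, exc)
    out.sort(key=lambda m: (m.interval.chrom, m.interval.start, m.mirna_id))
    return out


def write_mirna_gff(features: Sequence[MirnaFeature], path: str | Path) -> Path:
    """Write mature miRNAs as miRBase-dialect GFF3 (1-based inclusive)."""
    path = Path(path)
    rows = sorted(features, key=lambda m: (m.interval.chrom, m.interval.start,
                                           m.mirna_id))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in rows:
            strand = m.interval.strand if m.interval.strand != "." else "+"
            fh.write("\t".join([
                m.interval.chrom, ".", "miRNA",
                str(m.interval.start + 1), str(m.interval.end),
                ".", strand, ".",
                f"ID={m.mirna_id};Name={m.mirna_id}"]) + "\n")
    return path


@dataclasses.dataclass(frozen=True)
class HervMirnaRow:
    """One row of the packaged HERV-derived-miRNA coordinate table."""

    mirna: MirnaFeature
    family: str
    subfamily: str


def _herv_mirna_table_path() -> Path:
    return Path(str(resources.files("hervmir").joinpath(
        "data/herv_mirna_catalog.tsv")))


def read_herv_mirna_table() -> list[HervMirnaRow]:
    """Load the packaged table of the 29 HERV-derived mature miRNAs.

    Coordinates in the table are 1-based inclusive (miRBase convention) and
    are normalized on read; strand is not recorded in the source table and
    is stored as ".". The packaged file is integrity-checked by sha256.
    """
    path = _herv_mirna_table_path()
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != _HERV_MIRNA_TABLE_SHA256:
        raise AnnotationError(
            f"packaged HERV-miRNA table is corrupt (sha256 {digest})")
    rows: list[HervMirnaRow] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: header.index(c) for c in
               ("chrom", "start", "end", "mirna", "family", "subfamily")}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            iv = GenomicInterval(normalize_chrom(f[idx["chrom"]]),
                                 int(f[idx["start"]]) - 1, int(f[idx["end"]]))
            rows.append(HervMirnaRow(MirnaFeature(iv, f[idx["mirna"]]),
                                     f[idx["family"]], f[idx["subfamily"]]))
    return rows


def read_qpcr_primers() -> dict[str, tuple[str, str]]:
    """Packaged qPCR primer metadata: gene -> (forward, reverse)."""
    path = Path(str(resources.files("hervmir").joinpath(
        "data/qpcr_primers.tsv")))
    out: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            gene, fwd, rev = line.rstrip("\n").split("\t")
            out[gene] = (fwd, rev)
    return out


# ---------------------------------------------------------------------------
# generic call output
# ---------------------------------------------------------------------------

def _primary_interval(record) -> tuple[GenomicInterval, str]:
    """(interval, display name) of a call record, for BED output/sorting."""
    if hasattr(record, "mirna"):
        return record.mirna.interval, record.mirna.mirna_id
    if hasattr(record, "ltr"):
        return record.ltr.interval, record.ltr.rep_name
    if hasattr(record, "int_run"):
        iv = GenomicInterval(record.int_run.interval.chrom,
                             record.ltr5.interval.start,
                             record.ltr3.interval.end,
                             record.int_run.interval.strand)
        return iv, "full_length_provirus"
    if hasattr(record, "interval"):
        name = getattr(record, "rep_name", getattr(record, "mirna_id", "."))
        return record.interval, name
    raise TypeError(f"cannot locate an interval on {type(record).__name__}")


def _flatten(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _flatten(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _flatten(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_flatten(v) for v in obj]
    return obj


def _tsv_columns(flat: dict, prefix: str = "") -> dict:
    cols: dict = {}
    for k, v in flat.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            cols.update(_tsv_columns(v, key + "."))
        else:
            cols[key] = v
    return cols


CALL_FORMATS = ("tsv", "bed6", "json")


def write_calls(records: Sequence, path: str | Path, format: str = "tsv") -> Path:
    """Write a homogeneous list of call records.

    TSV and JSON carry every field (nested dataclasses flattened with
    dotted column names in TSV); BED6 carries the record's primary interval
    with 0-based half-open coordinates. Rows are sorted by
    (chrom, start, name) for deterministic output.
    """
    path = Path(path)
    if format not in CALL_FORMATS:
        raise AnnotationError(f"unknown call format {format!r}")
    if records:
        head = type(records[0])
        if any(type(r) is not head for r in records):
            raise AnnotationError("records must be homogeneous")
    order = sorted(
        range(len(records)),
        key=lambda i: (_primary_interval(records[i])[0].chrom,
                       _primary_interval(records[i])[0].start,
                       _primary_interval(records[i])[1]))
    with open(path, "w") as fh:
        if format == "bed6":
            for i in order:
                iv, name = _primary_interval(records[i])
                fh.write("\t".join([iv.chrom, str(iv.start), str(iv.end),
                                    name, "0", iv.strand]) + "\n")
        elif format == "json":
            json.dump([_flatten(records[i]) for i in order], fh, indent=1)
            fh.write("\n")
        else:
            rows = [_tsv_columns(_flatten(records[i])) for i in order]
            if rows:
                cols = list(rows[0])
                fh.write("\t".join(cols) + "\n")
                for row in rows:
                    fh.write("\t".join(str(row[c]) for c in cols) + "\n")
            else:
                fh.write("# no records\n")
    return path


def read_calls_json(path: str | Path) -> list[dict]:
    """Read back a JSON call file as a list of plain dicts."""
    with open(path) as fh:
        return json.load(fh)
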