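"""Readers and writers for the external formats the pipeline touches.

All genomic intervals are held internally as 0-based half-open ``[start, end)``.
GFF3 (1-based inclusive) is converted at the boundary; BED6 is already
half-open.  SAM handling is deliberately minimal: the pipeline only needs the
reference interval, strand and mate designation of each accepted mapping, so
only QNAME, FLAG, RNAME, POS and CIGAR are interpreted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import pysam

logger = logging.getLogger(__name__)

MATE_FIRST = "first"
MATE_SECOND = "second"
MATE_UNPAIRED = "unpaired"

_VALID_MATES = frozenset({MATE_FIRST, MATE_SECOND, MATE_UNPAIRED})


@dataclass(frozen=True, order=True)
class CdsFeature:
    """A protein-coding feature used as the counting unit.

    ``start``/``end`` are 0-based half-open on ``ref_id``.
    """

    ref_id: str
    start: int
    end: int
    gene_id: str
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid CDS interval for {self.gene_id!r}: "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r} for {self.gene_id!r}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start


class MappedRead(NamedTuple):
    """One aligned mate: reference interval, strand and pairing role."""

    read_id: str
    mate: str  # first | second | unpaired
    ref_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str  # + | -


@dataclass(frozen=True)
class SampleManifest:
    """One sequencing library in the 2-strain x 2-condition x replicate design."""

    sample_id: str
    strain: str  # WT | mutant
    condition: str  # unstressed | stressed
    replicate: int
    reads_path: str


# ---------------------------------------------------------------------------
# annotation


def _parse_gff3_attributes(field: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in field.rstrip(";").split(";"):
        if "=" in part:
            k, _, v = part.partition("=")
            out[k.strip()] = v.strip()
    return out


def read_annotation(path: str | Path) -> list[CdsFeature]:
    """Read CDS features from a GFF3 or BED6 file.

    GFF3 rows of type ``CDS`` or ``gene`` are accepted; the identifier is taken
    from the ``ID`` or ``locus_tag`` attribute (rows without either are
    rejected with a warning).  GFF3 1-based inclusive coordinates are converted
    to 0-based half-open.  Features are returned sorted by (ref_id, start).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".bed":
        feats = list(_read_bed6(path))
    else:
        feats = list(_read_gff3(path))
    seen: set[str] = set()
    for f in feats:
        if f.gene_id in seen:
            raise ValueError(f"duplicate gene_id {f.gene_id!r} in {path}")
        seen.add(f.gene_id)
    feats.sort(key=lambda f: (f.ref_id, f.start))
    return feats


def _read_gff3(path: Path) -> Iterator[CdsFeature]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            ref_id, _src, ftype, start1, end1, _score, strand, _phase, attrs = cols
            if ftype not in ("CDS", "gene"):
                continue
            start1, end1 = int(start1), int(end1)
            if end1 < start1:
                raise ValueError(f"{path}:{lineno}: end < start")
            attr = _parse_gff3_attributes(attrs)
            gene_id = attr.get("ID") or attr.get("locus_tag")
            if gene_id is None:
                logger.warning("%s:%d: row lacks ID/locus_tag, skipped", path, lineno)
                continue
            yield CdsFeature(ref_id, start1 - 1, end1, gene_id, strand)


def _read_bed6(path: Path) -> Iterator[CdsFeature]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            if len(cols) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED columns")
            ref_id, start, end, name, _score, strand = cols[:6]
            start, end = int(start), int(end)
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            yield CdsFeature(ref_id, start, end, name, strand)


def write_annotation_gff3(features: Iterable[CdsFeature], path: str | Path) -> None:
    """Write features as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{f.ref_id}\tstresseq\tCDS\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t0\tID={f.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# mapped reads


def _mate_of_flag(flag: int) -> str:
    if not flag & 0x1:
        return MATE_UNPAIRED
    if flag & 0x40:
        return MATE_FIRST
    if flag & 0x80:
        return MATE_SECOND
    return MATE_UNPAIRED


def read_mapped_reads(path: str | Path) -> Iterator[MappedRead]:
    """Stream accepted mappings from a SAM (subset) or TSV file.

    Unmapped records (FLAG 0x4) are skipped; records whose CIGAR consumes no
    reference are rejected with a warning.  The TSV fallback has columns
    read_id, mate, ref_id, start, end, strand (already 0-based half-open).
    """
    path = Path(path)
    if path.suffix.lower() in (".tsv", ".txt"):
        yield from _read_tsv_reads(path)
    else:
        yield from _read_sam_reads(path)


def _read_sam_reads(path: Path) -> Iterator[MappedRead]:
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as af:
        for rec in af:
            if rec.is_unmapped:
                continue
            end = rec.reference_end  # None when CIGAR consumes no reference
            if end is None:
                logger.warning("record %s has no reference-consuming CIGAR op", rec.query_name)
                continue
            yield MappedRead(
                read_id=rec.query_name,
                mate=_mate_of_flag(rec.flag),
                ref_id=rec.reference_name,
                start=rec.reference_start,
                end=end,
                strand="-" if rec.is_reverse else "+",
            )


def _read_tsv_reads(path: Path) -> Iterator[MappedRead]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        required = ("read_id", "mate", "ref_id", "start", "end", "strand")
        missing = [c for c in required if c not in idx]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        for lineno, line in enumerate(fh, start=2):
            cols = line.rstrip("\n").split("\t")
            mate = cols[idx["mate"]]
            if mate not in _VALID_MATES:
                raise ValueError(f"{path}:{lineno}: unknown mate designation {mate!r}")
            yield MappedRead(
                read_id=cols[idx["read_id"]],
                mate=mate,
                ref_id=cols[idx["ref_id"]],
                start=int(cols[idx["start"]]),
                end=int(cols[idx["end"]]),
                strand=cols[idx["strand"]],
            )


# ---------------------------------------------------------------------------
# tabular output

#: fields printed as floats with 2 decimals (MA statistics and fold changes)
_TWO_DECIMAL_FIELDS = {"M", "A", "fold_change", "mean_rpkm_ref", "mean_rpkm_trt",
                       "mean_cp_a", "mean_cp_b", "sd_a", "sd_b", "delta_cp",
                       "sd_delta", "rel_amount"}
#: fields printed as bare integers
_INT_FIELDS = {"reported_identity"}


def _format_value(name: str, value) -> str:
    if value is None:
        return ""
    if name in _INT_FIELDS:
        return str(int(value))
    if isinstance(value, float):
        if name in _TWO_DECIMAL_FIELDS:
            return f"{value:.2f}"
        return repr(value)
    return str(value)


def write_table(records, path: str | Path, columns: list[str] | None = None) -> None:
    """Write homogeneous records (dataclasses, NamedTuples or dicts) as TSV.

    MA statistics and fold changes are printed with 2 decimals and percent
    identity as an integer, mirroring the reporting precision of the source
    tables.  Rows are sorted by gene_id when present (else by percent identity,
    descending) so output is deterministic.
    """
    records = list(records)
    if records:
        first = records[0]
        if hasattr(first, "_asdict"):
            dicts = [r._asdict() for r in records]
        elif hasattr(first, "__dataclass_fields__"):
            from dataclasses import asdict

            dicts = [asdict(r) for r in records]
        else:
            dicts = [dict(r) for r in records]
        if columns is None:
            columns = list(dicts[0].keys())
        if "gene_id" in columns:
            dicts.sort(key=lambda d: str(d.get("gene_id")))
        elif "pct_identity" in dicts[0]:
            dicts.sort(key=lambda d: -d["pct_identity"])
    else:
        dicts = []
        if columns is None:
            raise ValueError("columns required to write an empty table")
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for d in dicts:
            fh.write("\t".join(_format_value(c, d.get(c)) for c in columns) + "\n")
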