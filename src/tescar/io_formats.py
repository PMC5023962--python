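"""Readers and writers for FASTA, GFF3, BED and TSV tables.

Coordinates are 0-based half-open everywhere in memory; conversion to
the 1-based inclusive convention of GFF3 (and back) happens only here.
Gzip-compressed input is handled transparently by file suffix.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_DNA = set("ACGTRYSWKMBDHVN")


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> dict[str, str]:
    """Read a (possibly gzipped) FASTA file into an ordered id -> sequence map.

    Sequences are upper-cased; duplicate ids and non-IUPAC characters
    raise ``ValueError``.
    """
    records: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in records:
                raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
            seq = str(rec.seq).upper()
            bad = set(seq) - IUPAC_DNA
            if bad:
                raise ValueError(
                    f"non-IUPAC characters {sorted(bad)} in record {rec.id!r}"
                )
            records[rec.id] = seq
    return records


def write_fasta(records: dict[str, str], path, width: int = 60) -> None:
    """Write sequences wrapped at ``width`` columns."""
    with _open_text(path, "wt") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
            if not seq:
                fh.write("\n")


@dataclass
class FeatureRecord:
    """One annotation feature; ``start``/``end`` are 0-based half-open."""

    seq_id: str
    source: str
    type: str
    start: int
    end: int
    strand: str = "+"
    score: str = "."
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(
                f"feature end < start ({self.end} < {self.start}) on {self.seq_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def attr(self, key: str, default: str | None = None) -> str | None:
        return self.attributes.get(key, default)


def _fmt_attributes(attrs: dict[str, str]) -> str:
    if not attrs:
        return "."
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    if text in (".", ""):
        return attrs
    for item in text.strip(";").split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff3(path) -> list[FeatureRecord]:
    """Parse a GFF3 file into validated :class:`FeatureRecord` objects.

    On-disk 1-based inclusive coordinates become 0-based half-open.
    """
    features: list[FeatureRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            seq_id, source, ftype, start, end, score, strand, _phase, attrs = fields
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise ValueError(f"{path}:{lineno}: end < start ({end_i} < {start_i})")
            features.append(
                FeatureRecord(
                    seq_id=seq_id,
                    source=source,
                    type=ftype,
                    start=start_i - 1,
                    end=end_i,
                    strand=strand,
                    score=score,
                    attributes=_parse_attributes(attrs),
                )
            )
    return features


def write_gff3(features: Iterable[FeatureRecord], path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                "\t".join(
                    [
                        f.seq_id,
                        f.source,
                        f.type,
                        str(f.start + 1),
                        str(f.end),
                        f.score,
                        f.strand,
                        ".",
                        _fmt_attributes(f.attributes),
                    ]
                )
                + "\n"
            )


def read_bed(path) -> list[tuple[str, int, int, str]]:
    """Read a BED file (0-based half-open) into (chrom, start, end, name) tuples."""
    rows = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            if end < start:
                raise ValueError(f"BED end < start: {line!r}")
            rows.append((chrom, start, end, name))
    return rows


def write_bed(intervals: Iterable[tuple], path) -> None:
    """Write (chrom, start, end[, name]) intervals as sorted BED."""
    rows = []
    for iv in intervals:
        chrom, start, end = iv[0], int(iv[1]), int(iv[2])
        if end < start:
            raise ValueError(f"invalid interval {iv}")
        name = str(iv[3]) if len(iv) > 3 else "."
        rows.append((chrom, start, end, name))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with _open_text(path, "wt") as fh:
        for chrom, start, end, name in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def as_seqrecords(records: dict[str, str]) -> list[SeqRecord]:
    return [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
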