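"""Readers and writers for FASTA, BED, alignment coordinate tables and report TSVs.

Internal coordinates are 1-based inclusive everywhere; the BED convention
(0-based half-open) is converted only at the file boundary.

The coordinate-table dialect is a fixed 9-column tab-separated layout modeled
on ``show-coords -T`` with the sequence identifiers appended::

    ref_start  ref_end  qry_start  qry_end  ref_alen  qry_alen  pct_identity  ref_id  qry_id

A query range with ``qry_start > qry_end`` encodes a reverse-orientation
alignment block.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


_IUPAC = set("ACGTRYSWKMBDHVN")

COORDS_COLUMNS = (
    "ref_start", "ref_end", "qry_start", "qry_end",
    "ref_alen", "qry_alen", "pct_identity", "ref_id", "qry_id",
)


@dataclass(frozen=True)
class CoordsRow:
    """One aligned block between a query contig and a reference chromosome.

    Coordinates are 1-based inclusive.  ``qry_start > qry_end`` means the
    block aligns in reverse orientation.
    """

    ref_start: int
    ref_end: int
    qry_start: int
    qry_end: int
    ref_alen: int
    qry_alen: int
    pct_identity: float
    ref_id: str
    qry_id: str

    def __post_init__(self) -> None:
        if self.ref_start > self.ref_end:
            raise FormatError(
                f"ref_start {self.ref_start} > ref_end {self.ref_end}")
        if self.ref_alen != self.ref_end - self.ref_start + 1:
            raise FormatError("ref_alen inconsistent with ref coordinates")
        if self.qry_alen != abs(self.qry_end - self.qry_start) + 1:
            raise FormatError("qry_alen inconsistent with qry coordinates")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise FormatError(f"pct_identity {self.pct_identity} outside [0, 100]")

    @property
    def is_reverse(self) -> bool:
        return self.qry_start > self.qry_end

    @property
    def qry_low(self) -> int:
        return min(self.qry_start, self.qry_end)

    @property
    def qry_high(self) -> int:
        return max(self.qry_start, self.qry_end)

    @property
    def ref_span(self) -> int:
        return self.ref_alen


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` map.

    Sequences are uppercased.  Duplicate identifiers and non-IUPAC
    characters raise :class:`FormatError`.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        bad = set(seq) - _IUPAC
        if bad:
            raise FormatError(
                f"non-IUPAC character(s) {sorted(bad)} in sequence {rec.id!r}")
        out[rec.id] = seq
    return out


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    """Write sequences as FASTA wrapped at ``width`` columns."""
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_coords(path: str | Path) -> list[CoordsRow]:
    """Parse a 9-column coordinate table into :class:`CoordsRow` objects."""
    rows: list[CoordsRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}")
            try:
                rows.append(CoordsRow(
                    ref_start=int(fields[0]), ref_end=int(fields[1]),
                    qry_start=int(fields[2]), qry_end=int(fields[3]),
                    ref_alen=int(fields[4]), qry_alen=int(fields[5]),
                    pct_identity=float(fields[6]),
                    ref_id=fields[7], qry_id=fields[8],
                ))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return rows


def write_coords(rows: Iterable[CoordsRow], path: str | Path) -> None:
    """Write rows in the 9-column dialect; read∘write is the identity."""
    with open(path, "w") as fh:
        for r in rows:
            fh.write(
                f"{r.ref_start}\t{r.ref_end}\t{r.qry_start}\t{r.qry_end}\t"
                f"{r.ref_alen}\t{r.qry_alen}\t{_fmt_pct(r.pct_identity)}\t"
                f"{r.ref_id}\t{r.qry_id}\n")


def _fmt_pct(x: float) -> str:
    # repr round-trips floats exactly; trim a trailing ".0" is NOT done so
    # that read(write(rows)) == rows bit-for-bit on the float value.
    return repr(x)


def read_bed(path: str | Path) -> list[tuple[str, int, int, tuple[str, ...]]]:
    """Read a BED file, converting to 1-based inclusive coordinates.

    Returns ``(chrom, start, end, extra_columns)`` tuples where BED
    ``(chrom, 0, 100)`` becomes ``(chrom, 1, 100)``.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = re.split(r"\t", line)
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if start0 >= end0:
                raise FormatError(
                    f"{path}:{lineno}: start {start0} >= end {end0}")
            out.append((fields[0], start0 + 1, end0, tuple(fields[3:])))
    return out


def write_bed(intervals: Iterable[tuple], path: str | Path) -> None:
    """Write 1-based inclusive ``(chrom, start, end, *extra)`` as BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            chrom, start, end, *extra = iv
            extras = list(extra[0]) if len(extra) == 1 and isinstance(extra[0], (tuple, list)) else extra
            cols = [chrom, str(start - 1), str(end)] + [str(x) for x in extras]
            fh.write("\t".join(cols) + "\n")
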