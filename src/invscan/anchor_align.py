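"""Lightweight whole-genome aligner: unique k-mer anchors plus collinear chaining.

The aligner seeds on k-mers that occur exactly once in the reference
(canonical over both strands), merges exactly-abutting seeds into maximal
exact-match anchors, and chains collinear same-orientation anchors into
alignment segments.  Repetitive sequence is suppressed automatically because
multi-copy k-mers never seed.  The default chaining parameters
(min_cluster=200, max_gap=2000) match the cluster and break settings
commonly used for fungal whole-genome comparisons.

Output is the 9-column coordinate-table dialect of :mod:`invscan.formats_io`,
which is what the inversion scanner consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .formats_io import CoordsRow

DEFAULT_K = 21
DEFAULT_MIN_CLUSTER = 200
DEFAULT_MAX_GAP = 2000

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


class Orientation(str, Enum):
    FORWARD = "forward"
    REVERSE = "reverse"


@dataclass(frozen=True)
class Anchor:
    """A maximal run of unique-k-mer exact matches.

    ``ref_start``/``qry_start`` are the leftmost 1-based coordinates of the
    matching spans on reference and query.  For a reverse anchor the query
    span matches the reverse complement of the reference span.
    """

    ref_id: str
    ref_start: int
    qry_start: int
    length: int
    orientation: Orientation

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.length - 1

    @property
    def qry_end(self) -> int:
        return self.qry_start + self.length - 1


@dataclass(frozen=True)
class AlignmentSegment:
    """A chained block of anchors reported as one aligned segment."""

    ref_id: str
    ref_start: int
    ref_end: int
    qry_id: str
    qry_start: int  # leftmost query coordinate
    qry_end: int    # rightmost query coordinate
    orientation: Orientation
    anchored_bases: int

    @property
    def identity(self) -> float:
        return self.anchored_bases / (self.ref_end - self.ref_start + 1)

    def to_coords_row(self) -> CoordsRow:
        fwd = self.orientation is Orientation.FORWARD
        qs, qe = (self.qry_start, self.qry_end) if fwd else (self.qry_end, self.qry_start)
        return CoordsRow(
            ref_start=self.ref_start, ref_end=self.ref_end,
            qry_start=qs, qry_end=qe,
            ref_alen=self.ref_end - self.ref_start + 1,
            qry_alen=self.qry_end - self.qry_start + 1,
            pct_identity=round(min(100.0, 100.0 * self.identity), 2),
            ref_id=self.ref_id, qry_id=self.qry_id,
        )


def _kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer encodings of all forward and reverse-complement k-mers.

    Returns ``(fwd, rev)`` arrays of length ``len(seq) - k + 1``; windows
    containing a non-ACGT base are set to -1 in both.
    """
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes.astype(np.int64), k)
    pow_f = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = win @ pow_f
    # reverse complement: complement each base (3 - c), read right-to-left
    rev = (3 - win) @ pow_f[::-1]
    ok = np.lib.stride_tricks.sliding_window_view(codes != 255, k).all(axis=1)
    return np.where(ok, fwd, -1), np.where(ok, rev, -1)


@dataclass
class ReferenceIndex:
    """Positions of the unique canonical k-mers of a reference genome.

    Stored as parallel arrays sorted by canonical code so contig k-mers can
    be resolved in one vectorized binary search.  Multi-copy k-mers are kept
    separately (``nonunique``) only as a flag set.
    """

    k: int
    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    canon: np.ndarray          # sorted canonical codes, unique occurrences only
    chrom_idx: np.ndarray      # int32 index into chrom_names
    pos: np.ndarray            # 1-based position of the k-mer on its chromosome
    fwd_is_canon: np.ndarray   # True when the forward-strand k-mer is canonical
    nonunique: np.ndarray      # sorted canonical codes with >= 2 occurrences

    def is_unique(self, canonical: int) -> bool:
        i = np.searchsorted(self.canon, canonical)
        return bool(i < len(self.canon) and self.canon[i] == canonical)

    def is_nonunique(self, canonical: int) -> bool:
        i = np.searchsorted(self.nonunique, canonical)
        return bool(i < len(self.nonunique) and self.nonunique[i] == canonical)

    def lookup(self, canonical: int) -> tuple[str, int, bool] | None:
        """(chromosome, 1-based position, forward-is-canonical) or None."""
        i = np.searchsorted(self.canon, canonical)
        if i < len(self.canon) and self.canon[i] == canonical:
            return (self.chrom_names[int(self.chrom_idx[i])],
                    int(self.pos[i]), bool(self.fwd_is_canon[i]))
        return None


def index_reference(reference: dict[str, str], k: int = DEFAULT_K) -> ReferenceIndex:
    """Index every canonical k-mer of the reference, flagging multi-copy ones.

    ``k`` must be odd (a canonical k-mer can then never equal its own
    reverse complement) and within [11, 31] so encodings fit an int64.
    """
    if k % 2 == 0 or not 11 <= k <= 31:
        raise ValueError(f"k must be odd and in [11, 31], got {k}")
    shortest = min(len(s) for s in reference.values())
    if k > shortest:
        raise ValueError(f"k={k} exceeds shortest chromosome ({shortest} bp)")

    names = list(reference)
    canon_parts, chrom_parts, pos_parts, strand_parts = [], [], [], []
    for ci, chrom in enumerate(names):
        fwd, rev = _kmer_codes(reference[chrom], k)
        canon = np.minimum(fwd, rev)
        valid = canon >= 0
        canon_parts.append(canon[valid])
        strand_parts.append((fwd <= rev)[valid])
        pos_parts.append(np.nonzero(valid)[0].astype(np.int64) + 1)
        chrom_parts.append(np.full(int(valid.sum()), ci, dtype=np.int32))
    canon = np.concatenate(canon_parts)
    chrom_idx = np.concatenate(chrom_parts)
    pos = np.concatenate(pos_parts)
    fwd_is_canon = np.concatenate(strand_parts)

    order = np.argsort(canon, kind="stable")
    canon, chrom_idx, pos, fwd_is_canon = (
        canon[order], chrom_idx[order], pos[order], fwd_is_canon[order])
    uniq, first, counts = np.unique(canon, return_index=True, return_counts=True)
    single = counts == 1
    sel = first[single]
    return ReferenceIndex(
        k=k,
        chrom_names=names,
        chrom_lengths={c: len(s) for c, s in reference.items()},
        canon=canon[sel], chrom_idx=chrom_idx[sel], pos=pos[sel],
        fwd_is_canon=fwd_is_canon[sel],
        nonunique=uniq[~single],
    )


def seed_anchors(index: ReferenceIndex, contig: str) -> list[Anchor]:
    """Find all unique-k-mer seed matches of ``contig`` and merge exactly
    abutting seeds into maximal exact-match anchors (both orientations)."""
    k = index.k
    if len(contig) < k:
        return []
    fwd, rev = _kmer_codes(contig, k)
    canon = np.minimum(fwd, rev)
    qry_fwd_is_canon = fwd <= rev

    i = np.searchsorted(index.canon, canon)
    i[i == len(index.canon)] = 0 if len(index.canon) else 0
    if len(index.canon) == 0:
        return []
    hit = index.canon[i] == canon
    hit &= canon >= 0
    if not hit.any():
        return []
    j = np.nonzero(hit)[0]              # 0-based qry k-mer starts
    ii = i[j]
    chrom = index.chrom_idx[ii]
    rpos = index.pos[ii]                # 1-based ref k-mer starts
    forward = index.fwd_is_canon[ii] == qry_fwd_is_canon[j]

    # a run continues while qry step is +1, same chromosome and strand, and
    # the ref position steps +1 (forward) or -1 (reverse)
    step = np.where(forward[:-1], 1, -1)
    brk = (
        (np.diff(j) != 1)
        | (chrom[1:] != chrom[:-1])
        | (forward[1:] != forward[:-1])
        | (np.diff(rpos) != step)
    )
    starts = np.concatenate(([0], np.nonzero(brk)[0] + 1))
    ends = np.concatenate((np.nonzero(brk)[0], [len(j) - 1]))

    anchors = []
    for s, e in zip(starts, ends):
        length = int(j[e] - j[s]) + k
        if forward[s]:
            anchors.append(Anchor(
                index.chrom_names[int(chrom[s])], int(rpos[s]),
                int(j[s]) + 1, length, Orientation.FORWARD))
        else:
            # ref positions decrease along the run; leftmost is the last hit
            anchors.append(Anchor(
                index.chrom_names[int(chrom[s])], int(rpos[e]),
                int(j[s]) + 1, length, Orientation.REVERSE))
    return anchors


def chain_anchors(
    anchors: list[Anchor],
    min_cluster: int = DEFAULT_MIN_CLUSTER,
    max_gap: int = DEFAULT_MAX_GAP,
    qry_id: str = "query",
) -> list[AlignmentSegment]:
    """Greedily chain collinear same-orientation anchors into segments.

    Anchors are chained per (chromosome, orientation) in reference order; a
    chain breaks when the reference gap or the query gap to the next anchor
    exceeds ``max_gap`` or the query order is inconsistent with the
    orientation.  Chains with fewer than ``min_cluster`` anchored bases are
    discarded.  Fully deterministic: ties are broken by longer anchor, then
    smaller coordinates.
    """
    segments: list[AlignmentSegment] = []
    groups: dict[tuple[str, Orientation], list[Anchor]] = {}
    for a in anchors:
        groups.setdefault((a.ref_id, a.orientation), []).append(a)

    for (chrom, orient), group in sorted(
        groups.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
    ):
        group = sorted(group, key=lambda a: (a.ref_start, -a.length, a.qry_start))
        chain: list[Anchor] = []

        def flush() -> None:
            if not chain:
                return
            anchored = sum(a.length for a in chain)
            if anchored < min_cluster:
                return
            segments.append(AlignmentSegment(
                ref_id=chrom,
                ref_start=chain[0].ref_start,
                ref_end=max(a.ref_end for a in chain),
                qry_id=qry_id,
                qry_start=min(a.qry_start for a in chain),
                qry_end=max(a.qry_end for a in chain),
                orientation=orient,
                anchored_bases=anchored,
            ))

        for a in group:
            if not chain:
                chain = [a]
                continue
            prev = chain[-1]
            ref_gap = a.ref_start - prev.ref_end - 1
            if orient is Orientation.FORWARD:
                qry_gap = a.qry_start - prev.qry_end - 1
                ordered = a.qry_start > prev.qry_start
            else:
                qry_gap = prev.qry_start - a.qry_end - 1
                ordered = a.qry_start < prev.qry_start
            if ordered and -max_gap <= ref_gap <= max_gap and qry_gap <= max_gap:
                chain.append(a)
            else:
                flush()
                chain = [a]
        flush()

    segments.sort(key=lambda s: (s.ref_id, s.ref_start, s.ref_end, s.qry_id))
    return segments


def align_contig(
    index: ReferenceIndex,
    contig: str,
    qry_id: str,
    min_cluster: int = DEFAULT_MIN_CLUSTER,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[AlignmentSegment]:
    return chain_anchors(
        seed_anchors(index, contig),
        min_cluster=min_cluster, max_gap=max_gap, qry_id=qry_id)


def align_assembly(
    reference: dict[str, str],
    assembly: dict[str, str],
    k: int = DEFAULT_K,
    min_cluster: int = DEFAULT_MIN_CLUSTER,
    max_gap: int = DEFAULT_MAX_GAP,
    index: ReferenceIndex | None = None,
) -> list[CoordsRow]:
    """Align every contig of ``assembly`` to ``reference``; rows sorted by
    (ref_id, ref_start).  A contig may yield zero, one or many rows."""
    if not reference or not assembly:
        raise ValueError("reference and assembly must be non-empty")
    if index is None:
        index = index_reference(reference, k)
    rows: list[CoordsRow] = []
    for qry_id in assembly:
        for seg in align_contig(
            index, assembly[qry_id], qry_id,
            min_cluster=min_cluster, max_gap=max_gap,
        ):
            rows.append(seg.to_coords_row())
    rows.sort(key=lambda r: (r.ref_id, r.ref_start, r.ref_end, r.qry_id))
    return rows


__all__ = [
    "Anchor", "AlignmentSegment", "Orientation", "ReferenceIndex",
    "index_reference", "seed_anchors", "chain_anchors", "align_contig",
    "align_assembly", "DEFAULT_K", "DEFAULT_MIN_CLUSTER", "DEFAULT_MAX_GAP",
]
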