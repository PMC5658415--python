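"""Inversion-candidate detection from alignment coordinate tables.

An inversion leaves a characteristic signature in a whole-genome alignment:
a block of reverse-orientation segments on the reference, flanked on both
sides by forward segments, with the orientation switches falling at the two
breakpoints.  In a complete assembly the whole pattern lies inside one
contig (``intra_contig`` mode).  In a fragmented assembly the pattern is
spread over contig pairs that align next to each other on the reference at
two different locations and in different directions (``contig_pair`` mode):
around the left breakpoint b1 a forward segment ends at b1 and a reverse
segment starts at b1+1; around the right breakpoint b2 a reverse segment
ends at b2 and a forward segment starts at b2+1.

The scanner turns every such orientation switch into a
:class:`BreakpointSignal` (pattern ``F|R`` or ``R|F``), pairs an ``F|R``
signal with the next ``R|F`` signal when the intervening reference interval
is covered by reverse segments (gaps no larger than the adjacency
tolerance), and reports the pair as one :class:`InversionCall`.  Signals
that cannot be paired are kept as ``unpaired`` — they are reported but the
downstream filters only admit calls with both breakpoints found.

A repeat screen discards signals whose flanking segment has a secondary
alignment elsewhere covering most of the same contig interval, the
automated equivalent of manually rejecting breakpoints caused by
misalignment to repetitive sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

from .formats_io import CoordsRow

DEFAULT_TOLERANCE = 5000
DEFAULT_MIN_FLANK = 1000
MIN_CALL_SIZE = 1000
REPEAT_COVER_FRACTION = 0.8


class SignalMode(str, Enum):
    INTRA_CONTIG = "intra_contig"
    CONTIG_PAIR = "contig_pair"


class Pattern(str, Enum):
    FR = "F|R"
    RF = "R|F"


@dataclass(frozen=True)
class BreakpointSignal:
    """An orientation switch between two reference-adjacent segments."""

    ref_id: str
    ref_pos: int              # reference coordinate of the junction (left segment end)
    left: CoordsRow
    right: CoordsRow
    pattern: Pattern
    junction_gap: int         # right.ref_start - left.ref_end - 1 (may be < 0)
    mode: SignalMode


@dataclass
class InversionCall:
    """A per-strain inversion candidate on the reference.

    ``start``/``end`` delimit the reversed reference block (1-based
    inclusive): start = left junction position + 1, end = right junction
    position, so ``size`` equals the length of the reversed block.
    """

    strain_id: str
    ref_id: str
    start: int
    end: int
    breakpoints: tuple[BreakpointSignal, ...]
    evidence_types: frozenset[str] = frozenset()
    status: str = "paired"    # "paired" | "unpaired"

    @property
    def size(self) -> int:
        return self.end - self.start + 1


def _flank_len(row: CoordsRow) -> int:
    return row.ref_span


def _signals_from_rows(
    rows: list[CoordsRow],
    tolerance: int,
    min_flank: int,
    same_contig_only: bool | None = None,
) -> list[BreakpointSignal]:
    """Enumerate F|R and R|F junction signals among reference-adjacent rows.

    ``same_contig_only``: True keeps only intra-contig junctions, False only
    cross-contig junctions, None keeps both.
    """
    signals: list[BreakpointSignal] = []
    by_ref: dict[str, list[CoordsRow]] = {}
    for r in rows:
        by_ref.setdefault(r.ref_id, []).append(r)
    for ref_id, group in sorted(by_ref.items()):
        group = sorted(group, key=lambda r: (r.ref_start, r.ref_end, r.qry_id))
        for left in group:
            for right in group:
                if left is right or left.is_reverse == right.is_reverse:
                    continue
                gap = right.ref_start - left.ref_end - 1
                if not -tolerance <= gap <= tolerance:
                    continue
                same = left.qry_id == right.qry_id
                if same_contig_only is True and not same:
                    continue
                if same_contig_only is False and same:
                    continue
                # the forward flank must be long enough to trust
                flank = left if not left.is_reverse else right
                if _flank_len(flank) < min_flank:
                    continue
                pattern = Pattern.FR if not left.is_reverse else Pattern.RF
                signals.append(BreakpointSignal(
                    ref_id=ref_id, ref_pos=left.ref_end,
                    left=left, right=right, pattern=pattern,
                    junction_gap=gap,
                    mode=SignalMode.INTRA_CONTIG if same else SignalMode.CONTIG_PAIR,
                ))
    signals.sort(key=lambda s: (s.ref_id, s.ref_pos, s.pattern.value,
                                s.left.qry_id, s.right.qry_id))
    return signals


def _best_signal_per_junction(
    signals: list[BreakpointSignal],
) -> list[BreakpointSignal]:
    """When several contig pairs support the same junction position and
    pattern, keep the pair with the longest total flank length (ties: by
    contig ids)."""
    best: dict[tuple[str, int, Pattern], BreakpointSignal] = {}
    for s in signals:
        key = (s.ref_id, s.ref_pos, s.pattern)
        cur = best.get(key)
        if cur is None:
            best[key] = s
            continue
        score = (s.left.ref_span + s.right.ref_span,
                 # prefer lexicographically smaller contig ids on ties
                 tuple(sorted((s.left.qry_id, s.right.qry_id))))
        cur_score = (cur.left.ref_span + cur.right.ref_span,
                     tuple(sorted((cur.left.qry_id, cur.right.qry_id))))
        if score[0] > cur_score[0] or (score[0] == cur_score[0]
                                       and score[1] < cur_score[1]):
            best[key] = s
    out = list(best.values())
    out.sort(key=lambda s: (s.ref_id, s.ref_pos, s.pattern.value))
    return out


def _reverse_cover_ok(
    start: int, end: int, reverse_rows: list[CoordsRow], tolerance: int
) -> bool:
    """True when [start, end] is covered by reverse segments with every
    uncovered gap (including at the two ends) <= tolerance."""
    ivs = sorted(
        (r.ref_start, r.ref_end) for r in reverse_rows
        if r.ref_end >= start - tolerance and r.ref_start <= end + tolerance)
    cursor = start - 1  # rightmost covered position so far
    for s, e in ivs:
        if s - cursor - 1 > tolerance:
            return False
        cursor = max(cursor, e)
        if cursor >= end:
            return True
    return end - cursor <= tolerance


def _pair_signals(
    signals: list[BreakpointSignal],
    rows: list[CoordsRow],
    strain_id: str,
    tolerance: int,
) -> tuple[list[InversionCall], list[BreakpointSignal]]:
    """Pair each F|R signal with the nearest following R|F signal whose
    intervening interval is reverse-covered; leftovers stay unpaired."""
    calls: list[InversionCall] = []
    unpaired: list[BreakpointSignal] = []
    by_ref: dict[str, list[BreakpointSignal]] = {}
    for s in signals:
        by_ref.setdefault(s.ref_id, []).append(s)
    rev_by_ref: dict[str, list[CoordsRow]] = {}
    for r in rows:
        if r.is_reverse:
            rev_by_ref.setdefault(r.ref_id, []).append(r)

    for ref_id, group in sorted(by_ref.items()):
        group = sorted(group, key=lambda s: (s.ref_pos, s.pattern.value))
        used = [False] * len(group)
        # match F|R signals right-to-left so the innermost (tightest) F|R
        # wins when several candidates precede the same R|F junction
        for i in range(len(group) - 1, -1, -1):
            fr = group[i]
            if fr.pattern is not Pattern.FR or used[i]:
                continue
            # take the FARTHEST reverse-covered R|F: the run of reverse
            # segments is maximal, so the call spans the whole reversed block
            for jj in range(len(group) - 1, i, -1):
                rf = group[jj]
                if rf.pattern is not Pattern.RF or used[jj]:
                    continue
                start, end = fr.ref_pos + 1, rf.ref_pos
                if end - start + 1 < MIN_CALL_SIZE:
                    continue
                if not _reverse_cover_ok(
                    start, end, rev_by_ref.get(ref_id, []), tolerance
                ):
                    continue
                calls.append(InversionCall(
                    strain_id=strain_id, ref_id=ref_id,
                    start=start, end=end, breakpoints=(fr, rf)))
                used[i] = used[jj] = True
                break
        unpaired.extend(s for i, s in enumerate(group) if not used[i])
    calls.sort(key=lambda c: (c.ref_id, c.start, c.end))
    return calls, unpaired


def detect_intra_contig(
    rows: list[CoordsRow],
    strain_id: str = "",
    tolerance: int = DEFAULT_TOLERANCE,
    min_flank: int = DEFAULT_MIN_FLANK,
) -> tuple[list[InversionCall], list[BreakpointSignal]]:
    """Detect inversions visible within single contigs: a run of reverse
    segments flanked by forward segments of the same contig."""
    by_contig: dict[str, list[CoordsRow]] = {}
    for r in rows:
        by_contig.setdefault(r.qry_id, []).append(r)
    calls: list[InversionCall] = []
    unpaired: list[BreakpointSignal] = []
    for contig in sorted(by_contig):
        sig = _signals_from_rows(
            by_contig[contig], tolerance, min_flank, same_contig_only=True)
        c, u = _pair_signals(sig, by_contig[contig], strain_id, tolerance)
        calls.extend(c)
        unpaired.extend(u)
    calls.sort(key=lambda c: (c.ref_id, c.start, c.end))
    return calls, unpaired


def detect_contig_pair(
    rows: list[CoordsRow],
    strain_id: str = "",
    tolerance: int = DEFAULT_TOLERANCE,
    min_flank: int = DEFAULT_MIN_FLANK,
) -> tuple[list[InversionCall], list[BreakpointSignal]]:
    """Detect inversions from cross-contig adjacency patterns: contigs that
    align next to each other on the reference at two locations in different
    directions."""
    sig = _best_signal_per_junction(_signals_from_rows(
        rows, tolerance, min_flank, same_contig_only=False))
    return _pair_signals(sig, rows, strain_id, tolerance)


def screen_repeats(
    calls: list[InversionCall],
    unpaired: list[BreakpointSignal],
    rows: list[CoordsRow],
    cover_fraction: float = REPEAT_COVER_FRACTION,
) -> tuple[list[InversionCall], list[BreakpointSignal]]:
    """Discard breakpoint signals whose flanking segments look repetitive.

    A signal is dropped when either of its two segments has an alternative
    alignment elsewhere on the reference covering >= ``cover_fraction`` of
    the same contig interval.  A paired call losing a signal is demoted to
    ``unpaired`` status.
    """
    by_qry: dict[str, list[CoordsRow]] = {}
    for r in rows:
        by_qry.setdefault(r.qry_id, []).append(r)

    def is_repetitive(row: CoordsRow) -> bool:
        lo, hi = row.qry_low, row.qry_high
        length = hi - lo + 1
        for other in by_qry.get(row.qry_id, []):
            if other is row:
                continue
            same_place = (other.ref_id == row.ref_id
                          and other.ref_start <= row.ref_end
                          and other.ref_end >= row.ref_start)
            if same_place:
                continue
            ov = min(hi, other.qry_high) - max(lo, other.qry_low) + 1
            if ov >= cover_fraction * length:
                return True
        return False

    def signal_ok(s: BreakpointSignal) -> bool:
        return not (is_repetitive(s.left) or is_repetitive(s.right))

    kept_calls: list[InversionCall] = []
    demoted: list[BreakpointSignal] = []
    for call in calls:
        ok = [s for s in call.breakpoints if signal_ok(s)]
        if len(ok) == 2:
            kept_calls.append(call)
        else:
            demoted.extend(ok)
    kept_unpaired = [s for s in unpaired if signal_ok(s)] + demoted
    kept_unpaired.sort(key=lambda s: (s.ref_id, s.ref_pos, s.pattern.value))
    return kept_calls, kept_unpaired


def scan_strain(
    rows: list[CoordsRow],
    strain_id: str,
    evidence_type: str = "",
    tolerance: int = DEFAULT_TOLERANCE,
    min_flank: int = DEFAULT_MIN_FLANK,
    include_unpaired: bool = True,
) -> list[InversionCall]:
    """Full per-strain scan: both detection modes, repeat screening, then a
    deduplicated, deterministically ordered call list.

    Junction signals from intra-contig and cross-contig adjacencies are
    pooled before pairing, so an inversion with one breakpoint inside a
    contig and the other at a contig junction is still called.  Unpaired
    signals are reported as ``status="unpaired"`` calls with a degenerate
    interval when ``include_unpaired`` is set; downstream filters never
    count them as events.
    """
    signals = _best_signal_per_junction(
        _signals_from_rows(rows, tolerance, min_flank, same_contig_only=None))
    calls, unpaired = _pair_signals(signals, rows, strain_id, tolerance)
    calls, unpaired = screen_repeats(calls, unpaired, rows)

    tagged = [
        replace(c, evidence_types=frozenset({evidence_type} if evidence_type else ()))
        for c in calls
    ]
    if include_unpaired:
        for s in unpaired:
            tagged.append(InversionCall(
                strain_id=strain_id, ref_id=s.ref_id,
                start=s.ref_pos, end=s.ref_pos,
                breakpoints=(s,),
                evidence_types=frozenset({evidence_type} if evidence_type else ()),
                status="unpaired"))
    tagged.sort(key=lambda c: (c.ref_id, c.start, c.end, c.status))
    return tagged


# ---------------------------------------------------------------------------
# tabular output

CALLS_COLUMNS = (
    "strain_id", "ref_id", "start", "end", "size", "status",
    "evidence_types", "bp1_pos", "bp1_mode", "bp2_pos", "bp2_mode",
)


def calls_to_table(calls: list[InversionCall]) -> "pandas.DataFrame":  # noqa: F821
    import pandas as pd

    rows = []
    for c in calls:
        bp = list(c.breakpoints)
        rows.append({
            "strain_id": c.strain_id, "ref_id": c.ref_id,
            "start": c.start, "end": c.end, "size": c.size,
            "status": c.status,
            "evidence_types": ",".join(sorted(c.evidence_types)),
            "bp1_pos": bp[0].ref_pos if bp else "",
            "bp1_mode": bp[0].mode.value if bp else "",
            "bp2_pos": bp[1].ref_pos if len(bp) > 1 else "",
            "bp2_mode": bp[1].mode.value if len(bp) > 1 else "",
        })
    return pd.DataFrame(rows, columns=list(CALLS_COLUMNS))


def write_calls(calls: list[InversionCall], path: str | Path) -> None:
    calls_to_table(calls).to_csv(path, sep="\t", index=False)
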