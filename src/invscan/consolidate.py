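"""Cross-strain consolidation of inversion calls into unique events.

The same inversion found in several strains must be counted once, and
clusters of mutually overlapping inversions likewise count as a single
event.  Both rules are implemented with one mechanism: connected components
of the interval-overlap graph (same chromosome, >= 1 bp overlap) become
events whose interval is the union envelope of their member calls.

Inclusion filters mirror the study design they model:

* only calls with both breakpoints identified (``paired``) are eligible;
* events below 1 kbp are dropped;
* large events (> 100 kbp) need support from at least two distinct
  evidence types (e.g. Illumina + PacBio, or Illumina + PCR/Sanger);
* small events (1-100 kbp) need at least two carrier strains.

Fixation is classified per lineage: an event is fixed within a mating type
when its carriers include every sampled strain of one mating type of that
lineage and no strain of the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .inv_scan import InversionCall
from .simgenome import StrainSpec

LARGE_EVENT_MIN = 100_000  # strictly greater than this is "large"
MIN_EVENT_SIZE = 1_000


@dataclass
class InversionEvent:
    """A consolidated inversion: overlapping per-strain calls counted once."""

    ref_id: str
    start: int
    end: int
    members: list[InversionCall]
    strains: frozenset[str]
    evidence_types: frozenset[str]
    fixation: dict[str, str] = field(default_factory=dict)  # lineage -> label

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    @property
    def size_class(self) -> str:
        return "large" if self.size > LARGE_EVENT_MIN else "small"

    @property
    def fixation_label(self) -> str:
        if not self.fixation:
            return "unclassified"
        if all(v == "fixed_in_mating_type" for v in self.fixation.values()):
            return "fixed_in_mating_type"
        return "polymorphic"


def cluster_events(calls: list[InversionCall]) -> list[InversionEvent]:
    """Merge overlapping paired calls (same chromosome, >= 1 bp overlap)
    into events; the event interval is the union envelope of its members."""
    paired = [c for c in calls if c.status == "paired"]
    by_ref: dict[str, list[InversionCall]] = {}
    for c in paired:
        by_ref.setdefault(c.ref_id, []).append(c)
    events: list[InversionEvent] = []
    for ref_id in sorted(by_ref):
        group = sorted(by_ref[ref_id], key=lambda c: (c.start, c.end, c.strain_id))
        cluster: list[InversionCall] = []
        env_end = -1

        def flush() -> None:
            if not cluster:
                return
            events.append(InversionEvent(
                ref_id=ref_id,
                start=min(c.start for c in cluster),
                end=max(c.end for c in cluster),
                members=list(cluster),
                strains=frozenset(c.strain_id for c in cluster),
                evidence_types=frozenset().union(
                    *(c.evidence_types for c in cluster)),
            ))

        for c in group:
            if cluster and c.start <= env_end:
                cluster.append(c)
                env_end = max(env_end, c.end)
            else:
                flush()
                cluster = [c]
                env_end = c.end
        flush()
    events.sort(key=lambda e: (e.ref_id, e.start, e.end))
    return events


def apply_filters(events: list[InversionEvent]) -> list[InversionEvent]:
    """Apply the inclusion rules; see the module docstring."""
    retained = []
    for e in events:
        if any(m.status != "paired" for m in e.members):
            continue
        if e.size < MIN_EVENT_SIZE:
            continue
        if e.size_class == "large":
            if len(e.evidence_types) < 2:
                continue
        else:
            if len(e.strains) < 2:
                continue
        retained.append(e)
    return retained


def classify_fixation(
    event: InversionEvent, metadata: list[StrainSpec]
) -> dict[str, str]:
    """Label the event per carrier lineage.

    ``fixed_in_mating_type``: carriers are exactly all sampled strains of
    one mating type of the lineage and none of the other; anything else is
    ``polymorphic``.  Carrier strains missing from the metadata raise.
    """
    by_strain = {m.strain_id: m for m in metadata}
    missing = sorted(e for e in event.strains if e not in by_strain)
    if missing:
        raise KeyError(f"strains {missing} absent from metadata")
    labels: dict[str, str] = {}
    carrier_lineages = {by_strain[s].lineage for s in event.strains}
    for lineage in sorted(carrier_lineages):
        in_lineage = [m for m in metadata if m.lineage == lineage]
        carriers = {m.strain_id for m in in_lineage} & event.strains
        fixed = False
        for mt in sorted({m.mating_type for m in in_lineage}):
            same = {m.strain_id for m in in_lineage if m.mating_type == mt}
            other = {m.strain_id for m in in_lineage if m.mating_type != mt}
            if carriers == same and same and not (carriers & other):
                fixed = True
        labels[lineage] = "fixed_in_mating_type" if fixed else "polymorphic"
    event.fixation = labels
    return labels


def consolidate(
    calls: list[InversionCall], metadata: list[StrainSpec]
) -> tuple[list[InversionEvent], list[InversionEvent]]:
    """Cluster, filter and classify.  Returns (all events, retained events)."""
    events = cluster_events(calls)
    retained = apply_filters(events)
    for e in retained:
        classify_fixation(e, metadata)
    return events, retained


# ---------------------------------------------------------------------------
# tabular output

EVENTS_COLUMNS = (
    "ref_id", "start", "end", "size", "size_class", "n_strains", "strains",
    "evidence_types", "fixation", "n_members", "member_calls",
)


def events_to_table(events: list[InversionEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        rows.append({
            "ref_id": e.ref_id, "start": e.start, "end": e.end,
            "size": e.size, "size_class": e.size_class,
            "n_strains": len(e.strains),
            "strains": ",".join(sorted(e.strains)),
            "evidence_types": ",".join(sorted(e.evidence_types)),
            "fixation": e.fixation_label,
            "n_members": len(e.members),
            "member_calls": ";".join(
                f"{m.strain_id}:{m.start}-{m.end}" for m in sorted(
                    e.members, key=lambda c: (c.strain_id, c.start))),
        })
    return pd.DataFrame(rows, columns=list(EVENTS_COLUMNS))


def write_events(events: list[InversionEvent], path: str | Path) -> None:
    events_to_table(events).to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> list[StrainSpec]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        StrainSpec(r.strain_id, r.lineage, r.mating_type, r.evidence_type)
        for r in df.itertuples()
    ]
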