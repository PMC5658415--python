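"""End-to-end orchestration: simulate -> align -> scan -> consolidate -> enrich.

``run_all`` drives every stage from one :class:`SimulationConfig`, writes all
intermediate artifacts to an output directory and records a manifest (config
hash, seed, stage timings, file paths) so a run is fully reproducible: the
same config and seed yield identical event and enrichment tables.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .anchor_align import align_assembly, index_reference
from .consolidate import InversionEvent, consolidate, write_events
from .enrich import (EnrichmentResult, LARGE_SIZE_MIN, RegionPartition,
                     compute_enrichment, enrichment_to_table)
from .formats_io import read_fasta, write_coords
from .inv_scan import DEFAULT_MIN_FLANK, DEFAULT_TOLERANCE, scan_strain, write_calls
from .simgenome import SimulationConfig, SimulationTruth, build_truth, emit_dataset


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stage_seconds: dict[str, float] = field(default_factory=dict)
    files: dict[str, str] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)


@dataclass
class RunResult:
    manifest: RunManifest
    events: list[InversionEvent]
    retained: list[InversionEvent]
    enrichment: dict[str, EnrichmentResult]
    recall: float
    precision: float
    breakpoint_errors: list[int]


def _config_hash(config: SimulationConfig) -> str:
    from .simgenome import config_to_yaml
    import tempfile, os

    fd, tmp = tempfile.mkstemp(suffix=".yaml")
    os.close(fd)
    try:
        config_to_yaml(config, tmp)
        data = Path(tmp).read_bytes()
    finally:
        os.unlink(tmp)
    return hashlib.sha256(data).hexdigest()[:16]


def compare_to_truth(
    events: list[InversionEvent],
    truth: SimulationTruth,
    tolerance: int = DEFAULT_TOLERANCE,
) -> tuple[float, float, list[int]]:
    """Score consolidated events against planted ground truth.

    A planted interval is recovered when some event has both breakpoints
    within ``tolerance`` of it.  Returns (recall, precision, per-breakpoint
    absolute error list over matched pairs).
    """
    intervals = truth.unique_intervals()
    matched_truth = set()
    matched_events = set()
    errors: list[int] = []
    for ti, (chrom, ts, te) in enumerate(intervals):
        for ei, e in enumerate(events):
            if e.ref_id != chrom:
                continue
            if abs(e.start - ts) <= tolerance and abs(e.end - te) <= tolerance:
                matched_truth.add(ti)
                if ei not in matched_events:
                    matched_events.add(ei)
                    errors.extend([abs(e.start - ts), abs(e.end - te)])
    recall = len(matched_truth) / len(intervals) if intervals else 1.0
    precision = len(matched_events) / len(events) if events else 1.0
    return recall, precision, errors


def run_all(
    config: SimulationConfig,
    outdir: str | Path,
    tolerance: int = DEFAULT_TOLERANCE,
    min_flank: int = DEFAULT_MIN_FLANK,
) -> RunResult:
    """Run the full pipeline into ``outdir``; deterministic under the
    config's seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=_config_hash(config), seed=config.seed, version=__version__)

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                manifest.stage_seconds[name] = round(
                    time.perf_counter() - self.t0, 3)
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, exc) from exc
        return _Timer()

    with stage("simulate"):
        paths = emit_dataset(config, outdir)
        truth = build_truth(config)
        manifest.files.update({k: str(v) for k, v in paths.items()})

    with stage("align"):
        reference = read_fasta(paths["reference"])
        index = index_reference(reference)
        coords_by_strain = {}
        for s in config.strains:
            assembly = read_fasta(paths[f"assembly:{s.strain_id}"])
            rows = align_assembly(reference, assembly, index=index)
            coords_by_strain[s.strain_id] = rows
            p = outdir / f"{s.strain_id}.coords"
            write_coords(rows, p)
            manifest.files[f"coords:{s.strain_id}"] = str(p)

    with stage("scan"):
        calls = []
        for s in config.strains:
            calls.extend(scan_strain(
                coords_by_strain[s.strain_id], s.strain_id,
                evidence_type=s.evidence_type,
                tolerance=tolerance, min_flank=min_flank))
        p = outdir / "calls.tsv"
        write_calls(calls, p)
        manifest.files["calls"] = str(p)

    with stage("consolidate"):
        events, retained = consolidate(calls, config.strains)
        p = outdir / "events.tsv"
        write_events(retained, p)
        manifest.files["events"] = str(p)

    with stage("enrich"):
        rc, rs, re_ = config.suppressed_region
        partition = RegionPartition.from_lengths(
            [(rc, rs, re_)], config.chromosome_lengths)
        enrichment = {
            "all": compute_enrichment(retained, partition, min_size=0),
            "large": compute_enrichment(retained, partition, min_size=LARGE_SIZE_MIN),
        }
        p = outdir / "enrichment.tsv"
        enrichment_to_table(enrichment).to_csv(p, sep="\t", index=False)
        manifest.files["enrichment"] = str(p)

    with stage("evaluate"):
        recall, precision, errors = compare_to_truth(retained, truth, tolerance)

    manifest.write(outdir / "manifest.json")
    with open(outdir / "summary.tsv", "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"n_events_all\t{len(events)}\n")
        fh.write(f"n_events_retained\t{len(retained)}\n")
        fh.write(f"recall\t{recall}\n")
        fh.write(f"precision\t{precision}\n")
        fh.write(f"fold_all\t{enrichment['all'].fold}\n")
        fh.write(f"p_value_all\t{enrichment['all'].p_value}\n")
        fh.write(f"fold_large\t{enrichment['large'].fold}\n")
        fh.write(f"p_value_large\t{enrichment['large'].p_value}\n")
    return RunResult(
        manifest=manifest, events=events, retained=retained,
        enrichment=enrichment, recall=recall, precision=precision,
        breakpoint_errors=errors)
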