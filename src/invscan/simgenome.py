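"""Synthetic genomes with planted inversions and fragmented assemblies.

This module generates the inputs the rest of the pipeline consumes: a random
reference genome, per-strain genomes that differ from it by planted
inversions (reverse-complemented blocks) and SNP divergence, and fragmented
contig sets emulating short-read de novo assemblies.  Every planted
rearrangement is recorded as ground truth so detection can be scored.

The emulation targets are fungal-genome scale: highly fragmented assemblies
(contig N50 on the order of 170 kbp), a multi-megabase region of suppressed
recombination on one chromosome, and inversions from ~1 kbp up to several
Mbp.  The default desk-scale configuration is a single 2 Mbp chromosome with
a 0.8 Mbp suppressed region, which exercises every code path in seconds; a
full-scale 38.4 Mbp / 8.32 Mbp configuration is provided for larger runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ._rng import fork_rng
from .formats_io import write_bed, write_fasta

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGTRYKMBDHVN", "TGCAYRMKVHDBN")


class ConfigError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass(frozen=True)
class StrainSpec:
    strain_id: str
    lineage: str
    mating_type: str
    evidence_type: str


@dataclass(frozen=True)
class InversionSpec:
    """A planted inversion: 1-based inclusive interval plus carrier strains."""

    chrom: str
    start: int
    end: int
    carriers: frozenset[str]

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass
class SimulationConfig:
    seed: int
    chromosome_lengths: dict[str, int]
    suppressed_region: tuple[str, int, int]  # chrom, start, end (1-based incl.)
    strains: list[StrainSpec]
    inversions: list[InversionSpec]
    snp_rate: float = 0.002
    target_n50: int = 172_026
    min_contig_length: int = 500
    breakpoint_fragmentation_prob: float = 0.5
    length_sigma: float = 0.5  # lognormal shape of contig lengths

    def __post_init__(self) -> None:
        for chrom, length in self.chromosome_lengths.items():
            if length <= 0:
                raise ConfigError(f"chromosome {chrom} has non-positive length")
        rc, rs, re_ = self.suppressed_region
        if rc not in self.chromosome_lengths:
            raise ConfigError(f"suppressed region chromosome {rc!r} unknown")
        if not 1 <= rs <= re_ <= self.chromosome_lengths[rc]:
            raise ConfigError("suppressed region outside chromosome bounds")
        if self.target_n50 < self.min_contig_length:
            raise ConfigError("target_n50 < min_contig_length")
        if not 0.0 <= self.breakpoint_fragmentation_prob <= 1.0:
            raise ConfigError("breakpoint_fragmentation_prob outside [0, 1]")
        seen_strains = {s.strain_id for s in self.strains}
        for inv in self.inversions:
            if inv.chrom not in self.chromosome_lengths:
                raise ConfigError(f"inversion chromosome {inv.chrom!r} unknown")
            if not 1 <= inv.start <= inv.end <= self.chromosome_lengths[inv.chrom]:
                raise ConfigError(
                    f"inversion [{inv.start}, {inv.end}] outside {inv.chrom}")
            unknown = inv.carriers - seen_strains
            if unknown:
                raise ConfigError(f"inversion carriers {sorted(unknown)} unknown")
        # overlap within one strain is a configuration error (polymorphic
        # overlapping clusters are represented across strains instead)
        for strain in self.strains:
            mine = sorted(
                (i for i in self.inversions if strain.strain_id in i.carriers),
                key=lambda i: (i.chrom, i.start))
            for a, b in zip(mine, mine[1:]):
                if a.chrom == b.chrom and b.start <= a.end:
                    raise ConfigError(
                        f"overlapping inversions for strain {strain.strain_id}: "
                        f"[{a.start},{a.end}] and [{b.start},{b.end}]")

    def inversions_for(self, strain_id: str) -> list[InversionSpec]:
        return sorted(
            (i for i in self.inversions if strain_id in i.carriers),
            key=lambda i: (i.chrom, i.start))


@dataclass(frozen=True)
class TruthRecord:
    strain_id: str
    chrom: str
    start: int
    end: int
    in_suppressed_region: bool

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass
class SimulationTruth:
    """Planted-inversion ground truth, one record per (strain, interval)."""

    records: list[TruthRecord] = field(default_factory=list)

    def for_strain(self, strain_id: str) -> list[TruthRecord]:
        return [r for r in self.records if r.strain_id == strain_id]

    def unique_intervals(self) -> list[tuple[str, int, int]]:
        """Distinct planted intervals across strains, sorted."""
        return sorted({(r.chrom, r.start, r.end) for r in self.records})


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def invert_segment(seq: str, start: int, end: int) -> str:
    """Reverse-complement the 1-based inclusive block [start, end] in place."""
    return seq[: start - 1] + reverse_complement(seq[start - 1 : end]) + seq[end:]


def generate_reference(config: SimulationConfig) -> dict[str, str]:
    """Generate a uniform-composition random reference genome."""
    for chrom, length in config.chromosome_lengths.items():
        if length < 10_000:
            raise ConfigError(f"chromosome {chrom} shorter than 10 kbp")
    genome = {}
    for chrom, length in config.chromosome_lengths.items():
        rng = fork_rng(config.seed, "reference", chrom)
        genome[chrom] = rng.choice(_BASES, size=length).tobytes().decode()
    return genome


def plant_inversions(
    reference: dict[str, str], config: SimulationConfig, strain_id: str
) -> dict[str, str]:
    """Derive a strain genome: reverse-complement each planted interval, then
    apply substitutions at ``snp_rate`` per base."""
    genome = dict(reference)
    for inv in config.inversions_for(strain_id):
        genome[inv.chrom] = invert_segment(genome[inv.chrom], inv.start, inv.end)
    if config.snp_rate > 0:
        for chrom in genome:
            rng = fork_rng(config.seed, "snp", strain_id, chrom)
            seq = np.frombuffer(genome[chrom].encode(), dtype="S1").copy()
            n_snp = rng.binomial(len(seq), config.snp_rate)
            if n_snp == 0:
                continue
            pos = rng.choice(len(seq), size=n_snp, replace=False)
            # substitute with a base different from the current one
            shift = rng.integers(1, 4, size=n_snp)
            idx = np.searchsorted(_BASES, seq[pos])
            seq[pos] = _BASES[(idx + shift) % 4]
            genome[chrom] = seq.tobytes().decode()
    return genome


def _draw_contig_lengths(
    total: int, config: SimulationConfig, rng: np.random.Generator
) -> list[int]:
    """Lengths of consecutive contig pieces tiling a region of ``total`` bp.

    Drawn from a lognormal whose length-weighted median equals target_n50
    (mu = ln(N50) - sigma^2), reproducing a heavy-tailed contig profile.
    """
    mu = np.log(config.target_n50) - config.length_sigma**2
    out: list[int] = []
    pos = 0
    while pos < total:
        ln = int(rng.lognormal(mu, config.length_sigma))
        ln = max(1, min(ln, total - pos))
        out.append(ln)
        pos += ln
    return out


def fragment_assembly(
    strain_genome: dict[str, str],
    config: SimulationConfig,
    strain_id: str,
) -> dict[str, str]:
    """Cut a strain genome into contigs emulating a fragmented assembly.

    Contigs tile each chromosome without overlap.  Each planted inversion
    breakpoint additionally becomes a contig boundary with probability
    ``breakpoint_fragmentation_prob``.  Pieces shorter than
    ``min_contig_length`` are dropped, and the surviving contigs are emitted
    in a shuffled order with opaque names.
    """
    for chrom, seq in strain_genome.items():
        if config.target_n50 >= len(seq):
            raise ConfigError(
                f"target_n50 {config.target_n50} >= length of {chrom}")
    rng = fork_rng(config.seed, "fragment", strain_id)
    contigs: list[str] = []
    for chrom in strain_genome:
        seq = strain_genome[chrom]
        length = len(seq)
        # forced cuts at planted breakpoints (positions after which a new
        # contig starts, in 1-based coordinates: cut after s-1 and after e)
        forced: set[int] = set()
        for inv in config.inversions_for(strain_id):
            if inv.chrom != chrom:
                continue
            for cut in (inv.start - 1, inv.end):
                if 0 < cut < length and rng.random() < config.breakpoint_fragmentation_prob:
                    forced.add(cut)
        bounds = [0] + sorted(forced) + [length]
        for lo, hi in zip(bounds, bounds[1:]):
            pos = lo
            for ln in _draw_contig_lengths(hi - lo, config, rng):
                contigs.append(seq[pos : pos + ln])
                pos += ln
    contigs = [c for c in contigs if len(c) >= config.min_contig_length]
    order = rng.permutation(len(contigs))
    width = max(5, len(str(len(contigs))))
    return {
        f"{strain_id}_ctg{str(i + 1).zfill(width)}": contigs[j]
        for i, j in enumerate(order)
    }


def _midpoint_in_region(
    start: int, end: int, region: tuple[str, int, int], chrom: str
) -> bool:
    rc, rs, re_ = region
    mid = (start + end) // 2
    return chrom == rc and rs <= mid <= re_


def build_truth(config: SimulationConfig) -> SimulationTruth:
    """Ground-truth records for every (strain, planted interval) pair."""
    recs = []
    for strain in config.strains:
        for inv in config.inversions_for(strain.strain_id):
            recs.append(TruthRecord(
                strain_id=strain.strain_id,
                chrom=inv.chrom, start=inv.start, end=inv.end,
                in_suppressed_region=_midpoint_in_region(
                    inv.start, inv.end, config.suppressed_region, inv.chrom),
            ))
    return SimulationTruth(records=recs)


def emit_dataset(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the full synthetic dataset to ``outdir``.

    Files: ``reference.fa``, ``assemblies/<strain>.fa``, ``truth.bed``
    (0-based half-open, name column = strain id), ``metadata.tsv``,
    ``region.bed`` and ``lengths.tsv``.  Byte-identical across runs with the
    same config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "assemblies").mkdir(exist_ok=True)
    paths: dict[str, Path] = {}

    reference = generate_reference(config)
    paths["reference"] = outdir / "reference.fa"
    write_fasta(reference, paths["reference"])

    for strain in config.strains:
        genome = plant_inversions(reference, config, strain.strain_id)
        assembly = fragment_assembly(genome, config, strain.strain_id)
        p = outdir / "assemblies" / f"{strain.strain_id}.fa"
        write_fasta(assembly, p)
        paths[f"assembly:{strain.strain_id}"] = p

    truth = build_truth(config)
    paths["truth"] = outdir / "truth.bed"
    write_bed(
        [(r.chrom, r.start, r.end, (r.strain_id,)) for r in truth.records],
        paths["truth"])

    paths["metadata"] = outdir / "metadata.tsv"
    with open(paths["metadata"], "w") as fh:
        fh.write("strain_id\tlineage\tmating_type\tevidence_type\n")
        for s in config.strains:
            fh.write(f"{s.strain_id}\t{s.lineage}\t{s.mating_type}\t{s.evidence_type}\n")

    rc, rs, re_ = config.suppressed_region
    paths["region"] = outdir / "region.bed"
    write_bed([(rc, rs, re_, ("suppressed_region",))], paths["region"])

    paths["lengths"] = outdir / "lengths.tsv"
    with open(paths["lengths"], "w") as fh:
        fh.write("chrom\tlength\n")
        for chrom, length in config.chromosome_lengths.items():
            fh.write(f"{chrom}\t{length}\n")
    return paths


# ---------------------------------------------------------------------------
# stock configurations


def default_desk_config(seed: int = 1, snp_rate: float = 0.002) -> SimulationConfig:
    """Desk-scale study configuration: one 2 Mbp chromosome, 0.8 Mbp
    suppressed region, six planted inversions (5 kbp - 500 kbp), four strains
    in two lineages with mixed evidence types.

    The two large (>100 kbp) inversions sit inside the suppressed region;
    the four smaller ones sit outside, mirroring the size asymmetry the
    pipeline is designed to quantify.  Every inversion is carried by two
    strains with distinct evidence tags so the cross-strain and
    two-evidence inclusion filters retain it.
    """
    strains = [
        StrainSpec("s1A", "L1", "A", "illumina"),
        StrainSpec("s1a", "L1", "a", "pacbio"),
        StrainSpec("s2A", "L2", "A", "illumina"),
        StrainSpec("s2a", "L2", "a", "pcr_sanger"),
    ]
    both_l1 = frozenset({"s1A", "s1a"})
    both_l2 = frozenset({"s2A", "s2a"})
    inversions = [
        InversionSpec("chr1", 50_001, 55_000, both_l1),       # 5 kbp, outside
        InversionSpec("chr1", 150_001, 162_000, both_l2),     # 12 kbp, outside
        InversionSpec("chr1", 300_001, 340_000, both_l1),     # 40 kbp, outside
        InversionSpec("chr1", 450_001, 540_000, both_l2),     # 90 kbp, outside
        InversionSpec("chr1", 650_001, 1_150_000, both_l1),   # 500 kbp, inside
        InversionSpec("chr1", 1_160_001, 1_360_000, both_l2), # 200 kbp, inside
    ]
    return SimulationConfig(
        seed=seed,
        chromosome_lengths={"chr1": 2_000_000},
        suppressed_region=("chr1", 600_001, 1_400_000),
        strains=strains,
        inversions=inversions,
        snp_rate=snp_rate,
    )


def paper_scale_config(seed: int = 1) -> SimulationConfig:
    """Full-scale configuration: a 38,417,195 bp genome over seven
    chromosomes with an 8,320,000 bp suppressed region on the mating-type
    chromosome.  Optional; desk scale covers all code paths far faster."""
    strains = [
        StrainSpec("s1A", "L1", "A", "illumina"),
        StrainSpec("s1a", "L1", "a", "pacbio"),
        StrainSpec("s2A", "L2", "A", "illumina"),
        StrainSpec("s2a", "L2", "a", "pcr_sanger"),
    ]
    both_l1 = frozenset({"s1A", "s1a"})
    both_l2 = frozenset({"s2A", "s2a"})
    lengths = {
        "chr1": 10_100_000, "chr2": 6_500_000, "chr3": 5_800_000,
        "chr4": 5_000_000, "chr5": 4_500_000, "chr6": 3_600_000,
        "chr7": 2_917_195,
    }
    inversions = [
        InversionSpec("chr1", 2_000_001, 3_900_000, both_l1),  # 1.9 Mbp, inside
        InversionSpec("chr1", 5_000_001, 5_260_000, both_l2),  # 260 kbp, inside
        InversionSpec("chr2", 1_000_001, 1_040_000, both_l1),  # 40 kbp, outside
        InversionSpec("chr5", 2_000_001, 2_012_000, both_l2),  # 12 kbp, outside
    ]
    return SimulationConfig(
        seed=seed,
        chromosome_lengths=lengths,
        suppressed_region=("chr1", 1_000_001, 9_320_000),
        strains=strains,
        inversions=inversions,
    )


# ---------------------------------------------------------------------------
# YAML config round-trip


def config_to_yaml(config: SimulationConfig, path: str | Path) -> None:
    d = dataclasses.asdict(config)
    d["strains"] = [list(dataclasses.astuple(s)) for s in config.strains]
    d["inversions"] = [
        [i.chrom, i.start, i.end, sorted(i.carriers)] for i in config.inversions]
    d["suppressed_region"] = list(config.suppressed_region)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def config_from_yaml(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["strains"] = [StrainSpec(*s) for s in d["strains"]]
    d["inversions"] = [
        InversionSpec(c, s, e, frozenset(carr)) for c, s, e, carr in d["inversions"]]
    d["suppressed_region"] = tuple(d["suppressed_region"])
    return SimulationConfig(**d)
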