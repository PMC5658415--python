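import numpy as np
import pytest

from invscan.formats_io import read_bed, read_fasta
from invscan.simgenome import (ConfigError, InversionSpec, SimulationConfig,
                               StrainSpec, build_truth, default_desk_config,
                               emit_dataset, fragment_assembly,
                               generate_reference, invert_segment,
                               plant_inversions, reverse_complement)


def small_config(seed=1, **kw):
    defaults = dict(
        seed=seed,
        chromosome_lengths={"chr1": 50_000},
        suppressed_region=("chr1", 10_001, 30_000),
        strains=[StrainSpec("sA", "L1", "A", "illumina"),
                 StrainSpec("sa", "L1", "a", "pacbio")],
        inversions=[InversionSpec("chr1", 20_001, 26_000,
                                  frozenset({"sA", "sa"}))],
        snp_rate=0.0,
        target_n50=5_000,
        min_contig_length=200,
        breakpoint_fragmentation_prob=0.0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestReference:
    def test_length_alphabet_and_determinism(self):
        cfg = small_config(seed=1)
        ref = generate_reference(cfg)
        assert len(ref["chr1"]) == 50_000
        assert set(ref["chr1"]) <= set("ACGT")
        assert generate_reference(cfg) == ref

    def test_different_seeds_differ(self):
        r1 = generate_reference(small_config(seed=1))
        r2 = generate_reference(small_config(seed=2))
        assert r1["chr1"] != r2["chr1"]

    def test_too_short_chromosome_rejected(self):
        cfg = small_config(chromosome_lengths={"chr1": 5_000},
                           suppressed_region=("chr1", 1, 2_000),
                           inversions=[], target_n50=1_000)
        with pytest.raises(ConfigError, match="10 kbp"):
            generate_reference(cfg)


class TestPlanting:
    def test_planted_block_is_reverse_complement(self):
        cfg = small_config()
        ref = generate_reference(cfg)
        strain = plant_inversions(ref, cfg, "sA")
        s, e = 20_001, 26_000
        assert strain["chr1"][s - 1:e] == reverse_complement(ref["chr1"][s - 1:e])
        assert strain["chr1"][:s - 1] == ref["chr1"][:s - 1]
        assert strain["chr1"][e:] == ref["chr1"][e:]

    def test_no_inversions_identity(self):
        cfg = small_config(inversions=[])
        ref = generate_reference(cfg)
        assert plant_inversions(ref, cfg, "sA") == ref

    def test_involution(self):
        cfg = small_config()
        ref = generate_reference(cfg)
        seq = ref["chr1"]
        assert invert_segment(invert_segment(seq, 101, 400), 101, 400) == seq

    def test_snp_count_binomial(self):
        cfg = small_config(chromosome_lengths={"chr1": 100_000},
                           suppressed_region=("chr1", 1, 40_000),
                           inversions=[], snp_rate=0.005)
        ref = generate_reference(cfg)
        strain = plant_inversions(ref, cfg, "sA")
        mismatches = sum(a != b for a, b in zip(ref["chr1"], strain["chr1"]))
        # Binomial(100000, 0.005): mean 500, sd ~22.3
        assert abs(mismatches - 500) <= 3 * np.sqrt(100_000 * 0.005 * 0.995)

    def test_overlapping_inversions_rejected(self):
        with pytest.raises(ConfigError, match="overlapping"):
            small_config(inversions=[
                InversionSpec("chr1", 20_001, 26_000, frozenset({"sA"})),
                InversionSpec("chr1", 25_000, 28_000, frozenset({"sA"})),
            ])

    def test_out_of_bounds_inversion_rejected(self):
        with pytest.raises(ConfigError, match="outside"):
            small_config(inversions=[
                InversionSpec("chr1", 40_001, 60_000, frozenset({"sA"}))])


class TestFragmentation:
    def test_tiling_reconstructs_genome(self):
        # without the min-length drop, contigs concatenated in genomic
        # order reconstruct the strain genome exactly
        cfg = small_config(min_contig_length=1)
        ref = generate_reference(cfg)
        strain = plant_inversions(ref, cfg, "sA")
        contigs = fragment_assembly(strain, cfg, "sA")
        assert sum(len(c) for c in contigs.values()) == 50_000
        # order was shuffled; greedy re-assembly by matching prefixes
        remaining = dict(contigs)
        rebuilt = ""
        while remaining:
            for name, seq in list(remaining.items()):
                if strain["chr1"].startswith(rebuilt + seq):
                    rebuilt += seq
                    del remaining[name]
                    break
            else:
                pytest.fail("contigs do not tile the strain genome")
        assert rebuilt == strain["chr1"]

    def test_short_contigs_dropped(self):
        cfg = small_config(min_contig_length=2_000)
        ref = generate_reference(cfg)
        contigs = fragment_assembly(plant_inversions(ref, cfg, "sA"), cfg, "sA")
        assert all(len(c) >= 2_000 for c in contigs.values())

    def test_forced_breakpoint_boundaries(self):
        cfg = small_config(breakpoint_fragmentation_prob=1.0, min_contig_length=1)
        ref = generate_reference(cfg)
        strain = plant_inversions(ref, cfg, "sA")
        contigs = fragment_assembly(strain, cfg, "sA")
        # with every breakpoint a contig boundary, the inverted block
        # [20001, 26000] is tiled exactly by whole contigs
        block = strain["chr1"][20_000:26_000]
        lengths = []
        pos = 0
        found = True
        while pos < len(block):
            for seq in contigs.values():
                if block.startswith(seq, pos):
                    lengths.append(len(seq))
                    pos += len(seq)
                    break
            else:
                found = False
                break
        assert found and sum(lengths) == 6_000

    def test_n50_within_25pct_of_target(self):
        # 10 Mbp genome, emulation target N50 = 172,026 bp
        cfg = SimulationConfig(
            seed=5, chromosome_lengths={"chr1": 10_000_000},
            suppressed_region=("chr1", 1, 1_000_000),
            strains=[StrainSpec("s", "L1", "A", "illumina")],
            inversions=[], snp_rate=0.0)
        ref = generate_reference(cfg)
        contigs = fragment_assembly(ref, cfg, "s")
        lengths = np.sort([len(c) for c in contigs.values()])[::-1]
        csum = np.cumsum(lengths)
        n50 = lengths[np.searchsorted(csum, csum[-1] / 2)]
        assert 129_020 <= n50 <= 215_032

    def test_invalid_n50_configuration(self):
        with pytest.raises(ConfigError):
            small_config(target_n50=100, min_contig_length=200)


class TestTruthAndDataset:
    def test_truth_records_and_region_flag(self):
        cfg = small_config()
        truth = build_truth(cfg)
        assert len(truth.records) == 2  # two carriers of one inversion
        r = truth.records[0]
        assert (r.start, r.end, r.size) == (20_001, 26_000, 6_000)
        assert r.in_suppressed_region  # midpoint 23000 in [10001, 30000]

    def test_emit_dataset_files_and_coordinates(self, tmp_path):
        cfg = small_config()
        paths = emit_dataset(cfg, tmp_path)
        assert read_fasta(paths["reference"]).keys() == {"chr1"}
        assert len(list((tmp_path / "assemblies").glob("*.fa"))) == 2
        bed = read_bed(paths["truth"])
        # BED half-open record maps back to the 1-based planted interval
        assert bed[0][:3] == ("chr1", 20_001, 26_000)
        meta = paths["metadata"].read_text().splitlines()
        assert meta[0] == "strain_id\tlineage\tmating_type\tevidence_type"
        assert len(meta) == 3

    def test_emit_dataset_byte_identical_across_runs(self, tmp_path):
        cfg = small_config()
        p1 = emit_dataset(cfg, tmp_path / "run1")
        p2 = emit_dataset(cfg, tmp_path / "run2")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key


def test_desk_config_is_valid_and_deterministic():
    cfg = default_desk_config(seed=3)
    assert cfg.chromosome_lengths == {"chr1": 2_000_000}
    region_len = cfg.suppressed_region[2] - cfg.suppressed_region[1] + 1
    assert region_len == 800_000
    assert len(cfg.inversions) == 6
    ref = generate_reference(cfg)
    assert generate_reference(cfg)["chr1"] == ref["chr1"]
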