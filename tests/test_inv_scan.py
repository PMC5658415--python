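import numpy as np
import pytest

from invscan.anchor_align import align_assembly, index_reference
from invscan.formats_io import CoordsRow
from invscan.inv_scan import (detect_contig_pair, detect_intra_contig,
                              scan_strain, screen_repeats)
from invscan.pipeline import compare_to_truth
from invscan.consolidate import consolidate
from invscan.simgenome import (InversionSpec, SimulationConfig, StrainSpec,
                               build_truth, fragment_assembly,
                               generate_reference, plant_inversions)

from oracles import brute_force_scan


def row(rs, re_, qs, qe, ref="chr1", qry="ctg1", pct=100.0):
    return CoordsRow(rs, re_, qs, qe, re_ - rs + 1, abs(qe - qs) + 1,
                     pct, ref, qry)


class TestIntraContig:
    def test_reverse_run_flanked_by_forwards(self):
        rows = [row(1, 5000, 1, 5000),
                row(5001, 8000, 8000, 5001),   # reverse
                row(8001, 12_000, 8001, 12_000)]
        calls, unpaired = detect_intra_contig(rows, "s")
        (c,) = calls
        assert (c.start, c.end, c.size) == (5001, 8000, 3000)
        assert c.status == "paired"
        assert unpaired == []

    def test_all_forward_no_calls(self):
        rows = [row(1, 5000, 1, 5000), row(5001, 9000, 5001, 9000)]
        assert detect_intra_contig(rows, "s") == ([], [])

    def test_reverse_at_contig_end_gives_unpaired_signal(self):
        rows = [row(1, 5000, 1, 5000), row(5001, 8000, 8000, 5001)]
        calls, unpaired = detect_intra_contig(rows, "s")
        assert calls == []
        (sig,) = unpaired
        assert sig.ref_pos == 5000 and sig.pattern.value == "F|R"


class TestContigPair:
    def test_published_adjacency_pattern(self):
        # contig A spans the left breakpoint, contig B the right one:
        # A: forward ending 4000, reverse ending 6000
        # B: reverse starting 4001, forward starting 6001
        rows = [row(1, 4000, 1, 4000, qry="A"),
                row(4001, 5000, 5500, 4501, qry="B"),
                row(5001, 6000, 5500, 4501, qry="A"),
                row(6001, 9000, 5501, 8500, qry="B")]
        calls, unpaired = detect_contig_pair(rows, "s")
        (c,) = calls
        assert (c.start, c.end, c.size) == (4001, 6000, 2000)
        assert {bp.mode.value for bp in c.breakpoints} == {"contig_pair"}

    def test_abutting_forward_contigs_no_calls(self):
        rows = [row(1, 4000, 1, 4000, qry="A"), row(4001, 9000, 1, 5000, qry="B")]
        assert detect_contig_pair(rows, "s") == ([], [])

    def test_second_junction_missing_yields_single_unpaired(self):
        # pattern (i) present at 4000; the reverse run never returns to a
        # forward segment (repeat ate the second junction)
        rows = [row(1, 4000, 1, 4000, qry="A"),
                row(4001, 6000, 6500, 4501, qry="B")]
        calls, unpaired = detect_contig_pair(rows, "s")
        assert calls == []
        assert len(unpaired) == 1 and unpaired[0].ref_pos == 4000


class TestScreenRepeats:
    def setup_rows(self, dup_fraction):
        rows = [row(1, 4000, 1, 4000, qry="A"),
                row(5001, 8000, 8000, 5001, qry="A"),
                row(8001, 12_000, 8001, 12_000, qry="A")]
        if dup_fraction:
            # left flank [1,4000] (qry 1..4000) also aligns elsewhere
            ln = int(4000 * dup_fraction)
            rows.append(row(20_001, 20_000 + ln, 1, ln, qry="A"))
        return rows

    def run(self, dup_fraction):
        rows = self.setup_rows(dup_fraction)
        calls, unpaired = detect_intra_contig(rows, "s")
        return screen_repeats(calls, unpaired, rows)

    def test_unique_flanks_retained(self):
        calls, _ = self.run(0)
        assert len(calls) == 1

    def test_duplicated_flank_demotes_call(self):
        calls, unpaired = self.run(0.95)
        assert calls == []
        # the signal whose flank was unique survives as unpaired
        assert any(s.ref_pos == 8000 for s in unpaired)

    def test_below_threshold_secondary_alignment_retained(self):
        calls, _ = self.run(0.5)
        assert len(calls) == 1


def simulate_and_scan(cfg):
    ref = generate_reference(cfg)
    idx = index_reference(ref)
    calls = []
    for s in cfg.strains:
        genome = plant_inversions(ref, cfg, s.strain_id)
        assembly = fragment_assembly(genome, cfg, s.strain_id)
        rows = align_assembly(ref, assembly, index=idx)
        calls.extend(scan_strain(rows, s.strain_id, evidence_type=s.evidence_type))
    return calls


def two_strain_config(seed, length, inversions, snp_rate=0.0, frag_prob=0.5,
                      n50=60_000):
    strains = [StrainSpec("sA", "L1", "A", "illumina"),
               StrainSpec("sa", "L1", "a", "pacbio")]
    carriers = frozenset({"sA", "sa"})
    return SimulationConfig(
        seed=seed, chromosome_lengths={"chr1": length},
        suppressed_region=("chr1", 1, length // 3),
        strains=strains,
        inversions=[InversionSpec("chr1", s, e, carriers) for s, e in inversions],
        snp_rate=snp_rate, target_n50=n50, min_contig_length=500,
        breakpoint_fragmentation_prob=frag_prob)


class TestScanStrain:
    @pytest.mark.parametrize("frag_prob", [0.0, 1.0])
    def test_perfect_recovery_snp_free(self, frag_prob):
        """SNP-free, repeat-free, >=5 kbp inversions with >=5 kbp flanks:
        every planted inversion recovered exactly, nothing spurious."""
        cfg = two_strain_config(
            seed=11, length=300_000,
            inversions=[(40_001, 60_000), (120_001, 200_000), (250_001, 258_000)],
            frag_prob=frag_prob)
        calls = simulate_and_scan(cfg)
        events, retained = consolidate(calls, cfg.strains)
        recall, precision, errors = compare_to_truth(retained, build_truth(cfg))
        assert recall == 1.0 and precision == 1.0

    def test_collinear_strain_empty(self):
        cfg = two_strain_config(seed=12, length=100_000, inversions=[])
        calls = simulate_and_scan(cfg)
        assert [c for c in calls if c.status == "paired"] == []

    def test_deterministic(self):
        cfg = two_strain_config(seed=13, length=100_000,
                                inversions=[(30_001, 50_000)])
        assert simulate_and_scan(cfg) == simulate_and_scan(cfg)

    def test_calls_within_chromosome_bounds(self):
        cfg = two_strain_config(seed=14, length=200_000,
                                inversions=[(10_001, 40_000), (150_001, 190_000)],
                                snp_rate=0.002)
        for c in simulate_and_scan(cfg):
            if c.status == "paired":
                assert 1 <= c.start < c.end <= 200_000

    def test_robust_recovery_with_snps(self):
        """snp_rate=0.005, seeds 1-20: recall >= 0.9 for inversions >= 50 kbp."""
        recovered = total = 0
        for seed in range(1, 21):
            cfg = two_strain_config(
                seed=seed, length=600_000,
                inversions=[(100_001, 160_000), (300_001, 400_000)],
                snp_rate=0.005, frag_prob=0.5)
            calls = simulate_and_scan(cfg)
            _, retained = consolidate(calls, cfg.strains)
            truth = build_truth(cfg)
            recall, _, _ = compare_to_truth(retained, truth)
            total += 2
            recovered += round(recall * 2)
        assert recovered / total >= 0.9


class TestOracleEquivalence:
    def test_scanner_matches_brute_force_on_small_genomes(self):
        """On 100 kbp simulated genomes, the scanner's paired calls equal a
        brute-force enumeration over segment pairs with per-base coverage."""
        rng = np.random.default_rng(2024)
        for rep in range(10):
            s1 = int(rng.integers(15_000, 30_000))
            e1 = s1 + int(rng.integers(4_000, 15_000))
            s2 = int(rng.integers(55_000, 70_000))
            e2 = s2 + int(rng.integers(4_000, 20_000))
            cfg = two_strain_config(
                seed=3000 + rep, length=100_000,
                inversions=[(s1, e1), (s2, e2)],
                snp_rate=0.002, frag_prob=float(rng.random()), n50=25_000)
            ref = generate_reference(cfg)
            idx = index_reference(ref)
            for s in cfg.strains:
                genome = plant_inversions(ref, cfg, s.strain_id)
                assembly = fragment_assembly(genome, cfg, s.strain_id)
                rows = align_assembly(ref, assembly, index=idx)
                got = {(c.ref_id, c.start, c.end)
                       for c in scan_strain(rows, s.strain_id)
                       if c.status == "paired"}
                expected = brute_force_scan(rows)
                assert got == expected, f"rep {rep} strain {s.strain_id}"
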