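from collections import Counter, defaultdict

import pytest

from mipscreen.panel import revcomp
from mipscreen.process import (
    AssignedRead,
    ProbeAssigner,
    coverage_report,
    dedup_consensus,
    extract_umi,
    process_read_pairs,
    trim_arms,
)
from mipscreen.simulate import PlantedVariant, ReadPair, SimParams, simulate_sample


class TestExtractUmi:
    def test_prefix_extraction(self):
        pair = ReadPair("r", "ACGT", "ACGTACGTTTTTCCCC")
        umi, trimmed = extract_umi(pair, 8)
        assert umi == "ACGTACGT"
        assert trimmed.read2 == "TTTTCCCC"

    def test_short_read_skipped(self):
        assert extract_umi(ReadPair("r", "ACGT", "ACGTAC"), 8) is None

    def test_extracted_umi_matches_truth(self, small_panel, reference):
        params = SimParams(seed=21, mean_unique_molecules_per_probe=20, error_rate=0.0)
        reads, truth = simulate_sample(small_panel, reference, [], params)
        truth_umi = dict(zip(truth.reads.read_id, truth.reads.umi))
        for rp in reads:
            umi, _ = extract_umi(rp, 8)
            assert umi == truth_umi[rp.name]


class TestAssignment:
    def test_simulated_reads_assign_to_truth_probe(self, small_panel, reference):
        params = SimParams(seed=22, mean_unique_molecules_per_probe=15, error_rate=0.0)
        reads, truth = simulate_sample(small_panel, reference, [], params)
        truth_probe = dict(zip(truth.reads.read_id, truth.reads.probe_id))
        assigner = ProbeAssigner(small_panel.probes)
        for rp in reads:
            _, trimmed = extract_umi(rp, 8)
            assert assigner.assign(trimmed.read1, trimmed.read2) == truth_probe[rp.name]

    def test_three_mismatches_unassigned(self, small_panel):
        probe = small_panel.probes[0]
        read1 = list(probe.ext_arm_seq + "A" * 110)
        for i in range(3):
            read1[i] = "A" if read1[i] != "A" else "C"
        assigner = ProbeAssigner(small_panel.probes, max_mismatches=2)
        assert assigner.assign("".join(read1), probe.lig_arm_seq + "A" * 100) is None

    def test_equal_mismatch_tie_unassigned(self):
        from mipscreen.panel import Probe

        def mk(pid, ext, lig):
            return Probe(
                id=pid, contig="chr1", strand="+",
                ext_start=0, ext_end=len(ext), ext_arm_seq=ext,
                lig_start=200, lig_end=200 + len(lig), lig_arm_seq=lig,
                gap_start=21, gap_end=131, gapfill_seq="A" * 110,
            )

        a = mk("a", "A" * 21, "C" * 24)
        b = mk("b", "A" * 20 + "G", "C" * 24)
        assigner = ProbeAssigner([a, b], max_mismatches=2)
        # read arm one mismatch away from both probes -> ambiguous
        read_arm = "A" * 20 + "T"
        assert assigner.assign(read_arm + "G" * 110, "C" * 24 + "G" * 80) is None


class TestTrimArms:
    def test_fixed_offset_arithmetic(self, small_panel):
        probe = small_panel.probes[0]
        target = probe.gapfill_seq if probe.strand == "+" else revcomp(probe.gapfill_seq)
        read1 = probe.ext_arm_seq + target + revcomp(probe.lig_arm_seq)
        out = trim_arms(read1[:150], probe)
        assert out == probe.gapfill_seq
        assert len(out) == 110

    def test_variant_in_arm_never_reaches_pileup(self, small_panel, reference):
        """A substitution planted inside an arm-annealing interval is erased
        by trimming and absent from all consensus fragments."""
        probe = next(p for p in small_panel.probes if p.strand == "+")
        arm_pos = probe.ext_start + 5  # inside the extension arm, not the gap-fill
        ref_base = reference[probe.contig][arm_pos]
        alt = "A" if ref_base != "A" else "G"
        v = PlantedVariant(probe.contig, arm_pos, ref_base, alt, "hom", "snv")
        params = SimParams(seed=23, mean_unique_molecules_per_probe=30, error_rate=0.0)
        reads, _ = simulate_sample(small_panel, reference, [v], params)
        assigned, _ = process_read_pairs(reads, small_panel.probes)
        frags = dedup_consensus(assigned, small_panel.probes)
        for f in frags:
            if f.probe_id == probe.id:
                assert f.consensus == probe.gapfill_seq

    def test_read_fully_inside_gapfill_unchanged(self, small_panel):
        probe = next(p for p in small_panel.probes if p.strand == "+")
        read1 = probe.ext_arm_seq + probe.gapfill_seq[:80]
        assert trim_arms(read1, probe) == probe.gapfill_seq[:80]


def _brute_force_dedup(records, probes):
    """Independent oracle: hash-group by (probe, UMI), then per position take
    the plurality base, breaking ties by summed quality and then by the
    reference base — written naively, without the implementation's machinery."""
    ref_of = {p.id: p.gapfill_seq for p in probes}
    groups = defaultdict(list)
    for r in records:
        groups[(r.probe_id, r.umi)].append(r)
    out = {}
    for key, members in groups.items():
        lengths = Counter(len(m.target_seq) for m in members)
        modal = max(lengths, key=lambda L: (lengths[L], -L))
        seqs_m = [m for m in members if len(m.target_seq) == modal]
        ref = ref_of[key[0]]
        cons = []
        for i in range(modal):
            votes = Counter(m.target_seq[i] for m in seqs_m)
            qual = Counter()
            for m in seqs_m:
                if m.qual and i < len(m.qual):
                    qual[m.target_seq[i]] += ord(m.qual[i])
            top = max(votes.values())
            tied = [b for b in sorted(votes) if votes[b] == top]
            if len(tied) > 1:
                qtop = max(qual[b] for b in tied)
                tied = [b for b in tied if qual[b] == qtop]
            if len(tied) > 1 and i < len(ref) and ref[i] in tied:
                cons.append(ref[i])
            else:
                cons.append(tied[0])
        out[key] = ("".join(cons), len(members))
    return out


class TestDedupConsensus:
    def test_grouping_count(self):
        recs = [
            AssignedRead("r1", "P", "AAAA", "ACGT"),
            AssignedRead("r2", "P", "AAAA", "ACGT"),
            AssignedRead("r3", "P", "AAAA", "ACGT"),
            AssignedRead("r4", "P", "CCCC", "ACGT"),
            AssignedRead("r5", "P", "CCCC", "ACGT"),
        ]
        from mipscreen.panel import Probe

        probe = Probe(
            id="P", contig="chr1", strand="+",
            ext_start=0, ext_end=21, ext_arm_seq="A" * 21,
            lig_start=131, lig_end=155, lig_arm_seq="C" * 24,
            gap_start=21, gap_end=25, gapfill_seq="ACGT",
        )
        frags = dedup_consensus(recs, [probe])
        assert len(frags) == 2
        assert {f.n_reads for f in frags} == {3, 2}

    def test_majority_base_wins(self):
        from mipscreen.panel import Probe

        probe = Probe(
            id="P", contig="chr1", strand="+",
            ext_start=0, ext_end=21, ext_arm_seq="A" * 21,
            lig_start=131, lig_end=155, lig_arm_seq="C" * 24,
            gap_start=21, gap_end=22, gapfill_seq="G",
        )
        recs = [AssignedRead(f"r{i}", "P", "AAAA", b) for i, b in enumerate("AAC")]
        (frag,) = dedup_consensus(recs, [probe])
        assert frag.consensus == "A"

    def test_tie_falls_back_to_reference(self):
        from mipscreen.panel import Probe

        probe = Probe(
            id="P", contig="chr1", strand="+",
            ext_start=0, ext_end=21, ext_arm_seq="A" * 21,
            lig_start=131, lig_end=155, lig_arm_seq="C" * 24,
            gap_start=21, gap_end=22, gapfill_seq="C",
        )
        recs = [AssignedRead(f"r{i}", "P", "AAAA", b) for i, b in enumerate("AC")]
        (frag,) = dedup_consensus(recs, [probe])
        assert frag.consensus == "C"

    def test_oracle_equivalence_on_simulation(self, small_panel, reference):
        params = SimParams(seed=24, mean_unique_molecules_per_probe=40, error_rate=0.005)
        reads, _ = simulate_sample(small_panel, reference, [], params)
        assigned, _ = process_read_pairs(reads, small_panel.probes)
        frags = dedup_consensus(assigned, small_panel.probes)
        oracle = _brute_force_dedup(assigned, small_panel.probes)
        assert len(frags) == len(oracle)
        for f in frags:
            cons, n = oracle[(f.probe_id, f.umi)]
            assert f.n_reads == n
            assert f.consensus == cons

    def test_idempotence(self, small_panel, reference):
        params = SimParams(seed=25, mean_unique_molecules_per_probe=20)
        reads, _ = simulate_sample(small_panel, reference, [], params)
        assigned, _ = process_read_pairs(reads, small_panel.probes)
        once = dedup_consensus(assigned, small_panel.probes)
        again = dedup_consensus(
            [AssignedRead("x", f.probe_id, f.umi, f.consensus) for f in once],
            small_panel.probes,
        )
        assert [(f.probe_id, f.umi, f.consensus) for f in once] == [
            (f.probe_id, f.umi, f.consensus) for f in again
        ]

    def test_error_suppression(self, small_panel, reference):
        """Consensus over duplicate groups of size >= 3 has a lower per-base
        error rate than single reads at 1% substitution error."""
        params = SimParams(
            seed=26, mean_unique_molecules_per_probe=60,
            pcr_duplicate_p=0.25, error_rate=0.01,
        )
        reads, truth = simulate_sample(small_panel, reference, [], params)
        assigned, _ = process_read_pairs(reads, small_panel.probes)
        by_id = {p.id: p for p in small_panel.probes}
        # single-read error rate over gap-fill bases
        read_err = read_n = 0
        for r in assigned[:2000]:
            ref = by_id[r.probe_id].gapfill_seq
            if len(r.target_seq) == len(ref):
                read_err += sum(a != b for a, b in zip(r.target_seq, ref))
                read_n += len(ref)
        frags = dedup_consensus(assigned, small_panel.probes)
        cons_err = cons_n = 0
        for f in frags:
            if f.n_reads < 3:
                continue
            ref = by_id[f.probe_id].gapfill_seq
            if len(f.consensus) == len(ref):
                cons_err += sum(a != b for a, b in zip(f.consensus, ref))
                cons_n += len(ref)
        assert read_n and cons_n
        assert cons_err / cons_n < read_err / read_n


class TestConservationAndCoverage:
    def test_read_conservation(self, small_panel, reference):
        params = SimParams(seed=27, mean_unique_molecules_per_probe=20)
        reads, _ = simulate_sample(small_panel, reference, [], params)
        # corrupt some reads so all three outcomes occur
        reads[0].read2 = "ACG"  # too short -> skipped
        reads[1].read1 = "T" * 150  # arms unmatchable -> unassigned
        assigned, stats = process_read_pairs(reads, small_panel.probes)
        assert stats.assigned + stats.unassigned + stats.skipped == len(reads)
        assert stats.assigned == len(assigned)
        assert stats.skipped >= 1 and stats.unassigned >= 1

    def test_breadth_counting(self):
        """Per-base depths [25, 25, 10, 30] against threshold 20 -> breadth 0.75."""
        from mipscreen.panel import Probe, TargetRegion
        from mipscreen.process import SequencedFragment

        base = dict(
            contig="chr9", strand="+",
            ext_start=0, ext_end=21, ext_arm_seq="A" * 21,
            lig_start=131, lig_end=155, lig_arm_seq="C" * 24,
        )
        seq = "ACGT"
        probes = [
            Probe(id=f"P{j}", gap_start=100 + j, gap_end=101 + j,
                  gapfill_seq=seq[j], **base)
            for j in range(4)
        ]
        frags, k = [], 0
        for j, d in enumerate([25, 25, 10, 30]):
            for _ in range(d):
                frags.append(SequencedFragment(f"P{j}", f"u{k}", seq[j], 1))
                k += 1
        region = [TargetRegion("chr9", 100, 104, gene="G")]
        report = coverage_report(frags, probes, region, threshold=20)
        assert report.breadth == 0.75

    def test_no_fragments_breadth_zero(self, small_panel):
        report = coverage_report([], small_panel.probes, small_panel.regions)
        assert report.breadth == 0.0

    def test_empty_regions_rejected(self, small_panel):
        with pytest.raises(ValueError):
            coverage_report([], small_panel.probes, [])

    def test_uniform_depth_panel_breadth_near_one(self, small_panel, reference):
        breadths = []
        for seed in range(5):
            params = SimParams(
                seed=seed, mean_unique_molecules_per_probe=50,
                efficiency_sigma=0.0, error_rate=0.0,
            )
            reads, _ = simulate_sample(small_panel, reference, [], params)
            assigned, _ = process_read_pairs(reads, small_panel.probes)
            frags = dedup_consensus(assigned, small_panel.probes)
            breadths.append(
                coverage_report(frags, small_panel.probes, small_panel.regions, 20).breadth
            )
        assert min(breadths) >= 0.99
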