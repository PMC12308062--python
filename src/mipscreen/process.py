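"""UMI-aware read processing: extraction, probe assignment, arm trimming,
duplicate collapsing and coverage reporting.

Genome alignment is replaced by arm-anchored probe assignment: the panel is
small and every probe carries genomic coordinates, so a read's position
follows from the probe whose arm sequences match its termini. Off-target
reads are simply unassigned. Duplicate groups (same probe, same UMI) are
collapsed to a per-molecule consensus rather than merely marked, which both
removes PCR duplicates and suppresses isolated sequencing errors.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

from mipscreen.panel import Probe, TargetRegion, revcomp
from mipscreen.simulate import ReadPair


@dataclass
class AssignedRead:
    """A read pair after UMI extraction, probe assignment and arm trimming."""

    read_id: str
    probe_id: str
    umi: str
    target_seq: str  # plus-strand genomic orientation over the gap-fill
    qual: str = ""


@dataclass
class SequencedFragment:
    """Consensus of one captured molecule (one probe + UMI group)."""

    probe_id: str
    umi: str
    consensus: str  # plus-strand genomic orientation
    n_reads: int
    support: list[int] = field(default_factory=list)  # per-position agreeing reads


@dataclass
class ProcessStats:
    assigned: int = 0
    unassigned: int = 0
    skipped: int = 0

    @property
    def total(self) -> int:
        return self.assigned + self.unassigned + self.skipped


def extract_umi(pair: ReadPair, umi_length: int = 8) -> tuple[str, ReadPair] | None:
    """Pull the UMI off the 5' end of read 2; None if the read is too short."""
    if len(pair.read2) <= umi_length:
        return None
    umi = pair.read2[:umi_length]
    trimmed = ReadPair(
        name=pair.name,
        read1=pair.read1,
        read2=pair.read2[umi_length:],
        qual1=pair.qual1,
        qual2=pair.qual2[umi_length:] if pair.qual2 else "",
    )
    return umi, trimmed


def _hamming(a: str, b: str, limit: int) -> int:
    """Mismatches between equal-offset prefixes, short-circuiting past limit."""
    n = min(len(a), len(b))
    d = abs(len(a) - len(b))
    for i in range(n):
        if a[i] != b[i]:
            d += 1
            if d > limit:
                return d
    return d


class ProbeAssigner:
    """Arm-anchored read-to-probe assignment with an exact-match fast path."""

    def __init__(self, probes: list[Probe], max_mismatches: int = 2):
        self.probes = list(probes)
        self.max_mismatches = max_mismatches
        self._exact: dict[tuple[str, str], str] = {}
        by_key: dict[tuple[str, str], list[str]] = defaultdict(list)
        for p in probes:
            by_key[(p.ext_arm_seq, p.lig_arm_seq)].append(p.id)
        for key, ids in by_key.items():
            if len(ids) == 1:
                self._exact[key] = ids[0]
        self._by_id = {p.id: p for p in probes}

    def probe(self, probe_id: str) -> Probe:
        return self._by_id[probe_id]

    def assign(self, read1: str, read2_trimmed: str) -> str | None:
        """Unique probe whose arms match the read termini within the mismatch
        budget; ties and no-matches return None."""
        best_id, best_d, best_count = None, self.max_mismatches + 1, 0
        for p in self.probes:
            e = len(p.ext_arm_seq)
            l = len(p.lig_arm_seq)
            key = (read1[:e], read2_trimmed[:l])
            if key == (p.ext_arm_seq, p.lig_arm_seq):
                d = 0
            else:
                d = _hamming(read1[:e], p.ext_arm_seq, self.max_mismatches)
                if d <= self.max_mismatches:
                    d += _hamming(read2_trimmed[:l], p.lig_arm_seq, self.max_mismatches - d)
            if d < best_d:
                best_id, best_d, best_count = p.id, d, 1
            elif d == best_d:
                best_count += 1
        if best_d > self.max_mismatches or best_count != 1:
            return None
        return best_id


def assign_probe(
    pair: ReadPair, probes: list[Probe], max_mismatches: int = 2, umi_length: int = 8
) -> str | None:
    """Convenience single-read wrapper around :class:`ProbeAssigner`."""
    ex = extract_umi(pair, umi_length)
    if ex is None:
        return None
    _, trimmed = ex
    return ProbeAssigner(probes, max_mismatches).assign(trimmed.read1, trimmed.read2)


def trim_arms(read1: str, probe: Probe, anchor_len: int = 12) -> str | None:
    """Recover the plus-strand target sequence from read 1, excluding arms.

    Read 1 is extension arm + captured target (+ the start of the trailing
    arm when the capture is shorter than the read). The trailing-arm anchor
    is searched so that molecules carrying small indels are trimmed at the
    true target boundary rather than at a fixed offset. Arm-derived bases
    never enter the returned sequence.
    """
    ext_len = len(probe.ext_arm_seq)
    trailing = revcomp(probe.lig_arm_seq)[:anchor_len]
    expected = ext_len + probe.gap_length
    idx = read1.find(trailing, ext_len)
    if idx == -1:
        target_read = read1[ext_len : expected]
    else:
        # prefer the occurrence nearest the expected boundary
        best = idx
        while True:
            nxt = read1.find(trailing, best + 1)
            if nxt == -1:
                break
            if abs(nxt - expected) < abs(best - expected):
                best = nxt
        target_read = read1[ext_len:best]
    if not target_read:
        return None
    return target_read if probe.strand == "+" else revcomp(target_read)


def process_read_pairs(
    pairs: list[ReadPair],
    probes: list[Probe],
    max_mismatches: int = 2,
) -> tuple[list[AssignedRead], ProcessStats]:
    """UMI extraction, probe assignment and arm trimming over a read set."""
    assigner = ProbeAssigner(probes, max_mismatches)
    umi_len = probes[0].umi_length if probes else 8
    out: list[AssignedRead] = []
    stats = ProcessStats()
    for pair in pairs:
        ex = extract_umi(pair, umi_len)
        if ex is None:
            stats.skipped += 1
            continue
        umi, trimmed = ex
        pid = assigner.assign(trimmed.read1, trimmed.read2)
        if pid is None:
            stats.unassigned += 1
            continue
        target = trim_arms(trimmed.read1, assigner.probe(pid))
        if target is None:
            stats.skipped += 1
            continue
        out.append(AssignedRead(pair.name, pid, umi, target, qual=pair.qual1))
        stats.assigned += 1
    return out, stats


def dedup_consensus(
    records: list[AssignedRead], probes: list[Probe]
) -> list[SequencedFragment]:
    """Collapse reads sharing (probe, UMI) into per-molecule consensus.

    Per position the majority base wins; ties break to the higher summed
    base quality, then to the reference base. When group members disagree in
    length (indel molecules vs. errored reads), the modal length is used.
    Output order is deterministic (probe id, then UMI).
    """
    ref_by_id = {p.id: p for p in probes}
    groups: dict[tuple[str, str], list[AssignedRead]] = defaultdict(list)
    for r in records:
        groups[(r.probe_id, r.umi)].append(r)
    fragments: list[SequencedFragment] = []
    for (pid, umi) in sorted(groups):
        members = groups[(pid, umi)]
        lengths = Counter(len(m.target_seq) for m in members)
        modal_len = max(lengths, key=lambda L: (lengths[L], -L))
        seqs = [m for m in members if len(m.target_seq) == modal_len]
        probe = ref_by_id[pid]
        ref = probe.gapfill_seq
        cons = []
        support = []
        for i in range(modal_len):
            votes: Counter = Counter()
            quals: Counter = Counter()
            for m in seqs:
                b = m.target_seq[i]
                votes[b] += 1
                if m.qual and i < len(m.qual):
                    quals[b] += ord(m.qual[i])
            top = max(votes.values())
            tied = sorted(b for b, c in votes.items() if c == top)
            if len(tied) > 1:
                qtop = max(quals[b] for b in tied)
                qtied = [b for b in tied if quals[b] == qtop]
                refbase = ref[i] if i < len(ref) else ""
                pick = refbase if refbase in qtied else qtied[0]
            else:
                pick = tied[0]
            cons.append(pick)
            support.append(votes[pick])
        fragments.append(
            SequencedFragment(
                probe_id=pid,
                umi=umi,
                consensus="".join(cons),
                n_reads=len(members),
                support=support,
            )
        )
    return fragments


@dataclass
class CoverageReport:
    """Deduplicated depth over the target space."""

    per_base_depth: dict[tuple[str, int], int]
    per_probe_depth: dict[str, float]
    per_gene_breadth: dict[str, float]
    breadth: float  # panel-wide fraction of target bases with depth > threshold
    threshold: int


def coverage_report(
    fragments: list[SequencedFragment],
    probes: list[Probe],
    regions: list[TargetRegion],
    threshold: int = 20,
) -> CoverageReport:
    """Per-base consensus depth and breadth (> threshold, strictly) over regions."""
    if not regions:
        raise ValueError("empty region set")
    by_id = {p.id: p for p in probes}
    depth: dict[tuple[str, int], int] = defaultdict(int)
    per_probe: Counter = Counter()
    for f in fragments:
        p = by_id[f.probe_id]
        per_probe[f.probe_id] += 1
        span = min(len(f.consensus), p.gap_length)
        for pos in range(p.gap_start, p.gap_start + span):
            depth[(p.contig, pos)] += 1
    gene_bases: dict[str, int] = Counter()
    gene_covered: dict[str, int] = Counter()
    total = covered = 0
    for r in regions:
        for pos in range(r.start, r.end):
            d = depth.get((r.contig, pos), 0)
            total += 1
            gene_bases[r.gene] += 1
            if d > threshold:
                covered += 1
                gene_covered[r.gene] += 1
    per_gene = {
        g: (gene_covered[g] / gene_bases[g]) if gene_bases[g] else 0.0 for g in gene_bases
    }
    return CoverageReport(
        per_base_depth=dict(depth),
        per_probe_depth={pid: float(per_probe.get(pid, 0)) for pid in by_id},
        per_gene_breadth=per_gene,
        breadth=(covered / total) if total else 0.0,
        threshold=threshold,
    )


def write_fragment_table(fragments: list[SequencedFragment], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            dict(
                probe_id=f.probe_id,
                umi=f.umi,
                consensus=f.consensus,
                n_reads=f.n_reads,
            )
            for f in fragments
        ]
    ).to_csv(path, sep="\t", index=False)
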