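"""Simplified pileup genotyping and probe-depth CNV calling.

The small-variant caller is a deterministic pileup over consensus fragments:
because arms are trimmed and fragments are short and probe-anchored, no local
reassembly is needed. Indels are inferred per fragment from a single-event
prefix/suffix decomposition against the probe's gap-fill and left-aligned
before counting, so homopolymer deletions always report at their leftmost
placement.

CNV calling is a median-ratio method over per-probe deduplicated depths: each
probe's library-size-normalised depth in the test sample is divided by the
median of the same quantity across a reference cohort, and runs of
consecutive probes with depressed (or elevated) ratios become segments.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from mipscreen.panel import Probe
from mipscreen.process import SequencedFragment


@dataclass
class PileupColumn:
    contig: str
    position: int  # 0-based
    ref_base: str
    alleles: Counter = field(default_factory=Counter)  # (ref, alt) -> fragment count

    @property
    def depth(self) -> int:
        return sum(self.alleles.values())


@dataclass(frozen=True)
class VariantCall:
    contig: str
    position: int  # 0-based
    ref: str
    alt: str
    genotype: str  # het | hom | hemi | ambiguous
    allele_fraction: float
    depth: int
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class CnvSegment:
    gene: str
    first_probe: str
    last_probe: str
    n_probes: int
    copy_ratio: float
    state: str  # het_del | hom_del | dup


def left_align_deletion(ref: str, q: int, d: int) -> int:
    """Shift a length-``d`` deletion at offset ``q`` of ``ref`` to its
    leftmost equivalent placement."""
    while q > 0 and ref[q - 1] == ref[q + d - 1]:
        q -= 1
    return q


def left_align_insertion(alt: str, q: int, d: int) -> int:
    """Leftmost placement of a length-``d`` insertion; ``alt`` is the
    sequence containing the insertion at offset ``q``."""
    while q > 0 and alt[q - 1] == alt[q + d - 1]:
        q -= 1
    return q


def _lcp(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def infer_single_indel(ref: str, obs: str) -> tuple[int, str, str] | None:
    """Explain ``obs`` as ``ref`` with one left-aligned indel.

    Returns ``(offset, ref_allele, alt_allele)`` in VCF-style anchored form,
    or None when the two sequences differ by something other than a single
    clean indel.
    """
    if len(ref) == len(obs):
        return None
    p = _lcp(ref, obs)
    if len(ref) > len(obs):  # deletion
        d = len(ref) - len(obs)
        q = min(p, len(obs))
        if ref[:q] + ref[q + d :] != obs:
            return None
        q = left_align_deletion(ref, q, d)
        if q > 0:
            return q - 1, ref[q - 1 : q + d], ref[q - 1]
        # no base to the left: anchor on the following base
        return 0, ref[: d + 1], ref[d]
    d = len(obs) - len(ref)  # insertion
    q = min(p, len(ref))
    if obs[:q] + obs[q + d :] != ref:
        return None
    q = left_align_insertion(obs, q, d)
    ins = obs[q : q + d]
    if q > 0:
        return q - 1, ref[q - 1], ref[q - 1] + ins
    return 0, ref[0], ins + ref[0]


def pileup(
    fragments: list[SequencedFragment], probes: list[Probe]
) -> dict[tuple[str, int], PileupColumn]:
    """One column per covered target base, from consensus fragments.

    Fragments matching the gap-fill length contribute one base call per
    position; fragments whose length differs contribute a single anchored
    indel allele (left-aligned) plus reference support elsewhere. Fragments
    that cannot be explained by a single clean indel are skipped.
    """
    by_id = {p.id: p for p in probes}
    columns: dict[tuple[str, int], PileupColumn] = {}

    def col(contig: str, pos: int, refbase: str) -> PileupColumn:
        key = (contig, pos)
        if key not in columns:
            columns[key] = PileupColumn(contig, pos, refbase)
        return columns[key]

    for f in sorted(fragments, key=lambda x: (x.probe_id, x.umi)):
        probe = by_id[f.probe_id]
        ref = probe.gapfill_seq
        obs = f.consensus
        contig, start = probe.contig, probe.gap_start
        if len(obs) == len(ref):
            for i, (rb, ob) in enumerate(zip(ref, obs)):
                col(contig, start + i, rb).alleles[(rb, ob)] += 1
            continue
        indel = infer_single_indel(ref, obs)
        if indel is None:
            continue
        off, ra, aa = indel
        col(contig, start + off, ref[off]).alleles[(ra, aa)] += 1
        span = range(off, off + len(ra)) if len(ra) > 1 else range(off, off + 1)
        deleted = set(span)
        for i, rb in enumerate(ref):
            if i in deleted:
                continue
            col(contig, start + i, rb).alleles[(rb, rb)] += 1
    return columns


@dataclass(frozen=True)
class CallThresholds:
    min_depth: int = 8
    hom_min_af: float = 0.85
    het_min_af: float = 0.25
    het_max_af: float = 0.75


def call_small_variants(
    columns: dict[tuple[str, int], PileupColumn],
    sex: str = "XX",
    thresholds: CallThresholds = CallThresholds(),
) -> tuple[list[VariantCall], int]:
    """Deterministic genotype calls from pileup columns.

    Returns (calls, n_low_depth_no_calls). Alt fractions in
    [het_min, het_max] call het, >= hom_min call hom (hemi on chrX for XY
    samples); fractions between het_max and hom_min are emitted flagged
    ambiguous; below het_min the alt is treated as noise.
    """
    calls: list[VariantCall] = []
    low_depth = 0
    for key in sorted(columns):
        c = columns[key]
        depth = c.depth
        for (ra, aa), count in sorted(c.alleles.items()):
            if ra == aa:
                continue
            if depth < thresholds.min_depth:
                low_depth += 1
                continue
            af = count / depth
            if af < thresholds.het_min_af:
                continue
            hemi_context = c.contig == "chrX" and sex == "XY"
            if af >= thresholds.hom_min_af:
                gt = "hemi" if hemi_context else "hom"
                flags: tuple[str, ...] = ()
            elif af <= thresholds.het_max_af:
                gt, flags = "het", ()
            else:
                gt, flags = "ambiguous", ("ambiguous_af",)
            calls.append(
                VariantCall(
                    contig=c.contig,
                    position=c.position,
                    ref=ra,
                    alt=aa,
                    genotype=gt,
                    allele_fraction=af,
                    depth=depth,
                    flags=flags,
                )
            )
    return calls, low_depth


@dataclass(frozen=True)
class CnvParams:
    het_del_max_ratio: float = 0.65
    hom_del_max_ratio: float = 0.10
    dup_min_ratio: float = 1.40
    min_probes: int = 3


def call_cnv(
    test_depths: dict[str, float],
    reference_depths: list[dict[str, float]],
    probe_order: list[tuple[str, str]],
    params: CnvParams = CnvParams(),
) -> list[CnvSegment]:
    """Median-ratio CNV calling over ordered per-probe depths.

    ``probe_order`` lists (probe_id, gene) in genomic order; segmentation
    runs within genes. Probes whose reference median normalised depth is
    zero are masked. At least three reference samples are required. The test
    sample's library size is normalised by the median per-probe ratio (not
    total counts), so depth lost inside a deletion does not inflate the
    ratios of unaffected probes.
    """
    if len(reference_depths) < 3:
        raise ValueError("need >= 3 reference samples")
    probes = [pid for pid, _ in probe_order]
    if sum(test_depths.get(p, 0.0) for p in probes) <= 0:
        raise ValueError("test sample has zero depth")
    raw: dict[str, float | None] = {}
    for pid in probes:
        ref_norms = []
        for ref in reference_depths:
            tot = sum(ref.get(p, 0.0) for p in probes)
            if tot > 0:
                ref_norms.append(ref.get(pid, 0.0) / tot)
        med = float(np.median(ref_norms)) if ref_norms else 0.0
        if med <= 0:
            raw[pid] = None  # masked
            continue
        raw[pid] = test_depths.get(pid, 0.0) / med
    # robust library-size scaling: divide by the median per-probe ratio, so a
    # deletion spanning part of the panel does not inflate the other probes
    # (breaks down if more than half the panel is deleted; see docs)
    observed = [r for r in raw.values() if r is not None]
    scale = float(np.median(observed))
    if scale <= 0:
        raise ValueError("cannot scale: median per-probe ratio is zero")
    ratios = {pid: (None if r is None else r / scale) for pid, r in raw.items()}

    def state_of(r: float) -> str:
        if r < params.hom_del_max_ratio:
            return "hom_del"
        if r < params.het_del_max_ratio:
            return "het_del"
        if r > params.dup_min_ratio:
            return "dup"
        return "normal"

    segments: list[CnvSegment] = []
    by_gene: dict[str, list[str]] = defaultdict(list)
    gene_order: list[str] = []
    for pid, gene in probe_order:
        if gene not in by_gene:
            gene_order.append(gene)
        by_gene[gene].append(pid)
    for gene in gene_order:
        run: list[tuple[str, float]] = []
        run_state = "normal"

        def flush():
            if run and run_state in ("het_del", "hom_del", "dup") and len(run) >= params.min_probes:
                segments.append(
                    CnvSegment(
                        gene=gene,
                        first_probe=run[0][0],
                        last_probe=run[-1][0],
                        n_probes=len(run),
                        copy_ratio=float(np.mean([r for _, r in run])),
                        state=run_state,
                    )
                )

        for pid in by_gene[gene]:
            r = ratios[pid]
            if r is None:
                flush()
                run, run_state = [], "normal"
                continue
            s = state_of(r)
            if s == run_state:
                run.append((pid, r))
            else:
                flush()
                run, run_state = [(pid, r)], s
        flush()
    return segments


def per_probe_depths(fragments: list[SequencedFragment]) -> dict[str, float]:
    """Deduplicated molecule count per probe (the CNV caller's input)."""
    c: Counter = Counter()
    for f in fragments:
        c[f.probe_id] += 1
    return {pid: float(n) for pid, n in c.items()}


_GT_FIELD = {"het": "0/1", "hom": "1/1", "hemi": "1", "ambiguous": "./."}


def write_vcf(calls: list[VariantCall], sample_id: str, path) -> None:
    """Write calls as a single-sample VCF 4.2 with GT/DP/AF format fields.

    Positions are converted to the standard's 1-based coordinates. Unsorted
    input is sorted internally.
    """
    ordered = sorted(calls, key=lambda c: (c.contig, c.position, c.ref, c.alt))
    contigs = []
    for c in ordered:
        if c.contig not in contigs:
            contigs.append(c.contig)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mipscreen\n")
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Consensus depth">\n')
        fh.write('##FORMAT=<ID=AF,Number=1,Type=Float,Description="Allele fraction">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}\n")
        for c in ordered:
            gt = _GT_FIELD[c.genotype]
            filt = "ambiguous" if "ambiguous_af" in c.flags else "PASS"
            fh.write(
                f"{c.contig}\t{c.position + 1}\t.\t{c.ref}\t{c.alt}\t.\t{filt}\t.\t"
                f"GT:DP:AF\t{gt}:{c.depth}:{c.allele_fraction:.4f}\n"
            )
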