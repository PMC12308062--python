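"""Simulated smMIP capture sequencing.

Generates paired FASTQ with the read structure produced by a UMI-bearing smMIP
library: read 1 starts at the extension arm and runs into the captured target;
read 2 begins with the UMI, then the ligation arm, then the target read from
the opposite end. Per-probe molecule counts are Poisson with log-normal
capture-efficiency skew, PCR duplication follows a geometric law, and
sequencing error is i.i.d. substitution. Every emitted read is recorded in a
truth ledger so downstream stages can be scored exactly.

The simulator emulates capture-efficiency variation, PCR duplication, UMI
collisions and substitution error; it does not emulate sequencer indels,
strand bias, index hopping or per-cycle quality decay.
"""

from __future__ import annotations

import gzip
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mipscreen.panel import PanelDefinition, Probe, revcomp

BASES = "ACGT"


def random_reference(contig_lengths: dict[str, int], seed: int = 0) -> dict[str, str]:
    """A synthetic reference genome: uniform random ACGT per contig."""
    rng = np.random.default_rng(seed)
    ref = {}
    for name, length in contig_lengths.items():
        ref[name] = "".join(rng.choice(list(BASES), size=length))
    return ref


def write_fasta(reference: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class SimParams:
    """Simulation conditions for one capture-sequencing run.

    Capture efficiency is probe-intrinsic: each probe's log-normal efficiency
    is derived deterministically from its id and ``efficiency_seed``, so the
    same probe under- or over-performs consistently across samples and runs
    (the property that makes pool rebalancing and reference-cohort CNV
    normalisation meaningful). Per-sample randomness (molecule counts, UMIs,
    PCR duplication, errors) is driven by ``seed``.
    """

    seed: int = 0
    mean_unique_molecules_per_probe: float = 100.0
    efficiency_sigma: float = 0.5  # log-normal sigma of per-probe capture skew
    efficiency_seed: int = 1234
    pcr_duplicate_p: float = 0.5  # geometric p; mean reads per molecule = 1/p
    error_rate: float = 0.001
    read_length: int = 150
    sex: str = "XX"
    quality_char: str = "I"  # constant Q40-ish placeholder quality

    def __post_init__(self):
        if self.mean_unique_molecules_per_probe <= 0:
            raise ValueError("mean_unique_molecules_per_probe must be positive")
        if self.efficiency_sigma < 0:
            raise ValueError("efficiency_sigma must be >= 0")
        if not (0 < self.pcr_duplicate_p <= 1):
            raise ValueError("pcr_duplicate_p must be in (0, 1]")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be in [0, 1)")
        if self.sex not in ("XX", "XY"):
            raise ValueError("sex must be XX or XY")


@dataclass(frozen=True)
class PlantedVariant:
    """A truth variant planted into simulated haplotypes.

    ``kind`` is ``snv``, ``ins``, ``del`` (small indel) or ``cnv`` (an exon- or
    window-scale deletion given by ``span_end``; ``alt`` is unused for CNVs).
    For small variants ``position`` is 0-based and ``ref``/``alt`` are allele
    strings (VCF-style, anchored for indels).
    """

    contig: str
    position: int
    ref: str = ""
    alt: str = ""
    zygosity: str = "het"  # het | hom | hemi
    kind: str = "snv"
    span_end: int = 0  # cnv only: deletion is [position, span_end)

    def __post_init__(self):
        if self.zygosity not in ("het", "hom", "hemi"):
            raise ValueError(f"bad zygosity {self.zygosity}")
        if self.kind not in ("snv", "ins", "del", "cnv"):
            raise ValueError(f"bad kind {self.kind}")


@dataclass
class ReadPair:
    name: str
    read1: str
    read2: str
    qual1: str = ""
    qual2: str = ""


@dataclass
class TruthTable:
    """Per-read and per-variant ground truth for a simulated run."""

    reads: pd.DataFrame  # read_id, sample, probe_id, umi, molecule_id
    variants: list[PlantedVariant] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _apply_small_variants(
    seq: str, gap_start: int, contig: str, variants: list[PlantedVariant]
) -> str:
    """Apply small variants (positions relative to the reference gap-fill)."""
    edits = []
    for v in variants:
        if v.kind == "cnv" or v.contig != contig:
            continue
        off = v.position - gap_start
        if 0 <= off < len(seq):
            edits.append((off, v))
    out = seq
    for off, v in sorted(edits, key=lambda t: -t[0]):  # right-to-left keeps offsets valid
        if v.kind == "snv":
            if out[off] == v.ref:
                out = out[:off] + v.alt + out[off + 1 :]
        else:
            # anchored indel: replace ref allele string by alt allele string
            if out[off : off + len(v.ref)] == v.ref:
                out = out[:off] + v.alt + out[off + len(v.ref) :]
    return out


def _probe_copy_number(probe: Probe, variants: list[PlantedVariant], sex: str) -> tuple[int, int]:
    """(copies of hap0, copies of hap1) for this probe's gap-fill."""
    base = [1, 1]
    if probe.contig == "chrX" and sex == "XY":
        base = [1, 0]
    for v in variants:
        if v.kind != "cnv" or v.contig != probe.contig:
            continue
        if probe.gap_start < v.span_end and v.position < probe.gap_end:
            if v.zygosity in ("hom",):
                base = [0, 0]
            elif v.zygosity == "hemi":
                base = [0, 0] if sex == "XY" and probe.contig == "chrX" else [0, base[1]]
            else:  # het: lose one copy
                base[0] = 0
    return base[0], base[1]


def _haplotype_variants(
    variants: list[PlantedVariant], hap: int, sex: str, contig: str
) -> list[PlantedVariant]:
    """Variants present on haplotype ``hap`` (0 or 1). Hets sit on hap 1."""
    out = []
    for v in variants:
        if v.kind == "cnv" or v.contig != contig:
            continue
        if v.zygosity == "hom":
            out.append(v)
        elif v.zygosity == "hemi":
            if contig == "chrX" and sex == "XY":
                out.append(v)
        elif v.zygosity == "het" and hap == 1:
            out.append(v)
    return out


def probe_efficiency(probe_id: str, params: SimParams) -> float:
    """Deterministic per-probe capture efficiency (log-normal skew)."""
    if params.efficiency_sigma <= 0:
        return 1.0
    digest = zlib.crc32(f"{params.efficiency_seed}:{probe_id}".encode())
    rng = np.random.default_rng(digest)
    return float(rng.lognormal(mean=0.0, sigma=params.efficiency_sigma))


def _add_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0 or not seq:
        return seq
    n = len(seq)
    hits = np.flatnonzero(rng.random(n) < rate)
    if hits.size == 0:
        return seq
    chars = list(seq)
    for i in hits:
        alts = [b for b in BASES if b != chars[i]]
        chars[i] = alts[rng.integers(3)]
    return "".join(chars)


def _capture_sequence(probe: Probe, reference, target_seq: str) -> str:
    """Full captured molecule in read-1 orientation: ext arm, target, lig arm."""
    contig_seq = reference[probe.contig]

    def fetch(a, b):
        return str(contig_seq[a:b]).upper()

    if probe.strand == "+":
        return fetch(probe.ext_start, probe.ext_end) + target_seq + fetch(
            probe.lig_start, probe.lig_end
        )
    # minus strand: capture is the reverse complement of lig-flank + target + ext-flank
    return revcomp(
        fetch(probe.lig_start, probe.lig_end) + target_seq + fetch(probe.ext_start, probe.ext_end)
    )


def simulate_sample(
    panel: PanelDefinition,
    reference,
    variants: list[PlantedVariant],
    params: SimParams,
    sample: str = "S1",
    _rng: np.random.Generator | None = None,
) -> tuple[list[ReadPair], TruthTable]:
    """Simulate one sample's capture sequencing over the panel's probes.

    Identical seeds (and panel/reference/variants) give byte-identical output.
    """
    if not panel.probes:
        raise ValueError("panel has no probes; run design first")
    rng = _rng if _rng is not None else np.random.default_rng(params.seed)
    warnings = []
    for v in variants:
        if v.kind == "cnv":
            covered = any(
                p.contig == v.contig and p.gap_start < v.span_end and v.position < p.gap_end
                for p in panel.probes
            )
        else:
            covered = any(
                p.contig == v.contig and p.gap_start <= v.position < p.gap_end
                for p in panel.probes
            )
        if not covered:
            warnings.append(
                f"variant {v.contig}:{v.position} outside all gap-fills (un-capturable)"
            )

    reads: list[ReadPair] = []
    ledger = []
    serial = 0
    molecule_id = 0
    for probe in panel.probes:
        eff = probe_efficiency(probe.id, params)
        c0, c1 = _probe_copy_number(probe, variants, params.sex)
        total_copies = c0 + c1
        lam = (
            params.mean_unique_molecules_per_probe
            * eff
            * probe.relative_concentration
            * total_copies
            / 2.0
        )
        n_mol = int(rng.poisson(lam)) if lam > 0 else 0
        if n_mol == 0:
            continue
        # haplotype sequences for this probe's gap-fill
        hap_seqs = []
        for hap, copies in ((0, c0), (1, c1)):
            hv = _haplotype_variants(variants, hap, params.sex, probe.contig)
            hap_seqs.append(
                _apply_small_variants(probe.gapfill_seq, probe.gap_start, probe.contig, hv)
            )
        weights = np.array([c0, c1], dtype=float)
        weights /= weights.sum()
        for _ in range(n_mol):
            hap = int(rng.choice(2, p=weights))
            target = hap_seqs[hap]
            capture = _capture_sequence(probe, reference, target)
            umi = "".join(BASES[i] for i in rng.integers(0, 4, size=probe.umi_length))
            n_reads = int(rng.geometric(params.pcr_duplicate_p))
            for _dup in range(n_reads):
                r1 = capture[: params.read_length]
                r2 = (umi + revcomp(capture))[: params.read_length]
                r1 = _add_errors(r1, rng, params.error_rate)
                r2 = _add_errors(r2, rng, params.error_rate)
                name = f"sim:{sample}:{serial}"
                reads.append(
                    ReadPair(
                        name=name,
                        read1=r1,
                        read2=r2,
                        qual1=params.quality_char * len(r1),
                        qual2=params.quality_char * len(r2),
                    )
                )
                ledger.append((name, sample, probe.id, umi, molecule_id))
                serial += 1
            molecule_id += 1
    truth = TruthTable(
        reads=pd.DataFrame(
            ledger, columns=["read_id", "sample", "probe_id", "umi", "molecule_id"]
        ),
        variants=list(variants),
        warnings=warnings,
    )
    return reads, truth


def simulate_cohort(
    panel: PanelDefinition,
    reference,
    variant_sets: dict[str, list[PlantedVariant]],
    params: SimParams,
    sexes: dict[str, str] | None = None,
) -> tuple[dict[str, list[ReadPair]], TruthTable]:
    """Simulate several samples with a reproducibly split seed stream."""
    if isinstance(variant_sets, dict):
        pairs = list(variant_sets.items())
    else:
        pairs = list(variant_sets)
    samples = [s for s, _ in pairs]
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids")
    variant_sets = dict(pairs)
    child_seeds = np.random.SeedSequence(params.seed).spawn(len(samples))
    all_reads: dict[str, list[ReadPair]] = {}
    frames = []
    variants = []
    warnings = []
    for sample, seedseq in zip(samples, child_seeds):
        p = params
        if sexes and sample in sexes and sexes[sample] != params.sex:
            p = SimParams(**{**params.__dict__, "sex": sexes[sample]})
        rng = np.random.default_rng(seedseq)
        reads, truth = simulate_sample(
            panel, reference, variant_sets[sample], p, sample=sample, _rng=rng
        )
        all_reads[sample] = reads
        frames.append(truth.reads)
        variants.extend(truth.variants)
        warnings.extend(truth.warnings)
    merged = TruthTable(
        reads=pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["read_id", "sample", "probe_id", "umi", "molecule_id"]
        ),
        variants=variants,
        warnings=warnings,
    )
    return all_reads, merged


def write_fastq_pair(reads: list[ReadPair], path1, path2) -> None:
    """Write the pair of gzip FASTQ files (4-line records)."""

    def _open(p):
        return gzip.open(p, "wt") if str(p).endswith(".gz") else open(p, "w")

    with _open(path1) as f1, _open(path2) as f2:
        for rp in reads:
            f1.write(f"@{rp.name}/1\n{rp.read1}\n+\n{rp.qual1}\n")
            f2.write(f"@{rp.name}/2\n{rp.read2}\n+\n{rp.qual2}\n")


def read_fastq_pair(path1, path2) -> list[ReadPair]:
    def _open(p):
        return gzip.open(p, "rt") if str(p).endswith(".gz") else open(p)

    out = []
    with _open(path1) as f1, _open(path2) as f2:
        while True:
            h1 = f1.readline()
            if not h1:
                break
            s1 = f1.readline().strip()
            f1.readline()
            q1 = f1.readline().strip()
            h2 = f2.readline()
            s2 = f2.readline().strip()
            f2.readline()
            q2 = f2.readline().strip()
            name = h1.strip().lstrip("@").rsplit("/", 1)[0]
            out.append(ReadPair(name=name, read1=s1, read2=s2, qual1=q1, qual2=q2))
    return out
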