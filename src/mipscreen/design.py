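"""smMIP probe design: tiling, arm extraction, scoring, selection, oligo
assembly and pool rebalancing.

Design geometry follows the standard smMIP architecture: a 110-nt gap-fill
target flanked by extension and ligation arms totalling 45 nt, joined by a
common backbone carrying universal PCR primer sites and an 8-nt degenerate
UMI. Adjacent probes tile each region with at least 10 bp of overlap.

Scoring is a transparent logistic stand-in built from arm/target GC deviation
and homopolymer content. It reproduces the *shape* of logistic probe-quality
scores (values in [0,1], a 0.5 selection floor, low scores in skewed-GC or
homopolymeric regions) but its values are not comparable to any external
design tool's output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from mipscreen.panel import Probe, TargetRegion, revcomp

# Fixed universal-primer linker halves of the probe backbone. These are
# reproducibility constants of this package (real reagents substitute their
# own primer sites): with the default 45-nt arms and an 8-nt UMI the
# assembled oligo is 90 nt = 82-nt backbone-plus-arms + UMI.
DEFAULT_LINKER_LIG = "CTTCAGCTTCCCGATTACGG"  # 20 nt, follows the ligation arm
DEFAULT_LINKER_EXT = "GATCGTCGGACTGTAGA"  # 17 nt, precedes the extension arm

# Logistic stand-in coefficients (documented, fixed):
#   score = sigmoid(B0 + B_ARM*|armGC-0.5| + B_TARGET*|targetGC-0.5|
#                   + B_HOMO*maxHomopolymerRun)
# An ideal probe (50% GC arms and target, no run > 1) scores sigmoid(1.7)=0.85;
# a 0%-GC arm drops the score below the 0.5 selection floor.
SCORE_B0 = 2.0
SCORE_B_ARM = -6.0
SCORE_B_TARGET = -4.0
SCORE_B_HOMO = -0.3


@dataclass(frozen=True)
class DesignParams:
    """Geometry and selection parameters for probe design."""

    gap_fill_length: int = 110
    extension_len: int = 21
    ligation_len: int = 24
    min_overlap: int = 10
    umi_length: int = 8
    score_floor: float = 0.5
    linker_lig: str = DEFAULT_LINKER_LIG
    linker_ext: str = DEFAULT_LINKER_EXT

    def __post_init__(self):
        if self.extension_len + self.ligation_len != 45:
            raise ValueError(
                f"arm lengths must total 45, got {self.extension_len}+{self.ligation_len}"
            )
        if not (0 < self.min_overlap < self.gap_fill_length):
            raise ValueError("min_overlap must be in (0, gap_fill_length)")
        if not (0.0 <= self.score_floor <= 1.0):
            raise ValueError("score_floor must be in [0,1]")

    @property
    def arm_total(self) -> int:
        return self.extension_len + self.ligation_len


def tile_region(
    region: TargetRegion, params: DesignParams = DesignParams(), contig_length: int | None = None
) -> list[tuple[int, int]]:
    """Tile a region into gap-fill windows.

    Windows are ``gap_fill_length`` long, cover every base of the region, and
    consecutive windows overlap by at least ``min_overlap``. Regions shorter
    than one window get a single window centred on the region, with flanks
    drawn from the surrounding reference.
    """
    L = len(region)
    g = params.gap_fill_length
    if contig_length is not None and region.end > contig_length:
        raise ValueError(
            f"region {region.contig}:{region.start}-{region.end} exceeds contig "
            f"length {contig_length}"
        )
    if L <= g:
        pad = g - L
        start = region.start - pad // 2
        if start < 0:
            start = 0
        if contig_length is not None and start + g > contig_length:
            start = contig_length - g
        return [(start, start + g)]
    step = g - params.min_overlap
    n = math.ceil((L - g) / step) + 1
    # even spacing so the actual step never exceeds g - min_overlap
    span = L - g
    starts = [region.start + round(i * span / (n - 1)) for i in range(n)]
    return [(s, s + g) for s in starts]


def _check_acgt(seq: str, what: str) -> None:
    bad = set(seq.upper()) - set("ACGT")
    if bad:
        raise ValueError(f"{what} contains non-ACGT base(s): {sorted(bad)}")


def design_probe(
    window: tuple[int, int],
    reference,
    contig: str,
    params: DesignParams = DesignParams(),
    strand: str = "+",
    probe_id: str | None = None,
) -> Probe:
    """Build one probe for a gap-fill window on the given strand.

    ``reference`` is any mapping supporting ``reference[contig][start:end]``
    returning sequence (a ``pyfaidx.Fasta`` or a plain dict of strings).

    Arm sequences are stored read-oriented: ``ext_arm_seq`` is what read 1
    begins with, ``lig_arm_seq`` is what follows the UMI in read 2. For a
    plus-strand probe the extension arm anneals to the left flank; for a
    minus-strand probe the capture is reverse complemented so the extension
    arm anneals to the right flank.
    """
    s, e = window
    ext_len, lig_len = params.extension_len, params.ligation_len
    contig_seq = reference[contig]
    contig_len = len(contig_seq)
    if strand == "+":
        ext_iv = (s - ext_len, s)
        lig_iv = (e, e + lig_len)
    else:
        ext_iv = (e, e + ext_len)
        lig_iv = (s - lig_len, s)
    lo = min(ext_iv[0], lig_iv[0])
    hi = max(ext_iv[1], lig_iv[1])
    if lo < 0 or hi > contig_len:
        raise ValueError(
            f"arm flank off contig end: window {contig}:{s}-{e} strand {strand}"
        )

    def fetch(a, b):
        return str(contig_seq[a:b]).upper()

    gapfill = fetch(s, e)
    if strand == "+":
        ext_seq = fetch(*ext_iv)
        lig_seq = revcomp(fetch(*lig_iv))
    else:
        ext_seq = revcomp(fetch(*ext_iv))
        lig_seq = fetch(*lig_iv)
    _check_acgt(ext_seq, "extension arm")
    _check_acgt(lig_seq, "ligation arm")
    pid = probe_id or f"{contig}:{s}-{e}:{strand}"
    return Probe(
        id=pid,
        contig=contig,
        strand=strand,
        ext_start=ext_iv[0],
        ext_end=ext_iv[1],
        ext_arm_seq=ext_seq,
        lig_start=lig_iv[0],
        lig_end=lig_iv[1],
        lig_arm_seq=lig_seq,
        gap_start=s,
        gap_end=e,
        gapfill_seq=gapfill,
        umi_length=params.umi_length,
    )


def _gc_fraction(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    return sum(1 for b in seq.upper() if b in "GC") / len(seq)


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def score_probe(probe: Probe) -> float:
    """Deterministic logistic quality score in [0, 1] (see module docstring)."""
    arms = probe.ext_arm_seq + probe.lig_arm_seq
    if not arms or not probe.gapfill_seq:
        raise ValueError("probe arms and gap-fill sequence must be populated")
    x = (
        SCORE_B0
        + SCORE_B_ARM * abs(_gc_fraction(arms) - 0.5)
        + SCORE_B_TARGET * abs(_gc_fraction(probe.gapfill_seq) - 0.5)
        + SCORE_B_HOMO * _max_homopolymer(arms + probe.gapfill_seq)
    )
    return 1.0 / (1.0 + math.exp(-x))


def select_probes(
    candidates_per_window: list[list[Probe]],
    params: DesignParams = DesignParams(),
) -> list[Probe]:
    """Pick one probe per window from strand candidates.

    Candidates at or above ``score_floor`` are preferred; when no candidate
    reaches the floor the best one is kept and flagged ``below_floor`` —
    mirroring the practice of relaxing the score threshold in challenging
    genomic regions. Ties break to the higher score, then the plus strand,
    then the leftmost gap-fill start.
    """
    selected = []
    for cands in candidates_per_window:
        if not cands:
            raise ValueError("empty candidate set for a window")
        # rank: score desc, '+' before '-', leftmost
        ranked = sorted(
            cands,
            key=lambda c: (-c.score, 0 if c.strand == "+" else 1, c.gap_start),
        )
        best = ranked[0]
        if best.score < params.score_floor and "below_floor" not in best.flags:
            best = Probe(**{**best.__dict__, "flags": tuple(best.flags) + ("below_floor",)})
        selected.append(best)
    return selected


def assemble_oligo(probe: Probe, params: DesignParams = DesignParams()) -> str:
    """Assemble the orderable single-strand oligo.

    Layout: ligation arm + linker (primer site) + UMI degenerate bases ('N' x
    umi_length) + linker (primer site) + extension arm.
    """
    if params.umi_length <= 0:
        raise ValueError("umi_length must be positive")
    return (
        probe.lig_arm_seq
        + params.linker_lig
        + "N" * params.umi_length
        + params.linker_ext
        + probe.ext_arm_seq
    )


def design_probes(
    regions: list[TargetRegion],
    reference,
    params: DesignParams = DesignParams(),
) -> list[Probe]:
    """End-to-end design: tile every region, build both-strand candidates,
    score and select one probe per window."""
    probes: list[Probe] = []
    for region in regions:
        contig_len = len(reference[region.contig])
        windows = tile_region(region, params, contig_length=contig_len)
        per_window: list[list[Probe]] = []
        for i, w in enumerate(windows):
            cands = []
            for strand in "+-":
                pid = f"{region.gene or region.contig}_{region.label or region.start}_{i}{strand}"
                try:
                    p = design_probe(w, reference, region.contig, params, strand, probe_id=pid)
                except ValueError:
                    continue
                cands.append(Probe(**{**p.__dict__, "score": score_probe(p)}))
            if cands:
                per_window.append(cands)
        probes.extend(select_probes(per_window, params))
    return probes


# --------------------------------------------------------------------------
# probe table I/O

_PROBE_COLUMNS = [
    "id", "contig", "strand", "ext_start", "ext_end", "ext_arm_seq",
    "lig_start", "lig_end", "lig_arm_seq", "gap_start", "gap_end",
    "gapfill_seq", "umi_length", "score", "relative_concentration", "flags",
]


def write_probe_table(probes: list[Probe], path) -> None:
    rows = []
    for p in probes:
        d = {k: getattr(p, k) for k in _PROBE_COLUMNS if k != "flags"}
        d["flags"] = ",".join(p.flags)
        rows.append(d)
    pd.DataFrame(rows, columns=_PROBE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_probe_table(path) -> list[Probe]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    probes = []
    for r in df.itertuples():
        probes.append(
            Probe(
                id=str(r.id), contig=r.contig, strand=r.strand,
                ext_start=int(r.ext_start), ext_end=int(r.ext_end),
                ext_arm_seq=r.ext_arm_seq,
                lig_start=int(r.lig_start), lig_end=int(r.lig_end),
                lig_arm_seq=r.lig_arm_seq,
                gap_start=int(r.gap_start), gap_end=int(r.gap_end),
                gapfill_seq=r.gapfill_seq, umi_length=int(r.umi_length),
                score=float(r.score),
                relative_concentration=float(r.relative_concentration),
                flags=tuple(f for f in str(r.flags).split(",") if f),
            )
        )
    return probes


# --------------------------------------------------------------------------
# rebalancing

@dataclass
class RebalancePlan:
    """Per-probe volume adjustment factors computed from observed depths."""

    factors: dict[str, float]
    status: dict[str, str]  # ok | boosted | reduced | failed
    params: dict = field(default_factory=dict)

    def redesign_candidates(self) -> list[str]:
        return [pid for pid, s in self.status.items() if s == "failed"]


def rebalance(
    mean_depths: dict[str, float],
    target_depth: float,
    min_factor: float = 0.25,
    max_factor: float = 4.0,
    fail_fraction: float = 0.05,
    eps: float = 1.0,
) -> RebalancePlan:
    """Compute per-probe volume factors equalising depth toward a target.

    ``factor = clip(target / max(depth, eps), min_factor, max_factor)``.
    Probes with depth below ``fail_fraction`` of the pool median are marked
    failed (factor 0): these are candidates for redesign rather than more
    volume.
    """
    if target_depth <= 0:
        raise ValueError("target depth must be positive")
    if any(d < 0 for d in mean_depths.values()):
        raise ValueError("depths must be non-negative")
    vals = sorted(mean_depths.values())
    if not vals or all(v == 0 for v in vals):
        raise ValueError("degenerate input: all probe depths are zero")
    median = vals[len(vals) // 2] if len(vals) % 2 else (
        (vals[len(vals) // 2 - 1] + vals[len(vals) // 2]) / 2
    )
    factors, status = {}, {}
    for pid, depth in mean_depths.items():
        if depth < fail_fraction * median:
            factors[pid] = 0.0
            status[pid] = "failed"
            continue
        f = target_depth / max(depth, eps)
        f = min(max(f, min_factor), max_factor)
        factors[pid] = f
        status[pid] = "ok" if abs(f - 1.0) < 1e-12 else ("boosted" if f > 1 else "reduced")
    return RebalancePlan(
        factors=factors,
        status=status,
        params=dict(
            target_depth=target_depth, min_factor=min_factor,
            max_factor=max_factor, fail_fraction=fail_fraction, eps=eps,
        ),
    )


def apply_rebalance(probes: list[Probe], plan: RebalancePlan) -> list[Probe]:
    """Return probes with relative concentrations multiplied by plan factors."""
    out = []
    for p in probes:
        f = plan.factors.get(p.id, 1.0)
        out.append(
            Probe(**{**p.__dict__, "relative_concentration": p.relative_concentration * f})
        )
    return out
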