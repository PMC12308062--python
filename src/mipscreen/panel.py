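"""Domain types for gene panels: genes, target regions, probes.

All coordinates are 0-based half-open. Published panel tables usually print
1-based inclusive coordinates; packaged fixtures are converted once at
transcription time so every arithmetic operation in the package is BED-native.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

VALID_MODES = {"AD", "AR", "XL"}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneTarget:
    """A panel gene: HGNC symbol, transcript, locus and inheritance modes."""

    symbol: str
    transcript: str
    contig: str
    start: int
    end: int
    cytoband: str = ""
    modes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"{self.symbol}: start {self.start} >= end {self.end}")
        if not self.modes:
            raise ValueError(f"{self.symbol}: modes must be non-empty")
        bad = set(self.modes) - VALID_MODES
        if bad:
            raise ValueError(f"{self.symbol}: unknown modes {sorted(bad)}")
        if "XL" in self.modes and self.contig != "chrX":
            raise ValueError(f"{self.symbol}: XL gene must be on chrX, not {self.contig}")


@dataclass(frozen=True)
class TargetRegion:
    """An interval to capture (typically a coding exon plus splice flanks)."""

    contig: str
    start: int
    end: int
    gene: str = ""
    label: str = ""

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end - self.start < 1:
            raise ValueError(f"region length < 1: {self.contig}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Probe:
    """One smMIP.

    The gap-fill interval is the captured target; the extension and ligation
    arms flank it and together are 45 nt. Arm sequences are stored in the
    orientation they appear in sequencing reads: ``ext_arm_seq`` is the prefix
    of read 1 and ``lig_arm_seq`` follows the UMI at the start of read 2.
    ``gapfill_seq`` is always the plus-strand reference sequence.
    """

    id: str
    contig: str
    strand: str
    ext_start: int
    ext_end: int
    ext_arm_seq: str
    lig_start: int
    lig_end: int
    lig_arm_seq: str
    gap_start: int
    gap_end: int
    gapfill_seq: str = ""
    backbone: str = ""
    umi_length: int = 8
    score: float = 1.0
    relative_concentration: float = 1.0
    flags: tuple[str, ...] = ()

    @property
    def arm_total(self) -> int:
        return (self.ext_end - self.ext_start) + (self.lig_end - self.lig_start)

    @property
    def gap_length(self) -> int:
        return self.gap_end - self.gap_start


@dataclass
class PanelDefinition:
    """A panel: genes, capture regions and (after design) probes."""

    genes: list[GeneTarget]
    regions: list[TargetRegion]
    probes: list[Probe] = field(default_factory=list)
    name: str = ""
    splice_flank: int = 10

    def gene(self, symbol: str) -> GeneTarget:
        for g in self.genes:
            if g.symbol == symbol:
                return g
        raise KeyError(symbol)

    @property
    def mode_map(self) -> dict[str, frozenset[str]]:
        return {g.symbol: g.modes for g in self.genes}


def _panel_fixture_path(name: str):
    res = importlib.resources.files("mipscreen") / "data" / f"panel_{name}.tsv"
    if not res.is_file():
        raise KeyError(f"unknown panel fixture: {name!r}")
    return res


def load_panel_fixture(name: str) -> PanelDefinition:
    """Load a packaged panel definition by name.

    The ``ai19`` fixture is the 19-gene amelogenesis imperfecta panel with
    per-gene inheritance modes (0-based half-open hg19 coordinates).
    """
    res = _panel_fixture_path(name)
    with res.open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    genes = [
        GeneTarget(
            symbol=r.symbol,
            transcript=r.transcript,
            contig=r.contig,
            start=int(r.start),
            end=int(r.end),
            cytoband=r.cytoband,
            modes=frozenset(str(r.modes).split(",")),
        )
        for r in df.itertuples()
    ]
    panel = PanelDefinition(genes=genes, regions=[], name=name)
    violations = validate_panel(panel)
    if violations:
        raise ValueError(f"fixture {name!r} fails validation: {violations}")
    return panel


def read_bed(path) -> list[TargetRegion]:
    """Parse a 3+-column BED file (0-based half-open) into target regions.

    The name column, when present, is interpreted as ``GENE|label``.
    Malformed lines raise ``ValueError`` naming the offending line number.
    """
    regions: list[TargetRegion] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: expected >=3 BED columns")
            contig = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"line {lineno}: non-integer coordinate") from None
            if start < 0:
                raise ValueError(f"line {lineno}: negative start {start}")
            if start >= end:
                raise ValueError(f"line {lineno}: start {start} >= end {end}")
            gene, label = "", ""
            if len(fields) >= 4 and fields[3] != ".":
                gene, _, label = fields[3].partition("|")
            regions.append(TargetRegion(contig, start, end, gene=gene, label=label))
    return regions


def write_bed(regions: list[TargetRegion], path) -> None:
    """Write regions as 4-column BED (name = ``GENE|label``)."""
    with open(path, "w") as fh:
        for r in regions:
            name = f"{r.gene}|{r.label}" if (r.gene or r.label) else "."
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{name}\n")


@dataclass(frozen=True)
class Violation:
    entity: str
    rule: str
    detail: str = ""


def validate_panel(panel: PanelDefinition) -> list[Violation]:
    """Check all panel invariants; violations are returned as data, never raised."""
    out: list[Violation] = []
    seen_symbols: set[str] = set()
    for g in panel.genes:
        if g.symbol in seen_symbols:
            out.append(Violation(g.symbol, "duplicate_gene_symbol"))
        seen_symbols.add(g.symbol)

    seen_regions: set[tuple] = set()
    for r in panel.regions:
        key = (r.contig, r.start, r.end)
        if key in seen_regions:
            out.append(Violation(f"{r.contig}:{r.start}-{r.end}", "duplicate_region"))
        seen_regions.add(key)
        if r.gene and r.gene not in seen_symbols:
            out.append(
                Violation(f"{r.contig}:{r.start}-{r.end}", "region_gene_missing", r.gene)
            )

    for p in panel.probes:
        if p.arm_total != 45:
            out.append(Violation(p.id, "arm_total_not_45", str(p.arm_total)))
        if p.gap_length > 110:
            out.append(Violation(p.id, "gapfill_exceeds_110", str(p.gap_length)))
        if not (0.0 <= p.score <= 1.0):
            out.append(Violation(p.id, "score_out_of_range", str(p.score)))
        if p.ext_end > p.gap_start and p.ext_start < p.gap_end:
            out.append(Violation(p.id, "extension_arm_overlaps_gapfill"))
        if p.lig_end > p.gap_start and p.lig_start < p.gap_end:
            out.append(Violation(p.id, "ligation_arm_overlaps_gapfill"))
        if panel.regions and not any(
            r.contig == p.contig and p.gap_start < r.end and r.start < p.gap_end
            for r in panel.regions
        ):
            out.append(Violation(p.id, "probe_outside_all_regions"))
    return out
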