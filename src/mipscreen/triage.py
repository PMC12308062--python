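"""Variant triage: annotation, the CADD/allele-frequency cascade, HGVS
consequence classification, gene-specific rules, inheritance-mode assembly
and cohort summarisation.

The cascade excludes a variant when its CADD score is below 15 (strictly) or
its population minor allele frequency exceeds the zygosity-dependent
threshold: 0.01 for biallelic context (homozygous, or a member of a putative
compound-heterozygous pair), 0.001 for monoallelic context (a lone
heterozygote) and for hemizygous X variants. Absent frequency counts as 0;
an unscored CADD passes the CADD test (many qualifying frameshifts carry no
score). Every exclusion records exactly one first-failing rule so the kept
set can be reproduced by replaying provenance.
"""

from __future__ import annotations

import importlib.resources
import math
import re
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from mipscreen.calling import VariantCall

COHORT_FIXTURE_SIZE = 181  # probands screened in the packaged cohort


@dataclass(frozen=True)
class TriageParams:
    cadd_min: float = 15.0
    maf_biallelic_max: float = 0.01
    maf_monoallelic_max: float = 0.001
    depth_threshold: int = 20

    def __post_init__(self):
        if not (0 < self.maf_monoallelic_max <= self.maf_biallelic_max):
            raise ValueError("need 0 < maf_monoallelic_max <= maf_biallelic_max")


@dataclass(frozen=True)
class AnnotationRecord:
    contig: str
    position: int  # 1-based, matching printed genomic nomenclature
    ref: str
    alt: str
    gene: str = ""
    cadd: float | None = None
    gnomad_af: float | None = None
    hgvs_c: str = ""
    hgvs_p: str = ""

    @property
    def key(self) -> tuple:
        return (self.contig, self.position, self.ref, self.alt)


@dataclass
class AnnotatedVariant:
    call: VariantCall
    annotation: AnnotationRecord | None

    @property
    def unannotated(self) -> bool:
        return self.annotation is None


def annotate(
    calls: list[VariantCall], records: list[AnnotationRecord]
) -> list[AnnotatedVariant]:
    """Left-join calls onto an annotation table keyed by (contig, pos, ref, alt)."""
    table: dict[tuple, AnnotationRecord] = {}
    for r in records:
        if r.key in table:
            raise ValueError(f"duplicate annotation key {r.key}")
        table[r.key] = r
    out = []
    for c in calls:
        key = (c.contig, c.position + 1, c.ref, c.alt)
        out.append(AnnotatedVariant(call=c, annotation=table.get(key)))
    return out


# --------------------------------------------------------------------------
# consequence classification

CONSEQUENCE_CLASSES = (
    "missense",
    "nonsense",
    "frameshift",
    "splice",
    "large_deletion",
    "other",
)

_MISSENSE_RE = re.compile(r"^p\.\(?([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})\)?$")
_INTRON_OFFSET_RE = re.compile(r"c\.[\d_*+-]*\d[+-]\d+")


def classify_consequence(
    hgvs_c: str, hgvs_p: str, structural: bool = False
) -> str:
    """Classify one variant from its HGVS strings.

    Precedence: structural > frameshift > nonsense > splice > missense >
    other. A frameshift is any protein change carrying an ``fs``
    designation; a nonsense change introduces a termination codon without
    frameshifting; splice variants carry an intronic offset in the cDNA
    position (or an unknown ``p.?`` protein with such a cDNA change).
    """
    if structural:
        return "large_deletion"
    p = (hgvs_p or "").replace("∗", "*").strip()
    c = (hgvs_c or "").strip()
    if "fs" in p:
        return "frameshift"
    if "*" in p or "Ter" in p:
        return "nonsense"
    if _INTRON_OFFSET_RE.search(c):
        return "splice"
    m = _MISSENSE_RE.match(p)
    if m and m.group(1) != m.group(3):
        return "missense"
    return "other"


# --------------------------------------------------------------------------
# filter cascade

def frequency_cadd_filter(
    cadd: float | None,
    gnomad_af: float | None,
    context: str,
    params: TriageParams = TriageParams(),
) -> tuple[bool, str | None]:
    """Apply the CADD and zygosity-aware MAF rules.

    ``context`` is ``biallelic``, ``monoallelic`` or ``hemizygous``.
    Returns (keep, first_failing_rule). Inequalities are strict on both
    sides: CADD exactly at the floor is kept; frequency exactly at a
    threshold is kept.
    """
    if context not in ("biallelic", "monoallelic", "hemizygous"):
        raise ValueError(f"bad zygosity context {context!r}")
    if cadd is not None and not math.isnan(cadd) and cadd < params.cadd_min:
        return False, "cadd_below_min"
    af = 0.0 if gnomad_af is None or (isinstance(gnomad_af, float) and math.isnan(gnomad_af)) else gnomad_af
    if context == "biallelic":
        if af > params.maf_biallelic_max:
            return False, "maf_above_biallelic_max"
    else:
        if af > params.maf_monoallelic_max:
            return False, "maf_above_monoallelic_max"
    return True, None


# --------------------------------------------------------------------------
# gene-specific rules

@dataclass(frozen=True)
class GeneRule:
    gene: str
    rule: str
    contig: str
    start: int
    end: int


def load_gene_rules() -> list[GeneRule]:
    res = importlib.resources.files("mipscreen") / "data" / "gene_rules.tsv"
    with res.open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    return [
        GeneRule(r.gene, r.rule, r.contig, int(r.start), int(r.end))
        for r in df.itertuples()
    ]


_GENOMIC_POS_RE = re.compile(r"^(chr[\dXYM]+):g\.(\d+)")


def genomic_position(genomic: str) -> tuple[str, int] | None:
    """(contig, 1-based position) from a genomic HGVS string, if parseable."""
    m = _GENOMIC_POS_RE.match(genomic or "")
    if not m:
        return None
    return m.group(1), int(m.group(2))


def apply_gene_rules(
    gene: str,
    consequence: str,
    genomic: str,
    rules: list[GeneRule] | None = None,
) -> tuple[bool, str | None]:
    """Gene-specific qualification. Currently one rule class:
    ``truncating_last_exon`` — truncating variants in the named gene qualify
    only inside the configured last-exon interval."""
    if rules is None:
        rules = load_gene_rules()
    for rule in rules:
        if rule.gene != gene or rule.rule != "truncating_last_exon":
            continue
        if consequence not in ("nonsense", "frameshift"):
            continue
        pos = genomic_position(genomic)
        if pos is None:
            continue
        contig, pos1 = pos
        inside = contig == rule.contig and rule.start < pos1 <= rule.end
        if not inside:
            return False, "gene_rule_failed"
    return True, None


# --------------------------------------------------------------------------
# cohort fixture

@dataclass
class CohortFixture:
    """The packaged family-level cohort: one row per variant per family."""

    variants: pd.DataFrame
    n_families_screened: int = COHORT_FIXTURE_SIZE

    @property
    def primary_gene(self) -> dict[str, str]:
        prim = self.variants[self.variants["primary"] == 1]
        return dict(zip(prim["family_id"], prim["gene"]))


def load_reported_cohort() -> CohortFixture:
    """Load the packaged cohort fixture (181 probands screened; variant rows
    for the families in which candidate variants were identified)."""
    res = importlib.resources.files("mipscreen") / "data" / "cohort_ai181.tsv"
    with res.open() as fh:
        df = pd.read_csv(
            fh, sep="\t", comment="#",
            dtype={"family_id": str, "structural": int, "primary": int},
        )
    return CohortFixture(variants=df)


def load_fam83h_example() -> pd.DataFrame:
    res = importlib.resources.files("mipscreen") / "data" / "example_fam83h_c601.tsv"
    with res.open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#", dtype={"family_id": str})


# --------------------------------------------------------------------------
# inheritance-mode assembly

@dataclass
class DiagnosisCandidate:
    family: str
    gene: str
    mode: str  # XL | AD | AR
    variants: list[dict] = field(default_factory=list)
    status: str = "candidate"  # solved | candidate
    flags: tuple[str, ...] = ()
    provenance: list[tuple[str, str]] = field(default_factory=list)


def zygosity_context(zygosity: str, n_het_in_gene: int) -> str:
    """The MAF-threshold context of one variant given its family-gene group."""
    if zygosity == "hom":
        return "biallelic"
    if zygosity == "hemi":
        return "hemizygous"
    return "biallelic" if n_het_in_gene >= 2 else "monoallelic"


def run_filter_cascade(
    variants: pd.DataFrame,
    params: TriageParams = TriageParams(),
    rules: list[GeneRule] | None = None,
) -> pd.DataFrame:
    """Classify and filter a variant table.

    Input columns: family_id, gene, genomic, hgvs_c, hgvs_p, zygosity,
    cadd, gnomad_af, structural (optional). Adds ``consequence``, ``kept``
    and ``rule`` (first failing rule for excluded variants) columns.
    """
    if rules is None:
        rules = load_gene_rules()
    df = variants.copy()
    if "structural" not in df.columns:
        df["structural"] = 0
    df["consequence"] = [
        classify_consequence(
            r.hgvs_c if isinstance(r.hgvs_c, str) else "",
            r.hgvs_p if isinstance(r.hgvs_p, str) else "",
            bool(r.structural),
        )
        for r in df.itertuples()
    ]
    het_counts = Counter()
    for r in df.itertuples():
        if r.zygosity == "het":
            het_counts[(r.family_id, r.gene)] += 1
    kept, rule_col, context_col = [], [], []
    for r in df.itertuples():
        ctx = zygosity_context(r.zygosity, het_counts[(r.family_id, r.gene)])
        context_col.append(ctx)
        cadd = None if pd.isna(r.cadd) else float(r.cadd)
        af = None if pd.isna(r.gnomad_af) else float(r.gnomad_af)
        ok, why = frequency_cadd_filter(cadd, af, ctx, params)
        if ok:
            ok, why = apply_gene_rules(r.gene, df.loc[r.Index, "consequence"], r.genomic, rules)
        kept.append(ok)
        rule_col.append(why or "")
    df["context"] = context_col
    df["kept"] = kept
    df["rule"] = rule_col
    return df


def assemble_diagnoses(
    filtered: pd.DataFrame,
    mode_map: dict[str, frozenset[str] | set[str]],
    sexes: dict[str, str] | None = None,
) -> tuple[list[DiagnosisCandidate], list[dict]]:
    """Build per-family gene-level diagnosis candidates from kept variants.

    Per family and gene: a qualifying variant in the X-linked gene (het in a
    female, hemi in a male) is an XL candidate; a homozygote or >= 2
    heterozygotes in an AR-capable gene is an AR candidate (compound hets
    flagged ``unphased``); a lone heterozygote in an AD-capable gene is an
    AD candidate; a lone heterozygote in an AR-only gene is a carrier note.
    Returns (candidates, carrier_notes).
    """
    sexes = sexes or {}
    candidates: list[DiagnosisCandidate] = []
    carriers: list[dict] = []
    kept = filtered[filtered["kept"]]
    for (family, gene), group in kept.groupby(["family_id", "gene"], sort=True):
        if gene not in mode_map:
            raise ValueError(f"unknown gene symbol {gene!r}")
        modes = set(mode_map[gene])
        rows = group.to_dict("records")
        zygs = [r["zygosity"] for r in rows]
        n_het = sum(z == "het" for z in zygs)
        has_hom = any(z == "hom" for z in zygs)
        has_hemi = any(z == "hemi" for z in zygs)
        status = "solved" if any(
            str(r.get("classification", "")) in ("P", "LP") for r in rows
        ) else "candidate"
        prov = [(r["genomic"], "kept") for r in rows]
        if "XL" in modes:
            candidates.append(
                DiagnosisCandidate(
                    family=family, gene=gene, mode="XL", variants=rows,
                    status=status, provenance=prov,
                )
            )
        elif "AR" in modes and (has_hom or n_het >= 2):
            flags = ("unphased",) if (n_het >= 2 and not has_hom) else ()
            candidates.append(
                DiagnosisCandidate(
                    family=family, gene=gene, mode="AR", variants=rows,
                    status=status, flags=flags, provenance=prov,
                )
            )
        elif "AD" in modes and (n_het >= 1 or has_hom):
            candidates.append(
                DiagnosisCandidate(
                    family=family, gene=gene, mode="AD", variants=rows,
                    status=status, provenance=prov,
                )
            )
        elif n_het == 1 and modes == {"AR"}:
            carriers.append({"family_id": family, "gene": gene, "variant": rows[0]})
        elif has_hemi and "AR" in modes:
            # autosomal hemizygosity cannot arise; record as carrier-grade
            carriers.append({"family_id": family, "gene": gene, "variant": rows[0]})
    return candidates, carriers


def digenic_report(candidates: list[DiagnosisCandidate],
                   primary_gene: dict[str, str] | None = None) -> pd.DataFrame:
    """Families with qualifying candidates in two or more genes."""
    by_family: dict[str, list[DiagnosisCandidate]] = {}
    for c in candidates:
        by_family.setdefault(c.family, []).append(c)
    rows = []
    for family in sorted(by_family, key=str):
        cands = by_family[family]
        genes = sorted({c.gene for c in cands})
        if len(genes) < 2:
            continue
        rows.append(
            {
                "family_id": family,
                "genes": ",".join(genes),
                "primary_gene": (primary_gene or {}).get(family, ""),
                "modes": ",".join(f"{c.gene}:{c.mode}" for c in sorted(cands, key=lambda x: x.gene)),
            }
        )
    return pd.DataFrame(rows, columns=["family_id", "genes", "primary_gene", "modes"])


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def summarize_cohort(
    candidates: list[DiagnosisCandidate],
    cohort_size: int,
    primary_gene: dict[str, str] | None = None,
) -> dict:
    """Cohort-level summary of assembled diagnoses.

    When a family has candidates in several genes, its diagnostic mode and
    gene are taken from the designated primary gene; distinct variants are
    deduplicated by genomic key over primary candidates only.
    """
    if cohort_size <= 0:
        raise ValueError("cohort size must be positive")
    primary_gene = primary_gene or {}
    by_family: dict[str, list[DiagnosisCandidate]] = {}
    for c in candidates:
        by_family.setdefault(c.family, []).append(c)
    solved = len(by_family)
    mode_counts: Counter = Counter()
    gene_counts: Counter = Counter()
    distinct: dict[str, str] = {}  # genomic key -> consequence
    for family, cands in by_family.items():
        primary = None
        if family in primary_gene:
            for c in cands:
                if c.gene == primary_gene[family]:
                    primary = c
                    break
        if primary is None:
            primary = sorted(cands, key=lambda c: c.gene)[0]
        mode_counts[primary.mode] += 1
        gene_counts[primary.gene] += 1
        for v in primary.variants:
            distinct[v["genomic"]] = v["consequence"]
    class_counts = Counter(distinct.values())
    return {
        "solved_families": solved,
        "cohort_size": cohort_size,
        "solved_percent": _round_half_away(100.0 * solved / cohort_size),
        "mode_counts": dict(mode_counts),
        "gene_counts": dict(
            sorted(gene_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ),
        "distinct_variants": len(distinct),
        "consequence_counts": dict(
            sorted(class_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ),
    }


def triage_cohort_fixture(
    params: TriageParams = TriageParams(),
) -> tuple[pd.DataFrame, list[DiagnosisCandidate], pd.DataFrame, dict]:
    """Replay the full triage cascade over the packaged cohort fixture.

    Returns (filtered variant table, candidates, digenic report, summary).
    """
    from mipscreen.panel import load_panel_fixture

    fixture = load_reported_cohort()
    panel = load_panel_fixture("ai19")
    filtered = run_filter_cascade(fixture.variants, params)
    sexes = dict(zip(fixture.variants["family_id"], fixture.variants["sex"]))
    candidates, _carriers = assemble_diagnoses(filtered, panel.mode_map, sexes)
    digenic = digenic_report(candidates, fixture.primary_gene)
    summary = summarize_cohort(
        candidates, fixture.n_families_screened, fixture.primary_gene
    )
    summary["digenic_families"] = len(digenic)
    summary["panel_genes"] = len(panel.genes)
    return filtered, candidates, digenic, summary
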