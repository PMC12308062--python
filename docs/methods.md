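# Methods

## Overview

`mipscreen` models a targeted screening workflow built on single-molecule
molecular inversion probes (smMIPs). An smMIP is a single-stranded oligo
whose two target-complementary ends — the extension and ligation arms —
hybridise on either side of a genomic gap-fill region. Polymerase fills the
gap, ligase circularises the product, and PCR through universal primer sites
in the probe backbone amplifies it. A degenerate 8-nt stretch in the
backbone acts as a unique molecular identifier (UMI): every captured
molecule carries its own random tag, so PCR duplicates can be collapsed
exactly and sequencing errors suppressed by per-molecule consensus.

Coordinates are 0-based half-open throughout the package; published 1-based
inclusive coordinates are converted once when fixtures are transcribed.
VCF output converts to 1-based positions at the boundary.

## Probe design

Regions are tiled into gap-fill windows of 110 nt with a step of
`gap_fill_length − min_overlap` (default 100), giving `⌈(L−110)/100⌉ + 1`
windows for a region of length L > 110 and guaranteeing at least 10 bp of
overlap between adjacent windows. Windows are spread evenly so the first
starts at the region start and the last ends at the region end. Regions
shorter than one window receive a single window centred on the region, with
flanks drawn from the reference — a necessary convention for short exons.

Arms total 45 nt, split 21 (extension) / 24 (ligation) by default; the
split is configurable but the total is enforced as an invariant. For each
window, candidates on both strands are scored and one is selected per
window: highest score wins, ties break to the plus strand and then the
leftmost start, so designs are byte-reproducible. Candidates below the 0.5
score floor are kept only when no candidate reaches it, and are flagged
`below_floor` — mirroring the practice of accepting lower-quality probes in
difficult genomic regions rather than leaving coverage gaps.

### Scoring

The score is a transparent logistic stand-in:

    score = σ(2.0 − 6.0·|GC_arms − 0.5| − 4.0·|GC_target − 0.5|
              − 0.3·maxHomopolymerRun)

It reproduces the qualitative behaviour of logistic probe-quality models —
values in [0, 1], penalties for GC skew and homopolymers, a meaningful 0.5
threshold (an ideal probe scores 0.85; a 0%-GC arm falls below 0.3) — but
its values are not comparable to any external design tool's output. The
coefficients are fixed constants, documented here and in the code.

### Oligo assembly

The orderable oligo is `ligation arm + linker + N×8 + linker + extension
arm`. The two linker halves (20 + 17 nt) are fixed package constants
standing in for universal PCR primer sites; with default arms the oligo is
90 nt (82 nt of backbone-plus-arms plus the 8-nt UMI). Users ordering real
reagents substitute their own primer sites.

### Rebalancing

Pool rebalancing computes per-probe volume factors
`clip(target_depth / max(depth, 1), 0.25, 4.0)` from observed mean depths.
Probes below 5% of the pool median depth are marked failed (factor 0) and
listed as redesign candidates — more volume does not rescue a probe whose
arms do not capture. The bounds, ε = 1 and the 5% failure fraction are
package defaults chosen to keep single-round corrections conservative;
rebalancing is intended to be iterated.

## Capture simulation

The simulator is first-class, tested code: it defines the conditions under
which every downstream stage is validated.

- Per-probe unique molecule count ~ Poisson(mean × efficiency × relative
  concentration × copies/2). The default mean is 100 molecules per probe,
  comparable to a well-covered targeted run after deduplication.
- Capture efficiency is log-normal (σ = 0.5 by default) and
  **probe-intrinsic**: it is derived deterministically from the probe id and
  an efficiency seed, not redrawn per sample. This reflects the empirical
  fact that a probe's capture performance is a property of its arms, and it
  is precisely what makes rebalancing and reference-cohort CNV
  normalisation meaningful. The σ value is a free parameter of the
  simulator, not an estimate from any particular reagent.
- Each molecule draws an independent UMI uniform over 4^8 and emits
  Geometric(p) read pairs (default p = 0.5, i.e. one duplicate per molecule
  on average).
- Read 1 is the extension-arm side of the capture; read 2 begins with the
  UMI, then the ligation arm, then the target from the opposite end. Reads
  are 150 bp; substitution errors are i.i.d. per base (default 10⁻³).
  Qualities are constant placeholders. Sequencer indels are deliberately
  not simulated so the truth ledger stays exact — indels enter only through
  planted haplotype variants.
- Planted variants: het variants sit on one haplotype, hom on both, hemi on
  the single X haplotype of an XY sample (chrX in XY samples captures half
  the molecules of an autosome). CNV deletions zero out one (het) or both
  (hom) haplotype contributions of every probe whose gap-fill intersects
  the span.
- Determinism: identical seeds give byte-identical FASTQ. Cohorts split a
  seed stream per sample via `SeedSequence.spawn`.

What the simulator does **not** emulate: strand bias, index hopping,
polymerase slippage, per-cycle quality decay, GC-dependent amplification,
and arm-indel chemistry. Tests passing under simulation therefore validate
the algorithmic contracts (dedup, consensus, genotyping arithmetic,
depth-ratio CNV logic) — not performance on any real library.

## Read processing

Genome alignment is replaced by arm-anchored probe assignment: each read
pair is assigned to the unique probe whose arm sequences match the read
termini with at most 2 mismatches (Hamming distance at fixed offsets; an
exact-match fast path covers the overwhelming majority of reads). Ties and
non-matches are unassigned. Since every probe carries genomic coordinates,
position follows from assignment; off-target reads simply never match.
This is the package's largest simplification relative to an
alignment-based pipeline, and it forgoes indel-tolerant arm matching — a
read with an indel inside an arm is lost, not recovered.

Arm trimming recovers the target sequence from read 1 by locating the
trailing-arm anchor (first 12 bases of the opposite arm as it appears in
the read), so molecules carrying small indels are trimmed at their true
boundary; when the anchor is absent the expected fixed offset is used.
Arm-derived bases never reach a pileup.

Duplicate groups (probe id, UMI) are collapsed to a consensus — majority
base per position, ties broken by summed base quality then the reference
base — rather than merely marking duplicates: equivalent for counting,
strictly better for error suppression. Group members whose length differs
from the modal length (e.g. an errored read in an indel molecule's group)
are excluded from the base vote but counted in `n_reads`. UMI collisions
(two molecules, same probe, same tag) merge silently; at 100 molecules per
probe against 65,536 tags this affects < 0.1% of molecules.

Coverage breadth is the fraction of target bases with consensus depth
strictly greater than the threshold (default 20), reported per gene and
panel-wide.

## Variant calling

The small-variant caller is a pileup over consensus fragments — local
reassembly is unnecessary because fragments are short, arm-trimmed and
probe-anchored. Fragments whose consensus length differs from the gap-fill
are explained as a single clean indel via prefix/suffix decomposition and
left-aligned by shifting while the flanking base matches (verified against
a brute-force enumeration of equivalent placements in the tests); fragments
explicable only by multiple events are skipped. Indel alleles are anchored
VCF-style on the base to the left (or right at offset 0).

Genotype thresholds: minimum depth 8; alt fraction ≥ 0.85 calls hom (hemi
on chrX in XY samples); [0.25, 0.75] calls het; (0.75, 0.85) is emitted
flagged ambiguous; below 0.25 is treated as noise. These are package
choices tuned for consensus depths of tens to hundreds, where binomial
noise keeps true hets well inside the window.

The CNV caller computes, per probe, the test sample's depth divided by the
median library-normalised depth across ≥ 3 reference samples, then rescales
by the median per-probe ratio — a robust library-size correction that keeps
unaffected probes at ratio 1 even when a deletion removes a sizeable slice
of the panel (it breaks down if more than half the panel is deleted).
Probes with zero reference median are masked. Runs of ≥ 3 consecutive
probes (within a gene, in genomic order) at ratio < 0.65 (het loss),
< 0.10 (hom loss) or > 1.40 (gain) become segments. A run-length rule over
median ratios was chosen over a likelihood model: at panel scale, with
probe-intrinsic efficiency cancelling in the ratio, the extra machinery
buys little and the rule is auditable.

## Triage

The cascade applies, in order: the CADD rule, the MAF rule, then gene
rules; the first failing rule is recorded, so exclusions have exactly one
cause and replaying the provenance reproduces the kept set.

- CADD < 15 excludes (strictly: a score of exactly 15 is kept). Missing
  scores pass — deleteriousness scores are routinely absent for
  frameshifts whose pathogenicity is not in question.
- The MAF threshold depends on the variant's zygosity context **in the
  candidate genotype**: homozygotes and members of putative
  compound-heterozygous pairs use 0.01; lone heterozygotes use 0.001;
  hemizygous X variants use the monoallelic threshold. Context is fixed by
  the pre-filter grouping so the cascade stays order-independent. Missing
  frequency counts as 0 (absence from population databases is evidence of
  rarity). Thresholds are strict: a biallelic variant at exactly 0.01 is
  kept.
- Gene rules: FAM83H truncating variants (nonsense/frameshift) qualify only
  inside the configured last-coding-exon interval — premature termination
  early in FAM83H does not cause dominant enamel disease, so a recurrent
  early-exon stop-gain is excluded however deleterious its score. The
  interval ships in `data/gene_rules.tsv` against the panel transcript.

Consequence classification parses HGVS strings with precedence structural >
frameshift > nonsense > splice > missense > other. Splice detection keys on
an intronic offset in the cDNA position (e.g. `c.954-2A>T`); an exonic
stop-gain such as `c.1083G>A p.(Trp361*)` therefore classifies as nonsense
even though it may also affect splicing in vivo.

Inheritance assembly per family and gene: any qualifying variant in the
X-linked gene → XL candidate; a homozygote or ≥ 2 heterozygotes in an
AR-capable gene → AR candidate (compound hets flagged `unphased` — without
parental genotypes, trans configuration is assumed, not demonstrated); a
lone heterozygote in an AD-capable gene → AD candidate; a lone heterozygote
in an AR-only gene → carrier note, family unsolved. Dual-mode genes
(ENAM, AMBN) resolve by genotype: biallelic → AR, monoallelic → AD.

When a family has candidates in two genes (the digenic report), its
diagnostic mode, gene and variants come from the designated primary gene;
the cohort's distinct-variant count deduplicates by genomic key over
primary candidates only. ACMG classifications in the fixtures are carried
as read-only labels — the package implements no classification engine —
and the solved percentage rounds half away from zero.

## Fixtures

`data/panel_ai19.tsv` defines the 19 AI genes with transcripts, loci,
cytobands and per-gene inheritance modes (AD: COL17A1, FAM83H, DLX3, LAMB3,
SP6, AMTN; AR: MMP20, WDR72, ACP4, FAM20A, SLC24A4, RELT, ITGB6, KLK4,
ODAPH, GPR68; AD+AR: ENAM, AMBN; XL: AMELX). It ships no probe set: probe
composition is always an output of design over supplied regions, and the
physical reagent's empirical per-probe performance is out of scope.

`data/cohort_ai181.tsv` is the variant-level record of a 181-proband
screening cohort: 63 solved families across X-linked, dominant and
recessive tables, plus the second-gene findings of four digenic families
(flagged non-primary). Obvious typographical slips in the source
nomenclature were normalised at transcription; recurrent variants keep the
per-family score/frequency values printed in their own rows.
`data/example_fam83h_c601.tsv` packages the FAM83H early-exon stop-gain
counter-example; its genomic coordinate is a synthetic placement inside
exon 3 (the file says so).

## Problem sizes and numerical choices

The test suite runs its simulation-backed checks on a two-gene synthetic
panel (13 probes over three exon-like regions, ~100 molecules per probe),
sizes at which the binomial/Poisson assertions have comfortable power while
the whole suite stays fast: dedup oracle equivalence on ≥ 10⁴ reads,
genotype recovery over 20 seeds, CNV null specificity over 10 seeds,
rebalancing efficacy over 5 seeds. Degenerate inputs fail loudly and
early: empty candidate sets, all-zero depth pools, zero-size cohorts and
fewer than three CNV references are errors, not silent defaults; low-depth
variant sites are counted no-calls.

## Known limitations

- Arm matching is substitution-only; indels in arms lose the read.
- The pileup caller handles one clean indel per fragment; complex alleles
  (MNVs, indel+SNV on one molecule) are dropped from pileups.
- The CNV caller needs ≥ 3 reference samples, ≥ 3 affected probes, and a
  majority of the panel at normal copy number; single-probe events and
  whole-panel aneuploidy are invisible.
- No UMI error-correction network: a UMI sequencing error creates a
  spurious singleton molecule rather than rejoining its group.
- Compound-heterozygous candidates are unphased assumptions pending
  segregation data; no pedigree likelihood is computed.
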