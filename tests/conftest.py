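import pytest

from mipscreen.design import design_probes
from mipscreen.panel import GeneTarget, PanelDefinition, TargetRegion
from mipscreen.simulate import random_reference


@pytest.fixture(scope="session")
def reference():
    """Synthetic two-contig reference (an autosome and a chrX stand-in)."""
    return random_reference({"chr1": 8000, "chrX": 4000}, seed=11)


@pytest.fixture(scope="session")
def small_panel(reference):
    """A two-gene synthetic panel with designed probes.

    G1 spans two autosomal exon-like regions; GX is a chrX gene, so
    hemizygous genotypes can be exercised.
    """
    genes = [
        GeneTarget("G1", "NM_0001.1", "chr1", 500, 7500, modes=frozenset({"AD", "AR"})),
        GeneTarget("GX", "NM_0002.1", "chrX", 500, 3500, modes=frozenset({"XL"})),
    ]
    regions = [
        TargetRegion("chr1", 1000, 1800, gene="G1", label="ex1"),
        TargetRegion("chr1", 3000, 3500, gene="G1", label="ex2"),
        TargetRegion("chrX", 1000, 1400, gene="GX", label="ex1"),
    ]
    probes = design_probes(regions, reference)
    return PanelDefinition(genes=genes, regions=regions, probes=probes)
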