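import pytest

from macrosynt.genome_model import GenomeAnnotation
from macrosynt.orthology import OrthologMap
from macrosynt.synthetic_data import EventPlan, simulate_pair


def make_annotation(label, scaffold_genes, gene_len=100, gap=50):
    """Small annotation builder: {scaffold_id: [(gene_id, strand), ...]}."""
    scaffolds = []
    loci = []
    for sid, genes in scaffold_genes.items():
        pos = 0
        for gene_id, strand in genes:
            pos += gap
            loci.append((gene_id, sid, pos, pos + gene_len, strand))
            pos += gene_len
        scaffolds.append((sid, pos + gap))
    return GenomeAnnotation.from_loci(label, scaffolds, loci)


@pytest.fixture
def identity_pair():
    """3 scaffolds x 10 genes, no events: perfect synteny and colinearity."""
    return simulate_pair(3, 10, EventPlan(), EventPlan(), seed=11)


@pytest.fixture
def two_genome_identity():
    """Two hand-built genomes with an identity-structured ortholog map."""
    a = make_annotation(
        "A", {"a1": [(f"g{i}", "+") for i in range(4)],
              "a2": [(f"g{i}", "+") for i in range(4, 10)]}
    )
    b = make_annotation(
        "B", {"b1": [(f"h{i}", "+") for i in range(4)],
              "b2": [(f"h{i}", "+") for i in range(4, 10)]}
    )
    omap = OrthologMap([(f"g{i}", f"h{i}") for i in range(10)])
    return a, b, omap
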