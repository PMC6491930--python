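import numpy as np
import pytest

from amix.ancestry_io import AncestryGenotypeMatrix, AncestrySegment, GeneAnnotation
from amix.synthetic_admixture import generate_fixture_dataset


def make_matrix(cells, population_id="pop"):
    """Build a genotype matrix from nested cell lists.

    ``cells[g][i]`` is a tuple of 0-2 ancestry labels, e.g. ("AFR", "EUR"),
    ("EUR",) or ().
    """
    from amix.ancestry_io import ANCESTRY_CODE, MISSING

    genes = [f"G{g + 1}" for g in range(len(cells))]
    n = len(cells[0])
    individuals = [f"ind{i + 1}" for i in range(n)]
    haps = np.full((len(cells), n, 2), MISSING, dtype=np.int8)
    for g, row in enumerate(cells):
        for i, cell in enumerate(row):
            for h, label in enumerate(cell):
                haps[g, i, h] = ANCESTRY_CODE[label]
    return AncestryGenotypeMatrix(population_id, genes, individuals, haps)


@pytest.fixture
def toy_segments():
    """Two individuals, one chromosome, mixed certainties."""
    return [
        AncestrySegment("ind1", 0, "chr1", 0, 10_000, "AFR", 0.999),
        AncestrySegment("ind1", 1, "chr1", 0, 4_000, "EUR", 0.995),
        AncestrySegment("ind1", 1, "chr1", 4_000, 10_000, "NAT", 0.999),
        AncestrySegment("ind2", 0, "chr1", 0, 10_000, "EUR", 0.98),
        AncestrySegment("ind2", 1, "chr1", 0, 10_000, "EUR", 1.0),
    ]


@pytest.fixture
def toy_genes():
    return [
        GeneAnnotation("GENE_A", "chr1", 1_000, 2_000),
        GeneAnnotation("GENE_B", "chr1", 3_500, 4_500),
        GeneAnnotation("GENE_C", "chr1", 6_000, 7_000),
    ]


@pytest.fixture(scope="session")
def fixture_dataset(tmp_path_factory):
    """The simulator's standard small 4-population dataset."""
    outdir = tmp_path_factory.mktemp("fixture")
    info = generate_fixture_dataset(outdir, seed=7)
    return outdir, info
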