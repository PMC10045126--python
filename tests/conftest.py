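import numpy as np
import pytest

from chukarpop.io_formats import GenotypeMatrix, PopulationMap, SequenceAlignment


@pytest.fixture
def toy_alignment():
    """4 sequences, 10 bp, haplotype frequencies {2, 1, 1}."""
    seqs = [
        "ACGTACGTAC",
        "ACGTACGTAC",
        "ACGTACGTAT",  # 1 diff from hap A
        "ACGAACGTAT",  # 2 diffs from hap A
    ]
    return SequenceAlignment(
        [f"s{i}" for i in range(4)], seqs, ["p1", "p1", "p2", "p2"]
    )


@pytest.fixture
def two_pop_alignment():
    """Two populations fixed for distinct haplotypes (3 + 3)."""
    a = "AAAAAAAAAA"
    b = "AAAAAAAATT"
    return SequenceAlignment(
        [f"s{i}" for i in range(6)],
        [a, a, a, b, b, b],
        ["p1"] * 3 + ["p2"] * 3,
    )


@pytest.fixture
def toy_genotypes():
    """2 populations x 3 individuals x 2 loci, one missing genotype."""
    alleles = np.array(
        [
            [[120, 140], [100, 100]],
            [[120, 120], [100, 102]],
            [[140, 140], [0, 0]],
            [[150, 150], [104, 104]],
            [[150, 152], [104, 104]],
            [[152, 152], [104, 106]],
        ]
    )
    return GenotypeMatrix(
        [f"i{k}" for k in range(6)],
        ["locA", "locB"],
        alleles,
        ["p1"] * 3 + ["p2"] * 3,
    )


@pytest.fixture
def square_popmap():
    return PopulationMap(
        ["a", "b", "c", "d"],
        ["A", "B", "C", "D"],
        np.array([30.0, 31.0, 31.0, 30.0]),
        np.array([38.0, 38.0, 39.0, 39.0]),
    )
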