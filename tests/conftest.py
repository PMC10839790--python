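import pytest

from hlakit.haplotypes import Haplotype, HaplotypeFrequencyTable
from hlakit.nomenclature import Allele, GGroupTable, parse_allele


def A(text: str) -> Allele:
    """Shorthand allele constructor for tests."""
    return parse_allele(text)


@pytest.fixture
def g_table() -> GGroupTable:
    """Two-entry-per-group G-group table for equivalence tests."""
    return GGroupTable.from_records([
        ("B", "44:02", "B*44:02:01G"),
        ("B", "44:27", "B*44:02:01G"),
        ("C", "07:01", "C*07:01:01G"),
        ("C", "07:06", "C*07:01:01G"),
        ("DQA1", "05:01", "DQA1*05:01:01G"),
        ("DQA1", "05:05", "DQA1*05:01:01G"),
    ])


def spaced_reference(n: int = 20) -> HaplotypeFrequencyTable:
    """A-B-C reference of n haplotypes pairwise divergent at all three loci.

    Reference i carries (A*i:01, B*i:01, C*i:01), so a single-locus
    perturbation of any entry stays at distance >= 2 from every other entry
    and classification outcomes are unambiguous.
    """
    pairs = []
    for i in range(1, n + 1):
        hap = Haplotype((
            Allele("A", i, 1), Allele("B", i, 1), Allele("C", i, 1),
        ), label=str(i))
        pairs.append((hap, 0.9 * (0.5 ** i) + 0.001))
    return HaplotypeFrequencyTable.from_haplotypes(pairs)


@pytest.fixture
def reference_20() -> HaplotypeFrequencyTable:
    return spaced_reference(20)
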