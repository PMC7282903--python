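import numpy as np
import pytest

from exsitu.genotype_io import (
    EX_SITU,
    IN_SITU,
    MISSING,
    GenotypeMatrix,
    IndividualRecord,
)


def make_matrix(rows, loci=None, source=IN_SITU):
    """Build a GenotypeMatrix from (id, population, genotypes) tuples.

    ``genotypes`` is a list of (a, b) pairs, one per locus; loci default
    to L1..Lk.
    """
    n_loci = len(rows[0][2])
    loci = tuple(loci or (f"L{i + 1}" for i in range(n_loci)))
    individuals = tuple(
        IndividualRecord(r[0], r[1], r[3] if len(r) > 3 else source, tuple(r[2]))
        for r in rows
    )
    return GenotypeMatrix(loci, individuals)


@pytest.fixture
def two_pop_matrix():
    """Two populations of four individuals, two loci, one missing cell."""
    rows = [
        ("a1", "p1", [(100, 100), (200, 202)]),
        ("a2", "p1", [(100, 102), (200, 200)]),
        ("a3", "p1", [(100, 100), (202, 202)]),
        ("a4", "p1", [(102, 104), (MISSING, MISSING)]),
        ("b1", "p2", [(104, 104), (204, 204)]),
        ("b2", "p2", [(104, 106), (200, 204)]),
        ("b3", "p2", [(106, 106), (204, 204)]),
        ("b4", "p2", [(104, 104), (200, 200)]),
    ]
    return make_matrix(rows)


@pytest.fixture
def category_ladder_matrix():
    """150 diploids at one locus with carrier counts ordered by frequency.

    Allele codes / copies / carriers / categories (note the common band
    f > 0.05 overlaps the low-frequency band 0.01 < f < 0.10):
      1: 182 copies, 92 carriers (very common + common, freq 0.6067)
      2:  80 copies, 40 carriers (very common + common, freq 0.2667)
      3:  24 copies, 12 carriers (common + low frequency, freq 0.08)
      4:   8 copies,  4 carriers (low frequency, freq 0.0267)
      5:   4 copies,  2 carriers (low frequency, freq 0.0133)
      6:   2 copies,  2 carriers (rare, freq 0.00667)
    """
    rows = []
    idx = 0

    def add(count, genotype):
        nonlocal idx
        for _ in range(count):
            idx += 1
            rows.append((f"i{idx}", "p1", [genotype]))

    add(90, (1, 1))
    add(2, (1, 6))
    add(40, (2, 2))
    add(12, (3, 3))
    add(4, (4, 4))
    add(2, (5, 5))
    return make_matrix(rows)


@pytest.fixture
def private_allele_matrix():
    """Ten individuals, each homozygous for its own private allele."""
    rows = [(f"i{k}", "p1", [(100 + k, 100 + k)]) for k in range(10)]
    return make_matrix(rows)


def random_fixture_matrix(rng, max_individuals=30, max_loci=5):
    """Small random diploid matrix for oracle-equivalence sweeps."""
    n = int(rng.integers(4, max_individuals + 1))
    n_loci = int(rng.integers(1, max_loci + 1))
    rows = []
    for i in range(n):
        genotypes = []
        for _ in range(n_loci):
            if rng.random() < 0.05:
                genotypes.append((MISSING, MISSING))
            else:
                genotypes.append(
                    (int(rng.integers(1, 6)), int(rng.integers(1, 6)))
                )
        rows.append((f"i{i}", "p1", genotypes))
    m = make_matrix(rows)
    # every locus must keep at least one non-missing genotype
    from exsitu.allele_accounting import tabulate_alleles

    table = tabulate_alleles(m)
    if len(table.denominators) < n_loci:
        return random_fixture_matrix(rng, max_individuals, max_loci)
    return m
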