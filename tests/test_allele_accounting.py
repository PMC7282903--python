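import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exsitu.allele_accounting import (
    CATEGORIES,
    CategoryThresholds,
    apply_min_copy_filter,
    capture_percentages,
    classify_allele_frequency,
    tabulate_alleles,
)
from exsitu.genotype_io import EX_SITU, MISSING, GenotypeMatrix
from exsitu.synthetic_data import (
    SyntheticSpec,
    generate_structured_population,
    simulate_ex_situ_collection,
)

from conftest import make_matrix


# ---------------------------------------------------------------------------
# tabulate_alleles
# ---------------------------------------------------------------------------


def test_tabulate_single_allele():
    m = make_matrix(
        [("i1", "p1", [(100, 100)]), ("i2", "p1", [(100, 100)])]
    )
    t = tabulate_alleles(m)
    assert len(t) == 1
    e = t.entries[0]
    assert (e.locus, e.allele, e.copies, e.frequency) == ("L1", 100, 4, 1.0)


def test_tabulate_frequencies():
    m = make_matrix(
        [("i1", "p1", [(100, 102)]), ("i2", "p1", [(100, 100)])]
    )
    t = tabulate_alleles(m)
    assert t.frequency("L1", 100) == 0.75
    assert t.frequency("L1", 102) == 0.25


def test_missing_excluded_from_denominator():
    m = make_matrix(
        [
            ("i1", "p1", [(100, 102)]),
            ("i2", "p1", [(100, 100)]),
            ("i3", "p1", [(MISSING, MISSING)]),
        ]
    )
    t = tabulate_alleles(m)
    assert t.denominators["L1"] == 4


def test_all_missing_locus_dropped_with_warning():
    m = make_matrix(
        [
            ("i1", "p1", [(100, 100), (MISSING, MISSING)]),
            ("i2", "p1", [(102, 102), (MISSING, MISSING)]),
        ]
    )
    with pytest.warns(UserWarning, match="L2"):
        t = tabulate_alleles(m)
    assert set(t.denominators) == {"L1"}


def test_per_locus_frequencies_sum_to_one(two_pop_matrix):
    t = tabulate_alleles(two_pop_matrix)
    for locus in t.loci():
        total = sum(e.frequency for e in t.entries if e.locus == locus)
        assert total == pytest.approx(1.0, abs=1e-12)


def test_source_filter_both_vs_in_situ(two_pop_matrix):
    ex = simulate_ex_situ_collection(two_pop_matrix, "random", n=3, seed=0)
    combined = GenotypeMatrix(
        two_pop_matrix.loci, two_pop_matrix.individuals + ex.individuals
    )
    t_wild = tabulate_alleles(combined, "in_situ")
    t_both = tabulate_alleles(combined, "both")
    assert t_wild.n_individuals == 8
    assert t_both.n_individuals == 11


# ---------------------------------------------------------------------------
# classify_allele_frequency
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "freq,expected",
    [
        (0.15, {"all", "very_common", "common"}),
        (0.02, {"all", "low_frequency"}),
        (0.10, {"all", "common"}),  # strict inequalities at the boundary
        (0.05, {"all", "low_frequency"}),
        (0.01, {"all"}),
        (0.005, {"all", "rare"}),
        (0.0, {"all", "rare"}),
        (1.0, {"all", "very_common", "common"}),
    ],
)
def test_category_membership(freq, expected):
    assert classify_allele_frequency(freq) == frozenset(expected)


def test_classify_rejects_out_of_range():
    with pytest.raises(ValueError):
        classify_allele_frequency(1.5)


@given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
def test_named_bands_mutually_exclusive(freq):
    cats = classify_allele_frequency(freq)
    assert "all" in cats
    assert len(cats & {"very_common", "low_frequency", "rare"}) <= 1


def test_custom_thresholds():
    t = CategoryThresholds(very_common_gt=0.5)
    assert "very_common" not in classify_allele_frequency(0.3, t)


def test_thresholds_must_be_in_unit_interval():
    with pytest.raises(ValueError):
        CategoryThresholds(rare_lt=0.0)


# ---------------------------------------------------------------------------
# apply_min_copy_filter
# ---------------------------------------------------------------------------


def _copy_fixture():
    # allele 100: 5 copies, 102: 3 copies, 104: 2 copies, 106: 1 copy, plus
    # one missing genotype (total copies 11, denominator excludes missing)
    return make_matrix(
        [
            ("i1", "p1", [(100, 100)]),
            ("i2", "p1", [(100, 100)]),
            ("i3", "p1", [(100, 102)]),
            ("i4", "p1", [(102, 102)]),
            ("i5", "p1", [(104, 104)]),
            ("i6", "p1", [(106, MISSING)]),  # normalized to missing
        ]
    )


def test_two_copy_allele_removed():
    t = apply_min_copy_filter(tabulate_alleles(_copy_fixture()))
    assert ("L1", 104) not in t.keys()


def test_three_copy_allele_retained():
    t = apply_min_copy_filter(tabulate_alleles(_copy_fixture()))
    assert ("L1", 102) in t.keys()


def test_zero_threshold_is_identity():
    t = tabulate_alleles(_copy_fixture())
    assert apply_min_copy_filter(t, 0) == t


def test_filter_keeps_original_denominators():
    t = apply_min_copy_filter(tabulate_alleles(_copy_fixture()))
    assert t.denominators["L1"] == 10
    assert t.frequency("L1", 100) == 0.5


def test_filter_emptying_locus_warns():
    m = make_matrix([("i1", "p1", [(100, 102)])])
    t = tabulate_alleles(m)
    with pytest.warns(UserWarning, match="L1"):
        apply_min_copy_filter(t, 2)


# ---------------------------------------------------------------------------
# capture_percentages
# ---------------------------------------------------------------------------


def test_full_self_capture(two_pop_matrix):
    t = tabulate_alleles(two_pop_matrix)
    ex = two_pop_matrix.relabel_source(EX_SITU)
    summary = capture_percentages(t, ex)
    for cat in CATEGORIES:
        cc = summary.categories[cat]
        if cc.n_existing:
            assert cc.percent == 100.0


def test_empty_collection_captures_nothing(two_pop_matrix):
    t = tabulate_alleles(two_pop_matrix)
    empty = GenotypeMatrix(two_pop_matrix.loci, ())
    summary = capture_percentages(t, empty)
    for cat in CATEGORIES:
        cc = summary.categories[cat]
        if cc.n_existing:
            assert cc.percent == 0.0


def test_half_capture():
    wild = make_matrix(
        [
            ("i1", "p1", [(1, 2)]),
            ("i2", "p1", [(3, 4)]),
        ]
    )
    ex = make_matrix([("x1", "p1", [(1, 2)])], source=EX_SITU)
    t = tabulate_alleles(wild)
    assert capture_percentages(t, ex).percent("all") == 50.0


def test_novel_ex_situ_alleles_ignored():
    wild = make_matrix([("i1", "p1", [(1, 1)])])
    ex = make_matrix([("x1", "p1", [(1, 99)])], source=EX_SITU)
    summary = capture_percentages(tabulate_alleles(wild), ex)
    assert summary.percent("all") == 100.0
    assert summary.categories["all"].n_existing == 1


def test_empty_category_reported_undefined():
    wild = make_matrix([("i1", "p1", [(1, 1)]), ("i2", "p1", [(1, 1)])])
    summary = capture_percentages(
        tabulate_alleles(wild), wild.relabel_source(EX_SITU)
    )
    assert summary.percent("rare") is None
    assert summary.percent("all") == 100.0


def test_empty_table_rejected():
    wild = make_matrix([("i1", "p1", [(1, 1)])])
    from exsitu.allele_accounting import AlleleTable

    with pytest.raises(ValueError):
        capture_percentages(AlleleTable((), 0, {}), wild)


def test_capture_monotone_in_collection_size():
    spec = SyntheticSpec(
        n_populations=2,
        individuals_per_population=12,
        n_loci=4,
        alleles_per_locus=6,
        target_fst=0.1,
        seed=7,
    )
    wild = generate_structured_population(spec)
    t = tabulate_alleles(wild)
    rng = np.random.default_rng(1)
    order = rng.permutation(wild.n_individuals)
    prev = {c: -1.0 for c in CATEGORIES}
    for k in range(1, wild.n_individuals + 1):
        ids = [wild.individuals[i].id for i in order[:k]]
        sub = wild.filter(ids=ids).relabel_source(EX_SITU)
        summary = capture_percentages(t, sub)
        for cat in CATEGORIES:
            pct = summary.percent(cat)
            if pct is not None:
                assert pct >= prev[cat]
                prev[cat] = pct


@pytest.mark.parametrize("seed", range(5))
def test_reduced_capture_at_least_full(seed):
    spec = SyntheticSpec(
        n_populations=2,
        individuals_per_population=20,
        n_loci=5,
        alleles_per_locus=6,
        target_fst=0.1,
        rare_tail_target=0.2,
        seed=seed,
    )
    wild = generate_structured_population(spec)
    full = tabulate_alleles(wild)
    reduced = apply_min_copy_filter(full, 2)
    ex = simulate_ex_situ_collection(wild, "random", n=12, seed=seed + 100)
    pct_full = capture_percentages(full, ex).percent("all")
    pct_reduced = capture_percentages(reduced, ex).percent("all")
    assert pct_reduced >= pct_full
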