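"""Allele tabulation, frequency categories, and capture percentages.

The wild (in situ) dataset defines the target diversity: every distinct
allele at every locus, with copy counts and relative frequencies.  Alleles
are binned into overlapping frequency categories (all, very common >0.10,
common >0.05, low frequency 0.01–0.10 exclusive, rare <0.01), and a
collection's success is the percentage of wild alleles it carries at
least once, per category.  A "reduced" variant drops alleles present in
at most two copies in the wild sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .genotype_io import EX_SITU, IN_SITU, GenotypeMatrix

__all__ = [
    "CATEGORIES",
    "CategoryThresholds",
    "AlleleEntry",
    "AlleleTable",
    "CategoryCapture",
    "CaptureSummary",
    "tabulate_alleles",
    "classify_allele_frequency",
    "apply_min_copy_filter",
    "capture_percentages",
    "category_allele_keys",
]

#: Category names in reporting order.
CATEGORIES = ("all", "very_common", "common", "low_frequency", "rare")


@dataclass(frozen=True)
class CategoryThresholds:
    """Strict-inequality boundaries of the allele frequency categories.

    An allele of frequency *f* is very common if ``f > very_common_gt``,
    common if ``f > common_gt``, low frequency if
    ``low_freq_gt < f < low_freq_lt`` and rare if ``f < rare_lt``.
    Every allele belongs to "all".  Categories overlap by design (a very
    common allele is also common).
    """

    very_common_gt: float = 0.10
    common_gt: float = 0.05
    low_freq_lt: float = 0.10
    low_freq_gt: float = 0.01
    rare_lt: float = 0.01

    def __post_init__(self) -> None:
        for name in (
            "very_common_gt",
            "common_gt",
            "low_freq_lt",
            "low_freq_gt",
            "rare_lt",
        ):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} outside (0, 1)")


def classify_allele_frequency(
    frequency: float, thresholds: CategoryThresholds | None = None
) -> frozenset[str]:
    """Return every category an allele of the given frequency belongs to."""
    if not 0.0 <= frequency <= 1.0:
        raise ValueError(f"frequency {frequency} outside [0, 1]")
    t = thresholds or CategoryThresholds()
    cats = {"all"}
    if frequency > t.very_common_gt:
        cats.add("very_common")
    if frequency > t.common_gt:
        cats.add("common")
    if t.low_freq_gt < frequency < t.low_freq_lt:
        cats.add("low_frequency")
    if frequency < t.rare_lt:
        cats.add("rare")
    return frozenset(cats)


@dataclass(frozen=True)
class AlleleEntry:
    locus: str
    allele: int
    copies: int
    frequency: float

    @property
    def key(self) -> tuple[str, int]:
        return (self.locus, self.allele)


@dataclass(frozen=True)
class AlleleTable:
    """Per-locus allele copy counts and frequencies for one dataset.

    ``denominators`` maps each locus to its number of non-missing allele
    copies; frequencies are copies divided by that per-locus denominator.
    After :func:`apply_min_copy_filter` the denominators (and hence the
    surviving frequencies) are deliberately NOT renormalized.
    """

    entries: tuple[AlleleEntry, ...]
    n_individuals: int
    denominators: Mapping[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        object.__setattr__(self, "denominators", dict(self.denominators))

    def __len__(self) -> int:
        return len(self.entries)

    def keys(self) -> tuple[tuple[str, int], ...]:
        return tuple(e.key for e in self.entries)

    def frequency(self, locus: str, allele: int) -> float:
        for e in self.entries:
            if e.locus == locus and e.allele == allele:
                return e.frequency
        raise KeyError((locus, allele))

    def loci(self) -> tuple[str, ...]:
        seen: list[str] = []
        for e in self.entries:
            if e.locus not in seen:
                seen.append(e.locus)
        return tuple(seen)


def tabulate_alleles(
    matrix: GenotypeMatrix, source_filter: str = IN_SITU
) -> AlleleTable:
    """Count every non-missing allele copy in the selected individuals.

    ``source_filter`` is ``"in_situ"``, ``"ex_situ"`` or ``"both"``.
    Missing genotypes contribute to neither numerator nor denominator.
    A locus with zero non-missing copies is dropped with a warning.
    """
    if source_filter == "both":
        sub = matrix
    elif source_filter in (IN_SITU, EX_SITU):
        sub = matrix.filter(source=source_filter)
    else:
        raise ValueError(f"unknown source_filter {source_filter!r}")

    sentinel = matrix.missing_sentinel
    arr = sub.allele_array()  # (n, L, 2)
    entries: list[AlleleEntry] = []
    denominators: dict[str, int] = {}
    for j, locus in enumerate(matrix.loci):
        copies = arr[:, j, :].ravel()
        copies = copies[copies != sentinel]
        if copies.size == 0:
            warnings.warn(
                f"locus {locus!r} has no non-missing copies under filter "
                f"{source_filter!r}; dropped from allele table",
                stacklevel=2,
            )
            continue
        denominators[locus] = int(copies.size)
        alleles, counts = np.unique(copies, return_counts=True)
        for allele, count in zip(alleles.tolist(), counts.tolist()):
            entries.append(
                AlleleEntry(locus, int(allele), int(count), count / copies.size)
            )
    return AlleleTable(tuple(entries), sub.n_individuals, denominators)


def apply_min_copy_filter(
    table: AlleleTable, max_excluded_copies: int = 2
) -> AlleleTable:
    """Drop alleles with at most ``max_excluded_copies`` copies.

    The default of 2 yields the "reduced" dataset; 0 is the identity
    ("full" dataset).  Frequencies of the survivors keep their original
    denominators.
    """
    if max_excluded_copies < 0:
        raise ValueError("max_excluded_copies must be >= 0")
    kept = tuple(e for e in table.entries if e.copies > max_excluded_copies)
    kept_loci = {e.locus for e in kept}
    for locus in table.denominators:
        if locus not in kept_loci:
            warnings.warn(
                f"min-copy filter removed every allele at locus {locus!r}",
                stacklevel=2,
            )
    return AlleleTable(kept, table.n_individuals, dict(table.denominators))


def category_allele_keys(
    table: AlleleTable, thresholds: CategoryThresholds | None = None
) -> dict[str, tuple[tuple[str, int], ...]]:
    """Map each category to the (locus, allele) keys it contains."""
    t = thresholds or CategoryThresholds()
    out: dict[str, list[tuple[str, int]]] = {c: [] for c in CATEGORIES}
    for e in table.entries:
        for cat in classify_allele_frequency(e.frequency, t):
            out[cat].append(e.key)
    return {c: tuple(v) for c, v in out.items()}


@dataclass(frozen=True)
class CategoryCapture:
    n_existing: int
    n_captured: int
    #: ``None`` when no allele exists in the category ("NA", not 0).
    percent: float | None

    def __post_init__(self) -> None:
        if self.n_captured > self.n_existing:
            raise ValueError("captured more alleles than exist")


@dataclass(frozen=True)
class CaptureSummary:
    """Percent of wild alleles present in a collection, per category."""

    categories: Mapping[str, CategoryCapture]
    dataset_variant: str = "full"

    def percent(self, category: str) -> float | None:
        return self.categories[category].percent

    def as_dict(self) -> dict[str, float | None]:
        return {c: self.categories[c].percent for c in CATEGORIES}


def capture_percentages(
    in_situ_table: AlleleTable,
    ex_situ_matrix: GenotypeMatrix,
    thresholds: CategoryThresholds | None = None,
    dataset_variant: str = "full",
) -> CaptureSummary:
    """Percentage of wild alleles carried at least once by a collection.

    Categories are assigned from the wild frequencies in
    ``in_situ_table`` and pooled across loci: the percentage is total
    captured over total existing, not a per-locus average.  Collection
    alleles absent from the wild table are ignored.
    """
    if len(in_situ_table) == 0:
        raise ValueError("empty in situ allele table")
    sentinel = ex_situ_matrix.missing_sentinel
    arr = ex_situ_matrix.allele_array()
    present: set[tuple[str, int]] = set()
    for j, locus in enumerate(ex_situ_matrix.loci):
        copies = arr[:, j, :].ravel()
        for allele in np.unique(copies[copies != sentinel]).tolist():
            present.add((locus, int(allele)))

    by_cat = category_allele_keys(in_situ_table, thresholds)
    captures: dict[str, CategoryCapture] = {}
    for cat in CATEGORIES:
        keys = by_cat[cat]
        n_existing = len(keys)
        n_captured = sum(1 for k in keys if k in present)
        percent = 100.0 * n_captured / n_existing if n_existing else None
        captures[cat] = CategoryCapture(n_existing, n_captured, percent)
    return CaptureSummary(captures, dataset_variant)
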