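"""Monte-Carlo resampling of the wild dataset over all subsample sizes.

For every subsample size n in 2..N (N = number of wild individuals) the
engine estimates the mean and spread of the percentage of wild alleles a
random collection of n individuals would capture, per frequency
category.  A hypergeometric closed form (`expected_capture_oracle`)
provides an independent check: the chance that a random subsample of n
individuals contains at least one of the m carriers of an allele is
1 - C(N-m, n)/C(N, n).

Each replicate draws one random permutation of the wild individuals;
its prefixes of length 2..N are uniform subsamples of every size, so a
single pass yields the whole curve.  Per-size marginal statistics are
identical to drawing each size independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Mapping, Sequence

import numpy as np

from .allele_accounting import (
    CATEGORIES,
    AlleleTable,
    CategoryThresholds,
    apply_min_copy_filter,
    category_allele_keys,
    tabulate_alleles,
)
from .genotype_io import GenotypeMatrix

__all__ = [
    "DEFAULT_REPLICATES",
    "ResamplingCurve",
    "SufficiencyResult",
    "subsample_individuals",
    "carrier_counts",
    "resample_capture_curve",
    "expected_capture_oracle",
    "minimum_sufficient_size",
]

DEFAULT_REPLICATES = 75_000


@dataclass(frozen=True)
class ResamplingCurve:
    """Mean/sd percent capture per category over subsample sizes 2..N."""

    sizes: np.ndarray
    mean: Mapping[str, np.ndarray]
    sd: Mapping[str, np.ndarray]
    replicates: int
    seed: int
    dataset_variant: str
    n_in_situ: int

    def mean_at(self, n: int, category: str = "all") -> float:
        """Mean percent captured at subsample size ``n``."""
        idx = np.searchsorted(self.sizes, n)
        if idx >= len(self.sizes) or self.sizes[idx] != n:
            raise KeyError(f"size {n} not on curve grid")
        return float(self.mean[category][idx])

    def standard_error(self, category: str = "all") -> np.ndarray:
        return self.sd[category] / np.sqrt(self.replicates)


@dataclass(frozen=True)
class SufficiencyResult:
    """Smallest subsample size whose mean capture exceeds a threshold."""

    category: str
    threshold_percent: float
    minimum_size: int | None  # None encodes "not attainable"
    dataset_variant: str

    @property
    def attainable(self) -> bool:
        return self.minimum_size is not None


def subsample_individuals(
    matrix: GenotypeMatrix, n: int, rng: np.random.Generator
) -> list[str]:
    """Draw ``n`` distinct wild individual ids, uniformly without
    replacement and pooled across populations."""
    wild = matrix.in_situ()
    N = wild.n_individuals
    if not 2 <= n <= N:
        raise ValueError(f"subsample size {n} outside [2, {N}]")
    ids = wild.ids()
    picks = rng.choice(N, size=n, replace=False)
    return [ids[i] for i in picks]


def carrier_counts(
    matrix: GenotypeMatrix, keys: Sequence[tuple[str, int]]
) -> np.ndarray:
    """Number of individuals in ``matrix`` carrying each (locus, allele)."""
    arr = matrix.allele_array()
    locus_index = {locus: j for j, locus in enumerate(matrix.loci)}
    out = np.zeros(len(keys), dtype=np.int64)
    for k, (locus, allele) in enumerate(keys):
        j = locus_index[locus]
        out[k] = int(np.any(arr[:, j, :] == allele, axis=1).sum())
    return out


def expected_capture_oracle(
    carrier_counts: Sequence[int], n: int, N: int
) -> float:
    """Exact expected percent of alleles captured by a random subsample.

    ``carrier_counts`` gives, per allele, the number m of wild
    individuals carrying it (1 <= m <= N).  Sampling n of N individuals
    without replacement captures an allele with probability
    1 - C(N-m, n)/C(N, n); the oracle returns 100 times the mean over
    alleles.
    """
    if not 0 <= n <= N:
        raise ValueError(f"n={n} outside [0, {N}]")
    ms = list(carrier_counts)
    if not ms:
        raise ValueError("no carrier counts supplied")
    total = 0.0
    denom = comb(N, n)
    for m in ms:
        if not 1 <= m <= N:
            raise ValueError(f"carrier count {m} outside [1, {N}]")
        total += 1.0 - comb(N - m, n) / denom
    return 100.0 * total / len(ms)


def _carrier_structure(
    matrix: GenotypeMatrix, keys: Sequence[tuple[str, int]]
) -> tuple[np.ndarray, np.ndarray]:
    """Flat carrier-index array plus reduceat offsets, one segment per key.

    Every key is guaranteed at least one carrier (keys come from the
    wild allele table), so the segments are non-empty.
    """
    arr = matrix.allele_array()
    locus_index = {locus: j for j, locus in enumerate(matrix.loci)}
    flat: list[np.ndarray] = []
    offsets = np.zeros(len(keys), dtype=np.int64)
    pos = 0
    for k, (locus, allele) in enumerate(keys):
        j = locus_index[locus]
        carriers = np.flatnonzero(np.any(arr[:, j, :] == allele, axis=1))
        if carriers.size == 0:
            raise ValueError(f"allele {allele} at {locus!r} has no carrier")
        offsets[k] = pos
        flat.append(carriers)
        pos += carriers.size
    return np.concatenate(flat) if flat else np.empty(0, np.int64), offsets


def resample_capture_curve(
    matrix: GenotypeMatrix,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
    thresholds: CategoryThresholds | None = None,
    variant: str = "full",
    max_excluded_copies: int = 2,
) -> ResamplingCurve:
    """Estimate the capture curve of the wild individuals in ``matrix``.

    ``variant="reduced"`` first drops wild alleles with at most
    ``max_excluded_copies`` copies; categories are then assigned from the
    surviving wild frequencies and frozen for every replicate.  Results
    are deterministic under a fixed ``seed``.  Categories with no allele
    get NaN curves.
    """
    if variant not in ("full", "reduced"):
        raise ValueError(f"unknown variant {variant!r}")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    wild = matrix.in_situ()
    N = wild.n_individuals
    if N < 2:
        raise ValueError("need at least 2 in situ individuals")

    table = tabulate_alleles(wild, source_filter="in_situ")
    if variant == "reduced":
        table = apply_min_copy_filter(table, max_excluded_copies)
    keys = table.keys()
    if not keys:
        raise ValueError("no alleles left to resample")
    flat, offsets = _carrier_structure(wild, keys)
    by_cat = category_allele_keys(table, thresholds)
    key_index = {k: i for i, k in enumerate(keys)}
    cat_cols = {
        c: np.asarray([key_index[k] for k in by_cat[c]], dtype=np.int64)
        for c in CATEGORIES
    }

    sizes = np.arange(2, N + 1)
    n_sizes = sizes.size
    sums = {c: np.zeros(n_sizes) for c in CATEGORIES}
    sqs = {c: np.zeros(n_sizes) for c in CATEGORIES}

    rng = np.random.default_rng(seed)
    inv = np.empty(N, dtype=np.int64)
    for _ in range(replicates):
        perm = rng.permutation(N)
        inv[perm] = np.arange(N)
        # position in the permutation at which each allele is first seen
        first = np.minimum.reduceat(inv[flat], offsets)
        for c in CATEGORIES:
            cols = cat_cols[c]
            if cols.size == 0:
                continue
            counts = np.cumsum(np.bincount(first[cols], minlength=N))
            pct = 100.0 * counts[sizes - 1] / cols.size
            sums[c] += pct
            sqs[c] += pct * pct

    mean: dict[str, np.ndarray] = {}
    sd: dict[str, np.ndarray] = {}
    for c in CATEGORIES:
        if cat_cols[c].size == 0:
            mean[c] = np.full(n_sizes, np.nan)
            sd[c] = np.full(n_sizes, np.nan)
            continue
        m = sums[c] / replicates
        var = np.maximum(sqs[c] / replicates - m * m, 0.0)
        mean[c] = m
        sd[c] = np.sqrt(var)
    return ResamplingCurve(
        sizes=sizes,
        mean=mean,
        sd=sd,
        replicates=replicates,
        seed=seed,
        dataset_variant=variant,
        n_in_situ=N,
    )


def minimum_sufficient_size(
    curve: ResamplingCurve,
    threshold_percent: float,
    category: str = "all",
) -> SufficiencyResult:
    """First grid size whose mean capture strictly exceeds the threshold.

    Returns ``minimum_size=None`` ("not attainable") when no size
    crosses, including for categories with no alleles.
    """
    means = curve.mean[category]
    above = np.flatnonzero(means > threshold_percent)
    minimum = int(curve.sizes[above[0]]) if above.size else None
    return SufficiencyResult(
        category=category,
        threshold_percent=float(threshold_percent),
        minimum_size=minimum,
        dataset_variant=curve.dataset_variant,
    )
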