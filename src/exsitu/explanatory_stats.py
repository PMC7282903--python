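"""Predictor statistics: pairwise FST, spectrum summaries, regression,
ANOVA and multiple-testing correction.

FST uses the Weir & Cockerham (1984) theta estimator, multilocus
ratio-of-sums, which handles unequal sample sizes and missing data and
may legitimately return slightly negative values (retained, never
clamped).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .allele_accounting import AlleleTable
from .genotype_io import GenotypeMatrix

__all__ = [
    "FstSummary",
    "RegressionFit",
    "pairwise_fst_matrix",
    "weir_cockerham_theta",
    "spectrum_summaries",
    "log_capture_fit",
    "one_way_anova",
    "bh_adjust",
]

DEFAULT_SPECTRUM_CUTOFFS = (0.001, 0.01, 0.05)


@dataclass(frozen=True)
class FstSummary:
    """Pairwise FST matrix between populations plus scalar summaries."""

    populations: tuple[str, ...]
    matrix: np.ndarray  # symmetric, NaN diagonal

    def _offdiag(self) -> np.ndarray:
        iu = np.triu_indices(len(self.populations), k=1)
        return self.matrix[iu]

    @property
    def mean(self) -> float:
        return float(np.mean(self._offdiag()))

    @property
    def min(self) -> float:
        return float(np.min(self._offdiag()))

    @property
    def max(self) -> float:
        return float(np.max(self._offdiag()))

    @property
    def sd(self) -> float:
        return float(np.std(self._offdiag(), ddof=1)) if len(self._offdiag()) > 1 else 0.0

    def as_dict(self) -> dict:
        return {
            "populations": list(self.populations),
            "pairs": {
                f"{a}|{b}": float(self.matrix[i, j])
                for (i, a), (j, b) in itertools.combinations(
                    enumerate(self.populations), 2
                )
            },
            "mean": self.mean,
            "min": self.min,
            "max": self.max,
            "sd": self.sd,
        }


def _per_locus_stats(
    arr: np.ndarray, sentinel: int
) -> list[tuple[np.ndarray, np.ndarray, int]]:
    """For one population's (n, L, 2) array: per locus, allele codes,
    allele counts, heterozygote counts per allele, and sample size."""
    out = []
    for j in range(arr.shape[1]):
        geno = arr[:, j, :]
        ok = geno[:, 0] != sentinel
        geno = geno[ok]
        n = geno.shape[0]
        if n == 0:
            out.append((np.empty(0, np.int64), np.empty((0, 2)), 0))
            continue
        alleles = np.unique(geno)
        freqs = np.empty(alleles.size)
        hets = np.empty(alleles.size)
        het_mask = geno[:, 0] != geno[:, 1]
        for k, a in enumerate(alleles):
            carries = geno == a
            freqs[k] = carries.sum() / (2 * n)
            hets[k] = (het_mask & carries.any(axis=1)).sum() / n
        out.append((alleles, np.column_stack([freqs, hets]), n))
    return out


def weir_cockerham_theta(
    pop_a: GenotypeMatrix, pop_b: GenotypeMatrix
) -> float:
    """Multilocus Weir–Cockerham (1984) theta between two populations.

    Variance components a (among populations), b (among individuals
    within populations) and c (within individuals) are summed over every
    allele at every locus; theta is sum(a) / sum(a + b + c).
    """
    if pop_a.loci != pop_b.loci:
        raise ValueError("populations genotyped at different loci")
    sentinel = pop_a.missing_sentinel
    stats_a = _per_locus_stats(pop_a.allele_array(), sentinel)
    stats_b = _per_locus_stats(pop_b.allele_array(), sentinel)

    num = 0.0
    den = 0.0
    r = 2
    for (al_a, fh_a, n1), (al_b, fh_b, n2) in zip(stats_a, stats_b):
        if n1 < 2 or n2 < 2:
            continue  # locus uninformative for this pair
        alleles = np.union1d(al_a, al_b)
        n_bar = (n1 + n2) / 2.0
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
        for a in alleles:
            i1 = np.searchsorted(al_a, a)
            i2 = np.searchsorted(al_b, a)
            p1, h1 = (
                fh_a[i1] if i1 < al_a.size and al_a[i1] == a else (0.0, 0.0)
            )
            p2, h2 = (
                fh_b[i2] if i2 < al_b.size and al_b[i2] == a else (0.0, 0.0)
            )
            p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
            s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / (
                (r - 1) * n_bar
            )
            h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
            va = (n_bar / n_c) * (
                s2
                - (
                    p_bar * (1 - p_bar)
                    - ((r - 1) / r) * s2
                    - h_bar / 4.0
                )
                / (n_bar - 1)
            )
            vb = (n_bar / (n_bar - 1)) * (
                p_bar * (1 - p_bar)
                - ((r - 1) / r) * s2
                - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
            )
            vc = h_bar / 2.0
            num += va
            den += va + vb + vc
    if den == 0.0:
        raise ValueError("no informative loci between the two populations")
    return num / den


def pairwise_fst_matrix(matrix: GenotypeMatrix) -> FstSummary:
    """Pairwise Weir–Cockerham FST among the populations of a matrix.

    Requires at least two populations with at least two genotyped
    individuals each.
    """
    pops = matrix.populations
    if len(pops) < 2:
        raise ValueError("pairwise FST needs at least two populations")
    subs = {p: matrix.filter(population=p) for p in pops}
    for p, sub in subs.items():
        if sub.n_individuals < 2:
            raise ValueError(f"population {p!r} has fewer than 2 individuals")
    k = len(pops)
    out = np.full((k, k), np.nan)
    for (i, a), (j, b) in itertools.combinations(enumerate(pops), 2):
        theta = weir_cockerham_theta(subs[a], subs[b])
        out[i, j] = out[j, i] = theta
    return FstSummary(tuple(pops), out)


def spectrum_summaries(
    table: AlleleTable, cutoffs: Sequence[float] = DEFAULT_SPECTRUM_CUTOFFS
) -> dict[float, float]:
    """Proportion of alleles strictly below each frequency cutoff."""
    if len(table) == 0:
        raise ValueError("empty allele table")
    freqs = np.asarray([e.frequency for e in table.entries])
    return {
        float(c): float(np.mean(freqs < c)) for c in cutoffs
    }


@dataclass(frozen=True)
class RegressionFit:
    intercept: float
    slope: float
    adjusted_r2: float
    n_points: int

    def predict(self, n_plants: float) -> float:
        return self.intercept + self.slope * np.log(n_plants)


def log_capture_fit(
    points: Sequence[tuple[float, float]]
) -> RegressionFit:
    """OLS of percent captured on the natural log of collection size."""
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    n_plants = np.asarray([p[0] for p in points], dtype=float)
    percent = np.asarray([p[1] for p in points], dtype=float)
    if np.any(n_plants < 1):
        raise ValueError("n_plants must be >= 1")
    x = np.log(n_plants)
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all collection sizes identical")
    X = sm.add_constant(x)
    fit = sm.OLS(percent, X).fit()
    n = len(points)
    r2 = float(fit.rsquared)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else 1.0
    return RegressionFit(
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        adjusted_r2=adj,
        n_points=n,
    )


def one_way_anova(
    groups: Mapping[str, Sequence[float]]
) -> tuple[float, float]:
    """Classical one-way ANOVA: F statistic and upper-tail p-value.

    Zero within-group variance with non-zero between-group variance
    yields (inf, 0.0).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group needs at least one value")
    n_total = sum(a.size for a in arrays)
    k = len(arrays)
    df_between = k - 1
    df_within = n_total - k
    if df_within < 1:
        raise ValueError("no residual degrees of freedom")
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ss_within == 0.0 and ss_between == 0.0:
        raise ValueError("zero variance everywhere; F undefined")
    if ss_within == 0.0:
        return float("inf"), 0.0
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(scipy.stats.f.sf(f, df_between, df_within))
    return float(f), p


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order kept."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
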