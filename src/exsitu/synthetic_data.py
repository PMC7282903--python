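"""Synthetic structured microsatellite datasets.

Populations are generated under the Balding–Nichols construction:
per-locus ancestral allele frequencies follow a geometric decay profile,
and each population's frequencies are a Dirichlet draw centred on the
ancestral vector with concentration (1 - F)/F, so the F parameter maps
directly onto expected pairwise FST.  Genotypes are two independent
draws per individual (Hardy–Weinberg within populations).

`shape_rare_tail` pushes a dataset's allele frequency spectrum toward a
target proportion of alleles at 1–2 copies by converting single allele
copies into novel private alleles.  `simulate_ex_situ_collection` builds
collections under random, single-population or maternal-cluster
sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .genotype_io import (
    EX_SITU,
    IN_SITU,
    MISSING,
    GenotypeMatrix,
    IndividualRecord,
)

__all__ = [
    "SyntheticSpec",
    "generate_structured_population",
    "shape_rare_tail",
    "simulate_ex_situ_collection",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a structured diploid microsatellite dataset."""

    n_populations: int = 4
    individuals_per_population: int = 50
    n_loci: int = 10
    alleles_per_locus: int = 8
    target_fst: float = 0.1
    #: geometric decay rate of the ancestral frequency profile; smaller
    #: values give a more even spectrum.
    profile_decay: float = 0.3
    rare_tail_target: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations < 1:
            raise ValueError("n_populations must be >= 1")
        if self.individuals_per_population < 1:
            raise ValueError("individuals_per_population must be >= 1")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.alleles_per_locus < 1:
            raise ValueError("alleles_per_locus must be >= 1")
        if not 0.0 <= self.target_fst < 1.0:
            raise ValueError("target_fst must be in [0, 1)")
        if not 0.0 < self.profile_decay < 1.0:
            raise ValueError("profile_decay must be in (0, 1)")


def _ancestral_profile(spec: SyntheticSpec) -> np.ndarray:
    """Geometric-decay ancestral frequencies, one row per locus."""
    k = np.arange(spec.alleles_per_locus)
    base = (1.0 - spec.profile_decay) ** k
    return np.tile(base / base.sum(), (spec.n_loci, 1))


def generate_structured_population(spec: SyntheticSpec) -> GenotypeMatrix:
    """Simulate wild (in situ) populations under Balding–Nichols drift.

    Allele codes at each locus are 100, 101, ...; population labels are
    ``pop_1..pop_k``; output is deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    ancestral = _ancestral_profile(spec)
    F = spec.target_fst
    n_pop = spec.n_populations
    n_ind = spec.individuals_per_population
    loci = tuple(f"L{j + 1}" for j in range(spec.n_loci))

    # per population, per locus: allele frequency vector
    pop_freqs = np.empty((n_pop, spec.n_loci, spec.alleles_per_locus))
    for j in range(spec.n_loci):
        for p in range(n_pop):
            if F == 0.0:
                pop_freqs[p, j] = ancestral[j]
            else:
                conc = ancestral[j] * (1.0 - F) / F
                pop_freqs[p, j] = rng.dirichlet(conc)

    individuals: list[IndividualRecord] = []
    for p in range(n_pop):
        pop = f"pop_{p + 1}"
        # two independent allele draws per individual per locus (HWE)
        draws = np.empty((n_ind, spec.n_loci, 2), dtype=np.int64)
        for j in range(spec.n_loci):
            draws[:, j, :] = rng.choice(
                spec.alleles_per_locus, size=(n_ind, 2), p=pop_freqs[p, j]
            )
        draws += 100
        for i in range(n_ind):
            individuals.append(
                IndividualRecord(
                    id=f"{pop}_ind_{i + 1}",
                    population=pop,
                    source=IN_SITU,
                    genotypes=tuple(map(tuple, draws[i].tolist())),
                )
            )
    matrix = GenotypeMatrix(loci, tuple(individuals))
    if spec.rare_tail_target is not None:
        matrix = shape_rare_tail(
            matrix, spec.rare_tail_target, seed=rng.integers(2**31)
        )
    return matrix


def _rare_tail_proportion(arr: np.ndarray, n_loci: int) -> float:
    """Proportion of distinct alleles present in 1 or 2 copies."""
    rare = 0
    total = 0
    for j in range(n_loci):
        copies = arr[:, j, :].ravel()
        copies = copies[copies != MISSING]
        _, counts = np.unique(copies, return_counts=True)
        total += counts.size
        rare += int((counts <= 2).sum())
    return rare / total if total else 0.0


def shape_rare_tail(
    matrix: GenotypeMatrix,
    rare_tail_target: float,
    seed: int = 0,
    tolerance: float = 0.05,
) -> GenotypeMatrix:
    """Mutate allele copies to novel private alleles until the proportion
    of alleles at 1–2 copies approaches ``rare_tail_target``.

    Each step rewrites one copy of a well-represented allele (>= 4
    copies, so no existing allele is pushed into the 1–2-copy band) to a
    fresh code, creating a singleton.  Individuals and loci are never
    added or removed.  If the target cannot be reached this way (too few
    individuals), a best-effort matrix is returned with a warning.
    """
    if not 0.0 <= rare_tail_target < 1.0:
        raise ValueError("rare_tail_target must be in [0, 1)")
    rng = np.random.default_rng(seed)
    arr = matrix.allele_array().copy()
    n_loci = matrix.n_loci
    next_code = int(arr[arr != MISSING].max(initial=999)) + 1

    if _rare_tail_proportion(arr, n_loci) >= rare_tail_target - tolerance:
        return matrix  # already at (or above) target

    while _rare_tail_proportion(arr, n_loci) < rare_tail_target - tolerance:
        candidates = []
        for j in range(n_loci):
            copies = arr[:, j, :]
            vals, counts = np.unique(
                copies[copies != MISSING], return_counts=True
            )
            if np.any(counts >= 4):
                candidates.append((j, vals, counts))
        if not candidates:
            break  # no allele can donate a copy without entering the band
        j, vals, counts = candidates[int(rng.integers(len(candidates)))]
        donor = int(vals[counts >= 4][np.argmax(counts[counts >= 4])])
        locs = np.argwhere(arr[:, j, :] == donor)
        pick = locs[rng.integers(len(locs))]
        arr[pick[0], j, pick[1]] = next_code
        next_code += 1

    achieved = _rare_tail_proportion(arr, n_loci)
    if achieved < rare_tail_target - tolerance:
        warnings.warn(
            f"rare-tail target {rare_tail_target:.2f} infeasible; "
            f"best effort {achieved:.2f}",
            stacklevel=2,
        )
    individuals = tuple(
        replace(ind, genotypes=tuple(map(tuple, arr[i].tolist())))
        for i, ind in enumerate(matrix.individuals)
    )
    return GenotypeMatrix(matrix.loci, individuals, matrix.missing_sentinel)


def simulate_ex_situ_collection(
    matrix: GenotypeMatrix,
    strategy: str = "random",
    n: int = 10,
    cluster_size: int = 5,
    seed: int = 0,
) -> GenotypeMatrix:
    """Build a simulated collection (source = ex_situ) from wild material.

    Strategies:

    * ``random`` — n wild individuals drawn uniformly without
      replacement, pooled across populations;
    * ``single_population`` — n individuals from one random population;
    * ``maternal_clusters`` — mothers are drawn at random and each
      contributes ``cluster_size`` simulated offspring (one maternal
      allele plus one allele drawn from the mother's population pool per
      locus), until n offspring are produced.
    """
    rng = np.random.default_rng(seed)
    wild = matrix.in_situ()
    N = wild.n_individuals
    if n < 1:
        raise ValueError("n must be >= 1")

    if strategy == "random":
        if n > N:
            raise ValueError(f"cannot draw {n} of {N} wild individuals")
        picks = rng.choice(N, size=n, replace=False)
        chosen = [wild.individuals[i] for i in sorted(picks)]
        collected = tuple(
            IndividualRecord(
                f"xs_{ind.id}", ind.population, EX_SITU, ind.genotypes
            )
            for ind in chosen
        )
        return GenotypeMatrix(wild.loci, collected, wild.missing_sentinel)

    if strategy == "single_population":
        pops = wild.populations
        pop = pops[int(rng.integers(len(pops)))]
        sub = wild.filter(population=pop)
        if n > sub.n_individuals:
            raise ValueError(
                f"population {pop!r} has only {sub.n_individuals} "
                f"individuals, cannot draw {n}"
            )
        picks = rng.choice(sub.n_individuals, size=n, replace=False)
        collected = tuple(
            IndividualRecord(
                f"xs_{sub.individuals[i].id}", pop, EX_SITU,
                sub.individuals[i].genotypes,
            )
            for i in sorted(picks)
        )
        return GenotypeMatrix(wild.loci, collected, wild.missing_sentinel)

    if strategy == "maternal_clusters":
        if cluster_size < 1:
            raise ValueError("cluster_size must be >= 1")
        # per-population allele pools per locus, for the paternal draw
        pools: dict[str, list[np.ndarray]] = {}
        for pop in wild.populations:
            arr = wild.filter(population=pop).allele_array()
            pools[pop] = [
                arr[:, j, :].ravel()[arr[:, j, :].ravel() != MISSING]
                for j in range(wild.n_loci)
            ]
        collected: list[IndividualRecord] = []
        k = 0
        while len(collected) < n:
            mother = wild.individuals[int(rng.integers(N))]
            for c in range(cluster_size):
                if len(collected) >= n:
                    break
                genotypes = []
                for j in range(wild.n_loci):
                    mat_pair = mother.genotypes[j]
                    pool = pools[mother.population][j]
                    if mat_pair[0] == MISSING or pool.size == 0:
                        genotypes.append((MISSING, MISSING))
                        continue
                    maternal = mat_pair[int(rng.integers(2))]
                    paternal = int(pool[int(rng.integers(pool.size))])
                    genotypes.append((maternal, paternal))
                k += 1
                collected.append(
                    IndividualRecord(
                        f"xs_offspring_{k}",
                        mother.population,
                        EX_SITU,
                        tuple(genotypes),
                    )
                )
        return GenotypeMatrix(wild.loci, tuple(collected), wild.missing_sentinel)

    raise ValueError(f"unknown strategy {strategy!r}")
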