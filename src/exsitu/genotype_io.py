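"""Input/output for diploid multilocus genotype data.

Two on-disk representations are supported:

* a small CSV dialect with columns ``id,population,source,<locus1>,...``
  where each genotype cell is ``"a/b"`` with integer allele codes and
  missing data written as ``"-9/-9"``;
* GenePop files (2- or 3-digit allele coding), read-only.

All data end up in a :class:`GenotypeMatrix`, the substrate for every
downstream computation.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "IN_SITU",
    "EX_SITU",
    "SOURCES",
    "GenotypeParseError",
    "IndividualRecord",
    "GenotypeMatrix",
    "read_genotype_table",
    "write_genotype_table",
    "read_genepop",
]

#: Reserved integer allele code marking missing data.
MISSING = -9

IN_SITU = "in_situ"
EX_SITU = "ex_situ"
SOURCES = (IN_SITU, EX_SITU)


class GenotypeParseError(ValueError):
    """Raised when a genotype file violates its format contract."""


def _normalize_pair(pair: Sequence[int], missing: int) -> tuple[int, int]:
    """Sort a diploid genotype; a half-missing pair becomes fully missing."""
    a, b = int(pair[0]), int(pair[1])
    if a == missing or b == missing:
        return (missing, missing)
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class IndividualRecord:
    """One diploid individual: identity, provenance, and its genotypes.

    ``genotypes`` holds one unordered allele pair per locus.  Pairs are
    normalized on construction: alleles sorted ascending, half-missing
    genotypes coerced to fully missing.
    """

    id: str
    population: str
    source: str
    genotypes: tuple[tuple[int, int], ...]
    missing: int = MISSING

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise GenotypeParseError(
                f"unknown source {self.source!r} for individual {self.id!r}; "
                f"expected one of {SOURCES}"
            )
        norm = tuple(_normalize_pair(p, self.missing) for p in self.genotypes)
        object.__setattr__(self, "genotypes", norm)

    def is_missing(self, locus_index: int) -> bool:
        return self.genotypes[locus_index][0] == self.missing


@dataclass(frozen=True)
class GenotypeMatrix:
    """Diploid multilocus genotypes with population and provenance labels."""

    loci: tuple[str, ...]
    individuals: tuple[IndividualRecord, ...]
    missing_sentinel: int = MISSING

    def __post_init__(self) -> None:
        object.__setattr__(self, "loci", tuple(self.loci))
        object.__setattr__(self, "individuals", tuple(self.individuals))
        n_loci = len(self.loci)
        seen: set[str] = set()
        for ind in self.individuals:
            if len(ind.genotypes) != n_loci:
                raise GenotypeParseError(
                    f"individual {ind.id!r} has {len(ind.genotypes)} genotypes, "
                    f"expected {n_loci}"
                )
            if ind.id in seen:
                raise GenotypeParseError(f"duplicate individual id {ind.id!r}")
            seen.add(ind.id)

    # -- basic views ---------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def populations(self) -> tuple[str, ...]:
        """Distinct population labels in first-appearance order."""
        out: list[str] = []
        for ind in self.individuals:
            if ind.population not in out:
                out.append(ind.population)
        return tuple(out)

    def ids(self) -> tuple[str, ...]:
        return tuple(ind.id for ind in self.individuals)

    def filter(
        self,
        *,
        source: str | None = None,
        population: str | None = None,
        ids: Iterable[str] | None = None,
    ) -> "GenotypeMatrix":
        """Return the sub-matrix of individuals matching every given filter."""
        keep = self.individuals
        if source is not None:
            if source not in SOURCES:
                raise ValueError(f"unknown source filter {source!r}")
            keep = tuple(i for i in keep if i.source == source)
        if population is not None:
            keep = tuple(i for i in keep if i.population == population)
        if ids is not None:
            wanted = set(ids)
            keep = tuple(i for i in keep if i.id in wanted)
        return GenotypeMatrix(self.loci, keep, self.missing_sentinel)

    def in_situ(self) -> "GenotypeMatrix":
        return self.filter(source=IN_SITU)

    def ex_situ(self) -> "GenotypeMatrix":
        return self.filter(source=EX_SITU)

    def allele_array(self) -> np.ndarray:
        """Genotypes as an ``(n_individuals, n_loci, 2)`` integer array."""
        if self.n_individuals == 0:
            return np.empty((0, self.n_loci, 2), dtype=np.int64)
        return np.asarray(
            [ind.genotypes for ind in self.individuals], dtype=np.int64
        )

    def relabel_source(self, source: str) -> "GenotypeMatrix":
        """Copy of the matrix with every individual's source replaced."""
        inds = tuple(
            IndividualRecord(i.id, i.population, source, i.genotypes, i.missing)
            for i in self.individuals
        )
        return GenotypeMatrix(self.loci, inds, self.missing_sentinel)


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

_FIXED_COLUMNS = ("id", "population", "source")
_PAIR_RE = re.compile(r"^(-?\d+)/(-?\d+)$")


def _parse_cell(cell: str, missing_code: str, row: int, column: str) -> tuple[int, int]:
    cell = cell.strip()
    if cell == missing_code:
        return (MISSING, MISSING)
    m = _PAIR_RE.match(cell)
    if m is None:
        raise GenotypeParseError(
            f"malformed allele pair {cell!r} at row {row}, column {column!r}"
        )
    return (int(m.group(1)), int(m.group(2)))


def read_genotype_table(path: str | Path, missing_code: str = "-9/-9") -> GenotypeMatrix:
    """Read a genotype matrix from the package's CSV dialect.

    The header must start with ``id,population,source`` followed by one
    column per locus; genotype cells are ``"a/b"`` and cells equal to
    ``missing_code`` are treated as missing.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise GenotypeParseError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        if tuple(header[:3]) != _FIXED_COLUMNS:
            raise GenotypeParseError(
                f"{path}: header must start with {','.join(_FIXED_COLUMNS)}, "
                f"got {header[:3]}"
            )
        loci = tuple(header[3:])
        individuals: list[IndividualRecord] = []
        for row_num, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 3 + len(loci):
                raise GenotypeParseError(
                    f"{path}: row {row_num} has {len(row)} fields, "
                    f"expected {3 + len(loci)}"
                )
            ind_id, population, source = (c.strip() for c in row[:3])
            genotypes = tuple(
                _parse_cell(cell, missing_code, row_num, locus)
                for locus, cell in zip(loci, row[3:])
            )
            individuals.append(
                IndividualRecord(ind_id, population, source, genotypes)
            )
    return GenotypeMatrix(loci, tuple(individuals))


def write_genotype_table(matrix: GenotypeMatrix, path: str | Path) -> Path:
    """Write ``matrix`` in the CSV dialect; returns the path written."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(_FIXED_COLUMNS) + list(matrix.loci))
        for ind in matrix.individuals:
            cells = [
                "-9/-9" if a == matrix.missing_sentinel else f"{a}/{b}"
                for a, b in ind.genotypes
            ]
            writer.writerow([ind.id, ind.population, ind.source] + cells)
    return path


# ---------------------------------------------------------------------------
# GenePop
# ---------------------------------------------------------------------------


def read_genepop(
    path: str | Path,
    digits: int | None = None,
    source: str = IN_SITU,
    population_labels: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Read a GenePop file (2- or 3-digit allele coding).

    Populations are labelled ``pop_1..pop_k`` in block order unless
    ``population_labels`` overrides them.  GenePop carries no provenance
    flag, so every individual gets ``source`` (default ``in_situ``).
    All-zero allele codes denote missing data.
    """
    if digits not in (None, 2, 3):
        raise ValueError("digits must be 2 or 3")
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise GenotypeParseError(f"{path}: empty file")

    # First line is a title; locus names follow, one per line or
    # comma-separated, until the first POP marker.
    idx = 1
    loci: list[str] = []
    while idx < len(lines) and lines[idx].strip().upper() != "POP":
        chunk = lines[idx].strip()
        if chunk:
            loci.extend(name.strip() for name in chunk.split(",") if name.strip())
        idx += 1
    if idx >= len(lines):
        raise GenotypeParseError(f"{path}: no POP block found")
    if not loci:
        raise GenotypeParseError(f"{path}: no locus names before first POP")

    individuals: list[IndividualRecord] = []
    pop_index = 0
    current_pop = ""
    counter = 0
    for line_num, line in enumerate(lines[idx:], start=idx + 1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.upper() == "POP":
            pop_index += 1
            if population_labels is not None:
                try:
                    current_pop = population_labels[pop_index - 1]
                except IndexError:
                    raise GenotypeParseError(
                        f"{path}: {pop_index} POP blocks but only "
                        f"{len(population_labels)} labels supplied"
                    ) from None
            else:
                current_pop = f"pop_{pop_index}"
            continue
        if "," not in stripped:
            raise GenotypeParseError(
                f"{path}: line {line_num} lacks the 'name , genotypes' comma"
            )
        name, geno_part = stripped.split(",", 1)
        name = name.strip()
        counter += 1
        if not name:
            name = f"ind_{counter}"
        entries = geno_part.split()
        if len(entries) != len(loci):
            raise GenotypeParseError(
                f"{path}: line {line_num} has {len(entries)} genotypes, "
                f"expected {len(loci)}"
            )
        genotypes: list[tuple[int, int]] = []
        for locus, entry in zip(loci, entries):
            d = digits if digits is not None else len(entry) // 2
            if d not in (2, 3) or len(entry) != 2 * d or not entry.isdigit():
                raise GenotypeParseError(
                    f"{path}: line {line_num}, locus {locus!r}: bad allele "
                    f"string {entry!r}"
                )
            a, b = int(entry[:d]), int(entry[d:])
            if a == 0 or b == 0:
                genotypes.append((MISSING, MISSING))
            else:
                genotypes.append((a, b))
        # Uniquify ids across blocks: GenePop names are often repeated.
        ind_id = f"{current_pop}:{name}"
        individuals.append(
            IndividualRecord(ind_id, current_pop, source, tuple(genotypes))
        )
    return GenotypeMatrix(tuple(loci), tuple(individuals))
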