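"""The genetic conservation gap and practical sizing conversions.

The gap between an actual collection and ideal random sampling is
expressed two ways: the fraction of the current collection size that
random sampling would need to match its capture (size ratio), and the
factor by which capture could grow at the current size (diversity
ratio).  Undefined values (threshold never crossed; collection larger
than the genotyped wild sample) are encoded as ``None`` and printed
"NA".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .resampling_engine import ResamplingCurve, minimum_sufficient_size

__all__ = [
    "GapReport",
    "gap_size_ratio",
    "gap_diversity_ratio",
    "attrition_adjust",
    "copies_to_frequency",
]


@dataclass(frozen=True)
class GapReport:
    taxon: str
    dataset_variant: str
    current_n_ex_situ: int
    current_capture_percent: float | None
    size_ratio: float | None
    diversity_ratio: float | None

    def rounded(self, ndigits: int = 2) -> dict[str, float | str]:
        """Table-style view with ratios rounded and None printed "NA"."""

        def fmt(v: float | None) -> float | str:
            return "NA" if v is None else round(v, ndigits)

        return {
            "taxon": self.taxon,
            "dataset_variant": self.dataset_variant,
            "current_n_ex_situ": self.current_n_ex_situ,
            "current_capture_percent": (
                "NA"
                if self.current_capture_percent is None
                else round(self.current_capture_percent, ndigits)
            ),
            "size_ratio": fmt(self.size_ratio),
            "diversity_ratio": fmt(self.diversity_ratio),
        }


def gap_size_ratio(
    current_capture_percent: float,
    current_n: int,
    curve: ResamplingCurve,
    category: str = "all",
) -> float | None:
    """Proportion of the current collection size that random sampling
    would need to reach the same capture.

    The threshold is the collection's own measured capture, so a 95%
    collection is compared against the curve's 95% sufficiency.  Returns
    ``None`` when the curve never crosses that capture level.
    """
    if current_n < 1:
        raise ValueError("current_n must be >= 1")
    suff = minimum_sufficient_size(curve, current_capture_percent, category)
    if suff.minimum_size is None:
        return None
    return suff.minimum_size / current_n


def gap_diversity_ratio(
    curve: ResamplingCurve,
    current_n: int,
    current_capture_percent: float,
    category: str = "all",
) -> float | None:
    """Factor by which capture could grow at the current collection size.

    Mean curve capture at n = ``current_n`` divided by the collection's
    measured capture.  ``None`` when the collection is larger than the
    genotyped wild sample (the curve grid ends at N wild individuals).
    """
    if current_capture_percent <= 0:
        raise ValueError("current_capture_percent must be > 0")
    if current_n > int(curve.sizes[-1]) or current_n < int(curve.sizes[0]):
        return None
    return curve.mean_at(current_n, category) / current_capture_percent


def attrition_adjust(minimum_size: int, survival_rate: float) -> int:
    """Seeds to collect so ``minimum_size`` plants survive attrition.

    Divides by the survival rate and rounds up, e.g. a minimum of 82
    with 10% seed survival requires 820 seeds.
    """
    if minimum_size < 1:
        raise ValueError("minimum_size must be >= 1")
    if not 0.0 < survival_rate <= 1.0:
        raise ValueError("survival_rate must be in (0, 1]")
    # guard against float noise pushing an exact quotient above the ceiling
    return math.ceil(round(minimum_size / survival_rate, 9))


def copies_to_frequency(copies: int, n_diploid_individuals: int) -> float:
    """Relative frequency of an allele present in ``copies`` copies among
    ``n_diploid_individuals`` diploids (2 copies carried per individual)."""
    if n_diploid_individuals < 1:
        raise ValueError("n_diploid_individuals must be >= 1")
    if copies < 0 or copies > 2 * n_diploid_individuals:
        raise ValueError(
            f"copies {copies} outside [0, {2 * n_diploid_individuals}]"
        )
    return copies / (2 * n_diploid_individuals)
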