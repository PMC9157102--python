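"""Estimators turning raw cross counts into drive performance rates.

These are the desk calculations behind the headline molecular rates:
drive inheritance from phenotype counts, drive conversion from inheritance,
the sex-averaged conversion rate, and the embryo resistance-allele
formation rate inferred from the sterility excess of drive-carrier
daughters of drive mothers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from scipy import stats

__all__ = [
    "CrossCounts",
    "SterilityCounts",
    "inheritance_rate",
    "conversion_from_inheritance",
    "average_conversion",
    "embryo_rate_from_sterility",
    "sterility_excess_test",
]


@dataclass(frozen=True)
class CrossCounts:
    """Pooled offspring phenotype counts from drive-heterozygote crosses.

    ``batches`` optionally keeps per-vial (with_drive, without_drive)
    subcounts; they must sum to the pooled totals.
    """

    parent_sex: str
    offspring_with_drive: int
    offspring_without_drive: int
    batches: list[tuple[int, int]] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.offspring_with_drive < 0 or self.offspring_without_drive < 0:
            raise ValueError("counts must be non-negative")
        if self.batches is not None:
            w = sum(b[0] for b in self.batches)
            wo = sum(b[1] for b in self.batches)
            if (w, wo) != (self.offspring_with_drive, self.offspring_without_drive):
                raise ValueError("batch subcounts do not sum to totals")

    @property
    def total(self) -> int:
        return self.offspring_with_drive + self.offspring_without_drive


@dataclass(frozen=True)
class SterilityCounts:
    """Sterility assay counts with a baseline control group."""

    sterile: int
    assessed: int
    baseline_sterile: int
    baseline_assessed: int

    def __post_init__(self) -> None:
        if not (0 <= self.sterile <= self.assessed):
            raise ValueError("sterile count must be between 0 and assessed")
        if not (0 <= self.baseline_sterile <= self.baseline_assessed):
            raise ValueError("baseline sterile count must be between 0 and baseline assessed")
        if self.assessed == 0 or self.baseline_assessed == 0:
            raise ValueError("assessed counts must be positive")


def inheritance_rate(x: CrossCounts) -> tuple[float, float]:
    """Pooled drive-inheritance proportion and its binomial standard error."""
    n = x.total
    if n == 0:
        raise ValueError("no offspring counted")
    rate = x.offspring_with_drive / n
    sem = math.sqrt(rate * (1.0 - rate) / n)
    return rate, sem


def conversion_from_inheritance(i: float) -> float:
    """Drive conversion rate c from the inheritance rate i = (1 + c) / 2.

    Valid when the drive does not affect offspring viability: a fraction c
    of wild-type alleles in the heterozygous germline is converted, so
    inheritance exceeds the Mendelian 1/2 by c/2.
    """
    if not (0.0 <= i <= 1.0):
        raise ValueError(f"inheritance rate must be in [0, 1], got {i!r}")
    if i < 0.5:
        warnings.warn(
            "inheritance below 50% implies negative conversion; "
            "check for viability effects",
            stacklevel=2,
        )
    return 2.0 * i - 1.0


def average_conversion(c_female: float, c_male: float) -> float:
    """Sex-averaged drive conversion rate (arithmetic mean)."""
    for name, c in (("c_female", c_female), ("c_male", c_male)):
        if not (0.0 <= c <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {c!r}")
    return 0.5 * (c_female + c_male)


def embryo_rate_from_sterility(s: SterilityCounts) -> float:
    """Embryo resistance-allele formation rate from a sterility excess.

    Solves ``baseline + (1 - baseline) * r = observed`` for ``r``: the
    probability that the paternal wild-type allele of a drive-carrier
    daughter was cleaved to a nonfunctional allele in the embryo, on top of
    the baseline sterility of the laboratory stock.
    """
    obs = s.sterile / s.assessed
    base = s.baseline_sterile / s.baseline_assessed
    if obs < base:
        raise ValueError(
            f"observed sterility {obs:.3f} is below the baseline {base:.3f}; "
            "a negative formation rate is not a rate"
        )
    if base >= 1.0:
        raise ValueError("baseline sterility of 100% leaves nothing to attribute")
    return (obs - base) / (1.0 - base)


def sterility_excess_test(s: SterilityCounts) -> float:
    """Two-sided Fisher's exact p-value for sterility above baseline."""
    table = [
        [s.sterile, s.assessed - s.sterile],
        [s.baseline_sterile, s.baseline_assessed - s.baseline_sterile],
    ]
    return float(stats.fisher_exact(table)[1])
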