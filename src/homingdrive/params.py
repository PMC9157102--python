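"""Drive efficiency parameters and fitness-cost model specifications."""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

__all__ = ["DriveParams", "FitnessModel", "FitnessSpec", "MEASURED_PARAMS"]


def _check_prob(name: str, x: float) -> None:
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"{name} must be a probability in [0, 1], got {x!r}")


@dataclass(frozen=True)
class DriveParams:
    """Molecular rates of the split homing suppression drive.

    Parameters
    ----------
    conversion_female, conversion_male
        Germline drive-conversion probability for a wild-type allele in a
        drive/wild-type heterozygote, by parent sex.  The default is the
        sex-averaged measured rate (76.7%) used for both sexes.
    germline_resistance_total
        Total probability that such a wild-type allele instead becomes a
        resistance allele in the germline (functional + nonfunctional).
        Conversion and resistance formation compete at the same germline
        stage, so ``conversion + germline_resistance_total <= 1`` per sex.
    embryo_cut_rate
        Probability that each wild-type allele in an offspring of a
        drive-carrying mother is cleaved by maternally deposited Cas9 and
        becomes a resistance allele.
    relative_r1_rate
        Fraction of newly formed resistance alleles that are functional
        (r1) rather than nonfunctional (r2).
    offtarget_germline_cut_rate
        Probability that each intact off-target allele is disrupted in the
        germline of a Cas9-bearing drive carrier.
    initial_offtarget_cut_fraction
        Fraction of off-target sites already disrupted in founder drive
        carriers (applied per allele, independently).
    cas9_present
        Split-drive switch: without the unlinked Cas9 allele the drive is
        inert (no conversion, no resistance formation, no off-target cuts).
    """

    conversion_female: float = 0.767
    conversion_male: float = 0.767
    germline_resistance_total: float = 0.222
    embryo_cut_rate: float = 0.522
    relative_r1_rate: float = 0.0
    offtarget_germline_cut_rate: float = 1.0
    initial_offtarget_cut_fraction: float = 0.5
    cas9_present: bool = True

    def __post_init__(self) -> None:
        for name in (
            "conversion_female",
            "conversion_male",
            "germline_resistance_total",
            "embryo_cut_rate",
            "relative_r1_rate",
            "offtarget_germline_cut_rate",
            "initial_offtarget_cut_fraction",
        ):
            _check_prob(name, getattr(self, name))
        for sex in ("female", "male"):
            c = getattr(self, f"conversion_{sex}")
            if c + self.germline_resistance_total > 1.0 + 1e-12:
                raise ValueError(
                    f"conversion_{sex} + germline_resistance_total exceeds 1 "
                    f"({c} + {self.germline_resistance_total})"
                )

    def conversion(self, female: bool) -> float:
        return self.conversion_female if female else self.conversion_male

    def without_cas9(self) -> "DriveParams":
        return replace(self, cas9_present=False)


#: Measured rates from the fly experiments, used as model defaults.
MEASURED_PARAMS = DriveParams()


class FitnessModel(str, enum.Enum):
    """Candidate fitness-cost architectures for the drive system.

    ``NEUTRAL``
        No cost beyond the engineered female sterility.
    ``SOMATIC_HET_FECUNDITY``
        Leaky somatic Cas9 cleavage reduces fecundity of female
        drive/wild-type heterozygotes only; the parameter is the net
        heterozygote fitness.
    ``DIRECT_VIABILITY``
        Drive alleles reduce viability of both sexes.
    ``DIRECT_FECUNDITY_MATING``
        Drive alleles reduce female fecundity and male mating success.
    ``OFFTARGET_VIABILITY`` / ``OFFTARGET_FECUNDITY_MATING``
        Same cost structures keyed on disrupted off-target alleles instead
        of drive alleles.
    """

    NEUTRAL = "neutral"
    SOMATIC_HET_FECUNDITY = "somatic_het_fecundity"
    DIRECT_VIABILITY = "direct_viability"
    DIRECT_FECUNDITY_MATING = "direct_fecundity_mating"
    OFFTARGET_VIABILITY = "offtarget_viability"
    OFFTARGET_FECUNDITY_MATING = "offtarget_fecundity_mating"


@dataclass(frozen=True)
class FitnessSpec:
    """A fitness model plus its homozygote-fitness parameter.

    ``homozygote_fitness`` is the fitness of individuals homozygous for the
    costly allele; heterozygotes get its square root (multiplicative costs
    per allele).  For ``SOMATIC_HET_FECUNDITY`` it is instead the net
    fitness of female drive/wild-type heterozygotes, applied directly.
    """

    model: FitnessModel = FitnessModel.NEUTRAL
    homozygote_fitness: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "model", FitnessModel(self.model))
        w = self.homozygote_fitness
        if not (w > 0.0 and math.isfinite(w)):
            raise ValueError(f"homozygote_fitness must be positive, got {w!r}")
        if self.model is FitnessModel.NEUTRAL and w != 1.0:
            raise ValueError("NEUTRAL fitness model requires homozygote_fitness = 1")

    @property
    def heterozygote_fitness(self) -> float:
        if self.model is FitnessModel.SOMATIC_HET_FECUNDITY:
            return self.homozygote_fitness
        return math.sqrt(self.homozygote_fitness)

    def with_fitness(self, w: float) -> "FitnessSpec":
        return replace(self, homozygote_fitness=w)


NEUTRAL = FitnessSpec(FitnessModel.NEUTRAL, 1.0)
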