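"""Two-locus diploid genotype space for a split homing suppression drive.

The drive locus (inside the female-fertility target gene) carries one of
four alleles: wild-type, the drive construct itself, a functional ("r1")
resistance allele that preserves target-gene function, or a nonfunctional
("r2") resistance allele.  A second, unlinked locus summarises off-target
cleavage damage with intact/disrupted alleles.  Allele pairs are unordered,
giving 10 x 3 = 30 two-locus genotypes per sex and 60 sexed states.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DriveAllele",
    "OffTargetAllele",
    "Sex",
    "Genotype",
    "DRIVE_PAIRS",
    "OFFTARGET_PAIRS",
    "N_GENOTYPES",
    "enumerate_genotypes",
    "genotype_index",
    "is_female_sterile",
]


class DriveAllele(enum.IntEnum):
    """Allele at the drive/target locus; order fixes canonical sorting."""

    WT = 0
    DRIVE = 1
    R1 = 2
    R2 = 3


class OffTargetAllele(enum.IntEnum):
    INTACT = 0
    DISRUPTED = 1


class Sex(enum.IntEnum):
    FEMALE = 0
    MALE = 1


# Canonical unordered pairs: sorted tuples, lexicographic order.
DRIVE_PAIRS: tuple[tuple[DriveAllele, DriveAllele], ...] = tuple(
    (DriveAllele(a), DriveAllele(b))
    for a, b in itertools.combinations_with_replacement(range(4), 2)
)
OFFTARGET_PAIRS: tuple[tuple[OffTargetAllele, OffTargetAllele], ...] = tuple(
    (OffTargetAllele(a), OffTargetAllele(b))
    for a, b in itertools.combinations_with_replacement(range(2), 2)
)

#: Number of unsexed two-locus genotypes (10 drive pairs x 3 off-target pairs).
N_GENOTYPES = len(DRIVE_PAIRS) * len(OFFTARGET_PAIRS)

_DRIVE_PAIR_INDEX = {p: i for i, p in enumerate(DRIVE_PAIRS)}
_OFFTARGET_PAIR_INDEX = {p: i for i, p in enumerate(OFFTARGET_PAIRS)}

# pair_index[a, b] == pair_index[b, a]: unordered-pair lookup tables used by
# the vectorised recursion.
DRIVE_PAIR_LOOKUP = np.zeros((4, 4), dtype=np.intp)
for (a, b), i in _DRIVE_PAIR_INDEX.items():
    DRIVE_PAIR_LOOKUP[a, b] = DRIVE_PAIR_LOOKUP[b, a] = i
OFFTARGET_PAIR_LOOKUP = np.zeros((2, 2), dtype=np.intp)
for (a, b), i in _OFFTARGET_PAIR_INDEX.items():
    OFFTARGET_PAIR_LOOKUP[a, b] = OFFTARGET_PAIR_LOOKUP[b, a] = i


@dataclass(frozen=True)
class Genotype:
    """An unordered two-locus diploid genotype with sex.

    ``drive_pair`` and ``offtarget_pair`` are stored in canonical sorted
    order, so ``Genotype`` instances compare equal under pair symmetry.
    """

    drive_pair: tuple[DriveAllele, DriveAllele]
    offtarget_pair: tuple[OffTargetAllele, OffTargetAllele]
    sex: Sex

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "drive_pair", tuple(sorted(DriveAllele(a) for a in self.drive_pair))
        )
        object.__setattr__(
            self,
            "offtarget_pair",
            tuple(sorted(OffTargetAllele(a) for a in self.offtarget_pair)),
        )
        object.__setattr__(self, "sex", Sex(self.sex))

    @property
    def has_drive(self) -> bool:
        return DriveAllele.DRIVE in self.drive_pair

    @property
    def n_wt(self) -> int:
        return sum(1 for a in self.drive_pair if a is DriveAllele.WT)

    @property
    def index(self) -> int:
        """Index into the canonical 30-state (per-sex) ordering."""
        return genotype_index(self.drive_pair, self.offtarget_pair)

    def __str__(self) -> str:  # e.g. "DRIVE/WT INTACT/DISRUPTED female"
        dp = "/".join(a.name for a in self.drive_pair)
        op = "/".join(a.name for a in self.offtarget_pair)
        return f"{dp} {op} {self.sex.name.lower()}"


def genotype_index(drive_pair, offtarget_pair) -> int:
    """Canonical per-sex index: drive pair major, off-target pair minor."""
    dp = tuple(sorted(DriveAllele(a) for a in drive_pair))
    op = tuple(sorted(OffTargetAllele(a) for a in offtarget_pair))
    return _DRIVE_PAIR_INDEX[dp] * len(OFFTARGET_PAIRS) + _OFFTARGET_PAIR_INDEX[op]


def enumerate_genotypes() -> list[Genotype]:
    """All 60 sexed genotypes in canonical order (females first).

    Within each sex, ordering follows allele sort WT < DRIVE < R1 < R2 and
    INTACT < DISRUPTED, drive pair varying slowest.
    """
    out = []
    for sex in (Sex.FEMALE, Sex.MALE):
        for dp in DRIVE_PAIRS:
            for op in OFFTARGET_PAIRS:
                out.append(Genotype(dp, op, sex))
    return out


def _pair_is_fertile(drive_pair) -> bool:
    return any(a in (DriveAllele.WT, DriveAllele.R1) for a in drive_pair)


def is_female_sterile(g: Genotype) -> bool:
    """Whether a female lacks any functional copy of the fertility target.

    Females whose drive locus carries only drive and/or nonfunctional (r2)
    resistance alleles are sterile; a wild-type or functional (r1) allele
    restores fertility.  The rule is female-specific.
    """
    if g.sex is not Sex.FEMALE:
        raise ValueError("sterility rule applies to females only")
    return not _pair_is_fertile(g.drive_pair)


# Per-index boolean mask used by the recursion: True where a female genotype
# is sterile.
STERILE_FEMALE_MASK = np.array(
    [not _pair_is_fertile(dp) for dp in DRIVE_PAIRS for _ in OFFTARGET_PAIRS],
    dtype=bool,
)

#: mask over the 30 per-sex states: genotype carries >=1 drive allele
CARRIER_MASK = np.array(
    [DriveAllele.DRIVE in dp for dp in DRIVE_PAIRS for _ in OFFTARGET_PAIRS],
    dtype=bool,
)

#: number of drive alleles per state
N_DRIVE_ALLELES = np.array(
    [sum(a is DriveAllele.DRIVE for a in dp) for dp in DRIVE_PAIRS for _ in OFFTARGET_PAIRS],
    dtype=np.intp,
)

#: number of disrupted off-target alleles per state
N_DISRUPTED_ALLELES = np.array(
    [
        sum(a is OffTargetAllele.DISRUPTED for a in op)
        for _ in DRIVE_PAIRS
        for op in OFFTARGET_PAIRS
    ],
    dtype=np.intp,
)

#: number of R1 alleles per state
N_R1_ALLELES = np.array(
    [sum(a is DriveAllele.R1 for a in dp) for dp in DRIVE_PAIRS for _ in OFFTARGET_PAIRS],
    dtype=np.intp,
)
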