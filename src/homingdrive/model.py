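"""Deterministic discrete-generation recursion for the suppression drive.

The population is tracked as a genotype-frequency distribution per sex
(30 two-locus states each).  One generation consists of: removal of sterile
females from the breeding pool, fecundity weighting of mothers, mating-
success-weighted random mate choice, germline gamete production with drive
conversion / resistance formation and off-target cleavage, embryo cleavage
by maternally deposited Cas9, and viability selection on offspring.  Sexes
are assigned 1:1 at birth and generations do not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .genotypes import (
    CARRIER_MASK,
    DRIVE_PAIR_LOOKUP,
    DRIVE_PAIRS,
    N_DISRUPTED_ALLELES,
    N_DRIVE_ALLELES,
    N_GENOTYPES,
    OFFTARGET_PAIR_LOOKUP,
    OFFTARGET_PAIRS,
    STERILE_FEMALE_MASK,
    DriveAllele,
    Genotype,
    OffTargetAllele,
    Sex,
    enumerate_genotypes,
    genotype_index,
)
from .params import DriveParams, FitnessModel, FitnessSpec

__all__ = [
    "PopulationState",
    "LoadReport",
    "ExtinctionError",
    "germline_gamete_distribution",
    "apply_embryo_cutting",
    "genotype_fitness",
    "next_generation",
    "carrier_frequency",
    "genetic_load",
    "equilibrium_carrier_frequency",
    "solve_homozygote_cost_for_equilibrium",
    "required_genetic_load",
    "artificial_selection_equilibrium_load",
    "founder_state",
]

_NORM_TOL = 1e-9

# Gamete types: (drive allele 0..3, off-target allele 0..1) -> 8 states,
# index = drive * 2 + offtarget.
_N_GAMETES = 8

# Map an (maternal gamete, paternal gamete) pair to the offspring's
# 30-state genotype index; precomputed once.
_OFFSPRING_INDEX = np.empty((_N_GAMETES, _N_GAMETES), dtype=np.intp)
for _gm in range(_N_GAMETES):
    for _gp in range(_N_GAMETES):
        _dp = DRIVE_PAIR_LOOKUP[_gm // 2, _gp // 2]
        _op = OFFTARGET_PAIR_LOOKUP[_gm % 2, _gp % 2]
        _OFFSPRING_INDEX[_gm, _gp] = _dp * len(OFFTARGET_PAIRS) + _op
_OFFSPRING_INDEX_FLAT = _OFFSPRING_INDEX.ravel()


class ExtinctionError(RuntimeError):
    """Raised when the modelled population has zero reproductive output."""


@dataclass
class PopulationState:
    """Per-sex genotype-frequency distributions (each sums to 1).

    ``female`` and ``male`` are length-30 arrays over the canonical
    genotype ordering; sexes are assumed equally frequent, so pooled
    quantities weight each sex by 1/2.
    """

    female: np.ndarray
    male: np.ndarray

    def __post_init__(self) -> None:
        self.female = np.asarray(self.female, dtype=float)
        self.male = np.asarray(self.male, dtype=float)
        for name, arr in (("female", self.female), ("male", self.male)):
            if arr.shape != (N_GENOTYPES,):
                raise ValueError(f"{name} distribution must have shape ({N_GENOTYPES},)")
            if (arr < -_NORM_TOL).any():
                raise ValueError(f"{name} distribution has negative entries")
            if abs(arr.sum() - 1.0) > 1e-6:
                raise ValueError(f"{name} distribution sums to {arr.sum()}, not 1")
        self.female = np.clip(self.female, 0.0, None)
        self.male = np.clip(self.male, 0.0, None)
        self.female /= self.female.sum()
        self.male /= self.male.sum()

    def pooled(self) -> np.ndarray:
        return 0.5 * (self.female + self.male)

    def copy(self) -> "PopulationState":
        return PopulationState(self.female.copy(), self.male.copy())

    @classmethod
    def from_frequencies(cls, freq: dict[Genotype, float]) -> "PopulationState":
        """Build a state from a mapping over sexed genotypes."""
        f = np.zeros(N_GENOTYPES)
        m = np.zeros(N_GENOTYPES)
        for g, x in freq.items():
            (f if g.sex is Sex.FEMALE else m)[g.index] += x
        return cls(f, m)

    def to_frequencies(self) -> dict[Genotype, float]:
        out: dict[Genotype, float] = {}
        for g in enumerate_genotypes():
            arr = self.female if g.sex is Sex.FEMALE else self.male
            out[g] = float(arr[g.index])
        return out


@dataclass(frozen=True)
class LoadReport:
    """Genetic load (relative loss of reproductive capacity) of a state."""

    genetic_load: float
    fertile_female_fraction: float


def founder_state(
    carrier_freq: float, p: DriveParams, *, carrier_offtarget_fraction: float | None = None
) -> PopulationState:
    """Release-generation state: drive/wild-type heterozygous carriers.

    Carriers are drive heterozygotes whose off-target alleles are already
    disrupted with probability ``initial_offtarget_cut_fraction`` each
    (independently); non-carriers are fully wild-type with intact
    off-target sites.  Both sexes share the same composition.
    """
    if not (0.0 <= carrier_freq <= 1.0):
        raise ValueError("carrier_freq must be in [0, 1]")
    q = (
        p.initial_offtarget_cut_fraction
        if carrier_offtarget_fraction is None
        else carrier_offtarget_fraction
    )
    dist = np.zeros(N_GENOTYPES)
    het = (DriveAllele.WT, DriveAllele.DRIVE)
    ot_probs = {
        (OffTargetAllele.INTACT, OffTargetAllele.INTACT): (1 - q) ** 2,
        (OffTargetAllele.INTACT, OffTargetAllele.DISRUPTED): 2 * q * (1 - q),
        (OffTargetAllele.DISRUPTED, OffTargetAllele.DISRUPTED): q**2,
    }
    for op, pr in ot_probs.items():
        dist[genotype_index(het, op)] += carrier_freq * pr
    wt_idx = genotype_index(
        (DriveAllele.WT, DriveAllele.WT), (OffTargetAllele.INTACT, OffTargetAllele.INTACT)
    )
    dist[wt_idx] += 1.0 - carrier_freq
    return PopulationState(dist, dist.copy())


# ---------------------------------------------------------------------------
# Gametes and embryo cutting
# ---------------------------------------------------------------------------


def _gamete_matrix(p: DriveParams, female: bool) -> np.ndarray:
    """(30, 8) matrix: row g = gamete distribution of a parent of genotype g."""
    c = p.conversion(female) if p.cas9_present else 0.0
    g_tot = p.germline_resistance_total if p.cas9_present else 0.0
    rho = p.relative_r1_rate
    q = p.offtarget_germline_cut_rate if p.cas9_present else 0.0

    out = np.zeros((N_GENOTYPES, _N_GAMETES))
    for i_dp, dp in enumerate(DRIVE_PAIRS):
        drive_dist = np.zeros(4)
        is_het_wt_drive = set(dp) == {DriveAllele.WT, DriveAllele.DRIVE}
        for allele in dp:
            if allele is DriveAllele.WT and is_het_wt_drive:
                # conversion and resistance formation compete at the same
                # germline stage
                drive_dist[DriveAllele.DRIVE] += 0.5 * c
                drive_dist[DriveAllele.R1] += 0.5 * rho * g_tot
                drive_dist[DriveAllele.R2] += 0.5 * (1 - rho) * g_tot
                drive_dist[DriveAllele.WT] += 0.5 * (1 - c - g_tot)
            else:
                drive_dist[allele] += 0.5
        has_drive = DriveAllele.DRIVE in dp
        for i_op, op in enumerate(OFFTARGET_PAIRS):
            ot_dist = np.zeros(2)
            for allele in op:
                if allele is OffTargetAllele.INTACT and has_drive:
                    ot_dist[OffTargetAllele.DISRUPTED] += 0.5 * q
                    ot_dist[OffTargetAllele.INTACT] += 0.5 * (1 - q)
                else:
                    ot_dist[allele] += 0.5
            row = np.outer(drive_dist, ot_dist).ravel()
            out[i_dp * len(OFFTARGET_PAIRS) + i_op] = row
    return out


def germline_gamete_distribution(parent: Genotype, p: DriveParams) -> dict:
    """Distribution over (DriveAllele, OffTargetAllele) gametes of a parent.

    In drive/wild-type heterozygotes with Cas9 the wild-type allele is
    converted to a drive allele with the sex-specific conversion rate, or
    to a resistance allele (r1:r2 split by ``relative_r1_rate``) with the
    total germline resistance rate, before Mendelian transmission.  Any
    Cas9-bearing drive carrier also cleaves intact off-target alleles at
    ``offtarget_germline_cut_rate``.  Loci are unlinked.
    """
    mat = _gamete_matrix(p, female=(parent.sex is Sex.FEMALE))
    row = mat[parent.index]
    out = {}
    for d in DriveAllele:
        for o in OffTargetAllele:
            pr = row[int(d) * 2 + int(o)]
            if pr > 0:
                out[(d, o)] = float(pr)
    return out


def _embryo_matrix(p: DriveParams) -> np.ndarray:
    """(30, 30) column-stochastic map applying embryo cutting to offspring.

    Entry [j, i] is P(offspring genotype i -> j) when the mother carries a
    drive allele and Cas9: each wild-type drive-locus allele is cleaved
    independently with probability ``embryo_cut_rate`` and becomes r1 or r2
    (split by ``relative_r1_rate``).  Off-target alleles are untouched.
    """
    e = p.embryo_cut_rate if p.cas9_present else 0.0
    rho = p.relative_r1_rate
    allele_fate = {  # WT allele -> distribution over alleles after embryo stage
        DriveAllele.WT: 1 - e,
        DriveAllele.R1: e * rho,
        DriveAllele.R2: e * (1 - rho),
    }
    mat = np.zeros((N_GENOTYPES, N_GENOTYPES))
    for i_dp, dp in enumerate(DRIVE_PAIRS):
        fates: list[dict] = []
        for allele in dp:
            if allele is DriveAllele.WT:
                fates.append(allele_fate)
            else:
                fates.append({allele: 1.0})
        for a1, p1 in fates[0].items():
            for a2, p2 in fates[1].items():
                j_dp = DRIVE_PAIR_LOOKUP[a1, a2]
                for i_op in range(len(OFFTARGET_PAIRS)):
                    mat[j_dp * len(OFFTARGET_PAIRS) + i_op, i_dp * len(OFFTARGET_PAIRS) + i_op] += (
                        p1 * p2
                    )
    return mat


def apply_embryo_cutting(
    offspring_dist: np.ndarray, mother: Genotype, p: DriveParams
) -> np.ndarray:
    """Apply maternal-Cas9 embryo cleavage to an offspring distribution.

    No-op unless the mother carries at least one drive allele and Cas9 is
    present.  ``offspring_dist`` is a normalized length-30 array.
    """
    dist = np.asarray(offspring_dist, dtype=float)
    if abs(dist.sum() - 1.0) > 1e-6 or (dist < 0).any():
        raise ValueError("offspring_dist must be a normalized distribution")
    if not (mother.has_drive and p.cas9_present):
        return dist.copy()
    return _embryo_matrix(p) @ dist


# ---------------------------------------------------------------------------
# Fitness
# ---------------------------------------------------------------------------


def _fitness_arrays(spec: FitnessSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(fecundity[30], mating[30], viability[30]) multiplier arrays.

    Fecundity applies to females, mating success to males, viability to
    both sexes; multipliers multiply across loci.
    """
    w = spec.homozygote_fitness
    ones = np.ones(N_GENOTYPES)
    fec, mat, via = ones.copy(), ones.copy(), ones.copy()
    model = spec.model
    if model is FitnessModel.NEUTRAL:
        pass
    elif model is FitnessModel.SOMATIC_HET_FECUNDITY:
        het_wt_drive = np.array(
            [set(dp) == {DriveAllele.WT, DriveAllele.DRIVE} for dp in DRIVE_PAIRS for _ in OFFTARGET_PAIRS]
        )
        fec = np.where(het_wt_drive, w, 1.0)
    else:
        n_cost = N_DRIVE_ALLELES if model.value.startswith("direct") else N_DISRUPTED_ALLELES
        mult = w ** (n_cost / 2.0)  # sqrt(w) per costly allele copy
        if model in (FitnessModel.DIRECT_VIABILITY, FitnessModel.OFFTARGET_VIABILITY):
            via = mult
        elif model in (
            FitnessModel.DIRECT_FECUNDITY_MATING,
            FitnessModel.OFFTARGET_FECUNDITY_MATING,
        ):
            fec = mult
            mat = mult
        else:  # pragma: no cover - FitnessModel is exhaustive
            raise ValueError(f"unknown fitness model {model!r}")
    return fec, mat, via


def genotype_fitness(g: Genotype, spec: FitnessSpec) -> tuple[float, float, float]:
    """(fecundity, mating-success, viability) multipliers for one genotype.

    Fecundity is meaningful for females and mating success for males; the
    engineered sterility of females without a functional fertility allele
    is handled separately and is *not* part of these multipliers.
    """
    fec, mat, via = _fitness_arrays(spec)
    i = g.index
    if g.sex is Sex.MALE:
        # female-only costs do not apply to males
        f = 1.0 if spec.model is FitnessModel.SOMATIC_HET_FECUNDITY else float(fec[i])
        return (f, float(mat[i]), float(via[i]))
    return (float(fec[i]), float(mat[i]), float(via[i]))


# ---------------------------------------------------------------------------
# The generation step
# ---------------------------------------------------------------------------


@lru_cache(maxsize=64)
def _operators(p: DriveParams, spec: FitnessSpec):
    """Precomputed matrices for a (params, fitness) pair."""
    return (
        _gamete_matrix(p, female=True),
        _gamete_matrix(p, female=False),
        _embryo_matrix(p),
        _fitness_arrays(spec),
    )


def _offspring_from_gametes(g_mom: np.ndarray, g_dad: np.ndarray) -> np.ndarray:
    """Combine maternal/paternal gamete distributions into 30 genotypes."""
    pair_probs = np.outer(g_mom, g_dad).ravel()
    return np.bincount(_OFFSPRING_INDEX_FLAT, weights=pair_probs, minlength=N_GENOTYPES)


def _reproduce(
    state: PopulationState, p: DriveParams, spec: FitnessSpec
) -> tuple[np.ndarray, float, float]:
    """One round of reproduction.

    Returns ``(offspring_dist, mean_output, fertile_fraction)`` where
    ``offspring_dist`` is the normalized post-viability offspring genotype
    distribution (identical for both sexes), ``mean_output`` is the mean
    per-female reproductive output relative to an all-wild-type population
    (the quantity whose complement is the genetic load) and
    ``fertile_fraction`` the fraction of females that are fertile.
    """
    gam_f, gam_m, embryo, (fec, mat, via) = _operators(p, spec)

    fertile = ~STERILE_FEMALE_MASK
    w_mothers = state.female * fertile * fec
    w_fathers = state.male * mat
    total_mothers = w_mothers.sum()
    total_fathers = w_fathers.sum()
    if total_mothers <= 0.0 or total_fathers <= 0.0:
        raise ExtinctionError("no fertile mothers or no available fathers")

    mothers = w_mothers / total_mothers
    fathers = w_fathers / total_fathers
    g_dad = fathers @ gam_m

    cas9_carrier = CARRIER_MASK & np.full(N_GENOTYPES, p.cas9_present)
    mom_drive = mothers * cas9_carrier
    mom_plain = mothers * ~cas9_carrier
    off = np.zeros(N_GENOTYPES)
    if mom_drive.sum() > 0:
        off += embryo @ _offspring_from_gametes(mom_drive @ gam_f, g_dad)
    if mom_plain.sum() > 0:
        off += _offspring_from_gametes(mom_plain @ gam_f, g_dad)

    off_viable = off * via
    survival = off_viable.sum()  # mean offspring viability, <= 1
    if survival <= 0.0:
        raise ExtinctionError("no viable offspring")

    # Mean per-female output relative to wild-type = fecundity-and-sterility
    # weighted share of mothers times mean offspring viability.  For the
    # wild-type reference each factor is 1.
    mean_output = total_mothers * survival
    return off_viable / survival, mean_output, float((state.female * fertile).sum())


def next_generation(
    state: PopulationState, p: DriveParams, spec: FitnessSpec
) -> PopulationState:
    """Advance the deterministic (infinite-population) recursion one step.

    Raises :class:`ExtinctionError` if all females are sterile or no
    offspring are viable.
    """
    off, _, _ = _reproduce(state, p, spec)
    return PopulationState(off.copy(), off.copy())


def carrier_frequency(state: PopulationState) -> float:
    """Pooled frequency of drive carriers (>= 1 drive allele; DsRed)."""
    return float(state.pooled() @ CARRIER_MASK)


def genetic_load(state: PopulationState, p: DriveParams, spec: FitnessSpec) -> LoadReport:
    """Fractional loss of reproductive capacity relative to wild-type.

    Load 0 means reproduction equals an all-wild-type population of the
    same size; load 1 means the population cannot reproduce at all.
    """
    try:
        _, mean_output, fertile_frac = _reproduce(state, p, spec)
    except ExtinctionError:
        fertile_frac = float((state.female * ~STERILE_FEMALE_MASK).sum())
        return LoadReport(genetic_load=1.0, fertile_female_fraction=fertile_frac)
    return LoadReport(
        genetic_load=max(0.0, 1.0 - mean_output),
        fertile_female_fraction=fertile_frac,
    )


def equilibrium_carrier_frequency(
    p: DriveParams,
    spec: FitnessSpec,
    init_carrier_freq: float = 0.2,
    tol: float = 1e-6,
    max_gens: int = 1000,
    *,
    return_state: bool = False,
):
    """Iterate the recursion until the carrier frequency stops changing.

    Returns the equilibrium carrier frequency (or ``(freq, state)`` with
    ``return_state=True``).  Raises ``RuntimeError`` on non-convergence and
    propagates :class:`ExtinctionError` if reproduction fails.
    """
    if not (0.0 < init_carrier_freq < 1.0):
        raise ValueError("init_carrier_freq must be strictly between 0 and 1")
    state = founder_state(init_carrier_freq, p)
    freq = carrier_frequency(state)
    for _ in range(max_gens):
        state = next_generation(state, p, spec)
        new = carrier_frequency(state)
        if abs(new - freq) < tol:
            return (new, state) if return_state else new
        freq = new
    raise RuntimeError(f"carrier frequency did not converge within {max_gens} generations")


def solve_homozygote_cost_for_equilibrium(
    target_carrier_freq: float,
    p: DriveParams,
    model: FitnessModel = FitnessModel.DIRECT_VIABILITY,
    *,
    tol: float = 1e-4,
) -> float:
    """Homozygote fitness cost (1 - w) giving a target equilibrium frequency.

    The equilibrium carrier frequency decreases monotonically in the cost,
    so bisection on cost in [0, 1) finds the unique root.  Raises
    ``ValueError`` if the target exceeds the zero-cost equilibrium.
    """

    def eq(cost: float) -> float:
        spec = FitnessSpec(model, 1.0 - cost) if cost > 0 else FitnessSpec()
        try:
            return equilibrium_carrier_frequency(p, spec)
        except ExtinctionError:
            return 0.0

    hi_freq = eq(0.0)
    if target_carrier_freq > hi_freq + 1e-9:
        raise ValueError(
            f"target {target_carrier_freq} exceeds the zero-cost equilibrium {hi_freq:.4f}"
        )
    lo, hi = 0.0, 1.0 - 1e-6
    if abs(target_carrier_freq - hi_freq) < 1e-9:
        return 0.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if eq(mid) > target_carrier_freq:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def required_genetic_load(eggs_per_female: float, egg_to_adult_survival: float) -> float:
    """Genetic load needed to push a population below replacement.

    With ``b = eggs_per_female * egg_to_adult_survival`` surviving
    offspring per female and a 1:1 sex ratio, each female is replaced as
    long as effective fertility exceeds ``2 / b``; the threshold load is
    ``1 - 2 / b``.
    """
    b = eggs_per_female * egg_to_adult_survival
    if b < 2.0:
        raise ValueError(
            "population is below replacement even without a drive "
            f"(eggs * survival = {b:.3f} < 2)"
        )
    return 1.0 - 2.0 / b


def artificial_selection_equilibrium_load(
    p: DriveParams,
    spec: FitnessSpec,
    *,
    tol: float = 1e-6,
    max_gens: int = 200,
) -> float:
    """Equilibrium genetic load of the discard-non-carriers protocol.

    Deterministic limit of the small-cage artificial-selection design: each
    generation all non-carrier adults are removed before mating, which
    drives wild-type alleles out and raises the genetic load.  Returns the
    load of the post-removal population at equilibrium.
    """
    state = founder_state(1.0, p)
    prev = None
    for _ in range(max_gens):
        load = genetic_load(state, p, spec).genetic_load
        if prev is not None and abs(load - prev) < tol:
            return load
        prev = load
        off, _, _ = _reproduce(state, p, spec)
        kept = off * CARRIER_MASK
        if kept.sum() <= 0:
            raise ExtinctionError("no drive carriers among offspring")
        kept = kept / kept.sum()
        state = PopulationState(kept.copy(), kept.copy())
    raise RuntimeError(f"selection-protocol load did not converge within {max_gens} generations")
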