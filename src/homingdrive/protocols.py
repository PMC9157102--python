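"""Stochastic simulators of the cage experiments.

Two designs are modelled: the large-cage study, where a fixed number of
adults is sampled each generation from the model-predicted offspring
distribution, and the artificial-selection small-cage study, where all
non-carrier adults are discarded before mating and the population size is
determined by the offspring the remaining flies produce.  These simulators
double as the synthetic-data generators for the inference and estimator
modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cross_stats import CrossCounts, SterilityCounts
from .genotypes import CARRIER_MASK, N_GENOTYPES, N_R1_ALLELES
from .model import (
    ExtinctionError,
    PopulationState,
    _reproduce,
    founder_state,
    genetic_load,
)
from .params import DriveParams, FitnessSpec

__all__ = [
    "SimConfig",
    "SimOutput",
    "simulate_cage",
    "simulate_artificial_selection",
    "generate_cross_dataset",
    "count_r1_alleles",
]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a stochastic cage run.

    ``population_size_per_generation`` fixes the adult census for the
    large-cage design; the artificial-selection design ignores it and lets
    offspring numbers (``eggs_per_female`` x ``egg_to_adult_survival``,
    defaults 20 eggs and 80% survival) determine the census.
    """

    population_size_per_generation: int = 4000
    n_generations: int = 10
    init_carrier_freq: float = 0.088
    seed: int = 0
    discard_noncarriers: bool = False
    eggs_per_female: float = 20.0
    egg_to_adult_survival: float = 0.8

    def __post_init__(self) -> None:
        if self.population_size_per_generation < 2:
            raise ValueError("population size must be at least 2")
        if not (0.0 <= self.init_carrier_freq <= 1.0):
            raise ValueError("init_carrier_freq must be in [0, 1]")
        if self.n_generations < 1:
            raise ValueError("n_generations must be positive")


@dataclass
class SimOutput:
    """Per-generation tallies of a simulated cage.

    ``table`` has one row per generation with columns ``generation``,
    ``carriers``, ``noncarriers``, ``load`` (genetic load of the adults of
    that generation) and ``popsize``.  ``genotype_tallies`` holds the raw
    per-sex genotype counts (generations x 2 x 30).  ``termination`` is
    ``"COMPLETED"`` or ``"EXTINCT"``.
    """

    table: pd.DataFrame
    genotype_tallies: np.ndarray
    termination: str = "COMPLETED"

    @property
    def carrier_frequencies(self) -> np.ndarray:
        tot = self.table["carriers"] + self.table["noncarriers"]
        return (self.table["carriers"] / tot).to_numpy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _sample_adults(
    rng: np.random.Generator, n: int, female_dist: np.ndarray, male_dist: np.ndarray
) -> np.ndarray:
    """Draw n adults; returns (2, 30) counts (females, males)."""
    probs = np.concatenate([0.5 * female_dist, 0.5 * male_dist])
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum()
    draw = rng.multinomial(n, probs)
    return draw.reshape(2, N_GENOTYPES)


def _tally_row(gen: int, counts: np.ndarray, load: float) -> dict:
    pooled = counts.sum(axis=0)
    carriers = int(pooled[CARRIER_MASK].sum())
    return {
        "generation": gen,
        "carriers": carriers,
        "noncarriers": int(pooled.sum()) - carriers,
        "load": load,
        "popsize": int(pooled.sum()),
    }


def _state_from_counts(counts: np.ndarray) -> PopulationState:
    f, m = counts[0].astype(float), counts[1].astype(float)
    if f.sum() == 0 or m.sum() == 0:
        raise ExtinctionError("one sex is absent")
    return PopulationState(f / f.sum(), m / m.sum())


def simulate_cage(p: DriveParams, spec: FitnessSpec, cfg: SimConfig) -> SimOutput:
    """Simulate the large-cage study with a fixed adult census.

    Founders are sampled from the release composition (drive/wild-type
    heterozygous carriers, wild-type non-carriers); each following
    generation draws ``population_size_per_generation`` adults
    multinomially from the deterministic next-generation distribution
    conditioned on the realized current genotype tallies.
    """
    if cfg.discard_noncarriers:
        raise ValueError("use simulate_artificial_selection for the discard design")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.population_size_per_generation
    init = founder_state(cfg.init_carrier_freq, p)

    rows, tallies = [], []
    counts = _sample_adults(rng, n, init.female, init.male)
    termination = "COMPLETED"
    for gen in range(cfg.n_generations + 1):
        try:
            state = _state_from_counts(counts)
            load = genetic_load(state, p, spec).genetic_load
        except ExtinctionError:
            rows.append(_tally_row(gen, counts, 1.0))
            tallies.append(counts)
            termination = "EXTINCT"
            break
        rows.append(_tally_row(gen, counts, load))
        tallies.append(counts)
        if gen == cfg.n_generations:
            break
        try:
            off, _, _ = _reproduce(state, p, spec)
        except ExtinctionError:
            termination = "EXTINCT"
            break
        counts = _sample_adults(rng, n, off, off)
    return SimOutput(pd.DataFrame(rows), np.array(tallies), termination)


def simulate_artificial_selection(
    p: DriveParams, spec: FitnessSpec, cfg: SimConfig, *, n_founder_pairs: int = 50
) -> SimOutput:
    """Simulate the artificial-selection small-cage protocol.

    Starts from ``n_founder_pairs`` drive-heterozygous females and males.
    Each generation all non-carrier adults are discarded, the survivors
    mate, and the number of adults in the next generation is drawn as
    Poisson with mean (fertile females x eggs_per_female x
    egg_to_adult_survival x mean relative output per female); genotypes are
    assigned multinomially.  Terminates on extinction.
    """
    rng = np.random.default_rng(cfg.seed)
    het = founder_state(1.0, p)
    counts = np.zeros((2, N_GENOTYPES), dtype=int)
    counts[0] = rng.multinomial(n_founder_pairs, het.female)
    counts[1] = rng.multinomial(n_founder_pairs, het.male)

    rows, tallies = [], []
    termination = "COMPLETED"
    for gen in range(cfg.n_generations + 1):
        # discard non-carrier adults (DsRed screen)
        counts = counts * CARRIER_MASK[np.newaxis, :]
        try:
            state = _state_from_counts(counts)
            load = genetic_load(state, p, spec).genetic_load
        except ExtinctionError:
            rows.append(_tally_row(gen, counts, 1.0))
            tallies.append(counts)
            termination = "EXTINCT"
            break
        rows.append(_tally_row(gen, counts, load))
        tallies.append(counts)
        if gen == cfg.n_generations:
            break
        try:
            off, mean_output, _ = _reproduce(state, p, spec)
        except ExtinctionError:
            termination = "EXTINCT"
            break
        n_females = counts[0].sum()
        expected_adults = (
            n_females * cfg.eggs_per_female * cfg.egg_to_adult_survival * mean_output
        )
        n_next = rng.poisson(expected_adults)
        if n_next == 0:
            counts = np.zeros((2, N_GENOTYPES), dtype=int)
            rows.append(_tally_row(gen + 1, counts, 1.0))
            tallies.append(counts)
            termination = "EXTINCT"
            break
        counts = _sample_adults(rng, int(n_next), off, off)
    return SimOutput(pd.DataFrame(rows), np.array(tallies), termination)


def count_r1_alleles(out: SimOutput) -> int:
    """Total functional (r1) resistance alleles ever observed in a run."""
    return int((out.genotype_tallies * N_R1_ALLELES[np.newaxis, np.newaxis, :]).sum())


def generate_cross_dataset(
    p: DriveParams,
    n_parents: int = 20,
    offspring_per_parent: int = 50,
    seed: int = 0,
    *,
    baseline_sterility: float = 0.05,
    n_sterility_assessed: int = 22,
    n_baseline_assessed: int = 20,
) -> tuple[list[CrossCounts], SterilityCounts]:
    """Synthetic cross data from the gamete/embryo model.

    Emulates the drive-conversion crosses (drive/Cas9 heterozygotes x
    wild-type, both parent sexes) and the fertility assay of drive-carrier
    daughters of drive mothers.  Offspring drive phenotypes are sampled per
    parent; sterility is sampled with the embryo nonfunctional-resistance
    probability on top of a baseline sterility rate.
    """
    if n_parents <= 0 or offspring_per_parent <= 0:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    crosses = []
    for sex, conv in (("female", p.conversion_female), ("male", p.conversion_male)):
        c = conv if p.cas9_present else 0.0
        p_drive_gamete = 0.5 + 0.5 * c
        batches = rng.binomial(offspring_per_parent, p_drive_gamete, size=n_parents)
        with_drive = int(batches.sum())
        total = n_parents * offspring_per_parent
        crosses.append(
            CrossCounts(
                parent_sex=sex,
                offspring_with_drive=with_drive,
                offspring_without_drive=total - with_drive,
                batches=[(int(b), offspring_per_parent - int(b)) for b in batches],
            )
        )
    # Drive-carrier daughters of drive mothers: paternal wild-type allele is
    # cleaved to a nonfunctional allele with probability
    # embryo_cut_rate * (1 - relative_r1_rate), which sterilises the female.
    p_r2 = (p.embryo_cut_rate * (1.0 - p.relative_r1_rate)) if p.cas9_present else 0.0
    p_sterile = baseline_sterility + (1.0 - baseline_sterility) * p_r2
    sterile = int(rng.binomial(n_sterility_assessed, p_sterile))
    baseline_sterile = int(rng.binomial(n_baseline_assessed, baseline_sterility))
    sterility = SterilityCounts(
        sterile=sterile,
        assessed=n_sterility_assessed,
        baseline_sterile=baseline_sterile,
        baseline_assessed=n_baseline_assessed,
    )
    return crosses, sterility
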