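"""Maximum-likelihood inference of drive fitness costs from cage counts.

The observable in a cage generation is the number of DsRed drive carriers
versus non-carriers among the phenotyped adults.  Each generation-to-
generation transition is modelled by conditioning the predicted genotype
distribution on the observed carrier frequency (within-phenotype genotype
proportions are taken from the model), advancing the deterministic
recursion one generation, and scoring the next generation's counts with a
binomial likelihood on the predicted carrier frequency.  The transition
out of the release generation is excluded: founder adults had atypical
fitness.

Model comparison uses AICc; confidence intervals come from the profile
likelihood (1.92 log-unit drop, the 95% chi-squared rule with one degree
of freedom).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import CARRIER_MASK
from .model import ExtinctionError, PopulationState, founder_state, next_generation
from .params import DriveParams, FitnessModel, FitnessSpec

__all__ = [
    "CageObservations",
    "FitResult",
    "reconstruct_state",
    "trajectory_loglik",
    "fit_fitness_model",
    "compare_models",
    "fit_relative_r1",
    "DEFAULT_MODELS",
]

#: chi-squared(1 df) 95% quantile / 2: profile-likelihood drop for a 95% CI
PROFILE_DROP = 1.92

#: search range for the homozygote-fitness parameter
FITNESS_BOUNDS = (1e-3, 1.5)

#: search range for the relative r1 rate
R1_BOUNDS = (0.0, 0.05)

#: model comparison order (also the tie-break order)
DEFAULT_MODELS = (
    FitnessModel.NEUTRAL,
    FitnessModel.SOMATIC_HET_FECUNDITY,
    FitnessModel.DIRECT_VIABILITY,
    FitnessModel.DIRECT_FECUNDITY_MATING,
    FitnessModel.OFFTARGET_VIABILITY,
    FitnessModel.OFFTARGET_FECUNDITY_MATING,
)


@dataclass(frozen=True)
class CageObservations:
    """Per-generation drive-carrier counts from one cage.

    ``generations``, ``carriers`` and ``noncarriers`` are parallel integer
    sequences; generation indices must start anywhere but be consecutive.
    Generation 0 is the release: all carriers are drive/wild-type
    heterozygotes (Cas9 fixed in the population).
    """

    generations: tuple[int, ...]
    carriers: tuple[int, ...]
    noncarriers: tuple[int, ...]
    label: str = "cage"

    def __post_init__(self) -> None:
        g = np.asarray(self.generations)
        if len(g) < 3:
            raise ValueError("need at least 3 generations for a fit")
        if not np.array_equal(np.diff(g), np.ones(len(g) - 1, dtype=int)):
            raise ValueError("generations must be strictly increasing and consecutive")
        for name in ("carriers", "noncarriers"):
            arr = np.asarray(getattr(self, name))
            if (arr < 0).any():
                raise ValueError(f"{name} must be non-negative")
        if any(c + n == 0 for c, n in zip(self.carriers, self.noncarriers)):
            raise ValueError("every generation needs a positive total count")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label: str = "cage") -> "CageObservations":
        required = {"generation", "carriers", "noncarriers"}
        if not required.issubset(df.columns):
            raise ValueError(f"table must have columns {sorted(required)}")
        df = df.sort_values("generation")
        return cls(
            tuple(int(x) for x in df["generation"]),
            tuple(int(x) for x in df["carriers"]),
            tuple(int(x) for x in df["noncarriers"]),
            label=label,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": self.generations,
                "carriers": self.carriers,
                "noncarriers": self.noncarriers,
            }
        )

    @property
    def totals(self) -> np.ndarray:
        return np.asarray(self.carriers) + np.asarray(self.noncarriers)

    @property
    def carrier_freqs(self) -> np.ndarray:
        return np.asarray(self.carriers) / self.totals

    @property
    def n_transitions_used(self) -> int:
        """Transitions entering the likelihood (first one excluded)."""
        return len(self.generations) - 2


@dataclass(frozen=True)
class FitResult:
    """MLE of one fitness model on one or more cages."""

    model: FitnessModel
    mle_fitness: float
    loglik: float
    aicc: float
    ci95: tuple[float, float]
    n_transitions_used: int
    mle_relative_r1: float | None = None
    r1_upper95: float | None = None
    identifiable: bool = True

    @property
    def n_params(self) -> int:
        k = 0 if self.model is FitnessModel.NEUTRAL else 1
        if self.mle_relative_r1 is not None:
            k += 1
        return k

    def to_dict(self) -> dict:
        d = {
            "model": self.model.value,
            "mle_fitness": self.mle_fitness,
            "loglik": self.loglik,
            "aicc": self.aicc,
            "ci_low": self.ci95[0],
            "ci_high": self.ci95[1],
            "n_transitions": self.n_transitions_used,
        }
        if self.mle_relative_r1 is not None:
            d["mle_relative_r1"] = self.mle_relative_r1
            d["r1_upper95"] = self.r1_upper95
        return d


def reconstruct_state(observed_carrier_freq: float, predicted: PopulationState) -> PopulationState:
    """Condition a predicted state on an observed carrier frequency.

    Carrier genotypes are rescaled to total ``observed_carrier_freq`` and
    non-carriers to the complement, preserving the model-predicted genotype
    proportions within each phenotype class (applied per sex).
    """
    if not (0.0 <= observed_carrier_freq <= 1.0):
        raise ValueError("observed carrier frequency must be in [0, 1]")
    out = []
    for dist in (predicted.female, predicted.male):
        car = dist * CARRIER_MASK
        non = dist * ~CARRIER_MASK
        car_mass, non_mass = car.sum(), non.sum()
        new = np.zeros_like(dist)
        if observed_carrier_freq > 0:
            if car_mass <= 0:
                raise ValueError(
                    "carriers observed but the model predicts none; cannot reconstruct"
                )
            new += car * (observed_carrier_freq / car_mass)
        if observed_carrier_freq < 1:
            if non_mass <= 0:
                raise ValueError(
                    "non-carriers observed but the model predicts none; cannot reconstruct"
                )
            new += non * ((1.0 - observed_carrier_freq) / non_mass)
        out.append(new)
    return PopulationState(*out)


def _predicted_carrier_freqs(
    obs: CageObservations, p: DriveParams, spec: FitnessSpec
) -> np.ndarray:
    """Model-predicted carrier frequency for each observed transition end.

    Element t is the prediction for generation t+1 given the observation at
    generation t (the forward pass conditions on each observed frequency in
    turn).  Extinction mid-trajectory yields a predicted frequency of NaN
    for the remaining entries.
    """
    freqs = obs.carrier_freqs
    preds = np.full(len(freqs) - 1, np.nan)
    state = founder_state(freqs[0], p)
    for t in range(len(freqs) - 1):
        try:
            conditioned = reconstruct_state(freqs[t], state)
            state = next_generation(conditioned, p, spec)
        except (ExtinctionError, ValueError):
            break
        preds[t] = float(state.pooled() @ CARRIER_MASK)
    return preds


def trajectory_loglik(
    obs: CageObservations, p: DriveParams, spec: FitnessSpec
) -> float:
    """Binomial log-likelihood of a carrier-count trajectory.

    Sums, over transitions t -> t+1 with t >= 1, the log probability of the
    observed carrier count at t+1 under Binomial(total_{t+1}, predicted
    carrier frequency).  The release-to-first-generation transition is
    excluded.  Returns ``-inf`` when a prediction of exactly 0 or 1
    contradicts the observation (rather than raising).
    """
    preds = _predicted_carrier_freqs(obs, p, spec)
    carriers = np.asarray(obs.carriers)
    totals = obs.totals
    ll = 0.0
    for t in range(1, len(preds)):  # transition t -> t+1, skip t = 0
        pred = preds[t]
        if np.isnan(pred):
            return -np.inf
        k, n = carriers[t + 1], totals[t + 1]
        if pred <= 0.0:
            if k > 0:
                return -np.inf
            continue
        if pred >= 1.0:
            if k < n:
                return -np.inf
            continue
        ll += float(stats.binom.logpmf(k, n, pred))
    return ll


def _pooled_loglik(
    cages: list[CageObservations], p: DriveParams, spec: FitnessSpec
) -> float:
    return sum(trajectory_loglik(obs, p, spec) for obs in cages)


def _aicc(loglik: float, k: int, n: int) -> float:
    aic = 2 * k - 2 * loglik
    if n - k - 1 <= 0:
        return np.inf
    return aic + (2 * k * (k + 1)) / (n - k - 1)


def _as_cage_list(obs) -> list[CageObservations]:
    return list(obs) if isinstance(obs, (list, tuple)) else [obs]


def _profile_ci(
    f, mle_x: float, max_ll: float, bounds: tuple[float, float], drop: float = PROFILE_DROP
) -> tuple[float, float]:
    """Profile-likelihood interval: where f(x) = max_ll - drop."""

    def g(x):
        return f(x) - (max_ll - drop)

    lo, hi = bounds
    if g(lo) >= 0:
        ci_lo = lo
    else:
        ci_lo = float(optimize.brentq(g, lo, mle_x, xtol=1e-6))
    if g(hi) >= 0:
        ci_hi = hi
    else:
        ci_hi = float(optimize.brentq(g, mle_x, hi, xtol=1e-6))
    return ci_lo, ci_hi


def fit_fitness_model(
    obs, p: DriveParams, model: FitnessModel
) -> FitResult:
    """Fit one fitness-cost model to one cage (or a list, pooled).

    The single homozygote-fitness parameter is maximized over
    ``FITNESS_BOUNDS`` by deterministic bounded search; the 95% CI is the
    profile-likelihood interval.  For the neutral model there is nothing to
    fit (k = 0).  Pooled fits share the fitness parameter across cages.
    """
    cages = _as_cage_list(obs)
    n = sum(c.n_transitions_used for c in cages)
    if model is FitnessModel.NEUTRAL:
        ll = _pooled_loglik(cages, p, FitnessSpec())
        return FitResult(
            model=model,
            mle_fitness=1.0,
            loglik=ll,
            aicc=_aicc(ll, 0, n),
            ci95=(1.0, 1.0),
            n_transitions_used=n,
        )

    def nll(w: float) -> float:
        return -_pooled_loglik(cages, p, FitnessSpec(model, w))

    res = optimize.minimize_scalar(nll, bounds=FITNESS_BOUNDS, method="bounded",
                                   options={"xatol": 1e-5})
    mle_w = float(res.x)
    max_ll = -float(res.fun)
    if not np.isfinite(max_ll):
        return FitResult(
            model=model,
            mle_fitness=mle_w,
            loglik=max_ll,
            aicc=np.inf,
            ci95=FITNESS_BOUNDS,
            n_transitions_used=n,
            identifiable=False,
        )
    ci = _profile_ci(lambda w: -nll(w), mle_w, max_ll, FITNESS_BOUNDS)
    # flat likelihood across the whole bound range -> not identifiable
    flat = (ci[0] <= FITNESS_BOUNDS[0] + 1e-6) and (ci[1] >= FITNESS_BOUNDS[1] - 1e-6)
    return FitResult(
        model=model,
        mle_fitness=mle_w,
        loglik=max_ll,
        aicc=_aicc(max_ll, 1, n),
        ci95=ci,
        n_transitions_used=n,
        identifiable=not flat,
    )


def compare_models(
    obs, p: DriveParams, models=DEFAULT_MODELS
) -> list[FitResult]:
    """Fit several fitness models and rank them by AICc (ascending).

    Ties are broken by the declared model order.  ``obs`` may be a single
    cage or a list of cages fitted jointly with a shared parameter.
    """
    models = list(models)
    if len(models) < 2:
        raise ValueError("need at least two models to compare")
    fits = [fit_fitness_model(obs, p, m) for m in models]
    order = sorted(range(len(fits)), key=lambda i: (fits[i].aicc, i))
    return [fits[i] for i in order]


def fit_relative_r1(
    obs, p: DriveParams, best_model: FitnessModel | FitnessSpec
) -> FitResult:
    """Profile the relative r1 rate on top of the best fitness model.

    The relative r1 rate (fraction of resistance alleles that are
    functional) is profiled over ``R1_BOUNDS`` while the fitness parameter
    is re-optimized at each value.  Returns a :class:`FitResult` whose
    ``mle_relative_r1`` is the MLE and ``r1_upper95`` the one-sided 95%
    upper bound (profile drop of 1.92 log units).  Multiply the relative
    rate by the total germline resistance rate or by the embryo cut rate to
    express it as an absolute germline or embryo r1 formation rate.
    """
    cages = _as_cage_list(obs)
    model = best_model.model if isinstance(best_model, FitnessSpec) else FitnessModel(best_model)
    n = sum(c.n_transitions_used for c in cages)

    def profile(rho: float) -> tuple[float, float]:
        """(max loglik over fitness, argmax fitness) at fixed rho."""
        pr = replace(p, relative_r1_rate=rho)
        if model is FitnessModel.NEUTRAL:
            return _pooled_loglik(cages, pr, FitnessSpec()), 1.0

        def nll(w: float) -> float:
            return -_pooled_loglik(cages, pr, FitnessSpec(model, w))

        res = optimize.minimize_scalar(
            nll, bounds=FITNESS_BOUNDS, method="bounded", options={"xatol": 1e-5}
        )
        return -float(res.fun), float(res.x)

    # Deterministic grid + refinement over the bounded r1 range.
    grid = np.linspace(R1_BOUNDS[0], R1_BOUNDS[1], 26)
    lls = np.array([profile(r)[0] for r in grid])
    i_best = int(np.argmax(lls))
    lo = grid[max(i_best - 1, 0)]
    hi = grid[min(i_best + 1, len(grid) - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda r: -profile(r)[0], bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-5},
        )
        cand_r, cand_ll = float(res.x), -float(res.fun)
    else:
        cand_r, cand_ll = float(grid[i_best]), float(lls[i_best])
    if lls[i_best] >= cand_ll:
        mle_r, max_ll = float(grid[i_best]), float(lls[i_best])
    else:
        mle_r, max_ll = cand_r, cand_ll
    if mle_r < 1e-6:
        mle_r = 0.0
        max_ll = float(profile(0.0)[0])

    _, upper = _profile_ci(lambda r: profile(r)[0], mle_r, max_ll, R1_BOUNDS)
    best_w = profile(mle_r)[1]
    k = (0 if model is FitnessModel.NEUTRAL else 1) + 1
    return FitResult(
        model=model,
        mle_fitness=best_w,
        loglik=max_ll,
        aicc=_aicc(max_ll, k, n),
        ci95=(np.nan, np.nan),
        n_transitions_used=n,
        mle_relative_r1=mle_r,
        r1_upper95=float(upper),
    )
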