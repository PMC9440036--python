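"""Simulated-annealing local search on binary feature masks.

The neighbourhood is the smallest Hamming move — flip one uniformly chosen
bit (with the usual empty-mask repair).  Moves are accepted by the Metropolis
rule: improvements always, deteriorations with probability ``exp(-delta/T)``,
with the temperature cooled geometrically (factor 0.93 per chain).  The
initial temperature defaults to ``2 * D_t``, twice the feature count.

That initial temperature is enormous relative to the objective's [0,1] scale,
so early chains accept essentially everything; the search only becomes
selective once the temperature has cooled by many orders of magnitude.  Two
things keep this useful: the annealer is *elitist* (it returns the best mask
ever visited, not the final state), and :func:`anneal` is resumable — the
hybrid driver threads the temperature through successive per-iteration calls
so one cooling schedule spans the whole run instead of restarting hot each
time.  At the bottom of the schedule the walk degenerates into
first-improvement hill climbing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError
from .fitness import FeatureMask, FitnessValue

__all__ = ["SAParams", "neighbor", "accept", "anneal", "AnnealResult"]


@dataclass(frozen=True)
class SAParams:
    """Annealing schedule parameters.

    ``t0=None`` means "resolve to ``2 * d`` at run time" where ``d`` is the
    mask length.  ``min_temp`` is an absolute stopping temperature; it
    defaults to essentially zero so that, under an evaluation cap, the tail
    of the schedule behaves as hill climbing rather than stopping early.
    ``max_evals`` caps fitness evaluations per call, keeping one call's cost
    independent of the dimension.  ``chain_length`` paces the schedule:
    since the high ``t0`` means only a narrow late temperature band
    discriminates between moves on the objective's [0,1] scale, a longer
    chain keeps the walk in that band for more proposals.
    """

    t0: float | None = None
    cooling: float = 0.93
    chain_length: int = 25
    min_temp: float = 1e-12
    max_evals: int = 100

    def __post_init__(self) -> None:
        if self.t0 is not None and self.t0 <= 0:
            raise ConfigError("t0 must be positive")
        if not 0.0 < self.cooling < 1.0:
            raise ConfigError("cooling factor must lie in (0,1)")
        if self.chain_length < 1:
            raise ConfigError("chain_length must be >= 1")
        if self.min_temp < 0:
            raise ConfigError("min_temp must be >= 0")
        if self.max_evals < 0:
            raise ConfigError("max_evals must be >= 0")

    def resolve_t0(self, d: int) -> float:
        return 2.0 * d if self.t0 is None else self.t0


def neighbor(mask: FeatureMask, rng: np.random.Generator) -> FeatureMask:
    """Flip one uniformly chosen bit; repair an emptied mask to one set bit."""
    bits = mask.bits.copy()
    j = int(rng.integers(bits.size))
    bits[j] ^= 1
    if not bits.any():
        bits[int(rng.integers(bits.size))] = 1
    return FeatureMask(bits)


def accept(delta: float, temp: float, rng: np.random.Generator) -> bool:
    """Metropolis rule: always accept ``delta <= 0``, else with prob
    ``exp(-delta/temp)``."""
    if temp <= 0:
        raise ConfigError("temperature must be positive")
    if delta <= 0:
        return True
    exponent = delta / temp
    if exponent > 700:  # exp underflows to 0
        return False
    return bool(rng.random() < math.exp(-exponent))


@dataclass
class AnnealResult:
    best_mask: FeatureMask
    best_value: FitnessValue
    evals: int
    final_temp: float


def anneal(
    start: FeatureMask,
    evaluator,
    params: SAParams,
    rng: np.random.Generator,
    t_start: float | None = None,
    max_evals: int | None = None,
    floor_temp: bool = False,
) -> AnnealResult:
    """Anneal from ``start``, returning the best mask ever visited.

    ``evaluator`` is any callable mapping a mask to a
    :class:`~bdmsao.fitness.FitnessValue`.  ``t_start`` resumes a cooling
    schedule mid-way (the hybrid driver's use); when the starting temperature
    is already below ``min_temp`` the chain is empty and ``start`` is
    returned unchanged.  With ``floor_temp=True`` the temperature is clamped
    at ``min_temp`` instead of stopping, so the call always spends its whole
    budget (hill climbing once cold).  ``max_evals`` overrides the per-call
    cap in params.
    """
    budget = params.max_evals if max_evals is None else max_evals
    temp = params.resolve_t0(len(start)) if t_start is None else t_start
    floor = max(params.min_temp, 1e-300)
    if floor_temp:
        temp = max(temp, floor)
    current_mask = start
    current = evaluator(start)
    best_mask, best = current_mask, current
    evals = 1 if budget > 0 else 0
    if budget == 0:
        return AnnealResult(start, current, 0, temp)
    while evals < budget and (floor_temp or temp >= params.min_temp):
        for _ in range(params.chain_length):
            if evals >= budget:
                break
            cand_mask = neighbor(current_mask, rng)
            cand = evaluator(cand_mask)
            evals += 1
            if accept(cand.fitness - current.fitness, temp, rng):
                current_mask, current = cand_mask, cand
                if cand < best:
                    best_mask, best = cand_mask, cand
        temp *= params.cooling
        if floor_temp:
            temp = max(temp, floor)
    return AnnealResult(best_mask, best, evals, temp)
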