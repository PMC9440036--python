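"""Binary dwarf mongoose optimization: the population search operators.

The dwarf mongoose optimizer models a mongoose troop foraging around a
sleeping mound.  A population of ``n`` agents holds continuous positions in
``[var_min, var_max]^d`` (binarized elsewhere for feature selection):

* the *alpha group* of ``n - bs`` foragers perturbs positions by the alpha
  female's vocalization scale (``peep``), one uniform draw per dimension;
* each move is scored by the *sleeping mound* statistic ``sm``, the fitness
  change normalized by the larger magnitude of the two fitnesses;
* the *scout phase* moves agents toward or away from a troop movement vector
  ``M`` depending on whether the average mound score improved, scaled by a
  collective-volatility factor ``CF = (1 - t/T)^(2 t/T)`` that decays from 1
  to 0 over the run;
* *babysitters* sit out foraging: periodically the ``bs`` worst agents are
  exchanged, i.e. re-initialized uniformly at random.

All moves are greedily accepted (an agent only keeps a candidate with lower
fitness), so the best-so-far fitness never worsens.  Every stochastic draw
flows through one seeded ``numpy`` generator per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError
from .fitness import FitnessValue

__all__ = [
    "Agent",
    "DMOParams",
    "ScoutState",
    "init_population",
    "alpha_probabilities",
    "tournament_select",
    "alpha_move",
    "sleeping_mound",
    "average_mound",
    "compute_cf",
    "movement_vector",
    "scout_move",
    "babysitter_exchange",
]


@dataclass
class Agent:
    """One mongoose: a continuous position with cached fitness and mound score."""

    position: np.ndarray
    fitness: FitnessValue | None = None
    sm: float = 0.0

    @property
    def fit(self) -> float:
        if self.fitness is None:
            raise ConfigError("agent has not been evaluated yet")
        return self.fitness.fitness


@dataclass(frozen=True)
class DMOParams:
    """Search parameters.

    Defaults follow the standard experimental setting for this optimizer:
    population 10, 50 iterations, positions in [0,1].  ``peep`` scales the
    alpha-group perturbation; ``n_babysitters`` agents are exchanged
    (re-initialized) every ``exchange_period`` iterations, which defaults to
    ``round(0.6 * max_iter)``.
    """

    d: int
    n: int = 10
    var_min: float = 0.0
    var_max: float = 1.0
    max_iter: int = 50
    peep: float = 2.0
    n_babysitters: int = 3
    exchange_period: int | None = None
    tournament_size: int = 2
    seed: int = 0
    scout_phi_per_dim: bool = False  # Eq-style coherent scalar move by default
    m_centroid: bool = False  # alternative sm-weighted centroid reading of M

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ConfigError("dimension must be >= 1")
        if self.n_babysitters < 0 or self.n <= self.n_babysitters:
            raise ConfigError(
                "need n > n_babysitters >= 0 so the foraging group is non-empty"
            )
        if self.max_iter < 1:
            raise ConfigError("max_iter must be >= 1")
        if self.var_min >= self.var_max:
            raise ConfigError("var_min must be strictly below var_max")
        if self.tournament_size < 1:
            raise ConfigError("tournament_size must be >= 1")
        if self.exchange_period is None:
            object.__setattr__(
                self, "exchange_period", max(1, round(0.6 * self.max_iter))
            )

    @property
    def n_foragers(self) -> int:
        return self.n - self.n_babysitters


@dataclass
class ScoutState:
    """Bookkeeping carried between iterations for the scout phase."""

    cf: float = 1.0
    m_vector: np.ndarray = field(default_factory=lambda: np.zeros(0))
    phi_avg_prev: float = 0.0
    phi_avg_curr: float = 0.0


def clamp(position: np.ndarray, params: DMOParams) -> np.ndarray:
    return np.clip(position, params.var_min, params.var_max)


def init_population(
    params: DMOParams, rng: np.random.Generator | None = None
) -> list[Agent]:
    """Uniformly random initial population of ``n`` agents in bounds."""
    rng = rng or np.random.default_rng(params.seed)
    return [
        Agent(position=rng.uniform(params.var_min, params.var_max, size=params.d))
        for _ in range(params.n)
    ]


def alpha_probabilities(fitnesses, eps: float = 1e-12) -> np.ndarray:
    """Selection probabilities for the alpha role from a minimized fitness.

    The share form ``fit_i / sum(fit)`` is applied to the maximization
    transform ``g_i = max(fit) - fit_i + eps`` so that lower fitness gets a
    strictly higher probability while the normalization is preserved.
    """
    f = np.asarray(fitnesses, dtype=float)
    if f.size == 0:
        raise ConfigError("empty fitness vector")
    if not np.isfinite(f).all():
        raise ConfigError("fitnesses must be finite")
    g = f.max() - f + eps
    return g / g.sum()


def tournament_select(
    agents: list[Agent], size: int, rng: np.random.Generator
) -> int:
    """Index of the best (minimum-fitness) of ``size`` draws with replacement."""
    if not agents:
        raise ConfigError("cannot select from an empty population")
    if size < 1:
        raise ConfigError("tournament size must be >= 1")
    candidates = rng.integers(len(agents), size=size)
    return int(min(candidates, key=lambda i: agents[i].fit))


def alpha_move(
    position: np.ndarray,
    peep: float,
    rng: np.random.Generator,
    params: DMOParams | None = None,
) -> np.ndarray:
    """Alpha-group foraging step: ``X + phi * peep`` with per-dimension
    ``phi ~ Uniform(-1, 1)``, clamped to bounds when params are given."""
    phi = rng.uniform(-1.0, 1.0, size=len(position))
    candidate = position + phi * peep
    return clamp(candidate, params) if params is not None else candidate


def sleeping_mound(fit_new: float, fit_old: float) -> float:
    """Normalized fitness change ``(fit_new - fit_old) / max(|new|, |old|)``;
    defined as 0 when both fitnesses are 0."""
    denom = max(abs(fit_new), abs(fit_old))
    if denom == 0.0:
        return 0.0
    return (fit_new - fit_old) / denom


def average_mound(sms) -> float:
    """The troop-average mound score (phi)."""
    s = np.asarray(sms, dtype=float)
    if s.size == 0:
        raise ConfigError("average_mound needs at least one value")
    return float(s.mean())


def compute_cf(iteration: int, max_iter: int) -> float:
    """Collective-volatility schedule ``(1 - t/T)^(2 t/T)``: 1 at t=0, 0 at t=T."""
    if max_iter < 1:
        raise ConfigError("max_iter must be >= 1")
    if not 0 <= iteration <= max_iter:
        raise ConfigError("iteration must lie in [0, max_iter]")
    frac = iteration / max_iter
    return float((1.0 - frac) ** (2.0 * frac))


def movement_vector(agents: list[Agent], centroid: bool = False) -> np.ndarray:
    """Troop movement vector M.

    The printed quotient form ``sum_i (X_i * sm_i) / X_i`` cancels the
    position elementwise, so the default is its simplification: every
    component equals ``sum_i sm_i``.  ``centroid=True`` instead returns the
    sm-weighted mean position ``sum_i X_i * sm_i / n``, a plausible variant in
    which M depends on where the troop actually is.
    """
    if not agents:
        raise ConfigError("movement_vector needs at least one agent")
    d = len(agents[0].position)
    sms = np.array([a.sm for a in agents])
    if centroid:
        positions = np.stack([a.position for a in agents])
        return (positions * sms[:, None]).sum(axis=0) / len(agents)
    return np.full(d, sms.sum())


def scout_move(
    position: np.ndarray,
    cf: float,
    m: np.ndarray,
    phi_new: float,
    phi_old: float,
    rng: np.random.Generator,
    params: DMOParams | None = None,
) -> np.ndarray:
    """Scout step toward (or away from) the movement vector.

    ``X -/+ CF * phi * rand * (X - M)``: minus when the average mound score
    improved (``phi_new > phi_old``), plus otherwise.  ``phi ~ Uniform(-1,1)``
    and ``rand ~ Uniform(0,1)`` are drawn once per agent (coherent group
    move); per-dimension ``phi`` is available via ``params.scout_phi_per_dim``.
    """
    per_dim = params is not None and params.scout_phi_per_dim
    phi = (
        rng.uniform(-1.0, 1.0, size=len(position))
        if per_dim
        else rng.uniform(-1.0, 1.0)
    )
    r = rng.uniform(0.0, 1.0)
    step = cf * phi * r * (position - m)
    candidate = position - step if phi_new > phi_old else position + step
    return clamp(candidate, params) if params is not None else candidate


def babysitter_exchange(
    agents: list[Agent],
    iteration: int,
    params: DMOParams,
    rng: np.random.Generator,
) -> list[int]:
    """Re-initialize the worst ``bs`` agents on the exchange schedule.

    Runs only when ``iteration`` is a positive multiple of
    ``exchange_period``; the current best agent is never re-initialized.
    Returns the indices of agents that were reset (their fitness is cleared
    and must be re-evaluated by the caller).
    """
    bs = params.n_babysitters
    if bs == 0 or iteration == 0 or iteration % params.exchange_period != 0:
        return []
    order = sorted(range(len(agents)), key=lambda i: agents[i].fit, reverse=True)
    best = min(range(len(agents)), key=lambda i: agents[i].fit)
    replaced = [i for i in order if i != best][:bs]
    for i in replaced:
        agents[i].position = rng.uniform(
            params.var_min, params.var_max, size=params.d
        )
        agents[i].fitness = None
        agents[i].sm = 0.0
    return replaced
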