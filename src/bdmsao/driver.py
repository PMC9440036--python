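"""Hybrid BDMSAO orchestration: global BDMO search with SA intensification.

One run proceeds as follows.  A population of continuous positions is
initialized uniformly in bounds and evaluated through the binarizing wrapper
fitness.  Each iteration then applies, in order:

1. *alpha phase* — every foraging agent tournament-selects a guide, proposes
   a peep-scaled perturbation of the guide's position, and greedily accepts
   it; the sleeping-mound score records the proposal's normalized fitness
   change;
2. *SA intensification* (hybrid mode) — the simulated annealer refines the
   current best agent's mask for a bounded number of evaluations, resuming
   one geometric cooling schedule threaded across iterations; the local
   improvement operator of the plain optimizer is thereby replaced with an
   annealed bit-flip search around the best solution;
3. *scout phase* — every foraging agent takes the CF-scaled move relative to
   the troop movement vector, greedily accepted;
4. *babysitter exchange* — on schedule, the worst agents are re-initialized.

After the loop a final SA polish (with a larger budget) refines the global
best mask, and the best solution ever evaluated is reported.  Greedy
acceptance plus elitist annealing make the best-so-far history monotone
non-increasing.  ``bdmo_only`` mode skips every SA call, which is the
baseline the hybrid is compared against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import dmo
from .annealing import SAParams, anneal
from .datasets import Dataset
from .dmo import Agent, DMOParams
from .exceptions import ConfigError
from .fitness import FeatureMask, FitnessConfig, FitnessValue, MaskEvaluator, binarize

__all__ = ["RunResult", "MultiRunResult", "run_bdmsao", "multi_run"]


@dataclass
class RunResult:
    """Outcome of one search run."""

    best_mask: FeatureMask
    best_fitness: FitnessValue
    accuracy: float
    n_selected: int
    history_fitness: list[float]
    history_accuracy: list[float]
    seed: int
    evals: int
    knn_evals: int
    mode: str
    dataset_name: str

    def to_dict(self, dataset: Dataset | None = None) -> dict:
        out = {
            "dataset": self.dataset_name,
            "mode": self.mode,
            "seed": self.seed,
            "best_mask": self.best_mask.to01(),
            "accuracy": self.accuracy,
            "fitness": self.best_fitness.fitness,
            "n_selected": self.n_selected,
            "evals": self.evals,
            "knn_evals": self.knn_evals,
            "history_fitness": self.history_fitness,
            "history_accuracy": self.history_accuracy,
        }
        if dataset is not None:
            out["selected_features"] = self.best_mask.feature_names(dataset)
        return out

    def to_json(self, dataset: Dataset | None = None, **kwargs) -> str:
        return json.dumps(self.to_dict(dataset), **kwargs)


@dataclass
class MultiRunResult:
    """Aggregate of repeated runs with consecutive seeds."""

    runs: list[RunResult]
    base_seed: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([r.accuracy for r in self.runs]))

    @property
    def mean_n_selected(self) -> float:
        return float(np.mean([r.n_selected for r in self.runs]))

    @property
    def mean_fitness(self) -> float:
        return float(np.mean([r.best_fitness.fitness for r in self.runs]))

    @property
    def best_run(self) -> RunResult:
        return min(self.runs, key=lambda r: r.best_fitness)


def _position_from_mask(mask: FeatureMask) -> np.ndarray:
    """Continuous position whose binarization is exactly ``mask``."""
    return mask.bits.astype(float)


def run_bdmsao(
    dataset: Dataset,
    dmo_params: DMOParams | None = None,
    sa_params: SAParams | None = None,
    fit_config: FitnessConfig | None = None,
    mode: str = "hybrid",
    final_sa_evals: int | None = None,
    per_agent_sa_gate: bool = False,
    evaluator: MaskEvaluator | None = None,
) -> RunResult:
    """One seeded hybrid (or plain-BDMO) feature-selection run.

    ``final_sa_evals`` is the budget of the post-loop SA polish (default
    ``10 * sa_params.max_evals``; ignored in ``bdmo_only`` mode).  With
    ``per_agent_sa_gate=True`` the hybrid instead gates each foraging agent
    individually: agents whose position has at least half of its coordinates
    above the 0.5 binarization threshold take the BDMO move, the others a
    short annealed refinement of their own mask — an alternative reading of
    the update-selection rule, off by default.
    """
    if mode not in ("hybrid", "bdmo_only"):
        raise ConfigError(f"unknown mode {mode!r}")
    dmo_params = dmo_params or DMOParams(d=dataset.n_features)
    if dmo_params.d != dataset.n_features:
        raise ConfigError(
            f"dmo_params.d={dmo_params.d} does not match the dataset's "
            f"{dataset.n_features} features"
        )
    sa_params = sa_params or SAParams()
    fit_config = fit_config or FitnessConfig()
    evaluator = evaluator or MaskEvaluator(dataset, fit_config)
    rng = np.random.default_rng(dmo_params.seed)
    calls_before = evaluator.n_calls

    agents = dmo.init_population(dmo_params, rng)
    masks = [binarize(a.position, rng) for a in agents]
    for a, m in zip(agents, masks):
        a.fitness = evaluator(m)

    def agent_mask(i: int) -> FeatureMask:
        return masks[i]

    best_idx = min(range(len(agents)), key=lambda i: agents[i].fitness)
    best_mask, best_fv = masks[best_idx], agents[best_idx].fitness

    history_fitness: list[float] = []
    history_accuracy: list[float] = []
    phi_prev = 0.0
    sa_temp: float | None = None  # one schedule threaded across iterations

    def consider(mask: FeatureMask, fv: FitnessValue) -> None:
        nonlocal best_mask, best_fv
        if fv < best_fv:
            best_mask, best_fv = mask, fv

    for iteration in range(1, dmo_params.max_iter + 1):
        cf = dmo.compute_cf(iteration, dmo_params.max_iter)
        # foragers are the n - bs currently fittest agents
        order = sorted(range(len(agents)), key=lambda i: agents[i].fitness)
        foragers = order[: dmo_params.n_foragers]

        # --- alpha phase ---
        forager_agents = [agents[i] for i in foragers]
        for i in foragers:
            gated_sa = False
            if mode == "hybrid" and per_agent_sa_gate:
                frac_above = float(np.mean(agents[i].position > 0.5))
                gated_sa = frac_above < 0.5
            if gated_sa:
                res = anneal(
                    masks[i],
                    evaluator,
                    sa_params,
                    rng,
                    t_start=sa_temp,
                    max_evals=sa_params.chain_length,
                    floor_temp=True,
                )
                sa_temp = res.final_temp
                cand_mask, cand_fv = res.best_mask, res.best_value
                cand_pos = _position_from_mask(cand_mask)
            else:
                guide = dmo.tournament_select(
                    forager_agents, dmo_params.tournament_size, rng
                )
                cand_pos = dmo.alpha_move(
                    forager_agents[guide].position,
                    dmo_params.peep,
                    rng,
                    dmo_params,
                )
                cand_mask = binarize(cand_pos, rng)
                cand_fv = evaluator(cand_mask)
            agents[i].sm = dmo.sleeping_mound(
                cand_fv.fitness, agents[i].fitness.fitness
            )
            consider(cand_mask, cand_fv)
            if cand_fv < agents[i].fitness:
                agents[i].position = cand_pos
                agents[i].fitness = cand_fv
                masks[i] = cand_mask

        # --- SA intensification of the current best agent ---
        if mode == "hybrid" and not per_agent_sa_gate and sa_params.max_evals > 0:
            bi = min(range(len(agents)), key=lambda i: agents[i].fitness)
            res = anneal(
                masks[bi],
                evaluator,
                sa_params,
                rng,
                t_start=sa_temp,
                floor_temp=True,
            )
            sa_temp = res.final_temp
            consider(res.best_mask, res.best_value)
            if res.best_value < agents[bi].fitness:
                agents[bi].position = _position_from_mask(res.best_mask)
                agents[bi].fitness = res.best_value
                masks[bi] = res.best_mask

        # --- scout phase ---
        phi_curr = dmo.average_mound([agents[i].sm for i in foragers])
        m_vec = dmo.movement_vector(
            [agents[i] for i in foragers], centroid=dmo_params.m_centroid
        )
        for i in foragers:
            cand_pos = dmo.scout_move(
                agents[i].position, cf, m_vec, phi_curr, phi_prev, rng, dmo_params
            )
            cand_mask = binarize(cand_pos, rng)
            cand_fv = evaluator(cand_mask)
            consider(cand_mask, cand_fv)
            if cand_fv < agents[i].fitness:
                agents[i].position = cand_pos
                agents[i].fitness = cand_fv
                masks[i] = cand_mask
        phi_prev = phi_curr

        # --- babysitter exchange ---
        replaced = dmo.babysitter_exchange(agents, iteration, dmo_params, rng)
        for i in replaced:
            masks[i] = binarize(agents[i].position, rng)
            agents[i].fitness = evaluator(masks[i])
            consider(masks[i], agents[i].fitness)

        history_fitness.append(best_fv.fitness)
        history_accuracy.append(best_fv.accuracy)

    # --- final SA polish of the global best ---
    if mode == "hybrid" and sa_params.max_evals > 0:
        budget = (
            10 * sa_params.max_evals if final_sa_evals is None else final_sa_evals
        )
        res = anneal(
            best_mask,
            evaluator,
            sa_params,
            rng,
            t_start=sa_temp,
            max_evals=budget,
            floor_temp=True,
        )
        consider(res.best_mask, res.best_value)
        history_fitness[-1] = best_fv.fitness
        history_accuracy[-1] = best_fv.accuracy

    return RunResult(
        best_mask=best_mask,
        best_fitness=best_fv,
        accuracy=best_fv.accuracy,
        n_selected=best_mask.d_s,
        history_fitness=history_fitness,
        history_accuracy=history_accuracy,
        seed=dmo_params.seed,
        evals=evaluator.n_calls - calls_before,
        knn_evals=evaluator.n_knn_evals,
        mode=mode,
        dataset_name=dataset.name,
    )


def multi_run(
    dataset: Dataset,
    dmo_params: DMOParams | None = None,
    sa_params: SAParams | None = None,
    fit_config: FitnessConfig | None = None,
    mode: str = "hybrid",
    n_runs: int = 10,
    base_seed: int = 0,
    **run_kwargs,
) -> MultiRunResult:
    """Repeat :func:`run_bdmsao` with seeds ``base_seed .. base_seed+n_runs-1``.

    Each run gets its own evaluator seeded consistently, so re-running with
    the same ``base_seed`` reproduces every per-run result bit-identically.
    """
    if n_runs < 1:
        raise ConfigError("n_runs must be >= 1")
    template = dmo_params or DMOParams(d=dataset.n_features)
    runs = []
    for r in range(n_runs):
        params = DMOParams(
            **{
                **{
                    k: getattr(template, k)
                    for k in template.__dataclass_fields__
                },
                "seed": base_seed + r,
            }
        )
        runs.append(
            run_bdmsao(
                dataset,
                dmo_params=params,
                sa_params=sa_params,
                fit_config=fit_config,
                mode=mode,
                **run_kwargs,
            )
        )
    return MultiRunResult(runs=runs, base_seed=base_seed)
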