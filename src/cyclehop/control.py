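"""Inhibitory control fields and the search for minimal target sets.

Inhibiting a gene is modeled as an infinitely negative external field on its
node, realized as a clamp to -1. A candidate target set is scored by
simulating a population through a relax -> inhibit protocol and measuring
the time-averaged occupancy <P_mu>_T of the objective attractor during
inhibition: an effective set traps cells in that cell-cycle state. Because
the number of size-n subsets of hundreds of genes is combinatorially large,
the search is done with a generational genetic algorithm over fixed-size
index sets; a brute-force enumerator over small pools serves as an
independent optimum for validating the GA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np

from .hopfield import CouplingMatrix, DynamicsParams, ExternalField, build_coupling
from .patterns import AttractorSet
from .population import simulate_population, state_distribution

__all__ = [
    "ControlCandidate",
    "GAConfig",
    "GASearchResult",
    "make_control_field",
    "objective_score",
    "ga_search",
    "exhaustive_search",
    "robustness_scores",
]


@dataclass(frozen=True)
class ControlCandidate:
    """A fixed-size set of inhibition targets and its measured score."""

    targets: tuple[int, ...]
    score: float
    mu_objective: int


@dataclass
class GAConfig:
    """Search and per-evaluation simulation budget.

    Each fitness evaluation simulates ``eval_kappa`` cells for
    ``relax_steps`` unperturbed steps followed by ``control_steps`` steps
    under the candidate's clamp field, and scores the mean occupancy of the
    objective attractor over the last ``eval_window`` control steps (the
    whole control window when None). Candidates within a generation share a
    random seed (common random numbers), so score differences reflect the
    target sets rather than noise realizations.
    """

    population_size: int = 50
    generations: int = 100
    crossover_rate: float = 0.9
    mutation_rate: float = 0.1
    elite_count: int = 2
    eval_kappa: int = 100
    relax_steps: int = 200
    control_steps: int = 400
    eval_window: int | None = None
    seed: int = 0
    exhaustive_cap: int = 5000

    def __post_init__(self) -> None:
        for name in ("crossover_rate", "mutation_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.elite_count >= self.population_size:
            raise ValueError("elite_count must be smaller than population_size")


@dataclass
class GASearchResult:
    """Best candidate, running-best history, and every score observed.

    ``archive`` maps each evaluated target set to all scores it received
    (multiple entries when a set survived across generations and was rescored
    under fresh seeds).
    """

    best: ControlCandidate
    history: list[float]
    evaluations: int
    archive: dict[tuple[int, ...], list[float]] = field(default_factory=dict)


def make_control_field(targets: set[int] | tuple[int, ...] | list[int], n: int) -> ExternalField:
    """Clamp field for a target set: forced inhibition on targets, zero elsewhere."""
    target_list = list(targets)
    if len(set(target_list)) != len(target_list):
        raise ValueError("duplicate target indices")
    for i in target_list:
        if not 0 <= i < n:
            raise ValueError(f"target index {i} outside [0, {n})")
    mask = np.zeros(n, dtype=bool)
    mask[target_list] = True
    return ExternalField(values=np.zeros(n), clamp_mask=mask)


def objective_score(
    targets: tuple[int, ...] | set[int],
    mu_objective: int,
    coupling: CouplingMatrix,
    attractors: AttractorSet,
    config: GAConfig,
    params: DynamicsParams,
    seed: int | None = None,
) -> float:
    """Time-averaged occupancy of the objective attractor under inhibition.

    Protocol: random initial states, ``relax_steps`` unperturbed (cells settle
    into the cycle with uniform phases), then the clamp field for
    ``control_steps``. The score is <P_mu>_T over the evaluation window at
    the end of the control interval, in [0, 1].
    """
    field_ = make_control_field(targets, attractors.n_genes)
    steps = config.relax_steps + config.control_steps
    schedule = [(config.relax_steps, steps, field_)]
    rng = np.random.default_rng(config.seed if seed is None else seed)
    trace = simulate_population(
        coupling, attractors, schedule, kappa=config.eval_kappa, steps=steps,
        params=params, init="random", rng=rng,
    )
    window = config.eval_window or config.control_steps
    dist = state_distribution(trace, t0=steps + 1 - window, tau=window)
    return float(dist.time_average[mu_objective])


def _mutate(targets: tuple[int, ...], pool: list[int], rng: np.random.Generator) -> tuple[int, ...]:
    """Swap one target for a random non-target from the pool."""
    outside = [g for g in pool if g not in targets]
    if not outside or not targets:
        return targets
    dropped = rng.integers(len(targets))
    added = outside[rng.integers(len(outside))]
    new = list(targets)
    new[dropped] = added
    return tuple(sorted(new))


def _crossover(
    a: tuple[int, ...], b: tuple[int, ...], rng: np.random.Generator
) -> tuple[int, ...]:
    """Uniform set crossover repaired to the parents' common size."""
    union = sorted(set(a) | set(b))
    child = rng.choice(union, size=len(a), replace=False)
    return tuple(sorted(int(g) for g in child))


def ga_search(
    n_targ: int,
    mu_objective: int,
    coupling: CouplingMatrix,
    attractors: AttractorSet,
    config: GAConfig,
    params: DynamicsParams,
    candidate_pool: list[int] | None = None,
) -> GASearchResult:
    """Generational GA over fixed-size target sets.

    Tournament selection (k=3), uniform set crossover repaired to size
    ``n_targ``, single-swap mutation, and elitism. All candidates in a
    generation are scored with a shared seed; surviving elites accumulate
    scores under fresh seeds across generations and are ranked by their mean,
    so a lucky noise realization cannot hold the top spot. The reported
    history is the running best mean score (nondecreasing).
    """
    pool = sorted(candidate_pool if candidate_pool is not None else range(attractors.n_genes))
    if not 0 <= n_targ <= len(pool):
        raise ValueError(f"n_targ={n_targ} infeasible for pool of {len(pool)}")
    rng = np.random.default_rng(config.seed)
    evaluations = 0
    archive: dict[tuple[int, ...], list[float]] = {}

    def evaluate(candidate: tuple[int, ...], seed: int) -> float:
        nonlocal evaluations
        evaluations += 1
        score = objective_score(
            candidate, mu_objective, coupling, attractors, config, params, seed=seed
        )
        archive.setdefault(candidate, []).append(score)
        return score

    def mean_score(candidate: tuple[int, ...]) -> float:
        return float(np.mean(archive[candidate]))

    if math.comb(len(pool), n_targ) == 1:  # degenerate search space
        only = tuple(pool[:n_targ]) if n_targ else ()
        evaluate(only, config.seed)
        best = ControlCandidate(only, mean_score(only), mu_objective)
        return GASearchResult(best=best, history=[best.score], evaluations=evaluations,
                              archive=archive)

    population = [
        tuple(sorted(int(g) for g in rng.choice(pool, size=n_targ, replace=False)))
        for _ in range(config.population_size)
    ]

    best_candidate: tuple[int, ...] | None = None
    history: list[float] = []
    for gen in range(config.generations):
        gen_seed = int((config.seed + 7919 * (gen + 1)) % (2**31))
        scored: dict[tuple[int, ...], float] = {}
        for cand in population:
            if cand not in scored:
                scored[cand] = evaluate(cand, gen_seed)

        ranked = sorted(scored, key=lambda c: mean_score(c), reverse=True)
        if best_candidate is None or mean_score(ranked[0]) > mean_score(best_candidate):
            best_candidate = ranked[0]
        # best-ever is a running max: re-evaluation of a surviving elite can
        # lower its mean, but the best score observed so far never drops
        current = mean_score(best_candidate)
        history.append(max(history[-1], current) if history else current)

        elites = ranked[: config.elite_count]
        gen_pop = list(scored)

        def tournament() -> tuple[int, ...]:
            contenders = [gen_pop[rng.integers(len(gen_pop))] for _ in range(3)]
            return max(contenders, key=lambda c: scored[c])

        offspring: list[tuple[int, ...]] = list(elites)
        while len(offspring) < config.population_size:
            parent1, parent2 = tournament(), tournament()
            child = (
                _crossover(parent1, parent2, rng)
                if rng.random() < config.crossover_rate
                else parent1
            )
            if rng.random() < config.mutation_rate:
                child = _mutate(child, pool, rng)
            offspring.append(child)
        population = offspring

    best = ControlCandidate(best_candidate, mean_score(best_candidate), mu_objective)
    return GASearchResult(best=best, history=history, evaluations=evaluations,
                          archive=archive)


def exhaustive_search(
    n_targ: int,
    mu_objective: int,
    coupling: CouplingMatrix,
    attractors: AttractorSet,
    config: GAConfig,
    params: DynamicsParams,
    candidate_pool: list[int] | None = None,
) -> GASearchResult:
    """Evaluate every size-``n_targ`` subset of the pool (small pools only).

    All candidates share one seed (common random numbers), making the argmax
    deterministic under a fixed configuration. Refuses pools whose subset
    count exceeds ``config.exhaustive_cap``.
    """
    pool = sorted(candidate_pool if candidate_pool is not None else range(attractors.n_genes))
    if not 0 <= n_targ <= len(pool):
        raise ValueError(f"n_targ={n_targ} infeasible for pool of {len(pool)}")
    n_subsets = math.comb(len(pool), n_targ)
    if n_subsets > config.exhaustive_cap:
        raise ValueError(
            f"{n_subsets} subsets exceed the cap of {config.exhaustive_cap}; "
            "use ga_search for pools this large"
        )
    best: ControlCandidate | None = None
    evaluations = 0
    archive: dict[tuple[int, ...], list[float]] = {}
    for subset in combinations(pool, n_targ):
        score = objective_score(
            subset, mu_objective, coupling, attractors, config, params, seed=config.seed
        )
        archive[tuple(subset)] = [score]
        evaluations += 1
        if best is None or score > best.score:
            best = ControlCandidate(tuple(subset), score, mu_objective)
    return GASearchResult(best=best, history=[best.score], evaluations=evaluations,
                          archive=archive)


def robustness_scores(
    candidate: ControlCandidate,
    attractors: AttractorSet,
    lambda_mix: float,
    config: GAConfig,
    params: DynamicsParams,
    rel: float = 0.05,
) -> dict[str, float]:
    """Re-score a candidate with T, lambda and update_prob each varied by +/-rel.

    A robust target set keeps a comparable score under small model-parameter
    perturbations; large swings indicate the hit is an artifact of one
    parameter choice.
    """
    out: dict[str, float] = {}
    variations: dict[str, tuple[float, float, float]] = {
        "T": (params.T, params.T * (1 - rel), params.T * (1 + rel)),
        "lambda": (lambda_mix, lambda_mix * (1 - rel), min(1.0, lambda_mix * (1 + rel))),
        "update_prob": (
            params.update_prob,
            params.update_prob * (1 - rel),
            min(1.0, params.update_prob * (1 + rel)),
        ),
    }
    for name, (base, lo, hi) in variations.items():
        for tag, value in (("-", lo), ("+", hi)):
            T = value if name == "T" else params.T
            q = value if name == "update_prob" else params.update_prob
            lam = value if name == "lambda" else lambda_mix
            coupling = build_coupling(attractors, lam)
            varied = replace(params, T=T, update_prob=q)
            out[f"{name}{tag}"] = objective_score(
                candidate.targets, candidate.mu_objective, coupling, attractors,
                config, varied, seed=config.seed,
            )
    return out
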