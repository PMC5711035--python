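"""Ensembles of independent simulated cells and population-level observables.

Each cell is an independent realization of the stochastic Hopfield dynamics
under a shared coupling matrix and external-field schedule (the cells do not
interact — the model population is homogeneous and well mixed). Population
readouts mirror what bulk expression experiments measure:

* the overlap m_k^mu of cell k with attractor mu,
* the discrete cell state s_k = argmax_mu m_k^mu (its phenotype),
* the occupancy distribution P_mu(t), the fraction of cells in state mu,
  and its time average <P_mu>_T over a window tau,
* the population-averaged expression <sigma_i(t)>_K of each gene, and
* 2-D projections of cell trajectories onto the principal components of the
  attractor configurations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.decomposition import PCA

from .hopfield import CellState, CouplingMatrix, DynamicsParams, ExternalField
from .patterns import AttractorSet

__all__ = [
    "PopulationTrace",
    "StateDistribution",
    "overlap",
    "assign_state",
    "population_mean_expression",
    "state_distribution",
    "simulate_population",
    "pc_projection",
]

Schedule = list[tuple[int, int, ExternalField]]


@dataclass
class PopulationTrace:
    """History of a simulated cell population.

    ``states`` has shape (kappa, T+1): the assigned attractor index of every
    cell at every recorded time, including the initial condition. The full
    spin history (kappa, N, T+1) is optional — it costs O(kappa N T) memory
    and is only needed for per-gene population-averaged expression.
    """

    states: np.ndarray
    attractors: AttractorSet
    params: DynamicsParams
    spins: np.ndarray | None = None
    final_sigma: np.ndarray | None = None

    @property
    def kappa(self) -> int:
        return self.states.shape[0]

    @property
    def n_steps(self) -> int:
        return self.states.shape[1] - 1


@dataclass
class StateDistribution:
    """Occupancy P_mu(t) of each attractor state, with a windowed time average."""

    P: np.ndarray
    time_average: np.ndarray
    window: tuple[int, int]


def overlap(state: CellState | np.ndarray, attractors: AttractorSet, mu: int) -> float:
    """Overlap m^mu = (1/N) sum_i sigma_i xi_i^mu, in [-1, +1]."""
    sigma = state.sigma if isinstance(state, CellState) else np.asarray(state)
    return float(sigma.astype(float) @ attractors.xi[mu].astype(float) / attractors.n_genes)


def _all_overlaps(sigma: np.ndarray, attractors: AttractorSet) -> np.ndarray:
    """Overlaps with every pattern; sigma may be (N,) or (kappa, N)."""
    return sigma.astype(np.float32) @ attractors.xi.T.astype(np.float32) / attractors.n_genes


def assign_state(state: CellState | np.ndarray, attractors: AttractorSet) -> int:
    """Index of the maximal-overlap attractor; ties go to the lowest index."""
    sigma = state.sigma if isinstance(state, CellState) else np.asarray(state)
    return int(np.argmax(_all_overlaps(sigma, attractors)))


def population_mean_expression(trace: PopulationTrace, gene: int) -> np.ndarray:
    """Population-averaged expression <sigma_i(t)>_K of one gene, in [-1, +1].

    This is the quantity bulk microarray / RNA-seq time courses report: for a
    synchronized initial population it is a decaying oscillation, the decay
    reflecting stochastic phase decoherence across cells.
    """
    if trace.spins is None:
        raise ValueError("trace was recorded without spin history")
    return trace.spins[:, gene, :].astype(float).mean(axis=0)


def state_distribution(
    trace: PopulationTrace, t0: int = 0, tau: int | None = None
) -> StateDistribution:
    """Exact occupancy histogram P_mu(t) plus its average over [t0, t0+tau)."""
    p = trace.attractors.p
    n_t = trace.states.shape[1]
    counts = np.stack([(trace.states == mu).sum(axis=0) for mu in range(p)])
    P = counts / trace.kappa
    if tau is None:
        tau = n_t - t0
    if t0 < 0 or tau <= 0 or t0 + tau > n_t:
        raise ValueError(
            f"window [{t0}, {t0 + tau}) outside recorded range [0, {n_t})"
        )
    return StateDistribution(
        P=P, time_average=P[:, t0 : t0 + tau].mean(axis=1), window=(t0, t0 + tau)
    )


def _validate_schedule(schedule: Schedule, steps: int) -> None:
    intervals = sorted((t0, t1) for t0, t1, _ in schedule)
    for (a0, a1) in intervals:
        if a0 >= a1:
            raise ValueError(f"empty or inverted schedule interval [{a0}, {a1})")
    for (_, a1), (b0, _) in zip(intervals, intervals[1:]):
        if b0 < a1:
            raise ValueError("schedule intervals overlap")


def _initial_spins(
    init: str | tuple[str, int] | np.ndarray,
    kappa: int,
    attractors: AttractorSet,
    rng: np.random.Generator,
) -> np.ndarray:
    if isinstance(init, np.ndarray):
        sigma = np.asarray(init, dtype=np.int8)
        if sigma.shape != (kappa, attractors.n_genes):
            raise ValueError("explicit init must have shape (kappa, N)")
        return sigma.copy()
    if init == "random":
        return rng.choice(np.array([-1, 1], dtype=np.int8), size=(kappa, attractors.n_genes))
    if isinstance(init, tuple) and init[0] == "synchronized":
        mu = int(init[1])
        return np.tile(attractors.xi[mu], (kappa, 1))
    raise ValueError(f"unknown init {init!r}")


def simulate_population(
    coupling: CouplingMatrix,
    attractors: AttractorSet,
    schedule: Schedule | None,
    kappa: int,
    steps: int,
    params: DynamicsParams,
    init: str | tuple[str, int] | np.ndarray = "random",
    record_spins: bool = False,
    rng: np.random.Generator | None = None,
) -> PopulationTrace:
    """Run ``kappa`` independent cells for ``steps`` asynchronous updates.

    ``schedule`` is a list of (t_start, t_end, field) with non-overlapping,
    half-open step intervals; outside all intervals the external field is
    zero. Supports the full relax -> inhibit -> release protocol as well as
    unperturbed runs (``schedule=None``).

    The per-step update semantics are identical to :func:`cyclehop.hopfield.step`,
    vectorized over cells; single-precision matrix products are used for the
    field (entries are sums of O(N) terms of size ~1/N, far from the float32
    resolution limit).
    """
    if kappa < 1:
        raise ValueError("need at least one cell")
    schedule = schedule or []
    _validate_schedule(schedule, steps)
    rng = rng or np.random.default_rng(params.rng_seed)

    n = attractors.n_genes
    J = coupling.J.astype(np.float32)
    sigma = _initial_spins(init, kappa, attractors, rng)

    states = np.empty((kappa, steps + 1), dtype=np.int16)
    states[:, 0] = np.argmax(_all_overlaps(sigma, attractors), axis=1)
    spins = None
    if record_spins:
        spins = np.empty((kappa, n, steps + 1), dtype=np.int8)
        spins[:, :, 0] = sigma

    T, q = params.T, params.update_prob
    for t in range(steps):
        active = next((f for t0, t1, f in schedule if t0 <= t < t1), None)
        h = sigma.astype(np.float32) @ J.T
        if active is not None:
            h = h + active.values.astype(np.float32)
        if T == 0:
            p_up = np.where(h > 0, 1.0, np.where(h < 0, 0.0, 0.5)).astype(np.float32)
        else:
            p_up = expit(2.0 * h / np.float32(T))
        selected = rng.random((kappa, n)) < q
        fresh = np.where(rng.random((kappa, n)) < p_up, 1, -1).astype(np.int8)
        sigma = np.where(selected, fresh, sigma)
        if active is not None and active.clamp_mask.any():
            sigma[:, active.clamp_mask] = -1
        states[:, t + 1] = np.argmax(_all_overlaps(sigma, attractors), axis=1)
        if record_spins:
            spins[:, :, t + 1] = sigma

    return PopulationTrace(
        states=states, attractors=attractors, params=params, spins=spins,
        final_sigma=sigma,
    )


def pc_projection(
    points: np.ndarray, attractors: AttractorSet
) -> tuple[np.ndarray, np.ndarray]:
    """Project spin configurations onto the attractors' first two PCs.

    The principal axes are computed from the p x N attractor matrix alone, so
    the map is fixed by the stored patterns and cells are visualized in the
    attractors' frame. Axis signs are made deterministic by forcing the
    largest-magnitude loading of each component positive.

    Returns ``(point_coords, attractor_coords)``, each with two columns.
    """
    if attractors.p < 3:
        raise ValueError("need p >= 3 attractors for a 2-D projection")
    X = attractors.xi.astype(float)
    pca = PCA(n_components=2)
    pca.fit(X)
    if np.any(pca.singular_values_ < 1e-12):
        raise ValueError("degenerate attractor covariance: fewer than 2 informative axes")
    components = pca.components_.copy()
    for k in range(2):
        if components[k, np.argmax(np.abs(components[k]))] < 0:
            components[k] = -components[k]
    center = pca.mean_

    def transform(Y: np.ndarray) -> np.ndarray:
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        return (Y - center) @ components.T

    return transform(points), transform(X)
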