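"""Coupling-matrix construction and stochastic spin dynamics for one cell.

The network stores the p attractor patterns with the pseudo-inverse
(projection) rule, which handles correlated patterns by normalizing with the
inverse pattern-overlap matrix Q. Two couplings are built from the same
patterns:

* the point coupling J', which makes each pattern a fixed point
  (J' xi^rho = xi^rho / p), and
* the cyclic coupling J~, which maps each pattern to its successor
  (J~ xi^rho = xi^(rho+1 mod p) / p),

and the working matrix is the convex blend J(lambda) = (1-lambda) J' +
lambda J~. With 0 < lambda < 1 and a finite effective temperature, the
dynamics dwell in each basin and hop forward under noise — the delayed cyclic
regime. Weak edges (|J_ij| below the median absolute coupling) are zeroed to
reflect the sparsity of real regulatory networks.

Spins follow the stochastic Glauber-style rule
P(sigma_i = +1) = 1 / (1 + exp(-2 h_i / T)) with local field
h_i = sum_j J_ij sigma_j + h_i^ext, updated asynchronously: each node is
selected independently with a fixed probability per step, and all selected
nodes update in parallel from the pre-step state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .patterns import AttractorSet

__all__ = [
    "CouplingMatrix",
    "CellState",
    "DynamicsParams",
    "ExternalField",
    "SingularOverlapError",
    "overlap_matrix",
    "build_point_coupling",
    "build_cyclic_coupling",
    "combine_couplings",
    "sparsify_median",
    "build_coupling",
    "local_field",
    "flip_probability",
    "step",
]


class SingularOverlapError(np.linalg.LinAlgError):
    """Patterns are not linearly independent: the overlap matrix Q is singular."""


@dataclass
class CouplingMatrix:
    """Dense N x N coupling strengths with provenance flags."""

    J: np.ndarray
    lambda_mix: float = 0.0
    sparsified: bool = False

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=float)
        if self.J.ndim != 2 or self.J.shape[0] != self.J.shape[1]:
            raise ValueError("J must be square")
        if not np.isfinite(self.J).all():
            raise ValueError("J must be finite")

    @property
    def n(self) -> int:
        return self.J.shape[0]


@dataclass
class CellState:
    """Spin configuration of a single cell at integer time t."""

    sigma: np.ndarray
    t: int = 0

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma)
        if not np.isin(self.sigma, (-1, 1)).all():
            raise ValueError("spins must be -1 or +1")
        self.sigma = self.sigma.astype(np.int8)


@dataclass
class DynamicsParams:
    """Noise level and asynchronous-update settings.

    T is the effective temperature of the update rule (dimensionless; the
    level of biochemical noise, not a physical temperature). ``update_prob``
    is the per-node probability of being updated at each step.
    """

    T: float = 0.035
    update_prob: float = 0.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 0:
            raise ValueError("temperature must be >= 0")
        if not 0 < self.update_prob <= 1:
            raise ValueError("update_prob must be in (0, 1]")


@dataclass
class ExternalField:
    """Per-gene external bias, plus clamps modeling full inhibition.

    ``values`` adds to the local field; ``clamp_mask`` marks genes whose
    inhibition is total (the minus-infinity field limit), realized by forcing
    their spins to -1 at every step instead of doing non-finite arithmetic.
    """

    values: np.ndarray
    clamp_mask: np.ndarray

    @classmethod
    def zero(cls, n: int) -> "ExternalField":
        return cls(values=np.zeros(n), clamp_mask=np.zeros(n, dtype=bool))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.clamp_mask = np.asarray(self.clamp_mask, dtype=bool)
        if self.values.shape != self.clamp_mask.shape:
            raise ValueError("values and clamp_mask must have the same length")
        if not np.isfinite(self.values).all():
            raise ValueError("finite bias only; use clamp_mask for full inhibition")


def overlap_matrix(attractors: AttractorSet) -> np.ndarray:
    """Pattern-overlap matrix Q_munu = (1/N) sum_i xi_i^mu xi_i^nu.

    Computed over the construction block: all p patterns in general, but only
    the first p/2 for antisymmetric (sinusoid-derived) sets, where the second
    half is linearly dependent on the first by negation.
    """
    block = attractors.construction_block().astype(float)
    q = block @ block.T / attractors.n_genes
    if np.linalg.matrix_rank(q) < q.shape[0]:
        raise SingularOverlapError(
            "overlap matrix is singular: patterns in the construction block "
            "are not linearly independent"
        )
    return q


def _projection_coupling(targets: np.ndarray, attractors: AttractorSet) -> np.ndarray:
    block = attractors.construction_block().astype(float)
    q = overlap_matrix(attractors)
    weights = np.linalg.solve(q, block)  # Q^-1 xi, shape (q, N)
    n, p = attractors.n_genes, attractors.p
    return targets.T @ weights / (n * p)


def build_point_coupling(attractors: AttractorSet) -> CouplingMatrix:
    """Pseudo-inverse rule storing each pattern as a point attractor.

    Satisfies the projection identity (J' xi^rho)_i = xi_i^rho / p for every
    stored pattern and, through the model's global spin-flip symmetry, for
    their negations.
    """
    block = attractors.construction_block().astype(float)
    return CouplingMatrix(J=_projection_coupling(block, attractors), lambda_mix=0.0)


def build_cyclic_coupling(attractors: AttractorSet) -> CouplingMatrix:
    """Pseudo-inverse rule mapping each pattern to its cyclic successor.

    Satisfies (J~ xi^rho)_i = xi_i^((rho+1) mod p) / p; at T=0 a synchronous
    sweep walks the stored cycle xi^0 -> xi^1 -> ... -> xi^(p-1) -> xi^0.
    """
    block_size = attractors.construction_block().shape[0]
    successors = np.array(
        [attractors.xi[(mu + 1) % attractors.p] for mu in range(block_size)],
        dtype=float,
    )
    return CouplingMatrix(J=_projection_coupling(successors, attractors), lambda_mix=1.0)


def combine_couplings(
    point: CouplingMatrix, cyclic: CouplingMatrix, lambda_mix: float
) -> CouplingMatrix:
    """Convex blend (1 - lambda) J' + lambda J~ of point and cyclic couplings."""
    if not 0 <= lambda_mix <= 1:
        raise ValueError(f"lambda_mix must be in [0, 1], got {lambda_mix}")
    if point.J.shape != cyclic.J.shape:
        raise ValueError("coupling matrices must share a shape")
    return CouplingMatrix(
        J=(1 - lambda_mix) * point.J + lambda_mix * cyclic.J, lambda_mix=lambda_mix
    )


def sparsify_median(coupling: CouplingMatrix) -> CouplingMatrix:
    """Zero all entries with |J_ij| strictly below the median of |J|.

    The median runs over all N^2 entries, diagonal included. Stricter
    thresholds are not offered: pruning more than half the edges breaks the
    stored cycle through the reduced capacity of diluted networks.
    """
    magnitude = np.abs(coupling.J)
    cutoff = np.median(magnitude)
    sparse = np.where(magnitude < cutoff, 0.0, coupling.J)
    return CouplingMatrix(J=sparse, lambda_mix=coupling.lambda_mix, sparsified=True)


def build_coupling(
    attractors: AttractorSet, lambda_mix: float, sparsify: bool = True
) -> CouplingMatrix:
    """Full construction pipeline: blend point and cyclic rules, then sparsify."""
    blended = combine_couplings(
        build_point_coupling(attractors), build_cyclic_coupling(attractors), lambda_mix
    )
    return sparsify_median(blended) if sparsify else blended


def local_field(
    coupling: CouplingMatrix,
    state: CellState,
    h_ext: ExternalField | None = None,
) -> np.ndarray:
    """Total field h_i = sum_j J_ij sigma_j + h_i^ext."""
    h = coupling.J @ state.sigma.astype(float)
    if h_ext is not None:
        h = h + h_ext.values
    return h


def flip_probability(h: np.ndarray | float, T: float) -> np.ndarray | float:
    """Probability the spin is +1 after an update: 1 / (1 + exp(-2h/T)).

    The T=0 limit is the sign rule, with probability 1/2 at h=0 (the
    symmetric limit of the logistic). Stable for large |h|/T via expit.
    """
    h = np.asarray(h, dtype=float)
    if T == 0:
        out = np.where(h > 0, 1.0, np.where(h < 0, 0.0, 0.5))
    else:
        out = expit(2.0 * h / T)
    return float(out) if out.ndim == 0 else out


def step(
    state: CellState,
    coupling: CouplingMatrix,
    h_ext: ExternalField | None,
    params: DynamicsParams,
    rng: np.random.Generator,
) -> CellState:
    """One asynchronous update step for a single cell.

    Each node is independently selected with probability ``update_prob``;
    selected nodes draw fresh spins from :func:`flip_probability` using the
    field computed once from the pre-step state (parallel within the step).
    Unselected nodes keep their spins. Clamped nodes are forced to -1.
    """
    n = state.sigma.size
    h = local_field(coupling, state, h_ext)
    p_up = flip_probability(h, params.T)
    selected = rng.random(n) < params.update_prob
    fresh = np.where(rng.random(n) < p_up, 1, -1).astype(np.int8)
    sigma = np.where(selected, fresh, state.sigma).astype(np.int8)
    if h_ext is not None and h_ext.clamp_mask.any():
        sigma[h_ext.clamp_mask] = -1
    return CellState(sigma=sigma, t=state.t + 1)
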