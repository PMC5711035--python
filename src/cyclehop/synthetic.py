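"""Ground-truth synthetic data: expression matrices and attractor sets.

The expression generator emulates a synchronized cell-cycle time course:
periodic genes follow decaying sinusoids with per-gene amplitude, baseline
and phase but a shared frequency and decay rate (the population slowly
decoheres at a common rate), aperiodic genes wander as white noise around a
constant, and additive Gaussian measurement noise covers everything. Ground-
truth labels and parameters are returned alongside, so selection accuracy
and parameter-recovery bias can be measured exactly.

The attractor generator skips the fitting stage entirely: it draws uniform
gene phases and discretizes sign(cos(2 pi mu / p - phi_i)) directly, giving
antisymmetric pattern sets of any size for dynamics tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .patterns import AttractorSet

__all__ = ["SyntheticSpec", "generate_expression", "generate_attractors"]

TWO_PI = 2.0 * math.pi


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic time course.

    Defaults are shaped like a budding-yeast metabolic/cell-cycle time course:
    ~70 min period (omega ~ 0.09 rad/min), 40 samples over 2.5 periods, 300
    periodic genes among 1000, amplitudes of order 1-3 expression units on
    baselines of 4-8, slow decay, and measurement noise at 5% of a typical
    amplitude.
    """

    n_periodic: int = 300
    n_noise: int = 700
    omega_true: float = TWO_PI / 70.0  # rad/min; ~70 min cycle
    period_count: float = 2.5
    n_times: int = 40
    decay_b: float = 0.005  # 1/min
    noise_sigma: float = 0.1  # additive measurement noise, expression units
    amp_range: tuple[float, float] = (1.0, 3.0)
    baseline_range: tuple[float, float] = (4.0, 8.0)
    noise_gene_sd_range: tuple[float, float] = (0.5, 1.5)
    phase_distribution: str | np.ndarray = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_periodic < 0 or self.n_noise < 0 or self.n_periodic + self.n_noise == 0:
            raise ValueError("gene counts must be nonnegative and not both zero")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.omega_true <= 0:
            raise ValueError("omega_true must be positive")


def generate_expression(spec: SyntheticSpec) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw a synthetic expression matrix plus its ground truth.

    Returns ``(matrix, truth)`` where ``truth`` has one row per gene with
    columns ``gene_id, is_periodic, a, b, omega, phi, x0``.
    """
    rng = np.random.default_rng(spec.seed)
    period = TWO_PI / spec.omega_true
    times = np.linspace(0.0, spec.period_count * period, spec.n_times)

    n_total = spec.n_periodic + spec.n_noise
    gene_ids = [f"G{i:04d}" for i in range(n_total)]

    a = rng.uniform(*spec.amp_range, size=spec.n_periodic)
    x0 = rng.uniform(*spec.baseline_range, size=n_total)
    if isinstance(spec.phase_distribution, str):
        if spec.phase_distribution != "uniform":
            raise ValueError(f"unknown phase distribution {spec.phase_distribution!r}")
        phi = rng.uniform(0.0, TWO_PI, size=spec.n_periodic)
    else:
        phi = np.asarray(spec.phase_distribution, dtype=float)
        if phi.size != spec.n_periodic:
            raise ValueError("explicit phase list must have n_periodic entries")

    values = np.empty((n_total, spec.n_times))
    envelope = np.exp(-spec.decay_b * times)
    values[: spec.n_periodic] = (
        a[:, None] * envelope[None, :] *
        np.cos(spec.omega_true * times[None, :] - phi[:, None])
        + x0[: spec.n_periodic, None]
    )
    sd = rng.uniform(*spec.noise_gene_sd_range, size=spec.n_noise)
    values[spec.n_periodic :] = (
        x0[spec.n_periodic :, None] + rng.normal(0.0, 1.0, (spec.n_noise, spec.n_times)) * sd[:, None]
    )
    if spec.noise_sigma > 0:
        values += rng.normal(0.0, spec.noise_sigma, values.shape)
    np.clip(values, 0.0, None, out=values)  # expression is nonnegative

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "is_periodic": [True] * spec.n_periodic + [False] * spec.n_noise,
            "a": np.concatenate([a, np.full(spec.n_noise, np.nan)]),
            "b": np.where(
                np.arange(n_total) < spec.n_periodic, spec.decay_b, np.nan
            ),
            "omega": np.where(
                np.arange(n_total) < spec.n_periodic, spec.omega_true, np.nan
            ),
            "phi": np.concatenate([phi, np.full(spec.n_noise, np.nan)]),
            "x0": x0,
        }
    )
    matrix = ExpressionMatrix(
        gene_ids=gene_ids, times=times, values=values, transient_skip=2
    )
    return matrix, truth


def generate_attractors(N: int, p: int = 8, seed: int = 0) -> AttractorSet:
    """Sinusoid-structured antisymmetric attractor set from random phases.

    Each gene i gets a uniform phase phi_i and pattern entries
    xi_i^mu = sign(cos(2 pi mu / p - phi_i)) for mu < p/2, with the second
    half the exact negation. Degenerate draws in which two of the first p/2
    patterns collide (possible only for tiny N) are redrawn.
    """
    if p < 2 or p % 2 != 0:
        raise ValueError("p must be even and >= 2")
    if N < p:
        raise ValueError(f"need N >= p, got N={N}, p={p}")
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:04d}" for i in range(N)]
    half = p // 2
    for _ in range(1000):
        phi = rng.uniform(0.0, TWO_PI, size=N)
        angles = TWO_PI * np.arange(half)[:, None] / p - phi[None, :]
        xi_half = np.where(np.cos(angles) >= 0, 1, -1).astype(np.int8)
        distinct = len({row.tobytes() for row in xi_half}) == half
        if distinct:
            xi = np.vstack([xi_half, -xi_half])
            return AttractorSet(xi=xi, gene_ids=gene_ids, antisymmetric=True)
    raise RuntimeError("could not draw distinct patterns; N too small for p")
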