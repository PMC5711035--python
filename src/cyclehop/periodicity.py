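"""Periodic-gene detection by decaying-sinusoid fitting and Boolean encoding.

Each gene's time course is fit to a decaying sinusoid

    x(t) = a * exp(-b t) * cos(omega t - phi) + x0

by bounded trust-region nonlinear least squares. Fit quality is summarized by
the maximum relative one-sigma parameter uncertainty r_max; genes below a
threshold are called periodic. Selected genes are refit with the angular
frequency fixed at the population mean, giving a coherent set of phases, and
the fitted curves are discretized to +/-1 (over/under the asymptotic mean x0)
at p uniformly spaced times across one period to yield the attractor cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

from .expression import ExpressionMatrix
from .patterns import AttractorSet

__all__ = [
    "SinusoidFit",
    "NoPeriodicGenesError",
    "DegeneratePatternsError",
    "fit_decaying_sinusoid",
    "relative_uncertainty",
    "select_periodic",
    "discretize",
    "extract_attractors",
    "write_fits",
    "read_fits",
]

TWO_PI = 2.0 * math.pi


class NoPeriodicGenesError(ValueError):
    """No gene passed the periodicity threshold; downstream needs N >= p."""


class DegeneratePatternsError(ValueError):
    """Two attractor patterns collide (phases too degenerate to separate)."""


@dataclass
class SinusoidFit:
    """Best-fit decaying-sinusoid parameters for one gene, with uncertainties.

    Canonical form: ``a >= 0`` (a negative amplitude is folded into the phase
    via cos(theta + pi) = -cos(theta)) and ``phi`` wrapped into [0, 2pi).
    ``r_max`` is the maximum relative parameter uncertainty; +inf marks a
    failed or degenerate fit, which no finite threshold will accept.
    """

    gene_id: str
    a: float
    b: float
    omega: float
    phi: float
    x0: float
    da: float = np.inf
    db: float = np.inf
    domega: float = np.inf
    dphi: float = np.inf
    dx0: float = np.inf
    r_max: float = np.inf
    converged: bool = True

    def predict(self, t: np.ndarray | float) -> np.ndarray | float:
        return _model(np.asarray(t, dtype=float), self.a, self.b, self.omega, self.phi, self.x0)


def _model(t, a, b, omega, phi, x0):
    return a * np.exp(-b * t) * np.cos(omega * t - phi) + x0


def _wrap_phase(phi: float) -> float:
    return float(np.mod(phi, TWO_PI))


def _fft_seed(t: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Seed (omega, phi) from the dominant nonzero DFT component.

    The least-squares surface is multimodal in (omega, phi); a spectral seed
    puts the optimizer in the right basin. Sampling is assumed near-uniform.
    """
    dt = float(np.mean(np.diff(t)))
    detrended = x - x.mean()
    spectrum = np.fft.rfft(detrended)
    freqs = np.fft.rfftfreq(x.size, d=dt)
    if spectrum.size <= 1:
        return math.pi / (2 * dt), 0.0
    k = 1 + int(np.argmax(np.abs(spectrum[1:])))
    omega0 = max(TWO_PI * freqs[k], 1e-6)
    # x ~ a cos(omega t - phi) has DFT phase angle(X_k) ~ omega t0 - phi
    phi0 = _wrap_phase(omega0 * t[0] - float(np.angle(spectrum[k])))
    return omega0, phi0


def fit_decaying_sinusoid(
    times: np.ndarray,
    values: np.ndarray,
    skip: int = 0,
    omega_fixed: float | None = None,
    allow_negative_decay: bool = False,
    gene_id: str = "",
) -> SinusoidFit:
    """Fit one gene's series to a decaying sinusoid.

    Parameters
    ----------
    times, values
        The full series; the first ``skip`` points (chemical-perturbation
        transients) are excluded from the fit.
    omega_fixed
        When given, the angular frequency is held at this value (the common-
        frequency refit) and only (a, b, phi, x0) are free.
    allow_negative_decay
        Let the decay rate go negative during optimization and take its
        absolute value afterwards. Useful for short series covering barely
        one period, where b is near zero and pinning it at the bound would
        bias the fit.

    Returns a :class:`SinusoidFit`; non-convergence or a singular covariance
    yields a flagged fit with ``r_max = +inf`` rather than an exception.
    """
    t = np.asarray(times, dtype=float)[skip:]
    x = np.asarray(values, dtype=float)[skip:]
    n_free = 4 if omega_fixed is not None else 5
    if t.size < n_free + 1:
        raise ValueError(f"need at least {n_free + 1} points after skip, got {t.size}")
    if not (np.isfinite(t).all() and np.isfinite(x).all()):
        raise ValueError("times and values must be finite")

    omega0, phi0 = _fft_seed(t, x)
    if omega_fixed is not None:
        omega0 = float(omega_fixed)
    a0 = 0.5 * (x.max() - x.min())
    x00 = float(x.mean())
    dt_min = float(np.min(np.diff(t))) if t.size > 1 else 1.0
    omega_hi = math.pi / dt_min  # Nyquist: avoid aliased frequencies
    b_lo = -np.inf if allow_negative_decay else 0.0

    failed = replace(
        SinusoidFit(gene_id, a0, 0.0, omega0, phi0, x00), r_max=np.inf, converged=False
    )

    try:
        if omega_fixed is None:
            p0 = [a0, 0.0, min(omega0, 0.99 * omega_hi), phi0, x00]
            bounds = ([0.0, b_lo, 1e-9, -TWO_PI, -np.inf],
                      [np.inf, np.inf, omega_hi, 2 * TWO_PI, np.inf])
            popt, pcov = curve_fit(_model, t, x, p0=p0, bounds=bounds, method="trf",
                                   maxfev=20000)
            a, b, omega, phi, x0 = popt
            da, db, domega, dphi, dx0 = np.sqrt(np.diag(pcov))
        else:
            w = float(omega_fixed)

            def fixed(t_, a_, b_, phi_, x0_):
                return _model(t_, a_, b_, w, phi_, x0_)

            p0 = [a0, 0.0, phi0, x00]
            bounds = ([0.0, b_lo, -TWO_PI, -np.inf],
                      [np.inf, np.inf, 2 * TWO_PI, np.inf])
            popt, pcov = curve_fit(fixed, t, x, p0=p0, bounds=bounds, method="trf",
                                   maxfev=20000)
            a, b, phi, x0 = popt
            omega = w
            da, db, dphi, dx0 = np.sqrt(np.diag(pcov))
            domega = 0.0
    except (RuntimeError, ValueError):
        return failed

    if not np.all(np.isfinite([da, db, domega, dphi, dx0])):
        return failed

    if a < 0:  # fold negative amplitude into the phase
        a, phi = -a, phi + math.pi
    if allow_negative_decay:
        b = abs(b)
    fit = SinusoidFit(
        gene_id=gene_id, a=float(a), b=float(b), omega=float(omega),
        phi=_wrap_phase(float(phi)), x0=float(x0),
        da=float(da), db=float(db), domega=float(domega), dphi=float(dphi),
        dx0=float(dx0),
    )
    fit.r_max = relative_uncertainty(fit, drop_decay_term=allow_negative_decay)
    return fit


def relative_uncertainty(fit: SinusoidFit, drop_decay_term: bool = False) -> float:
    """Maximum relative one-sigma uncertainty across the fit parameters.

    r_max = max(dx0/x0, da/a, db/b, domega/omega, dphi/2pi). A zero-valued
    denominator makes its ratio +inf. ``drop_decay_term`` removes db/b from
    the maximum — appropriate when the series covers barely one period, so
    the decay rate is indistinguishable from zero and its relative error is
    meaninglessly large while every other parameter is well determined.
    """

    def ratio(delta: float, value: float) -> float:
        if value == 0:
            return np.inf
        return abs(delta / value)

    terms = [
        ratio(fit.dx0, fit.x0),
        ratio(fit.da, fit.a),
        ratio(fit.domega, fit.omega),
        abs(fit.dphi) / TWO_PI,
    ]
    if not drop_decay_term:
        terms.append(ratio(fit.db, fit.b))
    return float(max(terms))


def select_periodic(
    matrix: ExpressionMatrix,
    threshold: float = 0.3,
    drop_decay_term: bool = False,
) -> list[SinusoidFit]:
    """Two-pass periodic-gene selection.

    Pass 1 fits every gene with a free frequency and keeps those with
    ``r_max < threshold``. Pass 2 fixes the frequency at the mean over kept
    genes and refits them, producing the final coherent phase set. The
    returned fits all share ``omega`` (the mean frequency).
    """
    if threshold <= 0:
        raise NoPeriodicGenesError("threshold must be positive; nothing can pass")

    skip = matrix.transient_skip
    free_fits = [
        fit_decaying_sinusoid(
            matrix.times, matrix.values[i], skip=skip,
            allow_negative_decay=drop_decay_term, gene_id=matrix.gene_ids[i],
        )
        for i in range(matrix.n_genes)
    ]
    kept = [
        (i, f)
        for i, f in enumerate(free_fits)
        if relative_uncertainty(f, drop_decay_term) < threshold
    ]
    if not kept:
        raise NoPeriodicGenesError(
            f"no gene passed r_max < {threshold}; cannot build attractors"
        )

    omega_mean = float(np.mean([f.omega for _, f in kept]))
    final = [
        fit_decaying_sinusoid(
            matrix.times, matrix.values[i], skip=skip, omega_fixed=omega_mean,
            allow_negative_decay=drop_decay_term, gene_id=f.gene_id,
        )
        for i, f in kept
    ]
    return final


def discretize(fit: SinusoidFit, t: float | np.ndarray) -> np.ndarray | int:
    """Boolean expression at time t: sign(x(t) - x0), with sign(0) -> +1.

    For a canonical fit (a >= 0) the positive decay envelope drops out and
    this equals sign(cos(omega t - phi)).
    """
    deviation = np.asarray(fit.predict(t)) - fit.x0
    out = np.where(deviation >= 0, 1, -1).astype(np.int8)
    return int(out) if out.ndim == 0 else out


def extract_attractors(
    fits: list[SinusoidFit],
    p: int = 8,
    t_start: float = 0.0,
) -> AttractorSet:
    """Sample the fitted Boolean curves at p uniform times over one period.

    State mu is the discretized expression at ``t_start + mu * period / p``.
    For even p the half-period antisymmetry of the cosine makes
    xi^(mu + p/2) = -xi^mu; the second half is constructed by explicit
    negation so the identity is machine-exact regardless of the sign(0)
    tie convention.
    """
    if p < 2:
        raise ValueError("need p >= 2 states")
    if len(fits) < p:
        raise ValueError(f"need at least N={p} genes for p={p} patterns, got {len(fits)}")

    omega = float(np.mean([f.omega for f in fits]))
    period = TWO_PI / omega
    half = p // 2 if p % 2 == 0 else p
    columns = []
    for mu in range(half):
        t_mu = t_start + mu * period / p
        columns.append([discretize(f, t_mu) for f in fits])
    xi = np.array(columns, dtype=np.int8)

    # degenerate phases collapse distinct states onto the same pattern
    for mu in range(half):
        for nu in range(mu + 1, half):
            if np.array_equal(xi[mu], xi[nu]):
                raise DegeneratePatternsError(
                    f"patterns {mu} and {nu} are identical; phases too degenerate"
                )

    antisymmetric = p % 2 == 0
    if antisymmetric:
        xi = np.vstack([xi, -xi])
    return AttractorSet(
        xi=xi, gene_ids=[f.gene_id for f in fits], antisymmetric=antisymmetric
    )


_FIT_COLUMNS = ["a", "b", "omega", "phi", "x0", "da", "db", "domega", "dphi", "dx0", "r_max"]


def write_fits(fits: list[SinusoidFit], path) -> None:
    """Write fits as TSV: gene_id, parameters, uncertainties, r_max."""
    import pandas as pd

    rows = {col: [getattr(f, col) for f in fits] for col in _FIT_COLUMNS}
    df = pd.DataFrame(rows, index=[f.gene_id for f in fits])
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_fits(path) -> list[SinusoidFit]:
    """Read the TSV written by :func:`write_fits`."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return [
        SinusoidFit(gene_id=str(gid), **{col: float(row[col]) for col in _FIT_COLUMNS})
        for gid, row in df.iterrows()
    ]
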