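"""Boolean attractor patterns: the p cell-cycle states stored in the network.

An :class:`AttractorSet` holds ``p`` patterns of N spins each, one per
coarse-grained cell-cycle state. Patterns derived from sinusoidal fits with
even ``p`` come in antipodal pairs, xi^(mu + p/2) = -xi^mu: each gene is over-
expressed for exactly half the cycle, so states half a period apart are exact
negations of each other.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["AttractorSet", "read_attractors", "write_attractors"]


@dataclass
class AttractorSet:
    """``p`` Boolean patterns over ``N`` genes, entries in {-1, +1}.

    ``antisymmetric`` marks the half-cycle negation structure
    xi^(mu + p/2) = -xi^mu; when set, coupling construction only needs the
    first ``p/2`` patterns (the rest follow by the global spin-flip symmetry
    of the model).
    """

    xi: np.ndarray
    gene_ids: list[str]
    antisymmetric: bool = False

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi)
        if self.xi.ndim != 2:
            raise ValueError("xi must be a 2-D (p x N) array")
        if not np.isin(self.xi, (-1, 1)).all():
            raise ValueError("attractor entries must be -1 or +1")
        self.xi = self.xi.astype(np.int8)
        if self.xi.shape[1] != len(self.gene_ids):
            raise ValueError(
                f"{self.xi.shape[1]} columns but {len(self.gene_ids)} gene ids"
            )
        if self.antisymmetric:
            p = self.p
            if p % 2 != 0:
                raise ValueError("antisymmetric attractor sets need even p")
            if not np.array_equal(self.xi[p // 2 :], -self.xi[: p // 2]):
                raise ValueError(
                    "antisymmetric flag set but xi^(mu+p/2) != -xi^mu"
                )

    @property
    def p(self) -> int:
        return self.xi.shape[0]

    @property
    def n_genes(self) -> int:
        return self.xi.shape[1]

    def construction_block(self) -> np.ndarray:
        """The pattern rows used to build couplings (first p/2 when antisymmetric)."""
        return self.xi[: self.p // 2] if self.antisymmetric else self.xi


def write_attractors(attractors: AttractorSet, path: str | Path) -> None:
    """Write patterns as TSV: gene_id rows, one +/-1 column per state."""
    df = pd.DataFrame(
        attractors.xi.T,
        index=attractors.gene_ids,
        columns=[f"state_{mu}" for mu in range(attractors.p)],
    )
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_attractors(path: str | Path) -> AttractorSet:
    """Read the TSV written by :func:`write_attractors`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    xi = df.to_numpy().T
    p = xi.shape[0]
    antisym = p % 2 == 0 and bool(np.array_equal(xi[p // 2 :], -xi[: p // 2]))
    return AttractorSet(
        xi=xi, gene_ids=[str(g) for g in df.index], antisymmetric=antisym
    )
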