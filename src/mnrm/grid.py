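"""Direct-product quadrature grids over the latent-trait space.

Integrals over the latent traits are approximated by rectangular quadrature:
a lattice of equally spaced nodes per dimension, with weights proportional
to the multivariate normal prior density (mean 0, unit variances,
correlation R) at each node, normalized to sum to one.  The normalized
weights W(x) then take the place of the prior density in every posterior
computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import multivariate_normal

from .errors import ValidationError

__all__ = ["LatentGrid", "build_grid"]


@dataclass(frozen=True)
class LatentGrid:
    """Direct-product quadrature nodes with normalized prior weights.

    ``axes[d]`` holds the ordered node values of dimension d; ``nodes`` is
    the (Q x D) direct product in row-major order (first dimension slowest);
    ``weights`` are the normalized prior weights W(x).
    """

    axes: tuple[np.ndarray, ...]
    nodes: np.ndarray
    weights: np.ndarray
    R: np.ndarray

    @property
    def D(self) -> int:
        return len(self.axes)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def axis_index(self, d: int) -> np.ndarray:
        """For each node, the index of its coordinate along axis d."""
        idx = np.searchsorted(self.axes[d], self.nodes[:, d])
        return idx

    def with_R(self, R: np.ndarray) -> "LatentGrid":
        """Same nodes, weights rebuilt for a new latent correlation matrix."""
        return build_grid(nodes=[ax for ax in self.axes], R=R)


def build_grid(
    nodes_per_dim: int | None = None,
    lo: float = -6.0,
    hi: float = 6.0,
    R: np.ndarray | None = None,
    nodes: Sequence[np.ndarray] | None = None,
    D: int | None = None,
) -> LatentGrid:
    """Build a rectangular quadrature grid.

    Either give ``nodes_per_dim`` (equally spaced nodes on [lo, hi] in every
    dimension; the default scoring grid is 49 nodes on [-6, 6]) or explicit
    per-dimension node arrays via ``nodes``.  The dimension count comes from
    ``R``, ``nodes``, or ``D``.
    """
    if R is not None:
        R = np.asarray(R, dtype=float)
    if nodes is not None:
        axes = tuple(np.sort(np.asarray(ax, dtype=float)) for ax in nodes)
    else:
        if nodes_per_dim is None or nodes_per_dim < 2:
            raise ValidationError("need nodes_per_dim >= 2 or explicit nodes")
        if not lo < hi:
            raise ValidationError(f"need lo < hi, got [{lo}, {hi}]")
        if D is None:
            D = 1 if R is None else R.shape[0]
        ax = np.linspace(lo, hi, nodes_per_dim)
        axes = tuple(ax.copy() for _ in range(D))
    D = len(axes)
    if R is None:
        R = np.eye(D)
    if R.shape != (D, D):
        raise ValidationError(f"R must be {D}x{D}, got {R.shape}")
    if np.linalg.eigvalsh((R + R.T) / 2)[0] <= 0:
        raise ValidationError("R is not positive definite")

    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([m.ravel() for m in mesh])
    logpdf = multivariate_normal(mean=np.zeros(D), cov=R).logpdf(pts)
    logpdf = np.atleast_1d(logpdf)
    w = np.exp(logpdf - logpdf.max())
    w /= w.sum()
    return LatentGrid(axes=axes, nodes=pts, weights=w, R=R)
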