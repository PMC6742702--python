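"""Shape-space affinity representation.

B-cell receptor (BCR) specificity is a point on a small integer lattice (the
"shape space"); the Manhattan distance ``d`` to the optimal clone sets the
binding affinity through a Gaussian measure ``a = exp(-d^2 / w^2)``.  Somatic
hypermutation is a unit step in a random dimension.  Secreted antibodies are
coarse-grained into ``n_bins`` affinity bins whose dissociation constants span
10^-5.5 .. 10^-9.5 M in steps of 0.4 decades.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ShapeSpace",
    "dissociation_constants",
    "affinity_to_bin",
]


def dissociation_constants(
    n_bins: int = 11, kd_top_log10: float = -5.5, kd_step_log10: float = 0.4
) -> np.ndarray:
    """K(i) = 10^(kd_top - kd_step * i) in molar, strictly decreasing in i."""
    i = np.arange(n_bins)
    return 10.0 ** (kd_top_log10 - kd_step_log10 * i)


def affinity_to_bin(a, n_bins: int = 11):
    """Map affinity in [0, 1] to a bin index (round-half-up).

    a = 0 lands in bin 0 (weakest K) and a = 1 in the top bin.  Scalar in,
    scalar out; array in, array out.
    """
    arr = np.asarray(a, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("affinity must lie in [0, 1]")
    # floor(x + 0.5) implements round-half-up (np.round would round-half-even)
    idx = np.floor(arr * (n_bins - 1) + 0.5).astype(np.int64)
    idx = np.clip(idx, 0, n_bins - 1)
    return idx if arr.ndim else int(idx)


@dataclass
class ShapeSpace:
    """The affinity landscape: box extent, Gaussian width, optimal clone."""

    dim: int = 4
    extent: int = 10
    width: float = 2.8
    optimal: Sequence[int] = (5, 5, 5, 5)

    def __post_init__(self) -> None:
        self.optimal = np.asarray(self.optimal, dtype=np.int64)
        if self.optimal.shape != (self.dim,):
            raise ValueError("optimal clone must have `dim` coordinates")
        if np.any(self.optimal < 0) or np.any(self.optimal >= self.extent):
            raise ValueError("optimal clone outside the shape-space box")

    # -- distances and affinities -----------------------------------------
    def distance(self, p, q=None) -> np.ndarray:
        """Manhattan distance; `p` may be (dim,) or (n, dim)."""
        q = self.optimal if q is None else np.asarray(q)
        p = np.asarray(p)
        if p.shape[-1] != self.dim or q.shape[-1] != self.dim:
            raise ValueError("shape points must have `dim` coordinates")
        return np.abs(p - q).sum(axis=-1)

    def affinity(self, p, q=None):
        """Gaussian affinity exp(-d^2/w^2) of p against q (default: optimum)."""
        d = self.distance(p, q)
        a = np.exp(-(d.astype(float) ** 2) / self.width**2)
        return a if np.ndim(d) else float(a)

    # -- mutation ----------------------------------------------------------
    def mutate(self, p, rng: np.random.Generator) -> np.ndarray:
        """One unit step (+/-1 in one dimension), uniform over in-box moves."""
        return self.mutate_many(np.asarray(p, dtype=np.int64)[None, :], rng)[0]

    def mutate_many(self, points: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Vectorised :meth:`mutate` on an (n, dim) array of points."""
        pts = np.array(points, dtype=np.int64, copy=True)
        n = len(pts)
        pending = np.arange(n)
        out = pts.copy()
        # rejection sampling: uniform over the 2*dim moves conditioned on
        # staying in the box == uniform over the in-box neighbour set
        while len(pending):
            dims = rng.integers(0, self.dim, size=len(pending))
            signs = rng.integers(0, 2, size=len(pending)) * 2 - 1
            cand = pts[pending].copy()
            cand[np.arange(len(pending)), dims] += signs
            ok = (cand[np.arange(len(pending)), dims] >= 0) & (
                cand[np.arange(len(pending)), dims] < self.extent
            )
            out[pending[ok]] = cand[ok]
            pending = pending[~ok]
        return out

    # -- founder sampling --------------------------------------------------
    def sample_founders(
        self, n: int, rng: np.random.Generator, d_min: int = 5, d_max: int = 10
    ) -> np.ndarray:
        """Low-affinity seed clones of a nascent GC.

        The target Manhattan distance to the optimum is drawn uniformly from
        [d_min, d_max], then a shape point is drawn uniformly from that
        distance shell (by rejection).  Sampling the distance first keeps the
        seed pool from being dominated by the far shells, which hold
        combinatorially more points.
        """
        if not 0 <= d_min <= d_max:
            raise ValueError("need 0 <= d_min <= d_max")
        out = np.empty((n, self.dim), dtype=np.int64)
        want = rng.integers(d_min, d_max + 1, size=n)
        pending = np.arange(n)
        while len(pending):
            cand = rng.integers(0, self.extent, size=(len(pending), self.dim))
            ok = self.distance(cand) == want[pending]
            out[pending[ok]] = cand[ok]
            pending = pending[~ok]
        return out
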