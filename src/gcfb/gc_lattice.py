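"""Spatial substrate: 3D lattice, spherical GC volume, zones, FDC/Tfh maps.

The reaction volume is the set of lattice nodes within ``gc_radius_um`` of the
centre, halved into a dark zone (DZ, z < 0) and a light zone (LZ, z > 0); the
equatorial plane is split by checkerboard parity so both zones hold the same
node count to well under 1%.  Nodes are addressed by a flat index into the
bounding cube; a precomputed (n_nodes, 6) neighbour table holds -1 for moves
that would leave the sphere.

Motile B cells obey single-occupancy exclusion.  FDCs and Tfh are immobile,
non-blocking landmarks: each covers a Chebyshev neighbourhood (its dendritic
reach / contact range) recorded in per-node lookup maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# the six lattice directions, index 0..5
DIRECTIONS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64,
)

DZ, LZ = 0, 1


@dataclass
class LatticeConfig:
    lattice_constant_um: float = 5.0
    gc_radius_um: float = 160.0


class Lattice:
    """Static geometry: sphere membership, zones, neighbours, landmark maps."""

    def __init__(self, cfg: LatticeConfig):
        if cfg.gc_radius_um < cfg.lattice_constant_um:
            raise ValueError("GC radius must be at least one lattice constant")
        self.cfg = cfg
        r = int(np.floor(cfg.gc_radius_um / cfg.lattice_constant_um))
        self.radius_nodes = r
        self.side = 2 * r + 1
        ax = np.arange(-r, r + 1)
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        self.coords = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
        r2 = (self.coords**2).sum(axis=1)
        self.in_sphere = r2 <= r * r
        self.n_nodes = self.side**3
        self.node_ids = np.flatnonzero(self.in_sphere)

        # zones: z sign; equatorial plane split by (x+y) parity for balance
        z = self.coords[:, 2]
        zone = np.where(z > 0, LZ, DZ).astype(np.int8)
        eq = z == 0
        zone[eq] = np.where((self.coords[eq, 0] + self.coords[eq, 1]) % 2 == 0, DZ, LZ)
        zone[~self.in_sphere] = -1
        self.zone = zone

        # neighbour table; -1 where the step leaves the sphere
        strides = np.array([self.side * self.side, self.side, 1], dtype=np.int64)
        self.nbr = np.full((self.n_nodes, 6), -1, dtype=np.int64)
        for d, vec in enumerate(DIRECTIONS):
            tgt = self.coords + vec
            ok = (np.abs(tgt) <= r).all(axis=1)
            flat = ((tgt + r) * strides).sum(axis=1)
            ok &= self.in_sphere[np.clip(flat, 0, self.n_nodes - 1)]
            self.nbr[ok & self.in_sphere, d] = flat[ok & self.in_sphere]

        self.is_border = self.in_sphere & (self.nbr == -1).any(axis=1)

        # landmark maps filled by place_* (node -> landmark id, -1 elsewhere)
        self.fdc_map = np.full(self.n_nodes, -1, dtype=np.int64)
        self.tfh_map = np.full(self.n_nodes, -1, dtype=np.int64)
        self.fdc_nodes = np.empty(0, dtype=np.int64)
        self.tfh_nodes = np.empty(0, dtype=np.int64)

        # unit outward direction per node, used to bias output cells toward
        # the border: the axis direction with the largest radial gain
        gain = np.einsum("nd,kd->nk", self.coords, DIRECTIONS)
        self.outward_dir = np.argmax(gain, axis=1).astype(np.int8)

    # ------------------------------------------------------------------
    def zone_nodes(self, zone: int) -> np.ndarray:
        return np.flatnonzero(self.in_sphere & (self.zone == zone))

    def _stamp(self, target_map: np.ndarray, centres: np.ndarray, reach: int) -> None:
        r = self.radius_nodes
        strides = np.array([self.side * self.side, self.side, 1], dtype=np.int64)
        offs = np.arange(-reach, reach + 1)
        OX, OY, OZ = np.meshgrid(offs, offs, offs, indexing="ij")
        offsets = np.stack([OX.ravel(), OY.ravel(), OZ.ravel()], axis=1)
        for idx, node in enumerate(centres):
            tgt = self.coords[node] + offsets
            ok = (np.abs(tgt) <= r).all(axis=1)
            flat = ((tgt[ok] + r) * strides).sum(axis=1)
            flat = flat[self.in_sphere[flat]]
            target_map[flat] = idx

    def place_fdc_network(self, n_sites: int, rng: np.random.Generator, reach: int = 2) -> np.ndarray:
        """Choose ``n_sites`` distinct LZ nodes as FDC antigen sites and stamp
        their contact neighbourhoods into ``fdc_map``. Returns the site nodes."""
        lz = self.zone_nodes(LZ)
        if n_sites > len(lz):
            raise ValueError("more FDC sites than light-zone nodes")
        self.fdc_nodes = np.sort(rng.choice(lz, size=n_sites, replace=False))
        self.fdc_map[:] = -1
        self._stamp(self.fdc_map, self.fdc_nodes, reach)
        return self.fdc_nodes

    def place_tfh(self, n_tfh: int, rng: np.random.Generator, reach: int = 2) -> np.ndarray:
        """Immobile Tfh in the LZ; contact neighbourhoods go into ``tfh_map``."""
        lz = self.zone_nodes(LZ)
        if n_tfh > len(lz):
            raise ValueError("more Tfh than light-zone nodes")
        self.tfh_nodes = np.sort(rng.choice(lz, size=n_tfh, replace=False))
        self.tfh_map[:] = -1
        self._stamp(self.tfh_map, self.tfh_nodes, reach)
        return self.tfh_nodes


def resolve_moves(
    occupancy: np.ndarray,
    movers: np.ndarray,
    targets: np.ndarray,
    rng: np.random.Generator,
    scratch: np.ndarray | None = None,
) -> np.ndarray:
    """Exclusion-respecting parallel move resolution.

    ``movers`` are agent indices proposing in-sphere ``targets``.  A move is
    granted iff the target node is currently empty and exactly one randomly
    chosen claimant per contested node wins.  Returns a boolean mask over
    ``movers``.  Swaps and chains are not granted (a vacated node only frees
    on the next step), which keeps the update order-free and exclusion exact.

    ``scratch`` is an optional reusable int array of node length (left reset
    to -1) that avoids an O(n log n) sort on the contested targets.
    """
    granted = np.zeros(len(movers), dtype=bool)
    if len(movers) == 0:
        return granted
    free = occupancy[targets] == -1
    cand = np.flatnonzero(free)
    if len(cand) == 0:
        return granted
    # randomise write order, then last-write-wins picks a uniform claimant
    cand = cand[rng.permutation(len(cand))]
    tgt = targets[cand]
    if scratch is None:
        scratch = np.full(occupancy.shape, -1, dtype=np.int64)
    scratch[tgt] = cand
    granted[cand[scratch[tgt] == cand]] = True
    scratch[tgt] = -1
    return granted
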