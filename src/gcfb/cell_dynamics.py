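"""B-cell agent life cycle: states, division, selection, output.

Agents are stored struct-of-arrays in :class:`Population` for speed; the
simulation loop (``gcfb.engine``) drives the transitions

    centroblast --divide x n--> centrocyte --collect + Tfh help--> selected
    selected --p_recycle--> centroblast (2 more divisions)
    selected --else--> output cell --> exits at the GC border
    exited output --rate ln2/24 /h--> plasma cell (binned antibody producer)

Centrocytes that fail to be selected within the collection period apoptose.
Tfh help is polarised: among the centrocytes in contact with one Tfh, only
the cell that collected the most antigen accrues signal (ties random); cells
that collected nothing present no pMHC and never accrue signal.
"""

from __future__ import annotations

import numpy as np

from .shape_space import affinity_to_bin

# agent states
CB, CC, OUTPUT = 0, 1, 2
STATE_NAMES = {CB: "centroblast", CC: "centrocyte", OUTPUT: "output"}


def collection_success_probability(
    affinity, g_free, g_initial: float
):
    """P(successful antigen capture) = affinity * (free / initial antigen).

    Binding requires both a fitting BCR and antigen that is neither masked by
    antibody nor already consumed; the product is capped to [0, 1].
    """
    p = np.asarray(affinity, dtype=float) * (np.asarray(g_free, dtype=float) / g_initial)
    return np.clip(p, 0.0, 1.0)


def polarized_winners(
    tfh_ids: np.ndarray,
    collected: np.ndarray,
    rng: np.random.Generator,
    min_collected: int = 1,
) -> np.ndarray:
    """Indices (into the input arrays) of the max-collector per Tfh group.

    One winner per distinct Tfh id; ties broken uniformly at random.  Cells
    below ``min_collected`` captured portions present too little pMHC to
    attract help and never win.
    """
    tfh_ids = np.asarray(tfh_ids)
    collected = np.asarray(collected)
    ok = np.flatnonzero(collected >= max(min_collected, 1))
    if len(ok) == 0:
        return ok
    # integer collected + uniform(0,1) jitter: the scatter-max per Tfh picks
    # the max collector, with ties broken uniformly at random
    key = collected[ok].astype(float) + rng.random(len(ok))
    ids = tfh_ids[ok]
    best = np.full(int(ids.max()) + 1, -np.inf)
    np.maximum.at(best, ids, key)
    return ok[key == best[ids]]


class Population:
    """Struct-of-arrays store for all B-cell agents ever created.

    Dead and exited agents stay in the arrays with ``active=False``; the
    engine keeps an index of live agents.  Conservation counters make the
    bookkeeping invariant checkable at every sample:
    founders + division_births == active + apoptosed + exited.
    """

    def __init__(self, shape_dim: int, capacity: int = 4096):
        self.capacity = capacity
        self.size = 0
        self.state = np.zeros(capacity, dtype=np.int8)
        self.node = np.full(capacity, -1, dtype=np.int64)
        self.direction = np.zeros(capacity, dtype=np.int8)
        self.shape = np.zeros((capacity, shape_dim), dtype=np.int64)
        self.affinity = np.zeros(capacity)
        self.div_left = np.zeros(capacity, dtype=np.int16)
        self.collected = np.zeros(capacity, dtype=np.int32)
        self.tfh_signal_h = np.zeros(capacity)
        self.cc_deadline_h = np.zeros(capacity)
        self.next_attempt_h = np.zeros(capacity)
        self.active = np.zeros(capacity, dtype=bool)
        # conservation counters
        self.n_founders = 0
        self.n_division_births = 0
        self.n_apoptosed = 0
        self.n_exited = 0

    def _ensure(self, extra: int) -> None:
        need = self.size + extra
        if need <= self.capacity:
            return
        new_cap = self.capacity
        while new_cap < need:
            new_cap *= 2

        def grow(a):
            out = np.zeros((new_cap,) + a.shape[1:], dtype=a.dtype)
            out[: self.size] = a[: self.size]
            return out

        self.state = grow(self.state)
        self.node = grow(self.node)
        self.direction = grow(self.direction)
        self.shape = grow(self.shape)
        self.affinity = grow(self.affinity)
        self.div_left = grow(self.div_left)
        self.collected = grow(self.collected)
        self.tfh_signal_h = grow(self.tfh_signal_h)
        self.cc_deadline_h = grow(self.cc_deadline_h)
        self.next_attempt_h = grow(self.next_attempt_h)
        self.active = grow(self.active)
        self.capacity = new_cap

    def add(
        self,
        nodes: np.ndarray,
        shapes: np.ndarray,
        affinities: np.ndarray,
        div_left: int,
        directions: np.ndarray,
    ) -> np.ndarray:
        """Append centroblasts; returns their agent indices."""
        n = len(nodes)
        self._ensure(n)
        idx = np.arange(self.size, self.size + n)
        self.size += n
        self.state[idx] = CB
        self.node[idx] = nodes
        self.direction[idx] = directions
        self.shape[idx] = shapes
        self.affinity[idx] = affinities
        self.div_left[idx] = div_left
        self.collected[idx] = 0
        self.tfh_signal_h[idx] = 0.0
        self.active[idx] = True
        return idx

    def alive_count(self) -> int:
        return int(self.active[: self.size].sum())

    def conservation_ok(self) -> bool:
        created = self.n_founders + self.n_division_births
        gone = self.n_apoptosed + self.n_exited
        return created == self.alive_count() + gone


class OutputPool:
    """Exited output cells waiting to differentiate, plus the plasma tally.

    Plasma cells are cumulative (no death within the simulated window; the
    antibody pool's decay term handles turnover).  ``n_p[i]`` counts plasma
    cells whose affinity maps to antibody bin i.
    """

    def __init__(self, n_bins: int, diff_rate_per_h: float, binned_affinity: bool = False):
        self.n_bins = n_bins
        self.rate = diff_rate_per_h
        self.binned_affinity = binned_affinity
        self.exited_affinities = np.empty(0)
        self.n_p = np.zeros(n_bins, dtype=np.int64)
        self.plasma_affinity_sum = 0.0
        self.total_exited = 0

    @property
    def plasma_total(self) -> int:
        return int(self.n_p.sum())

    def add_exited(self, affinities: np.ndarray) -> None:
        affinities = np.atleast_1d(np.asarray(affinities, dtype=float))
        self.exited_affinities = np.concatenate([self.exited_affinities, affinities])
        self.total_exited += len(affinities)

    def differentiate(self, dt: float, rng: np.random.Generator) -> int:
        """Each exited cell turns into a plasma cell with the exponential
        per-step probability 1 - exp(-rate*dt).  Returns how many did."""
        if dt < 0:
            raise ValueError("dt must be non-negative")
        n = len(self.exited_affinities)
        if n == 0 or dt == 0:
            return 0
        p = 1.0 - np.exp(-self.rate * dt)
        hit = rng.random(n) < p
        if hit.any():
            aff = self.exited_affinities[hit]
            bins = np.atleast_1d(affinity_to_bin(aff, self.n_bins))
            np.add.at(self.n_p, bins, 1)
            if self.binned_affinity:
                self.plasma_affinity_sum += float(np.sum(bins / (self.n_bins - 1)))
            else:
                self.plasma_affinity_sum += float(aff.sum())
            self.exited_affinities = self.exited_affinities[~hit]
        return int(hit.sum())

    def mean_affinity(self) -> float | None:
        if self.plasma_total == 0:
            return None
        return self.plasma_affinity_sum / self.plasma_total
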