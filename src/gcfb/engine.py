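"""The hybrid simulation loop.

Motion, contacts and cell-fate decisions advance on a fine clock
(``dt_motion_h``); the antibody pool, immune-complex chemistry and plasma
differentiation on a coarser chemistry clock (``dt_chemistry_h``); readouts
are sampled hourly.  One :class:`Simulation` owns the lattice, the agent
population, the antibody pool and the FDC sites, and is fully deterministic
given (config, seed).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import cell_dynamics as cd
from .antibody_feedback import AntibodyPool, EarlyAntibodyProfile, FDCSites
from .cell_dynamics import CB, CC, OUTPUT, OutputPool, Population
from .config import GCConfig
from .gc_lattice import DZ, LZ, Lattice, LatticeConfig, resolve_moves
from .readouts import GCTimeSeries, ic_fraction, immune_power
from .shape_space import ShapeSpace, dissociation_constants

logger = logging.getLogger(__name__)

# direction indices into gc_lattice.DIRECTIONS
_PLUS_Z, _MINUS_Z = 4, 5


class InvariantViolation(RuntimeError):
    pass


class Simulation:
    def __init__(
        self,
        cfg: GCConfig,
        seed: int,
        early_profile: EarlyAntibodyProfile | None = None,
        record_transitions: bool = False,
    ):
        self.cfg = cfg
        self.seed = int(seed)
        self.rng = np.random.default_rng(self.seed)
        self.space = ShapeSpace(
            dim=cfg.shape_dim,
            extent=cfg.shape_extent,
            width=cfg.affinity_width,
            optimal=cfg.optimal_clone,
        )
        self.lattice = Lattice(
            LatticeConfig(cfg.lattice_constant_um, cfg.gc_radius_um)
        )
        self.lattice.place_fdc_network(cfg.n_fdc_sites, self.rng, reach=cfg.fdc_contact_range)
        self.lattice.place_tfh(cfg.n_tfh, self.rng, reach=cfg.tfh_contact_range)
        self.occupancy = np.full(self.lattice.n_nodes, -1, dtype=np.int64)
        self._move_scratch = np.full(self.lattice.n_nodes, -1, dtype=np.int64)
        self.dz_nodes = self.lattice.zone_nodes(DZ)

        self.kd = dissociation_constants(cfg.n_bins, cfg.kd_top_log10, cfg.kd_step_log10)
        self.pool = AntibodyPool(cfg.n_bins, cfg.k1_molar_per_h, cfg.k2_per_h)
        self.sites = FDCSites(cfg.n_fdc_sites, cfg.g_initial_molar, self.kd, cfg.kon_per_molar_h)
        self.pop = Population(cfg.shape_dim)
        self.out = OutputPool(
            cfg.n_bins, cfg.plasma_diff_rate_per_h, binned_affinity=cfg.mean_affinity_binned
        )
        self.early_profile = early_profile
        self.alive = np.empty(0, dtype=np.int64)
        self.t = 0.0
        self.samples: list[dict] = []
        self.record_transitions = record_transitions
        self.transitions: set[str] = set()

        # clock ratios
        self.chem_every = max(1, round(cfg.dt_chemistry_h / cfg.dt_motion_h))
        self.sample_every = max(1, round(cfg.sample_dt_h / cfg.dt_motion_h))
        self._influx_backlog = 0

    # ------------------------------------------------------------------
    def _mark(self, name: str) -> None:
        if self.record_transitions:
            self.transitions.add(name)

    # -- founder influx -------------------------------------------------
    def influx_founders(self, dt: float) -> int:
        cfg = self.cfg
        if dt <= 0 or self.t >= cfg.founder_influx_stop_h:
            return 0
        n_new = int(self.rng.poisson(cfg.founder_rate_per_h * dt)) + self._influx_backlog
        self._influx_backlog = 0
        if n_new == 0:
            return 0
        # uniform free DZ nodes; entries that find no room are deferred
        placed_nodes = []
        cand = self.rng.choice(self.dz_nodes, size=4 * n_new + 8, replace=False)
        free = cand[self.occupancy[cand] == -1]
        placed = min(len(free), n_new)
        if placed < n_new:
            self._influx_backlog = n_new - placed
            logger.warning(
                "t=%.2f h: no free dark-zone node for %d founder(s); deferred",
                self.t,
                n_new - placed,
            )
        if placed == 0:
            return 0
        nodes = free[:placed]
        shapes = self.space.sample_founders(
            placed, self.rng, cfg.founder_distance_min, cfg.founder_distance_max
        )
        affs = self.space.affinity(shapes)
        dirs = self.rng.integers(0, 6, size=placed)
        idx = self.pop.add(nodes, shapes, np.atleast_1d(affs), cfg.founder_divisions, dirs)
        self.occupancy[nodes] = idx
        self.pop.n_founders += placed
        self.alive = np.concatenate([self.alive, idx])
        self._mark("founder_influx")
        return placed

    # -- motion ----------------------------------------------------------
    def _repolarize(self, idx: np.ndarray) -> None:
        """Persistent walk: a fraction dt/persistence re-picks a direction,
        zone-biased when the cell is outside its home zone."""
        cfg = self.cfg
        n = len(idx)
        if n == 0:
            return
        redo = self.rng.random(n) < cfg.dt_motion_h / cfg.persistence_time_h
        ridx = idx[redo]
        if len(ridx) == 0:
            return
        new_dir = self.rng.integers(0, 6, size=len(ridx)).astype(np.int8)
        biased = self.rng.random(len(ridx)) < cfg.zone_bias
        state = self.pop.state[ridx]
        zone = self.lattice.zone[self.pop.node[ridx]]
        # centroblasts head for the DZ, centrocytes for the LZ, output cells
        # for the border
        want_dz = biased & (state == CB) & (zone == LZ)
        want_lz = biased & (state == CC) & (zone == DZ)
        want_out = biased & (state == OUTPUT)
        new_dir[want_dz] = _MINUS_Z
        new_dir[want_lz] = _PLUS_Z
        new_dir[want_out] = self.lattice.outward_dir[self.pop.node[ridx[want_out]]]
        self.pop.direction[ridx] = new_dir

    def move_agents(self) -> None:
        cfg = self.cfg
        idx = self.alive
        if len(idx) == 0:
            return
        self._repolarize(idx)
        p = cfg.move_probability
        movers = idx if p >= 1.0 else idx[self.rng.random(len(idx)) < p]
        if len(movers) == 0:
            return
        targets = self.lattice.nbr.ravel()[
            self.pop.node[movers] * 6 + self.pop.direction[movers]
        ]
        leaving = targets < 0
        if leaving.any():
            # output cells stepping over the border exit toward the T zone
            exit_mask = leaving & (self.pop.state[movers] == OUTPUT)
            if exit_mask.any():
                self._exit_cells(movers[exit_mask])
            movers, targets = movers[~leaving], targets[~leaving]
        granted = resolve_moves(
            self.occupancy, movers, targets, self.rng, scratch=self._move_scratch
        )
        moved, dest = movers[granted], targets[granted]
        self.occupancy[self.pop.node[moved]] = -1
        self.occupancy[dest] = moved
        self.pop.node[moved] = dest

    def _exit_cells(self, idx: np.ndarray) -> None:
        self.occupancy[self.pop.node[idx]] = -1
        self.pop.active[idx] = False
        self.pop.n_exited += len(idx)
        self.out.add_exited(self.pop.affinity[idx])
        self.alive = self.alive[self.pop.active[self.alive]]
        self._mark("output_exit")

    # -- centrocyte antigen collection -----------------------------------
    def collect_antigen(self, cc: np.ndarray | None = None) -> None:
        cfg = self.cfg
        if cc is None:
            idx = self.alive
            cc = idx[self.pop.state[idx] == CC]
        if len(cc) == 0:
            return
        ready = cc[self.pop.next_attempt_h[cc] <= self.t]
        if len(ready) == 0:
            return
        site = self.lattice.fdc_map[self.pop.node[ready]]
        ready, site = ready[site >= 0], site[site >= 0]
        if len(ready) == 0:
            return
        p = cd.collection_success_probability(
            self.pop.affinity[ready], self.sites.G_free[site], self.sites.g_initial
        )
        self.pop.next_attempt_h[ready] = self.t + cfg.collection_refractory_h
        hit = self.rng.random(len(ready)) < p
        if hit.any():
            self.pop.collected[ready[hit]] += 1
            self.sites.consume_portion(site[hit], cfg.portion_molar)
            self._mark("antigen_collected")

    # -- Tfh help and selection ------------------------------------------
    def tfh_select(self, cc: np.ndarray | None = None) -> None:
        cfg = self.cfg
        if cc is None:
            idx = self.alive
            cc = idx[self.pop.state[idx] == CC]
        if len(cc) == 0:
            return
        tfh = self.lattice.tfh_map[self.pop.node[cc]]
        contact = tfh >= 0
        cc, tfh = cc[contact], tfh[contact]
        if len(cc) == 0:
            return
        win = cd.polarized_winners(
            tfh, self.pop.collected[cc], self.rng, cfg.min_collected_portions
        )
        if len(win) == 0:
            return
        winners = cc[win]
        self.pop.tfh_signal_h[winners] += cfg.dt_motion_h
        self._mark("tfh_signal")
        sel = winners[self.pop.tfh_signal_h[winners] >= cfg.tfh_selection_threshold_h]
        if len(sel):
            self.route_selected(sel)

    def route_selected(self, sel: np.ndarray) -> None:
        """Selected centrocytes either recycle to the dark zone for further
        division or become output cells heading for the border."""
        cfg = self.cfg
        recycle = self.rng.random(len(sel)) < cfg.p_recycle
        rec, out = sel[recycle], sel[~recycle]
        if len(rec):
            self.pop.state[rec] = CB
            self.pop.div_left[rec] = cfg.recycle_divisions
            self.pop.collected[rec] = 0
            self.pop.tfh_signal_h[rec] = 0.0
            self._mark("recycled")
        if len(out):
            self.pop.state[out] = OUTPUT
            self._mark("output_created")

    # -- apoptosis --------------------------------------------------------
    def apoptose_unsuccessful(self, cc: np.ndarray | None = None) -> None:
        if cc is None:
            idx = self.alive
            cc = idx[self.pop.state[idx] == CC]
        else:
            # cells routed out of the centrocyte state this step are exempt
            cc = cc[self.pop.state[cc] == CC]
        dead = cc[self.pop.cc_deadline_h[cc] <= self.t]
        if len(dead) == 0:
            return
        self.occupancy[self.pop.node[dead]] = -1
        self.pop.active[dead] = False
        self.pop.n_apoptosed += len(dead)
        self.alive = self.alive[self.pop.active[self.alive]]
        self._mark("apoptosis")

    # -- division ---------------------------------------------------------
    def divide_centroblasts(self, cb: np.ndarray | None = None) -> None:
        cfg = self.cfg
        if cb is None:
            idx = self.alive
            cb = idx[self.pop.state[idx] == CB]
        cb = cb[self.pop.div_left[cb] > 0]
        if len(cb) == 0:
            return
        firing = cb[self.rng.random(len(cb)) < cfg.dt_motion_h / cfg.cycle_time_h]
        if len(firing) == 0:
            return
        # one random free neighbour per divider; dividers without a free node
        # (and collision losers) defer to a later firing
        nbrs = self.lattice.nbr[self.pop.node[firing]]
        free = (nbrs >= 0) & (self.occupancy[np.maximum(nbrs, 0)] == -1)
        has = free.any(axis=1)
        firing, nbrs, free = firing[has], nbrs[has], free[has]
        if len(firing) == 0:
            return
        pick = np.argmax(self.rng.random(nbrs.shape) * free, axis=1)
        new_nodes = nbrs[np.arange(len(firing)), pick]
        order = self.rng.permutation(len(firing))
        s = self._move_scratch
        s[new_nodes[order]] = order
        win = s[new_nodes] == np.arange(len(firing))
        s[new_nodes] = -1
        parents, new_nodes = firing[win], new_nodes[win]
        if len(parents) == 0:
            return
        d = self.pop.div_left[parents] - 1
        self.pop.div_left[parents] = d
        daughters = self.pop.add(
            new_nodes,
            self.pop.shape[parents],
            self.pop.affinity[parents],
            0,
            self.rng.integers(0, 6, size=len(parents)),
        )
        self.pop.div_left[daughters] = d
        self.occupancy[new_nodes] = daughters
        self.pop.n_division_births += len(daughters)
        self.alive = np.concatenate([self.alive, daughters])
        self._mark("division")

        # somatic hypermutation: each daughter cell independently, only from
        # day `mutation_onset_h` of the reaction onward
        both = np.concatenate([parents, daughters])
        if self.t >= cfg.mutation_onset_h and cfg.mutation_probability > 0:
            mut = both[self.rng.random(len(both)) < cfg.mutation_probability]
            if len(mut):
                self.pop.shape[mut] = self.space.mutate_many(self.pop.shape[mut], self.rng)
                self.pop.affinity[mut] = self.space.affinity(self.pop.shape[mut])
                self._mark("mutation")

        # cells out of division budget differentiate to centrocytes
        done = both[self.pop.div_left[both] == 0]
        if len(done):
            self.pop.state[done] = CC
            self.pop.cc_deadline_h[done] = self.t + cfg.collection_period_h
            self.pop.next_attempt_h[done] = self.t
            self.pop.collected[done] = 0
            self.pop.tfh_signal_h[done] = 0.0
            self._mark("cb_to_cc")

    # -- chemistry --------------------------------------------------------
    def step_chemistry(self, dt: float) -> None:
        cfg = self.cfg
        self.pool.step(self.out.n_p, dt)
        a_early = (
            self.early_profile.evaluate(self.t)
            if self.early_profile is not None
            else np.zeros(cfg.n_bins)
        )
        a_eff = cfg.feedback_scale * self.pool.A + a_early
        self.sites.step_immune_complex(a_eff, dt, self.rng, cfg.chemistry_substeps)
        if self.out.differentiate(dt, self.rng):
            self._mark("plasma_differentiation")

    # -- sampling ---------------------------------------------------------
    def sample(self) -> None:
        idx = self.alive
        state = self.pop.state[idx]
        n_cb = int((state == CB).sum())
        n_cc = int((state == CC).sum())
        if not self.pop.conservation_ok():
            raise InvariantViolation(
                f"cell bookkeeping broken at t={self.t}: "
                f"{self.pop.n_founders}+{self.pop.n_division_births} != "
                f"{self.pop.alive_count()}+{self.pop.n_apoptosed}+{self.pop.n_exited}"
            )
        if self.sites.mass_error() > 1e-10:
            raise InvariantViolation(f"antigen mass conservation broken at t={self.t}")
        mean_aff = self.out.mean_affinity()
        rec = {
            "time_h": self.t,
            "gc_volume": n_cb + n_cc,
            "n_centroblasts": n_cb,
            "n_centrocytes": n_cc,
            "plasma_total": self.out.plasma_total,
            "plasma_mean_affinity": np.nan if mean_aff is None else mean_aff,
            "ic_fraction": ic_fraction(self.sites.G_free, self.sites.C),
            "free_antigen_total_molar": float(self.sites.G_free.sum()),
            "free_antigen_mean_molar": float(self.sites.G_free.mean()),
            "immune_power": immune_power(self.pool.A, self.kd, self.cfg.ip_antigen_molar),
        }
        for i in range(self.cfg.n_bins):
            rec[f"A_bin_{i}"] = self.pool.A[i]
        self.samples.append(rec)

    # -- main loop --------------------------------------------------------
    def step(self) -> None:
        dt = self.cfg.dt_motion_h
        self.influx_founders(dt)
        self.move_agents()
        idx = self.alive
        st = self.pop.state[idx]
        cc = idx[st == CC]
        self.collect_antigen(cc)
        self.tfh_select(cc)
        self.apoptose_unsuccessful(cc)
        self.divide_centroblasts(idx[st == CB])
        self.t += dt

    def run(self) -> GCTimeSeries:
        cfg = self.cfg
        n_steps = round(cfg.t_end_h / cfg.dt_motion_h)
        self.sample()  # t = 0
        for k in range(1, n_steps + 1):
            self.step()
            if k % self.chem_every == 0:
                self.step_chemistry(cfg.dt_chemistry_h)
            if k % self.sample_every == 0:
                self.t = round(self.t / cfg.dt_motion_h) * cfg.dt_motion_h
                self.sample()
        df = pd.DataFrame(self.samples)
        return GCTimeSeries(df, seed=self.seed, config_digest=cfg.digest())
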