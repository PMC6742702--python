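"""Small deterministic testbeds: mini configuration, frozen chemistry, pools.

Everything here is code-generated at call time; nothing is read from disk.
The mini configuration shrinks only geometry, cell numbers and horizon — all
rate constants equal the full defaults, so unit behaviour transfers.
"""

from __future__ import annotations

import numpy as np

from .antibody_feedback import FDCSites
from .cell_dynamics import OutputPool
from .config import GCConfig
from .shape_space import dissociation_constants

__all__ = ["mini_config", "frozen_chemistry_testbed", "synthetic_exited_pool"]


def mini_config(**overrides) -> GCConfig:
    """A 40 um GC with 10 FDC sites, 20 Tfh and a 3-day horizon."""
    base = dict(
        gc_radius_um=40.0,
        n_fdc_sites=10,
        n_tfh=20,
        t_end_h=72.0,
    )
    base.update(overrides)
    return GCConfig(**base)


def frozen_chemistry_testbed(
    n_sites: int,
    a_eff: np.ndarray,
    duration_h: float,
    cfg: GCConfig | None = None,
    seed: int = 0,
    record_every_h: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, FDCSites]:
    """Run only the immune-complex chemistry under constant A_eff.

    Returns ``(times_h, G_free_traj, C_traj, sites)`` with trajectories of
    shape (T, n_sites) and (T, n_sites, n_bins) — a clean target for dense
    ODE-oracle comparison.
    """
    cfg = cfg or GCConfig()
    rng = np.random.default_rng(seed)
    kd = dissociation_constants(cfg.n_bins, cfg.kd_top_log10, cfg.kd_step_log10)
    sites = FDCSites(n_sites, cfg.g_initial_molar, kd, cfg.kon_per_molar_h)
    a_eff = np.asarray(a_eff, dtype=float)
    n_rec = int(round(duration_h / record_every_h))
    steps_per_rec = max(1, int(round(record_every_h / cfg.dt_chemistry_h)))
    times = [0.0]
    g_traj = [sites.G_free.copy()]
    c_traj = [sites.C.copy()]
    t = 0.0
    for _ in range(n_rec):
        for _ in range(steps_per_rec):
            sites.step_immune_complex(a_eff, cfg.dt_chemistry_h, rng, cfg.chemistry_substeps)
            t += cfg.dt_chemistry_h
        times.append(t)
        g_traj.append(sites.G_free.copy())
        c_traj.append(sites.C.copy())
    return np.array(times), np.array(g_traj), np.array(c_traj), sites


def synthetic_exited_pool(
    n_cells: int,
    affinities,
    cfg: GCConfig | None = None,
) -> OutputPool:
    """An output pool preloaded with exited cells of given affinities,
    for exercising plasma differentiation and mean-affinity readouts."""
    cfg = cfg or GCConfig()
    affinities = np.broadcast_to(np.asarray(affinities, dtype=float), (n_cells,))
    if np.any(affinities < 0) or np.any(affinities > 1):
        raise ValueError("affinities must lie in [0, 1]")
    pool = OutputPool(cfg.n_bins, cfg.plasma_diff_rate_per_h, cfg.mean_affinity_binned)
    if n_cells:
        pool.add_exited(affinities.copy())
    return pool
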