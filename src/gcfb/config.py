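"""Simulation configuration.

Every tunable of the model lives in :class:`GCConfig`, a flat dataclass that
can round-trip through YAML.  Units are encoded in the field names: lengths in
micrometres, times in hours, concentrations in molar.  Rate constants quoted
per second in the literature (``k_on``) are converted to per-hour on access.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import yaml

LN2 = math.log(2.0)


@dataclass
class GCConfig:
    # --- shape space / affinity -------------------------------------------
    shape_dim: int = 4
    shape_extent: int = 10              # coordinates in [0, shape_extent-1]
    affinity_width: float = 2.8         # Gaussian width of a = exp(-d^2/w^2)
    optimal_clone: Sequence[int] = (5, 5, 5, 5)
    founder_distance_min: int = 5       # Manhattan distance of founders from
    founder_distance_max: int = 10      # the optimal clone (low affinity)

    # --- antibody affinity bins -------------------------------------------
    n_bins: int = 11
    kd_top_log10: float = -5.5          # K(i) = 10^(kd_top - kd_step*i) M
    kd_step_log10: float = 0.4

    # --- lattice geometry --------------------------------------------------
    lattice_constant_um: float = 5.0
    gc_radius_um: float = 160.0
    n_fdc_sites: int = 200
    n_tfh: int = 250
    fdc_contact_range: int = 2          # Chebyshev radius of an FDC site's
                                        # dendritic reach, in lattice units
    tfh_contact_range: int = 2

    # --- motility ----------------------------------------------------------
    cell_speed_um_per_min: float = 7.5
    persistence_time_h: float = 0.025   # ~1.5 min between repolarisations
    zone_bias: float = 0.5              # prob. of zone-ward direction on
                                        # repolarisation (else uniform)

    # --- clocks ------------------------------------------------------------
    # one lattice constant per step at the default speed (5 um / 450 um/h)
    dt_motion_h: float = 1.0 / 90.0
    dt_chemistry_h: float = 0.1
    chemistry_substeps: int = 10
    sample_dt_h: float = 1.0
    t_end_h: float = 504.0              # 21 days

    # --- cell dynamics -----------------------------------------------------
    founder_rate_per_h: float = 2.0
    founder_influx_stop_h: float = 96.0
    founder_divisions: int = 6
    mutation_probability: float = 0.5
    mutation_onset_h: float = 24.0
    cycle_time_h: float = 6.0           # mean centroblast division interval
    collection_period_h: float = 10.0   # centrocyte lifetime for antigen search
    collection_refractory_h: float = 0.5
    tfh_selection_threshold_h: float = 0.75
    min_collected_portions: int = 2     # pMHC density needed to attract help
    p_recycle: float = 0.8
    recycle_divisions: int = 2
    plasma_diff_halflife_h: float = 24.0

    # --- antibody pool & immune complexes ---------------------------------
    k1_molar_per_h: float = 1e-15       # 1e-17 mol/h per plasma cell / 10 ml
    antibody_halflife_h: float = 720.0  # 30 days
    kon_per_molar_s: float = 1e6
    feedback_scale: float = 1.0         # N in the immune-complex equation
    g_initial_molar: float = 3e-5       # free antigen per FDC site
    portion_molar: float = 1e-8         # antigen removed per B-cell uptake

    # --- readouts ----------------------------------------------------------
    ip_antigen_molar: float = 1e-6      # reference G for immune power
    mean_affinity_binned: bool = False  # bin-midpoint instead of continuous

    # ----------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.optimal_clone = tuple(int(c) for c in self.optimal_clone)
        if len(self.optimal_clone) != self.shape_dim:
            raise ValueError("optimal_clone must have shape_dim coordinates")
        if self.gc_radius_um < self.lattice_constant_um:
            raise ValueError("GC radius must be at least one lattice constant")
        if not 0 < self.n_bins:
            raise ValueError("n_bins must be positive")

    # Derived rates -------------------------------------------------------
    @property
    def k2_per_h(self) -> float:
        return LN2 / self.antibody_halflife_h

    @property
    def kon_per_molar_h(self) -> float:
        return self.kon_per_molar_s * 3600.0

    @property
    def plasma_diff_rate_per_h(self) -> float:
        return LN2 / self.plasma_diff_halflife_h

    @property
    def move_probability(self) -> float:
        """Per-step probability of attempting a one-node move."""
        p = self.cell_speed_um_per_min * 60.0 * self.dt_motion_h / self.lattice_constant_um
        if p > 1.0 + 1e-9:
            raise ValueError("dt_motion_h too large: >1 node per motion step")
        return min(p, 1.0)

    # Serialisation -------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kwargs) -> "GCConfig":
        return dataclasses.replace(self, **kwargs)

    def to_yaml(self, path: str | Path) -> None:
        d = self.to_dict()
        d["optimal_clone"] = list(d["optimal_clone"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GCConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def digest(self) -> str:
        """Stable hash of the full configuration, for run metadata."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
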