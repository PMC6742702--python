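"""Soluble-antibody pool, immune-complex chemistry, and antigen accounting.

The GC's output antibodies live in a well-mixed pool of ``n_bins`` affinity
bins.  Each bin obeys the linear balance

    dA(i)/dt = k1 * n_p(i) - k2 * A(i)

with k1 the per-plasma-cell secretion rate expressed as a concentration
(1e-17 mol/h diluted over 10 ml -> 1e-15 M/h per cell) and k2 the decay rate
of a 30-day antibody half-life.  On every FDC antigen site the effective
antibody A_eff(i) = N*A(i) + A_early(i) reversibly binds free antigen:

    dC(i)/dt = k_on * G_free * A_eff(i) - k_off(i) * C(i)
    dG_free/dt = -sum_i [ k_on * G_free * A_eff(i) - k_off(i) * C(i) ]

with a shared k_on and k_off(i) = k_on * K(i).  Antibody depletion by complex
formation is neglected, so A_eff is an external forcing of the site chemistry.
Complexed antigen is masked: B cells can only consume from G_free, in fixed
portions, and consumed antigen never returns.

Stiffness: k_off(0) ~ 1.1e4 /h far exceeds the chemistry clock, so each
(G_free, C(i)) pair is relaxed analytically toward its conditional equilibrium
(the pair update is an exact linear solve given the other bins frozen), swept
over bins in randomised order with sub-stepping to keep the splitting error
small.  Each pair update conserves G_free + C(i) exactly, so per-site antigen
mass G_free + sum_i C(i) + G_consumed is conserved to rounding error.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AntibodyPool",
    "FDCSites",
    "EarlyAntibodyProfile",
    "IntegratorFailure",
]


class IntegratorFailure(RuntimeError):
    """A chemistry step produced a negative concentration."""


class AntibodyPool:
    """Well-mixed soluble antibody concentrations A(i), one per affinity bin."""

    def __init__(self, n_bins: int, k1: float, k2: float):
        if k2 <= 0:
            raise ValueError("k2 must be positive")
        self.k1 = float(k1)
        self.k2 = float(k2)
        self.A = np.zeros(n_bins)

    def step(self, n_p: np.ndarray, dt: float) -> None:
        """Exact update over dt with the plasma-cell counts n_p held fixed:
        A <- A e^{-k2 dt} + (k1 n_p / k2)(1 - e^{-k2 dt})."""
        n_p = np.asarray(n_p, dtype=float)
        if np.any(n_p < 0):
            raise ValueError("plasma-cell counts must be non-negative")
        if dt < 0:
            raise ValueError("dt must be non-negative")
        decay = np.exp(-self.k2 * dt)
        self.A = self.A * decay + (self.k1 / self.k2) * n_p * (1.0 - decay)

    # convenience for tests / readouts
    def steady_state(self, n_p: np.ndarray) -> np.ndarray:
        return self.k1 * np.asarray(n_p, dtype=float) / self.k2


# keep the name the domain uses for a single site while the implementation is
# a struct-of-arrays over all sites
class FDCSites:
    """All FDC antigen sites of one GC (vectorised over sites).

    Per site: free antigen ``G_free`` (M), immune complex ``C[site, bin]``
    (M), cumulative consumed antigen ``G_consumed`` (M).  The invariant
    G_free + C.sum() + G_consumed == G_initial holds per site.
    """

    def __init__(
        self,
        n_sites: int,
        g_initial: float,
        kd: np.ndarray,
        kon_per_h: float,
    ):
        self.n_sites = int(n_sites)
        self.g_initial = float(g_initial)
        self.kd = np.asarray(kd, dtype=float)
        self.kon = float(kon_per_h)
        self.koff = self.kon * self.kd  # per hour, per bin
        self.G_free = np.full(n_sites, g_initial, dtype=float)
        self.C = np.zeros((n_sites, len(self.kd)))
        self.G_consumed = np.zeros(n_sites)

    # ------------------------------------------------------------------
    def step_immune_complex(
        self,
        a_eff: np.ndarray,
        dt: float,
        rng: np.random.Generator,
        substeps: int = 10,
    ) -> None:
        """Advance the site chemistry by ``dt`` under constant A_eff per bin.

        Sequential analytic relaxation: for one bin with the others frozen,
        M = G_free + C(i) is conserved and C(i) relaxes exponentially with
        rate lam = k_on*A_eff(i) + k_off(i) toward M * A_eff/(A_eff + K(i)).
        """
        if dt < 0:
            raise ValueError("dt must be non-negative")
        a_eff = np.asarray(a_eff, dtype=float)
        if a_eff.shape != self.kd.shape:
            raise ValueError("a_eff must have one entry per affinity bin")
        if dt == 0 or self.n_sites == 0:
            return
        dt_sub = dt / substeps
        active = np.flatnonzero((a_eff > 0) | (self.C.max(axis=0) > 0))
        if len(active) == 0:
            return
        for _ in range(substeps):
            for i in rng.permutation(active):
                lam = self.kon * a_eff[i] + self.koff[i]
                M = self.G_free + self.C[:, i]
                c_eq = M * (a_eff[i] / (a_eff[i] + self.kd[i]))
                self.C[:, i] = c_eq + (self.C[:, i] - c_eq) * np.exp(-lam * dt_sub)
                self.G_free = M - self.C[:, i]
        if (self.G_free < -1e-25).any() or (self.C < -1e-25).any():
            raise IntegratorFailure("negative concentration after chemistry step")
        # clamp pure rounding dust
        np.maximum(self.G_free, 0.0, out=self.G_free)
        np.maximum(self.C, 0.0, out=self.C)

    # ------------------------------------------------------------------
    def consume_portion(self, site_indices: np.ndarray, portion: float) -> None:
        """Remove one antigen portion per listed uptake event (sites may
        repeat), floored at zero free antigen; shortfalls are forfeited."""
        demand = np.zeros(self.n_sites)
        np.add.at(demand, np.asarray(site_indices, dtype=np.int64), portion)
        removed = np.minimum(self.G_free, demand)
        self.G_free -= removed
        self.G_consumed += removed

    # ------------------------------------------------------------------
    def total_on_fdc(self) -> float:
        """Antigen still displayed (free + complexed), summed over sites."""
        return float(self.G_free.sum() + self.C.sum())

    def mass_error(self) -> float:
        """Max relative deviation from per-site mass conservation."""
        total = self.G_free + self.C.sum(axis=1) + self.G_consumed
        return float(np.abs(total - self.g_initial).max() / self.g_initial)


@dataclass
class EarlyAntibodyProfile:
    """Time profile of antibodies from earlier-initialised GCs.

    ``evaluate(t)`` returns ``rescale * profile(t + delay_h)`` per bin: the
    late GC's clock starts at 0 while the early GCs are already ``delay_h``
    into their own reaction.  Beyond the stored grid the profile decays
    exponentially at the antibody decay rate; the profile never sees the late
    GC's own antibodies (one-way feedback).
    """

    times_h: np.ndarray
    A: np.ndarray  # (T, n_bins), molar
    rescale: float = 300.0
    delay_h: float = 0.0
    decay_rate_per_h: float = np.log(2.0) / 720.0

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2 or self.A.shape[0] != len(self.times_h):
            raise ValueError("A must be (len(times_h), n_bins)")
        if (self.A < 0).any():
            raise ValueError("profile concentrations must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.A.shape[1]

    def with_delay(self, delay_h: float) -> "EarlyAntibodyProfile":
        return replace(self, delay_h=float(delay_h))

    def evaluate(self, t: float) -> np.ndarray:
        tt = t + self.delay_h
        t_end = self.times_h[-1]
        if tt > t_end:
            return self.rescale * self.A[-1] * np.exp(-self.decay_rate_per_h * (tt - t_end))
        vals = np.empty(self.n_bins)
        for i in range(self.n_bins):
            vals[i] = np.interp(tt, self.times_h, self.A[:, i])
        return self.rescale * vals

    @classmethod
    def zero(cls, n_bins: int = 11, rescale: float = 300.0) -> "EarlyAntibodyProfile":
        return cls(np.array([0.0, 1.0]), np.zeros((2, n_bins)), rescale=rescale)

    # -- CSV round trip (columns time_h, A_bin_0 .. A_bin_k) ---------------
    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.A, columns=[f"A_bin_{i}" for i in range(self.n_bins)])
        df.insert(0, "time_h", self.times_h)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, rescale: float = 300.0, **kwargs) -> "EarlyAntibodyProfile":
        df = pd.read_csv(path)
        bins = [c for c in df.columns if c.startswith("A_bin_")]
        bins.sort(key=lambda c: int(c.split("_")[-1]))
        return cls(df["time_h"].to_numpy(), df[bins].to_numpy(), rescale=rescale, **kwargs)
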