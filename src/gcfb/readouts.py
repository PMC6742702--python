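"""Observables of a GC run: volume, output, affinity, masking, immune power.

The immune-power (IP) statistic summarises quality times quantity of the
secreted antibody: with a reference antigen concentration G and the bin
dissociation constants K(i), the antigen bound by bin i at steady state is
G_bound(i) = A(i) * G / (K(i) + G) and IP = sum_i G_bound(i) / G.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "immune_power",
    "ic_fraction",
    "termination_time",
    "mean_plasma_affinity",
    "GCTimeSeries",
]


def immune_power(A: np.ndarray, kd: np.ndarray, antigen_molar: float = 1e-6) -> float:
    """Fraction of the reference antigen bound by the GC's own antibodies.

    Linear in A; increasing in bin affinity at fixed total antibody.
    """
    A = np.asarray(A, dtype=float)
    kd = np.asarray(kd, dtype=float)
    if antigen_molar <= 0:
        raise ValueError("reference antigen concentration must be positive")
    if A.shape != kd.shape:
        raise ValueError("A and kd must have one entry per bin")
    if (A < 0).any():
        raise ValueError("antibody concentrations must be non-negative")
    return float(np.sum(A / (kd + antigen_molar)))


def ic_fraction(g_free: np.ndarray, complexes: np.ndarray) -> float:
    """Fraction of antigen still on FDCs that is masked in immune complexes.

    Consumed antigen is excluded (it is no longer displayed).  If every last
    bit of antigen has been consumed the fraction is 1 when any complex
    remains, otherwise undefined (NaN).
    """
    g = float(np.sum(g_free))
    c = float(np.sum(complexes))
    if g + c == 0.0:
        return 1.0 if c > 0 else float("nan")
    return c / (g + c)


def termination_time(times_h: np.ndarray, gc_volume: np.ndarray) -> float | None:
    """First sampled time at which the GC volume is zero and stays zero.

    Transient zeros (e.g. before founder influx accumulates) do not count.
    Returns None when the GC is still alive at the last sample.
    """
    v = np.asarray(gc_volume)
    t = np.asarray(times_h, dtype=float)
    if len(v) == 0 or v[-1] != 0:
        return None
    nz = np.flatnonzero(v != 0)
    start = 0 if len(nz) == 0 else nz[-1] + 1
    return float(t[start])


def mean_plasma_affinity(affinity_sum: float, count: int) -> float | None:
    """Mean shape-space affinity over all plasma cells produced so far."""
    if count == 0:
        return None
    return affinity_sum / count


@dataclass
class GCTimeSeries:
    """Hourly snapshots of one GC run, plus run metadata."""

    df: pd.DataFrame
    seed: int | None = None
    config_digest: str | None = None

    def __post_init__(self) -> None:
        required = {"time_h", "gc_volume", "plasma_total", "ic_fraction"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"time series missing columns: {sorted(missing)}")

    # -- derived ------------------------------------------------------------
    def termination_time_h(self) -> float | None:
        return termination_time(self.df["time_h"].to_numpy(), self.df["gc_volume"].to_numpy())

    def peak_volume(self) -> int:
        return int(self.df["gc_volume"].max())

    def at_time(self, t_h: float) -> pd.Series:
        i = (self.df["time_h"] - t_h).abs().idxmin()
        return self.df.loc[i]

    def first_time_ic_above(self, threshold: float) -> float | None:
        hit = self.df.loc[self.df["ic_fraction"] >= threshold, "time_h"]
        return None if hit.empty else float(hit.iloc[0])

    # -- IO ------------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.df.to_csv(path, index=False)
        meta = {"seed": self.seed, "config_digest": self.config_digest}
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True)
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "GCTimeSeries":
        path = Path(path)
        df = pd.read_csv(path)
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        seed = digest = None
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            seed, digest = meta.get("seed"), meta.get("config_digest")
        return cls(df, seed=seed, config_digest=digest)
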