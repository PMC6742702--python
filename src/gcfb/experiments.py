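"""Experiment drivers: single runs, feedback sweeps, delayed GC initialization.

Two experiment families are supported:

* **feedback sweep** — one GC simulated per feedback scaling factor N
  (N multiplies the GC's own antibody concentration in the immune-complex
  equation, standing in for N synchronous GCs secreting into the same
  serum pool), replicated over seeds;
* **delayed initialization** — a reference antibody profile is generated
  from a baseline N = 1 run, rescaled (x300 by default), time-shifted by the
  delay, and fed one-way into a fresh N = 1 GC as external early antibody.

Seeds: ``seed(condition c, replicate r) = base_seed + c * 10_000 + r``,
injective as long as conditions use fewer than 10,000 replicates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .antibody_feedback import EarlyAntibodyProfile
from .config import GCConfig
from .engine import Simulation
from .readouts import GCTimeSeries

__all__ = [
    "ExperimentSpec",
    "run_gc",
    "make_reference_profile",
    "run_delayed",
    "sweep",
    "condition_seed",
]


def condition_seed(base_seed: int, condition_index: int, replicate: int) -> int:
    return int(base_seed) + condition_index * 10_000 + replicate


def run_gc(
    cfg: GCConfig,
    seed: int,
    early_profile: EarlyAntibodyProfile | None = None,
) -> GCTimeSeries:
    """Simulate one GC; deterministic (bit-identical output) per (cfg, seed)."""
    sim = Simulation(cfg, seed, early_profile=early_profile)
    return sim.run()


def make_reference_profile(
    cfg: GCConfig,
    seed: int,
    rescale: float = 300.0,
    replicates: int = 1,
) -> EarlyAntibodyProfile:
    """Antibody concentration profile A(i, t) of a first-initialized GC.

    Runs ``replicates`` baseline GCs at N = 1 (a single run by default) and
    records the hourly bin concentrations; the rescale factor is applied
    lazily at evaluation time.
    """
    base = cfg.replace(feedback_scale=1.0)
    stacks = []
    times = None
    for r in range(replicates):
        ts = run_gc(base, seed + r)
        cols = [f"A_bin_{i}" for i in range(cfg.n_bins)]
        stacks.append(ts.df[cols].to_numpy())
        times = ts.df["time_h"].to_numpy()
    A = np.mean(stacks, axis=0)
    return EarlyAntibodyProfile(
        times, A, rescale=rescale, decay_rate_per_h=cfg.k2_per_h
    )


def run_delayed(
    cfg: GCConfig,
    profile: EarlyAntibodyProfile,
    delay_h: float,
    seed: int,
) -> GCTimeSeries:
    """A fresh N = 1 GC under the early GCs' antibody profile shifted by
    ``delay_h``.  The late GC's own antibodies never enter the profile."""
    return run_gc(
        cfg.replace(feedback_scale=1.0),
        seed,
        early_profile=profile.with_delay(delay_h),
    )


@dataclass
class ExperimentSpec:
    """Declarative description of a condition grid."""

    mode: str = "feedback_sweep"  # or "delayed_init"
    n_values: Sequence[float] = (1.0, 10.0, 30.0, 300.0)
    delays_h: Sequence[float] = (0.0, 72.0, 120.0)
    profile_rescales: Sequence[float] = (300.0,)
    replicates: int = 5
    base_seed: int = 0
    out_dir: str | Path | None = None
    config: GCConfig = field(default_factory=GCConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("feedback_sweep", "delayed_init"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(n < 0 for n in self.n_values) or any(d < 0 for d in self.delays_h):
            raise ValueError("N values and delays must be non-negative")

    def conditions(self) -> list[dict]:
        if self.mode == "feedback_sweep":
            return [{"N": n, "delay_h": 0.0, "rescale": 0.0} for n in self.n_values]
        return [
            {"N": 1.0, "delay_h": d, "rescale": s}
            for s in self.profile_rescales
            for d in self.delays_h
        ]


def _summarise_run(ts: GCTimeSeries, cfg: GCConfig) -> dict:
    day5 = ts.at_time(120.0)
    day21 = ts.at_time(min(504.0, float(ts.df["time_h"].iloc[-1])))
    term = ts.termination_time_h()
    return {
        "day5_mean_affinity": day5["plasma_mean_affinity"],
        "day21_mean_affinity": day21["plasma_mean_affinity"],
        "day5_immune_power": day5["immune_power"],
        "day21_immune_power": day21["immune_power"],
        "day21_ic_fraction": day21["ic_fraction"],
        "termination_time_h": np.nan if term is None else term,
        "peak_gc_volume": ts.peak_volume(),
        "final_plasma_total": int(ts.df["plasma_total"].iloc[-1]),
        "seed": ts.seed,
    }


def sweep(spec: ExperimentSpec, progress: bool = False) -> pd.DataFrame:
    """Run the full condition x replicate grid and summarise per condition.

    Per-run CSVs (plus JSON sidecars) are written when ``spec.out_dir`` is
    set.  The summary holds mean and SD over replicates per condition; runs
    that fail leave NaN rows, recorded but not fatal.
    """
    out_dir = Path(spec.out_dir) if spec.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    profile_cache: dict[float, EarlyAntibodyProfile] = {}
    rows = []
    seed_log = {}
    for ci, cond in enumerate(spec.conditions()):
        for r in range(spec.replicates):
            seed = condition_seed(spec.base_seed, ci, r)
            seed_log[f"c{ci}_r{r}"] = seed
            tag = f"cond{ci}_rep{r}"
            try:
                if spec.mode == "feedback_sweep":
                    cfg = spec.config.replace(feedback_scale=float(cond["N"]))
                    ts = run_gc(cfg, seed)
                else:
                    s = float(cond["rescale"])
                    if s not in profile_cache:
                        profile_cache[s] = make_reference_profile(
                            spec.config, spec.base_seed + 9_000_000, rescale=s
                        )
                    ts = run_delayed(
                        spec.config, profile_cache[s], float(cond["delay_h"]), seed
                    )
                row = {**cond, "condition": ci, "replicate": r, **_summarise_run(ts, spec.config)}
                if out_dir:
                    ts.to_csv(out_dir / f"{tag}.csv")
            except Exception as err:  # partial failure: mark and continue
                row = {**cond, "condition": ci, "replicate": r, "seed": seed, "error": str(err)}
            rows.append(row)
            if progress:
                print(f"done {tag} (seed {seed})")
    per_run = pd.DataFrame(rows)
    if out_dir:
        per_run.to_csv(out_dir / "runs.csv", index=False)
        (out_dir / "seeds.json").write_text(json.dumps(seed_log, indent=2, sort_keys=True))
    metrics = [
        c
        for c in per_run.columns
        if c.startswith(("day5_", "day21_")) or c in ("termination_time_h", "peak_gc_volume", "final_plasma_total")
    ]
    summary = (
        per_run.groupby(["condition", "N", "delay_h", "rescale"], dropna=False)[metrics]
        .agg(["mean", "std", "median"])
        .reset_index()
    )
    summary.columns = [
        "_".join(c).rstrip("_") if isinstance(c, tuple) else c for c in summary.columns
    ]
    if out_dir:
        summary.to_csv(out_dir / "summary.csv", index=False)
    return summary
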