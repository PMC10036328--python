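"""End-to-end orchestration: simulate/load → segment → metrics → stats.

``run`` takes a :class:`RunConfig`, processes every embryo of every
condition, and returns (and optionally writes) a result bundle with
per-embryo dynamics and ring tables, cross-condition statistics, and a
run manifest.  Metric failures are isolated per embryo and recorded, not
fatal.
"""

from __future__ import annotations

import dataclasses
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dynamics import summarize_dynamics
from .geometry import segment_wound
from .io import write_results
from .piv import piv_interval, radial_inward_speed
from .ring import measure_ring, unwounded_reference_mean
from .simulate import SimulationResult, embryo_seed, preset, simulate_stack
from .stats import compare_conditions

__all__ = ["RunConfig", "RunResult", "run", "simulate_condition"]


@dataclasses.dataclass
class RunConfig:
    """Configuration of an end-to-end simulated run."""

    presets: tuple[str, ...] = ("control",)
    n_embryos: int = 10
    seed: int = 0
    channel: str | None = None  # default: first channel
    measure_dynamics: bool = True
    measure_ring: bool = True
    measure_piv: bool = False
    ring_time: float = 90.0  # s
    piv_window: int = 32
    piv_interval_s: tuple[float, float] = (60.0, 90.0)
    stats_test: str = "kruskal_wallis"
    out_dir: str | None = None
    preset_overrides: dict = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class RunResult:
    """Bundle of tables produced by :func:`run`."""

    dynamics: pd.DataFrame
    ring: pd.DataFrame
    piv: pd.DataFrame
    stats: dict[str, pd.DataFrame]
    failures: list[dict]
    manifest: dict


def simulate_condition(
    name: str, n_embryos: int, master_seed: int, **overrides
) -> list[SimulationResult]:
    """Simulate an ensemble of embryos for one preset condition.

    Each embryo gets its own RNG stream derived from the master seed, the
    condition name and its index, so ensemble size can change without
    reshuffling earlier embryos.
    """
    results = []
    # condition tag from the name bytes (str hash is salted per process)
    cond_tag = int.from_bytes(name.encode()[:4].ljust(4, b"\0"), "big") % 2**16
    for i in range(n_embryos):
        cfg = preset(name, seed=embryo_seed(master_seed, cond_tag * 1000 + i), **overrides)
        results.append(simulate_stack(cfg))
    return results


def run(config: RunConfig) -> RunResult:
    """Execute the full pipeline for every condition in ``config``."""
    dyn_rows: list[dict] = []
    ring_rows: list[dict] = []
    piv_rows: list[dict] = []
    failures: list[dict] = []

    for cond in config.presets:
        sims = simulate_condition(
            cond, config.n_embryos, config.seed, **config.preset_overrides
        )
        for i, sim in enumerate(sims):
            tag = {"condition": cond, "embryo": i}
            try:
                traj = segment_wound(sim.stack, config.channel)
            except Exception as exc:  # no trajectory → nothing downstream
                failures.append({**tag, "step": "segment", "error": str(exc)})
                continue
            if config.measure_dynamics:
                try:
                    summary = summarize_dynamics(traj, sim.stack)
                    dyn_rows.append({**tag, **summary.to_dict()})
                except Exception as exc:
                    failures.append({**tag, "step": "dynamics", "error": str(exc)})
            if config.measure_ring:
                try:
                    uw = sim.unwounded[0]
                    m = measure_ring(
                        sim.stack,
                        traj,
                        config.channel,
                        at_time=config.ring_time,
                        i_uw=unwounded_reference_mean(uw),
                    )
                    ring_rows.append(
                        {
                            **tag,
                            "time": m.time,
                            "width": m.width,
                            "mean_intensity": m.mean_intensity,
                            "relative_intensity": m.relative_intensity,
                            "d_out": m.d_out,
                            "d_in": m.d_in,
                        }
                    )
                except Exception as exc:
                    failures.append({**tag, "step": "ring", "error": str(exc)})
            if config.measure_piv:
                try:
                    field = piv_interval(
                        sim.stack,
                        config.channel,
                        *config.piv_interval_s,
                        window=config.piv_window,
                    )
                    inward, _ = radial_inward_speed(field, sim.manifest.center)
                    piv_rows.append(
                        {**tag, "median_inward_um_s": float(np.nanmedian(inward))}
                    )
                except Exception as exc:
                    failures.append({**tag, "step": "piv", "error": str(exc)})

    dynamics = pd.DataFrame(dyn_rows)
    ring = pd.DataFrame(ring_rows)
    piv = pd.DataFrame(piv_rows)

    stats_tables: dict[str, pd.DataFrame] = {}
    if len(config.presets) >= 2 and not dynamics.empty:
        for metric in ("fold_expansion", "contraction_rate"):
            groups = {
                cond: dynamics.loc[dynamics.condition == cond, metric].to_numpy()
                for cond in config.presets
                if (dynamics.condition == cond).sum() >= 2
            }
            if len(groups) >= 2:
                res = compare_conditions(groups, test=config.stats_test)
                stats_tables[metric] = res.pairwise

    manifest = {
        "config": config.to_dict(),
        "package_version": __version__,
        "python": platform.python_version(),
        "n_failures": len(failures),
    }
    result = RunResult(dynamics, ring, piv, stats_tables, failures, manifest)

    if config.out_dir is not None:
        tables = {"dynamics": dynamics, "ring": ring, "piv": piv}
        tables.update({f"stats_{k}": v for k, v in stats_tables.items()})
        if failures:
            tables["failures"] = pd.DataFrame(failures)
        write_results(tables, Path(config.out_dir), metadata=manifest)
    return result
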