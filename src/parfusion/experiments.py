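"""Parameter sweeps, mutation-drift-equilibrium baselines and deviation tables.

The outcome measure is the deviation of the mean final fusion frequency from
the mutation-drift equilibrium (MDE): the mean final frequency of the same
scenario, dominance and recombination setting with selection switched off
(s = 0).  Deviations are in absolute frequency units (percentage points of
frequency), matching how the simulation results are summarized.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import results_to_frame, run_batch
from .model import FusionScenario, SimParams

__all__ = [
    "SweepGrid",
    "cell_seed",
    "run_cell",
    "run_sweep",
    "compute_mde_deviation",
    "fixation_threshold",
    "render_fig3",
]

SWEEP_COLUMNS = [
    "scenario",
    "location",
    "s",
    "h",
    "r",
    "n_reps",
    "mean_freq",
    "var_freq",
    "mde_baseline",
    "deviation",
]


def _default_s_grid() -> list[float]:
    return [round(0.1 * i, 1) for i in range(11)]


@dataclass(frozen=True)
class SweepGrid:
    """A (scenario x s x h x r) grid of simulation cells.

    ``s = 0`` must be present: it defines the MDE baseline for every
    (scenario, h, r) stratum.
    """

    scenarios: tuple = tuple(FusionScenario)
    s_values: tuple = field(default_factory=lambda: tuple(_default_s_grid()))
    h_values: tuple = (0.0, 0.5, 1.0)
    r_values: tuple = (0.1, 0.2, 0.4)
    replicates: int = 1000
    base_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "scenarios",
            tuple(
                FusionScenario.from_string(sc) if isinstance(sc, str) else sc
                for sc in self.scenarios
            ),
        )
        if not any(s == 0.0 for s in self.s_values):
            raise ValueError("s_values must include 0 (the MDE baseline)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def cells(self):
        for sc in self.scenarios:
            for h in self.h_values:
                for r in self.r_values:
                    for s in self.s_values:
                        yield sc, s, h, r

    def __len__(self) -> int:
        return (
            len(self.scenarios)
            * len(self.s_values)
            * len(self.h_values)
            * len(self.r_values)
        )


def cell_seed(base_seed: int, scenario: FusionScenario, s: float, h: float, r: float) -> int:
    """Deterministic per-cell seed, independent of grid composition."""
    key = (base_seed, scenario.label, round(s, 6), round(h, 6), round(r, 6))
    digest = hashlib.sha256(repr(key).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _cell_cache_path(cache_dir: Path, params: SimParams, n_reps: int) -> Path:
    key = (
        params.scenario.label,
        params.s,
        params.h,
        params.r,
        params.mu,
        params.N,
        params.generations,
        params.seed,
        n_reps,
    )
    digest = hashlib.sha256(repr(key).encode()).hexdigest()[:16]
    return cache_dir / f"cell-{digest}.csv"


def run_cell(
    params: SimParams,
    n_reps: int,
    workers: int = 1,
    cache_dir: str | Path | None = None,
) -> dict:
    """Run one grid cell (a replicate batch) and summarize it."""
    frame = None
    cache_path = None
    if cache_dir is not None:
        cache_dir = Path(cache_dir)
        cache_dir.mkdir(parents=True, exist_ok=True)
        cache_path = _cell_cache_path(cache_dir, params, n_reps)
        if cache_path.exists():
            frame = pd.read_csv(cache_path)
    if frame is None:
        frame = results_to_frame(run_batch(params, n_reps, workers=workers))
        if cache_path is not None:
            frame.to_csv(cache_path, index=False)
    freqs = frame["final_fusion_frequency"].to_numpy()
    return {
        "scenario": params.scenario.label,
        "location": params.scenario.location.value,
        "s": params.s,
        "h": params.h,
        "r": params.r,
        "n_reps": n_reps,
        "mean_freq": float(freqs.mean()),
        "var_freq": float(freqs.var(ddof=1)) if n_reps > 1 else float("nan"),
    }


def run_sweep(
    grid: SweepGrid,
    defaults: SimParams | None = None,
    workers: int = 1,
    cache_dir: str | Path | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run every cell of the grid and return the deviation table.

    Each cell gets its own seed derived from ``grid.base_seed`` and the cell
    coordinates, so the table is reproducible and cells can be cached and
    reused across overlapping grids (``cache_dir``).
    """
    if defaults is None:
        defaults = SimParams(scenario=FusionScenario.Y_NONPAR)
    rows = []
    for sc, s, h, r in grid.cells():
        params = defaults.with_(
            scenario=sc, s=s, h=h, r=r, seed=cell_seed(grid.base_seed, sc, s, h, r)
        )
        rows.append(run_cell(params, grid.replicates, workers, cache_dir))
        if progress:
            print(f"cell {rows[-1]['scenario']} s={s} h={h} r={r} done", flush=True)
    return compute_mde_deviation(pd.DataFrame(rows))


def compute_mde_deviation(raw: pd.DataFrame) -> pd.DataFrame:
    """Attach the MDE baseline and the deviation column to a raw cell table.

    Baselines are matched within the (scenario, h, r) stratum; a stratum
    without an s=0 cell is an error.
    """
    raw = raw.copy()
    baselines = {}
    for key, group in raw.groupby(["scenario", "h", "r"]):
        zero = group[group["s"] == 0.0]
        if zero.empty:
            raise ValueError(f"stratum {key} has no s=0 cell for the MDE baseline")
        baselines[key] = float(zero["mean_freq"].iloc[0])
    raw["mde_baseline"] = [
        baselines[(row.scenario, row.h, row.r)] for row in raw.itertuples()
    ]
    raw["deviation"] = raw["mean_freq"] - raw["mde_baseline"]
    return raw[SWEEP_COLUMNS + [c for c in raw.columns if c not in SWEEP_COLUMNS]]


def fixation_threshold(
    table: pd.DataFrame,
    scenario: FusionScenario | str,
    h: float,
    r: float,
    threshold: float = 0.99,
) -> float | None:
    """Smallest s on the grid whose mean final frequency reaches ``threshold``.

    Returns None when no grid point crosses it.
    """
    if isinstance(scenario, str):
        scenario = FusionScenario.from_string(scenario)
    sub = table[
        (table["scenario"] == scenario.label)
        & (table["h"] == h)
        & (table["r"] == r)
    ].sort_values("s")
    crossed = sub[sub["mean_freq"] >= threshold]
    if crossed.empty:
        return None
    return float(crossed["s"].iloc[0])


def render_fig3(
    table: pd.DataFrame,
    out_dir: str | Path,
    formats: tuple = ("png",),
) -> list[Path]:
    """Deviation-from-MDE curves: one panel file per h value.

    Each panel plots deviation against s with one line per (scenario, r),
    colored by scenario and dashed by r, annotated with the replicate count.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    missing = [c for c in SWEEP_COLUMNS if c not in table.columns]
    if missing or table.empty:
        raise ValueError(
            f"sweep table is incomplete (missing columns {missing or 'rows'})"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    colors = {
        "X-nonPAR": "tab:blue",
        "Y-nonPAR": "tab:red",
        "X-PAR": "tab:cyan",
        "Y-PAR": "tab:orange",
    }
    styles = {0.1: "-", 0.2: "--", 0.4: ":"}
    paths = []
    for h in sorted(table["h"].unique()):
        sub_h = table[table["h"] == h]
        fig, ax = plt.subplots(figsize=(6, 4.5))
        for (scenario, r), grp in sub_h.groupby(["scenario", "r"]):
            grp = grp.sort_values("s")
            ax.plot(
                grp["s"],
                grp["deviation"],
                color=colors.get(scenario, "gray"),
                linestyle=styles.get(r, "-"),
                marker="o",
                markersize=3,
                label=f"{scenario}, r={r}",
            )
            n = grp["n_reps"].iloc[0]
            se = np.sqrt(grp["var_freq"].to_numpy() / n)
            ax.fill_between(
                grp["s"],
                grp["deviation"] - 1.96 * se,
                grp["deviation"] + 1.96 * se,
                color=colors.get(scenario, "gray"),
                alpha=0.12,
                linewidth=0,
            )
        ax.axhline(0.0, color="k", linewidth=0.8)
        n_reps = int(sub_h["n_reps"].iloc[0])
        ax.set_xlabel("selection coefficient s")
        ax.set_ylabel("deviation from MDE (fusion frequency)")
        ax.set_title(f"h = {h} ({n_reps} replicates per point)")
        ax.legend(fontsize=6, ncol=2)
        fig.tight_layout()
        for fmt in formats:
            path = out_dir / f"fig3_h{h}.{fmt}"
            fig.savefig(path, dpi=150)
            paths.append(path)
        plt.close(fig)
    return paths
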