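"""Replicate runner and per-replicate summaries.

A replicate initializes a fusion-free population, forces one fusion of the
chosen type in the first generation, runs the full generation count (no early
stopping at fixation or loss), and records the final state.  Replicate ``i``
of a batch draws every random number from ``default_rng([seed, i])``, so a
batch is reproducible replicate-by-replicate and its results do not depend on
how work is scheduled across workers.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .model import (
    Chrom,
    FusionScenario,
    Population,
    SimParams,
    female_fitness_by_genotype,
    initialize_population,
    male_fitness_by_genotype,
    next_generation,
    seed_initial_fusion,
)

__all__ = [
    "ReplicateResult",
    "fusion_frequency",
    "summarize_population",
    "run_replicate",
    "run_trajectory",
    "run_batch",
    "results_to_frame",
]


@dataclass(frozen=True)
class ReplicateResult:
    """Final-state summary of one replicate, with its parameters echoed."""

    scenario: str
    s: float
    h: float
    r: float
    mu: float
    N: int
    generations: int
    seed: int
    replicate_index: int
    final_fusion_frequency: float
    allele1_freq_overall: float
    allele1_freq_on_fused_X: float  # NaN when no fused X copies exist
    allele1_freq_on_fused_Y: float  # NaN when no fused Y copies exist
    mean_fitness_females: float
    mean_fitness_males: float
    fused_count_X: int
    fused_count_Y: int

    def as_dict(self) -> dict:
        return asdict(self)


def _fused_copy_counts(pop: Population) -> tuple[int, int]:
    """(fused X copies, fused Y copies) in the population."""
    half = pop.n_females
    fused_x = int(pop.fused[:, 0].sum() + pop.fused[:half, 1].sum())
    fused_y = int(pop.fused[half:, 1].sum())
    return fused_x, fused_y


def fusion_frequency(pop: Population, scenario: FusionScenario) -> float:
    """Population frequency of the fusion.

    For non-PAR scenarios the denominator is the copy number of the target
    chromosome (3N/2 X copies, or N/2 Y copies), so fixation corresponds to
    1.0.  For PAR scenarios the fusion hops between X and Y every male
    meiosis, so all 2N sex-chromosome copies form the denominator.
    """
    n, half = pop.n, pop.n_females
    fused_x, fused_y = _fused_copy_counts(pop)
    if scenario.is_par:
        return (fused_x + fused_y) / (2 * n)
    if scenario.target_chrom is Chrom.X:
        return fused_x / (n + half)
    return fused_y / half


def summarize_population(pop: Population, params: SimParams) -> dict:
    """Exhaustive final-state counts and frequencies for one population."""
    n, half = pop.n, pop.n_females
    fused_x, fused_y = _fused_copy_counts(pop)

    x_mask_allele = np.concatenate([pop.allele[:, 0], pop.allele[:half, 1]])
    x_mask_fused = np.concatenate([pop.fused[:, 0], pop.fused[:half, 1]])
    y_allele = pop.allele[half:, 1]
    y_fused = pop.fused[half:, 1]

    a1_fused_x = (
        float(x_mask_allele[x_mask_fused].mean()) if fused_x else math.nan
    )
    a1_fused_y = float(y_allele[y_fused].mean()) if fused_y else math.nan

    g = pop.allele.sum(axis=1)
    w_f = female_fitness_by_genotype(params.s, params.h)[g[:half]]
    w_m = male_fitness_by_genotype(params.s, params.h)[g[half:]]

    return {
        "final_fusion_frequency": fusion_frequency(pop, params.scenario),
        "allele1_freq_overall": float(pop.allele.sum() / (2 * n)),
        "allele1_freq_on_fused_X": a1_fused_x,
        "allele1_freq_on_fused_Y": a1_fused_y,
        "mean_fitness_females": float(w_f.mean()),
        "mean_fitness_males": float(w_m.mean()),
        "fused_count_X": fused_x,
        "fused_count_Y": fused_y,
    }


def _replicate_rng(params: SimParams, replicate_index: int) -> np.random.Generator:
    return np.random.default_rng([params.seed, replicate_index])


def run_replicate(
    params: SimParams, replicate_index: int = 0, seed_fusion: bool = True
) -> ReplicateResult:
    """Run one full replicate and summarize its final population."""
    rng = _replicate_rng(params, replicate_index)
    pop = initialize_population(params, rng)
    if seed_fusion:
        pop = seed_initial_fusion(pop, params, rng)
    for _ in range(params.generations):
        pop = next_generation(pop, params, rng)
    summary = summarize_population(pop, params)
    return ReplicateResult(
        scenario=params.scenario.label,
        s=params.s,
        h=params.h,
        r=params.r,
        mu=params.mu,
        N=params.N,
        generations=params.generations,
        seed=params.seed,
        replicate_index=replicate_index,
        **summary,
    )


def run_trajectory(
    params: SimParams,
    replicate_index: int = 0,
    seed_fusion: bool = True,
) -> np.ndarray:
    """Fusion-frequency trajectory of one replicate.

    Returns an array of length ``generations + 1``; entry 0 is the frequency
    right after the initial fusion is introduced.
    """
    rng = _replicate_rng(params, replicate_index)
    pop = initialize_population(params, rng)
    if seed_fusion:
        pop = seed_initial_fusion(pop, params, rng)
    out = np.empty(params.generations + 1)
    out[0] = fusion_frequency(pop, params.scenario)
    for t in range(1, params.generations + 1):
        pop = next_generation(pop, params, rng)
        out[t] = fusion_frequency(pop, params.scenario)
    return out


def run_batch(
    params: SimParams,
    n_reps: int | None = None,
    workers: int = 1,
    seed_fusion: bool = True,
) -> list[ReplicateResult]:
    """Run ``n_reps`` independent replicates, ordered by replicate index.

    Because every replicate owns its seed stream, the result list is
    identical for any worker count.
    """
    if n_reps is None:
        n_reps = params.replicates
    if n_reps < 0:
        raise ValueError("n_reps must be >= 0")
    if n_reps == 0:
        return []
    if workers == 1:
        return [run_replicate(params, i, seed_fusion) for i in range(n_reps)]
    results = Parallel(n_jobs=workers)(
        delayed(run_replicate)(params, i, seed_fusion) for i in range(n_reps)
    )
    return list(results)


def results_to_frame(results: list[ReplicateResult]) -> pd.DataFrame:
    """Tidy one-row-per-replicate table."""
    return pd.DataFrame([res.as_dict() for res in results])
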