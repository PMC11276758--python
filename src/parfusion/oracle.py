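"""Exact infinite-population recursion over the model's finite genotype space.

The finite state space is small because an individual is fully described by
the transmissible unit it received from each parent: an egg type (X
chromosome, fusion flag, SAL allele; 4 types) and a sperm type (X or Y,
fusion flag, allele; 8 types).  That gives 32 ordered genotype states, 16
female (X-bearing sperm) and 16 male.  Iterating the expected per-generation
update over a probability distribution on these states yields the
deterministic (infinite-N) limit of the stochastic engine; the two share the
same meiosis rules, so the recursion doubles as a brute-force oracle for the
engine's gametogenesis code and as a fast equilibrium solver.

Encoding: egg type ``e`` in 0..3 has ``fused = e >> 1``, ``allele = e & 1``;
sperm type ``s`` in 0..7 has ``chrom = X if s < 4 else Y``,
``fused = (s >> 1) & 1``, ``allele = s & 1``.  A distribution is a (4, 8)
array over (egg, sperm) with the female block (``s < 4``) and male block
(``s >= 4``) each holding mass 1/2, mirroring the engine's enforced 50:50
sex ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    Chrom,
    FusionScenario,
    SimParams,
    female_fitness_by_genotype,
    male_fitness_by_genotype,
)

__all__ = [
    "GenotypeState",
    "GameteDistribution",
    "enumerate_genotypes",
    "egg_distribution",
    "sperm_distributions",
    "gamete_distribution",
    "initial_distribution",
    "seed_fusion_mass",
    "step_expected",
    "fusion_frequency_dist",
    "allele1_frequency_dist",
    "mean_fitness_dist",
    "run_deterministic",
]

N_EGG_TYPES = 4
N_SPERM_TYPES = 8


@dataclass(frozen=True)
class GenotypeState:
    """One of the 32 diploid states: (maternal egg type, paternal sperm type)."""

    egg: int
    sperm: int

    @property
    def is_female(self) -> bool:
        return self.sperm < 4

    @property
    def genotype(self) -> int:
        return (self.egg & 1) + (self.sperm & 1)


def enumerate_genotypes() -> list[GenotypeState]:
    """The 32 states in fixed order: all 16 female states (egg-major, then
    X-sperm type), followed by the 16 male states."""
    states = [GenotypeState(e, s) for e in range(4) for s in range(4)]
    states += [GenotypeState(e, s) for e in range(4) for s in range(4, 8)]
    return states


def _unit(idx: int) -> tuple[int, int]:
    """(fused, allele) of an egg-type index or of a sperm index modulo chrom."""
    return (idx >> 1) & 1, idx & 1


def egg_distribution(state: GenotypeState, r: float) -> np.ndarray:
    """Egg-type distribution (length 4) produced by a female state.

    With probability ``r`` the SAL crossover exchanges the two alleles, then
    either haplotype is transmitted with probability 1/2.
    """
    mf, ma = _unit(state.egg)
    pf, pa = _unit(state.sperm)
    out = np.zeros(N_EGG_TYPES)
    p_sw = r if (mf or pf) else 0.5  # no fusion: independent assortment
    for p_branch, am, ap in ((1.0 - p_sw, ma, pa), (p_sw, pa, ma)):
        out[(mf << 1) | am] += p_branch / 2.0
        out[(pf << 1) | ap] += p_branch / 2.0
    return out


def sperm_distributions(
    state: GenotypeState, r: float, par: bool
) -> tuple[np.ndarray, np.ndarray]:
    """(X-conditioned, Y-conditioned) sperm-unit distributions of a male state.

    Each output has length 4 over (fused, allele).  In PAR scenarios the
    obligate PAR crossover swaps the (fused, allele) payloads between the X
    and Y units whenever at least one carries a fusion.
    """
    mf, ma = _unit(state.egg)  # the male's X-bearing unit
    pf, pa = _unit(state.sperm)  # the male's Y-bearing unit
    x_out = np.zeros(4)
    y_out = np.zeros(4)
    p_sw = r if (mf or pf) else 0.5  # no fusion: independent assortment
    for p_branch, am, ap in ((1.0 - p_sw, ma, pa), (p_sw, pa, ma)):
        xf, xa, yf, ya = mf, am, pf, ap
        if par and (mf or pf):
            xf, xa, yf, ya = pf, ap, mf, am
        x_out[(xf << 1) | xa] += p_branch
        y_out[(yf << 1) | ya] += p_branch
    return x_out, y_out


@dataclass(frozen=True)
class GameteDistribution:
    """Gamete output of one genotype state; ``egg`` for females, the two
    conditioned sperm pools for males."""

    egg: np.ndarray | None
    sperm_x: np.ndarray | None
    sperm_y: np.ndarray | None


def gamete_distribution(state: GenotypeState, params: SimParams) -> GameteDistribution:
    """Closed-form gamete distribution of one state under ``params``."""
    if state.is_female:
        return GameteDistribution(egg_distribution(state, params.r), None, None)
    sx, sy = sperm_distributions(state, params.r, params.scenario.is_par)
    return GameteDistribution(None, sx, sy)


# ---------------------------------------------------------------------------
# distribution-level operators

_FEMALE = np.zeros((4, 8), dtype=bool)
_FEMALE[:, :4] = True
_MALE = ~_FEMALE


def initial_distribution() -> np.ndarray:
    """No fusions, SAL alleles independent with frequency 1/2, sexes at 1/2."""
    dist = np.zeros((4, 8))
    for e in (0, 1):  # unfused egg types
        for s in (0, 1):  # unfused X sperm
            dist[e, s] = 0.125
        for s in (4, 5):  # unfused Y sperm
            dist[e, s] = 0.125
    return dist


def _fuse_slot(dist: np.ndarray, slot: int, p: float, mask: np.ndarray) -> np.ndarray:
    """Mix in a probability-``p`` fusion of one haplotype slot.

    ``slot`` 0 is the maternal (egg) unit, 1 the paternal (sperm) unit; the
    flow applies only to cells selected by ``mask``, and only to cells whose
    slot is currently unfused (mutation events landing on fused copies are
    no-ops).  Fusion attaches the individual's own free autosome or, when
    the other haplotype is also unfused, either free autosome with equal
    probability (the latter choice trades the two alleles) — identical to
    the engine's per-copy rule.
    """
    if p == 0.0:
        return dist
    out = dist.copy()
    for e in range(4):
        for s in range(8):
            m = dist[e, s]
            if m == 0.0 or not mask[e, s]:
                continue
            chrom_bits = s & 0b100
            if slot == 0:
                tf, ta = _unit(e)
                of, oa = _unit(s)
            else:
                tf, ta = _unit(s)
                of, oa = _unit(e)
            if tf:  # already fused: event is a no-op
                continue
            if of:  # only own autosome free
                dests = [((1 << 1) | ta, (of << 1) | oa, 1.0)]
            else:  # two free autosomes: attach own, or other with allele swap
                dests = [
                    ((1 << 1) | ta, oa, 0.5),
                    ((1 << 1) | oa, ta, 0.5),
                ]
            out[e, s] -= p * m
            for t_new, o_new, w in dests:
                if slot == 0:
                    out[t_new, o_new | chrom_bits] += w * p * m
                else:
                    out[o_new, t_new | chrom_bits] += w * p * m
    return out


def _apply_mutation(dist: np.ndarray, params: SimParams) -> np.ndarray:
    """Mean-field mutation flow: the Poisson(N*mu) event process becomes a
    per-copy fusion probability (N*mu events spread over the target-copy
    count: 2mu/3 per X copy, 2mu per Y copy; events on fused copies are
    no-ops)."""
    if params.mu == 0.0:
        return dist
    if params.scenario.target_chrom is Chrom.X:
        p = 2.0 * params.mu / 3.0
        dist = _fuse_slot(dist, 0, p, _FEMALE | _MALE)  # every maternal X
        dist = _fuse_slot(dist, 1, p, _FEMALE)  # female paternal X
    else:
        p = 2.0 * params.mu
        dist = _fuse_slot(dist, 1, p, _MALE)  # male paternal Y
    return dist


def _fitness_weights(params: SimParams) -> np.ndarray:
    wf = female_fitness_by_genotype(params.s, params.h)
    wm = male_fitness_by_genotype(params.s, params.h)
    w = np.empty((4, 8))
    for e in range(4):
        for s in range(8):
            g = (e & 1) + (s & 1)
            w[e, s] = wf[g] if s < 4 else wm[g]
    return w


def step_expected(dist: np.ndarray, params: SimParams) -> np.ndarray:
    """One expected generation: mutation, selection, gamete pooling, union.

    Sex classes are renormalized to mass 1/2 each (the enforced sex ratio);
    eggs and the X- and Y-conditioned sperm pools are each renormalized
    before random union.
    """
    dist = _apply_mutation(np.asarray(dist, dtype=float), params)

    w = _fitness_weights(params) * dist
    w[_FEMALE] *= 0.5 / w[_FEMALE].sum()
    w[_MALE] *= 0.5 / w[_MALE].sum()

    egg_pool = np.zeros(4)
    x_pool = np.zeros(4)
    y_pool = np.zeros(4)
    par = params.scenario.is_par
    for e in range(4):
        for s in range(4):
            if w[e, s] > 0.0:
                egg_pool += w[e, s] * egg_distribution(GenotypeState(e, s), params.r)
        for s in range(4, 8):
            if w[e, s] > 0.0:
                sx, sy = sperm_distributions(GenotypeState(e, s), params.r, par)
                x_pool += w[e, s] * sx
                y_pool += w[e, s] * sy
    egg_pool /= egg_pool.sum()
    x_pool /= x_pool.sum()
    y_pool /= y_pool.sum()

    out = np.zeros((4, 8))
    out[:, :4] = 0.5 * np.outer(egg_pool, x_pool)
    out[:, 4:] = 0.5 * np.outer(egg_pool, y_pool)
    return out


# ---------------------------------------------------------------------------
# summaries

def _fused_expectations(dist: np.ndarray) -> tuple[float, float, float]:
    e_idx, s_idx = np.meshgrid(np.arange(4), np.arange(8), indexing="ij")
    mat_fused = (e_idx >> 1) & 1
    pat_fused = (s_idx >> 1) & 1
    e_mat = float((dist * mat_fused).sum())
    e_pat_f = float((dist * pat_fused)[_FEMALE].sum())
    e_pat_m = float((dist * pat_fused)[_MALE].sum())
    return e_mat, e_pat_f, e_pat_m


def fusion_frequency_dist(dist: np.ndarray, scenario: FusionScenario) -> float:
    """Fusion frequency under the same normalization as the engine."""
    e_mat, e_pat_f, e_pat_m = _fused_expectations(dist)
    if scenario.is_par:
        return (e_mat + e_pat_f + e_pat_m) / 2.0
    if scenario.target_chrom is Chrom.X:
        return (e_mat + e_pat_f) / 1.5
    return e_pat_m / 0.5


def allele1_frequency_dist(dist: np.ndarray) -> float:
    e_idx, s_idx = np.meshgrid(np.arange(4), np.arange(8), indexing="ij")
    g = (e_idx & 1) + (s_idx & 1)
    return float((dist * g).sum() / 2.0)


def mean_fitness_dist(dist: np.ndarray, params: SimParams) -> tuple[float, float]:
    """(female, male) mean fitness of the standing distribution."""
    w = _fitness_weights(params)
    wf = float((dist * w)[_FEMALE].sum() / dist[_FEMALE].sum())
    wm = float((dist * w)[_MALE].sum() / dist[_MALE].sum())
    return wf, wm


def seed_fusion_mass(
    dist: np.ndarray, params: SimParams, frequency: float | None = None
) -> np.ndarray:
    """Introduce the initial fusion as an independent per-copy probability.

    The stochastic engine fuses exactly one copy among the target copies, so
    the matching per-copy marginal is ``1 / (1.5 N)`` for X scenarios and
    ``1 / (0.5 N)`` for Y scenarios; ``frequency`` overrides it.
    """
    if frequency is None:
        if params.scenario.target_chrom is Chrom.X:
            frequency = 1.0 / (1.5 * params.N)
        else:
            frequency = 1.0 / (0.5 * params.N)
    if params.scenario.target_chrom is Chrom.X:
        dist = _fuse_slot(dist, 0, frequency, _FEMALE | _MALE)
        dist = _fuse_slot(dist, 1, frequency, _FEMALE)
    else:
        dist = _fuse_slot(dist, 1, frequency, _MALE)
    return dist


def run_deterministic(
    params: SimParams,
    T: int | None = None,
    seed_frequency: float | None = None,
) -> pd.DataFrame:
    """Iterate the expected recursion from the standard start.

    Starts from the no-fusion, allele-frequency-1/2 distribution, introduces
    the fusion at the engine-matched initial mass, and records fusion
    frequency, overall allele-1 frequency and sex-specific mean fitness for
    generations 0..T.
    """
    if T is None:
        T = params.generations
    if T < 0:
        raise ValueError("T must be >= 0")
    dist = seed_fusion_mass(initial_distribution(), params, seed_frequency)
    rows = []

    def record(t: int, d: np.ndarray) -> None:
        wf, wm = mean_fitness_dist(d, params)
        rows.append(
            {
                "generation": t,
                "fusion_freq": fusion_frequency_dist(d, params.scenario),
                "allele1_freq": allele1_frequency_dist(d),
                "mean_fitness_females": wf,
                "mean_fitness_males": wm,
            }
        )

    record(0, dist)
    for t in range(1, T + 1):
        dist = step_expected(dist, params)
        record(t, dist)
    return pd.DataFrame(rows)
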