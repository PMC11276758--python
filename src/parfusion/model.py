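"""Core two-locus diploid model of autosome / sex-chromosome fusions.

The model tracks two loci in an XY system.  The sex-determining locus sits in
the non-recombining region (non-PAR) of the sex chromosomes: XX individuals
are female, XY individuals are male.  The second locus is a sexually
antagonistic locus (SAL) on an autosome, with allele 0 beneficial to males and
allele 1 beneficial to females.  A fusion mutation can attach the autosome to
either the PAR or the non-PAR end of a sex chromosome; an attached autosome is
inherited with its host chromosome, while an unfused autosome co-segregates
with the unfused sex chromosome through the meiotic trivalent.

Each generation cycles through four phases: fusion/fission mutation, fitness
assignment, gametogenesis and fertilization.  Male meiosis always includes an
obligate crossover in the PAR; when the fusion is in the PAR this crossover
moves the attached autosome (with its current SAL allele) onto the other sex
chromosome every generation, so a PAR fusion can never stay linked to the
sex-determining region.  In a fusion carrier a crossover between the SAL and
the fusion point occurs with probability ``r`` per meiosis and exchanges the
SAL alleles carried by the two autosome copies; in an individual with no
fusion the autosome bivalent assorts independently of the sex chromosomes,
so no heritable chromosome-allele association survives meiosis.

Populations are stored column-wise in numpy arrays for speed; the
:class:`Haplotype` / :class:`Individual` dataclasses give a one-individual
view used by the single-meiosis operations and the tests.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "Chrom",
    "Location",
    "FusionScenario",
    "SimParams",
    "Haplotype",
    "Individual",
    "Population",
    "fitness",
    "female_fitness_by_genotype",
    "male_fitness_by_genotype",
    "initialize_population",
    "apply_fusion_mutations",
    "seed_initial_fusion",
    "make_egg",
    "make_sperm",
    "sample_eggs",
    "sample_meioses",
    "next_generation",
]


class Chrom(str, enum.Enum):
    """Sex-chromosome identity."""

    X = "X"
    Y = "Y"


class Location(str, enum.Enum):
    """Where on the sex chromosome the autosome fuses."""

    PAR = "PAR"
    NONPAR = "nonPAR"


class FusionScenario(enum.Enum):
    """The four fusion scenarios: autosome to the PAR or non-PAR of X or Y."""

    X_PAR = (Chrom.X, Location.PAR)
    X_NONPAR = (Chrom.X, Location.NONPAR)
    Y_PAR = (Chrom.Y, Location.PAR)
    Y_NONPAR = (Chrom.Y, Location.NONPAR)

    @property
    def target_chrom(self) -> Chrom:
        return self.value[0]

    @property
    def location(self) -> Location:
        return self.value[1]

    @property
    def is_par(self) -> bool:
        return self.location is Location.PAR

    @property
    def label(self) -> str:
        return f"{self.target_chrom.value}-{self.location.value}"

    @classmethod
    def from_string(cls, text: str) -> "FusionScenario":
        """Parse labels such as ``"Y-nonPAR"`` (case-insensitive on location)."""
        try:
            chrom_s, loc_s = text.strip().split("-", 1)
            chrom = Chrom(chrom_s.upper())
            loc = {"par": Location.PAR, "nonpar": Location.NONPAR}[loc_s.lower()]
        except (ValueError, KeyError):
            raise ValueError(
                f"invalid scenario {text!r}; expected one of "
                "X-PAR, X-nonPAR, Y-PAR, Y-nonPAR"
            ) from None
        return cls((chrom, loc))


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class SimParams:
    """All model and run parameters for one simulation condition.

    Parameters
    ----------
    scenario
        Which fusion is simulated (target chromosome and PAR / non-PAR end).
    s
        Selection coefficient at the sexually antagonistic locus, in [0, 1].
    h
        Dominance of the female-benefit allele (allele 1), in [0, 1].
        Heterozygote fitness is ``1 + h*s`` in females and ``1 + (1-h)*s``
        in males.
    r
        Probability per meiosis of a crossover between the SAL and the
        fusing end of the autosome.
    mu
        Per-individual per-generation fusion/fission mutation probability;
        the population-wide number of events per generation is
        Poisson(``N * mu``).
    N
        Diploid population size (must be even; a 50:50 sex ratio is enforced).
    generations
        Number of generations to simulate per replicate.
    seed
        Base seed; replicate ``i`` uses the stream seeded by ``(seed, i)``.
    replicates
        Default batch size for this condition.
    """

    scenario: FusionScenario
    s: float = 0.0
    h: float = 0.5
    r: float = 0.1
    mu: float = 1e-3
    N: int = 1000
    generations: int = 1000
    seed: int = 0
    replicates: int = 1000

    def __post_init__(self) -> None:
        if isinstance(self.scenario, str):
            object.__setattr__(
                self, "scenario", FusionScenario.from_string(self.scenario)
            )
        for name in ("s", "h", "r", "mu"):
            _check_prob(name, getattr(self, name))
        if self.N <= 0 or self.N % 2:
            raise ValueError(f"N must be a positive even integer, got {self.N}")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.replicates < 0:
            raise ValueError("replicates must be >= 0")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    def with_(self, **kwargs) -> "SimParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Haplotype:
    """One transmissible unit: a sex chromosome plus the SAL allele that
    travels with it (physically attached when ``fused``; otherwise the allele
    of the free autosome co-segregating with it through the trivalent)."""

    chrom: Chrom
    fused: bool
    sal_allele: int

    def __post_init__(self) -> None:
        if self.sal_allele not in (0, 1):
            raise ValueError("sal_allele must be 0 or 1")


@dataclass(frozen=True)
class Individual:
    maternal: Haplotype
    paternal: Haplotype

    def __post_init__(self) -> None:
        if self.maternal.chrom is not Chrom.X:
            raise ValueError("maternal haplotype must carry an X chromosome")

    @property
    def is_female(self) -> bool:
        return self.paternal.chrom is Chrom.X

    @property
    def sal_genotype(self) -> int:
        """Number of allele-1 copies (0, 1 or 2)."""
        return self.maternal.sal_allele + self.paternal.sal_allele


@dataclass
class Population:
    """N diploid individuals stored column-wise.

    ``fused`` and ``allele`` have shape (N, 2): column 0 is the maternal
    haplotype (always an X), column 1 the paternal haplotype.  Rows
    ``[0, N/2)`` are females (paternal X), rows ``[N/2, N)`` males
    (paternal Y).
    """

    fused: np.ndarray
    allele: np.ndarray
    generation: int = 0

    @property
    def n(self) -> int:
        return self.fused.shape[0]

    @property
    def n_females(self) -> int:
        return self.n // 2

    def copy(self) -> "Population":
        return Population(self.fused.copy(), self.allele.copy(), self.generation)

    def individual(self, i: int) -> Individual:
        pat_chrom = Chrom.X if i < self.n_females else Chrom.Y
        return Individual(
            maternal=Haplotype(Chrom.X, bool(self.fused[i, 0]), int(self.allele[i, 0])),
            paternal=Haplotype(pat_chrom, bool(self.fused[i, 1]), int(self.allele[i, 1])),
        )

    def individuals(self) -> list[Individual]:
        return [self.individual(i) for i in range(self.n)]

    @classmethod
    def from_individuals(cls, members: list[Individual], generation: int = 0) -> "Population":
        females = [m for m in members if m.is_female]
        males = [m for m in members if not m.is_female]
        if len(females) != len(males):
            raise ValueError("population must contain equal numbers of each sex")
        ordered = females + males
        n = len(ordered)
        fused = np.zeros((n, 2), dtype=bool)
        allele = np.zeros((n, 2), dtype=np.int8)
        for i, ind in enumerate(ordered):
            fused[i] = (ind.maternal.fused, ind.paternal.fused)
            allele[i] = (ind.maternal.sal_allele, ind.paternal.sal_allele)
        return cls(fused, allele, generation)

    def check_invariants(self, scenario: FusionScenario | None = None) -> None:
        """Raise AssertionError if a structural invariant is violated."""
        n, half = self.n, self.n_females
        assert n % 2 == 0 and self.fused.shape == (n, 2) == self.allele.shape
        assert self.fused.dtype == bool
        assert np.isin(self.allele, (0, 1)).all()
        if scenario is not None and not scenario.is_par:
            if scenario.target_chrom is Chrom.X:
                # Y copies (male paternal) never fused
                assert not self.fused[half:, 1].any()
            else:
                # no X copy (any maternal, or female paternal) ever fused
                assert not self.fused[:, 0].any()
                assert not self.fused[:half, 1].any()


# ---------------------------------------------------------------------------
# fitness

def female_fitness_by_genotype(s: float, h: float) -> np.ndarray:
    """Fitness of female genotypes (00, 01, 11): 1, 1+h*s, 1+s."""
    return 1.0 + s * np.array([0.0, h, 1.0])


def male_fitness_by_genotype(s: float, h: float) -> np.ndarray:
    """Fitness of male genotypes (00, 01, 11): 1+s, 1+(1-h)*s, 1."""
    return 1.0 + s * np.array([1.0, 1.0 - h, 0.0])


def fitness(sex: str, genotype: int, s: float, h: float) -> float:
    """Fitness of one individual from its sex and SAL genotype.

    ``genotype`` counts allele-1 copies (0, 1 or 2); strings "00", "01",
    "10", "11" are also accepted.  Allele 0 benefits males, allele 1 benefits
    females; ``h`` is the dominance of the female-benefit allele, so the
    symmetric scheme is: male 00 -> 1+s, male 01 -> 1+(1-h)s, male 11 -> 1;
    female 00 -> 1, female 01 -> 1+h*s, female 11 -> 1+s.
    """
    _check_prob("s", s)
    _check_prob("h", h)
    if isinstance(genotype, str):
        if sorted(genotype) not in (["0", "0"], ["0", "1"], ["1", "1"]):
            raise ValueError(f"invalid genotype {genotype!r}")
        genotype = genotype.count("1")
    if genotype not in (0, 1, 2):
        raise ValueError(f"invalid genotype {genotype!r}; expected 0, 1 or 2")
    if sex == "female":
        return float(female_fitness_by_genotype(s, h)[genotype])
    if sex == "male":
        return float(male_fitness_by_genotype(s, h)[genotype])
    raise ValueError(f"invalid sex {sex!r}")


# ---------------------------------------------------------------------------
# initialization and mutation

def initialize_population(params: SimParams, rng: np.random.Generator) -> Population:
    """Start-state population: no fusions, SAL alleles i.i.d. Bernoulli(1/2)."""
    n = params.N
    fused = np.zeros((n, 2), dtype=bool)
    allele = rng.integers(0, 2, size=(n, 2), dtype=np.int8)
    return Population(fused, allele, generation=0)


def _sample_target_copy(
    n: int, target: Chrom, rng: np.random.Generator
) -> tuple[int, int]:
    """Uniformly pick one (row, column) copy of the target sex chromosome.

    X copies: every maternal slot (N) plus the paternal slot of each female
    (N/2), 3N/2 total.  Y copies: the paternal slot of each male, N/2 total.
    """
    half = n // 2
    if target is Chrom.X:
        k = int(rng.integers(0, n + half))
        return (k, 0) if k < n else (k - n, 1)
    return half + int(rng.integers(0, half)), 1


def _fuse_copy(
    fused: np.ndarray,
    allele: np.ndarray,
    i: int,
    c: int,
    rng: np.random.Generator,
) -> None:
    """Fuse one sex-chromosome copy in place; a no-op if already fused.

    Fusion attaches a uniformly chosen free autosome of the individual: its
    own co-segregating one, or the other haplotype's autosome when that
    haplotype is also unfused (in which case the two SAL alleles trade
    places).
    """
    if fused[i, c]:
        return
    o = 1 - c
    if not fused[i, o] and rng.random() < 0.5:
        allele[i, c], allele[i, o] = allele[i, o], allele[i, c]
    fused[i, c] = True


def _mutate_inplace(
    fused: np.ndarray,
    allele: np.ndarray,
    params: SimParams,
    rng: np.random.Generator,
) -> int:
    """Apply Poisson(N*mu) mutation events to the target chromosome.

    Each event lands on a uniformly chosen copy; unfused copies gain a
    fusion, already-fused copies are left unchanged, so the influx of new
    fusions is lambda*(1-p) per generation at fusion frequency p.  Returns
    the number of events drawn.
    """
    lam = params.N * params.mu
    if lam == 0.0:
        return 0
    k = int(rng.poisson(lam))
    target = params.scenario.target_chrom
    for _ in range(k):
        i, c = _sample_target_copy(params.N, target, rng)
        _fuse_copy(fused, allele, i, c, rng)
    return k


def apply_fusion_mutations(
    pop: Population, params: SimParams, rng: np.random.Generator
) -> Population:
    """Fusion mutation phase.

    Draws ``k ~ Poisson(N * mu)`` events; each event lands on one uniformly
    chosen copy of the scenario's target chromosome and fuses it if it is
    not fused already.  Under neutrality the expected fusion frequency at
    generation t is therefore 1 - exp(-lambda*t/C) for C target copies,
    which defines the mutation-drift baseline the deviations are measured
    against.  Returns a new population; the input is not modified.
    """
    out = pop.copy()
    _mutate_inplace(out.fused, out.allele, params, rng)
    return out


def seed_initial_fusion(
    pop: Population, params: SimParams, rng: np.random.Generator
) -> Population:
    """Force exactly one fusion onto a uniformly chosen target-chromosome copy."""
    if pop.fused.any():
        raise ValueError("seed_initial_fusion expects a fusion-free population")
    out = pop.copy()
    i, c = _sample_target_copy(params.N, params.scenario.target_chrom, rng)
    _fuse_copy(out.fused, out.allele, i, c, rng)
    return out


# ---------------------------------------------------------------------------
# meiosis kernels
#
# A single meiosis is one function for each sex; the scalar make_egg /
# make_sperm wrappers and the compiled whole-generation kernel all call the
# same functions, so there is exactly one encoding of the meiosis rules.

@njit(cache=True)
def _meiosis_female(
    f0: bool, a0: np.int8, f1: bool, a1: np.int8, r: float, u_swap: float, u_pick: float
):
    """One female meiosis.

    With a fusion present the trivalent holds each autosome with its host
    unit, and only a SAL<->fusion-point crossover (probability r) exchanges
    the two SAL alleles.  With no fusion the autosome bivalent assorts
    independently of the sex chromosomes, so either allele accompanies the
    transmitted chromosome with probability 1/2 (and r is genotypically
    silent).  Either haplotype is then transmitted with probability 1/2.
    """
    thr = r if (f0 or f1) else 0.5
    if u_swap < thr:
        a0, a1 = a1, a0
    if u_pick < 0.5:
        return f0, a0
    return f1, a1


@njit(cache=True)
def _meiosis_male(
    fx: bool,
    ax: np.int8,
    fy: bool,
    ay: np.int8,
    r: float,
    par: bool,
    u_swap: float,
):
    """One male meiosis; returns its X- and Y-bearing products.

    Phase 1: with a fusion present, a SAL <-> fusion-point crossover with
    probability r exchanges the SAL alleles between the two autosome copies;
    with no fusion the autosome bivalent assorts independently of the sex
    chromosomes (alleles exchange with probability 1/2, making r silent).
    Phase 2 (PAR scenarios only): the obligate PAR crossover moves any
    PAR-attached autosome, with its current allele, onto the other sex
    chromosome — at the transmitted gamete level this swaps the
    (fused, allele) payloads of the X- and Y-haplotypes whenever at least
    one is fused.  With no fusion the PAR crossover exchanges only the
    (empty) PARs and has no genotypic effect.
    """
    thr = r if (fx or fy) else 0.5
    if u_swap < thr:
        ax, ay = ay, ax
    if par and (fx or fy):
        fx, ax, fy, ay = fy, ay, fx, ax
    return fx, ax, fy, ay


@njit(cache=True)
def _generation_kernel(
    fused,
    allele,
    s,
    h,
    r,
    par,
    u_mothers,
    u_fathers,
    u_swap_f,
    u_pick_f,
    u_swap_m,
    out_fused,
    out_allele,
):
    """Selection, gametogenesis and fertilization for one whole generation.

    Parents are drawn with replacement, fitness-proportionally within each
    sex (inverse-CDF on the cumulative weights); offspring slot i < N/2 is a
    daughter (takes the X-bearing product of her father's meiosis), the rest
    are sons (Y-bearing product).  Every offspring gets a fresh meiosis.
    """
    n = fused.shape[0]
    half = n // 2
    cum_f = np.empty(half)
    cum_m = np.empty(half)
    acc_f = 0.0
    acc_m = 0.0
    for i in range(half):
        g = allele[i, 0] + allele[i, 1]
        if g == 0:
            w = 1.0
        elif g == 1:
            w = 1.0 + h * s
        else:
            w = 1.0 + s
        acc_f += w
        cum_f[i] = acc_f
        g = allele[half + i, 0] + allele[half + i, 1]
        if g == 0:
            w = 1.0 + s
        elif g == 1:
            w = 1.0 + (1.0 - h) * s
        else:
            w = 1.0
        acc_m += w
        cum_m[i] = acc_m
    for i in range(n):
        v = u_mothers[i] * acc_f
        lo = 0
        hi = half
        while lo < hi:
            mid = (lo + hi) // 2
            if cum_f[mid] <= v:
                lo = mid + 1
            else:
                hi = mid
        m = min(lo, half - 1)
        v = u_fathers[i] * acc_m
        lo = 0
        hi = half
        while lo < hi:
            mid = (lo + hi) // 2
            if cum_m[mid] <= v:
                lo = mid + 1
            else:
                hi = mid
        fa = half + min(lo, half - 1)
        ef, ea = _meiosis_female(
            fused[m, 0], allele[m, 0], fused[m, 1], allele[m, 1],
            r, u_swap_f[i], u_pick_f[i],
        )
        fx, ax, fy, ay = _meiosis_male(
            fused[fa, 0], allele[fa, 0], fused[fa, 1], allele[fa, 1],
            r, par, u_swap_m[i],
        )
        out_fused[i, 0] = ef
        out_allele[i, 0] = ea
        if i < half:
            out_fused[i, 1] = fx
            out_allele[i, 1] = ax
        else:
            out_fused[i, 1] = fy
            out_allele[i, 1] = ay


def make_egg(
    mother: Individual, params: SimParams, rng: np.random.Generator
) -> Haplotype:
    """Simulate one female meiosis and return the transmitted X-bearing unit."""
    if not mother.is_female:
        raise ValueError("make_egg requires a female parent")
    ef, ea = _meiosis_female(
        mother.maternal.fused,
        np.int8(mother.maternal.sal_allele),
        mother.paternal.fused,
        np.int8(mother.paternal.sal_allele),
        params.r,
        rng.random(),
        rng.random(),
    )
    return Haplotype(Chrom.X, bool(ef), int(ea))


def make_sperm(
    father: Individual,
    required_chrom: Chrom,
    params: SimParams,
    rng: np.random.Generator,
) -> Haplotype:
    """Simulate one male meiosis and return its product bearing ``required_chrom``."""
    if father.is_female:
        raise ValueError("make_sperm requires a male parent")
    required_chrom = Chrom(required_chrom)
    fx, ax, fy, ay = _meiosis_male(
        father.maternal.fused,
        np.int8(father.maternal.sal_allele),
        father.paternal.fused,
        np.int8(father.paternal.sal_allele),
        params.r,
        params.scenario.is_par,
        rng.random(),
    )
    if required_chrom is Chrom.X:
        return Haplotype(Chrom.X, bool(fx), int(ax))
    return Haplotype(Chrom.Y, bool(fy), int(ay))


@njit(cache=True)
def _sample_eggs_kernel(f0, a0, f1, a1, r, u_swap, u_pick, out_f, out_a):
    for i in range(u_swap.size):
        ef, ea = _meiosis_female(f0, a0, f1, a1, r, u_swap[i], u_pick[i])
        out_f[i] = ef
        out_a[i] = ea


@njit(cache=True)
def _sample_meioses_kernel(fx, ax, fy, ay, r, par, u_swap, oxf, oxa, oyf, oya):
    for i in range(u_swap.size):
        xf, xa, yf, ya = _meiosis_male(fx, ax, fy, ay, r, par, u_swap[i])
        oxf[i] = xf
        oxa[i] = xa
        oyf[i] = yf
        oya[i] = ya


def sample_eggs(
    mother: Individual, params: SimParams, rng: np.random.Generator, size: int
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo egg sample from one female: (fused, allele) arrays."""
    if not mother.is_female:
        raise ValueError("sample_eggs requires a female parent")
    out_f = np.empty(size, dtype=bool)
    out_a = np.empty(size, dtype=np.int8)
    _sample_eggs_kernel(
        mother.maternal.fused,
        np.int8(mother.maternal.sal_allele),
        mother.paternal.fused,
        np.int8(mother.paternal.sal_allele),
        params.r,
        rng.random(size),
        rng.random(size),
        out_f,
        out_a,
    )
    return out_f, out_a


def sample_meioses(
    father: Individual, params: SimParams, rng: np.random.Generator, size: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Monte-Carlo male meioses: (x_fused, x_allele, y_fused, y_allele) arrays."""
    if father.is_female:
        raise ValueError("sample_meioses requires a male parent")
    oxf = np.empty(size, dtype=bool)
    oxa = np.empty(size, dtype=np.int8)
    oyf = np.empty(size, dtype=bool)
    oya = np.empty(size, dtype=np.int8)
    _sample_meioses_kernel(
        father.maternal.fused,
        np.int8(father.maternal.sal_allele),
        father.paternal.fused,
        np.int8(father.paternal.sal_allele),
        params.r,
        params.scenario.is_par,
        rng.random(size),
        oxf,
        oxa,
        oyf,
        oya,
    )
    return oxf, oxa, oyf, oya


# ---------------------------------------------------------------------------
# one full generation

def next_generation(
    pop: Population, params: SimParams, rng: np.random.Generator
) -> Population:
    """Advance one generation: mutation, selection, gametogenesis, fertilization.

    Mutations occur before selection.  For each of the N/2 daughter and N/2
    son slots a mother and a father are drawn independently with replacement,
    each sex sampled proportionally to fitness; every offspring gets a fresh
    meiosis from each parent, with sons receiving the Y-bearing and daughters
    the X-bearing product of their father's meiosis.
    """
    n, half = pop.n, pop.n_females
    fused = pop.fused.copy()
    allele = pop.allele.copy()
    _mutate_inplace(fused, allele, params, rng)

    new_fused = np.empty((n, 2), dtype=bool)
    new_allele = np.empty((n, 2), dtype=np.int8)
    _generation_kernel(
        fused,
        allele,
        float(params.s),
        float(params.h),
        float(params.r),
        params.scenario.is_par,
        rng.random(n),
        rng.random(n),
        rng.random(n),
        rng.random(n),
        rng.random(n),
        new_fused,
        new_allele,
    )
    return Population(new_fused, new_allele, pop.generation + 1)
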