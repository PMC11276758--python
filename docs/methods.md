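# Methods

## Model

The simulator follows a diploid Wright–Fisher population with discrete,
non-overlapping generations, a fixed size `N` and an enforced 50:50 sex
ratio. Two loci are tracked. The sex-determining locus lies in the
non-recombining region (non-PAR) of the sex chromosome pair: XX individuals
are female, XY male. The sexually antagonistic locus (SAL) lies on an
autosome; allele 0 benefits males, allele 1 females, with the symmetric
fitness scheme

* males: 00 → 1+s, 01 → 1+(1−h)s, 11 → 1;
* females: 00 → 1, 01 → 1+h·s, 11 → 1+s,

where `h` is the dominance of the *female-benefit* allele. (The mirrored
convention, h′ = 1−h read as dominance of the male-benefit allele, describes
the same family of models; we standardise on the female-benefit reading
because the qualitative regimes — recessive h=0 permits full resolution of
the antagonism, dominant h=1 forbids it — are naturally stated in it. At
h = 0.5 the two conventions coincide.)

The state of an individual is two transmissible units ("haplotypes"): the
maternally inherited unit (always X-bearing) and the paternally inherited
unit (X in daughters, Y in sons). Each unit records the sex chromosome, a
fusion flag, and the SAL allele that travels with it — physically attached
when fused, or the free autosome co-segregating through the meiotic
trivalent when the partner is fused.

### Generation cycle

Each generation applies, in order:

1. **Fusion mutation.** The number of events is Poisson with mean `N·µ`
   (λ = 1 at defaults). Each event lands on a uniformly chosen copy of the
   scenario's target chromosome (3N/2 X copies, or N/2 Y copies). An
   unfused copy gains a fusion, attaching a uniformly chosen free autosome
   of that individual (when both autosomes are free, attaching the partner's
   trades the two alleles); an event landing on an already-fused copy does
   nothing. Mutation is therefore irreversible at the copy level: the
   neutral expectation of the fusion frequency at generation t is
   `1 − exp(−λ·t/C)` for `C` target copies, and fixation is an absorbing
   state. We chose irreversible gain over a fusion⇄fission toggle because it
   gives the model a well-defined fixation regime — a toggle process floors
   the unfused fraction at the fission influx and makes "reaching fixation"
   impossible at any selection strength — and because its closed-form
   neutral baseline makes the mutation–drift reference transparent.
2. **Selection.** Fitness is assigned from sex and SAL genotype as above.
3. **Gametogenesis and fertilization.** For each of N/2 daughter slots and
   N/2 son slots, a mother and a father are drawn independently, with
   replacement, with probability proportional to fitness within their sex.
   Every offspring triggers a fresh meiosis in each parent; daughters
   receive the X-bearing product of their father's meiosis, sons the
   Y-bearing product.

### Meiosis

* **Fusion carrier** (one or both units fused): the trivalent (or double
  attachment) holds each autosome with its unit. With probability `r` a
  crossover between the SAL and the fusion point exchanges the two SAL
  alleles. Either unit is then transmitted with probability 1/2.
* **No fusion:** the autosome bivalent assorts independently of the sex
  chromosomes — the transmitted chromosome carries either SAL allele with
  probability 1/2, and `r` has no genotypic effect. This is the crux of the
  model: only a fusion creates a *heritable* association between the SAL
  and the sex-determining region; without it, any association is destroyed
  every generation.
* **Obligate PAR crossover** (male meiosis, every generation): in PAR
  scenarios any PAR-attached autosome moves, with its current allele, to
  the other sex chromosome; at the transmitted-gamete level this swaps the
  (fusion, allele) payloads of the X- and Y-units whenever at least one is
  fused. We model the swap as deterministic rather than as a 50%
  chromatid-level outcome, the reading under which a PAR fusion can never
  remain sex-linked; the weaker chromatid-level variant would dilute, not
  remove, that effect. In non-PAR scenarios (and in fusion-free males) the
  crossover exchanges only the homologous PARs and is genotypically silent.
  Female X–X recombination within the sex-chromosome pair is omitted: with
  one marker per autosome it can only relabel which X carries the fusion,
  which does not change the gamete distribution.

### Runs and outcome measures

A replicate starts from a fusion-free population with SAL alleles i.i.d.
Bernoulli(1/2), forces exactly one fusion of the chosen type in the first
generation, runs the full generation count with no early stopping, and
records the final state. The fusion frequency divides fused copies by the
target-chromosome copy number (3N/2 for X, N/2 for Y) so that fixation is
1.0; in PAR scenarios, where the fusion hops between X and Y, the
denominator is all 2N sex-chromosome copies. Conditional summaries with an
empty denominator (e.g. allele frequency on fused X copies when none exist)
are reported as missing values, never as zeros. Mean fitness is measured on
the standing (pre-selection) adults.

The outcome measure is the deviation of the mean final frequency from the
mutation–drift equilibrium (MDE): the mean final frequency of the matched
`s = 0` run (same scenario, h, r, seed policy, replicate count). Deviations
are in absolute frequency units. Deviation at s = 0 is identically zero by
construction.

## Default parameters

| parameter | meaning | default |
|---|---|---|
| `s` | selection coefficient at the SAL (dimensionless, [0,1]) | 0 |
| `h` | dominance of the female-benefit allele | 0.5 (grid 0, 0.5, 1) |
| `r` | SAL↔fusion-point crossover probability per meiosis | 0.1 (grid 0.1, 0.2, 0.4) |
| `µ` | per-individual fusion-mutation probability per generation | 1/1000 |
| `N` | diploid population size (even) | 1000 |
| `generations` | generations per replicate | 1000 |
| `replicates` | batch size per parameter cell | 1000 |

These defaults are the study conditions; tests and the acceptance script
use 100–200 replicates per cell, which puts ~0.01–0.02 Monte-Carlo standard
errors on batch mean frequencies — small against the effects of interest.

## Deterministic recursion (oracle)

Because an individual is fully described by its maternal unit (4 types) and
paternal unit (8 types), the genotype space has 32 states, 16 per sex. The
`oracle` module iterates the expected one-generation map on a probability
distribution over these states: mean-field mutation (per-copy fusion
probability `λ/C`; an approximation used for testing, since the engine's
event process is Poisson), sex-specific fitness reweighting with each sex
class pinned at mass 1/2, closed-form gamete pooling using *the same
meiosis rules*, and random union of eggs with X- or Y-conditioned sperm.
This is the infinite-N limit of the engine. It provides (i) exact
expectations for every meiosis configuration, checked against 10⁵-draw
Monte-Carlo samples from the engine's kernels, and (ii) trajectory
expectations that 200-replicate engine means must track over the first ~50
generations, before drift-dominated divergence. At `s = 0, µ = 0` the
fusion frequency is a martingale and the recursion conserves it exactly; at
h = 0 with the Y fusion fixed, allele 1 fixed on X-borne copies and allele 0
on the fused Y, the recursion has an exact fixed point at r = 0 with both
sexes at the fitness ceiling 1+s, and a nearby equilibrium with a standing
recombination load for r > 0.

## What the simulation does and does not emulate

The model is a deliberately minimal caricature: one sexually antagonistic
locus with symmetric, frequency-independent fitness; exactly even sex
ratio; mating success exactly proportional to fitness; no interference,
no chromatid-level meiosis, no aneuploid gametes from PAR non-recombination,
no ZW systems, no dosage or degeneration effects on the neo-sex chromosome.
Passing tests therefore demonstrate the internal logic of the
PAR-versus-non-PAR contrast — heritable linkage versus enforced swapping —
not quantitative predictions for any real genome. Quantities that depend
only on that contrast (signs of the deviations, the martingale under
neutrality, the r-monotonicity of the non-PAR advantage) are robust;
quantities that depend on the absolute rate of indirect selection (the size
of the X-fusion deviation at a given s, the s at which batch means cross a
fixation threshold) shift substantially under small changes to mating,
mutation or recombination details and should be read as properties of this
implementation's exact update rule.

## Numerical choices

* Replicate i of a batch draws every random number from
  `numpy.random.default_rng([base_seed, i])`; batches are reproducible
  replicate-by-replicate and independent of worker count or scheduling.
  Parameter-grid cells derive their base seed from a SHA-256 hash of the
  cell coordinates, so overlapping grids share cells and caching by
  parameter hash is safe.
* The per-generation update is a compiled (numba) kernel; parent sampling
  uses inverse-CDF lookup on the cumulative fitness weights. Single-meiosis
  functions are shared verbatim between the kernel, the scalar
  `make_egg`/`make_sperm` operations and the Monte-Carlo gamete samplers,
  so the meiosis rules exist in exactly one place (plus their closed-form
  mirror in the oracle, kept independent on purpose).
* Fitness is ≥ 1 for every genotype, so the sampling weights can never be
  all zero; no renormalisation guards are needed.
* Populations store females in rows [0, N/2) and males in [N/2, N); the
  maternal unit is column 0. Structural invariants (size, sex counts,
  maternal X, no off-target fusions in non-PAR runs) are assertable via
  `Population.check_invariants` and exercised over full runs in the tests.

## Known limitations

* The fusion-gain-only mutation process makes the s = 0 baseline
  time-dependent (`1 − exp(−λt/C)`), so MDE baselines must always come from
  matched-length runs, which the sweep machinery enforces.
* At h = 0 the antagonism resolves (female-benefit allele fixes on X,
  male-benefit on the fused Y), but the SAL↔fusion-point crossover keeps
  regenerating maladapted gametes, leaving mean fitness near 1 + (1−2.4r)s
  rather than at the 1+s ceiling for r = 0.1.
* `h` enters only through heterozygote fitness; meiotic drive, sex-specific
  recombination modifiers and multi-locus antagonism are out of scope.
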