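"""Neutral-mutation kinetics: branching-process drift and the mutation clock.

A new neutral mutation starts as a single copy.  In a demographically
stable population the number of descendant copies is a critical
Galton–Watson branching process (mean offspring per copy = 1).  Classical
results: the chance the mutation is still present after n generations is
approximately 2/(sigma^2 n) for large n (2/n for the default Poisson
offspring, sigma^2 = 1), and the copy number conditional on survival is
close to n/2.  Both are estimated here by direct Monte-Carlo simulation of
the process.

The clock side is plain arithmetic: with ~3 miscopies per cell division
over the diploid genome and ~100 divisions of parental germ lines per
generation, each zygote inherits ~150 new base changes; dividing the
observed pairwise divergence (~1 base in 300) by the per-generation input
dates the accumulation at ~100,000 generations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import ModelParams
from .errors import ParameterError, ConvergenceError

__all__ = [
    "ClockParams",
    "BranchingEstimate",
    "simulate_branching",
    "branching_survival",
    "branching_survival_profile",
    "copies_given_survival",
    "per_division_mutations",
    "new_mutations_per_zygote",
    "divergence_clock",
]


@dataclass(frozen=True)
class ClockParams:
    """Inputs of the mutation-clock arithmetic.

    divergence: pairwise difference density between homologous strands
    (per bp); new_per_generation: new base changes per individual per
    generation used as the clock rate; haploid_bp: aligned haploid length;
    divisions_maternal/paternal: germ-line cell divisions from zygote to
    oocyte / spermatozoon.
    """

    divergence: float = 1.0 / 300.0
    new_per_generation: float = 100.0
    haploid_bp: float = 3e9
    divisions_maternal: int = 40
    divisions_paternal: int = 60

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")


@dataclass(frozen=True)
class BranchingEstimate:
    """A Monte-Carlo estimate with its standard error."""

    value: float
    se: float
    n_generations: int
    reps: int


def simulate_branching(n: int, reps: int, seed: int,
                       offspring: str = "poisson") -> np.ndarray:
    """Copy numbers of ``reps`` independent lineages after ``n`` generations.

    Each lineage starts with one copy.  ``offspring`` selects the per-copy
    offspring law: ``poisson`` (unit-mean Poisson, the stable-population
    default) or ``binomial2`` (two children per family, each inheriting
    with probability 1/2 — the 25/50/25% quartet argument, variance 1/2).
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if reps < 1000:
        raise ParameterError("reps must be >= 1000")
    if offspring not in ("poisson", "binomial2"):
        raise ParameterError(f"unknown offspring model {offspring!r}")
    rng = np.random.default_rng(seed)
    copies = np.ones(reps, dtype=np.int64)
    for _ in range(n):
        alive = copies > 0
        if not alive.any():
            break
        c = copies[alive]
        if offspring == "poisson":
            # sum of c iid Poisson(1) variables
            copies[alive] = rng.poisson(c)
        else:
            # sum of c iid Binomial(2, 1/2) variables
            copies[alive] = rng.binomial(2 * c, 0.5)
    return copies


def branching_survival(n: int, reps: int, seed: int,
                       offspring: str = "poisson") -> BranchingEstimate:
    """Fraction of lineages with at least one copy after n generations."""
    copies = simulate_branching(n, reps, seed, offspring)
    p = float((copies > 0).mean())
    se = float(np.sqrt(p * (1 - p) / reps))
    return BranchingEstimate(value=p, se=se, n_generations=n, reps=reps)


def branching_survival_profile(n_list: list[int], reps: int, seed: int,
                               offspring: str = "poisson") -> dict[int, BranchingEstimate]:
    """Survival at several horizons from one set of lineages.

    Using common lineages across horizons makes the estimates nested
    (survival cannot increase with n) as the underlying events are.
    """
    horizons = sorted(set(n_list))
    rng_seed = seed
    rng = np.random.default_rng(rng_seed)
    copies = np.ones(reps, dtype=np.int64)
    out: dict[int, BranchingEstimate] = {}
    g = 0
    for n in horizons:
        for _ in range(n - g):
            alive = copies > 0
            if alive.any():
                c = copies[alive]
                if offspring == "poisson":
                    copies[alive] = rng.poisson(c)
                else:
                    copies[alive] = rng.binomial(2 * c, 0.5)
        g = n
        p = float((copies > 0).mean())
        out[n] = BranchingEstimate(
            value=p, se=float(np.sqrt(p * (1 - p) / reps)),
            n_generations=n, reps=reps)
    return out


def copies_given_survival(n: int, reps: int, seed: int,
                          offspring: str = "poisson") -> BranchingEstimate:
    """Mean copy number among lineages that survive to generation n."""
    copies = simulate_branching(n, reps, seed, offspring)
    surv = copies[copies > 0]
    if len(surv) == 0:
        raise ConvergenceError(
            f"no surviving lineages at n={n} with reps={reps}; "
            "increase reps", {"n": n, "reps": reps})
    mean = float(surv.mean())
    se = float(surv.std(ddof=1) / np.sqrt(len(surv))) if len(surv) > 1 else 0.0
    return BranchingEstimate(value=mean, se=se, n_generations=n, reps=reps)


def per_division_mutations(params: ModelParams) -> float:
    """Expected miscopied bases per mitotic division of a diploid cell."""
    return params.mu_per_bp_div * params.genome_bp_diploid


def new_mutations_per_zygote(clock: ClockParams, params: ModelParams) -> float:
    """Expected new base changes a zygote inherits from parental gametogenesis.

    Each parental germ line accumulates ``per_division * divisions`` diploid
    miscopies, of which half sit on the transmitted haploid set — hence the
    factor 1/2.  Defaults give 3 * (40 + 60) / 2 = 150.
    """
    per_div = per_division_mutations(params)
    return per_div * (clock.divisions_maternal + clock.divisions_paternal) / 2.0


def divergence_clock(clock: ClockParams, params: ModelParams) -> dict:
    """Generations (and years) needed to accumulate the observed divergence.

    generations = divergence * haploid_bp / new_per_generation; the
    comparison is between two homologous haploid strands.
    """
    generations = clock.divergence * clock.haploid_bp / clock.new_per_generation
    return {
        "generations": generations,
        "years": generations * params.generation_years,
    }
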