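"""Forward-in-time simulator of synergistic selection on mutational load.

The genome is partitioned into a small number of large, essential genetic
systems (hundreds to thousands of genes each).  Heterozygous deleterious
mutations interact synergistically *within* a system: one or two mutations
leave the system robust, three leave it fragile (risk of postnatal death
under environmental stress, e.g. infection), four make it fail outright
(loss at or shortly after conception).  Each generation:

1. adults are paired at random,
2. each parent transmits half its mutations per system (binomial thinning),
3. gametogenesis adds Poisson(N) new mutations, placed in systems in
   proportion to system size,
4. zygotes are screened by the per-system viability tiers,
5. survivors are sampled back to the fixed population size.

Under these rules the mean adult load equilibrates: selection removes the
mutational input each generation instead of letting the load grow without
bound.  The simulator reports conception-stage loss and postnatal death
separately, since the model does not fix how the total loss divides
between them.

The per-individual operations (:func:`transmit_gamete`,
:func:`form_zygote`, :func:`classify_viability`) define the semantics; the
generational loop uses an equivalent vectorised path (new mutations per
system drawn as independent Poisson(N·w_i), which is the same distribution
as multinomial placement of a Poisson(N) total, by Poisson splitting).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .core_model import ModelParams
from .errors import ParameterError, ContractError, ExtinctionError

__all__ = [
    "GenomeArchitecture",
    "Individual",
    "SelectionRule",
    "GenerationStats",
    "transmit_gamete",
    "form_zygote",
    "classify_viability",
    "run_generations",
    "equilibrium_summary",
    "stats_to_frame",
]


@dataclass(frozen=True)
class GenomeArchitecture:
    """Partition of the conserved genes into essential systems.

    ``system_sizes`` are haploid gene counts; their sum may not exceed the
    haploid gene total of the accompanying :class:`ModelParams`.
    """

    system_sizes: tuple[int, ...] = (2000,) * 10
    essential_flags: tuple[bool, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.system_sizes) < 1:
            raise ParameterError("need at least one genetic system")
        if any(s < 1 for s in self.system_sizes):
            raise ParameterError("system sizes must be >= 1 gene")
        flags = self.essential_flags
        if flags is None:
            flags = (True,) * len(self.system_sizes)
            object.__setattr__(self, "essential_flags", flags)
        if len(flags) != len(self.system_sizes):
            raise ParameterError("essential_flags length must match systems")

    @property
    def n_systems(self) -> int:
        return len(self.system_sizes)

    @property
    def weights(self) -> np.ndarray:
        """Per-system share of the conserved genome (sums to 1)."""
        sizes = np.asarray(self.system_sizes, dtype=float)
        return sizes / sizes.sum()

    def validate_against(self, params: ModelParams) -> None:
        if sum(self.system_sizes) > params.L_haploid:
            raise ParameterError(
                f"systems hold {sum(self.system_sizes)} genes, more than the "
                f"haploid total {params.L_haploid}")


@dataclass
class Individual:
    """Per-system deleterious-mutation counts of one (diploid) person."""

    per_system_counts: np.ndarray
    sex: Literal["male", "female"]
    x_count: int = 0

    def __post_init__(self) -> None:
        counts = np.asarray(self.per_system_counts, dtype=np.int64)
        if (counts < 0).any() or self.x_count < 0:
            raise ParameterError("mutation counts must be nonnegative")
        self.per_system_counts = counts

    @property
    def total_load(self) -> int:
        return int(self.per_system_counts.sum())


@dataclass(frozen=True)
class SelectionRule:
    """Per-system viability tiers.

    ``lethal_threshold`` mutations in any essential system kill the zygote
    at conception; below that, death in infancy/childhood occurs with
    probability ``postnatal_death_prob[max essential count]`` (0 where
    unspecified).  q3 and q2 are free parameters — the model states only
    that three mutations are riskier than two, which are riskier than one.
    """

    lethal_threshold: float = 4
    postnatal_death_prob: dict[int, float] = field(
        default_factory=lambda: {3: 0.3, 2: 0.05})

    def __post_init__(self) -> None:
        if self.lethal_threshold < 1:
            raise ParameterError("lethal_threshold must be >= 1")
        probs = self.postnatal_death_prob
        if any(not 0.0 <= q <= 1.0 for q in probs.values()):
            raise ParameterError("death probabilities must lie in [0, 1]")
        counts = sorted(probs)
        qs = [probs[c] for c in counts]
        if any(b < a for a, b in zip(qs, qs[1:])):
            raise ParameterError(
                "postnatal death probability must be nondecreasing in count")

    def death_prob_vector(self, up_to: int) -> np.ndarray:
        """q indexed by per-system count, 0..up_to inclusive."""
        q = np.zeros(up_to + 1)
        for c, p in self.postnatal_death_prob.items():
            if c <= up_to:
                q[c] = p
        return q


@dataclass(frozen=True)
class GenerationStats:
    generation: int
    mean_adult_load: float
    zygote_loss_fraction: float
    postnatal_death_fraction: float
    population_size: int

    def __post_init__(self) -> None:
        for name in ("zygote_loss_fraction", "postnatal_death_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v!r}")
        if self.population_size < 0:
            raise ParameterError("population_size must be >= 0")


def transmit_gamete(parent: Individual, rng: np.random.Generator) -> np.ndarray:
    """Haploid per-system counts: each mutation passes with probability 1/2."""
    return rng.binomial(parent.per_system_counts, 0.5)


def form_zygote(gamete_a: np.ndarray, gamete_b: np.ndarray,
                params: ModelParams, arch: GenomeArchitecture,
                rng: np.random.Generator) -> Individual:
    """Fuse two gametes and add Poisson(N) new mutations.

    New mutations land in systems with probability proportional to system
    size.  Sex is assigned 1:1.  The X-linked count is kept as a
    Poisson(M·x_fraction/2) side-channel; it does not enter the per-system
    viability tiers.
    """
    gamete_a = np.asarray(gamete_a, dtype=np.int64)
    gamete_b = np.asarray(gamete_b, dtype=np.int64)
    if len(gamete_a) != arch.n_systems or len(gamete_b) != arch.n_systems:
        raise ContractError("gametes do not match the genome architecture")
    counts = gamete_a + gamete_b
    n_new = rng.poisson(params.N)
    if n_new:
        counts = counts + rng.multinomial(n_new, arch.weights)
    sex = "male" if rng.random() < 0.5 else "female"
    x_count = int(rng.poisson(params.M * params.x_fraction_haploid / 2.0))
    return Individual(per_system_counts=counts, sex=sex, x_count=x_count)


def classify_viability(ind: Individual, rule: SelectionRule,
                       rng: np.random.Generator,
                       arch: GenomeArchitecture | None = None) -> str:
    """One of ``lethal_conception``, ``postnatal_death``, ``survivor``.

    Only essential systems count; without an architecture every system is
    treated as essential.
    """
    if arch is None:
        counts = ind.per_system_counts
    else:
        counts = ind.per_system_counts[np.asarray(arch.essential_flags, bool)]
    if (counts >= rule.lethal_threshold).any():
        return "lethal_conception"
    max_count = int(counts.max(initial=0))
    q = rule.postnatal_death_prob.get(max_count, 0.0)
    if q > 0 and rng.random() < q:
        return "postnatal_death"
    return "survivor"


def _initial_population(params: ModelParams, arch: GenomeArchitecture,
                        pop_size: int, rng: np.random.Generator) -> np.ndarray:
    """Adults with per-system counts ~ independent Poisson(M·w_i)."""
    lam = params.M * arch.weights
    return rng.poisson(lam, size=(pop_size, arch.n_systems))


def _classify_batch(counts: np.ndarray, essential: np.ndarray,
                    rule: SelectionRule, rng: np.random.Generator):
    """Vectorised viability tiers; returns (lethal, postnatal, survivor) masks."""
    ess = counts[:, essential]
    if np.isfinite(rule.lethal_threshold):
        lethal = (ess >= rule.lethal_threshold).any(axis=1)
    else:
        lethal = np.zeros(len(counts), dtype=bool)
    max_count = ess.max(axis=1) if ess.shape[1] else np.zeros(len(counts), int)
    qvec = rule.death_prob_vector(int(max_count.max(initial=0)))
    q = qvec[np.minimum(max_count, len(qvec) - 1)]
    postnatal = (~lethal) & (rng.random(len(counts)) < q)
    return lethal, postnatal, ~(lethal | postnatal)


def run_generations(params: ModelParams, arch: GenomeArchitecture,
                    rule: SelectionRule, pop_size: int, n_generations: int,
                    seed: int) -> list[GenerationStats]:
    """Iterate the population for ``n_generations`` at constant size.

    Fully reproducible under a fixed seed.  Raises :class:`ExtinctionError`
    (with partial statistics attached) if no zygote batch yields survivors.
    """
    if pop_size < 100:
        raise ParameterError("pop_size must be >= 100")
    if n_generations < 1:
        raise ParameterError("n_generations must be >= 1")
    arch.validate_against(params)

    rng = np.random.default_rng(seed)
    essential = np.asarray(arch.essential_flags, dtype=bool)
    lam_new = params.N * arch.weights
    adults = _initial_population(params, arch, pop_size, rng)
    series: list[GenerationStats] = []

    for g in range(1, n_generations + 1):
        survivors: list[np.ndarray] = []
        n_surv = n_zygotes = n_lethal = n_postnatal = 0
        batch = max(pop_size, 1000)
        while n_surv < pop_size:
            if n_zygotes > 1000 * pop_size:
                raise ExtinctionError(
                    f"population extinct at generation {g}: "
                    f"{n_zygotes} zygotes produced {n_surv} survivors",
                    partial_stats=series)
            idx_a = rng.integers(0, len(adults), size=batch)
            idx_b = rng.integers(0, len(adults), size=batch)
            gam_a = rng.binomial(adults[idx_a], 0.5)
            gam_b = rng.binomial(adults[idx_b], 0.5)
            zygotes = gam_a + gam_b + rng.poisson(
                lam_new, size=(batch, arch.n_systems))
            lethal, postnatal, alive = _classify_batch(
                zygotes, essential, rule, rng)
            n_zygotes += batch
            n_lethal += int(lethal.sum())
            n_postnatal += int(postnatal.sum())
            n_surv += int(alive.sum())
            survivors.append(zygotes[alive])

        pool = np.concatenate(survivors)
        keep = rng.choice(len(pool), size=pop_size, replace=False)
        adults = pool[keep]
        live_births = n_zygotes - n_lethal
        series.append(GenerationStats(
            generation=g,
            mean_adult_load=float(adults.sum(axis=1).mean()),
            zygote_loss_fraction=n_lethal / n_zygotes,
            postnatal_death_fraction=(
                n_postnatal / live_births if live_births else 0.0),
            population_size=pop_size,
        ))
    return series


def equilibrium_summary(series: list[GenerationStats]) -> dict:
    """Averages over the final third of a run, with Monte-Carlo SEs."""
    if len(series) < 100:
        raise ContractError(
            f"need >= 100 generations to summarise, got {len(series)}")
    tail = series[-(len(series) // 3):]
    loads = np.array([s.mean_adult_load for s in tail])
    losses = np.array([s.zygote_loss_fraction for s in tail])
    post = np.array([s.postnatal_death_fraction for s in tail])
    n = len(tail)

    def mean_se(x: np.ndarray) -> tuple[float, float]:
        return float(x.mean()), float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0

    m_eq, m_se = mean_se(loads)
    l_eq, l_se = mean_se(losses)
    p_eq, p_se = mean_se(post)
    return {
        "M_eq": m_eq, "M_eq_se": m_se,
        "loss_eq": l_eq, "loss_eq_se": l_se,
        "postnatal_eq": p_eq, "postnatal_eq_se": p_se,
        "n_generations_averaged": n,
    }


def sweep_loss_fraction(N_values, params: ModelParams | None = None,
                        arch: GenomeArchitecture | None = None,
                        rule: SelectionRule | None = None,
                        pop_size: int = 1000, n_generations: int = 120,
                        seed: int = 0) -> pd.DataFrame:
    """Equilibrium loss fractions across mutational-input values N.

    Runs the forward simulator once per N and tabulates the equilibrated
    mean load, conception-stage loss and postnatal death (final-third
    averages with Monte-Carlo SEs).  The documented way to explore how the
    zygote loss depends on the model's free parameters.
    """
    params = params or ModelParams()
    arch = arch or GenomeArchitecture()
    rule = rule or SelectionRule()
    rows = []
    for i, N in enumerate(N_values):
        p = ModelParams(**{**params.to_dict(), "N": float(N)})
        series = run_generations(p, arch, rule, pop_size, n_generations,
                                 seed=seed + i)
        summary = equilibrium_summary(series)
        rows.append({"N": float(N), **summary})
    return pd.DataFrame(rows)


def stats_to_frame(series: list[GenerationStats]) -> pd.DataFrame:
    """Tabular view of a run (one row per generation)."""
    return pd.DataFrame([{
        "generation": s.generation,
        "mean_adult_load": s.mean_adult_load,
        "zygote_loss_fraction": s.zygote_loss_fraction,
        "postnatal_death_fraction": s.postnatal_death_fraction,
        "population_size": s.population_size,
    } for s in series])
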