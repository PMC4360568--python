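"""Analytic Poisson-load model of deleterious mutations.

The model: an adult diploid germ line carries on average ``M`` heterozygous
deleterious mutations; gametogenesis adds on average ``N`` new ones per
zygote.  Random assortment in meiosis makes the zygote load Poisson with
mean ``M + N``.  For ``M`` to be stationary across generations, selection
must remove exactly the mutational input each generation, acting against
zygotes at the upper end of the load distribution.  This module provides
that machinery in closed form:

* the zygote load distribution (:func:`zygote_load_pmf`),
* the hard-truncation selection equilibrium — the threshold ``k*`` and the
  fractional acceptance at ``k*`` that bring the survivor mean back to
  ``M`` (:func:`solve_truncation_equilibrium`),
* the post-selection adult distribution (:func:`apply_selection`),
* the expected X-chromosome share of the load
  (:func:`x_linked_expected_load`).

Hard truncation is the minimal selection scheme consistent with removal
"at the upper end" of the distribution; the richer multi-system synergy
model is simulated forward in :mod:`genload.meiosis_simulator`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .errors import ParameterError, ContractError, ConvergenceError

__all__ = [
    "ModelParams",
    "LoadDistribution",
    "SelectionSolution",
    "zygote_load_pmf",
    "solve_truncation_equilibrium",
    "apply_selection",
    "x_linked_expected_load",
]

#: probability mass allowed beyond the truncated support of a pmf
_TAIL_TOL = 1e-12


@dataclass(frozen=True)
class ModelParams:
    """Global constants of the load model.

    Parameters
    ----------
    M : float
        Mean deleterious mutations per adult diploid germ line.
    N : float
        Mean new deleterious mutations per zygote per generation.
    L_haploid : int
        Conserved (functioning) genes per haploid set; the diploid genome
        carries ``2 * L_haploid``.
    genome_bp_diploid : float
        Base pairs in the diploid genome.
    mu_per_bp_div : float
        Mutation probability per base pair per mitotic division.
    x_fraction_haploid : float
        Fraction of the haploid genome carried by the X chromosome.
    generation_years : float
        Years per human generation.
    """

    M: float = 7.0
    N: float = 1.0
    L_haploid: int = 20_000
    genome_bp_diploid: float = 6e9
    mu_per_bp_div: float = 5e-10
    x_fraction_haploid: float = 0.05
    generation_years: float = 25.0

    def __post_init__(self) -> None:
        for name in ("M", "N", "L_haploid", "genome_bp_diploid",
                     "mu_per_bp_div", "generation_years"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be nonnegative, got "
                                     f"{getattr(self, name)!r}")
        if not 0.0 <= self.x_fraction_haploid <= 1.0:
            raise ParameterError("x_fraction_haploid must lie in [0, 1], got "
                                 f"{self.x_fraction_haploid!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParameterError(f"unknown model parameter(s): {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class LoadDistribution:
    """Probability mass over deleterious-mutation counts ``k = 0..k_max``."""

    pmf: np.ndarray
    mean: float
    truncated: bool = False
    k_max: int = field(default=0)

    def __post_init__(self) -> None:
        pmf = np.asarray(self.pmf, dtype=float)
        object.__setattr__(self, "pmf", pmf)
        object.__setattr__(self, "k_max", len(pmf) - 1)
        if (pmf < 0).any():
            raise ParameterError("pmf entries must be nonnegative")
        if abs(pmf.sum() - 1.0) > 1e-12:
            raise ParameterError(f"pmf must sum to 1, got {pmf.sum()!r}")
        implied = float(np.arange(len(pmf)) @ pmf)
        if abs(implied - self.mean) > 1e-12:
            raise ParameterError(
                f"declared mean {self.mean} inconsistent with pmf mean {implied}")

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.k_max + 1)


@dataclass(frozen=True)
class SelectionSolution:
    """Hard-truncation selection: all zygotes with ``k < k_star`` survive,
    a fraction ``accept_at_k_star`` of those with ``k == k_star`` survive,
    none above.  ``k_star is None`` encodes the identity (no-selection)
    solution."""

    k_star: int | None
    accept_at_k_star: float
    loss_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.accept_at_k_star <= 1.0:
            raise ParameterError("accept_at_k_star must lie in [0, 1]")
        if not 0.0 <= self.loss_fraction < 1.0:
            raise ParameterError("loss_fraction must lie in [0, 1)")

    @property
    def is_identity(self) -> bool:
        return self.k_star is None

    def to_record(self, params: ModelParams) -> dict:
        """JSON-ready summary of the equilibrium."""
        return {
            "k_star": self.k_star,
            "accept_at_k_star": self.accept_at_k_star,
            "loss_fraction": self.loss_fraction,
            "mean_zygote": params.M + params.N,
            "mean_adult": params.M,
        }

    def to_json(self, params: ModelParams) -> str:
        return json.dumps(self.to_record(params), indent=2)


def _poisson_support(lam: float, k_max: int | None) -> int:
    """Smallest support bound whose Poisson tail mass is below tolerance,
    at least ``k_max`` if given."""
    k = 20 if k_max is None else max(k_max, 1)
    # tail far below the 1e-12 normalisation tolerance so the renormalised
    # pmf is indistinguishable from the exact Poisson
    while stats.poisson.sf(k, lam) >= _TAIL_TOL * 1e-2:
        k *= 2
    return k


def zygote_load_pmf(params: ModelParams, k_max: int | None = None) -> LoadDistribution:
    """Poisson(M+N) distribution of deleterious mutations among zygotes.

    The support is auto-extended until the neglected tail mass is far below
    the 1e-12 normalisation tolerance, then renormalised.
    """
    lam = params.M + params.N
    if lam == 0:
        return LoadDistribution(pmf=np.array([1.0]), mean=0.0)
    k_hi = _poisson_support(lam, k_max)
    k = np.arange(k_hi + 1)
    pmf = stats.poisson.pmf(k, lam)
    pmf = pmf / pmf.sum()
    mean = float(k @ pmf)
    return LoadDistribution(pmf=pmf, mean=mean)


def solve_truncation_equilibrium(params: ModelParams,
                                 tol: float = 1e-9) -> SelectionSolution:
    """Find the hard-truncation selection that returns the survivor mean to M.

    Survivors are every zygote with load below ``k_star`` plus a fraction
    ``a`` of those with exactly ``k_star``.  ``a`` solves

        (sum_{k<k*} k p_k + a k* p_{k*}) / (sum_{k<k*} p_k + a p_{k*}) = M,

    i.e. ``a = (M S − m) / (p_{k*} (k* − M))`` with ``S``/``m`` the
    sub-threshold mass and mass-weighted load.  ``k_star`` is the unique
    threshold for which ``a`` lands in [0, 1].
    """
    if tol <= 0:
        raise ParameterError(f"tol must be positive, got {tol!r}")
    if params.N == 0:
        return SelectionSolution(k_star=None, accept_at_k_star=1.0,
                                 loss_fraction=0.0)

    dist = zygote_load_pmf(params)
    pmf, M = dist.pmf, params.M
    S = 0.0   # mass below threshold
    m = 0.0   # mass-weighted load below threshold
    for t in range(len(pmf)):
        p_t = pmf[t]
        if t > M and p_t > 0:
            a = (M * S - m) / (p_t * (t - M))
            if -1e-12 <= a <= 1.0 + 1e-12:
                a = min(max(a, 0.0), 1.0)
                surviving = S + a * p_t
                mean_surv = (m + a * t * p_t) / surviving
                if abs(mean_surv - M) > tol:
                    raise ConvergenceError(
                        "post-selection mean missed tolerance",
                        {"k_star": t, "accept": a, "mean": mean_surv,
                         "target": M, "tol": tol})
                return SelectionSolution(k_star=t, accept_at_k_star=float(a),
                                         loss_fraction=float(1.0 - surviving))
        S += p_t
        m += t * p_t
    raise ConvergenceError("no feasible truncation threshold found",
                           {"support": len(pmf), "M": M, "N": params.N})


def apply_selection(dist: LoadDistribution,
                    sol: SelectionSolution) -> LoadDistribution:
    """Renormalised survivor distribution after truncation selection."""
    if sol.is_identity:
        return dist
    if sol.k_star > dist.k_max:
        raise ContractError(
            f"selection threshold k*={sol.k_star} outside distribution "
            f"support [0, {dist.k_max}]")
    pmf = dist.pmf[: sol.k_star + 1].copy()
    pmf[sol.k_star] *= sol.accept_at_k_star
    total = pmf.sum()
    if total <= 0:
        raise ContractError("selection removes the entire distribution")
    pmf /= total
    mean = float(np.arange(len(pmf)) @ pmf)
    return LoadDistribution(pmf=pmf, mean=mean, truncated=True)


def x_linked_expected_load(params: ModelParams,
                           male_viability_factor: float = 1.0) -> float:
    """Expected deleterious mutations on one X chromosome.

    The X carries ``x_fraction_haploid`` of the haploid genome, i.e. half
    that fraction of the diploid load: ``M * x_fraction / 2`` (M/40 at the
    default 5%).  ``male_viability_factor`` scales the result downward to
    discount X alleles that are lethal in males and therefore depleted
    among live-born males (1.0 = no discount).
    """
    if not 0.0 <= male_viability_factor <= 1.0:
        raise ParameterError("male_viability_factor must lie in [0, 1]")
    return params.M * params.x_fraction_haploid / 2.0 * male_viability_factor
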