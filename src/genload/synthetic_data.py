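"""Synthetic cohorts for exercising the estimators.

No measured cohort accompanies the load model, so each estimator is
validated on data generated from its own assumed process:

* a general population with Poisson(M) adult loads and an X-linked
  sub-count (:func:`simulate_population`),
* first-cousin offspring produced by full pedigree gene dropping
  (:func:`simulate_cousin_cohort`), against which :func:`~genload.consanguinity.estimate_M`
  is checked for parameter recovery,
* case/control cohorts with an X-linked carrier excess at a specified
  relative risk (:func:`simulate_case_control`), whose carrier rates come
  from the same attribution algebra as :mod:`genload.x_linked_risk`
  (single source of truth).

Cohorts are deterministic under a fixed seed and echo their full
generator parameters, so any cohort can be regenerated bit-identically
from its own header.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import ModelParams
from .consanguinity import CousinParams
from .x_linked_risk import XRiskParams, carrier_freq_from_rr, case_carrier_fraction
from .errors import ParameterError

__all__ = [
    "SyntheticCohort",
    "simulate_population",
    "simulate_cousin_cohort",
    "simulate_case_control",
    "regenerate",
]


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated table plus the exact parameters that produced it."""

    kind: str                       # population | cousin_offspring | case_control
    records: pd.DataFrame
    generator_params: dict

    def to_tsv(self, path=None) -> str | None:
        """TSV with a commented ``# param: value`` header block."""
        buf = io.StringIO()
        buf.write(f"# kind: {self.kind}\n")
        for k, v in self.generator_params.items():
            buf.write(f"# {k}: {v}\n")
        self.records.to_csv(buf, sep="\t", index=False)
        text = buf.getvalue()
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None


def simulate_population(params: ModelParams, n: int, seed: int) -> SyntheticCohort:
    """n adults with load ~ Poisson(M), sex ~ Bernoulli(1/2), and an
    X-linked sub-count ~ Binomial(load, x_fraction/2) so that
    E[x_count] = M/40 at the default 5% X share."""
    if n < 0:
        raise ParameterError("n must be >= 0")
    rng = np.random.default_rng(seed)
    load = rng.poisson(params.M, size=n)
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    x_share = params.x_fraction_haploid / 2.0
    x_count = rng.binomial(load, x_share)
    records = pd.DataFrame({"load": load, "sex": sex, "x_count": x_count})
    return SyntheticCohort(
        kind="population", records=records,
        generator_params={"M": params.M, "x_fraction_haploid":
                          params.x_fraction_haploid, "n": n, "seed": seed})


def simulate_cousin_cohort(M: float, n: int, seed: int,
                           cousin: CousinParams | None = None) -> SyntheticCohort:
    """n first-cousin offspring with autozygous loads from gene dropping.

    Each offspring has its shared-grandparental alleles (Poisson(M) per
    grandparent) dropped through the pedigree's meioses; the disease flag
    is set when at least one allele arrives homozygous.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if M < 0:
        raise ParameterError("M must be nonnegative")
    cousin = cousin or CousinParams()
    rng = np.random.default_rng(seed)
    if M == 0:
        counts = np.zeros(n, dtype=int)
    else:
        n_alleles = rng.poisson(cousin.shared_grandparents * M, size=n)
        total = int(n_alleles.sum())
        coins = rng.random((total, cousin.transmission_steps)) < 0.5
        autozygous = coins.all(axis=1)
        owner = np.repeat(np.arange(n), n_alleles)
        counts = np.bincount(owner[autozygous], minlength=n)
    records = pd.DataFrame({
        "autozygous_load": counts,
        "disease": counts >= 1,
    })
    return SyntheticCohort(
        kind="cousin_offspring", records=records,
        generator_params={"M": M, "shared_grandparents":
                          cousin.shared_grandparents, "transmission_steps":
                          cousin.transmission_steps, "n": n, "seed": seed})


def simulate_case_control(p: float, rr: float, n_cases: int, n_controls: int,
                          seed: int) -> SyntheticCohort:
    """Case/control cohort with carrier rates from the X-risk algebra.

    Controls carry at prevalence p; cases at RR·p / (1 + p(RR−1)) — the
    carrier fraction among deaths when non-carrier males share the
    baseline risk.
    """
    if not 0.0 <= p <= 1.0:
        raise ParameterError("p must lie in [0, 1]")
    if rr < 1.0:
        raise ParameterError("rr must be >= 1")
    if n_cases < 1 or n_controls < 1:
        raise ParameterError("need at least one case and one control")
    if rr == 1.0 or p == 0.0:
        case_rate = p   # null model (or no carriers): cases match controls
    else:
        sex_ratio = 1.0 + p * (rr - 1.0)
        params = XRiskParams(sex_ratio=sex_ratio, rr=rr)
        # consistency check via the shared algebra; equals rr*p/sex_ratio
        assert abs(carrier_freq_from_rr(params) - p) < 1e-12
        case_rate = case_carrier_fraction(params)
    if case_rate > 1.0:
        raise ParameterError("infeasible (p, rr): case carrier rate exceeds 1")
    rng = np.random.default_rng(seed)
    carrier = np.concatenate([
        rng.random(n_cases) < case_rate,
        rng.random(n_controls) < p,
    ])
    is_case = np.concatenate([
        np.ones(n_cases, dtype=bool), np.zeros(n_controls, dtype=bool)])
    records = pd.DataFrame({"is_case": is_case, "carrier": carrier})
    return SyntheticCohort(
        kind="case_control", records=records,
        generator_params={"p": p, "rr": rr, "n_cases": n_cases,
                          "n_controls": n_controls, "seed": seed})


def regenerate(cohort: SyntheticCohort) -> SyntheticCohort:
    """Rebuild a cohort from its echoed parameters (bit-identical)."""
    gp = cohort.generator_params
    if cohort.kind == "population":
        params = ModelParams(M=gp["M"], x_fraction_haploid=gp["x_fraction_haploid"])
        return simulate_population(params, gp["n"], gp["seed"])
    if cohort.kind == "cousin_offspring":
        cousin = CousinParams(shared_grandparents=gp["shared_grandparents"],
                              transmission_steps=gp["transmission_steps"])
        return simulate_cousin_cohort(gp["M"], gp["n"], gp["seed"], cousin)
    if cohort.kind == "case_control":
        return simulate_case_control(gp["p"], gp["rr"], gp["n_cases"],
                                     gp["n_controls"], gp["seed"])
    raise ParameterError(f"unknown cohort kind {cohort.kind!r}")
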