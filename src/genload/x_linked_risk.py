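"""X-linked attribution of excess male infant mortality.

Males carry a single X chromosome, so a deleterious mutation on X causes
recessive disease in males but not in (heterozygous) females.  If the
observed male:female death-rate ratio rho (3:2 in sudden unexpected death
in infancy) is attributed entirely to X-linked carriers — non-carrier
males sharing the female baseline risk — then with carrier prevalence p
and carrier relative risk RR the male rate is (1 − p) + p·RR times the
female rate, giving

    1 + p(RR − 1) = rho          =>   p  = (rho − 1)/(RR − 1)
    carrier fraction among cases =  RR·p / rho.

The algebra here converts between RR, p and rho in all directions and
builds the case/control carrier-percentage table for a list of candidate
relative risks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, InfeasibleParametersError

__all__ = [
    "XRiskParams",
    "XRiskTable",
    "carrier_freq_from_rr",
    "case_carrier_fraction",
    "rr_from_carrier_freq",
    "implied_sex_ratio",
    "build_table",
    "estimate_rr",
]


@dataclass(frozen=True)
class XRiskParams:
    """sex_ratio: male:female death-rate ratio (>1 for a male excess);
    rr: relative risk of death for carrier males vs non-carriers (>1)."""

    sex_ratio: float = 1.5
    rr: float = 3.0

    def __post_init__(self) -> None:
        if self.sex_ratio <= 1.0:
            raise ParameterError(
                f"sex_ratio must exceed 1 for a male excess, got {self.sex_ratio!r}")
        if self.rr <= 1.0:
            raise ParameterError(f"rr must exceed 1, got {self.rr!r}")


@dataclass(frozen=True)
class XRiskTable:
    """Carrier percentages among male cases and control males per RR."""

    rows: pd.DataFrame            # columns: rr, pct_cases, pct_controls
    raw: pd.DataFrame             # same, before display rounding
    rounding: int = 0

    def to_tsv(self) -> str:
        return self.rows.to_csv(sep="\t", index=False)


def carrier_freq_from_rr(params: XRiskParams) -> float:
    """Carrier prevalence p among control males solving 1 + p(RR−1) = rho."""
    p = (params.sex_ratio - 1.0) / (params.rr - 1.0)
    if p > 1.0:
        raise InfeasibleParametersError(
            f"rr={params.rr} cannot explain sex_ratio={params.sex_ratio}: "
            f"implied carrier prevalence {p:.3f} exceeds 1")
    return p


def case_carrier_fraction(params: XRiskParams) -> float:
    """Carrier fraction among male cases: RR·p / rho."""
    p = carrier_freq_from_rr(params)
    return params.rr * p / params.sex_ratio


def rr_from_carrier_freq(p: float, sex_ratio: float = 1.5) -> float:
    """Relative risk implied by carrier prevalence p: 1 + (rho − 1)/p."""
    if not 0.0 < p <= 1.0:
        raise ParameterError(f"carrier prevalence must lie in (0, 1], got {p!r}")
    return 1.0 + (sex_ratio - 1.0) / p


def implied_sex_ratio(p: float, rr: float) -> float:
    """Male:female death ratio implied by prevalence p and relative risk rr."""
    if not 0.0 <= p <= 1.0:
        raise ParameterError(f"carrier prevalence must lie in [0, 1], got {p!r}")
    if rr < 1.0:
        raise ParameterError(f"rr must be >= 1, got {rr!r}")
    return 1.0 + p * (rr - 1.0)


def build_table(rr_list, sex_ratio: float = 1.5, rounding: int = 0) -> XRiskTable:
    """Case/control carrier percentages for each candidate relative risk.

    Percentages are displayed rounded to ``rounding`` decimals (nearest
    whole percent by default); the unrounded values are kept in ``raw``.
    """
    records = []
    for rr in rr_list:
        params = XRiskParams(sex_ratio=sex_ratio, rr=rr)
        p = carrier_freq_from_rr(params)
        records.append({
            "rr": rr,
            "pct_cases": 100.0 * case_carrier_fraction(params),
            "pct_controls": 100.0 * p,
        })
    raw = pd.DataFrame(records, columns=["rr", "pct_cases", "pct_controls"])
    rows = raw.copy()
    if len(rows):
        rows["pct_cases"] = rows["pct_cases"].round(rounding)
        rows["pct_controls"] = rows["pct_controls"].round(rounding)
        if rounding == 0:
            rows["pct_cases"] = rows["pct_cases"].astype(int)
            rows["pct_controls"] = rows["pct_controls"].astype(int)
    return XRiskTable(rows=rows, raw=raw, rounding=rounding)


def estimate_rr(case_carriers: int, n_cases: int,
                control_carriers: int, n_controls: int,
                alpha: float = 0.05) -> dict:
    """Estimate the carrier relative risk from a case/control 2x2 table.

    Under the attribution model (non-carrier males at baseline risk) the
    carrier-status odds ratio between cases and controls equals the death
    relative risk RR, so the estimator is the sample odds ratio with a
    Woolf (log-scale normal) confidence interval.  A Haldane–Anscombe 0.5
    correction is applied when any cell is empty.
    """
    if min(n_cases, n_controls) < 1:
        raise ParameterError("need at least one case and one control")
    a = case_carriers
    b = n_cases - case_carriers
    c = control_carriers
    d = n_controls - control_carriers
    if min(a, b, c, d) < 0:
        raise ParameterError("carrier counts exceed cohort sizes")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    rr_hat = (a * d) / (b * c)
    se_log = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    return {
        "rr_hat": float(rr_hat),
        "ci_low": float(np.exp(np.log(rr_hat) - z * se_log)),
        "ci_high": float(np.exp(np.log(rr_hat) + z * se_log)),
        "alpha": alpha,
    }
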