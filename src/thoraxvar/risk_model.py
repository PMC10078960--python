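"""Strain-based probabilistic rib fracture risk and NFR2+ aggregation.

Each rib's peak first-principal cortical strain is mapped to a fracture
probability by an age-adjusted probit in log strain,

    p = Phi((ln eps - (b0 + b_age * age)) / sigma),

and per-rib probabilities are aggregated, assuming independent fractures,
into NFR2+ -- the probability that an occupant sustains two or more
fractured ribs.  With fracture indicators Bernoulli(p_i), the number of
fractured ribs is Poisson-binomial and

    NFR2+ = 1 - prod(1 - p_i) - sum_i p_i * prod_{j != i}(1 - p_j).

The published risk-function coefficients are not part of this package; the
default below is a documented placeholder with the right qualitative
behaviour (risk increasing in strain and in age) whose absolute level is
absorbed by load-case calibration.  Users with access to published
coefficients supply them through :class:`RiskFunction` / the JSON config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RiskFunction",
    "RiskResult",
    "DEFAULT_RISK_FUNCTION",
    "DEFAULT_AGE_YEARS",
    "rib_fracture_probability",
    "nfr2plus",
    "nfr2plus_bruteforce",
    "compute_risk",
    "load_risk_function",
    "save_risk_function",
    "write_risk_csv",
]

#: occupant age used in all NFR2+ calculations unless overridden; roughly the
#: age of average strain sensitivity of strain-based rib risk functions
DEFAULT_AGE_YEARS: float = 45.0

#: strains below this are treated as exactly zero risk (log undefined at 0)
EPSILON_MIN: float = 1e-12


@dataclass(frozen=True)
class RiskFunction:
    """Age-adjusted probit risk function in log engineering strain.

    ``b0 + b_age * age`` is the median log fracture strain at a given age;
    ``sigma`` the log-strain scale.  ``b_age`` is negative so that the
    fracture threshold decreases (risk increases) with age.  The defaults
    are placeholders: median threshold ~1.5% strain at age 45 with a
    plausible age drift, calibrated in absolute level by the load cases.
    """

    b0: float = -3.7
    b_age: float = -0.011
    sigma: float = 0.4
    form: str = "lognormal_probit"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.form != "lognormal_probit":
            raise ValueError(f"unsupported risk-function form {self.form!r}")


DEFAULT_RISK_FUNCTION = RiskFunction()


def rib_fracture_probability(
    strain,
    age: float = DEFAULT_AGE_YEARS,
    rf: RiskFunction = DEFAULT_RISK_FUNCTION,
):
    """Per-rib fracture probability at the given peak strain and age.

    Accepts scalar or array strain (unitless engineering strain, >= 0).
    Strain below ``EPSILON_MIN`` maps to probability 0.
    """
    if not 0.0 < age < 120.0:
        raise ValueError("age must lie in (0, 120) years")
    strain = np.asarray(strain, dtype=float)
    if np.any(strain < 0):
        raise ValueError("strain must be non-negative")
    threshold = rf.b0 + rf.b_age * age
    with np.errstate(divide="ignore"):
        z = (np.log(np.where(strain > EPSILON_MIN, strain, 1.0)) - threshold) / rf.sigma
    p = np.where(strain > EPSILON_MIN, stats.norm.cdf(z), 0.0)
    return float(p) if p.ndim == 0 else p


def _validate_p(p) -> np.ndarray:
    p = np.asarray(p, dtype=float).ravel()
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return p


def nfr2plus(p) -> float:
    """Probability of two or more fractured ribs under independence.

    Computed as 1 - P(no fracture) - P(exactly one fracture); the exactly-one
    term uses prefix/suffix products so probabilities of exactly 1 are stable
    even when some p_i equal 0 or 1.
    """
    p = _validate_p(p)
    q = 1.0 - p
    n = p.size
    if n == 0:
        return 0.0
    # prefix[i] = prod(q[:i]), suffix[i] = prod(q[i+1:])
    prefix = np.concatenate(([1.0], np.cumprod(q)[:-1]))
    suffix = np.concatenate((np.cumprod(q[::-1])[:-1][::-1], [1.0]))
    p_none = float(np.prod(q))
    p_one = float(np.sum(p * prefix * suffix))
    return float(np.clip(1.0 - p_none - p_one, 0.0, 1.0))


def nfr2plus_bruteforce(p) -> float:
    """Enumeration oracle: sum outcome-mask probabilities with >= 2 ones.

    Refuses vectors longer than 20 entries (2^n outcomes).
    """
    p = _validate_p(p)
    n = p.size
    if n > 20:
        raise ValueError("brute-force enumeration limited to length <= 20")
    if n < 2:
        return 0.0
    masks = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
    probs = np.where(masks == 1, p, 1.0 - p).prod(axis=1)
    return float(probs[masks.sum(axis=1) >= 2].sum())


@dataclass
class RiskResult:
    """Per-rib fracture probabilities and the aggregated NFR2+ risk."""

    p: np.ndarray
    nfr2plus: float
    age: float
    load_case: str = ""

    def __post_init__(self) -> None:
        self.p = _validate_p(self.p)
        upper = 1.0 - float(np.prod(1.0 - self.p))
        if self.nfr2plus > upper + 1e-12:
            raise ValueError("NFR2+ cannot exceed the any-fracture probability")


def compute_risk(
    strains,
    age: float = DEFAULT_AGE_YEARS,
    rf: RiskFunction = DEFAULT_RISK_FUNCTION,
    load_case: str = "",
) -> RiskResult:
    """Strain vector -> per-rib probabilities -> NFR2+."""
    p = np.atleast_1d(rib_fracture_probability(strains, age=age, rf=rf))
    return RiskResult(p=p, nfr2plus=nfr2plus(p), age=age, load_case=load_case)


def save_risk_function(rf: RiskFunction, path, age_default: float = DEFAULT_AGE_YEARS) -> None:
    payload = dict(asdict(rf), age_default=age_default)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def load_risk_function(path) -> RiskFunction:
    with open(path) as fh:
        payload = json.load(fh)
    payload.pop("age_default", None)
    return RiskFunction(**payload)


def write_risk_csv(result: RiskResult, strains, path) -> None:
    """Per-rib (case, rib_index, strain, p) rows plus an NFR2+ summary row."""
    strains = np.asarray(strains, dtype=float).ravel()
    frame = pd.DataFrame(
        {
            "case": result.load_case,
            "rib_index": np.arange(1, result.p.size + 1),
            "strain": strains,
            "p": result.p,
        }
    )
    summary = pd.DataFrame(
        {"case": [result.load_case], "rib_index": ["NFR2+"], "strain": [np.nan], "p": [result.nfr2plus]}
    )
    pd.concat([frame, summary], ignore_index=True).to_csv(path, index=False)
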