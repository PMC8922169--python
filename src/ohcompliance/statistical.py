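"""Lognormal group compliance tests: 5%-exceedance and UTL₉₅,₇₀ rules.

Full-shift exposure concentrations within a SEG are modelled as lognormal,
``ln X ~ Normal(mu, sigma²)``.  Two decision rules on a fitted SEG:

* **5% exceedance** (EN689:1995, with the original green/orange zoning
  dropped): the plug-in exceedance fraction
  ``P(X > OEL) = 1 − Φ((ln OEL − ȳ)/s)`` must stay below 0.05.
* **UTL₉₅,₇₀** (EN689:2018, Annex-F style): the one-sided upper tolerance
  limit ``exp(ȳ + k(n)·s)``, which bounds the true 95th percentile with 70%
  confidence, must stay below the OEL.

The tolerance factor ``k(n)`` comes from the non-central-t distribution:
``k = t'_{γ}(n−1, z_p·√n)/√n`` with p = 0.95, γ = 0.70.  Because
``k(n) > z₀.₉₅`` for every finite n, the 2018 rule is strictly more
stringent than the 1995 rule on the same data.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import (
    ComplianceDecision,
    InsufficientDataError,
    OELSpec,
    Outcome,
    Strategy,
)

__all__ = [
    "Z95",
    "LognormalFit",
    "ToleranceFactor",
    "fit_lognormal",
    "exceedance_probability",
    "statistical_test_1995",
    "tolerance_factor",
    "utl_95_70",
    "statistical_test_2018",
    "MIN_N_STATISTICAL",
]

#: standard-normal 0.95 quantile, z_0.95
Z95: float = float(stats.norm.ppf(0.95))

#: minimum SEG size for the distribution-based tests
MIN_N_STATISTICAL = 6


@dataclass(frozen=True)
class LognormalFit:
    """Sample lognormal fit of one SEG's concentrations.

    ``mean_log`` and ``sd_log`` are the mean and (n−1 denominator) SD of the
    natural-log concentrations; ``gm = exp(mean_log)`` and
    ``gsd = exp(sd_log)`` are the geometric mean and geometric SD.
    """

    n: int
    mean_log: float
    sd_log: float

    def __post_init__(self) -> None:
        if self.sd_log < 0:
            raise ValueError("sd_log must be non-negative")

    @property
    def gm(self) -> float:
        return math.exp(self.mean_log)

    @property
    def gsd(self) -> float:
        return math.exp(self.sd_log)


@dataclass(frozen=True)
class ToleranceFactor:
    """One-sided normal tolerance-limit factor k for coverage p at confidence gamma."""

    n: int
    p: float
    gamma: float
    k: float


def fit_lognormal(values: Sequence[float]) -> LognormalFit:
    """Fit a lognormal distribution by moments of the log data.

    Requires n ≥ 2 strictly positive values; the SD uses the n−1
    denominator.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise InsufficientDataError(
            f"lognormal fit needs at least 2 values, got {vals.size}"
        )
    if not np.all(vals > 0):
        raise ValueError("all concentrations must be strictly positive")
    logs = np.log(vals)
    return LognormalFit(
        n=int(vals.size),
        mean_log=float(np.mean(logs)),
        sd_log=float(np.std(logs, ddof=1)),
    )


def exceedance_probability(fit: LognormalFit, oel: OELSpec) -> float:
    """Plug-in probability that a random full-shift exposure exceeds the OEL.

    ``1 − Φ((ln OEL − mean_log)/sd_log)``.  For the degenerate sd_log = 0
    case the distribution is a point mass at the GM: the exceedance is 0
    below the OEL, 1 above it, and 0.5 exactly at it.
    """
    log_oel = math.log(oel.oel)
    if fit.sd_log == 0.0:
        if fit.mean_log < log_oel:
            return 0.0
        if fit.mean_log > log_oel:
            return 1.0
        return 0.5
    z = (log_oel - fit.mean_log) / fit.sd_log
    return float(stats.norm.sf(z))


def statistical_test_1995(fit: LognormalFit, oel: OELSpec) -> ComplianceDecision:
    """EN689:1995-style statistical test: compliance iff exceedance < 5%.

    The original Annex-D green/orange zones are not used; the decision is
    binary on the conventional 5% exceedance probability.  Requires n ≥ 6.
    A SEG sitting exactly at 5% is non-compliant (conservative boundary).
    """
    _require_min_n(fit)
    p_exc = exceedance_probability(fit, oel)
    outcome = Outcome.COMPLIANCE if p_exc < 0.05 else Outcome.NON_COMPLIANCE
    return ComplianceDecision(
        strategy=Strategy.EN689_1995_STAT,
        outcome=outcome,
        statistic=p_exc,
        n_used=fit.n,
    )


def tolerance_factor(n: int, p: float = 0.95, gamma: float = 0.70) -> ToleranceFactor:
    """Exact one-sided normal tolerance-limit factor.

    ``ȳ + k·s`` exceeds the true p-quantile of the generating normal with
    probability gamma; ``k = t'_{gamma}(df=n−1, ncp=z_p·√n)/√n`` via the
    non-central t quantile.  k decreases in n towards z_p.
    """
    if n < 2:
        raise ValueError(f"tolerance factor needs n >= 2, got {n}")
    if not (0 < p < 1 and 0 < gamma < 1):
        raise ValueError("p and gamma must lie in (0, 1)")
    zp = float(stats.norm.ppf(p))
    sqrt_n = math.sqrt(n)
    k = float(stats.nct.ppf(gamma, df=n - 1, nc=zp * sqrt_n)) / sqrt_n
    return ToleranceFactor(n=int(n), p=p, gamma=gamma, k=k)


def utl_95_70(fit: LognormalFit) -> float:
    """Upper tolerance limit: bounds the true 95th percentile with 70% confidence.

    ``UTL = exp(mean_log + k(n)·sd_log)`` on the lognormal scale; requires
    n ≥ 6 as the standard does for its statistical test.
    """
    _require_min_n(fit)
    k = tolerance_factor(fit.n).k
    return math.exp(fit.mean_log + k * fit.sd_log)


def statistical_test_2018(fit: LognormalFit, oel: OELSpec) -> ComplianceDecision:
    """EN689:2018 statistical test: compliance iff UTL₉₅,₇₀ < OEL.

    Requires n ≥ 6.  A UTL exactly at the OEL is non-compliant.
    """
    _require_min_n(fit)
    utl = utl_95_70(fit)
    outcome = Outcome.COMPLIANCE if utl < oel.oel else Outcome.NON_COMPLIANCE
    return ComplianceDecision(
        strategy=Strategy.EN689_2018_STAT,
        outcome=outcome,
        statistic=utl,
        n_used=fit.n,
    )


def _require_min_n(fit: LognormalFit) -> None:
    if fit.n < MIN_N_STATISTICAL:
        raise InsufficientDataError(
            f"statistical tests need at least {MIN_N_STATISTICAL} "
            f"measurements, got {fit.n}"
        )
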