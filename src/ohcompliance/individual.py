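"""BOHS-NVvA individual compliance test.

The BOHS-NVvA guidance decomposes log-exposure variability within a SEG
into a between-worker component (differences among workers' personal mean
exposures, sigma²_B) and a within-worker component (day-to-day fluctuation,
sigma²_W) using a one-way random-effects ANOVA with worker as the random
factor.  Under this model worker i's personal exposure distribution is
lognormal with log-mean b_i ~ Normal(mu, sigma²_B) and log-SD √sigma²_W, so
the fraction of workers whose *personal* 95th percentile exceeds the OEL is

    theta = 1 − Φ((ln OEL − mu − z₀.₉₅·√sigma²_W) / √sigma²_B).

Individual compliance requires more than 80% of SEG members to have at
least 95% of their exposures below the OEL, i.e. theta < 0.20 (exactly 20%
fails).  The individual criterion is only meaningful when workers genuinely
differ, so it is applied when the between-worker share of total variance
rho_B = sigma²_B/(sigma²_B + sigma²_W) is at least 20%; below that the SEG
is treated as homogeneous and the group 5%-exceedance test decides.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import (
    ComplianceDecision,
    InsufficientDataError,
    NoRepeatsError,
    OELSpec,
    Outcome,
    SEG,
    Strategy,
)
from .statistical import Z95, exceedance_probability, fit_lognormal

__all__ = [
    "Route",
    "VarianceComponents",
    "IndividualComplianceResult",
    "variance_components",
    "individual_theta",
    "bohs_nvva_test",
    "sensitivity_filter",
    "RHO_B_ROUTING_THRESHOLD",
    "THETA_COMPLIANCE_THRESHOLD",
]

#: between-worker variance share at or above which the individual test applies
RHO_B_ROUTING_THRESHOLD = 0.20
#: maximum tolerated fraction of overexposed workers ("more than 80% comply")
THETA_COMPLIANCE_THRESHOLD = 0.20

MIN_N_INDIVIDUAL = 6


class Route(str, enum.Enum):
    INDIVIDUAL_TEST = "individual_test"
    GROUP_TEST = "group_test"


@dataclass(frozen=True)
class VarianceComponents:
    """One-way random-effects decomposition of log concentrations by worker.

    ``n0`` is the effective per-worker replication for unbalanced designs,
    ``(N − Σnᵢ²/N)/(K−1)``; NaN when only one worker holds all the repeats
    (between-worker variance then has zero degrees of freedom and sigma2_b
    is reported as 0).
    """

    mu_log: float
    sigma2_b: float
    sigma2_w: float
    n_workers: int
    n_total: int
    n0: float

    @property
    def rho_b(self) -> float:
        """Between-worker share of total log-variance; 0 when both are 0."""
        total = self.sigma2_b + self.sigma2_w
        if total == 0.0:
            return 0.0
        return self.sigma2_b / total


@dataclass(frozen=True)
class IndividualComplianceResult:
    theta: float
    rho_b: float
    route: Route
    decision: ComplianceDecision
    components: VarianceComponents


def variance_components(seg: SEG) -> VarianceComponents:
    """ANOVA moment estimates of between-/within-worker log-variances.

    sigma²_W is the within-worker mean square; sigma²_B the moment estimate
    ``(MSB − MSW)/n0`` clamped at 0.  Requires at least 6 measurements and
    at least one worker sampled twice (otherwise the within-worker mean
    square is undefined).
    """
    if seg.n_measurements < MIN_N_INDIVIDUAL:
        raise InsufficientDataError(
            f"SEG {seg.seg_id!r} has {seg.n_measurements} measurements, "
            f"need at least {MIN_N_INDIVIDUAL}"
        )
    if not seg.has_repeats:
        raise NoRepeatsError(
            f"SEG {seg.seg_id!r} has no worker with repeated measurements"
        )
    logs_by_worker: dict[str, list[float]] = {}
    for m in seg.measurements:
        logs_by_worker.setdefault(m.worker_id, []).append(math.log(m.concentration))
    groups = [np.asarray(v) for v in logs_by_worker.values()]
    sizes = np.array([g.size for g in groups], dtype=float)
    n_total = int(sizes.sum())
    k = len(groups)
    grand = float(np.concatenate(groups).mean())

    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    msw = ssw / (n_total - k)  # n_total > k guaranteed by has_repeats

    if k == 1:
        return VarianceComponents(
            mu_log=grand,
            sigma2_b=0.0,
            sigma2_w=msw,
            n_workers=k,
            n_total=n_total,
            n0=float("nan"),
        )

    means = np.array([g.mean() for g in groups])
    ssb = float((sizes * (means - grand) ** 2).sum())
    msb = ssb / (k - 1)
    n0 = (n_total - float((sizes**2).sum()) / n_total) / (k - 1)
    sigma2_b = max(0.0, (msb - msw) / n0)
    return VarianceComponents(
        mu_log=grand,
        sigma2_b=sigma2_b,
        sigma2_w=msw,
        n_workers=k,
        n_total=n_total,
        n0=n0,
    )


def individual_theta(vc: VarianceComponents, oel: OELSpec) -> float:
    """Model-based fraction of workers whose personal 95th percentile exceeds the OEL.

    Worker i's personal 95th percentile of daily exposure is
    ``exp(b_i + z₀.₉₅·√sigma²_W)`` with b_i ~ Normal(mu, sigma²_B); theta is
    the probability this exceeds the OEL.  When sigma²_B = 0 all workers
    share one percentile and theta degenerates to a 0/1 indicator.
    """
    log_oel = math.log(oel.oel)
    group_p95_log = vc.mu_log + Z95 * math.sqrt(vc.sigma2_w)
    if vc.sigma2_b == 0.0:
        return 1.0 if group_p95_log >= log_oel else 0.0
    z = (log_oel - group_p95_log) / math.sqrt(vc.sigma2_b)
    return float(stats.norm.sf(z))


def bohs_nvva_test(seg: SEG, oel: OELSpec) -> IndividualComplianceResult:
    """Full BOHS-NVvA decision for one SEG.

    SEGs with a between-worker variance share of 20% or more are routed to
    the individual test (compliance iff theta < 0.20, i.e. more than 80% of
    members comply); more homogeneous SEGs fall back to the group
    5%-exceedance test on the pooled lognormal fit.  Either way the decision
    is tagged with the BOHS-NVvA strategy and is never *uncertain*.
    """
    vc = variance_components(seg)
    theta = individual_theta(vc, oel)
    rho_b = vc.rho_b
    if rho_b >= RHO_B_ROUTING_THRESHOLD:
        route = Route.INDIVIDUAL_TEST
        outcome = (
            Outcome.COMPLIANCE
            if theta < THETA_COMPLIANCE_THRESHOLD
            else Outcome.NON_COMPLIANCE
        )
        statistic = theta
    else:
        route = Route.GROUP_TEST
        p_exc = exceedance_probability(fit_lognormal(seg.concentrations()), oel)
        outcome = Outcome.COMPLIANCE if p_exc < 0.05 else Outcome.NON_COMPLIANCE
        statistic = p_exc
    decision = ComplianceDecision(
        strategy=Strategy.BOHS_NVVA,
        outcome=outcome,
        statistic=statistic,
        n_used=seg.n_measurements,
    )
    return IndividualComplianceResult(
        theta=theta, rho_b=rho_b, route=route, decision=decision, components=vc
    )


def sensitivity_filter(segs: list[SEG]) -> list[SEG]:
    """Keep only SEGs whose repeat structure rests on at least two workers.

    Removes SEGs in which fewer than two workers have two or more
    measurements — the sensitivity analysis that drops groups whose
    between-/within-worker decomposition hinges on a single worker's
    repeats.
    """
    return [s for s in segs if s.n_workers_with_repeats >= 2]
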