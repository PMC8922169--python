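"""Synthetic similar-exposure-group generator.

Emulates the structure of a multi-site industrial dust-monitoring dataset:
many SEGs of at least six full-shift measurements each, a subset with
repeated measurements per worker, concentrations lognormal with a
between-worker and a within-worker (day-to-day) variance component:

    ln X_ij = b_i + e_ij,  b_i ~ N(mu, sigma²_B),  e_ij ~ N(0, sigma²_W).

The study-level defaults produce 210 SEGs (158 with repeats, 1383
measurements in total) with GM between 0.02 and 0.8 mg m⁻³ and total GSD
between 1.5 and 3.5 — a realistic spread around an OEL of 1 mg m⁻³ that
exercises all three decision categories.  Everything is driven by a single
integer seed through deterministic per-SEG substreams, so SEG k is
reproducible and (in the default per-SEG sizing mode) independent of how
many other SEGs are generated.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass, field

import numpy as np

from .data_model import Measurement, SEG

__all__ = ["SEGSpec", "StudyParams", "generate_seg", "generate_study"]

DEFAULT_START_DATE = datetime.date(2019, 1, 7)


@dataclass(frozen=True)
class SEGSpec:
    """Fully explicit recipe for one synthetic SEG."""

    seg_id: str
    n_workers: int
    repeats_per_worker: tuple[int, ...]
    mu_log: float
    sigma2_b: float
    sigma2_w: float
    start_date: datetime.date = DEFAULT_START_DATE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_workers != len(self.repeats_per_worker):
            raise ValueError("repeats_per_worker must have n_workers entries")
        if any(r < 1 for r in self.repeats_per_worker):
            raise ValueError("every worker needs at least one measurement")
        if sum(self.repeats_per_worker) < 1:
            raise ValueError("SEG must contain at least one measurement")
        if self.sigma2_b < 0 or self.sigma2_w < 0:
            raise ValueError("variance components must be non-negative")


@dataclass(frozen=True)
class StudyParams:
    """Study-level parameter ranges for randomly drawn SEG recipes.

    GM is drawn log-uniformly, the total GSD uniformly, and the
    between-worker variance share rho_B uniformly; sigma²_B and sigma²_W
    then split (ln GSD)² accordingly.  Sizes are 6 plus a Poisson excess
    (mean 0.6 ≈ 6.6 measurements per SEG).  SEGs with repeats get 2 to
    n−1 workers; SEGs without repeats get one worker per measurement.
    """

    gm_range: tuple[float, float] = (0.02, 0.8)
    gsd_range: tuple[float, float] = (1.5, 3.5)
    rho_b_range: tuple[float, float] = (0.0, 0.5)
    extra_measurements_mean: float = 0.6
    start_date: datetime.date = DEFAULT_START_DATE


def generate_seg(spec: SEGSpec) -> SEG:
    """Generate one SEG from an explicit recipe; identical seed ⇒ identical SEG.

    Worker i gets a latent log-mean b_i ~ N(mu_log, sigma²_B); measurement j
    of worker i is exp(b_i + e_ij) with e_ij ~ N(0, sigma²_W).  Sampling
    dates are assigned on consecutive days starting at ``start_date``,
    cycling round-robin over the workers so repeated visits are spread over
    the campaign (mirroring progressive per-date sampling).
    """
    rng = np.random.default_rng(spec.seed)
    b = spec.mu_log + math.sqrt(spec.sigma2_b) * rng.standard_normal(spec.n_workers)
    e = [
        math.sqrt(spec.sigma2_w) * rng.standard_normal(r)
        for r in spec.repeats_per_worker
    ]
    measurements: list[Measurement] = []
    t = 0
    for round_idx in range(max(spec.repeats_per_worker)):
        for i in range(spec.n_workers):
            if spec.repeats_per_worker[i] > round_idx:
                measurements.append(
                    Measurement(
                        seg_id=spec.seg_id,
                        worker_id=f"{spec.seg_id}-W{i + 1:03d}",
                        sample_date=spec.start_date + datetime.timedelta(days=t),
                        concentration=float(np.exp(b[i] + e[i][round_idx])),
                    )
                )
                t += 1
    return SEG(seg_id=spec.seg_id, measurements=tuple(measurements))


def _substream_seed(seed: int, *key: int) -> int:
    """Deterministic child seed for a keyed substream of the master seed."""
    return int(np.random.SeedSequence([seed, *key]).generate_state(1)[0])


def _draw_spec(
    seg_index: int,
    seed: int,
    with_repeats: bool,
    n_measurements: int,
    params: StudyParams,
) -> SEGSpec:
    rng = np.random.default_rng(_substream_seed(seed, seg_index, 0))
    lo, hi = params.gm_range
    gm = math.exp(rng.uniform(math.log(lo), math.log(hi)))
    gsd = rng.uniform(*params.gsd_range)
    sigma2_tot = math.log(gsd) ** 2
    rho = rng.uniform(*params.rho_b_range)
    if with_repeats:
        n_workers = int(rng.integers(2, max(3, n_measurements)))  # < n ⇒ repeats
        repeats = np.ones(n_workers, dtype=int)
        extras = rng.choice(n_workers, size=n_measurements - n_workers, replace=True)
        np.add.at(repeats, extras, 1)
    else:
        n_workers = n_measurements
        repeats = np.ones(n_workers, dtype=int)
    start = params.start_date + datetime.timedelta(days=int(rng.integers(0, 365)))
    return SEGSpec(
        seg_id=f"SEG{seg_index + 1:03d}",
        n_workers=n_workers,
        repeats_per_worker=tuple(int(r) for r in repeats),
        mu_log=math.log(gm),
        sigma2_b=rho * sigma2_tot,
        sigma2_w=(1.0 - rho) * sigma2_tot,
        start_date=start,
        seed=_substream_seed(seed, seg_index, 1),
    )


def generate_study(
    n_segs: int,
    n_with_repeats: int,
    params: StudyParams | None = None,
    seed: int = 0,
    total_measurements: int | None = None,
) -> list[SEG]:
    """Generate a full study of SEGs: deterministic given the seed.

    Exactly ``n_with_repeats`` SEGs (the first ones) contain at least one
    worker with repeated measurements; every SEG has at least 6
    measurements.  When ``total_measurements`` is given, SEG sizes are 6
    plus extras distributed from a study-level stream so that the exact
    total is hit (this is how the 210-SEG / 158-repeats / 1383-measurement
    reference fixture is built); otherwise sizes come from each SEG's own
    substream.
    """
    if params is None:
        params = StudyParams()
    if not (0 <= n_with_repeats <= n_segs):
        raise ValueError(
            f"n_with_repeats must lie in [0, n_segs], got "
            f"{n_with_repeats} with n_segs={n_segs}"
        )
    if n_segs < 1:
        raise ValueError("need at least one SEG")

    if total_measurements is not None:
        extras_total = total_measurements - 6 * n_segs
        if extras_total < 0:
            raise ValueError(
                f"total_measurements={total_measurements} cannot cover "
                f"{n_segs} SEGs of at least 6 measurements"
            )
        size_rng = np.random.default_rng(_substream_seed(seed, n_segs, 2))
        sizes = np.full(n_segs, 6, dtype=int)
        np.add.at(
            sizes, size_rng.choice(n_segs, size=extras_total, replace=True), 1
        )
    else:
        sizes = np.array(
            [
                6
                + int(
                    np.random.default_rng(
                        _substream_seed(seed, k, 3)
                    ).poisson(params.extra_measurements_mean)
                )
                for k in range(n_segs)
            ]
        )

    segs = []
    for k in range(n_segs):
        spec = _draw_spec(
            seg_index=k,
            seed=seed,
            with_repeats=k < n_with_repeats,
            n_measurements=int(sizes[k]),
            params=params,
        )
        segs.append(generate_seg(spec))
    return segs
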