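"""Domain types and I/O for similar-exposure-group (SEG) compliance testing.

A *measurement* is one full-shift personal air sample (concentration in
mg m⁻³) taken on a worker who belongs to a SEG — a group of workers assumed
to share a common exposure distribution.  Compliance with an occupational
exposure limit (OEL) is tested per SEG, so the central container here is the
:class:`SEG`, an ordered collection of :class:`Measurement` records with the
repeat structure (which workers were sampled more than once) made explicit.

CSV schema: ``seg_id,worker_id,sample_date,concentration`` with ISO-8601
dates and strictly positive concentrations.  Non-positive concentrations are
rejected, not imputed: every downstream test works on the log scale.
"""

from __future__ import annotations

import datetime
import enum
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Strategy",
    "Outcome",
    "Measurement",
    "OELSpec",
    "SEG",
    "ComplianceDecision",
    "ValidationError",
    "SchemaError",
    "InsufficientDataError",
    "NoRepeatsError",
    "read_measurements",
    "write_measurements",
    "build_segs",
    "select_preliminary_subset",
]

REQUIRED_COLUMNS = ("seg_id", "worker_id", "sample_date", "concentration")


class ValidationError(ValueError):
    """Input rows violated the measurement invariants."""


class SchemaError(ValueError):
    """Input file does not follow the expected CSV schema."""


class InsufficientDataError(ValueError):
    """Too few measurements for the requested operation."""


class NoRepeatsError(ValueError):
    """Operation requires at least one worker with repeated measurements."""


class Strategy(str, enum.Enum):
    """Compliance-testing strategy variants compared by the package."""

    EN689_1995_PRELIM = "en689_1995_prelim"
    EN689_2018_PRELIM = "en689_2018_prelim"
    EN689_1995_STAT = "en689_1995_stat"
    EN689_2018_STAT = "en689_2018_stat"
    BOHS_NVVA = "bohs_nvva"


#: Strategies whose small-sample screens may end without a final decision.
PRELIMINARY_STRATEGIES = frozenset(
    {Strategy.EN689_1995_PRELIM, Strategy.EN689_2018_PRELIM}
)


class Outcome(str, enum.Enum):
    COMPLIANCE = "compliance"
    UNCERTAIN = "uncertain"
    NON_COMPLIANCE = "non_compliance"


#: Severity ordering used by monotonicity properties.
OUTCOME_ORDER = {
    Outcome.COMPLIANCE: 0,
    Outcome.UNCERTAIN: 1,
    Outcome.NON_COMPLIANCE: 2,
}


@dataclass(frozen=True)
class Measurement:
    """One full-shift personal exposure measurement."""

    seg_id: str
    worker_id: str
    sample_date: datetime.date
    concentration: float

    def __post_init__(self) -> None:
        if not self.seg_id:
            raise ValidationError("seg_id must be non-empty")
        if not self.worker_id:
            raise ValidationError("worker_id must be non-empty")
        if not isinstance(self.sample_date, datetime.date):
            raise ValidationError("sample_date must be a datetime.date")
        if not (self.concentration > 0 and np.isfinite(self.concentration)):
            raise ValidationError(
                f"concentration must be a positive finite number, "
                f"got {self.concentration!r}"
            )


@dataclass(frozen=True)
class OELSpec:
    """Occupational exposure limit for one substance, in mg m⁻³."""

    substance: str = "respirable dust"
    oel: float = 1.0

    def __post_init__(self) -> None:
        if not (self.oel > 0 and np.isfinite(self.oel)):
            raise ValidationError(f"OEL must be positive, got {self.oel!r}")


@dataclass(frozen=True)
class SEG:
    """A similar exposure group: the unit of compliance testing.

    Measurements are stored in ascending ``sample_date`` order (ties keep
    input order), which is the order the preliminary-phase subsets are
    drawn in.
    """

    seg_id: str
    measurements: tuple[Measurement, ...]

    def __post_init__(self) -> None:
        for m in self.measurements:
            if m.seg_id != self.seg_id:
                raise ValidationError(
                    f"measurement seg_id {m.seg_id!r} != SEG id {self.seg_id!r}"
                )

    @property
    def n_measurements(self) -> int:
        return len(self.measurements)

    @property
    def n_workers(self) -> int:
        return len({m.worker_id for m in self.measurements})

    @property
    def worker_counts(self) -> Counter:
        return Counter(m.worker_id for m in self.measurements)

    @property
    def has_repeats(self) -> bool:
        """True iff at least one worker was sampled more than once."""
        return any(c >= 2 for c in self.worker_counts.values())

    @property
    def n_workers_with_repeats(self) -> int:
        return sum(1 for c in self.worker_counts.values() if c >= 2)

    def concentrations(self) -> np.ndarray:
        return np.array([m.concentration for m in self.measurements], dtype=float)


@dataclass(frozen=True)
class ComplianceDecision:
    """Strategy-tagged compliance outcome with its supporting statistic.

    ``statistic`` holds the quantity the decision was based on: the plug-in
    exceedance probability, the UTL₉₅,₇₀, or the individual-overexposure
    fraction theta; ``None`` for the threshold-only preliminary screens.
    """

    strategy: Strategy
    outcome: Outcome
    statistic: float | None = None
    n_used: int = 0

    def __post_init__(self) -> None:
        if (
            self.outcome is Outcome.UNCERTAIN
            and self.strategy not in PRELIMINARY_STRATEGIES
        ):
            raise ValidationError(
                "uncertain outcomes are only defined for preliminary strategies"
            )


def read_measurements(path) -> list[Measurement]:
    """Read measurements from a CSV file.

    The file must contain the columns ``seg_id``, ``worker_id``,
    ``sample_date`` (ISO-8601) and ``concentration`` (mg m⁻³, > 0).  Every
    offending row is reported by its (1-based, header-excluded) row number in
    a single :class:`ValidationError`.
    """
    try:
        frame = pd.read_csv(path, dtype={"seg_id": str, "worker_id": str})
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty input file: {path}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if len(frame) == 0:
        raise ValidationError(f"no measurement rows in {path}")

    measurements: list[Measurement] = []
    problems: list[str] = []
    for idx, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            date = datetime.date.fromisoformat(str(row.sample_date))
            conc = float(row.concentration)
            measurements.append(
                Measurement(
                    seg_id=str(row.seg_id),
                    worker_id=str(row.worker_id),
                    sample_date=date,
                    concentration=conc,
                )
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"row {idx}: {exc}")
    if problems:
        raise ValidationError(
            "invalid measurement rows:\n" + "\n".join(problems)
        )
    return measurements


def write_measurements(measurements: list[Measurement], path) -> None:
    """Write measurements to the four-column CSV schema."""
    frame = pd.DataFrame(
        {
            "seg_id": [m.seg_id for m in measurements],
            "worker_id": [m.worker_id for m in measurements],
            "sample_date": [m.sample_date.isoformat() for m in measurements],
            "concentration": [m.concentration for m in measurements],
        }
    )
    frame.to_csv(path, index=False)


def build_segs(measurements: list[Measurement]) -> list[SEG]:
    """Group measurements into SEGs by ``seg_id``.

    SEGs are returned in order of first appearance; within a SEG the
    measurements are sorted by sample date, date ties keeping input order.
    The result is a partition of the input.
    """
    if not measurements:
        raise ValidationError("cannot build SEGs from an empty measurement list")
    by_seg: dict[str, list[Measurement]] = {}
    for m in measurements:
        by_seg.setdefault(m.seg_id, []).append(m)
    segs = []
    for seg_id, group in by_seg.items():
        ordered = sorted(group, key=lambda m: m.sample_date)  # stable sort
        segs.append(SEG(seg_id=seg_id, measurements=tuple(ordered)))
    return segs


ALLOWED_PRELIMINARY_SIZES = frozenset({1, 3, 4, 5})


def select_preliminary_subset(seg: SEG, n: int) -> list[Measurement]:
    """The first *n* measurements of a SEG in sampling-date order.

    This is the progressive per-date selection used by the preliminary
    screens: the earliest ``n`` samples, same-day ties broken by input
    order.  Subsets nest: the n-subset is a prefix of the n'-subset for
    n < n'.
    """
    if n not in ALLOWED_PRELIMINARY_SIZES:
        raise ValueError(
            f"preliminary subset size must be one of "
            f"{sorted(ALLOWED_PRELIMINARY_SIZES)}, got {n}"
        )
    if seg.n_measurements < n:
        raise InsufficientDataError(
            f"SEG {seg.seg_id!r} has {seg.n_measurements} measurements, "
            f"need at least {n}"
        )
    ordered = sorted(seg.measurements, key=lambda m: m.sample_date)
    return list(ordered[:n])
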