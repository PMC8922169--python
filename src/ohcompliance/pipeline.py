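"""Run all compliance strategies over a dataset and tally the decisions.

Produces decision tables in the layout the three-strategy comparison is
usually reported in: one column per strategy variant (EN689:1995
preliminary from 1 or 3 samples; EN689:2018 preliminary from 3, 4 or 5;
the two statistical tests; the BOHS-NVvA test), one row per outcome
(compliance / uncertain compliance / non-compliance), cells formatted
``count (percent%)``.  Two subgroups are tallied: all SEGs, and the SEGs
with repeated measurements (the only ones the BOHS-NVvA test applies to).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import pandas as pd

from .data_model import (
    ComplianceDecision,
    OELSpec,
    Outcome,
    SEG,
    ValidationError,
    select_preliminary_subset,
)
from .individual import bohs_nvva_test
from .preliminary import preliminary_1995, preliminary_2018
from .statistical import (
    MIN_N_STATISTICAL,
    fit_lognormal,
    statistical_test_1995,
    statistical_test_2018,
)

__all__ = [
    "VARIANTS",
    "VARIANT_LABELS",
    "VariantTally",
    "SubgroupTable",
    "ComparisonTable",
    "decide_seg",
    "run_comparison",
    "write_report",
    "render_report",
]

logger = logging.getLogger(__name__)

#: strategy-variant keys in display order
VARIANTS = (
    "prelim_1995_n1",
    "prelim_1995_n3",
    "prelim_2018_n3",
    "prelim_2018_n4",
    "prelim_2018_n5",
    "stat_1995",
    "stat_2018",
    "bohs_nvva",
)

VARIANT_LABELS = {
    "prelim_1995_n1": "EN689:1995 prelim #1 <0.1 OEL",
    "prelim_1995_n3": "EN689:1995 prelim #3 <0.25 OEL",
    "prelim_2018_n3": "EN689:2018 prelim #3 <0.1 OEL",
    "prelim_2018_n4": "EN689:2018 prelim #4 <0.15 OEL",
    "prelim_2018_n5": "EN689:2018 prelim #5 <0.2 OEL",
    "stat_1995": "EN689:1995 stat 5% exc.",
    "stat_2018": "EN689:2018 stat UTL95,70",
    "bohs_nvva": "BOHS-NVvA I.C.",
}

OUTCOME_ROWS = (Outcome.COMPLIANCE, Outcome.UNCERTAIN, Outcome.NON_COMPLIANCE)
OUTCOME_LABELS = {
    Outcome.COMPLIANCE: "Compliance",
    Outcome.UNCERTAIN: "Uncertain compliance",
    Outcome.NON_COMPLIANCE: "Non-compliance",
}


@dataclass
class VariantTally:
    """Outcome counts for one strategy variant within one subgroup."""

    variant: str
    counts: dict[Outcome, int] = field(
        default_factory=lambda: {o: 0 for o in OUTCOME_ROWS}
    )

    def add(self, outcome: Outcome) -> None:
        self.counts[outcome] += 1

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def percentage(self, outcome: Outcome) -> float:
        return 100.0 * self.counts[outcome] / self.n if self.n else 0.0


@dataclass
class SubgroupTable:
    """Decision tallies for one subgroup of SEGs across its applicable variants."""

    label: str
    n_segs: int
    tallies: dict[str, VariantTally]


@dataclass
class ComparisonTable:
    """Full comparison output: all-SEGs and repeats-only subgroup tables.

    ``skipped`` lists SEG ids that were too small for any test (fewer than
    six measurements) and were excluded from every denominator.
    """

    subgroups: list[SubgroupTable]
    skipped: list[str] = field(default_factory=list)


def decide_seg(seg: SEG, oel: OELSpec) -> dict[str, ComplianceDecision]:
    """All applicable strategy decisions for one SEG (needs ≥ 6 measurements).

    The preliminary variants use the date-ordered subsets of the required
    sizes; the statistical tests use every measurement; the BOHS-NVvA test
    runs only when the SEG has repeated measurements.
    """
    decisions: dict[str, ComplianceDecision] = {}
    values = {
        n: [m.concentration for m in select_preliminary_subset(seg, n)]
        for n in (1, 3, 4, 5)
    }
    decisions["prelim_1995_n1"] = preliminary_1995(values[1], oel)
    decisions["prelim_1995_n3"] = preliminary_1995(values[3], oel)
    decisions["prelim_2018_n3"] = preliminary_2018(values[3], oel)
    decisions["prelim_2018_n4"] = preliminary_2018(values[4], oel)
    decisions["prelim_2018_n5"] = preliminary_2018(values[5], oel)
    fit = fit_lognormal(seg.concentrations())
    decisions["stat_1995"] = statistical_test_1995(fit, oel)
    decisions["stat_2018"] = statistical_test_2018(fit, oel)
    if seg.has_repeats:
        result = bohs_nvva_test(seg, oel)
        decisions["bohs_nvva"] = result.decision
        logger.debug(
            "SEG %s: rho_B=%.3f route=%s theta=%.3f -> %s",
            seg.seg_id,
            result.rho_b,
            result.route.value,
            result.theta,
            result.decision.outcome.value,
        )
    for variant, dec in decisions.items():
        logger.debug(
            "SEG %s %s: %s (statistic=%s, n=%d)",
            seg.seg_id,
            variant,
            dec.outcome.value,
            f"{dec.statistic:.4g}" if dec.statistic is not None else "-",
            dec.n_used,
        )
    return decisions


def run_comparison(
    segs: list[SEG],
    oel: OELSpec,
    variants: tuple[str, ...] = VARIANTS,
) -> ComparisonTable:
    """Apply every strategy variant to every eligible SEG and tally outcomes.

    SEGs with fewer than six measurements are reported in ``skipped`` and
    excluded.  The BOHS-NVvA column is tallied over the repeats-only
    subgroup — its denominator is the number of SEGs with repeated
    measurements, the other columns use the full subgroup.
    """
    if not segs:
        raise ValidationError("no SEGs to analyse")
    unknown = set(variants) - set(VARIANTS)
    if unknown:
        raise ValueError(f"unknown strategy variants: {sorted(unknown)}")

    eligible = [s for s in segs if s.n_measurements >= MIN_N_STATISTICAL]
    skipped = [s.seg_id for s in segs if s.n_measurements < MIN_N_STATISTICAL]
    for seg_id in skipped:
        logger.warning("SEG %s skipped: fewer than %d measurements", seg_id, MIN_N_STATISTICAL)
    if not eligible:
        raise ValidationError("no SEG has the minimum of six measurements")

    repeats_only = [s for s in eligible if s.has_repeats]
    group_variants = tuple(v for v in variants if v != "bohs_nvva")
    subgroups = [
        SubgroupTable(
            label="all_segs",
            n_segs=len(eligible),
            tallies={v: VariantTally(v) for v in group_variants},
        ),
        SubgroupTable(
            label="repeats_only",
            n_segs=len(repeats_only),
            tallies={v: VariantTally(v) for v in variants},
        ),
    ]
    all_table, repeats_table = subgroups

    for seg in eligible:
        decisions = decide_seg(seg, oel)
        for variant in group_variants:
            all_table.tallies[variant].add(decisions[variant].outcome)
        if seg.has_repeats:
            for variant in variants:
                if variant in decisions:
                    repeats_table.tallies[variant].add(decisions[variant].outcome)
    return ComparisonTable(subgroups=subgroups, skipped=skipped)


def _format_cell(count: int, n: int) -> str:
    pct = 100.0 * count / n if n else 0.0
    return f"{count} ({int(pct + 0.5)}%)"  # round half up, Table-style display


def _table_frame(sub: SubgroupTable) -> pd.DataFrame:
    """Long-form machine-readable frame: one row per variant × outcome."""
    rows = []
    for variant, tally in sub.tallies.items():
        for outcome in OUTCOME_ROWS:
            rows.append(
                {
                    "subgroup": sub.label,
                    "variant": variant,
                    "outcome": outcome.value,
                    "count": tally.counts[outcome],
                    "denominator": tally.n,
                    "percent": tally.percentage(outcome),
                    "display": _format_cell(tally.counts[outcome], tally.n),
                }
            )
    return pd.DataFrame(rows)


def render_report(table: ComparisonTable, fmt: str = "markdown") -> str:
    """Serialize a comparison table deterministically as CSV or markdown."""
    if fmt == "csv":
        frames = [_table_frame(sub) for sub in table.subgroups]
        buf = io.StringIO()
        pd.concat(frames, ignore_index=True).to_csv(buf, index=False)
        return buf.getvalue()
    if fmt == "markdown":
        lines: list[str] = []
        for sub in table.subgroups:
            variants = list(sub.tallies)
            lines.append(f"## {sub.label} (n = {sub.n_segs} SEGs)")
            lines.append("")
            header = ["Decision"] + [VARIANT_LABELS[v] for v in variants]
            lines.append("| " + " | ".join(header) + " |")
            lines.append("|" + "---|" * len(header))
            for outcome in OUTCOME_ROWS:
                cells = [OUTCOME_LABELS[outcome]]
                for v in variants:
                    tally = sub.tallies[v]
                    cells.append(_format_cell(tally.counts[outcome], tally.n))
                lines.append("| " + " | ".join(cells) + " |")
            lines.append("")
        if table.skipped:
            lines.append(
                f"Skipped (fewer than {MIN_N_STATISTICAL} measurements): "
                + ", ".join(table.skipped)
            )
            lines.append("")
        return "\n".join(lines)
    raise ValueError(f"unknown report format: {fmt!r}")


def write_report(table: ComparisonTable, path, fmt: str = "markdown") -> None:
    """Write a rendered report to ``path`` (format 'csv' or 'markdown')."""
    text = render_report(table, fmt)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)
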