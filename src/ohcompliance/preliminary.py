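"""Preliminary (screening) compliance tests of EN689:1995 and EN689:2018.

Both standards allow an early decision from a handful of measurements by
comparing each result with a fraction of the OEL.  The screens differ:

* EN689:1995 — 1 measurement below 0.1·OEL, or 3 measurements all below
  0.25·OEL, declare compliance.
* EN689:2018 — 3, 4 or 5 measurements all below 0.1·OEL, 0.15·OEL or
  0.2·OEL respectively declare compliance.

Any single result above the OEL is immediate non-compliance under either
standard.  Anything in between is *uncertain compliance*: no decision yet,
more sampling needed.  Screen inequalities are strict (a value exactly at a
threshold does not pass the screen), matching the "<" the screens are
stated with; a value exactly at the OEL is uncertain, not non-compliant.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np

from .data_model import ComplianceDecision, OELSpec, Outcome, Strategy

__all__ = [
    "SCREEN_FRACTIONS_1995",
    "SCREEN_FRACTIONS_2018",
    "preliminary_1995",
    "preliminary_2018",
]

#: compliance screen fraction of the OEL, keyed by number of measurements
SCREEN_FRACTIONS_1995 = {1: 0.10, 3: 0.25}
SCREEN_FRACTIONS_2018 = {3: 0.10, 4: 0.15, 5: 0.20}


def _screen(
    values: Sequence[float],
    oel: OELSpec,
    fractions: dict[int, float],
    strategy: Strategy,
) -> ComplianceDecision:
    vals = np.asarray(values, dtype=float)
    n = vals.size
    if n not in fractions:
        raise ValueError(
            f"{strategy.value} accepts n in {sorted(fractions)}, got {n}"
        )
    if not np.all(vals > 0):
        raise ValueError("concentrations must be strictly positive")
    if np.any(vals > oel.oel):
        outcome = Outcome.NON_COMPLIANCE
    elif np.all(vals < fractions[n] * oel.oel):
        outcome = Outcome.COMPLIANCE
    else:
        outcome = Outcome.UNCERTAIN
    return ComplianceDecision(strategy=strategy, outcome=outcome, n_used=n)


def preliminary_1995(values: Sequence[float], oel: OELSpec) -> ComplianceDecision:
    """EN689:1995 preliminary screen from 1 or 3 measurements.

    Compliance if the single value is below 0.1·OEL (n=1) or all three are
    below 0.25·OEL (n=3); non-compliance if any value exceeds the OEL;
    otherwise uncertain.
    """
    return _screen(values, oel, SCREEN_FRACTIONS_1995, Strategy.EN689_1995_PRELIM)


def preliminary_2018(values: Sequence[float], oel: OELSpec) -> ComplianceDecision:
    """EN689:2018 preliminary screen from 3, 4 or 5 measurements.

    Compliance if all values are below 0.1·OEL (n=3), 0.15·OEL (n=4) or
    0.2·OEL (n=5); non-compliance if any value exceeds the OEL; otherwise
    uncertain.
    """
    return _screen(values, oel, SCREEN_FRACTIONS_2018, Strategy.EN689_2018_PRELIM)
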