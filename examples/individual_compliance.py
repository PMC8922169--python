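"""BOHS-NVvA individual compliance test on a SEG with repeated measurements.

Decomposes log-exposure variability into between-worker and within-worker
components; when workers genuinely differ (between-worker share ≥ 20%) the
decision is based on theta, the fraction of workers whose personal 95th
percentile exceeds the OEL — compliance needs more than 80% of members
below it.
"""

import datetime

from ohcompliance import Measurement, OELSpec, SEG, bohs_nvva_test

oel = OELSpec(oel=1.0)

# three workers, repeated full-shift samples; worker C runs notably higher
raw = {
    "A": [0.10, 0.14, 0.12],
    "B": [0.22, 0.18],
    "C": [0.75, 0.95, 0.85],
}
measurements = []
day = datetime.date(2020, 3, 2)
for worker, values in raw.items():
    for v in values:
        measurements.append(
            Measurement("demo", worker, day, v)
        )
        day += datetime.timedelta(days=1)
seg = SEG("demo", tuple(measurements))

res = bohs_nvva_test(seg, oel)
vc = res.components
print(f"between-worker variance sigma2_B = {vc.sigma2_b:.3f}")
print(f"within-worker variance  sigma2_W = {vc.sigma2_w:.3f}")
print(f"between-worker share rho_B = {res.rho_b:.2f} -> route: {res.route.value}")
print(f"theta (workers overexposed at their own 95th pct) = {res.theta:.3f}")
print(f"decision: {res.decision.outcome.value}")
# rho_B above 0.20 routes the SEG to the individual criterion: theta is
# the estimated fraction of overexposed workers, and at 0.17 (< 0.20, i.e.
# more than 80% of members comply) the SEG scrapes through — worker C's
# high exposures nearly tip it.
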