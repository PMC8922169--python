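import datetime

import pytest

from ohcompliance import SEG, Measurement, OELSpec


def make_seg(
    seg_id: str,
    worker_values: dict[str, list[float]],
    start: datetime.date = datetime.date(2020, 1, 1),
) -> SEG:
    """Build a SEG from per-worker concentration lists, round-robin dates."""
    measurements = []
    t = 0
    max_rep = max(len(v) for v in worker_values.values())
    for r in range(max_rep):
        for worker, vals in worker_values.items():
            if len(vals) > r:
                measurements.append(
                    Measurement(
                        seg_id=seg_id,
                        worker_id=worker,
                        sample_date=start + datetime.timedelta(days=t),
                        concentration=vals[r],
                    )
                )
                t += 1
    return SEG(seg_id=seg_id, measurements=tuple(measurements))


@pytest.fixture
def oel() -> OELSpec:
    return OELSpec(substance="respirable dust", oel=1.0)
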