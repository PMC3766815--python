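from datetime import datetime

import numpy as np
import pytest

from circafly import ActivitySeries, LightSchedule

T0 = datetime(2024, 1, 1, 8, 0, 0)


@pytest.fixture
def ld_dd_schedule() -> LightSchedule:
    """3 entrained days then 7 free-running days, 12:12 photoperiod."""
    return LightSchedule(n_days_ld=3, n_days_dd=7)


@pytest.fixture
def make_series():
    """Factory for hand-built activity series on the standard origin."""

    def _make(counts, bin_min=5, schedule=None, status=None, fly_id="fly001"):
        return ActivitySeries(fly_id, T0, bin_min, np.asarray(counts),
                              schedule=schedule, status=status)

    return _make
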