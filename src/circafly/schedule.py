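"""Light schedules for entrainment experiments.

A :class:`LightSchedule` describes a block of light:dark (LD) days followed
by a block of constant-darkness (DD) days, the standard design for
free-running circadian assays.  Time inside the package is minutes from the
start of recording, which coincides with lights-on (ZT0) of the first LD
day; Zeitgeber time is derived from that origin (ZT0 = lights-on).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MIN_PER_DAY = 1440


@dataclass(frozen=True)
class LightSchedule:
    """An LD block followed contiguously by a DD block.

    Parameters
    ----------
    photoperiod_h
        Hours of light per LD day (0 < photoperiod_h < 24).  ZT0 is
        lights-on, so lights-off falls at ZT ``photoperiod_h``.
    n_days_ld, n_days_dd
        Number of entrained (LD) and free-running (DD) days.
    lights_on_clock
        Wall-clock time of lights-on, ``"HH:MM"``; only used to stamp
        absolute timestamps on monitor files.
    """

    photoperiod_h: float = 12.0
    n_days_ld: int = 3
    n_days_dd: int = 7
    lights_on_clock: str = "08:00"

    def __post_init__(self) -> None:
        if not 0 < self.photoperiod_h < 24:
            raise ValueError("photoperiod_h must be in (0, 24)")
        if self.n_days_ld < 0 or self.n_days_dd < 0:
            raise ValueError("day counts must be non-negative")
        if self.n_days_ld + self.n_days_dd == 0:
            raise ValueError("schedule must span at least one day")

    @property
    def total_days(self) -> int:
        return self.n_days_ld + self.n_days_dd

    @property
    def duration_min(self) -> int:
        return self.total_days * MIN_PER_DAY

    @property
    def photoperiod_min(self) -> float:
        return self.photoperiod_h * 60.0

    def is_light(self, minute):
        """Vectorized lights-on predicate for minutes from recording start."""
        m = np.asarray(minute)
        day = m // MIN_PER_DAY
        return (day < self.n_days_ld) & (m % MIN_PER_DAY < self.photoperiod_min)

    def lights_on_times_min(self) -> list[float]:
        """Lights-on event times (minutes from start), one per LD day."""
        return [float(d * MIN_PER_DAY) for d in range(self.n_days_ld)]

    def lights_off_times_min(self) -> list[float]:
        """Lights-off event times (minutes from start), one per LD day."""
        return [
            float(d * MIN_PER_DAY + self.photoperiod_min)
            for d in range(self.n_days_ld)
        ]

    def aligned_to(self, bin_min: int) -> bool:
        """True when every light transition falls on a bin boundary."""
        return (
            MIN_PER_DAY % bin_min == 0
            and float(self.photoperiod_min) % bin_min == 0
        )
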