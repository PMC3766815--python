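"""Trikinetics DAM monitor file I/O and per-fly activity series.

Exactly one dialect is supported, bit-exactly: the 42-column DAM System 3
style text file, one tab-separated row per reading with

    record index, date (DD Mon YY), time (HH:MM:SS), monitor status code,
    five device fields, a light-sensor field, then 32 channel counts.

Other Trikinetics variants are rejected loudly (dialect proliferation is
the main corruption source in DAM parsing).  A monitor status code of 1
means a valid reading; rows with any other code are retained but flagged,
never silently dropped, and analyses exclude flagged bins.

Time is kept internally as minutes from the first bin start; bins are
half-open ``[start, start + bin_min)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np

from .schedule import MIN_PER_DAY, LightSchedule

N_CHANNELS = 32
N_COLUMNS = 42
STATUS_OK = 1


class DAMParseError(ValueError):
    """Raised when a monitor file deviates from the supported dialect."""


@dataclass
class ActivitySeries:
    """One fly's beam-break counts on a uniform time grid.

    ``status`` holds the per-bin monitor status code (1 = OK); flagged bins
    carry the raw non-OK code so nothing is lost on round trip.
    """

    fly_id: str
    t0: datetime
    bin_min: int
    counts: np.ndarray
    schedule: LightSchedule | None = None
    status: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative integers")
        if self.bin_min not in (1, 5):
            raise ValueError("bin_min must be 1 or 5 minutes")
        if self.status is None:
            self.status = np.full(self.counts.shape, STATUS_OK, dtype=np.int64)
        else:
            self.status = np.asarray(self.status, dtype=np.int64)
        if self.status.shape != self.counts.shape:
            raise ValueError("status must match counts length")

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def duration_min(self) -> int:
        return self.n_bins * self.bin_min

    @property
    def times_min(self) -> np.ndarray:
        """Bin start times in minutes from recording start."""
        return np.arange(self.n_bins, dtype=np.int64) * self.bin_min

    @property
    def ok_mask(self) -> np.ndarray:
        return self.status == STATUS_OK

    def replace(self, **kw) -> "ActivitySeries":
        return dataclasses.replace(self, **kw)


def _parse_timestamp(date_s: str, time_s: str, lineno: int) -> datetime:
    try:
        return datetime.strptime(f"{date_s} {time_s}", "%d %b %y %H:%M:%S")
    except ValueError as exc:
        raise DAMParseError(f"line {lineno}: unparseable date/time "
                            f"{date_s!r} {time_s!r}") from exc


def read_dam_monitor(
    path, schedule: LightSchedule | None = None
) -> tuple[list[ActivitySeries], dict]:
    """Read a 42-column DAM monitor file into 32 per-channel series.

    Returns the 32 :class:`ActivitySeries` (channels 1..32) and file-level
    metadata (t0, bin width, row count, distinct status codes).  The bin
    width is inferred from consecutive timestamps and must be constant.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != N_COLUMNS:
                raise DAMParseError(
                    f"line {lineno}: expected {N_COLUMNS} tab-separated "
                    f"columns, found {len(fields)} (unsupported dialect)"
                )
            ts = _parse_timestamp(fields[1], fields[2], lineno)
            try:
                status = int(fields[3])
                counts = [int(v) for v in fields[10:42]]
            except ValueError as exc:
                raise DAMParseError(
                    f"line {lineno}: non-integer status or count field"
                ) from exc
            if any(c < 0 for c in counts):
                raise DAMParseError(f"line {lineno}: negative count")
            rows.append((ts, status, counts))
    if not rows:
        raise DAMParseError(f"{path}: no data rows")

    times = [r[0] for r in rows]
    if len(rows) > 1:
        deltas = {
            (b - a).total_seconds() for a, b in zip(times[:-1], times[1:])
        }
        if len(deltas) != 1:
            raise DAMParseError(
                f"{path}: non-uniform timestamp spacing {sorted(deltas)}"
            )
        bin_min = next(iter(deltas)) / 60.0
        if bin_min not in (1.0, 5.0):
            raise DAMParseError(f"{path}: unsupported bin width {bin_min} min")
        bin_min = int(bin_min)
    else:
        bin_min = 5  # single row: width unknowable; default protocol width

    status_col = np.array([r[1] for r in rows], dtype=np.int64)
    count_mat = np.array([r[2] for r in rows], dtype=np.int64)
    stem = path.stem
    series = [
        ActivitySeries(
            fly_id=f"{stem}#{ch + 1:02d}",
            t0=times[0],
            bin_min=bin_min,
            counts=count_mat[:, ch],
            schedule=schedule,
            status=status_col.copy(),
        )
        for ch in range(N_CHANNELS)
    ]
    meta = {
        "path": str(path),
        "t0": times[0],
        "bin_min": bin_min,
        "n_rows": len(rows),
        "status_codes": sorted(set(status_col.tolist())),
    }
    return series, meta


def write_dam_monitor(series: list[ActivitySeries], path) -> None:
    """Write up to 32 series sharing one grid as a 42-column monitor file.

    Unused channels are emitted as all-zero columns.  The per-row status
    code is taken from the (identical) per-bin status of the series.
    """
    if not series:
        raise ValueError("cannot write an empty channel set")
    if len(series) > N_CHANNELS:
        raise ValueError(f"at most {N_CHANNELS} channels per monitor file")
    first = series[0]
    for s in series[1:]:
        if s.bin_min != first.bin_min:
            raise ValueError("mixed bin widths in one monitor file")
        if s.n_bins != first.n_bins or s.t0 != first.t0:
            raise ValueError("all series must share one time grid")
        if not np.array_equal(s.status, first.status):
            raise ValueError("per-bin status must agree across channels")

    n = first.n_bins
    counts = np.zeros((n, N_CHANNELS), dtype=np.int64)
    for ch, s in enumerate(series):
        counts[:, ch] = s.counts
    sched = first.schedule
    light = (
        sched.is_light(first.times_min).astype(int)
        if sched is not None
        else np.zeros(n, dtype=int)
    )
    with open(path, "w") as fh:
        for i in range(n):
            ts = first.t0 + timedelta(minutes=int(i * first.bin_min))
            fields = [
                str(i + 1),
                ts.strftime("%d %b %y"),
                ts.strftime("%H:%M:%S"),
                str(int(first.status[i])),
                "0", "0", "0", "0", "0",
                str(int(light[i])),
            ] + [str(int(c)) for c in counts[i]]
            fh.write("\t".join(fields) + "\n")


def rebin_series(series: ActivitySeries, new_bin_min: int) -> ActivitySeries:
    """Sum counts into coarser bins; total activity is conserved exactly.

    Downsampling only: ``new_bin_min`` must be an integer multiple of the
    current width and the series length divisible by the factor.
    """
    if new_bin_min == series.bin_min:
        return series.replace(counts=series.counts.copy(),
                              status=series.status.copy())
    if new_bin_min % series.bin_min != 0 or new_bin_min < series.bin_min:
        raise ValueError(
            f"target bin {new_bin_min} min is not an integer multiple of "
            f"{series.bin_min} min (downsampling only)"
        )
    factor = new_bin_min // series.bin_min
    if series.n_bins % factor != 0:
        raise ValueError("series length not divisible by rebin factor")
    counts = series.counts.reshape(-1, factor).sum(axis=1)
    grouped = series.status.reshape(-1, factor)
    # a coarse bin is OK only if every constituent fine bin was OK
    status = np.where((grouped == STATUS_OK).all(axis=1),
                      STATUS_OK, grouped.max(axis=1))
    return series.replace(bin_min=new_bin_min, counts=counts, status=status)


def slice_dd(series: ActivitySeries) -> ActivitySeries:
    """Restrict a series to its constant-darkness (DD) days.

    Rhythm analysis operates on free-running data only; this drops the LD
    entrainment block.  The returned series carries an all-DD schedule.
    """
    sched = series.schedule
    if sched is None:
        raise ValueError("series has no light schedule attached")
    if sched.n_days_dd < 1:
        raise ValueError("schedule has no DD days to slice")
    start_min = sched.n_days_ld * MIN_PER_DAY
    start = start_min // series.bin_min
    if start_min % series.bin_min != 0:
        raise ValueError("LD block boundary does not align with bin grid")
    if start >= series.n_bins:
        raise ValueError("recording ends before the DD block starts")
    end = min(series.n_bins, sched.duration_min // series.bin_min)
    new_sched = dataclasses.replace(sched, n_days_ld=0)
    return series.replace(
        t0=series.t0 + timedelta(minutes=start_min),
        counts=series.counts[start:end].copy(),
        status=series.status[start:end].copy(),
        schedule=new_sched,
    )
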