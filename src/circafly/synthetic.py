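"""Synthetic datasets with planted ground truth for every pipeline stage.

Each generator is a pure function of its spec (including the seed): the
same spec yields bit-identical data.  Every dataset comes with a
machine-readable truth record sufficient to score the downstream analysis
(planted rhythmicity and periods, startle magnitudes, lifespans, planted
differentially expressed genes, reference-concordant genes).

What is emulated, per input class:

* activity -- Poisson beam-break counts per bin whose rate carries a
  rectified-cosine circadian component for rhythmic flies, a lights-on
  masking multiplier during LD days, and startle counts spread uniformly
  over the 10 min after each light transition;
* luminescence -- a linearly decaying mesor modulated by a cosine, plus
  Gaussian noise;
* survival -- integer lifespans from a discretized Weibull whose discrete
  median equals the requested median, right-censored at the horizon;
* expression -- Gaussian log2 intensities with additive gene baseline,
  timepoint effect, planted genotype effects, and a below-floor gene
  subset, together with a reference fold-change table in which a
  controlled fraction of planted genes escapes the reference's 99%
  interval with matching sign.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .dam import ActivitySeries
from .expression import ExpressionStudy
from .luciferase import LuciferaseTrace
from .schedule import MIN_PER_DAY, LightSchedule
from .survival import SurvivalCohort

STARTLE_WINDOW_MIN = 10
T0 = datetime(2024, 1, 1, 8, 0, 0)  # nominal lights-on wall-clock origin


class ScheduleMismatchError(ValueError):
    """Light-transition times do not align with the bin grid."""


# ---------------------------------------------------------------------------
# activity


@dataclass(frozen=True)
class ActivitySimSpec:
    """Conditions for a DAM-style locomotor simulation.

    ``modulation_depth`` is the peak-to-mesor ratio of the rectified-cosine
    circadian rate component; ``day_multiplier`` is the lights-on masking
    multiplier applied during LD days; ``startle_on``/``startle_off`` are
    extra expected counts spread uniformly over the 10 min after each
    transition.
    """

    n_flies: int = 32
    fraction_rhythmic: float = 1.0
    period_h: float = 24.0
    phase_h: float = 0.0
    baseline_rate: float = 0.5        # expected counts per minute
    modulation_depth: float = 3.0
    day_multiplier: float = 4.5
    startle_on: float = 8.0
    startle_off: float = 6.0
    bin_min: int = 5
    n_days_ld: int = 3
    n_days_dd: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_flies < 1:
            raise ValueError("n_flies must be positive")
        if not 0.0 <= self.fraction_rhythmic <= 1.0:
            raise ValueError("fraction_rhythmic must be in [0, 1]")
        if self.period_h <= 0 or not 0 <= self.phase_h < self.period_h:
            raise ValueError("need period_h > 0 and phase_h in [0, period_h)")
        for name in ("baseline_rate", "modulation_depth", "day_multiplier",
                     "startle_on", "startle_off"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.bin_min not in (1, 5):
            raise ValueError("bin_min must be 1 or 5")

    @property
    def n_rhythmic(self) -> int:
        return int(round(self.fraction_rhythmic * self.n_flies))


def default_schedule(spec: ActivitySimSpec) -> LightSchedule:
    return LightSchedule(n_days_ld=spec.n_days_ld, n_days_dd=spec.n_days_dd)


def _startle_rate(schedule: LightSchedule, times_min: np.ndarray,
                  bin_min: int, startle_on: float, startle_off: float
                  ) -> np.ndarray:
    """Expected extra counts per bin from post-transition startles."""
    extra = np.zeros(times_min.size)
    for amount, events in (
        (startle_on, schedule.lights_on_times_min()),
        (startle_off, schedule.lights_off_times_min()),
    ):
        if amount == 0:
            continue
        for ev in events:
            if ev % bin_min != 0:
                raise ScheduleMismatchError(
                    f"transition at {ev} min does not align with "
                    f"{bin_min}-min bins"
                )
            starts = times_min
            overlap = (np.minimum(starts + bin_min, ev + STARTLE_WINDOW_MIN)
                       - np.maximum(starts, ev))
            overlap = np.clip(overlap, 0, None)
            extra += amount * overlap / STARTLE_WINDOW_MIN
    return extra


def expected_activity_rate(spec: ActivitySimSpec, schedule: LightSchedule,
                           rhythmic: bool) -> np.ndarray:
    """Expected counts per bin for one fly (the Poisson rate vector)."""
    n_bins = schedule.duration_min // spec.bin_min
    t_min = np.arange(n_bins, dtype=float) * spec.bin_min
    # the circadian component is evaluated at bin midpoints: that keeps the
    # rectified-cosine mass split exactly evenly across the 12:12 day/night
    # halves (so the planted day/night ratio equals day_multiplier)
    t_h = (t_min + spec.bin_min / 2.0) / 60.0
    rate = np.full(n_bins, spec.baseline_rate * spec.bin_min)
    if rhythmic and spec.modulation_depth > 0:
        circ = np.cos(2 * np.pi * (t_h - spec.phase_h) / spec.period_h)
        rate *= 1.0 + spec.modulation_depth * np.maximum(0.0, circ)
    light = schedule.is_light(t_min)
    rate = np.where(light, rate * spec.day_multiplier, rate)
    rate += _startle_rate(schedule, t_min, spec.bin_min,
                          spec.startle_on, spec.startle_off)
    return rate


def simulate_activity(
    spec: ActivitySimSpec, schedule: LightSchedule | None = None,
    id_prefix: str = "fly",
) -> tuple[list[ActivitySeries], pd.DataFrame]:
    """Simulate a cohort of DAM activity series plus the per-fly truth table."""
    if schedule is None:
        schedule = default_schedule(spec)
    if (schedule.n_days_ld != spec.n_days_ld
            or schedule.n_days_dd != spec.n_days_dd):
        raise ScheduleMismatchError("schedule duration differs from spec")
    if not schedule.aligned_to(spec.bin_min):
        raise ScheduleMismatchError(
            "light transitions do not fall on bin boundaries"
        )
    rng = np.random.default_rng(spec.seed)
    rate_rhythmic = expected_activity_rate(spec, schedule, rhythmic=True)
    rate_flat = expected_activity_rate(spec, schedule, rhythmic=False)
    series, truth_rows = [], []
    for i in range(spec.n_flies):
        rhythmic = i < spec.n_rhythmic
        rate = rate_rhythmic if rhythmic else rate_flat
        counts = rng.poisson(rate)
        fly_id = f"{id_prefix}{i + 1:03d}"
        series.append(ActivitySeries(fly_id, T0, spec.bin_min, counts,
                                     schedule=schedule))
        truth_rows.append({
            "fly_id": fly_id,
            "rhythmic": rhythmic,
            "period_h": spec.period_h if rhythmic else np.nan,
            "phase_h": spec.phase_h if rhythmic else np.nan,
        })
    return series, pd.DataFrame(truth_rows).set_index("fly_id")


# ---------------------------------------------------------------------------
# luciferase


@dataclass(frozen=True)
class LuciferaseSimSpec:
    """Conditions for a decaying oscillatory bioluminescence simulation."""

    n_flies: int = 16
    mesor0: float = 1000.0            # luminescence units at t = 0
    decay_per_h: float = 3.0
    rel_amplitude: float = 0.3
    period_h: float = 24.0
    phase_h: float = 14.0             # reporter acrophase, early night
    noise_sd: float = 25.0
    sample_interval_h: float = 1.0
    n_days: int = 5
    level_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_flies < 1 or self.n_days < 1:
            raise ValueError("n_flies and n_days must be positive")
        if not 0.0 <= self.rel_amplitude < 1.0:
            raise ValueError("rel_amplitude must be in [0, 1)")
        if self.decay_per_h < 0 or self.noise_sd < 0 or self.level_scale <= 0:
            raise ValueError("decay, noise and level_scale must be valid")
        duration = self.n_days * 24.0
        if self.mesor0 - self.decay_per_h * duration <= 0:
            raise ValueError(
                "emission would go non-positive before the run ends"
            )


def luciferase_expected(spec: LuciferaseSimSpec, times_h: np.ndarray
                        ) -> np.ndarray:
    trend = spec.mesor0 - spec.decay_per_h * times_h
    osc = 1.0 + spec.rel_amplitude * np.cos(
        2 * np.pi * (times_h - spec.phase_h) / spec.period_h)
    return spec.level_scale * trend * osc


def simulate_luciferase(
    spec: LuciferaseSimSpec, id_prefix: str = "fly"
) -> tuple[list[LuciferaseTrace], pd.DataFrame]:
    """Simulate per-fly luminescence traces plus the truth table."""
    rng = np.random.default_rng(spec.seed)
    times = np.arange(0.0, spec.n_days * 24.0, spec.sample_interval_h)
    expected = luciferase_expected(spec, times)
    traces, rows = [], []
    for i in range(spec.n_flies):
        noise = rng.normal(0.0, spec.noise_sd, size=times.size) \
            if spec.noise_sd > 0 else np.zeros(times.size)
        fly_id = f"{id_prefix}{i + 1:03d}"
        traces.append(LuciferaseTrace(fly_id, times.copy(), expected + noise,
                                      alive=True))
        rows.append({
            "fly_id": fly_id,
            "mesor0": spec.level_scale * spec.mesor0,
            "decay_per_h": spec.level_scale * spec.decay_per_h,
            "rel_amplitude": spec.rel_amplitude,
            "period_h": spec.period_h,
            "phase_h": spec.phase_h,
            "level_scale": spec.level_scale,
        })
    return traces, pd.DataFrame(rows).set_index("fly_id")


# ---------------------------------------------------------------------------
# survival


@dataclass(frozen=True)
class SurvivalSimSpec:
    """Conditions for a vial-cohort lifespan simulation.

    Lifespans are ``ceil`` of a continuous Weibull whose median is set to
    ``median_lifespan_d - 0.5``, which makes the median of the resulting
    integer-day distribution exactly ``median_lifespan_d`` (and reproduces
    the all-die-on-the-median-day deterministic limit as shape grows).
    """

    n_vials: int = 3
    flies_per_vial: int = 20
    median_lifespan_d: int = 6
    shape: float = 3.0
    horizon_d: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_vials, self.flies_per_vial, self.horizon_d) < 1:
            raise ValueError("counts and horizon must be positive")
        if self.median_lifespan_d < 1 or self.shape <= 0:
            raise ValueError("median and shape must be positive")


def simulate_survival(
    spec: SurvivalSimSpec, genotype: str = "cohort"
) -> tuple[SurvivalCohort, dict]:
    """Simulate a cohort's vial alive-counts plus the per-fly lifespan truth."""
    heavy_censoring = spec.median_lifespan_d > spec.horizon_d
    if heavy_censoring:
        import warnings

        warnings.warn(
            "median lifespan exceeds the horizon: curve will be heavily "
            "censored", stacklevel=2,
        )
    rng = np.random.default_rng(spec.seed)
    scale = (spec.median_lifespan_d - 0.5) / np.log(2.0) ** (1.0 / spec.shape)
    vials, lifespans = [], []
    days = np.arange(spec.horizon_d + 1)
    for _ in range(spec.n_vials):
        cont = scale * rng.weibull(spec.shape, size=spec.flies_per_vial)
        life = np.maximum(1, np.ceil(cont).astype(int))
        censored = life > spec.horizon_d
        alive = (life[None, :] > days[:, None]).sum(axis=1)
        vials.append(pd.Series(alive, index=days))
        lifespans.append({
            "lifespan_d": life.tolist(),
            "censored": censored.tolist(),
        })
    cohort = SurvivalCohort(genotype, vials, spec.flies_per_vial,
                            spec.horizon_d)
    truth = {
        "median_lifespan_d": spec.median_lifespan_d,
        "heavy_censoring": heavy_censoring,
        "vials": lifespans,
    }
    return cohort, truth


# ---------------------------------------------------------------------------
# expression


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Conditions for a two-genotype x two-timepoint log2 expression matrix.

    ``floor_fraction`` of genes get baselines planted below the expression
    floor; ``ref_concordance`` of planted DE genes also escape the
    reference experiment's central 99% interval with matching sign in the
    generated reference table.
    """

    n_genes: int = 4000
    samples_per_cell: int = 3
    n_up: int = 40
    n_down: int = 20
    planted_log2fc: float = 1.0
    time_effect_sd: float = 0.3
    noise_sd: float = 0.25
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    floor_fraction: float = 0.15
    ref_concordance: float = 0.8
    expression_floor: float = 4.0
    seed: int = 0

    # spread of the reference experiment's null fold changes (log2 units)
    REF_NULL_SD = 0.5

    def __post_init__(self) -> None:
        if self.samples_per_cell < 2:
            raise ValueError(
                "samples_per_cell must be >=2 (the ANOVA needs residual "
                "degrees of freedom)"
            )
        if self.n_up + self.n_down > self.n_genes:
            raise ValueError("more planted genes than genes")
        for name in ("time_effect_sd", "noise_sd", "baseline_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.floor_fraction <= 1 or not 0 <= self.ref_concordance <= 1:
            raise ValueError("fractions must be in [0, 1]")


def simulate_expression(
    spec: ExpressionSimSpec,
) -> tuple[ExpressionStudy, dict, pd.Series]:
    """Simulate the expression study, its truth record, and the reference
    fold-change table.

    Planted genes are never drawn from the below-floor pool; non-floored
    baselines keep a 0.5 log2-unit margin above the floor so that in the
    noise-free limit the expression filter removes exactly the planted
    below-floor genes.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"g{i + 1:05d}" for i in range(spec.n_genes)]
    n_planted = spec.n_up + spec.n_down
    n_floor = int(round(spec.floor_fraction * spec.n_genes))
    if n_planted + n_floor > spec.n_genes:
        raise ValueError("floor_fraction leaves no room for planted genes")
    up_genes = genes[: spec.n_up]
    down_genes = genes[spec.n_up : n_planted]
    floor_genes = genes[n_planted : n_planted + n_floor]

    baseline = np.maximum(
        rng.normal(spec.baseline_mean, spec.baseline_sd, spec.n_genes),
        spec.expression_floor + 0.5,
    )
    # planted-truth closure: planted genes keep a margin above the floor
    # wide enough that time-effect and noise tails cannot sink a whole
    # genotype group below it, so every planted gene stays analyzable
    planted_min = (spec.expression_floor + 0.5
                   + 3.0 * spec.time_effect_sd + 3.0 * spec.noise_sd)
    baseline[:n_planted] = np.maximum(baseline[:n_planted], planted_min)
    fl = slice(n_planted, n_planted + n_floor)
    baseline[fl] = rng.uniform(spec.expression_floor - 1.5,
                               spec.expression_floor - 0.5, n_floor)
    time_effect = rng.normal(0.0, spec.time_effect_sd, spec.n_genes)
    geno_effect = np.zeros(spec.n_genes)
    geno_effect[: spec.n_up] = spec.planted_log2fc
    geno_effect[spec.n_up : n_planted] = -spec.planted_log2fc

    sample_rows, columns = [], []
    for geno in ("mutant", "control"):
        for tp in ("ZT3", "ZT15"):
            for rep in range(1, spec.samples_per_cell + 1):
                sid = f"{geno}_{tp}_r{rep}"
                columns.append(sid)
                sample_rows.append({"sample": sid, "genotype": geno,
                                    "timepoint": tp, "replicate": rep})
    samples = pd.DataFrame(sample_rows).set_index("sample")

    mat = np.empty((spec.n_genes, len(columns)))
    for j, sid in enumerate(columns):
        geno = samples.loc[sid, "genotype"]
        tp = samples.loc[sid, "timepoint"]
        mu = baseline.copy()
        if tp == "ZT15":
            mu = mu + time_effect
        if geno == "mutant":
            mu = mu + geno_effect
        noise = (rng.normal(0.0, spec.noise_sd, spec.n_genes)
                 if spec.noise_sd > 0 else 0.0)
        mat[:, j] = mu + noise
    matrix = pd.DataFrame(mat, index=pd.Index(genes, name="gene"),
                          columns=columns)
    study = ExpressionStudy(matrix, samples, floor=spec.expression_floor)

    # reference table: null background, then push a controlled fraction of
    # planted genes beyond the background's central 99% interval with the
    # planted sign
    ref = pd.Series(rng.normal(0.0, spec.REF_NULL_SD, spec.n_genes),
                    index=genes, name="log2fc")
    alpha = 0.005
    lo, hi = np.quantile(ref.to_numpy(), [alpha, 1 - alpha])
    n_conc = int(round(spec.ref_concordance * n_planted))
    planted = np.array(up_genes + down_genes)
    conc_idx = rng.choice(n_planted, size=n_conc, replace=False)
    conc_genes = planted[conc_idx]
    margins = np.abs(rng.normal(0.4, 0.1, size=n_conc)) + 0.05
    signs = np.where(np.isin(conc_genes, up_genes), 1.0, -1.0)
    ref.loc[conc_genes] = np.where(signs > 0, hi + margins, lo - margins)

    truth = {
        "planted_up": up_genes,
        "planted_down": down_genes,
        "floored": floor_genes,
        "ref_concordant": sorted(conc_genes.tolist()),
        "planted_log2fc": spec.planted_log2fc,
    }
    return study, truth, ref


# ---------------------------------------------------------------------------
# truth record I/O


def write_truth(truth, path) -> None:
    """Persist a truth record as structured JSON text."""
    path = Path(path)
    if isinstance(truth, pd.DataFrame):
        payload = {"format": "dataframe",
                   "records": json.loads(
                       truth.reset_index().to_json(orient="records"))}
    else:
        payload = {"format": "dict", "records": truth}
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path):
    payload = json.loads(Path(path).read_text())
    if payload["format"] == "dataframe":
        return pd.DataFrame(payload["records"])
    return payload["records"]
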