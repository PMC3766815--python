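"""End-to-end orchestration: simulate two genotypes, analyze, report.

A :class:`StudyConfig` bundles the simulation specs for each input class
(a control-like and a disease-like genotype) with every analysis parameter,
each defaulting to its standard value (RI threshold 0.2, 10-min transition
window, responder threshold 2, expression floor 4.0, strict/lenient FDR
0.05/0.15 with 1.5-fold, 99% interval coverage).  Stage seeds are derived
deterministically from the master seed by stable hashing of stage names, so
a fixed master seed yields byte-identical report tables.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import (day_night_ratio, score_all_transitions,
                       summarize_transitions)
from .dam import write_dam_monitor
from .expression import (differential_expression, select_signature,
                         signature_overlap, write_expression_tsv,
                         write_reference_tsv)
from .luciferase import (assess_alive, compare_group_levels, cosinor_fit,
                         detrend_trace, write_luciferase_csv)
from .rhythm import analyze_rhythm, results_frame, ri_histogram
from .schedule import LightSchedule
from .survival import build_survival_curve, gehan_wilcoxon_test, write_survival_csv
from .synthetic import (ActivitySimSpec, ExpressionSimSpec, LuciferaseSimSpec,
                        SurvivalSimSpec, simulate_activity,
                        simulate_expression, simulate_luciferase,
                        simulate_survival, write_truth)

CSV_FLOAT_FORMAT = "%.6g"


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable (version-independent) per-stage seed below 2**31."""
    return (master_seed * 2654435761 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class StudyConfig:
    """All simulation specs and analysis parameters for one study run."""

    seed: int = 0
    genotype_a: str = "control"
    genotype_b: str = "disease"

    # 5-min rhythm assay (LD entrainment then DD free-run)
    activity_a: ActivitySimSpec = field(default_factory=ActivitySimSpec)
    activity_b: ActivitySimSpec = field(default_factory=lambda: ActivitySimSpec(
        fraction_rhythmic=0.5, day_multiplier=2.0))
    # 1-min light-response assay (LD only; the acute startle is the planted
    # response driver, so masking and circadian modulation are switched off
    # in this cohort -- either one would swamp the 10-min differential)
    light_response_a: ActivitySimSpec = field(
        default_factory=lambda: ActivitySimSpec(
            bin_min=1, n_days_ld=7, n_days_dd=0, day_multiplier=1.0,
            modulation_depth=0.0))
    light_response_b: ActivitySimSpec = field(
        default_factory=lambda: ActivitySimSpec(
            bin_min=1, n_days_ld=7, n_days_dd=0, day_multiplier=1.0,
            modulation_depth=0.0, startle_on=4.0, startle_off=3.0))
    luciferase_a: LuciferaseSimSpec = field(default_factory=LuciferaseSimSpec)
    luciferase_b: LuciferaseSimSpec = field(
        default_factory=lambda: LuciferaseSimSpec(level_scale=0.7))
    survival_a: SurvivalSimSpec = field(
        default_factory=lambda: SurvivalSimSpec(median_lifespan_d=40))
    survival_b: SurvivalSimSpec = field(
        default_factory=lambda: SurvivalSimSpec(median_lifespan_d=6))
    expression: ExpressionSimSpec = field(default_factory=ExpressionSimSpec)

    # analysis parameters (defaults = the standard thresholds)
    ri_threshold: float = 0.2
    ri_window_h: tuple = (18.0, 30.0)
    responder_threshold: int = 2
    transition_window_min: int = 10
    last_n_days: int = 4
    responder_mode: str = "majority"
    expression_floor: float = 4.0
    strict_q: float = 0.05
    lenient_q: float = 0.15
    fold_threshold: float = 1.5
    interval_coverage: float = 0.99
    n_perm: int = 10000
    n_boot: int = 2000

    def reseeded(self) -> "StudyConfig":
        """Copy with every sim-spec seed derived from the master seed."""
        def rs(spec, stage):
            return dataclasses.replace(spec, seed=derive_seed(self.seed, stage))

        return dataclasses.replace(
            self,
            activity_a=rs(self.activity_a, "activity_a"),
            activity_b=rs(self.activity_b, "activity_b"),
            light_response_a=rs(self.light_response_a, "light_response_a"),
            light_response_b=rs(self.light_response_b, "light_response_b"),
            luciferase_a=rs(self.luciferase_a, "luciferase_a"),
            luciferase_b=rs(self.luciferase_b, "luciferase_b"),
            survival_a=rs(self.survival_a, "survival_a"),
            survival_b=rs(self.survival_b, "survival_b"),
            expression=dataclasses.replace(
                self.expression, seed=derive_seed(self.seed, "expression")),
        )


def config_from_yaml(path) -> StudyConfig:
    """Build a config from a YAML mapping of (nested) field overrides."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    spec_types = {
        "activity_a": ActivitySimSpec, "activity_b": ActivitySimSpec,
        "light_response_a": ActivitySimSpec,
        "light_response_b": ActivitySimSpec,
        "luciferase_a": LuciferaseSimSpec, "luciferase_b": LuciferaseSimSpec,
        "survival_a": SurvivalSimSpec, "survival_b": SurvivalSimSpec,
        "expression": ExpressionSimSpec,
    }
    base = StudyConfig()
    kwargs = {}
    for key, value in raw.items():
        if key in spec_types:
            defaults = dataclasses.asdict(getattr(base, key))
            defaults.update(value or {})
            kwargs[key] = spec_types[key](**defaults)
        else:
            kwargs[key] = tuple(value) if key == "ri_window_h" else value
    return dataclasses.replace(base, **kwargs)


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, float_format=CSV_FLOAT_FORMAT, index=index)


def _manifest(config: StudyConfig, out_dir: Path, extra: dict) -> None:
    payload = {
        "package": "circafly",
        "version": __version__,
        "config": dataclasses.asdict(config),
        **extra,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(payload, indent=1, sort_keys=True, default=str))


def simulate_all(config: StudyConfig, out_dir) -> None:
    """Write every simulated input class (and truth records) to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.reseeded()
    for label, spec in (("a", cfg.activity_a), ("b", cfg.activity_b)):
        series, truth = simulate_activity(spec)
        for start in range(0, len(series), 32):
            write_dam_monitor(series[start : start + 32],
                              out / f"activity_{label}_m{start // 32 + 1}.txt")
        write_truth(truth, out / f"activity_{label}_truth.json")
    for label, spec in (("a", cfg.luciferase_a), ("b", cfg.luciferase_b)):
        traces, truth = simulate_luciferase(spec)
        write_luciferase_csv(traces, out / f"luciferase_{label}.csv")
        write_truth(truth, out / f"luciferase_{label}_truth.json")
    for label, spec, geno in (("a", cfg.survival_a, cfg.genotype_a),
                              ("b", cfg.survival_b, cfg.genotype_b)):
        cohort, truth = simulate_survival(spec, genotype=geno)
        write_survival_csv(cohort, out / f"survival_{label}.csv")
        write_truth(truth, out / f"survival_{label}_truth.json")
    study, truth, ref = simulate_expression(cfg.expression)
    write_expression_tsv(study, out / "expression_matrix.tsv",
                         out / "expression_samples.tsv")
    write_reference_tsv(ref, out / "reference_foldchanges.tsv")
    write_truth(truth, out / "expression_truth.json")
    _manifest(cfg, out, {"stage": "simulate"})


def run_behavior_pipeline(config: StudyConfig, out_dir) -> dict:
    """Simulate and analyze both genotypes' behavioral assays.

    Emits per-fly rhythm results, per-genotype rhythm summaries, RI
    histograms, transition-response summaries, day/night totals, survival
    curves and the curve test, luciferase level comparison and cosinor
    summaries, plus a machine-readable manifest.  Returns the tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.reseeded()
    genotypes = {cfg.genotype_a: "a", cfg.genotype_b: "b"}
    exclusions: list[str] = []

    # --- rhythm assay (5-min, LD then DD) -------------------------------
    from .dam import slice_dd

    rhythm_tables, summary_rows, hist_tables = [], [], []
    for geno, label in genotypes.items():
        spec = getattr(cfg, f"activity_{label}")
        series, truth = simulate_activity(spec, id_prefix=f"{geno}_")
        results = [
            analyze_rhythm(slice_dd(s), window_h=cfg.ri_window_h,
                           threshold=cfg.ri_threshold)
            for s in series
        ]
        frame = results_frame(results)
        frame.insert(0, "genotype", geno)
        rhythm_tables.append(frame)
        exclusions += [f"rhythm/{geno}/{r.fly_id}: {r.reason}"
                       for r in results if r.excluded]
        kept = frame[~frame["excluded"]]
        rhythmic = kept[kept["rhythmic"]]
        summary_rows.append({
            "genotype": geno,
            "n": len(kept),
            "n_excluded": int(frame["excluded"].sum()),
            "pct_rhythmic": 100.0 * len(rhythmic) / len(kept),
            "mean_ri": kept["ri"].mean(),
            "mean_period_h": rhythmic["period_h"].mean(),
            "true_fraction_rhythmic": spec.fraction_rhythmic,
        })
        hist = ri_histogram(results)
        hist.insert(0, "genotype", geno)
        hist_tables.append(hist)

    rhythm_results = pd.concat(rhythm_tables, ignore_index=True)
    rhythm_summary = pd.DataFrame(summary_rows)
    ri_hist = pd.concat(hist_tables, ignore_index=True)

    # --- light-response assay (1-min, LD only) --------------------------
    transition_tables, daynight_rows = [], []
    for geno, label in genotypes.items():
        spec = getattr(cfg, f"light_response_{label}")
        series, _ = simulate_activity(spec, id_prefix=f"{geno}_")
        responses = score_all_transitions(
            series, last_n_days=cfg.last_n_days,
            threshold=cfg.responder_threshold)
        summ = summarize_transitions(responses, mode=cfg.responder_mode)
        summ = summ.reset_index()
        summ.insert(0, "genotype", geno)
        transition_tables.append(summ)

    # day/night partition from the masking-bearing rhythm assay LD days
    for geno, label in genotypes.items():
        spec = getattr(cfg, f"activity_{label}")
        series, _ = simulate_activity(spec, id_prefix=f"{geno}_")
        ratios = [day_night_ratio(s) for s in series]
        defined = [r for r in ratios if r.ratio_defined]
        daynight_rows.append({
            "genotype": geno,
            "n": len(defined),
            "mean_ratio": float(np.mean([r.ratio for r in defined])),
            "sem_ratio": float(np.std([r.ratio for r in defined], ddof=1)
                               / np.sqrt(len(defined))),
            "mean_day_total": float(np.mean([r.day_total for r in defined])),
            "mean_night_total": float(np.mean([r.night_total
                                               for r in defined])),
            "true_day_multiplier": spec.day_multiplier,
        })
    transitions = pd.concat(transition_tables, ignore_index=True)
    daynight = pd.DataFrame(daynight_rows)

    # --- survival -------------------------------------------------------
    cohort_a, _ = simulate_survival(cfg.survival_a, genotype=cfg.genotype_a)
    cohort_b, _ = simulate_survival(cfg.survival_b, genotype=cfg.genotype_b)
    curves = []
    for cohort in (cohort_a, cohort_b):
        c = build_survival_curve(cohort)
        curves.append(pd.DataFrame({
            "genotype": c.genotype, "day": c.days,
            "surviving_fraction": c.surviving_fraction,
            "deaths": c.deaths, "at_risk": c.at_risk,
        }))
    test = gehan_wilcoxon_test(cohort_a, cohort_b)
    survival_curves = pd.concat(curves, ignore_index=True)
    survival_summary = pd.DataFrame([{
        "genotype_a": cfg.genotype_a,
        "genotype_b": cfg.genotype_b,
        "median_a_d": build_survival_curve(cohort_a).median_lifespan_d,
        "median_b_d": build_survival_curve(cohort_b).median_lifespan_d,
        "gehan_u": test.statistic_u,
        "z": test.z,
        "p_value": test.p_value,
    }])

    # --- luciferase -----------------------------------------------------
    groups = {}
    for geno, label in genotypes.items():
        spec = getattr(cfg, f"luciferase_{label}")
        traces, _ = simulate_luciferase(spec, id_prefix=f"{geno}_")
        traces = [cosinor_fit(detrend_trace(assess_alive(t))) for t in traces]
        groups[label] = traces
    comparison = compare_group_levels(
        groups["a"], groups["b"], n_boot=cfg.n_boot,
        seed=derive_seed(cfg.seed, "luciferase_bootstrap"))
    cosinor_rows = []
    for (geno, label) in genotypes.items():
        fits = [t.fit for t in groups[label]]
        cosinor_rows.append({
            "genotype": geno,
            "n": len(fits),
            "mean_period_h": float(np.mean([f.period_h for f in fits])),
            "mean_rel_amplitude": float(np.mean([f.rel_amplitude
                                                 for f in fits])),
            "mean_acrophase_h": float(np.mean([f.acrophase_h for f in fits])),
        })
    luciferase_summary = pd.DataFrame([{
        "fractional_reduction": comparison.fractional_reduction,
        "ci_low": comparison.ci_low,
        "ci_high": comparison.ci_high,
        "n_a": comparison.n_a,
        "n_b": comparison.n_b,
    }])
    cosinor_summary = pd.DataFrame(cosinor_rows)

    tables = {
        "rhythm_results": rhythm_results,
        "rhythm_summary": rhythm_summary,
        "ri_histogram": ri_hist,
        "transitions": transitions,
        "day_night": daynight,
        "survival_curves": survival_curves,
        "survival_summary": survival_summary,
        "luciferase_summary": luciferase_summary,
        "cosinor_summary": cosinor_summary,
    }
    for name, df in tables.items():
        _write_csv(df, out / f"{name}.csv")
    _manifest(cfg, out, {"stage": "behavior", "exclusions": exclusions})
    return tables


def run_expression_pipeline(config: StudyConfig, out_dir) -> dict:
    """Simulate and analyze the expression study; report DE and overlap.

    When the truth record is present (always, for simulated input) the
    report includes a truth-scored confusion table of the strict signature.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.reseeded()
    study, truth, ref = simulate_expression(cfg.expression)
    results = differential_expression(study)
    selection = select_signature(results, strict_q=cfg.strict_q,
                                 lenient_q=cfg.lenient_q,
                                 fold_threshold=cfg.fold_threshold)
    sig = selection.lenient
    overlap = signature_overlap(
        results.loc[sig, "log2fc"], ref, coverage=cfg.interval_coverage,
        n_perm=cfg.n_perm, seed=derive_seed(cfg.seed, "overlap"))

    planted = set(truth["planted_up"]) | set(truth["planted_down"])
    strict = set(selection.strict)
    universe = set(results.index)
    confusion = pd.DataFrame([{
        "true_positive": len(strict & planted),
        "false_positive": len(strict - planted),
        "false_negative": len((planted & universe) - strict),
        "planted_total": len(planted),
        "planted_expressed": len(planted & universe),
    }])
    overlap_df = pd.DataFrame([dataclasses.asdict(overlap)])
    summary = pd.DataFrame([{
        "n_genes": cfg.expression.n_genes,
        "n_expressed": len(results),
        "n_strict": len(strict),
        "n_strict_up": len(selection.up_strict),
        "n_strict_down": len(selection.down_strict),
        "n_lenient_up": len(selection.up_lenient),
        "n_lenient_down": len(selection.down_lenient),
        "overlap_permutation_p": overlap.permutation_p,
    }])

    _write_csv(selection.table.reset_index(), out / "de_results.csv")
    _write_csv(summary, out / "expression_summary.csv")
    _write_csv(overlap_df, out / "overlap_summary.csv")
    _write_csv(confusion, out / "confusion.csv")
    for name, genes in (("up_strict", selection.up_strict),
                        ("down_strict", selection.down_strict),
                        ("up_lenient", selection.up_lenient),
                        ("down_lenient", selection.down_lenient)):
        (out / f"signature_{name}.txt").write_text(
            "\n".join(genes) + ("\n" if genes else ""))
    _manifest(cfg, out, {"stage": "expression"})
    return {
        "de_results": selection.table,
        "summary": summary,
        "overlap": overlap_df,
        "confusion": confusion,
    }


def run_all(config: StudyConfig, out_dir) -> dict:
    out = Path(out_dir)
    tables = run_behavior_pipeline(config, out / "behavior")
    tables.update(run_expression_pipeline(config, out / "expression"))
    return tables
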