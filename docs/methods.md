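# Methods

This note documents the models, estimators, parameter defaults and
numerical choices behind `circafly`, and what the synthetic-data generators
do and do not emulate.

## Time, schedules and DAM files

Time is minutes from recording start, which is defined to coincide with
lights-on (ZT0) of the first LD day; bins are half-open `[start, start +
bin)`, so a count landing exactly on a light transition belongs to the
post-transition bin. A `LightSchedule` is an LD block (12:12 by default)
followed contiguously by a DD block.

Exactly one DAM dialect is supported, bit-exactly: 42 tab-separated columns
(record index, date `DD Mon YY`, time `HH:MM:SS`, status code, five device
fields, light sensor, 32 channel counts). Status 1 is a valid reading;
rows with any other code are kept but flagged per bin, and analyses exclude
flagged bins rather than silently dropping them. Rebinning sums integer
counts (total conserved exactly) and only downsamples. A fly whose final
24 h of recording contain zero counts is excluded from rhythm analysis as
presumed dead, mirroring the lived-through-the-assay rule used for
reporter flies; every exclusion is logged with its reason.

## Rhythm index and period

The correlogram is the biased (1/N-normalized) sample autocovariance over
sample variance — values bounded in [−1, 1], lag 0 = 1. Flagged bins are
mean-imputed before the transform (count recorded in the result); series
with more than 10% flagged bins are excluded, as the ACF needs a complete
grid. RI is the maximum raw correlogram value over lags in the 18–30 h
window (smallest lag wins exact ties), and the rhythmic call is strictly
`RI > 0.2`. Among the variants of the correlogram-based rhythm statistic
in the literature, the windowed maximum was chosen because it is monotone
in rhythm strength for 7–14 day records and preserves the usual >0.2
threshold semantics.

The **period** is the circadian peak lag, but localized on a corrected
correlogram rather than by raw argmax, for two reasons measured during
development: (i) the biased estimator carries a triangular `(N − k)/N`
taper that drags the peak systematically toward shorter lags (about one
bin at N = 2016, lag 288), and (ii) the circadian ACF bump is ~6 h wide at
5-min bins, so per-lag Poisson noise jitters the discrete argmax by
several bins. The estimate is therefore the argmax of the taper-corrected
correlogram after a 1.75-h moving-average smoothing — wide enough to
suppress bin-level jitter, narrow relative to the 6-h bump so the peak
location is preserved. On noise-free signals this recovers the planted
period to within one bin; on Poisson cohorts at modulation depth ≥ 2 it
recovers 20/24/28-h periods within ±0.5 h for every fly at the standard
7-day DD design. A residual deterministic bias of ≈ −0.1 to −0.2 h remains
from finite-record ripple (non-integer cycle counts in the truncated lag
sums); it is well inside the reporting resolution. No periodogram is
implemented — the period is an ACF-peak estimate only.

## Light-transition scoring

At 1-min resolution, the pre window is the 10 bins strictly before an
event and the post window the 10 bins from the event onward; the
differential is the integer count difference and a response is
`differential > 2`, strictly. Events with truncated or flagged windows are
invalidated per fly and logged. "Response amplitude" is defined as the
mean differential over a fly's valid events (the only quantity the scoring
rule itself defines). Group summaries aggregate the last four LD days;
a fly is a responder for an event kind if it responds on the majority of
that kind's valid events (`majority` mode), with a `per_event` mode
(fraction of all valid fly × event scores) available because "% responding
flies" admits both readings. Responder fractions carry Wilson 95% CIs.
Day/night partitioning totals counts over lights-on vs lights-off bins of
complete LD days; the ratio is flagged undefined (never infinite) when the
night total is zero.

## Luciferase detrending and cosinor

"Removing linear decay" is subtractive: an OLS line on (t, y) per fly,
detrended = y − fit + mean(y), preserving the mean exactly (a divisive
variant is available behind a flag since multiplicative decay is equally
plausible; per-fly rather than shared trends are used). Note that an OLS
line is not exactly orthogonal to a sampled cosine: the leakage vanishes
only when the sampling grid is symmetric about the acrophase, and
otherwise perturbs the recovered amplitude by a few percent — hence exact
recovery claims are stated for the undetrended pure-cosinor configuration.

The cosinor is linear least squares on a {1, cos, sin} basis per candidate
period (20–28 h grid, 0.1-h steps; ties resolve to the smaller period;
grid refinement can only lower the residual). Amplitude is
`hypot(β_c, β_s)`; acrophase comes from atan2, mapped to [0, period). A
flat input (RSS indistinguishable across the grid, tolerance 1e-9
relative) is flagged degenerate and reported at the grid minimum.

A reporter fly is "alive" if its final-day mean emission exceeds 5% of its
first-day mean (threshold config-exposed); only alive flies enter group
statistics. Group level comparison uses raw (pre-detrend) per-fly mean
emission, because level claims concern overall output, and reports
`1 − mean_B/mean_A` with a seeded **studentized bootstrap-t** CI: with 16
flies per group, percentile-type intervals on a mean ratio are z-width and
measurably undercover, while the bootstrap-t pivot (delta-method standard
errors inside each resample) restores near-nominal coverage.

## Survival

Cohorts are per-vial alive counts on possibly sparse observation days
(flies counted every day or two). The pooled curve is a step function:
counts carry forward across unobserved days, so reconstructed deaths land
on the observation day that closes a gap (a midpoint alternative is
config-exposed). The median lifespan is the first day with surviving
fraction ≤ 0.5 and is flagged absent — not reported as the horizon — when
never reached. Survivors at the horizon are right-censored.

Curves are compared with the Gehan–Breslow generalized Wilcoxon: the
weighted log-rank with at-risk-count weights, which emphasizes early
differences; the variance uses the hypergeometric tie correction. The
statistic equals (minus) the classic pairwise Gehan score sum, which the
test suite verifies, along with exact agreement with lifelines'
`weightings="wilcoxon"`. A seeded Monte-Carlo label-permutation mode (add-
one p estimator) is provided for small cohorts where the normal
approximation is rough; type-I error of the asymptotic test is calibrated
at 1,000 null replicates in the acceptance suite. A signed-rank test on
paired daily fractions is included as an audit variant only.

## Expression

The design is two genotypes × two timepoints (ZT3/ZT15, i.e. three hours
after lights-on/off) with ≥2 replicates per cell. A gene is expressed iff
*every* sample of at least one genotype exceeds the 4.0 log2 floor
(strict). Per expressed gene the model is additive, `y ~ genotype +
timepoint` — an ANOVA for the genotype effect controlling for time of day;
the genotype × time interaction is available behind a flag but excluded by
default. The fit is vectorized across genes (shared design matrix, RSS by
model reduction), which the suite checks per gene against statsmodels
ANOVA. log2 fold change is the difference of genotype marginal means
(cell means averaged over timepoints, robust to mild imbalance).
Benjamini–Hochberg q-values are computed across expressed genes only.
Signatures: strict q < 0.05, lenient q < 0.15, both with |FC| > 1.5 on the
linear scale (|log2FC| > log2 1.5 ≈ 0.585 — the alternative reading
|log2FC| > 1.5 is rejected; "FCR < 0.15" in common usage is an FDR
q-threshold and is treated as such).

Signature overlap against a reference experiment: the reference's central
99% empirical interval is the 0.5th–99.5th percentile (linear-interpolation
quantiles) of its fold changes; a signature gene is *outside* when its
reference fold change escapes the interval and *concordant* when the signs
also agree. Significance is by permutation — same-size gene sets drawn
without replacement from the reference universe, study signs kept paired
by position — with the add-one estimator; a hypergeometric test would
ignore the continuous fold-change structure, hence permutation. Because
the concordance count is a small discrete statistic, the reported
(conservative) p is super-uniform under the null; calibration studies use
randomized tie-broken p-values built from the returned null draws.

## Synthetic data: what is emulated

Each generator is a pure function of its spec including the seed
(bit-identical reruns), and writes a truth record sufficient to score the
downstream stage.

* **Activity**: Poisson counts per bin with rate `baseline · bin ·
  (1 + depth · max(0, cos(2π(t − φ)/P)))` for rhythmic flies (baseline
  only for arrhythmic), times a masking multiplier during lights-on bins
  of LD days, plus startle mass spread uniformly over the 10 min after
  each transition. Poisson because beam breaks are event counts; the
  rectified cosine is the simplest shape giving a distinct active phase;
  the cosine is evaluated at bin midpoints so the modulation mass splits
  exactly evenly across the 12:12 day/night halves (making the planted
  day/night ratio equal the masking multiplier). Defaults: baseline 0.5
  counts/min and day multiplier 4.5 for control-like flies (magnitude
  calibration choices — activity-count scales are rarely reported);
  phase 0; depth 3; startles 8 (on) and 6 (off) expected counts, chosen so
  the scoring rule yields the ~90%/~80% control responder fractions
  typical of intact vision. In the default two-genotype study the 1-min
  transition-assay cohort sets masking and modulation to zero — the acute
  startle is the planted response driver, and either other term swamps a
  10-min differential — while the 5-min rhythm-assay cohort carries the
  masking and supplies the day/night analysis.
* **Luciferase**: `level · (mesor₀ − decay·t)(1 + a·cos(2π(t − φ)/P))` +
  Gaussian noise, hourly for 5 days; defaults mesor₀ 1000, decay 3 /h,
  relative amplitude 0.3, acrophase 14 h (early-night reporter peak),
  noise SD 25, n = 16/group. Emission is validated to stay positive.
* **Survival**: lifespan = ⌈X⌉ with X Weibull (shape 3 by default) whose
  continuous median is `median − 0.5`, making the integer distribution's
  median exactly the requested value and reproducing the all-die-on-one-
  day limit as shape → ∞; 3 vials × 20 flies, censored at the horizon.
* **Expression**: log2 value = gene baseline + timepoint effect (ZT15) ±
  planted genotype effect + Gaussian noise; 4000 genes, 3 replicates per
  cell, 40 up / 20 down planted at 1.0 log2 units, noise SD 0.25, time
  effect SD 0.3, baseline N(7, 1.5) clipped ≥ 4.5. A floor fraction of
  genes is planted in [2.5, 3.5]; planted DE genes get an extra baseline
  margin (floor + 0.5 + 3·(time SD + noise SD)) so tail draws cannot sink
  a whole genotype group below the floor and silently remove a planted
  gene (planted-truth closure). The reference table is N(0, 0.5)
  background with a controlled fraction of planted genes moved beyond the
  background's 99% interval with matching sign. Note a structural limit:
  a rank-based central 99% interval excludes only ~1% of values, so when
  the planted concordant set exceeds 1% of the universe the analysis-time
  interval saturates; the planted enrichment remains overwhelming, which
  is the property under test.

What the generators do **not** emulate: bimodal (morning/evening) activity
profiles, sleep structure, anticipatory activity, between-fly baseline
heterogeneity, luciferin-depletion kinetics or plate-position effects,
vial-level frailty in survival, probe-level microarray noise or
inter-gene correlation. Passing tests therefore demonstrate correctness of
the estimators under the stated statistical structure, not robustness to
every feature of real recordings.

## Orchestration and problem sizes

Stage seeds derive from the master seed by stable hashing of stage names
(CRC-32 based, version-independent, < 2³¹), so a fixed master seed gives
byte-identical report tables; every parameter that influences a reported
number is written to the run manifest. Default study sizes — 32 flies per
genotype per behavioral assay, 16 reporter flies per group, 3 vials × 20
flies per survival cohort, 4000 genes × 12 arrays — follow the designs the
assays are normally run at (monitor capacity, plate layout, vial
replication) and keep the full simulate-analyze-report cycle and the test
suite fast. Calibration checks in the acceptance tests use 100–1000
replicates per property, sized so Monte-Carlo error is small against each
stated tolerance.
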