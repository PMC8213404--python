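# Methods

## Breath model and segmentation

Airflow is treated as a zero-mean oscillation in mL/s with inspiration
negative. A breath is the interval from one inspiration onset (downward
zero crossing) to the next; instantaneous frequency is the reciprocal of
that interval, PIF is the most negative flow sample during inspiration,
and inspired volume is the trapezoidal integral of −flow over the
inspiratory interval with linearly interpolated endpoint values.

Crossings are found on the (optionally boxcar-smoothed) trace. Two
numerical choices matter:

* **Sub-sample interpolation.** Crossing times are linearly interpolated
  between the two samples that bracket a sign change, which removes the
  sample-rate quantization bias from frequency estimates. A run of exact
  zeros between two lobes contributes a crossing at its first zero (end of
  the earlier lobe) and its last zero (start of the later lobe); an exact
  zero at a trace boundary lets the adjacent lobe count as crossing-bounded.
  This makes a trace that starts at zero flow going negative begin its
  first breath at t = 0, and makes breath-count conservation exact on
  noiseless synthetic traces with trailing zero padding.
* **Hysteresis.** A candidate lobe is accepted only if its extreme |flow|
  exceeds `hysteresis_ml_s` (default 0.1 mL/s); rejected ripple lobes merge
  into the surrounding breath. If sub-threshold activity follows the last
  accepted expiratory lobe, the final breath never settles back to zero and
  is treated as incomplete rather than closed at a ripple crossing.

Quality control is deliberately minimal and fully logged: duration within
[`min_breath_s`, `max_breath_s`] (defaults 0.05–2 s, bracketing plausible
murine breaths from hypercapnic panting to post-morphine bradypnea) and
|PIF| ≥ `min_pif_ml_s` (default 0.1 mL/s). Defaults for smoothing (5 ms)
and hysteresis were chosen once as small fractions of typical breath
duration (~150 ms) and PIF (~3 mL/s). Every CLI output records the full
configuration so a segmentation run is auditable.

Two ambiguities in the breath definition are exposed as switches rather
than silently resolved: `exclude_pause` ends a breath at the expiratory
lobe's end instead of the next inspiration onset (relevant only when
end-expiratory pauses exist), and `flip_sign` in the reader accepts data
recorded with the opposite sign convention after inverting it.

## OIRD metrics

OIRD is the per-animal morphine/saline ratio of condition means, computed
separately for frequency and PIF within a gas condition; pairing within an
animal cancels stable between-animal differences. The group value is the
**mean of per-animal ratios** (primary; the per-animal pairing is the
design's point) with the ratio of group means available as a proxy — the
two agree at two-decimal rounding for the published normoxic frequency and
PIF values. Group dispersion is reported as SD, SEM, and a z-based 95% CI
(mean ± 1.96·SEM); the z convention is pinned by the published CI bounds
(7.05 ± 1.96·0.34 = 6.38→7.72). Medians are emitted alongside means since
one published hypercapnic cell is a median. PIF keeps its negative sign
throughout; the ratio of two negative means is positive. Pooled per-breath
histograms are density-normalized (default bins 0.2 Hz / 0.25 mL/s,
configurable; the binning is a presentation choice, not an inference).

## Statistical decision tree

Per genotype group of OIRD ratios, Shapiro–Wilk (3 ≤ n ≤ 50) gates the
branch; the parametric branch requires **every** group to pass at
p ≥ α — per-group gating is stricter than gating the pooled data and the
gate decision is recorded in the report. Boundary p = α counts as passing.
Parametric: one-way ANOVA, then Tukey HSD post-hoc in the Kramer form
(unequal n: SE_ij = sqrt(MSW/2·(1/n_i + 1/n_j)), p from the studentized
range on (k, N−k)) only when the omnibus p < α, plus a pooled-variance
unpaired t-test with a t-based 95% CI for the focused wildtype-vs-knockout
contrast. Nonparametric: Kruskal–Wallis (tie-corrected, chi-square p) and
Mann–Whitney U (exact for tie-free groups of n ≤ 8, tie-corrected normal
approximation otherwise). The two-way genotype × drug interaction is fit by
regression with Type-II sums of squares, which is unbalanced-safe and
reduces to the textbook table in balanced designs. No multiple-comparison
correction is applied by default (a Holm switch exists, off), matching the
study's deliberately anti-conservative choice.

Standard statistics are delegated to scipy and statsmodels; the gating
logic, Tukey–Kramer assembly and reporting are this package's, and tests
cross-check them against independent least-squares, permutation and
scipy.stats.tukey_hsd oracles.

## Power analysis

The design question is the percent difference between a hypothetical
wildtype mean and the measured knockout mean detectable with the study's
cohort sizes (5 and 7) and observed SDs (recovered from printed SEMs as
sd = SEM·√n). The mean difference is |reference mean|·Δ%/100 with the
knockout mean as reference.

For the pooled equal-variance test, power is the exact noncentral-t
expression. For the Welch test (default, since the group SDs differ) the
popular shortcut — noncentral t with fixed Welch–Satterthwaite df — was
found to overshoot simulated power by up to ~0.02 at n = (5, 7), so power
is instead computed exactly: conditional on the two sample variances the
rejection region is a fixed interval for a normal mean difference, and the
2-D integral over the two scaled chi-square variance laws is evaluated by
Gauss–Legendre quadrature (96 points per axis; agrees with 200k-replicate
simulation to < 0.002). One consequence is honest rather than cosmetic:
power at zero difference equals the true size of the Welch test (≈ 0.046
at these n), not the nominal α; the pooled variant returns α exactly.

The minimum detectable difference inverts the power curve by bisection to
0.01 percentage points; `required_n` scans equal group sizes from n = 2
upward for a mean difference expressed as a fraction of a reference mean
(default 1.0, the natural scale for OIRD ratios).

## Burst detection and dose–response

Integrated nerve signals are boxcar-smoothed (default 0.1 s), thresholded
at median + k·MAD (k = 5) — robust to sparse bursts since the baseline
dominates both statistics — and supra-threshold excursions shorter than
`min_event_s` (default 0.1 s) are discarded as noise. Events closer than
the refractory interval (default 1 s, well below the slowest preBötC
period of interest) merge. On a noiseless signal the MAD threshold falls
to zero and onsets sit at the burst feet. Burst rate per dose epoch counts
event **peaks** in the final `analysis_window_s` (default 300 s of each
1200 s epoch, letting each dose equilibrate), which is unambiguous for
bursts straddling the window edge. Dose–response rows divide each epoch's
rate by the baseline epoch's; a silenced slice is a valid 0, not missing
data, and doses are ordered labels so no functional form is assumed.

## Synthetic data

The generators emulate the statistical structure the analysis assumes, not
lung mechanics. Breaths are half-sine inspiratory and expiratory lobes of
equal area (insp_fraction default 0.4, optional end-expiratory pause);
cycle length and PIF magnitude are per-breath gamma multipliers with unit
mean and specified CV (gamma keeps them positive and reduces to exact
periodicity at CV = 0); sensor noise is additive white Gaussian. Cohorts
apply per-animal multiplicative random effects (one factor for frequency,
one for PIF, shared by all four of an animal's recordings) and per-condition
multipliers; morphine's defaults (0.40 frequency, 0.65 PIF magnitude) sit
in the published normoxic range, hypercapnia raises frequency/PIF (1.09,
1.65) and halves the breath-to-breath CVs, emulating its stabilizing
effect. Drug and gas effects are multiplicatively separable in the
generator, so the real data's drug × gas interaction (milder depression
under hypercapnia) is representable only by swapping multiplier sets per
gas — a recorded limitation. Burst trains place half-sine bumps on
rectified Gaussian baseline noise, either Poisson or jittered-regular
(evenly spaced ± 25% spacing jitter; the quasi-regular mode reflects the
preBötC rhythm and guarantees non-overlapping, non-merging bursts).

Randomness: one top-level seed; per-animal and per-recording substreams
derive from `np.random.SeedSequence([seed, stage, genotype, animal, ...])`,
so enlarging one genotype's cohort leaves every other animal's data
bit-identical. Ground truth (breath onsets/durations/PIF; burst peak
times) is always returned next to the samples.

What passing tests show — and don't: the generators contain no movement
artifacts, sighs, sniffs, apneas, drifting baselines or chamber
calibration error, so green tests certify the algorithms against the
assumed signal model, not robustness to every artifact of real
plethysmography.

## Problem sizes used in the test suite

Monte-Carlo suites run at sizes chosen to make their tolerances
meaningful: type-I calibration uses 2000 null replicates at n = 5/6/7
(band ±0.02 ≈ 4× the binomial SE); power checks use 20 000 replicates per
grid point; OIRD multiplier recovery uses 100 cohort seeds of 3 animals ×
15 s recordings at 250 Hz (the PIF tolerance floor of 0.004 reflects
reading peaks off a 250 Hz sample grid); detector recall/precision uses
100 seeds of 300 s epochs at 50 Hz and amplitude/noise-SD = 5. Segmentation
oracle equivalence runs on traces of ≤ 5000 samples against a brute-force
rule-following scan.

## Known limitations

* QC is a declared stand-in (duration window + PIF floor + hysteresis);
  the original study's full metric list is unpublished.
* Flows are taken at face value; no chamber calibration to true volumes.
* The burst detector is a validated stand-in; the original counting
  method is unstated.
* No apnea/sigh classification, no naloxone-epoch quantification, no
  Bayesian or equivalence reanalysis.
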