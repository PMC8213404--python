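# oirdkit

Quantification of **opioid-induced respiratory depression (OIRD)** from
whole-body plethysmography airflow traces and in-vitro preBötzinger-complex
(preBötC) nerve recordings, for respiratory physiologists comparing breathing
between treatment groups — here, β-arrestin-2 (*Arrb2*) wildtype (+/+),
heterozygous (+/-) and knockout (-/-) littermates after intraperitoneal
saline vs morphine, under normoxic or hypercapnic gas.

## What it computes

**Breath segmentation.** An airflow trace (mL/s, inspiration negative) is
split into breaths at zero crossings with a hysteresis rule: a lobe of flow
only counts if its extreme magnitude exceeds a threshold, so sensor ripple
merges into the surrounding breath. Per breath *i* the pipeline reports the
instantaneous frequency f_i = 1 / (t_onset,i+1 − t_onset,i) (Hz), the peak
inspiratory flow PIF_i = min flow during inspiration (mL/s, negative), and
the inspired volume −∫ flow dt (mL). Configurable quality control drops
breaths outside a duration window or with |PIF| below a floor, and every
rejection is labelled.

**OIRD ratio.** For each animal and gas condition,

    OIRD = mean(parameter | morphine) / mean(parameter | saline)

computed per animal, then summarized per genotype as mean of per-animal
ratios with SEM and z-based 95% CI (mean ± 1.96·SEM). A ratio of 0.38 means
morphine cut breathing frequency to 38% of its saline value.

**Normality-gated statistics.** Shapiro–Wilk per genotype gates the branch:
if all groups look normal, one-way ANOVA across genotypes with Tukey
HSD/Kramer post-hoc (when the omnibus p < α) and an unpaired pooled-variance
t-test for the wildtype-vs-knockout contrast; otherwise Kruskal–Wallis and
Mann–Whitney U. A two-way (genotype × drug) regression ANOVA with Type-II
sums of squares tests the interaction on the raw values. No
multiple-comparison correction by default.

**Power analysis.** Exact power of the two-sided two-sample (Welch) t-test
as a function of the percent difference between group means, given the
cohort sizes and observed SDs, plus the minimum detectable difference at
80% power and the per-group n required for a given effect.

**In-vitro rhythm.** Bursts in integrated hypoglossal (∫CNXII) signals are
detected by a robust median + k·MAD threshold with refractory merging;
burst rate is measured over the last five minutes of each 20-minute DAMGO
dose epoch and normalized to the baseline epoch for dose–response
summaries.

**Synthetic data.** Generators produce ground-truth-annotated airflow
traces (half-sine inspiratory/expiratory lobes with per-breath variability,
animal-level random effects, multiplicative drug/gas condition effects) and
burst trains with per-epoch rates, so the whole pipeline is testable
without animal recordings.

## Worked example

```python
import pandas as pd
from oirdkit import *
from oirdkit import oird as om
from oirdkit.published import GROUP_STATS, group_sd

# desk check against the published normoxic group means
for g in ("+/+", "-/-"):
    sal = GROUP_STATS["normoxic"]["freq"]["saline"][g][0]
    mor = GROUP_STATS["normoxic"]["freq"]["morphine"][g][0]
    print(f"normoxic frequency OIRD {g}: {mor/sal:.2f}")

# synthetic cohort -> segmentation -> OIRD -> decision tree
base = BreathModelSpec(mean_frequency=7.0, mean_pif=-3.2, cycle_cv=0.1,
                       amplitude_cv=0.1, noise_sd=0.05)
sim = generate_cohort(CohortSpec(duration_s=30, sample_rate=250, seed=42), base)
summ = pd.DataFrame([om.summarize_animal(segment_recording(r)[0], r.metadata).__dict__
                     for r in sim.recordings])
ratios = om.oird_from_summaries(summ)
sub = ratios[ratios.gas == "normoxic"]
report = run_decision_tree({g: s["freq_ratio"].to_numpy()
                            for g, s in sub.groupby("genotype")})
print(f"branch: {report.branch}")
print(f"omnibus: {report.omnibus[0]} F={report.omnibus[1]:.2f} p={report.omnibus[2]:.3f}")

cfg = PowerConfig(n1=5, n2=7, sd1=group_sd("normoxic", "freq", "saline", "+/+"),
                  sd2=group_sd("normoxic", "freq", "saline", "-/-"))
print(f"min detectable difference: {min_detectable_difference(cfg, 7.05):.1f}%")
```

prints

```
normoxic frequency OIRD +/+: 0.47
normoxic frequency OIRD -/-: 0.38
branch: parametric
omnibus: one_way_anova F=2.04 p=0.164
min detectable difference: 21.1%
```

The two OIRD values say morphine depressed breathing frequency to 47%
(wildtype) and 38% (knockout) of the saline rate — the knockout is *not*
protected. The synthetic cohort (generated with identical drug effects in
every genotype) correctly shows no omnibus genotype effect, and the power
line says that with these cohort sizes and variances only mean-frequency
differences above ~21% would be detected at 80% power.

A `oirdkit` command-line interface mirrors these stages
(`simulate`, `segment`, `oird`, `stats`, `power`, `bursts`); see
`oirdkit --help`.

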