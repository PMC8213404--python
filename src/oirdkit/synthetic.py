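"""Synthetic plethysmography traces, cohorts and burst trains.

The generators provide ground-truth-annotated stand-ins for the three
kinds of recordings the pipeline analyzes:

* single airflow traces built from half-sine inspiratory and expiratory
  lobes with per-breath cycle-length and amplitude variability;
* cohorts of recordings (animal × drug × gas) with animal-level random
  effects and multiplicative drug/gas condition effects, emulating a
  saline-day / morphine-day plethysmography design under normoxic and
  hypercapnic gas;
* integrated nerve-root signals carrying rhythmic bursts whose rate is
  set per 20-minute dose epoch, emulating a DAMGO dose–response
  experiment on the preBötzinger complex rhythm.

Ground truth (true breath onsets/durations/PIF, true burst times) is
always emitted next to the samples so downstream accuracy can be scored
without re-deriving it.  All randomness flows from explicit integer
seeds; per-animal and per-recording substreams are derived with
``np.random.SeedSequence`` so that changing cohort membership does not
perturb the data of other animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AirflowRecording, IntegratedSignal, RecordingMetadata


@dataclass(frozen=True)
class BreathModelSpec:
    """Parameters of the per-breath waveform model.

    mean_frequency : Hz, > 0
    mean_pif : mL/s, < 0 (inspiration-negative convention)
    cycle_cv / amplitude_cv : coefficients of variation of breath
        duration and PIF magnitude (0 gives an exactly periodic trace)
    insp_fraction : fraction of the cycle spent in inspiration, in (0,1)
    pause_fraction : fraction of the cycle spent in end-expiratory pause
    noise_sd : additive Gaussian sensor noise, mL/s
    """

    mean_frequency: float
    mean_pif: float
    cycle_cv: float = 0.0
    amplitude_cv: float = 0.0
    insp_fraction: float = 0.4
    noise_sd: float = 0.0
    pause_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_frequency <= 0:
            raise ValueError("mean_frequency must be > 0")
        if self.mean_pif >= 0:
            raise ValueError("mean_pif must be < 0 (inspiration negative)")
        if not (0 < self.insp_fraction < 1):
            raise ValueError("insp_fraction must lie in (0, 1)")
        if not (0 <= self.pause_fraction < 1 - self.insp_fraction):
            raise ValueError("pause_fraction must lie in [0, 1 - insp_fraction)")
        if self.cycle_cv < 0 or self.amplitude_cv < 0 or self.noise_sd < 0:
            raise ValueError("cycle_cv, amplitude_cv and noise_sd must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic plethysmography cohort.

    ``drug_multipliers`` and ``gas_multipliers`` map condition labels to
    ``(frequency multiplier, PIF-magnitude multiplier)`` pairs applied to
    the base breath model; saline and normoxic are the (1, 1) reference.
    ``animal_effect_cv`` is the between-animal CV of multiplicative
    random effects shared by all four recordings of an animal.
    ``gas_cv_scale`` scales the breath-to-breath CVs per gas (hypercapnia
    stabilizes breathing, so its default shrinks them).
    """

    genotypes: tuple[str, ...] = ("+/+", "+/-", "-/-")
    n_per_genotype: tuple[int, ...] = (5, 6, 7)
    animal_effect_cv: float = 0.1
    drug_multipliers: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"saline": (1.0, 1.0), "morphine": (0.40, 0.65)})
    gas_multipliers: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"normoxic": (1.0, 1.0), "hypercapnic": (1.09, 1.65)})
    gas_cv_scale: Mapping[str, float] = field(
        default_factory=lambda: {"normoxic": 1.0, "hypercapnic": 0.5})
    duration_s: float = 60.0
    sample_rate: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.genotypes) != len(self.n_per_genotype):
            raise ValueError("genotypes and n_per_genotype must have equal length")
        if any(n < 1 for n in self.n_per_genotype):
            raise ValueError("n_per_genotype entries must be >= 1")
        for name, mult in (("drug", self.drug_multipliers), ("gas", self.gas_multipliers)):
            for label, (mf, mp) in mult.items():
                if mf <= 0 or mp <= 0:
                    raise ValueError(f"{name} multiplier for {label!r} must be > 0")
        if "saline" in self.drug_multipliers and self.drug_multipliers["saline"] != (1.0, 1.0):
            raise ValueError("the saline multiplier pair must be (1, 1)")


@dataclass(frozen=True)
class BurstTrainSpec:
    """Parameters of a synthetic integrated nerve-root signal.

    ``epoch_rates`` maps ordered dose labels to burst rates (bursts/s);
    each epoch lasts ``epoch_duration_s`` (the dose-response protocol
    uses 20-minute epochs).  ``placement`` selects Poisson or
    jittered-regular burst placement.
    """

    epoch_rates: Mapping[str, float]
    epoch_duration_s: float = 1200.0
    burst_width_s: float = 0.6
    burst_amplitude: float = 1.0
    baseline_noise_sd: float = 0.05
    sample_rate: float = 100.0
    seed: int = 0
    placement: str = "jittered_regular"

    def __post_init__(self) -> None:
        if not self.epoch_rates:
            raise ValueError("epoch_rates must be non-empty")
        for label, rate in self.epoch_rates.items():
            if rate < 0:
                raise ValueError(f"rate for epoch {label!r} must be >= 0")
            if self.burst_width_s * rate >= 1:
                raise ValueError(
                    f"burst_width_s x rate >= 1 for epoch {label!r}: bursts would overlap")
        if self.placement not in ("poisson", "jittered_regular"):
            raise ValueError("placement must be 'poisson' or 'jittered_regular'")


# ---------------------------------------------------------------------------


def generate_airflow_trace(spec: BreathModelSpec, duration_s: float,
                           sample_rate: float, seed: int,
                           metadata: RecordingMetadata | None = None
                           ) -> tuple[AirflowRecording, pd.DataFrame]:
    """Generate one airflow trace plus its per-breath ground truth.

    Each breath is a half-sine inspiratory lobe (negative) followed by a
    half-sine expiratory lobe (positive) of equal area, optionally
    followed by an end-expiratory pause at zero flow.  Whole breaths are
    appended until the next one would overrun ``duration_s``; the
    remainder is zero-padded, so the trace begins and ends at (near-)
    zero flow.

    Returns ``(recording, truth)`` where ``truth`` has one row per
    generated breath: onset_s, duration_s, inst_freq_hz, pif_ml_s.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    if sample_rate < 100:
        raise ValueError("sample_rate must be >= 100 Hz")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    x = np.zeros(n)
    t = np.arange(n) / sample_rate
    mean_T = 1.0 / spec.mean_frequency
    amp_mean = -spec.mean_pif

    rows = []
    cursor = 0.0
    while True:
        T = mean_T * _unit_mean_gamma(rng, spec.cycle_cv)
        if cursor + T > duration_s + 1e-12:
            break
        A = amp_mean * _unit_mean_gamma(rng, spec.amplitude_cv)
        ti = spec.insp_fraction * T
        te = (1.0 - spec.insp_fraction - spec.pause_fraction) * T
        amp_e = A * ti / te  # equal inspired and expired half-sine areas
        i0 = int(np.ceil(cursor * sample_rate - 1e-9))
        i1 = min(int(np.ceil((cursor + T) * sample_rate - 1e-9)), n)
        tau = t[i0:i1] - cursor
        seg = np.zeros(i1 - i0)
        in_insp = tau < ti
        in_exp = (tau >= ti) & (tau < ti + te)
        seg[in_insp] = -A * np.sin(np.pi * tau[in_insp] / ti)
        seg[in_exp] = amp_e * np.sin(np.pi * (tau[in_exp] - ti) / te)
        x[i0:i1] = seg
        rows.append({"onset_s": cursor, "duration_s": T,
                     "inst_freq_hz": 1.0 / T, "pif_ml_s": -A})
        cursor += T

    if spec.noise_sd > 0:
        x += rng.normal(0.0, spec.noise_sd, n)
    truth = pd.DataFrame(rows, columns=["onset_s", "duration_s", "inst_freq_hz", "pif_ml_s"])
    return AirflowRecording(x, sample_rate, metadata), truth


def _unit_mean_gamma(rng: np.random.Generator, cv: float) -> float:
    """Positive multiplicative factor with mean 1 and the given CV."""
    if cv == 0:
        return 1.0
    shape = 1.0 / cv**2
    return float(rng.gamma(shape, scale=1.0 / shape))


@dataclass
class SyntheticCohort:
    """A generated cohort: recordings plus per-recording truth tables."""

    recordings: list[AirflowRecording]
    breath_truth: list[pd.DataFrame]          # parallel to recordings
    manifest: pd.DataFrame                    # one row per recording

    def __iter__(self):
        return iter(self.recordings)


def generate_cohort(cohort: CohortSpec, breath_base: BreathModelSpec) -> SyntheticCohort:
    """Generate one recording per animal × drug × gas.

    Within an animal the same multiplicative random effect (one factor
    for frequency, one for PIF magnitude, CV ``animal_effect_cv``)
    applies to all recordings, so the morphine/saline ratio of that
    animal's true means equals the drug multiplier exactly when the
    breath-to-breath CVs are zero.
    """
    recs: list[AirflowRecording] = []
    truths: list[pd.DataFrame] = []
    manifest_rows = []
    for g_idx, (genotype, n_animals) in enumerate(zip(cohort.genotypes, cohort.n_per_genotype)):
        for a_idx in range(n_animals):
            animal_id = f"{genotype}_{a_idx:02d}"
            a_rng = np.random.default_rng(
                np.random.SeedSequence([cohort.seed, 1, g_idx, a_idx]))
            f_eff = _unit_mean_gamma(a_rng, cohort.animal_effect_cv)
            p_eff = _unit_mean_gamma(a_rng, cohort.animal_effect_cv)
            for d_idx, (drug, (d_f, d_p)) in enumerate(cohort.drug_multipliers.items()):
                for s_idx, (gas, (s_f, s_p)) in enumerate(cohort.gas_multipliers.items()):
                    cv_scale = cohort.gas_cv_scale.get(gas, 1.0)
                    spec = BreathModelSpec(
                        mean_frequency=breath_base.mean_frequency * f_eff * d_f * s_f,
                        mean_pif=breath_base.mean_pif * p_eff * d_p * s_p,
                        cycle_cv=breath_base.cycle_cv * cv_scale,
                        amplitude_cv=breath_base.amplitude_cv * cv_scale,
                        insp_fraction=breath_base.insp_fraction,
                        noise_sd=breath_base.noise_sd,
                        pause_fraction=breath_base.pause_fraction,
                    )
                    rec_seed = int(np.random.SeedSequence(
                        [cohort.seed, 2, g_idx, a_idx, d_idx, s_idx]).generate_state(1)[0])
                    meta = RecordingMetadata(animal_id=animal_id, genotype=genotype,
                                             drug=drug, gas=gas, session_day=d_idx + 1)
                    rec, truth = generate_airflow_trace(
                        spec, cohort.duration_s, cohort.sample_rate, rec_seed, meta)
                    recs.append(rec)
                    truths.append(truth)
                    manifest_rows.append({
                        "animal_id": animal_id, "genotype": genotype,
                        "drug": drug, "gas": gas,
                        "true_mean_freq_hz": spec.mean_frequency,
                        "true_mean_pif_ml_s": spec.mean_pif,
                        "n_breaths_true": len(truth),
                    })
    return SyntheticCohort(recs, truths, pd.DataFrame(manifest_rows))


def generate_burst_signal(spec: BurstTrainSpec
                          ) -> tuple[IntegratedSignal, pd.DataFrame]:
    """Generate an integrated nerve-root signal with epoch-wise burst rates.

    Bursts are half-sine bumps of width ``burst_width_s`` riding on
    rectified Gaussian baseline noise.  Placement per epoch is either
    homogeneous Poisson or jittered-regular (evenly spaced with ±25%
    spacing jitter); ``rate == 0`` produces no bursts in that epoch.

    Returns ``(signal, truth)`` where ``truth`` has one row per burst:
    epoch label and peak_s.
    """
    rng = np.random.default_rng(spec.seed)
    labels = list(spec.epoch_rates)
    n_epoch = int(round(spec.epoch_duration_s * spec.sample_rate))
    n = n_epoch * len(labels)
    t = np.arange(n) / spec.sample_rate
    x = np.abs(rng.normal(0.0, spec.baseline_noise_sd, n)) if spec.baseline_noise_sd > 0 \
        else np.zeros(n)

    half = spec.burst_width_s / 2.0
    rows = []
    epochs = []
    for e_idx, label in enumerate(labels):
        rate = spec.epoch_rates[label]
        start = e_idx * spec.epoch_duration_s
        end = start + spec.epoch_duration_s
        epochs.append((label, start, end))
        if rate <= 0:
            continue
        if spec.placement == "poisson":
            count = rng.poisson(rate * spec.epoch_duration_s)
            peaks = np.sort(rng.uniform(start + half, end - half, count))
        else:
            count = int(round(rate * spec.epoch_duration_s))
            spacing = spec.epoch_duration_s / count
            centers = start + (np.arange(count) + 0.5) * spacing
            jitter = rng.uniform(-0.25, 0.25, count) * spacing
            peaks = np.clip(centers + jitter, start + half, end - half)
        for pk in peaks:
            i0 = max(int(np.ceil((pk - half) * spec.sample_rate)), 0)
            i1 = min(int(np.floor((pk + half) * spec.sample_rate)) + 1, n)
            tau = t[i0:i1] - (pk - half)
            x[i0:i1] += spec.burst_amplitude * np.sin(np.pi * tau / spec.burst_width_s)
            rows.append({"epoch": label, "peak_s": float(pk)})

    truth = pd.DataFrame(rows, columns=["epoch", "peak_s"])
    return IntegratedSignal(x, spec.sample_rate, epochs), truth
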