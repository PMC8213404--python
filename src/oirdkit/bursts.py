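"""Burst detection and DAMGO dose–response analysis of integrated
nerve-root signals.

Inspiratory bursts of the preBötzinger-complex rhythm appear in the
integrated hypoglossal signal as discrete unimodal bumps.  The detector
thresholds the signal at a robust baseline level (median + k·MAD by
default), takes upward/downward threshold crossings as burst bounds,
and merges events closer than a refractory interval.  Per-epoch burst
frequency is counted over the final analysis window (the last five
minutes of each 20-minute dose epoch by default) and normalized to the
first (baseline) epoch for dose–response summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .io import IntegratedSignal
from . import stats as st


@dataclass(frozen=True)
class BurstDetectConfig:
    threshold_mode: str = "mad"     # "mad": median + k*MAD; "absolute"
    k: float = 5.0
    absolute_threshold: float | None = None
    refractory_s: float = 1.0       # minimum inter-burst (peak-to-peak) interval
    analysis_window_s: float = 300.0
    epoch_length_s: float = 1200.0
    smoothing_s: float = 0.1        # boxcar applied before thresholding
    min_event_s: float = 0.1        # shorter supra-threshold excursions are noise

    def __post_init__(self) -> None:
        if self.refractory_s <= 0:
            raise ValueError("refractory_s must be > 0")
        if self.analysis_window_s > self.epoch_length_s:
            raise ValueError("analysis_window_s must not exceed epoch_length_s")
        if self.threshold_mode not in ("mad", "absolute"):
            raise ValueError("threshold_mode must be 'mad' or 'absolute'")
        if self.threshold_mode == "absolute" and self.absolute_threshold is None:
            raise ValueError("absolute mode requires absolute_threshold")
        if self.smoothing_s < 0 or self.min_event_s < 0:
            raise ValueError("smoothing_s and min_event_s must be >= 0")


@dataclass(frozen=True)
class BurstEvent:
    onset_s: float
    peak_s: float
    offset_s: float
    peak_amplitude: float

    def __post_init__(self) -> None:
        if not (self.onset_s <= self.peak_s <= self.offset_s):
            raise ValueError("burst event requires onset <= peak <= offset")


def _boxcar(x: np.ndarray, k: int) -> np.ndarray:
    if k <= 1:
        return x
    kernel = np.ones(k)
    return np.convolve(x, kernel, "same") / np.convolve(np.ones_like(x), kernel, "same")


def detection_threshold(samples: np.ndarray,
                        config: BurstDetectConfig | None = None) -> float:
    """Robust baseline threshold: median + k·MAD of the (smoothed) signal.
    With sparse bursts the median and MAD reflect the low-activity baseline."""
    config = config or BurstDetectConfig()
    if config.threshold_mode == "absolute":
        return float(config.absolute_threshold)
    med = float(np.median(samples))
    mad = float(np.median(np.abs(samples - med)))
    return med + config.k * mad


def detect_bursts(signal: IntegratedSignal,
                  config: BurstDetectConfig | None = None) -> list[BurstEvent]:
    """Threshold-crossing burst detection with refractory merging.

    The signal is boxcar-smoothed before thresholding; supra-threshold
    excursions shorter than ``min_event_s`` are discarded as noise.
    A flat or sub-threshold signal yields an empty list.
    """
    config = config or BurstDetectConfig()
    fs = signal.sample_rate
    x = _boxcar(signal.samples, int(round(config.smoothing_s * fs)))
    thr = detection_threshold(x, config)
    above = x > thr
    if not above.any():
        return []
    edges = np.diff(above.astype(int))
    onsets = np.flatnonzero(edges == 1) + 1
    offsets = np.flatnonzero(edges == -1) + 1
    if above[0]:
        onsets = np.insert(onsets, 0, 0)
    if above[-1]:
        offsets = np.append(offsets, x.size)

    min_len = int(round(config.min_event_s * fs))
    events: list[BurstEvent] = []
    for i0, i1 in zip(onsets, offsets):
        if i1 - i0 < min_len:
            continue
        pk = i0 + int(np.argmax(x[i0:i1]))
        ev = BurstEvent(onset_s=i0 / fs, peak_s=pk / fs, offset_s=(i1 - 1) / fs,
                        peak_amplitude=float(x[pk]))
        if events and ev.peak_s - events[-1].peak_s < config.refractory_s:
            prev = events[-1]
            keep = prev if prev.peak_amplitude >= ev.peak_amplitude else ev
            events[-1] = BurstEvent(onset_s=prev.onset_s, peak_s=keep.peak_s,
                                    offset_s=ev.offset_s,
                                    peak_amplitude=keep.peak_amplitude)
        else:
            events.append(ev)
    return events


def epoch_frequency(events: list[BurstEvent], epoch: tuple[str, float, float],
                    config: BurstDetectConfig | None = None) -> float:
    """Bursts/s over the final ``analysis_window_s`` of the epoch; a burst
    belongs to the window by its peak time."""
    config = config or BurstDetectConfig()
    label, start, end = epoch
    if end - start < config.analysis_window_s:
        raise ValueError(f"analysis window longer than epoch {label!r}")
    w0 = end - config.analysis_window_s
    count = sum(1 for e in events if w0 <= e.peak_s < end)
    return count / config.analysis_window_s


def analyze_slice(signal: IntegratedSignal,
                  config: BurstDetectConfig | None = None) -> dict[str, float]:
    """Per-epoch burst frequency for one slice recording."""
    config = config or BurstDetectConfig()
    events = detect_bursts(signal, config)
    return {label: epoch_frequency(events, (label, a, b), config)
            for label, a, b in signal.epochs}


def normalize_dose_response(freqs: dict[str, float],
                            baseline_label: str | None = None) -> dict[str, float]:
    """Divide each epoch's frequency by the baseline (first) epoch's.

    The baseline entry of the result is exactly 1.
    """
    labels = list(freqs)
    baseline_label = baseline_label or labels[0]
    base = freqs[baseline_label]
    if base <= 0:
        raise ZeroDivisionError("baseline burst frequency is zero; cannot normalize")
    return {label: f / base for label, f in freqs.items()}


def dose_response_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble per-slice rows (slice_id, genotype, dose, raw_freq,
    normalized_freq) into a long DataFrame."""
    df = pd.DataFrame(rows, columns=["slice_id", "genotype", "dose",
                                     "raw_freq", "normalized_freq"])
    if (df["normalized_freq"] < 0).any():
        raise ValueError("normalized frequency must be >= 0")
    return df


def genotype_dose_summary(dose_response: pd.DataFrame,
                          alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-genotype mean ± SEM of normalized frequency at each dose, plus
    Kruskal–Wallis across genotypes and pairwise Mann–Whitney per dose."""
    summaries = []
    tests = []
    for dose, grp in dose_response.groupby("dose", sort=False):
        by_geno = {g: sub["normalized_freq"].to_numpy()
                   for g, sub in grp.groupby("genotype")}
        if any(v.size < 2 for v in by_geno.values()):
            raise InsufficientDataError(f"need >= 2 slices per genotype at dose {dose!r}")
        for g, v in by_geno.items():
            summaries.append({"dose": dose, "genotype": g, "mean": v.mean(),
                              "sem": v.std(ddof=1) / np.sqrt(v.size), "n": v.size})
        try:
            h, p = st.kruskal_wallis(list(by_geno.values()))
        except Exception:
            h, p = np.nan, np.nan
        tests.append({"dose": dose, "test": "kruskal_wallis", "pair": "",
                      "statistic": h, "p": p})
        names = list(by_geno)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                u, up = st.mann_whitney_u(by_geno[names[i]], by_geno[names[j]])
                tests.append({"dose": dose, "test": "mann_whitney_u",
                              "pair": f"{names[i]} vs {names[j]}",
                              "statistic": u, "p": up})
    return pd.DataFrame(summaries), pd.DataFrame(tests)
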