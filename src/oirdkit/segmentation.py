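"""Breath segmentation of airflow traces.

Breaths are delimited by zero crossings of the (optionally smoothed)
airflow signal.  A candidate lobe — a maximal run of same-signed flow
between crossings — only counts if its extreme flow exceeds the
hysteresis magnitude; sub-threshold ripple lobes are merged into the
surrounding breath.  A breath runs from the downward crossing that
starts inspiration, through the upward crossing that starts expiration,
to the downward crossing that starts the next inspiration; its
reciprocal duration is the instantaneous frequency and the most
negative inspiratory flow is the PIF (peak inspiratory flow).

Crossing times are placed by linear interpolation between samples, so
breath timing is not quantized to the sample grid.  Exact-zero samples
are handled as first-class crossings: a run of zeros between two lobes
contributes a crossing at its first zero (end of the earlier lobe) and
at its last zero (start of the later lobe), and an exact zero at the
trace boundary lets a lobe that starts or ends there count as
crossing-bounded rather than partial.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .io import AirflowRecording


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable parameters of the segmentation + QC stage.

    All thresholds are deliberately explicit and recorded in outputs so
    a segmentation run is auditable.
    """

    smoothing_window_s: float = 0.005
    hysteresis_ml_s: float = 0.1
    min_breath_s: float = 0.05
    max_breath_s: float = 2.0
    min_pif_ml_s: float = 0.1   # minimum |PIF| for a valid breath
    drop_edge_breaths: bool = True
    exclude_pause: bool = False  # end breath at expiratory-lobe end, not next onset

    def __post_init__(self) -> None:
        if self.smoothing_window_s < 0:
            raise ValueError("smoothing_window_s must be >= 0")
        if self.hysteresis_ml_s < 0:
            raise ValueError("hysteresis_ml_s must be >= 0")
        if not (0 < self.min_breath_s < self.max_breath_s):
            raise ValueError("need 0 < min_breath_s < max_breath_s")


@dataclass(frozen=True)
class Breath:
    """One segmented breath with its derived metrics."""

    insp_onset_s: float
    insp_offset_s: float
    exp_offset_s: float
    pif_ml_s: float
    insp_volume_ml: float

    def __post_init__(self) -> None:
        if not (self.insp_onset_s < self.insp_offset_s < self.exp_offset_s):
            raise ValueError("breath boundaries must satisfy onset < insp_offset < exp_offset")

    @property
    def duration_s(self) -> float:
        return self.exp_offset_s - self.insp_onset_s

    @property
    def inst_freq_hz(self) -> float:
        return 1.0 / self.duration_s


def smooth_trace(recording: AirflowRecording, window_s: float) -> AirflowRecording:
    """Boxcar-smooth a recording; the window is truncated at the edges so
    no padding bias is introduced.  ``window_s == 0`` (or a window of a
    single sample) is the identity."""
    if window_s < 0:
        raise ValueError("window_s must be >= 0")
    x = recording.samples
    k = int(round(window_s * recording.sample_rate))
    if k > x.size:
        raise ValueError("smoothing window longer than the trace")
    if k <= 1:
        return replace(recording, samples=x.copy())
    kernel = np.ones(k)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return replace(recording, samples=num / den)


# ---------------------------------------------------------------------------
# lobe extraction

@dataclass
class _Lobe:
    sign: int            # -1 inspiratory, +1 expiratory
    start_t: float | None  # crossing time; None = truncated by trace edge
    end_t: float | None
    peak_abs: float      # max |flow| over the lobe's samples


def _extract_lobes(x: np.ndarray, fs: float) -> list[_Lobe]:
    """Split the trace into maximal same-sign lobes with interpolated
    crossing times; zero-runs yield crossings at their first/last zero."""
    n = x.size
    t = np.arange(n) / fs
    sgn = np.sign(x).astype(int)

    lobes: list[_Lobe] = []
    i = 0
    while i < n:
        if sgn[i] == 0:
            i += 1
            continue
        j = i
        while j < n and (sgn[j] == sgn[i] or sgn[j] == 0):
            # a zero-run only stays inside the lobe if the same sign resumes
            if sgn[j] == 0:
                k = j
                while k < n and sgn[k] == 0:
                    k += 1
                if k == n or sgn[k] != sgn[i]:
                    break
                j = k
            j += 1
        # lobe samples span [i, j)
        if i > 0:
            if sgn[i - 1] == 0:
                start = t[i - 1]          # last zero of the preceding zero-run
            else:
                # strict sign flip between i-1 and i: interpolate
                start = t[i - 1] + (x[i - 1] / (x[i - 1] - x[i])) / fs
        else:
            start = None                  # truncated at trace start
        if j < n:
            if sgn[j] == 0:
                end = t[j]                # first zero of the following zero-run
            else:
                end = t[j - 1] + (x[j - 1] / (x[j - 1] - x[j])) / fs
        else:
            end = None                    # truncated at trace end
        lobes.append(_Lobe(sign=int(sgn[i]), start_t=start, end_t=end,
                           peak_abs=float(np.max(np.abs(x[i:j])))))
        i = j
    return lobes


def _merge_hysteresis(lobes: list[_Lobe], hysteresis: float) -> list[_Lobe]:
    """Drop lobes whose extreme flow does not exceed the hysteresis and
    merge the surviving same-sign neighbours they separated."""
    valid = [l for l in lobes if l.peak_abs > hysteresis]
    merged: list[_Lobe] = []
    for l in valid:
        if merged and merged[-1].sign == l.sign:
            prev = merged[-1]
            prev.end_t = l.end_t
            prev.peak_abs = max(prev.peak_abs, l.peak_abs)
        else:
            merged.append(_Lobe(l.sign, l.start_t, l.end_t, l.peak_abs))
    return merged


def find_breath_boundaries(recording: AirflowRecording,
                           config: SegmentationConfig | None = None
                           ) -> list[tuple[float, float, float]]:
    """Return ``(insp_onset, insp_offset, exp_offset)`` triples in seconds.

    A trace that never crosses zero yields an empty list.  With
    ``drop_edge_breaths`` every boundary must be a genuine crossing, so
    breaths truncated by the trace edges are discarded.
    """
    config = config or SegmentationConfig()
    raw = _extract_lobes(recording.samples, recording.sample_rate)
    lobes = _merge_hysteresis(raw, config.hysteresis_ml_s)
    # unresolved sub-threshold activity after the last accepted lobe means the
    # final breath never settles back to zero: its closing crossing is spurious
    trailing_ripple = False
    if lobes and lobes[-1].end_t is not None:
        last_end = lobes[-1].end_t
        trailing_ripple = any(
            l.peak_abs <= config.hysteresis_ml_s and l.start_t is not None
            and l.start_t >= last_end - 1e-12 for l in raw)
    triples: list[tuple[float, float, float]] = []
    t_end = recording.duration_s
    for idx, lobe in enumerate(lobes):
        if lobe.sign != -1:
            continue
        if idx + 1 >= len(lobes):
            break
        exp = lobes[idx + 1]
        onset, insp_off = lobe.start_t, lobe.end_t
        # breath ends where the next inspiration starts (pause included),
        # or at the expiratory lobe's end for the last breath / pause-excluded mode
        if not config.exclude_pause and idx + 2 < len(lobes) and lobes[idx + 2].start_t is not None:
            exp_off = lobes[idx + 2].start_t
        else:
            exp_off = exp.end_t
            if idx + 2 >= len(lobes) and trailing_ripple and not config.exclude_pause:
                exp_off = None
        if onset is None or insp_off is None or exp_off is None:
            if config.drop_edge_breaths:
                continue
            onset = 0.0 if onset is None else onset
            insp_off = insp_off if insp_off is not None else min(exp_off or t_end, t_end)
            exp_off = t_end if exp_off is None else exp_off
        if onset < insp_off < exp_off:
            triples.append((float(onset), float(insp_off), float(exp_off)))
    return triples


def compute_breath_metrics(recording: AirflowRecording,
                           boundaries: Sequence[tuple[float, float, float]]
                           ) -> list[Breath]:
    """Per-breath instantaneous frequency, PIF and inspired volume.

    PIF is the most negative flow sample during inspiration; volume is
    the trapezoidal integral of −flow over the inspiratory interval with
    linearly interpolated endpoint values.
    """
    x = recording.samples
    fs = recording.sample_rate
    t = recording.times
    dur = recording.duration_s
    breaths = []
    for onset, insp_off, exp_off in boundaries:
        if onset < -1e-9 or exp_off > dur + 1e-9:
            raise ValueError("breath boundary outside the trace")
        i0 = int(np.ceil(onset * fs - 1e-9))
        i1 = int(np.floor(insp_off * fs + 1e-9))
        i1 = min(i1, x.size - 1)
        seg = x[i0:i1 + 1]
        if seg.size == 0:
            raise ValueError("inspiratory interval contains no samples")
        pif = float(np.min(seg))
        # trapezoid over [onset, insp_off] with interpolated end values
        tt = np.concatenate(([onset], t[i0:i1 + 1], [insp_off]))
        vv = np.concatenate(([np.interp(onset, t, x)], seg, [np.interp(insp_off, t, x)]))
        volume = -float(np.trapezoid(vv, tt))
        breaths.append(Breath(onset, insp_off, exp_off, pif, volume))
    return breaths


def apply_qc(breaths: Sequence[Breath], config: SegmentationConfig | None = None
             ) -> tuple[list[Breath], list[tuple[Breath, str]]]:
    """Partition breaths into kept and rejected-with-reason.

    Rules: duration outside ``[min_breath_s, max_breath_s]`` and
    ``|PIF| < min_pif_ml_s``.  ``kept + rejected`` always equals the input.
    """
    config = config or SegmentationConfig()
    kept: list[Breath] = []
    rejected: list[tuple[Breath, str]] = []
    for b in breaths:
        if b.duration_s < config.min_breath_s:
            rejected.append((b, "too_short"))
        elif b.duration_s > config.max_breath_s:
            rejected.append((b, "too_long"))
        elif abs(b.pif_ml_s) < config.min_pif_ml_s:
            rejected.append((b, "weak_pif"))
        else:
            kept.append(b)
    return kept, rejected


def segment_recording(recording: AirflowRecording,
                      config: SegmentationConfig | None = None
                      ) -> tuple[list[Breath], list[tuple[Breath, str]]]:
    """Full pipeline: smooth → boundaries → metrics → QC."""
    config = config or SegmentationConfig()
    smoothed = smooth_trace(recording, config.smoothing_window_s)
    bounds = find_breath_boundaries(smoothed, config)
    breaths = compute_breath_metrics(smoothed, bounds)
    return apply_qc(breaths, config)
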