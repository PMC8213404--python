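"""Per-animal and group-level OIRD summaries.

OIRD (opioid-induced respiratory depression) is quantified per animal
as the ratio of the mean breathing parameter after morphine to the mean
after saline, separately for instantaneous frequency and PIF, within a
gas condition.  Group values are the mean of per-animal ratios (the
ratio of group means is also exposed); 95% confidence intervals use the
normal z = 1.96 multiplier on the SEM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, PairingError
from .io import RecordingMetadata
from .segmentation import Breath

Z95 = 1.96

DEFAULT_BIN_WIDTH = {"freq": 0.2, "pif": 0.25}


@dataclass(frozen=True)
class AnimalConditionSummary:
    """Arithmetic means over an animal's kept breaths in one condition."""

    animal_id: str
    genotype: str
    drug: str
    gas: str
    mean_freq_hz: float
    mean_pif_ml_s: float
    n_breaths: int


@dataclass(frozen=True)
class OIRDResult:
    """Morphine/saline ratios for one animal in one gas condition."""

    animal_id: str
    genotype: str
    gas: str
    freq_ratio: float
    pif_ratio: float


@dataclass(frozen=True)
class GroupSummary:
    """Mean, SD, SEM and z-based 95% CI of one parameter in one group."""

    genotype: str
    gas: str
    parameter: str
    mean: float
    sd: float
    sem: float
    ci95: tuple[float, float]
    n: int
    median: float


@dataclass(frozen=True)
class HistogramPDF:
    """Density-normalized histogram of a pooled per-breath parameter."""

    bin_edges: np.ndarray
    density: np.ndarray
    parameter: str


def summarize_animal(breaths: Sequence[Breath],
                     metadata: RecordingMetadata) -> AnimalConditionSummary:
    """Per-animal arithmetic means of instantaneous frequency and PIF."""
    if len(breaths) == 0:
        raise InsufficientDataError("cannot summarize an animal with zero kept breaths")
    freqs = np.array([b.inst_freq_hz for b in breaths])
    pifs = np.array([b.pif_ml_s for b in breaths])
    return AnimalConditionSummary(
        animal_id=metadata.animal_id, genotype=metadata.genotype,
        drug=metadata.drug, gas=metadata.gas,
        mean_freq_hz=float(freqs.mean()), mean_pif_ml_s=float(pifs.mean()),
        n_breaths=len(breaths))


def summarize_breath_table(breaths: pd.DataFrame,
                           genotype_of: dict[str, str] | None = None) -> pd.DataFrame:
    """Aggregate a breath table into one row per animal × drug × gas."""
    if breaths.empty:
        raise InsufficientDataError("empty breath table")
    g = breaths.groupby(["animal_id", "drug", "gas"], sort=True)
    out = g.agg(mean_freq_hz=("inst_freq_hz", "mean"),
                mean_pif_ml_s=("pif_ml_s", "mean"),
                n_breaths=("inst_freq_hz", "size")).reset_index()
    if genotype_of is not None:
        out.insert(1, "genotype", out["animal_id"].map(genotype_of))
    return out


def oird_ratio(saline: AnimalConditionSummary,
               morphine: AnimalConditionSummary) -> OIRDResult:
    """Morphine/saline ratio of the per-animal means (one animal, one gas)."""
    for attr in ("animal_id", "gas"):
        if getattr(saline, attr) != getattr(morphine, attr):
            raise PairingError(f"summaries differ in {attr}: cannot pair")
    if saline.drug != "saline" or morphine.drug != "morphine":
        raise PairingError("expected one saline and one morphine summary")
    return OIRDResult(
        animal_id=saline.animal_id, genotype=saline.genotype, gas=saline.gas,
        freq_ratio=morphine.mean_freq_hz / saline.mean_freq_hz,
        pif_ratio=morphine.mean_pif_ml_s / saline.mean_pif_ml_s)


def oird_from_summaries(summaries: pd.DataFrame) -> pd.DataFrame:
    """Pair drug conditions per animal × gas and compute the ratios.

    Raises PairingError for any animal × gas missing one drug condition.
    """
    wide = summaries.pivot_table(index=["animal_id", "gas"], columns="drug",
                                 values=["mean_freq_hz", "mean_pif_ml_s"],
                                 aggfunc="first")
    if ("mean_freq_hz", "saline") not in wide.columns or \
            ("mean_freq_hz", "morphine") not in wide.columns:
        raise PairingError("both drug conditions are required")
    if wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index.tolist()
        raise PairingError(f"missing drug condition for: {missing}")
    out = pd.DataFrame({
        "animal_id": wide.index.get_level_values("animal_id"),
        "gas": wide.index.get_level_values("gas"),
        "freq_ratio": (wide[("mean_freq_hz", "morphine")] /
                       wide[("mean_freq_hz", "saline")]).to_numpy(),
        "pif_ratio": (wide[("mean_pif_ml_s", "morphine")] /
                      wide[("mean_pif_ml_s", "saline")]).to_numpy(),
    }).reset_index(drop=True)
    if "genotype" in summaries.columns:
        geno = summaries.drop_duplicates("animal_id").set_index("animal_id")["genotype"]
        out.insert(1, "genotype", out["animal_id"].map(geno))
    return out


def group_summary(values: Sequence[float], genotype: str = "", gas: str = "",
                  parameter: str = "") -> GroupSummary:
    """Mean, sample SD (n−1), SEM and z-based 95% CI of a group of values."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError("group_summary needs n >= 2")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    sem = sd / np.sqrt(v.size)
    return GroupSummary(genotype=genotype, gas=gas, parameter=parameter,
                        mean=mean, sd=sd, sem=sem,
                        ci95=(mean - Z95 * sem, mean + Z95 * sem),
                        n=int(v.size), median=float(np.median(v)))


def ratio_of_group_means(saline_mean: float, morphine_mean: float) -> float:
    """Morphine/saline ratio of two group means (sign-preserving for PIF)."""
    return morphine_mean / saline_mean


def pooled_histogram(values: Sequence[float], parameter: str = "freq",
                     bin_width: float | None = None) -> HistogramPDF:
    """Density-normalized histogram of per-breath values pooled across
    all animals of a group; the density integrates to 1."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InsufficientDataError("pooled_histogram needs at least one breath")
    if bin_width is None:
        bin_width = DEFAULT_BIN_WIDTH.get(parameter, 0.2)
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    lo = np.floor(v.min() / bin_width) * bin_width
    hi = np.ceil(v.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    density, edges = np.histogram(v, bins=edges, density=True)
    return HistogramPDF(bin_edges=edges, density=density, parameter=parameter)


def group_oird_report(oird: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype × gas summaries of the per-animal OIRD ratios.

    Reports both the mean of per-animal ratios (primary) and the median,
    with SEM and z-based 95% CI of the mean.
    """
    rows = []
    for (genotype, gas), grp in oird.groupby(["genotype", "gas"]):
        for param, col in (("freq", "freq_ratio"), ("pif", "pif_ratio")):
            s = group_summary(grp[col].to_numpy(), genotype, gas, param)
            rows.append({"genotype": genotype, "gas": gas, "parameter": param,
                         "mean": s.mean, "median": s.median, "sd": s.sd,
                         "sem": s.sem, "ci95_lo": s.ci95[0], "ci95_hi": s.ci95[1],
                         "n": s.n})
    return pd.DataFrame(rows)
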