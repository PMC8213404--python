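"""Published group-level reference values for the Arrb2 OIRD study design.

These are the printed group summaries (mean ± SEM per genotype, drug
and gas, plus the reported OIRD ratios) for whole-body plethysmography
in β-arrestin-2 wildtype (+/+), heterozygous (+/-) and knockout (-/-)
littermates after intraperitoneal saline or morphine (20 mg/kg), under
normoxic and hypercapnic gas.  They serve as desk-check inputs: the
OIRD ratio recomputed from the printed means must reproduce the printed
OIRD value at two-decimal rounding, and the printed CI bounds pin down
the z-based CI convention.

Structure: ``GROUP_STATS[gas][parameter][drug][genotype] = (mean, sem)``
with frequency in Hz and PIF in mL/s (inspiration negative), and
``OIRD_PRINTED[gas][parameter][genotype] = printed ratio``.
"""

from __future__ import annotations

N_ANIMALS = {"+/+": 5, "+/-": 6, "-/-": 7}

GROUP_STATS = {
    "normoxic": {
        "freq": {
            "saline":   {"-/-": (7.05, 0.34), "+/-": (7.51, 0.41), "+/+": (6.93, 0.32)},
            "morphine": {"-/-": (2.67, 0.16), "+/-": (2.83, 0.14), "+/+": (3.27, 0.16)},
        },
        "pif": {
            "saline":   {"-/-": (-3.17, 0.15), "+/-": (-4.03, 0.25), "+/+": (-3.50, 0.23)},
            "morphine": {"-/-": (-2.09, 0.09), "+/-": (-2.19, 0.10), "+/+": (-2.33, 0.10)},
        },
    },
    "hypercapnic": {
        "freq": {
            "saline":   {"-/-": (7.68, 0.19), "+/-": (7.69, 0.16), "+/+": (7.77, 0.39)},
            "morphine": {"-/-": (5.20, 0.10), "+/-": (4.79, 0.19), "+/+": (5.38, 0.18)},
        },
        "pif": {
            "saline":   {"-/-": (-5.34, 0.27), "+/-": (-5.75, 0.25), "+/+": (-5.71, 0.20)},
            "morphine": {"-/-": (-3.54, 0.16), "+/-": (-3.86, 0.15), "+/+": (-3.93, 0.24)},
        },
    },
}

#: printed per-genotype OIRD ratios (mean of per-animal morphine/saline ratios)
OIRD_PRINTED = {
    "normoxic": {
        "freq": {"-/-": 0.38, "+/-": 0.38, "+/+": 0.47},
        "pif":  {"-/-": 0.66, "+/-": 0.55, "+/+": 0.68},
    },
    "hypercapnic": {
        "freq": {"-/-": 0.66, "+/-": 0.63, "+/+": 0.70},
        "pif":  {"-/-": 0.66, "+/-": 0.68, "+/+": 0.69},
    },
}

#: printed 95% CI of the normoxic saline frequency for -/- (CI-convention check)
FREQ_SALINE_KO_CI = (6.38, 7.72)


def group_mean(gas: str, parameter: str, drug: str, genotype: str) -> float:
    return GROUP_STATS[gas][parameter][drug][genotype][0]


def group_sem(gas: str, parameter: str, drug: str, genotype: str) -> float:
    return GROUP_STATS[gas][parameter][drug][genotype][1]


def group_sd(gas: str, parameter: str, drug: str, genotype: str) -> float:
    """Sample SD recovered from the printed SEM: sd = sem * sqrt(n)."""
    mean, sem = GROUP_STATS[gas][parameter][drug][genotype]
    return sem * N_ANIMALS[genotype] ** 0.5
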