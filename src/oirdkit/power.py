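"""Power of the two-sample genotype comparison.

Answers the study-design question: given the cohort sizes and the
observed between-animal variation, how large a percent difference
between the knockout and a hypothetical wildtype mean could the
experiment detect with a two-sided unpaired t-test?

Power is computed analytically from the noncentral t distribution.
With unequal group SDs the Welch–Satterthwaite degrees of freedom are
used (the default); the classic pooled equal-variance formula is
available behind a switch.  The minimum detectable difference inverts
the power curve by bisection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps


@dataclass(frozen=True)
class PowerConfig:
    n1: int
    n2: int
    sd1: float
    sd2: float
    alpha: float = 0.05
    target_power: float = 0.8
    equal_var: bool = False   # True: pooled-variance df instead of Welch
    grid: tuple[float, ...] = field(default_factory=lambda: tuple(np.arange(0., 50.5, 0.5)))

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("group sizes must be >= 2")
        if self.sd1 <= 0 or self.sd2 <= 0:
            raise ValueError("group SDs must be > 0")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0 < self.target_power < 1):
            raise ValueError("target_power must lie in (0, 1)")


def _df_and_se(config: PowerConfig) -> tuple[float, float]:
    v1, v2 = config.sd1 ** 2 / config.n1, config.sd2 ** 2 / config.n2
    se = np.sqrt(v1 + v2)
    if config.equal_var:
        df = config.n1 + config.n2 - 2
        sp2 = (((config.n1 - 1) * config.sd1 ** 2 + (config.n2 - 1) * config.sd2 ** 2)
               / df)
        se = np.sqrt(sp2 * (1.0 / config.n1 + 1.0 / config.n2))
    else:
        df = (v1 + v2) ** 2 / (v1 ** 2 / (config.n1 - 1) + v2 ** 2 / (config.n2 - 1))
    return float(df), float(se)


def _welch_power_exact(delta: float, n1: int, n2: int, sd1: float, sd2: float,
                       alpha: float, m: int = 96) -> float:
    """Exact power of the two-sided Welch t-test by quadrature over the
    joint distribution of the two sample variances.

    Conditional on the sample variances, the mean difference is normal
    and the rejection region is a fixed interval, so power is a 2-D
    integral over two independent scaled chi-square laws.  At the tiny
    cohort sizes used here this is visibly more accurate than the
    fixed-df noncentral-t shortcut (which can overshoot by ~0.02).
    """
    from numpy.polynomial.legendre import leggauss
    nodes, weights = leggauss(m)
    u = 0.5 * (nodes + 1.0)
    w = 0.5 * weights
    s1sq = sd1 ** 2 * sps.chi2.ppf(u, n1 - 1) / (n1 - 1)
    s2sq = sd2 ** 2 * sps.chi2.ppf(u, n2 - 1) / (n2 - 1)
    v1 = s1sq[:, None] / n1
    v2 = s2sq[None, :] / n2
    se2 = v1 + v2
    nu = se2 ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, nu)
    bound = tcrit * np.sqrt(se2)
    sigma_e = np.sqrt(sd1 ** 2 / n1 + sd2 ** 2 / n2)
    p_rej = sps.norm.sf((bound - delta) / sigma_e) + \
        sps.norm.cdf((-bound - delta) / sigma_e)
    return float(w @ p_rej @ w)


def power_two_sample(delta_percent: float, reference_mean: float,
                     config: PowerConfig) -> float:
    """Analytic power of the two-sided two-sample t-test for a mean
    difference of ``|reference_mean| * delta_percent / 100``.

    The pooled (``equal_var``) variant uses the exact noncentral-t
    expression; the Welch default integrates out the sample variances
    (see :func:`_welch_power_exact`)."""
    if reference_mean == 0:
        raise ValueError("reference_mean must be non-zero")
    delta = abs(reference_mean) * abs(delta_percent) / 100.0
    if not config.equal_var:
        return _welch_power_exact(delta, config.n1, config.n2,
                                  config.sd1, config.sd2, config.alpha)
    df, se = _df_and_se(config)
    ncp = delta / se
    tcrit = sps.t.ppf(1.0 - config.alpha / 2.0, df)
    return float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))


def power_curve(config: PowerConfig, reference_mean: float) -> pd.DataFrame:
    """Power over the configured percent-difference grid."""
    return pd.DataFrame({
        "delta_percent": list(config.grid),
        "power": [power_two_sample(d, reference_mean, config) for d in config.grid],
    })


def min_detectable_difference(config: PowerConfig, reference_mean: float) -> float:
    """Smallest percent difference reaching ``target_power``, found by
    bisection to within 0.01 percentage points."""
    if config.target_power <= config.alpha:
        return 0.0
    lo, hi = 0.0, 1.0
    while power_two_sample(hi, reference_mean, config) < config.target_power:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("power never reaches target")
    f = lambda d: power_two_sample(d, reference_mean, config) - config.target_power
    return float(optimize.brentq(f, lo, hi, xtol=0.01))


def required_n(effect_fraction: float, sd: float, alpha: float = 0.05,
               target_power: float = 0.8, reference_mean: float = 1.0,
               max_n: int = 10_000) -> int:
    """Smallest equal per-group n detecting a mean difference of
    ``effect_fraction * reference_mean`` with the given SD in both groups."""
    if effect_fraction <= 0:
        raise ValueError("effect_fraction must be > 0")
    for n in range(2, max_n + 1):
        cfg = PowerConfig(n1=n, n2=n, sd1=sd, sd2=sd, alpha=alpha,
                          target_power=target_power, equal_var=True)
        if power_two_sample(100.0 * effect_fraction, reference_mean, cfg) >= target_power:
            return n
    raise RuntimeError("no n <= max_n reaches the target power")
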