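"""Normality-gated hypothesis-testing scheme for genotype comparisons.

The decision tree applied to per-animal OIRD ratios:

1. Shapiro–Wilk normality test per genotype group.
2. If every group passes (p >= alpha): one-way ANOVA across genotypes;
   when the omnibus p < alpha, Tukey HSD/Kramer post-hoc pairwise
   comparisons (Kramer form for unequal n).  The focused wildtype vs
   knockout contrast additionally uses an unpaired pooled-variance
   two-sample t-test with a t-based 95% CI of the mean difference.
3. If any group fails: Kruskal–Wallis omnibus and a Mann–Whitney U test
   for the focused pair.
4. Independently, a two-way ANOVA (regression formulation, Type-II sums
   of squares, unbalanced-safe) on the raw saline/morphine values tests
   the genotype × drug interaction.

No multiple-comparison correction is applied by default; a Holm switch
exists.  Standard test statistics are delegated to scipy/statsmodels;
the gating logic, Tukey–Kramer assembly and report structure live here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateSampleError, DesignError, InsufficientDataError


@dataclass(frozen=True)
class DecisionConfig:
    alpha: float = 0.05
    correct_multiple_comparisons: bool = False
    t_test_tails: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.t_test_tails not in (1, 2):
            raise ValueError("t_test_tails must be 1 or 2")


@dataclass
class TestReport:
    """Outcome of one run of the decision tree."""

    branch: str                                   # "parametric" | "nonparametric"
    normality_p: dict[str, float]
    omnibus: tuple[str, float, float]             # (test name, statistic, p)
    posthoc: list[tuple[tuple[str, str], float, float]] = field(default_factory=list)
    pairwise_focus: tuple[tuple[str, str], str, float, float,
                          tuple[float, float] | None] | None = None
    two_way: tuple[float, float] | None = None    # (interaction F, p)


def _as_groups(groups) -> list[np.ndarray]:
    return [np.asarray(g, dtype=float) for g in groups]


def shapiro_wilk(sample: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk W and p (Royston approximation), for 3 <= n <= 50."""
    x = np.asarray(sample, dtype=float)
    if not (3 <= x.size <= 50):
        raise ValueError("shapiro_wilk requires 3 <= n <= 50")
    if np.ptp(x) == 0:
        raise DegenerateSampleError("constant sample has no normality test")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def choose_branch(groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
                  config: DecisionConfig | None = None
                  ) -> tuple[str, dict[str, float]]:
    """Gate on per-group normality: parametric iff every group's
    Shapiro–Wilk p >= alpha (boundary p == alpha counts as parametric)."""
    config = config or DecisionConfig()
    if not isinstance(groups, Mapping):
        groups = {str(i): g for i, g in enumerate(groups)}
    if len(groups) < 2:
        raise InsufficientDataError("need at least two groups")
    pvals = {name: shapiro_wilk(g)[1] for name, g in groups.items()}
    branch = "parametric" if all(p >= config.alpha for p in pvals.values()) \
        else "nonparametric"
    return branch, pvals


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Single-factor ANOVA F and p (between/within decomposition)."""
    gs = _as_groups(groups)
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise InsufficientDataError("one_way_anova needs >= 2 groups of n >= 2")
    if all(np.ptp(g) == 0 for g in gs):
        raise DegenerateSampleError("zero within-group variance in every group")
    f, p = sps.f_oneway(*gs)
    return float(f), float(p)


def tukey_hsd_kramer(groups: Mapping[str, Sequence[float]],
                     omnibus_p: float | None = None,
                     config: DecisionConfig | None = None,
                     allow_nonsignificant: bool = False
                     ) -> list[tuple[tuple[str, str], float, float]]:
    """Tukey HSD post-hoc comparisons, Kramer form for unequal n.

    q = |mean_i − mean_j| / sqrt(MSW/2 · (1/n_i + 1/n_j)), with p from
    the studentized-range distribution on (k, N−k).  By contract this
    runs only after a significant omnibus ANOVA unless overridden.
    """
    config = config or DecisionConfig()
    if omnibus_p is not None and omnibus_p >= config.alpha and not allow_nonsignificant:
        raise ValueError("post-hoc requested without a significant omnibus test")
    names = list(groups)
    gs = {k: np.asarray(groups[k], dtype=float) for k in names}
    k = len(names)
    n_total = sum(g.size for g in gs.values())
    df_w = n_total - k
    if df_w <= 0:
        raise InsufficientDataError("no within-group degrees of freedom")
    grand_means = {k_: g.mean() for k_, g in gs.items()}
    ssw = sum(float(((g - g.mean()) ** 2).sum()) for g in gs.values())
    msw = ssw / df_w
    if msw == 0:
        raise DegenerateSampleError("zero within-group variance")
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = names[i], names[j]
            se = np.sqrt(msw / 2.0 * (1.0 / gs[a].size + 1.0 / gs[b].size))
            q = abs(grand_means[a] - grand_means[b]) / se
            p = float(sps.studentized_range.sf(q, k, df_w))
            out.append(((a, b), float(q), min(p, 1.0)))
    return out


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal–Wallis H with tie correction; chi-square p."""
    gs = _as_groups(groups)
    if len(gs) < 2 or any(g.size < 3 for g in gs):
        raise InsufficientDataError("kruskal_wallis needs >= 2 groups of n >= 3")
    if np.ptp(np.concatenate(gs)) == 0:
        raise DegenerateSampleError("all values tied")
    h, p = sps.kruskal(*gs)
    return float(h), float(p)


def mann_whitney_u(a: Sequence[float], b: Sequence[float],
                   tails: int = 2) -> tuple[float, float]:
    """Mann–Whitney U: exact enumeration for small tie-free samples
    (n <= 8 per group), tie-corrected normal approximation otherwise."""
    x, y = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InsufficientDataError("mann_whitney_u needs non-empty samples")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and not has_ties) else "asymptotic"
    alt = "two-sided" if tails == 2 else "greater"
    res = sps.mannwhitneyu(x, y, alternative=alt, method=method)
    return float(res.statistic), float(res.pvalue)


def unpaired_t_test(a: Sequence[float], b: Sequence[float], tails: int = 2
                    ) -> tuple[float, float, tuple[float, float]]:
    """Pooled-variance two-sample t-test with a t-based 95% CI of the
    mean difference (a − b)."""
    x, y = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("unpaired_t_test needs n >= 2 per group")
    df = x.size + y.size - 2
    sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / df
    if sp2 == 0:
        raise DegenerateSampleError("zero pooled variance")
    alt = "two-sided" if tails == 2 else "greater"
    res = sps.ttest_ind(x, y, equal_var=True, alternative=alt)
    se = np.sqrt(sp2 * (1.0 / x.size + 1.0 / y.size))
    tcrit = sps.t.ppf(0.975, df)
    diff = x.mean() - y.mean()
    return float(res.statistic), float(res.pvalue), (float(diff - tcrit * se),
                                                     float(diff + tcrit * se))


def two_way_anova_interaction(values: Sequence[float],
                              factor_genotype: Sequence[str],
                              factor_drug: Sequence[str]) -> tuple[float, float]:
    """Genotype × drug interaction F and p from a Type-II regression
    (linear-model) two-way ANOVA; safe for unbalanced designs."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "genotype": list(factor_genotype),
                       "drug": list(factor_drug)})
    cells = df.groupby(["genotype", "drug"]).size()
    n_geno = df["genotype"].nunique()
    n_drug = df["drug"].nunique()
    if n_geno < 2 or n_drug < 2:
        raise DesignError("need >= 2 levels per factor")
    if len(cells) < n_geno * n_drug:
        raise DesignError("empty cell in the genotype x drug design")
    model = smf.ols("value ~ C(genotype) * C(drug)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    row = table.loc["C(genotype):C(drug)"]
    return float(row["F"]), float(row["PR(>F)"])


def holm_correct(pvals: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (used only when the correction
    switch is on)."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj.tolist()


def run_decision_tree(oird_by_genotype: Mapping[str, Sequence[float]],
                      config: DecisionConfig | None = None,
                      focus: tuple[str, str] = ("+/+", "-/-"),
                      raw: pd.DataFrame | None = None) -> TestReport:
    """Execute the full gate → omnibus → post-hoc/pairwise scheme.

    ``oird_by_genotype`` maps genotype label to per-animal OIRD ratios.
    ``raw``, if given, is a long table with columns value/genotype/drug
    on which the two-way interaction ANOVA is run.
    """
    config = config or DecisionConfig()
    branch, norm_p = choose_branch(oird_by_genotype, config)
    groups = {k: np.asarray(v, dtype=float) for k, v in oird_by_genotype.items()}
    fa, fb = focus
    if fa not in groups or fb not in groups:
        raise DesignError(f"focus pair {focus} not present in the groups")

    report = TestReport(branch=branch, normality_p=norm_p, omnibus=("", np.nan, np.nan))
    if branch == "parametric":
        f, p = one_way_anova(list(groups.values()))
        report.omnibus = ("one_way_anova", f, p)
        if p < config.alpha:
            report.posthoc = tukey_hsd_kramer(groups, omnibus_p=p, config=config)
            if config.correct_multiple_comparisons and report.posthoc:
                adj = holm_correct([ph[2] for ph in report.posthoc])
                report.posthoc = [(pair, q, pv) for (pair, q, _), pv
                                  in zip(report.posthoc, adj)]
        t, tp, ci = unpaired_t_test(groups[fa], groups[fb], config.t_test_tails)
        report.pairwise_focus = (focus, "unpaired_t_test", t, tp, ci)
    else:
        h, p = kruskal_wallis(list(groups.values()))
        report.omnibus = ("kruskal_wallis", h, p)
        u, up = mann_whitney_u(groups[fa], groups[fb], config.t_test_tails)
        report.pairwise_focus = (focus, "mann_whitney_u", u, up, None)

    if raw is not None:
        report.two_way = two_way_anova_interaction(
            raw["value"], raw["genotype"], raw["drug"])
    return report
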