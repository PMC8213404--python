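"""Independent brute-force reference implementations used as oracles.

These follow the documented segmentation/testing rules with plain
Python loops, deliberately avoiding the vectorized code paths of the
package, so agreement is a meaningful cross-check.
"""

from __future__ import annotations

import itertools

import numpy as np


def _sign(v: float) -> int:
    return 0 if v == 0 else (1 if v > 0 else -1)


def oracle_boundaries(x, fs: float, hysteresis: float,
                      drop_edge: bool = True) -> list[tuple[float, float, float]]:
    """Rule-following breath segmentation by exhaustive scan.

    Rules: lobes are maximal same-sign runs (interior zero-runs stay in
    the lobe only if the same sign resumes); crossings are interpolated
    between adjacent opposite-sign samples, or sit at the first/last
    zero of a separating zero-run; lobes whose extreme |flow| does not
    exceed the hysteresis are dropped and surviving same-sign
    neighbours merge; a breath is inspiration onset -> expiration onset
    of the next breath (or the expiratory lobe's end crossing for the
    final breath, unless sub-threshold activity follows it).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    t = [i / fs for i in range(n)]

    # maximal constant-sign runs, zeros as their own runs
    runs: list[tuple[int, int, int]] = []
    i = 0
    while i < n:
        s = _sign(x[i])
        j = i
        while j + 1 < n and _sign(x[j + 1]) == s:
            j += 1
        runs.append((s, i, j))
        i = j + 1

    # collapse (sign, zeros..., same sign) into lobes; record zero-run gaps
    lobes = []  # dict: sign, i0, i1, start, end, peak
    k = 0
    while k < len(runs):
        s, i0, i1 = runs[k]
        if s == 0:
            k += 1
            continue
        j1 = i1
        m = k + 1
        while m + 1 < len(runs) and runs[m][0] == 0 and runs[m + 1][0] == s:
            j1 = runs[m + 1][2]
            m += 2
        # start crossing
        if i0 == 0:
            start = None
        elif _sign(x[i0 - 1]) == 0:
            start = t[i0 - 1]
        else:
            a, b = x[i0 - 1], x[i0]
            start = t[i0 - 1] + (a / (a - b)) / fs
        if j1 == n - 1:
            end = None
        elif _sign(x[j1 + 1]) == 0:
            end = t[j1 + 1]
        else:
            a, b = x[j1], x[j1 + 1]
            end = t[j1] + (a / (a - b)) / fs
        peak = max(abs(v) for v in x[i0:j1 + 1])
        lobes.append({"sign": s, "start": start, "end": end, "peak": peak})
        k = m if m > k + 1 else k + 1

    valid = [l for l in lobes if l["peak"] > hysteresis]
    merged: list[dict] = []
    for l in valid:
        if merged and merged[-1]["sign"] == l["sign"]:
            merged[-1]["end"] = l["end"]
            merged[-1]["peak"] = max(merged[-1]["peak"], l["peak"])
        else:
            merged.append(dict(l))

    trailing = False
    if merged and merged[-1]["end"] is not None:
        last_end = merged[-1]["end"]
        for l in lobes:
            if l["peak"] <= hysteresis and l["start"] is not None \
                    and l["start"] >= last_end - 1e-12:
                trailing = True

    out = []
    for idx, lobe in enumerate(merged):
        if lobe["sign"] != -1 or idx + 1 >= len(merged):
            continue
        exp = merged[idx + 1]
        onset, insp_off = lobe["start"], lobe["end"]
        if idx + 2 < len(merged) and merged[idx + 2]["start"] is not None:
            exp_off = merged[idx + 2]["start"]
        else:
            exp_off = None if (trailing and idx + 2 >= len(merged)) else exp["end"]
        if onset is None or insp_off is None or exp_off is None:
            if drop_edge:
                continue
        if onset is not None and insp_off is not None and exp_off is not None \
                and onset < insp_off < exp_off:
            out.append((onset, insp_off, exp_off))
    return out


def permutation_mann_whitney_p(a, b) -> float:
    """Exact two-sided Mann–Whitney p by full enumeration of group
    relabelings (tie-free data)."""
    a, b = list(a), list(b)
    pooled = a + b
    na = len(a)

    def u_stat(xs, ys):
        return sum(1 for x in xs for y in ys if x > y) \
            + 0.5 * sum(1 for x in xs for y in ys if x == y)

    u_obs = u_stat(a, b)
    n_ab = na * len(b)
    dev_obs = abs(u_obs - n_ab / 2.0)
    count = 0
    total = 0
    for comb in itertools.combinations(range(len(pooled)), na):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(len(pooled)) if i not in comb]
        total += 1
        if abs(u_stat(xs, ys) - n_ab / 2.0) >= dev_obs - 1e-12:
            count += 1
    return count / total


def lstsq_anova_f(groups) -> tuple[float, float]:
    """One-way ANOVA F via an explicit design-matrix least-squares fit."""
    from scipy import stats as sps
    y = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = y.size
    k = len(groups)
    X = np.zeros((n, k))
    row = 0
    for j, g in enumerate(groups):
        X[row:row + len(g), j] = 1.0
        row += len(g)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    sse = float(((y - X @ beta) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    ssb = sst - sse
    f = (ssb / (k - 1)) / (sse / (n - k))
    return f, float(sps.f.sf(f, k - 1, n - k))


def lstsq_t_test(a, b) -> float:
    """Pooled two-sample t statistic via a regression slope fit."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    y = np.concatenate([a, b])
    X = np.column_stack([np.ones(y.size),
                         np.concatenate([np.ones(a.size), np.zeros(b.size)])])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = y.size - 2
    s2 = float((resid ** 2).sum()) / df
    cov = s2 * np.linalg.inv(X.T @ X)
    return float(beta[1] / np.sqrt(cov[1, 1]))


def simulate_welch_power(delta: float, n1: int, n2: int, sd1: float, sd2: float,
                         alpha: float, n_reps: int, rng) -> float:
    """Monte-Carlo power of the two-sided Welch t-test (vectorized)."""
    from scipy import stats as sps
    x = rng.normal(delta, sd1, size=(n_reps, n1))
    y = rng.normal(0.0, sd2, size=(n_reps, n2))
    v1 = x.var(axis=1, ddof=1) / n1
    v2 = y.var(axis=1, ddof=1) / n2
    t = (x.mean(axis=1) - y.mean(axis=1)) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return float((p < alpha).mean())
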