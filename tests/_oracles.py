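"""Independent brute-force oracles used only by the test suite.

Everything here is deliberately written from first principles (explicit
loops, sorted-list medians, direct quadrature), sharing no code with the
package implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate


def _median(vals: list[float]) -> float:
    s = sorted(vals)
    m = len(s)
    return (s[(m - 1) // 2] + s[m // 2]) / 2.0


def brute_velocity(position: np.ndarray, window: int = 5) -> list[list[float]]:
    n = len(position)
    dt = 0.001
    v = [[0.0, 0.0] for _ in range(n)]
    for t in range(n):
        for c in range(2):
            if window >= 5 and 2 <= t <= n - 3:
                v[t][c] = (
                    position[t + 2][c]
                    + position[t + 1][c]
                    - position[t - 1][c]
                    - position[t - 2][c]
                ) / (6 * dt)
            elif 1 <= t <= n - 2:
                v[t][c] = (position[t + 1][c] - position[t - 1][c]) / (2 * dt)
    return v


def brute_supra_threshold(
    position: np.ndarray,
    valid: np.ndarray,
    lambda_sd: float = 6.0,
    mode: str = "norm_median",
    window: int = 5,
) -> list[bool]:
    """Per-sample above-threshold flags, recomputed from scratch."""
    n = len(position)
    v = brute_velocity(position, window)
    z = [[math.nan, math.nan] for _ in range(n)]
    for c in range(2):
        ref = [v[t][c] for t in range(n) if valid[t] and math.isfinite(v[t][c])]
        med = _median(ref)
        var = _median([x * x for x in ref]) - med * med
        sig = math.sqrt(max(var, 0.0))
        if sig == 0.0:
            return [False] * n
        for t in range(n):
            z[t][c] = (v[t][c] - med) / sig
    rho = [math.hypot(z[t][0], z[t][1]) for t in range(n)]
    if mode == "norm_median":
        ref = [rho[t] for t in range(n) if valid[t] and math.isfinite(rho[t])]
        mr = _median(ref)
        sig = 1.4826 * _median([abs(x - mr) for x in ref])
        if sig == 0.0:
            return [False] * n
        thr = mr + lambda_sd * sig
    else:
        thr = lambda_sd
    return [
        bool(valid[t]) and math.isfinite(rho[t]) and rho[t] > thr for t in range(n)
    ]


def brute_detect_mono(
    position: np.ndarray,
    valid: np.ndarray,
    lambda_sd: float = 6.0,
    min_dur: int = 6,
    mode: str = "norm_median",
    window: int = 5,
) -> list[tuple[int, int]]:
    """Saccade (onset, offset) pairs by testing every window of length
    ``min_dur``: a sample belongs to an event iff some full window of
    consecutive above-threshold valid samples covers it."""
    above = brute_supra_threshold(position, valid, lambda_sd, mode, window)
    n = len(above)
    support: set[int] = set()
    for i in range(n - min_dur + 1):
        if all(above[i : i + min_dur]):
            support.update(range(i, i + min_dur))
    events = []
    for t in sorted(support):
        if events and t == events[-1][1] + 1:
            events[-1][1] = t
        else:
            events.append([t, t])
    return [(a, b) for a, b in events]


def brute_binocular(
    left: list[tuple[int, int]],
    right: list[tuple[int, int]],
    isi_ms: float = 50.0,
) -> list[tuple[int, int]]:
    """Naive pairing + overshoot rule on (onset, offset) pairs."""
    pairs = []
    used = set()
    for lo, lf in left:
        for j, (ro, rf) in enumerate(right):
            if j in used:
                continue
            if max(lo, ro) <= min(lf, rf):
                used.add(j)
                pairs.append((min(lo, ro), max(lf, rf)))
                break
    pairs.sort()
    kept: list[tuple[int, int]] = []
    for on, off in pairs:
        if kept and on - kept[-1][1] < isi_ms:
            continue
        kept.append((on, off))
    return kept


# ---------------------------------------------------------------------------
# ANOVA


def brute_rm_anova_oneway(Y: np.ndarray) -> tuple[float, int, int, float]:
    """(F, df1, df2, p) by explicit sums-of-squares loops."""
    from scipy import stats as sps

    n, k = Y.shape
    grand = sum(Y[i][j] for i in range(n) for j in range(k)) / (n * k)
    col = [sum(Y[i][j] for i in range(n)) / n for j in range(k)]
    row = [sum(Y[i][j] for j in range(k)) / k for i in range(n)]
    ss_eff = n * sum((c - grand) ** 2 for c in col)
    ss_err = sum(
        (Y[i][j] - row[i] - col[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    df1, df2 = k - 1, (n - 1) * (k - 1)
    F = (ss_eff / df1) / (ss_err / df2)
    return F, df1, df2, float(sps.f.sf(F, df1, df2))


def brute_rm_anova_twoway(Y: np.ndarray) -> dict:
    """Effect -> (F, df1, df2, p) for an n x p x q within-subject cube."""
    from scipy import stats as sps

    n, p, q = Y.shape
    rng_n, rng_p, rng_q = range(n), range(p), range(q)
    grand = sum(Y[i][a][b] for i in rng_n for a in rng_p for b in rng_q) / (n * p * q)
    subj = [sum(Y[i][a][b] for a in rng_p for b in rng_q) / (p * q) for i in rng_n]
    A = [sum(Y[i][a][b] for i in rng_n for b in rng_q) / (n * q) for a in rng_p]
    B = [sum(Y[i][a][b] for i in rng_n for a in rng_p) / (n * p) for b in rng_q]
    AB = [
        [sum(Y[i][a][b] for i in rng_n) / n for b in rng_q] for a in rng_p
    ]
    iA = [[sum(Y[i][a][b] for b in rng_q) / q for a in rng_p] for i in rng_n]
    iB = [[sum(Y[i][a][b] for a in rng_p) / p for b in rng_q] for i in rng_n]

    out = {}
    ss_a = n * q * sum((A[a] - grand) ** 2 for a in rng_p)
    err_a = q * sum(
        (iA[i][a] - subj[i] - A[a] + grand) ** 2 for i in rng_n for a in rng_p
    )
    df1, df2 = p - 1, (n - 1) * (p - 1)
    F = (ss_a / df1) / (err_a / df2)
    out["condition"] = (F, df1, df2, float(sps.f.sf(F, df1, df2)))

    ss_b = n * p * sum((B[b] - grand) ** 2 for b in rng_q)
    err_b = p * sum(
        (iB[i][b] - subj[i] - B[b] + grand) ** 2 for i in rng_n for b in rng_q
    )
    df1, df2 = q - 1, (n - 1) * (q - 1)
    F = (ss_b / df1) / (err_b / df2)
    out["foreperiod"] = (F, df1, df2, float(sps.f.sf(F, df1, df2)))

    ss_ab = n * sum(
        (AB[a][b] - A[a] - B[b] + grand) ** 2 for a in rng_p for b in rng_q
    )
    err_ab = sum(
        (
            Y[i][a][b]
            - iA[i][a]
            - iB[i][b]
            - AB[a][b]
            + A[a]
            + B[b]
            + subj[i]
            - grand
        )
        ** 2
        for i in rng_n
        for a in rng_p
        for b in rng_q
    )
    df1, df2 = (p - 1) * (q - 1), (n - 1) * (p - 1) * (q - 1)
    F = (ss_ab / df1) / (err_ab / df2)
    out["condition:foreperiod"] = (F, df1, df2, float(sps.f.sf(F, df1, df2)))
    return out


# ---------------------------------------------------------------------------
# JZS Bayes factor (Zellner-g mixture form; independent of the package's
# Cauchy-mixture quadrature)


def bf01_g_integral(t: float, n: int, r: float = math.sqrt(2) / 2) -> float:
    v = n - 1

    def num(g: float) -> float:
        c = 1.0 + n * g * r * r
        return (
            c**-0.5
            * (1.0 + t * t / (c * v)) ** (-(v + 1) / 2.0)
            * (2 * math.pi) ** -0.5
            * g**-1.5
            * math.exp(-1.0 / (2 * g))
        )

    I, _ = integrate.quad(num, 0, np.inf, limit=300)
    bf10 = I / (1.0 + t * t / v) ** (-(v + 1) / 2.0)
    return 1.0 / bf10
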