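"""Repeated-measures statistics for the pre-target saccade-rate table.

Implements the full battery applied to the subject x condition x
foreperiod table of mean pre-target saccade rates:

* one- and two-way repeated-measures ANOVA with Mauchly's sphericity
  test; on violation (p < .05) the p-value is corrected with
  Greenhouse-Geisser when epsilon < 0.7 and Huynh-Feldt otherwise;
  partial eta^2 is reported with a 95% CI from noncentral-F inversion;
* planned paired contrasts with Benjamini-Hochberg FDR adjustment per
  family, Cohen's dz with a 95% CI from noncentral-t inversion;
* the Jeffreys-Zellner-Siow Bayes factor BF01 (null in the numerator)
  under a Cauchy(0, sqrt(2)/2) prior on effect size, with a quadrature
  error estimate;
* the within-subject standard error of cell means (between-subject
  offsets removed, sqrt(M/(M-1)) bias correction for M cells);
* a linear-trend analysis of the five low-certainty foreperiods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, linalg, optimize
from scipy import stats as sps

from .core import CONDITIONS
from .hypotheses import HypothesisVerdict, evaluate_against, predictions

__all__ = [
    "AnovaResult",
    "rm_anova_oneway",
    "rm_anova_twoway",
    "ContrastSpec",
    "ContrastResult",
    "DEFAULT_CONTRAST_FAMILIES",
    "planned_contrasts",
    "fdr_bh",
    "bf01_ttest",
    "within_subject_sem",
    "TrendResult",
    "foreperiod_trend",
    "AnalysisResults",
    "analyze_sr_table",
]


# ---------------------------------------------------------------------------
# helpers


def pivot_cells(
    table: pd.DataFrame,
    conditions: tuple[str, ...],
    foreperiods: tuple[int, ...],
) -> tuple[list, np.ndarray]:
    """(subjects, n x p x q cube) from the tidy SR table; rejects missing
    or NaN cells, naming the offending subject/cell."""
    subjects = sorted(table["subject_id"].unique())
    cube = np.full((len(subjects), len(conditions), len(foreperiods)), np.nan)
    idx = table.set_index(["subject_id", "condition", "foreperiod_ms"])["mean_sr"]
    for i, s in enumerate(subjects):
        for a, cond in enumerate(conditions):
            for b, fp in enumerate(foreperiods):
                try:
                    cube[i, a, b] = idx.loc[(s, cond, fp)]
                except KeyError:
                    raise ValueError(
                        f"missing cell: subject {s!r}, {cond} @ {fp} ms"
                    ) from None
    bad = np.argwhere(~np.isfinite(cube))
    if len(bad):
        i, a, b = bad[0]
        raise ValueError(
            f"cell not computable (NaN): subject {subjects[i]!r}, "
            f"{conditions[a]} @ {foreperiods[b]} ms"
        )
    return subjects, cube


def _helmert(k: int) -> np.ndarray:
    """k x (k-1) orthonormal contrast basis orthogonal to the unit vector."""
    return linalg.helmert(k).T


def _sphericity(scores: np.ndarray) -> tuple[float, float, float, float]:
    """(mauchly_w, mauchly_p, eps_gg, eps_hf) from n x d contrast scores."""
    n, d = scores.shape
    if d < 2:
        return float("nan"), float("nan"), 1.0, 1.0
    S = np.cov(scores, rowvar=False, ddof=1)
    tr = float(np.trace(S))
    eps_gg = tr**2 / (d * float(np.trace(S @ S)))
    eps_hf = min(1.0, (n * d * eps_gg - 2.0) / (d * (n - 1.0 - d * eps_gg)))
    if n - 1 <= d:
        return float("nan"), float("nan"), eps_gg, eps_hf
    det = float(np.linalg.det(S))
    if det <= 0:
        return 0.0, 0.0, eps_gg, eps_hf
    w = det / (tr / d) ** d
    f = d * (d + 1) // 2 - 1
    c = 1.0 - (2 * d**2 + d + 2) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * c * math.log(w)
    # second-order chi-square approximation (as in ezANOVA/pingouin)
    k = d + 1
    w2 = (
        (d + 2) * (d - 1) * (d - 2) * (2 * d**3 + 6 * d**2 + 3 * k + 2)
        / (288.0 * ((n - 1) * d * c) ** 2)
    )
    p1 = float(sps.chi2.sf(chi2, f))
    p2 = float(sps.chi2.sf(chi2, f + 4))
    p = p1 + w2 * (p2 - p1)
    return w, p, eps_gg, eps_hf


def _eta_sq_ci(
    F: float, df1: float, df2: float, conf: float = 0.95
) -> tuple[float, float]:
    """95% CI for partial eta^2 by inverting the noncentral-F distribution."""
    alpha = 1.0 - conf

    def _bound(q: float) -> float:
        # ncp lambda with P(F' <= F_obs; lambda) = q
        if sps.ncf.cdf(F, df1, df2, 0.0) < q:
            return 0.0
        hi = 1.0
        while sps.ncf.cdf(F, df1, df2, hi) > q:
            hi *= 2.0
            if hi > 1e7:
                return hi
        return float(optimize.brentq(
            lambda lam: sps.ncf.cdf(F, df1, df2, lam) - q, 0.0, hi, xtol=1e-10
        ))

    lam_lo = _bound(1.0 - alpha / 2.0)
    lam_hi = _bound(alpha / 2.0)
    conv = lambda lam: lam / (lam + df1 + df2 + 1.0)  # noqa: E731
    return conv(lam_lo), conv(lam_hi)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


@dataclass
class AnovaResult:
    effect: str
    F: float
    df1: float
    df2: float
    p: float  # reported p (sphericity-corrected when applied)
    p_uncorrected: float
    partial_eta_sq: float
    eta_ci: tuple[float, float]
    epsilon_gg: float
    epsilon_hf: float
    mauchly_w: float
    mauchly_p: float
    correction: str  # "none" | "greenhouse_geisser" | "huynh_feldt"
    df1_corr: float
    df2_corr: float


def _finish_effect(
    effect: str,
    ss_eff: float,
    ss_err: float,
    df1: int,
    df2: int,
    scores: np.ndarray,
    alpha_sphericity: float = 0.05,
) -> AnovaResult:
    ms_eff = ss_eff / df1
    ms_err = ss_err / df2
    F = ms_eff / ms_err if ms_err > 0 else float("inf") if ms_eff > 0 else 0.0
    p_unc = float(sps.f.sf(F, df1, df2))
    w, wp, eps_gg, eps_hf = _sphericity(scores)
    correction, eps = "none", 1.0
    if np.isfinite(wp) and wp < alpha_sphericity:
        if eps_gg < 0.7:
            correction, eps = "greenhouse_geisser", eps_gg
        else:
            correction, eps = "huynh_feldt", eps_hf
    df1c, df2c = df1 * eps, df2 * eps
    p = float(sps.f.sf(F, df1c, df2c)) if correction != "none" else p_unc
    eta = ss_eff / (ss_eff + ss_err) if ss_eff + ss_err > 0 else 0.0
    ci = _eta_sq_ci(F, df1, df2) if np.isfinite(F) else (float("nan"),) * 2
    return AnovaResult(
        effect=effect,
        F=float(F),
        df1=df1,
        df2=df2,
        p=p,
        p_uncorrected=p_unc,
        partial_eta_sq=float(eta),
        eta_ci=ci,
        epsilon_gg=float(eps_gg),
        epsilon_hf=float(eps_hf),
        mauchly_w=float(w),
        mauchly_p=float(wp),
        correction=correction,
        df1_corr=float(df1c),
        df2_corr=float(df2c),
    )


def rm_anova_oneway(data: np.ndarray, effect: str = "factor") -> AnovaResult:
    """One-way within-subject ANOVA on an n x k matrix of cell means."""
    Y = np.asarray(data, dtype=float)
    n, k = Y.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 levels")
    grand = Y.mean()
    col = Y.mean(axis=0)
    row = Y.mean(axis=1)
    ss_eff = n * float(((col - grand) ** 2).sum())
    resid = Y - row[:, None] - col[None, :] + grand
    ss_err = float((resid**2).sum())
    scores = Y @ _helmert(k)
    return _finish_effect(effect, ss_eff, ss_err, k - 1, (n - 1) * (k - 1), scores)


def rm_anova_twoway(
    table: pd.DataFrame,
    conditions: tuple[str, ...] = CONDITIONS,
    foreperiods: tuple[int, ...] = (1000, 2000),
) -> list[AnovaResult]:
    """Two-way within-subject ANOVA (Condition x Foreperiod) on the tidy
    SR table. Returns results for both main effects and the interaction."""
    _, Y = pivot_cells(table, conditions, foreperiods)
    n, p, q = Y.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    grand = Y.mean()
    subj = Y.mean(axis=(1, 2))
    A = Y.mean(axis=(0, 2))
    B = Y.mean(axis=(0, 1))
    AB = Y.mean(axis=0)
    iA = Y.mean(axis=2)  # subject x A
    iB = Y.mean(axis=1)  # subject x B

    Ca, Cb = _helmert(p), _helmert(q)

    ss_a = n * q * float(((A - grand) ** 2).sum())
    err_a = q * float(
        ((iA - subj[:, None] - A[None, :] + grand) ** 2).sum()
    )
    res_a = _finish_effect(
        "condition", ss_a, err_a, p - 1, (n - 1) * (p - 1), iA @ Ca
    )

    ss_b = n * p * float(((B - grand) ** 2).sum())
    err_b = p * float(
        ((iB - subj[:, None] - B[None, :] + grand) ** 2).sum()
    )
    res_b = _finish_effect(
        "foreperiod", ss_b, err_b, q - 1, (n - 1) * (q - 1), iB @ Cb
    )

    ss_ab = n * float(
        ((AB - A[:, None] - B[None, :] + grand) ** 2).sum()
    )
    resid = (
        Y
        - iA[:, :, None]
        - iB[:, None, :]
        - AB[None, :, :]
        + A[None, :, None]
        + B[None, None, :]
        + subj[:, None, None]
        - grand
    )
    err_ab = float((resid**2).sum())
    scores_ab = Y.reshape(n, p * q) @ np.kron(Ca, Cb)
    res_ab = _finish_effect(
        "condition:foreperiod",
        ss_ab,
        err_ab,
        (p - 1) * (q - 1),
        (n - 1) * (p - 1) * (q - 1),
        scores_ab,
    )
    return [res_a, res_b, res_ab]


# ---------------------------------------------------------------------------
# planned contrasts


@dataclass(frozen=True)
class ContrastSpec:
    label: str
    foreperiod_ms: int
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]


#: The planned-contrast families: three contrasts at the 1 s foreperiod,
#: two at 2 s (full-certainty vs the two high-certainty cells combined).
DEFAULT_CONTRAST_FAMILIES: dict[str, list[ContrastSpec]] = {
    "fp1000": [
        ContrastSpec("full_vs_low@1s", 1000, ("full_certainty",), ("low_certainty",)),
        ContrastSpec(
            "rare_vs_frequent@1s",
            1000,
            ("high_certainty_rare",),
            ("high_certainty_frequent",),
        ),
        ContrastSpec(
            "rare_vs_low@1s", 1000, ("high_certainty_rare",), ("low_certainty",)
        ),
    ],
    "fp2000": [
        ContrastSpec("full_vs_low@2s", 2000, ("full_certainty",), ("low_certainty",)),
        ContrastSpec(
            "full_vs_high_combined@2s",
            2000,
            ("full_certainty",),
            ("high_certainty_frequent", "high_certainty_rare"),
        ),
    ],
}


@dataclass
class ContrastResult:
    label: str
    family: str
    foreperiod_ms: int
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    n: int
    mean_diff: float
    t: float
    df: int
    p_raw: float
    p_fdr: float
    dz: float
    dz_ci: tuple[float, float]
    bf01: float
    bf01_err_pct: float


def fdr_bh(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, >= raw)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _nct_cdf(t: float, df: float, nc: float) -> float:
    """nct CDF with far-tail NaNs resolved by monotonicity in nc."""
    val = sps.nct.cdf(t, df, nc)
    if np.isnan(val):
        return 0.0 if nc > t else 1.0
    return float(val)


def _dz_ci(t: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    """CI for Cohen's dz by inverting the noncentral-t distribution."""
    alpha = 1.0 - conf
    df = n - 1

    def _bound(q: float) -> float:
        # ncp with P(T <= t_obs; ncp) = q; cdf decreases in ncp
        lo, hi = t - 2.0, t + 2.0
        while _nct_cdf(t, df, lo) < q:
            lo -= 10.0
        while _nct_cdf(t, df, hi) > q:
            hi += 10.0
        return float(optimize.brentq(
            lambda nc: _nct_cdf(t, df, nc) - q, lo, hi, xtol=1e-9
        ))

    return _bound(1.0 - alpha / 2.0) / math.sqrt(n), _bound(alpha / 2.0) / math.sqrt(n)


def bf01_ttest(
    t: float, n: int, cauchy_scale: float = math.sqrt(2) / 2
) -> tuple[float, float]:
    """JZS Bayes factor BF01 for a one-sample (paired) t statistic.

    The alternative places a Cauchy(0, ``cauchy_scale``) prior on the
    standardized effect size; BF01 > 1 favors the null. Returns
    (bf01, percentage error of the quadrature).
    """
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    if n < 2:
        raise ValueError("n must be >= 2")
    df = n - 1
    sqn = math.sqrt(n)

    def integrand(theta: float) -> float:
        delta = cauchy_scale * math.tan(theta)
        return sps.nct.pdf(t, df, delta * sqn)

    marg_alt, err = integrate.quad(
        integrand, -math.pi / 2, math.pi / 2, limit=200, epsabs=1e-12, epsrel=1e-10
    )
    marg_alt /= math.pi
    err /= math.pi
    like_null = sps.t.pdf(t, df)
    bf01 = like_null / marg_alt
    err_pct = 100.0 * err / marg_alt if marg_alt > 0 else float("inf")
    return float(bf01), float(err_pct)


def planned_contrasts(
    table: pd.DataFrame,
    families: dict[str, list[ContrastSpec]] | None = None,
    cauchy_scale: float = math.sqrt(2) / 2,
) -> list[ContrastResult]:
    """Paired t contrasts on subject cell means, BH-FDR adjusted per family.

    Combined cells (e.g. the two high-certainty conditions) are averaged
    within subject before the paired t. Cohen's dz = mean(diff)/SD(diff).
    """
    if families is None:
        families = DEFAULT_CONTRAST_FAMILIES
    idx = table.set_index(["subject_id", "condition", "foreperiod_ms"])["mean_sr"]
    subjects = sorted(table["subject_id"].unique())
    results: list[ContrastResult] = []
    for family, specs in families.items():
        fam_results = []
        for spec in specs:
            diffs = []
            for s in subjects:
                try:
                    a = np.mean([idx.loc[(s, c, spec.foreperiod_ms)] for c in spec.group_a])
                    b = np.mean([idx.loc[(s, c, spec.foreperiod_ms)] for c in spec.group_b])
                except KeyError as exc:
                    raise ValueError(
                        f"contrast {spec.label}: missing cell {exc} for subject {s!r}"
                    ) from None
                diffs.append(a - b)
            d = np.asarray(diffs, dtype=float)
            n = len(d)
            sd = float(np.std(d, ddof=1))
            mean = float(np.mean(d))
            if sd == 0.0:
                t_stat = 0.0 if mean == 0.0 else math.copysign(math.inf, mean)
                dz = float("nan")
                p_raw = 1.0 if mean == 0.0 else 0.0
                dz_ci = (float("nan"), float("nan"))
                bf01, bf_err = float("nan"), float("nan")
            else:
                t_stat = mean / (sd / math.sqrt(n))
                dz = mean / sd
                p_raw = float(2.0 * sps.t.sf(abs(t_stat), n - 1))
                dz_ci = _dz_ci(t_stat, n)
                bf01, bf_err = bf01_ttest(t_stat, n, cauchy_scale)
            fam_results.append(
                ContrastResult(
                    label=spec.label,
                    family=family,
                    foreperiod_ms=spec.foreperiod_ms,
                    group_a=spec.group_a,
                    group_b=spec.group_b,
                    n=n,
                    mean_diff=mean,
                    t=float(t_stat),
                    df=n - 1,
                    p_raw=p_raw,
                    p_fdr=float("nan"),
                    dz=dz,
                    dz_ci=dz_ci,
                    bf01=bf01,
                    bf01_err_pct=bf_err,
                )
            )
        adj = fdr_bh(np.array([r.p_raw for r in fam_results]))
        for r, pa in zip(fam_results, adj):
            r.p_fdr = float(pa)
        results.extend(fam_results)
    return results


# ---------------------------------------------------------------------------
# within-subject SEM


def within_subject_sem(table: pd.DataFrame) -> pd.DataFrame:
    """Within-subject standard error per cell.

    Subject offsets are removed (each subject's cell values are centered
    on their own mean, the grand mean restored) and the per-cell SD/sqrt(n)
    is inflated by sqrt(M/(M-1)) for M cells.
    """
    wide = table.pivot_table(
        index="subject_id", columns=["condition", "foreperiod_ms"], values="mean_sr"
    )
    if wide.isna().any().any():
        raise ValueError("within_subject_sem requires a complete table")
    n, m = wide.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    centered = wide.sub(wide.mean(axis=1), axis=0) + wide.values.mean()
    sem = centered.std(axis=0, ddof=1) / math.sqrt(n) * math.sqrt(m / (m - 1.0))
    out = sem.reset_index()
    out.columns = ["condition", "foreperiod_ms", "sem"]
    return out


# ---------------------------------------------------------------------------
# low-certainty foreperiod trend


@dataclass
class TrendResult:
    anova: AnovaResult
    trend_t: float
    trend_p: float
    trend_df: int
    mean_score: float  # mean linear-trend score; negative = decreasing SR
    dz: float


def foreperiod_trend(
    table: pd.DataFrame,
    foreperiods: tuple[int, ...] = (1000, 1500, 2000, 2500, 3000),
) -> TrendResult:
    """One-way RM-ANOVA over the five low-certainty foreperiods plus a
    linear-trend contrast (weights -2,-1,0,1,2); a negative mean score is
    the signature of hazard-driven inhibition growing with elapsed time."""
    low = table[table["condition"] == "low_certainty"]
    _, cube = pivot_cells(low, ("low_certainty",), foreperiods)
    Y = cube[:, 0, :]  # n x 5
    anova = rm_anova_oneway(Y, effect="foreperiod(low_certainty)")
    w = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
    scores = Y @ w
    n = len(scores)
    sd = float(np.std(scores, ddof=1))
    mean = float(np.mean(scores))
    if sd == 0.0:
        t_stat, p = (0.0, 1.0) if mean == 0.0 else (math.copysign(math.inf, mean), 0.0)
        dz = float("nan")
    else:
        t_stat = mean / (sd / math.sqrt(n))
        p = float(2.0 * sps.t.sf(abs(t_stat), n - 1))
        dz = mean / sd
    return TrendResult(
        anova=anova, trend_t=float(t_stat), trend_p=p, trend_df=n - 1,
        mean_score=mean, dz=float(dz),
    )


# ---------------------------------------------------------------------------
# full battery


@dataclass
class AnalysisResults:
    anova_twoway: list[AnovaResult]
    anova_fp1000: AnovaResult
    anova_fp2000: AnovaResult
    contrasts: list[ContrastResult]
    sem: pd.DataFrame
    trend: TrendResult | None
    verdicts: dict[str, HypothesisVerdict] = field(default_factory=dict)


def analyze_sr_table(
    table: pd.DataFrame,
    alpha: float = 0.05,
    bf01_min: float = 1 / 3,
) -> AnalysisResults:
    """Run the complete statistical battery on a tidy pre-target SR table
    and evaluate both hypotheses' predictions against the contrasts."""
    anova2 = rm_anova_twoway(table)
    _, cube = pivot_cells(table, CONDITIONS, (1000, 2000))
    a1 = rm_anova_oneway(cube[:, :, 0], effect="condition@1s")
    a2 = rm_anova_oneway(cube[:, :, 1], effect="condition@2s")
    contrasts = planned_contrasts(table)
    sem = within_subject_sem(
        table[table["foreperiod_ms"].isin((1000, 2000))]
    )
    has_low5 = (
        table[table["condition"] == "low_certainty"]["foreperiod_ms"].nunique() == 5
    )
    trend = foreperiod_trend(table) if has_low5 else None
    verdicts = {
        h: evaluate_against(contrasts, predictions(h), alpha=alpha, bf01_min=bf01_min)
        for h in ("certainty", "orienting")
    }
    return AnalysisResults(
        anova_twoway=anova2,
        anova_fp1000=a1,
        anova_fp2000=a2,
        contrasts=contrasts,
        sem=sem,
        trend=trend,
        verdicts=verdicts,
    )
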