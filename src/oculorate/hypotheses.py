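"""Foreperiod hazard rates and the competing hypotheses' ordinal predictions.

A temporal cue starts a foreperiod drawn from a block-specific discrete
distribution; the *hazard rate* at a possible target time t is the
probability that the target occurs at t given that it has not occurred
earlier. Two accounts of pre-target oculomotor inhibition make different
ordinal predictions for the mean pre-target saccade rate across the four
trial conditions:

* **certainty** — inhibition tracks the overall temporal certainty of the
  block, identical for every trial in a block;
* **temporal orienting** — inhibition tracks the momentary conditional
  probability of the target (at 1 s, the marginal foreperiod frequency;
  at 2 s, the hazard rate, which reaches 1 in every design whose support
  ends at 2 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CONDITIONS

__all__ = [
    "ForeperiodDistribution",
    "BLOCK_DISTRIBUTIONS",
    "hazard",
    "hazard_profile",
    "anticipation",
    "PredictionTable",
    "predictions",
    "EqualityCheck",
    "InequalityCheck",
    "HypothesisVerdict",
    "evaluate_against",
]


@dataclass(frozen=True)
class ForeperiodDistribution:
    """Discrete foreperiod distribution: strictly increasing support (ms)
    with probabilities summing to one."""

    support: tuple[int, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.support) != len(self.probs):
            raise ValueError("support and probs must have equal length")
        if np.any(np.diff(self.support) <= 0):
            raise ValueError("support must be strictly increasing")
        if any(p < 0 for p in self.probs):
            raise ValueError("probs must be nonnegative")
        if abs(sum(self.probs) - 1.0) > 1e-12:
            raise ValueError("probs must sum to 1")

    def prob(self, t: int) -> float:
        try:
            return self.probs[self.support.index(t)]
        except ValueError:
            return 0.0

    def survival(self, t: float) -> float:
        """P(foreperiod >= t)."""
        return float(sum(p for s, p in zip(self.support, self.probs) if s >= t))


#: The five block designs: per-block foreperiod percentages.
BLOCK_DISTRIBUTIONS: dict[str, ForeperiodDistribution] = {
    "full_certainty_1s": ForeperiodDistribution((1000,), (1.0,)),
    "full_certainty_2s": ForeperiodDistribution((2000,), (1.0,)),
    "high_certainty_1s": ForeperiodDistribution((1000, 2000), (0.8, 0.2)),
    "high_certainty_2s": ForeperiodDistribution((1000, 2000), (0.2, 0.8)),
    "low_certainty": ForeperiodDistribution(
        (1000, 1500, 2000, 2500, 3000), (0.2,) * 5
    ),
}


def hazard(dist: ForeperiodDistribution, t: int) -> float:
    """Conditional probability P(FP = t | FP >= t) at support point t.

    Evaluated exactly at support points: "not occurred up until t" means the
    foreperiod did not end at any earlier support point.
    """
    if t not in dist.support:
        raise ValueError(f"t={t} is not a support point of the distribution")
    surv = dist.survival(t)
    if surv == 0.0:
        raise ZeroDivisionError("P(FP >= t) = 0: hazard undefined")
    return dist.prob(t) / surv


@dataclass(frozen=True)
class HazardProfile:
    dist: ForeperiodDistribution
    eval_times: tuple[int, ...]
    hazard: tuple[float, ...]


def hazard_profile(dist: ForeperiodDistribution) -> HazardProfile:
    """Hazard at every support point of the distribution."""
    hz = tuple(hazard(dist, t) for t in dist.support)
    return HazardProfile(dist=dist, eval_times=dist.support, hazard=hz)


def anticipation(dist: ForeperiodDistribution, tau_ms: float, window_ms: float) -> float:
    """P(target occurs within ``window_ms`` after ``tau_ms`` | no target yet).

    This is the generative 'anticipation' driving pre-target inhibition in
    the simulator: the conditional probability mass of the foreperiod
    falling in (tau, tau + window], given survival past tau.
    """
    surv = float(sum(p for s, p in zip(dist.support, dist.probs) if s > tau_ms))
    if surv <= 0.0:
        return 0.0
    mass = float(
        sum(
            p
            for s, p in zip(dist.support, dist.probs)
            if tau_ms < s <= tau_ms + window_ms
        )
    )
    return mass / surv


# ---------------------------------------------------------------------------
# Ordinal predictions


@dataclass(frozen=True)
class PredictionTable:
    """Ordinal inhibition levels per condition at each analyzed foreperiod.

    Lower level = stronger inhibition = lower pre-target saccade rate.
    Conditions sharing a level form an equality class.
    """

    hypothesis: str
    levels: dict[int, dict[str, int]]  # foreperiod -> condition -> level

    def equality_classes(self, foreperiod_ms: int) -> list[frozenset[str]]:
        by_level: dict[int, set[str]] = {}
        for cond, lvl in self.levels[foreperiod_ms].items():
            by_level.setdefault(lvl, set()).add(cond)
        return [frozenset(by_level[k]) for k in sorted(by_level)]

    def relation(self, foreperiod_ms: int, a: str, b: str) -> str:
        """'lt', 'gt' or 'eq' between conditions a and b."""
        la, lb = self.levels[foreperiod_ms][a], self.levels[foreperiod_ms][b]
        return "eq" if la == lb else ("lt" if la < lb else "gt")


def predictions(hypothesis: str) -> PredictionTable:
    """Prediction table for 'certainty' or 'orienting'.

    certainty (both foreperiods): full < {freq = rare} < low — inhibition
    follows block-level certainty only.

    orienting at 1 s: full < freq < {rare = low} — inhibition follows the
    marginal foreperiod frequency (100/80/20/20%).

    orienting at 2 s: {full = freq = rare} < low — inhibition follows the
    hazard rate (1/1/1 vs 1/3).
    """
    full, freq, rare, low = CONDITIONS
    if hypothesis == "certainty":
        per_fp = {full: 0, freq: 1, rare: 1, low: 2}
        levels = {1000: dict(per_fp), 2000: dict(per_fp)}
    elif hypothesis == "orienting":
        levels = {
            1000: {full: 0, freq: 1, rare: 2, low: 2},
            2000: {full: 0, freq: 0, rare: 0, low: 1},
        }
    else:
        raise ValueError(f"unknown hypothesis: {hypothesis!r}")
    return PredictionTable(hypothesis=hypothesis, levels=levels)


# ---------------------------------------------------------------------------
# Verdicts


@dataclass(frozen=True)
class InequalityCheck:
    contrast_label: str
    foreperiod_ms: int
    expected_sign: int  # sign expected for the contrast's mean difference
    passed: bool
    detail: str


@dataclass(frozen=True)
class EqualityCheck:
    contrast_label: str
    foreperiod_ms: int
    passed: bool
    detail: str


@dataclass
class HypothesisVerdict:
    hypothesis: str
    consistent: bool | None  # None when gaps prevent a verdict
    checks: list = field(default_factory=list)
    gaps: list[str] = field(default_factory=list)

    @property
    def verdict(self) -> str:
        if self.consistent is None:
            return "undetermined"
        return "consistent" if self.consistent else "inconsistent"

    def describe(self) -> str:
        """Human-readable verdict report."""
        lines = [f"{self.hypothesis} hypothesis: {self.verdict}"]
        for ch in self.checks:
            kind = "equality" if isinstance(ch, EqualityCheck) else "inequality"
            mark = "pass" if ch.passed else "FAIL"
            lines.append(
                f"  [{mark}] {kind} {ch.contrast_label} "
                f"(@{ch.foreperiod_ms} ms): {ch.detail}"
            )
        for gap in self.gaps:
            lines.append(f"  [gap] {gap}")
        return "\n".join(lines)


def evaluate_against(
    contrasts,
    table: PredictionTable,
    alpha: float = 0.05,
    bf01_min: float = 1 / 3,
) -> HypothesisVerdict:
    """Check every planned contrast against a hypothesis' ordinal predictions.

    Each contrast (see :mod:`oculorate.stats`) compares groups of conditions
    at one foreperiod; its predicted relation is read off the prediction
    table. A predicted inequality passes when the FDR-adjusted p-value is
    below ``alpha`` *and* the mean difference has the predicted sign. A
    predicted equality passes when the contrast is non-significant
    (FDR p >= alpha) and BF01 exceeds ``bf01_min`` (i.e. no substantial
    evidence against the null).
    """
    verdict = HypothesisVerdict(hypothesis=table.hypothesis, consistent=None)
    any_gap = False
    for c in contrasts:
        fp = c.foreperiod_ms
        if fp not in table.levels:
            verdict.gaps.append(f"{c.label}: no predictions at {fp} ms")
            any_gap = True
            continue
        try:
            lvls_a = {table.levels[fp][cond] for cond in c.group_a}
            lvls_b = {table.levels[fp][cond] for cond in c.group_b}
        except KeyError as exc:
            verdict.gaps.append(f"{c.label}: condition {exc} missing from predictions")
            any_gap = True
            continue
        if len(lvls_a) > 1 or len(lvls_b) > 1:
            verdict.gaps.append(
                f"{c.label}: combined cells are not an equality class under "
                f"{table.hypothesis}; relation undefined"
            )
            any_gap = True
            continue
        (la,), (lb,) = lvls_a, lvls_b
        if not np.isfinite(c.t):
            verdict.gaps.append(f"{c.label}: contrast not computable")
            any_gap = True
            continue
        if la == lb:
            ok = c.p_fdr >= alpha and c.bf01 > bf01_min
            verdict.checks.append(
                EqualityCheck(
                    contrast_label=c.label,
                    foreperiod_ms=fp,
                    passed=bool(ok),
                    detail=f"p_fdr={c.p_fdr:.4g}, BF01={c.bf01:.3g} (needs >= {alpha} and > {bf01_min:.3g})",
                )
            )
        else:
            expected = -1 if la < lb else 1  # mean diff is group_a - group_b
            ok = c.p_fdr < alpha and np.sign(c.mean_diff) == expected
            verdict.checks.append(
                InequalityCheck(
                    contrast_label=c.label,
                    foreperiod_ms=fp,
                    expected_sign=expected,
                    passed=bool(ok),
                    detail=f"p_fdr={c.p_fdr:.4g}, mean_diff={c.mean_diff:.4g} (expected sign {expected:+d})",
                )
            )
    if any_gap:
        verdict.consistent = None
    else:
        verdict.consistent = all(ch.passed for ch in verdict.checks)
    return verdict
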