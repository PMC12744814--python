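"""Ground-truth labeling from invasive coronary physiology and diagnostic
test statistics.

Invasive physiology is the reference standard: fractional flow reserve
(FFR) ≤ 0.80, or a non-hyperemic pressure ratio (NHPR, e.g. iFR) ≤ 0.89,
marks a stenosis as hemodynamically significant.  When both indices are
measured they are OR-ed ("and/or" rule, no hierarchy).

The 2x2 machinery follows the conventions of diagnostic-accuracy studies:
sensitivity/specificity/PPV/NPV with Wilson score intervals, the diagnostic
odds ratio with a Wald interval on the log-odds scale (Haldane–Anscombe 0.5
correction only when a cell is empty), rank-based (Mann–Whitney) ROC AUC
with tie correction, Cohen's kappa and Bland–Altman limits of agreement for
observer studies, and an exhaustive reconstruction oracle that recovers an
unpublished 2x2 table from its printed rounded summary statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

FFR_THRESHOLD = 0.80
NHPR_THRESHOLD = 0.89

__all__ = [
    "FFR_THRESHOLD",
    "NHPR_THRESHOLD",
    "PhysiologyResult",
    "classify_physiology",
    "ConfusionTable",
    "confusion_table",
    "Estimate",
    "DiagnosticSummary",
    "diagnostic_metrics",
    "odds_ratio_ci",
    "roc_auc",
    "cohen_kappa",
    "bland_altman",
    "round_half_up",
    "reconstruct_confusion",
]


@dataclass(frozen=True)
class PhysiologyResult:
    """One patient's invasive physiology; ``None`` marks an unmeasured index."""

    ffr: Optional[float] = None
    nhpr: Optional[float] = None

    def __post_init__(self) -> None:
        for name, v in (("ffr", self.ffr), ("nhpr", self.nhpr)):
            if v is not None and not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")


def classify_physiology(
    result: PhysiologyResult,
    ffr_threshold: float = FFR_THRESHOLD,
    nhpr_threshold: float = NHPR_THRESHOLD,
) -> str:
    """"positive" iff FFR ≤ 0.80 and/or NHPR ≤ 0.89 (boundaries positive)."""
    if result.ffr is None and result.nhpr is None:
        raise ValueError("at least one of ffr/nhpr must be measured")
    pos = (result.ffr is not None and result.ffr <= ffr_threshold) or (
        result.nhpr is not None and result.nhpr <= nhpr_threshold
    )
    return "positive" if pos else "negative"


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts: condition = physiology truth, test = pattern prediction."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn

    @property
    def n(self) -> int:
        return self.n_pos + self.n_neg

    def cells(self) -> Tuple[int, int, int, int]:
        return (self.tp, self.fp, self.fn, self.tn)


def _as_bool(labels: Sequence) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "USO":
        known = {"positive": True, "negative": False, "+": True, "-": False}
        try:
            return np.array([known[str(x)] for x in arr])
        except KeyError as e:
            raise ValueError(f"unknown label {e.args[0]!r}") from None
    return arr.astype(bool)


def confusion_table(predictions: Sequence, truths: Sequence) -> ConfusionTable:
    """Tally predicted vs true binary labels into a :class:`ConfusionTable`.

    Labels may be booleans, 0/1, or the strings "positive"/"negative"/"+"/"-".
    """
    pred = _as_bool(predictions)
    true = _as_bool(truths)
    if pred.shape != true.shape or pred.ndim != 1 or pred.size == 0:
        raise ValueError("predictions and truths must be equal-length, non-empty 1-D")
    return ConfusionTable(
        tp=int(np.sum(pred & true)),
        fp=int(np.sum(pred & ~true)),
        fn=int(np.sum(~pred & true)),
        tn=int(np.sum(~pred & ~true)),
    )


@dataclass(frozen=True)
class Estimate:
    """A point estimate with its confidence interval."""

    point: float
    lower: float
    upper: float

    def __iter__(self):
        return iter((self.point, self.lower, self.upper))


@dataclass(frozen=True)
class DiagnosticSummary:
    """Sensitivity/specificity/PPV/NPV (proportions with Wilson CIs) and the
    diagnostic odds ratio (Wald log-odds CI).  A metric whose margin is zero
    is ``None`` — flagged absent, never NaN."""

    sensitivity: Optional[Estimate]
    specificity: Optional[Estimate]
    ppv: Optional[Estimate]
    npv: Optional[Estimate]
    dor: Optional[Estimate]
    level: float = 0.95

    def to_dict(self) -> Dict[str, Optional[Dict[str, float]]]:
        def conv(e: Optional[Estimate]):
            return None if e is None else {"point": e.point, "lower": e.lower,
                                           "upper": e.upper}
        return {
            "sensitivity": conv(self.sensitivity),
            "specificity": conv(self.specificity),
            "ppv": conv(self.ppv),
            "npv": conv(self.npv),
            "dor": conv(self.dor),
            "level": self.level,
        }


def _proportion(count: int, nobs: int, level: float) -> Optional[Estimate]:
    if nobs == 0:
        return None
    lo, hi = proportion_confint(count, nobs, alpha=1 - level, method="wilson")
    return Estimate(count / nobs, float(lo), float(hi))


def _dor(table: ConfusionTable, level: float) -> Optional[Estimate]:
    tp, fp, fn, tn = table.cells()
    if min(table.n_pos, table.n_neg) == 0:
        return None
    if 0 in (tp, fp, fn, tn):  # Haldane–Anscombe correction
        a, b, c, d = (tp + 0.5, fp + 0.5, fn + 0.5, tn + 0.5)
    else:
        a, b, c, d = (float(tp), float(fp), float(fn), float(tn))
    dor = (a * d) / (b * c)
    lo, hi = _wald_or_ci(a, b, c, d, level)
    return Estimate(dor, lo, hi)


def _wald_or_ci(a: float, b: float, c: float, d: float, level: float) -> Tuple[float, float]:
    z = stats.norm.ppf((1 + level) / 2)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log((a * d) / (b * c))
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def diagnostic_metrics(table: ConfusionTable, level: float = 0.95) -> DiagnosticSummary:
    """All 2x2 summary statistics of a diagnostic test.

    sensitivity = tp/(tp+fn), specificity = tn/(tn+fp), ppv = tp/(tp+fp),
    npv = tn/(tn+fn), each with a Wilson score interval; DOR = tp*tn/(fp*fn)
    with a Wald interval on log odds, Haldane-corrected iff a cell is zero.
    """
    return DiagnosticSummary(
        sensitivity=_proportion(table.tp, table.n_pos, level),
        specificity=_proportion(table.tn, table.n_neg, level),
        ppv=_proportion(table.tp, table.tp + table.fp, level),
        npv=_proportion(table.tn, table.tn + table.fn, level),
        dor=_dor(table, level),
        level=level,
    )


def odds_ratio_ci(table: ConfusionTable, level: float = 0.95) -> Tuple[float, float]:
    """Wald CI for the 2x2 cross-product odds ratio,
    ``exp(ln OR ± z·sqrt(1/tp + 1/fp + 1/fn + 1/tn))``; Haldane 0.5 is added
    to every cell first when any cell is zero."""
    tp, fp, fn, tn = table.cells()
    if 0 in (tp, fp, fn, tn):
        cells = (tp + 0.5, fp + 0.5, fn + 0.5, tn + 0.5)
    else:
        cells = (float(tp), float(fp), float(fn), float(tn))
    return _wald_or_ci(*cells, level)


def roc_auc(scores: Sequence[float], truths: Sequence) -> float:
    """Rank-based (Mann–Whitney) AUC with tie correction.

    Equals the probability that a random positive outscores a random
    negative, ties counting one half; higher scores are read as more
    disease-positive.  Invariant under strictly monotone transforms of the
    scores.
    """
    y = _as_bool(truths)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and truths must have equal length")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = stats.rankdata(s)  # average ranks handle ties
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def cohen_kappa(ratings_a: Sequence, ratings_b: Sequence) -> float:
    """Cohen's kappa for two binary raters: (p_obs − p_exp)/(1 − p_exp) with
    marginal-product expected agreement.  Degenerate marginals (p_exp = 1)
    leave kappa undefined and raise."""
    a = _as_bool(ratings_a)
    b = _as_bool(ratings_b)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("ratings must be equal-length and non-empty")
    n = a.size
    p_obs = float(np.mean(a == b))
    p_exp = float(np.mean(a) * np.mean(b) + np.mean(~a) * np.mean(~b))
    if p_exp >= 1.0:
        raise ValueError("kappa undefined: degenerate marginals (expected agreement 1)")
    return (p_obs - p_exp) / (1 - p_exp)


def bland_altman(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float, float]:
    """Bland–Altman agreement: (bias, lower limit, upper limit).

    bias = mean(x − y); limits = bias ± 1.96 · sd(x − y) with the sample
    (n−1) standard deviation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length sequences with n >= 2")
    d = x - y
    bias = float(d.mean())
    half = 1.96 * float(d.std(ddof=1))
    return bias, bias - half, bias + half


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal round-half-up (2.5 → 3), as tables in clinical papers round."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


_STAT_NAMES = ("sensitivity", "specificity", "ppv", "npv", "dor")


def reconstruct_confusion(
    n_pos: int,
    n_neg: int,
    constraints: Iterable[Tuple[str, float, int]],
) -> List[ConfusionTable]:
    """Recover 2x2 tables from printed, rounded summary statistics.

    Enumerates every integer table with margins ``tp + fn = n_pos`` and
    ``fp + tn = n_neg`` and keeps those whose statistics round (half-up, at
    the stated number of decimals) to every constraint.  Proportion
    constraints are on the percent scale (38 means 38 %); ``dor`` is on its
    natural scale.  An empty list is a valid result (infeasible constraints).
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("n_pos and n_neg must be positive")
    cons = list(constraints)
    for name, _, _ in cons:
        if name not in _STAT_NAMES:
            raise ValueError(f"unknown statistic {name!r}; expected one of {_STAT_NAMES}")

    matches: List[ConfusionTable] = []
    for tp in range(n_pos + 1):
        fn = n_pos - tp
        for tn in range(n_neg + 1):
            fp = n_neg - tn
            ok = True
            for name, value, decimals in cons:
                if name == "sensitivity":
                    stat = 100.0 * tp / n_pos
                elif name == "specificity":
                    stat = 100.0 * tn / n_neg
                elif name == "ppv":
                    if tp + fp == 0:
                        ok = False
                        break
                    stat = 100.0 * tp / (tp + fp)
                elif name == "npv":
                    if tn + fn == 0:
                        ok = False
                        break
                    stat = 100.0 * tn / (tn + fn)
                else:  # dor
                    if 0 in (tp, fp, fn, tn):
                        stat = ((tp + 0.5) * (tn + 0.5)) / ((fp + 0.5) * (fn + 0.5))
                    else:
                        stat = (tp * tn) / (fp * fn)
                if round_half_up(stat, decimals) != round_half_up(value, decimals):
                    ok = False
                    break
            if ok:
                matches.append(ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn))
    return matches
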