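"""Diagnostic-accuracy statistics over file-level wheeze decisions.

Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), PPV = TP/(TP+FP),
NPV = TN/(TN+FN), each with a 95% confidence interval (Clopper-Pearson
exact by default, Wilson optionally). Subgroup reports break the counts
down by age band and sex. The Jonckheere-Terpstra trend test assesses a
monotone relationship across ordered groups (e.g. detection indicator
versus age band).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from math import sqrt
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/FN/TN file counts, wheeze being the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def display_round(x: float, decimals: int = 1) -> float:
    """Round half-up to the given number of decimals (display convention)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class Proportion:
    """A percentage with its defining counts and 95% interval bounds."""

    numerator: int
    denominator: int
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None

    @property
    def defined(self) -> bool:
        return self.denominator > 0

    @property
    def pct(self) -> Optional[float]:
        if not self.defined:
            return None
        return display_round(100.0 * self.numerator / self.denominator)


@dataclass
class AccuracyReport:
    """The four headline statistics plus optional subgroup rows."""

    sensitivity: Proportion
    specificity: Proportion
    ppv: Proportion
    npv: Proportion
    rows: Optional[pd.DataFrame] = None

    def as_dict(self) -> Dict[str, Optional[float]]:
        return {
            "sensitivity_pct": self.sensitivity.pct,
            "specificity_pct": self.specificity.pct,
            "ppv_pct": self.ppv.pct,
            "npv_pct": self.npv.pct,
        }


POSITIVE = "wheeze"


def _as_bool(labels: Sequence) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr
    return arr == POSITIVE


def confusion(reference: Sequence, predicted: Sequence) -> ConfusionMatrix:
    """Confusion counts with the reference (specialist) labels as truth."""
    ref, pred = _as_bool(reference), _as_bool(predicted)
    if ref.shape != pred.shape:
        raise ValueError("reference and predicted label sets differ in size")
    return ConfusionMatrix(
        tp=int(np.sum(ref & pred)),
        fp=int(np.sum(~ref & pred)),
        fn=int(np.sum(ref & ~pred)),
        tn=int(np.sum(~ref & ~pred)),
    )


def _proportion(k: int, n: int, ci_method: str) -> Proportion:
    if n == 0:
        return Proportion(numerator=k, denominator=n)
    method = {"exact": "beta", "wilson": "wilson"}[ci_method]
    lo, hi = proportion_confint(k, n, alpha=0.05, method=method)
    return Proportion(
        numerator=k,
        denominator=n,
        ci_low=display_round(100 * lo),
        ci_high=display_round(100 * hi),
    )


def diagnostic_stats(cm: ConfusionMatrix, ci_method: str = "exact") -> AccuracyReport:
    """Sensitivity / specificity / PPV / NPV with 95% intervals."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return AccuracyReport(
        sensitivity=_proportion(cm.tp, cm.tp + cm.fn, ci_method),
        specificity=_proportion(cm.tn, cm.tn + cm.fp, ci_method),
        ppv=_proportion(cm.tp, cm.tp + cm.fp, ci_method),
        npv=_proportion(cm.tn, cm.tn + cm.fn, ci_method),
    )


DEFAULT_AGE_BANDS: Tuple[Tuple[int, int], ...] = ((0, 11), (12, 23), (24, 35), (36, 107))


def subgroup_report(
    results: pd.DataFrame,
    age_bands: Sequence[Tuple[int, int]] = DEFAULT_AGE_BANDS,
    ci_method: str = "exact",
) -> pd.DataFrame:
    """Sensitivity/specificity per age band and sex.

    ``results`` needs columns ``reference``, ``predicted``, ``age_months``,
    ``sex`` (coded "M"/"F" or "male"/"female"). Rows whose denominator is
    zero are flagged undefined. The final row merges all files and equals
    the overall report.
    """
    req = {"reference", "predicted", "age_months", "sex"}
    if not req.issubset(results.columns):
        raise ValueError(f"results must have columns {sorted(req)}")
    if (results["age_months"] < 0).any():
        raise ValueError("negative age")
    sex_norm = results["sex"].astype(str).str.upper().str[0]
    if not sex_norm.isin({"M", "F"}).all():
        raise ValueError("unknown sex code")

    def row(name: str, sub: pd.DataFrame) -> dict:
        cm = confusion(sub["reference"], sub["predicted"])
        sens = _proportion(cm.tp, cm.tp + cm.fn, ci_method)
        spec = _proportion(cm.tn, cm.tn + cm.fp, ci_method)
        return {
            "group": name,
            "n_wheeze": cm.tp + cm.fn,
            "tp": cm.tp,
            "sensitivity_pct": sens.pct,
            "sensitivity_ci": (sens.ci_low, sens.ci_high) if sens.defined else None,
            "n_no_wheeze": cm.tn + cm.fp,
            "tn": cm.tn,
            "specificity_pct": spec.pct,
            "specificity_ci": (spec.ci_low, spec.ci_high) if spec.defined else None,
        }

    rows = []
    for lo, hi in age_bands:
        sub = results[(results["age_months"] >= lo) & (results["age_months"] <= hi)]
        rows.append(row(f"age_{lo}-{hi}m", sub))
    for code, name in (("M", "male"), ("F", "female")):
        rows.append(row(name, results[sex_norm == code]))
    rows.append(row("total", results))
    return pd.DataFrame(rows)


def _jt_statistic(groups: Sequence[np.ndarray]) -> float:
    j = 0.0
    for gi, gj in itertools.combinations(groups, 2):
        diff = gj[None, :] - gi[:, None]
        j += np.sum(diff > 0) + 0.5 * np.sum(diff == 0)
    return float(j)


def _jt_normal_p(groups: Sequence[np.ndarray], j: float, alternative: str) -> float:
    ns = np.array([len(g) for g in groups], dtype=float)
    n = ns.sum()
    pooled = np.concatenate(groups)
    _, tie_counts = np.unique(pooled, return_counts=True)
    t = tie_counts.astype(float)
    mean = (n**2 - np.sum(ns**2)) / 4.0
    a = n * (n - 1) * (2 * n + 5) - np.sum(ns * (ns - 1) * (2 * ns + 5)) - np.sum(
        t * (t - 1) * (2 * t + 5)
    )
    b = np.sum(ns * (ns - 1) * (ns - 2)) * np.sum(t * (t - 1) * (t - 2))
    c = np.sum(ns * (ns - 1)) * np.sum(t * (t - 1))
    var = a / 72.0
    if n > 2:
        var += b / (36.0 * n * (n - 1) * (n - 2))
    var += c / (8.0 * n * (n - 1))
    if var <= 0:
        return 1.0
    from scipy.stats import norm

    # continuity-corrected z
    delta = j - mean
    cc = 0.5 if delta != 0 else 0.0
    z = (delta - np.sign(delta) * cc) / sqrt(var)
    if alternative == "increasing":
        return float(norm.sf(z))
    if alternative == "decreasing":
        return float(norm.cdf(z))
    return float(min(1.0, 2 * norm.sf(abs(z))))


def _jt_exact_p(groups: Sequence[np.ndarray], j_obs: float, alternative: str) -> float:
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    idx = list(range(len(pooled)))

    def assignments(remaining: List[int], sizes_left: List[int]):
        if not sizes_left:
            yield []
            return
        k = sizes_left[0]
        for combo in itertools.combinations(remaining, k):
            rest = [i for i in remaining if i not in combo]
            for tail in assignments(rest, sizes_left[1:]):
                yield [list(combo)] + tail

    js = []
    for assign in assignments(idx, sizes):
        gs = [pooled[g] for g in assign]
        js.append(_jt_statistic(gs))
    js = np.array(js)
    ge = np.mean(js >= j_obs - 1e-12)
    le = np.mean(js <= j_obs + 1e-12)
    if alternative == "increasing":
        return float(ge)
    if alternative == "decreasing":
        return float(le)
    return float(min(1.0, 2 * min(ge, le)))


def jonckheere_terpstra(
    grouped_values: Sequence[Sequence[float]],
    alternative: str = "two-sided",
    method: str = "auto",
) -> Tuple[float, float]:
    """Jonckheere-Terpstra trend test across ordered groups.

    J sums the pairwise Mann-Whitney counts over all ordered group pairs
    (ties count one half). The p value is exact (full permutation of group
    assignments) when the pooled sample size is <= 12 and ``method`` is
    "auto" or "exact"; otherwise a tie-corrected normal approximation with
    continuity correction is used. Returns ``(J, p)``.
    """
    groups = [np.asarray(g, dtype=float) for g in grouped_values if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    if alternative not in ("two-sided", "increasing", "decreasing"):
        raise ValueError(f"unknown alternative {alternative!r}")
    j = _jt_statistic(groups)
    n = sum(len(g) for g in groups)
    if method == "exact" or (method == "auto" and n <= 12):
        p = _jt_exact_p(groups, j, alternative)
    else:
        p = _jt_normal_p(groups, j, alternative)
    return j, p
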