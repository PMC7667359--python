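"""Diagnostic-accuracy statistics for the two estimators.

Confusion matrices, the five standard proportions (sensitivity,
specificity, accuracy, PPV, NPV) with exact binomial confidence
intervals, the rank-based C-statistic (ROC AUC), percent overestimation
of the median volume, and an integer reconstructor that recovers a
confusion matrix from published marginals (n, prevalence, sensitivity,
specificity) — useful for verifying printed accuracy/PPV/NPV values when
the underlying patient data are unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.proportion import proportion_confint

from .estimators import ThresholdConfig, DEFAULT_THRESHOLDS, reported

_CI_METHODS = {"clopper-pearson": "beta", "wilson": "wilson"}


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
            object.__setattr__(self, name, int(v))

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @property
    def prevalence(self) -> float:
        return self.n_pos / self.n


class MetricCI(NamedTuple):
    """A proportion with its two-sided confidence interval."""

    estimate: float
    lower: float
    upper: float


@dataclass(frozen=True)
class BinaryMetrics:
    """The five diagnostic proportions; ``None`` marks an undefined metric
    (zero denominator), never a silent zero."""

    sensitivity: MetricCI | None
    specificity: MetricCI | None
    accuracy: MetricCI | None
    ppv: MetricCI | None
    npv: MetricCI | None
    ci_level: float = 0.95


def confusion(predicted, truth) -> ConfusionMatrix:
    """Standard 2x2 counts from parallel boolean vectors."""
    pred = np.asarray(predicted, dtype=bool)
    true = np.asarray(truth, dtype=bool)
    if pred.shape != true.shape or pred.ndim != 1 or pred.size == 0:
        raise ValueError(
            f"predicted and truth must be equal-length 1D vectors of length >= 1, "
            f"got shapes {pred.shape} and {true.shape}"
        )
    return ConfusionMatrix(
        tp=int(np.sum(pred & true)),
        fp=int(np.sum(pred & ~true)),
        tn=int(np.sum(~pred & ~true)),
        fn=int(np.sum(~pred & true)),
    )


def _proportion_ci(count: int, nobs: int, ci_level: float, method: str) -> MetricCI | None:
    if nobs == 0:
        return None
    lo, hi = proportion_confint(count, nobs, alpha=1 - ci_level, method=method)
    return MetricCI(count / nobs, float(lo), float(hi))


def binary_metrics(
    cm: ConfusionMatrix,
    ci_level: float = 0.95,
    ci_method: str = "clopper-pearson",
) -> BinaryMetrics:
    """Point estimates and binomial CIs for the five diagnostic proportions.

    Intervals are exact Clopper-Pearson by default (conservative, the
    convention in diagnostic-accuracy studies); ``ci_method='wilson'``
    selects the Wilson score interval instead.
    """
    if ci_method not in _CI_METHODS:
        raise ValueError(f"unknown ci_method {ci_method!r}; options: {sorted(_CI_METHODS)}")
    method = _CI_METHODS[ci_method]
    return BinaryMetrics(
        sensitivity=_proportion_ci(cm.tp, cm.n_pos, ci_level, method),
        specificity=_proportion_ci(cm.tn, cm.n_neg, ci_level, method),
        accuracy=_proportion_ci(cm.tp + cm.tn, cm.n, ci_level, method),
        ppv=_proportion_ci(cm.tp, cm.tp + cm.fp, ci_level, method),
        npv=_proportion_ci(cm.tn, cm.tn + cm.fn, ci_level, method),
        ci_level=ci_level,
    )


def c_statistic(scores, truth) -> float:
    """Rank-based ROC AUC: P(score_pos > score_neg) + 0.5 * P(tie).

    Computed from midranks (Mann-Whitney); identical to the brute-force
    average over all positive-negative pairs.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if scores.shape != truth.shape or scores.ndim != 1:
        raise ValueError("scores and truth must be equal-length 1D vectors")
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("c-statistic undefined: both classes must be present")
    ranks = rankdata(scores)  # midranks handle ties exactly
    rank_sum_pos = float(ranks[truth].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def median_overestimation(est_ml, manual_ml) -> float:
    """Percent overestimation of the median: 100*(med(est)-med(manual))/med(manual)."""
    est = np.asarray(est_ml, dtype=float)
    man = np.asarray(manual_ml, dtype=float)
    if est.shape != man.shape or est.ndim != 1 or est.size == 0:
        raise ValueError("estimate and manual vectors must be equal-length, length >= 1")
    med_man = float(np.median(man))
    if med_man == 0:
        raise ValueError("median manual volume is zero; overestimation undefined")
    return 100.0 * (float(np.median(est)) - med_man) / med_man


def _solve_count(nobs: int, target_pct: float, what: str) -> int:
    """The unique count k whose percentage prints as target_pct (half-up
    rounding to one decimal, the convention of published tables)."""
    k = np.arange(nobs + 1)
    printed = np.array([reported(100.0 * ki / nobs) for ki in k])
    hits = k[np.abs(printed - reported(target_pct)) < 1e-9]
    if hits.size == 0:
        raise ValueError(f"no integer {what} count in 0..{nobs} rounds to {target_pct}%")
    if hits.size > 1:
        raise ValueError(
            f"{what} count not unique at one-decimal rounding: "
            f"{hits.tolist()} all round to {target_pct}%"
        )
    return int(hits[0])


def reconstruct_confusion(
    n: int, n_pos: int, sensitivity_pct: float, specificity_pct: float
) -> ConfusionMatrix:
    """Recover the 2x2 table from published marginals by integer search.

    Finds the unique (tp, tn) with ``round(100*tp/n_pos, 1)`` equal to the
    printed sensitivity and likewise for specificity; errors if no
    solution or more than one exists at one-decimal rounding.
    """
    if not 0 <= n_pos <= n:
        raise ValueError(f"n_pos={n_pos} must lie in [0, n={n}]")
    for pct in (sensitivity_pct, specificity_pct):
        if not 0 <= pct <= 100:
            raise ValueError(f"percentage {pct} outside [0, 100]")
    n_neg = n - n_pos
    tp = _solve_count(n_pos, sensitivity_pct, "true-positive")
    tn = _solve_count(n_neg, specificity_pct, "true-negative")
    return ConfusionMatrix(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)


@dataclass(frozen=True)
class CohortEvaluation:
    """Per-method, per-threshold accuracy summary for one cohort."""

    confusions: dict
    metrics: dict
    c_statistics: dict
    overestimation_pct: dict
    ci_level: float
    ci_method: str

    def to_frame(self) -> pd.DataFrame:
        """Tabular report: one row per method x threshold, percent scale.

        Accuracy CIs appear on both the percent and the proportion scale
        (published tables sometimes mix the two), clearly labelled.
        """
        rows = []
        for (method, label), bm in self.metrics.items():
            cm = self.confusions[(method, label)]
            row = {
                "method": method,
                "threshold": label,
                "tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn,
            }
            for name in ("sensitivity", "specificity", "accuracy", "ppv", "npv"):
                m = getattr(bm, name)
                if m is None:
                    row[f"{name}_pct"] = np.nan
                    row[f"{name}_ci_lo_pct"] = np.nan
                    row[f"{name}_ci_hi_pct"] = np.nan
                else:
                    row[f"{name}_pct"] = 100 * m.estimate
                    row[f"{name}_ci_lo_pct"] = 100 * m.lower
                    row[f"{name}_ci_hi_pct"] = 100 * m.upper
            acc = bm.accuracy
            row["accuracy_ci_lo_prop"] = acc.lower if acc else np.nan
            row["accuracy_ci_hi_prop"] = acc.upper if acc else np.nan
            row["c_statistic"] = self.c_statistics.get((method, label), np.nan)
            row["median_overestimation_pct"] = self.overestimation_pct.get(method, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)


def evaluate_cohort(
    results: pd.DataFrame,
    config: ThresholdConfig = DEFAULT_THRESHOLDS,
    ci_level: float = 0.95,
    ci_method: str = "clopper-pearson",
) -> CohortEvaluation:
    """Full accuracy evaluation from a per-patient results table.

    ``results`` must carry the classification columns (``od_class_70``,
    ``abc2_class_100``, ..., ``truth_70``, ``truth_100``) plus the
    continuous scores ``od_volume_ml`` and ``abc2_volume_ml`` and the
    gold standard ``manual_volume_ml``.
    """
    if len(results) == 0:
        raise ValueError("empty results table")
    confusions, metrics, cstats = {}, {}, {}
    score_col = {"od_cutoff": "od_volume_ml", "abc2": "abc2_volume_ml"}
    class_col = {"od_cutoff": "od_class", "abc2": "abc2_class"}
    for method in ("od_cutoff", "abc2"):
        for label, suffix in (("70ml", "70"), ("100ml", "100")):
            truth = results[f"truth_{suffix}"].to_numpy(dtype=bool)
            pred = results[f"{class_col[method]}_{suffix}"].to_numpy(dtype=bool)
            cm = confusion(pred, truth)
            confusions[(method, label)] = cm
            metrics[(method, label)] = binary_metrics(cm, ci_level, ci_method)
            if 0 < truth.sum() < truth.size:
                cstats[(method, label)] = c_statistic(
                    results[score_col[method]].to_numpy(dtype=float), truth
                )
            else:
                cstats[(method, label)] = np.nan
    manual = results["manual_volume_ml"].to_numpy(dtype=float)
    over = {
        "od_cutoff": median_overestimation(results["od_volume_ml"], manual),
        "abc2": median_overestimation(results["abc2_volume_ml"], manual),
    }
    return CohortEvaluation(
        confusions=confusions,
        metrics=metrics,
        c_statistics=cstats,
        overestimation_pct=over,
        ci_level=ci_level,
        ci_method=ci_method,
    )
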