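"""Diagnostic performance of a severity-predicting score.

Empirical ROC analysis with the classification rule ``score >= threshold ->
predicted severe (Cluster B)``, the closest-to-(0,1) optimal cutpoint,
confusion-matrix metrics, McNemar comparison of two paired classifiers and
percentile-bootstrap inference for metrics and for a paired AUC difference.

AUC is computed as the trapezoidal integral of the empirical ROC curve, which
for this rule equals the Mann-Whitney concordance probability with ties
counted 1/2 (the equality is asserted in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .exceptions import SingleClassError

#: discordant-pair count at which the McNemar test switches from the exact
#: binomial to the continuity-corrected chi-square form
MCNEMAR_EXACT_MAX = 25


def _check_binary(labels: np.ndarray) -> tuple[int, int]:
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("both outcome classes must be present")
    return n_pos, n_neg


def auc_mann_whitney(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Tie-corrected Mann-Whitney AUC: P(score_pos > score_neg) + 1/2 P(tie)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos, n_neg = _check_binary(y)
    r = stats.rankdata(s)
    return float((r[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class RocAnalysis:
    """Full ROC analysis of one score against a binary severity label."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    optimal_cutpoint: float | None = None
    cutpoint_metrics: "ConfusionMetrics | None" = None
    bootstrap_ci: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "auc": self.auc,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "optimal_cutpoint": self.optimal_cutpoint,
        }
        if self.cutpoint_metrics is not None:
            d["cutpoint_metrics"] = self.cutpoint_metrics.to_dict()
        if self.bootstrap_ci:
            d["bootstrap_ci"] = self.bootstrap_ci
        return d


def roc_and_auc(scores: Sequence[float], labels: Sequence[int]) -> RocAnalysis:
    """Empirical ROC over all distinct thresholds (rule: score >= t -> positive).

    The threshold sweep starts above the maximum score (sensitivity 0,
    specificity 1) and ends at the minimum (sensitivity 1); AUC is the
    trapezoidal integral of sensitivity over 1 - specificity.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.size != y.size:
        raise ValueError("scores and labels must have the same length")
    n_pos, n_neg = _check_binary(y)

    uniq = np.unique(s)  # ascending
    thresholds = np.concatenate([[np.inf], uniq[::-1]])
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        pred = s >= t
        sens[i] = (pred & (y == 1)).sum() / n_pos
        spec[i] = (~pred & (y == 0)).sum() / n_neg
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))
    return RocAnalysis(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def optimal_cutpoint_roc01(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, "ConfusionMetrics"]:
    """Threshold minimising the Euclidean distance from (1-spec, sens) to (0, 1).

    Ties are broken by higher sensitivity, then by lower threshold.  The
    +inf sentinel (classify nothing as severe) is excluded from candidates.
    """
    roc = roc_and_auc(scores, labels)
    cand = roc.thresholds[1:]
    sens = roc.sensitivity[1:]
    spec = roc.specificity[1:]
    dist = np.sqrt((1.0 - sens) ** 2 + (1.0 - spec) ** 2)
    # lexicographic: min distance, then max sensitivity, then min threshold;
    # candidates are in descending threshold order so reversing prefers lower t
    best = min(range(cand.size)[::-1], key=lambda i: (dist[i], -sens[i]))
    cut = float(cand[best])
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    return cut, confusion_metrics((s >= cut).astype(int), y)


@dataclass(frozen=True)
class ConfusionMetrics:
    """Standard 2x2 classifier metrics; undefined ratios are NaN + flagged."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    undefined: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "undefined": list(self.undefined),
        }


def confusion_metrics(predicted: Sequence[int], labels: Sequence[int]) -> ConfusionMetrics:
    """Sensitivity, specificity, PPV and NPV of binary predictions."""
    p = np.asarray(predicted, dtype=int)
    y = np.asarray(labels, dtype=int)
    if p.size != y.size:
        raise ValueError("predicted and labels must have the same length")
    _check_binary(y)
    tp = int(((p == 1) & (y == 1)).sum())
    fp = int(((p == 1) & (y == 0)).sum())
    tn = int(((p == 0) & (y == 0)).sum())
    fn = int(((p == 0) & (y == 1)).sum())

    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    return ConfusionMetrics(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=ratio(tp, tp + fn, "sensitivity"),
        specificity=ratio(tn, tn + fp, "specificity"),
        ppv=ratio(tp, tp + fp, "ppv"),
        npv=ratio(tn, tn + fn, "npv"),
        undefined=tuple(undefined),
    )


@dataclass(frozen=True)
class McNemarResult:
    metric: str  # "sensitivity" | "specificity"
    b: int  # correct by classifier 1 only
    c: int  # correct by classifier 2 only
    p_value: float
    method: str  # "exact" | "chi2_cc"
    zero_discordance: bool = False

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "b": self.b,
            "c": self.c,
            "p_value": self.p_value,
            "method": self.method,
            "zero_discordance": self.zero_discordance,
        }


def mcnemar_paired(
    pred_1: Sequence[int],
    pred_2: Sequence[int],
    labels: Sequence[int],
    restrict: str,
) -> McNemarResult:
    """McNemar test of two paired classifiers on the same subjects.

    ``restrict="positives"`` compares sensitivities (only truly severe
    subjects enter; "correct" = predicted severe); ``restrict="negatives"``
    compares specificities.  With b + c < 25 the exact binomial two-sided p is
    used, otherwise the continuity-corrected chi-square.
    """
    p1 = np.asarray(pred_1, dtype=int)
    p2 = np.asarray(pred_2, dtype=int)
    y = np.asarray(labels, dtype=int)
    if not (p1.size == p2.size == y.size):
        raise ValueError("pred_1, pred_2 and labels must have the same length")
    if restrict == "positives":
        mask, correct = y == 1, 1
        metric = "sensitivity"
    elif restrict == "negatives":
        mask, correct = y == 0, 0
        metric = "specificity"
    else:
        raise ValueError("restrict must be 'positives' or 'negatives'")
    c1 = p1[mask] == correct
    c2 = p2[mask] == correct
    b = int((c1 & ~c2).sum())
    c = int((~c1 & c2).sum())
    if b + c == 0:
        return McNemarResult(metric, b, c, 1.0, "exact", zero_discordance=True)
    exact = (b + c) < MCNEMAR_EXACT_MAX
    # concordant cells do not enter the statistic; only b and c matter
    table = [[0, b], [c, 0]]
    res = _sm_mcnemar(table, exact=exact, correction=True)
    p = min(float(res.pvalue), 1.0)
    return McNemarResult(metric, b, c, p, "exact" if exact else "chi2_cc")


def _resample_indices(rng: np.random.Generator, n: int, B: int) -> np.ndarray:
    return rng.integers(0, n, size=(B, n))


def _auc_rows(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Row-wise tie-corrected Mann-Whitney AUC for (B, n) resample matrices."""
    r = stats.rankdata(scores, axis=1)
    npos = labels.sum(axis=1)
    nneg = labels.shape[1] - npos
    sum_pos = (r * labels).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (sum_pos - npos * (npos + 1) / 2.0) / (npos * nneg)


@dataclass(frozen=True)
class BootstrapAucComparison:
    auc_1: float
    auc_2: float
    auc_diff: float
    ci: tuple[float, float]
    p_value: float
    B: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "auc_1": self.auc_1,
            "auc_2": self.auc_2,
            "auc_diff": self.auc_diff,
            "ci": list(self.ci),
            "p_value": self.p_value,
            "B": self.B,
            "seed": self.seed,
        }


def bootstrap_compare_auc(
    scores_1: Sequence[float],
    scores_2: Sequence[float],
    labels: Sequence[int],
    B: int = 2000,
    seed: int = 0,
    level: float = 0.95,
    max_redraw_rounds: int = 100,
) -> BootstrapAucComparison:
    """Paired patient-level bootstrap of an AUC difference.

    Subjects are resampled with replacement; both scores are evaluated on the
    same resample, preserving the pairing.  Degenerate resamples (a single
    outcome class) are redrawn, with a capped number of redraw rounds.  The
    two-sided p is ``2 * min(frac(diff <= 0), frac(diff >= 0))``, floored at
    1/B and capped at 1.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    s1 = np.asarray(scores_1, dtype=float)
    s2 = np.asarray(scores_2, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not (s1.size == s2.size == y.size):
        raise ValueError("paired scores and labels must have the same length")
    _check_binary(y)
    n = y.size
    rng = np.random.default_rng(seed)

    idx = _resample_indices(rng, n, B)
    for _ in range(max_redraw_rounds):
        lab = y[idx]
        bad = np.flatnonzero((lab.sum(axis=1) == 0) | (lab.sum(axis=1) == n))
        if bad.size == 0:
            break
        idx[bad] = _resample_indices(rng, n, bad.size)
    else:
        raise SingleClassError("could not draw non-degenerate bootstrap resamples")

    lab = y[idx]
    diffs = _auc_rows(s1[idx], lab) - _auc_rows(s2[idx], lab)
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    ci = (float(np.quantile(diffs, lo_q)), float(np.quantile(diffs, hi_q)))
    frac_le = float((diffs <= 0).mean())
    frac_ge = float((diffs >= 0).mean())
    p = min(1.0, max(2.0 * min(frac_le, frac_ge), 1.0 / B))
    return BootstrapAucComparison(
        auc_1=auc_mann_whitney(s1, y),
        auc_2=auc_mann_whitney(s2, y),
        auc_diff=auc_mann_whitney(s1, y) - auc_mann_whitney(s2, y),
        ci=ci,
        p_value=p,
        B=B,
        seed=seed,
    )


def bootstrap_ci(
    metric_fn: Callable[..., float],
    data: Sequence[np.ndarray],
    B: int = 2000,
    seed: int = 0,
    level: float = 0.95,
    max_retries_per_draw: int = 100,
) -> tuple[float, float]:
    """Seeded percentile bootstrap interval for an arbitrary row-level metric.

    ``data`` is a sequence of equal-length arrays resampled jointly (patient-
    level resampling); ``metric_fn`` receives the resampled arrays and returns
    a scalar.  A draw on which the metric is undefined (raises or returns a
    non-finite value) is redrawn, up to a cap.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    arrays = [np.asarray(a) for a in data]
    n = arrays[0].shape[0]
    if any(a.shape[0] != n for a in arrays):
        raise ValueError("all data arrays must have the same length")
    rng = np.random.default_rng(seed)
    stats_out = np.empty(B)
    for b in range(B):
        for _ in range(max_retries_per_draw):
            take = rng.integers(0, n, size=n)
            try:
                val = float(metric_fn(*(a[take] for a in arrays)))
            except SingleClassError:
                continue
            if np.isfinite(val):
                stats_out[b] = val
                break
        else:
            raise SingleClassError("metric undefined on every attempted resample")
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    return (float(np.quantile(stats_out, lo_q)), float(np.quantile(stats_out, hi_q)))
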