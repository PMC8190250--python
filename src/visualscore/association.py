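"""Score-severity association: logistic odds per point and 2x2 exact tests.

Two complementary views of the association between the VISUAL total and
severe clinical evolution (Cluster B):

* a univariable logistic regression of cluster membership on the total,
  reported as the odds ratio per additional point with a Wald 95% CI; and
* a 2x2 cross-tabulation at the dichotomising cutoff (VISUAL >= 10 by
  default) with the sample odds ratio ad/bc and Fisher's exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .exceptions import SeparationError, SingleClassError

Z_95 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass(frozen=True)
class LogisticFit:
    """Univariable logistic fit: log-odds intercept/slope and Wald inference."""

    beta_0: float
    beta_1: float
    se_1: float
    odds_ratio: float
    wald_ci: tuple[float, float]
    p_wald: float
    n: int
    converged: bool
    iterations: int

    def to_dict(self) -> dict:
        return {
            "beta_0": self.beta_0,
            "beta_1": self.beta_1,
            "se_1": self.se_1,
            "odds_ratio": self.odds_ratio,
            "wald_ci": list(self.wald_ci),
            "p_wald": self.p_wald,
            "n": self.n,
            "converged": self.converged,
        }


def _check_separation(x: np.ndarray, y: np.ndarray) -> None:
    x0, x1 = x[y == 0], x[y == 1]
    if x1.min() > x0.max() or x0.min() > x1.max():
        raise SeparationError(
            "covariate completely separates the outcome; the MLE does not exist"
        )


def fit_logistic(x, y) -> LogisticFit:
    """Maximum-likelihood logistic regression of a binary outcome on one covariate.

    Fitted by Newton iterations (iteratively reweighted least squares),
    converging when the parameter/score change falls below 1e-8 or after 100
    iterations.  The Wald CI for the odds ratio is exp(beta_1 +/- 1.96 se_1).

    Raises
    ------
    SingleClassError
        If the outcome is constant.
    SeparationError
        If the covariate completely separates the outcome classes.
    ValueError
        If the covariate is constant.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=int)
    if xv.size != yv.size:
        raise ValueError("x and y must have the same length")
    if yv.min() == yv.max():
        raise SingleClassError("outcome is constant; logistic MLE undefined")
    if xv.min() == xv.max():
        raise ValueError("covariate is constant")
    _check_separation(xv, yv)

    X = sm.add_constant(xv)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # quasi-separation warnings already screened above
        res = sm.Logit(yv, X).fit(method="newton", tol=1e-8, maxiter=100, disp=0)
    beta_0, beta_1 = (float(v) for v in res.params)
    se_1 = float(res.bse[1])
    or_ = float(np.exp(beta_1))
    ci = (float(np.exp(beta_1 - Z_95 * se_1)), float(np.exp(beta_1 + Z_95 * se_1)))
    return LogisticFit(
        beta_0=beta_0,
        beta_1=beta_1,
        se_1=se_1,
        odds_ratio=or_,
        wald_ci=ci,
        p_wald=min(float(res.pvalues[1]), 1.0),
        n=int(yv.size),
        converged=bool(res.mle_retvals.get("converged", True)),
        iterations=int(res.mle_retvals.get("iterations", 0)),
    )


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 table (exposure = score >= cutoff, outcome = Cluster B) and exact test.

    Cells: a = exposed & severe, b = exposed & non-severe, c = unexposed &
    severe, d = unexposed & non-severe.  The odds ratio is the cross-product
    ad/bc; with any zero cell a Haldane-Anscombe 0.5 correction is applied to
    the OR and its CI (flagged), never silently.
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    ci: tuple[float, float]
    fisher_p: float
    haldane_corrected: bool = False
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "d": self.d,
            "odds_ratio": self.odds_ratio,
            "ci": list(self.ci),
            "fisher_p": self.fisher_p,
            "haldane_corrected": self.haldane_corrected,
            "degenerate": self.degenerate,
        }


def fisher_exact_2x2(a: int, b: int, c: int, d: int, level: float = 0.95) -> TwoByTwo:
    """Two-sided Fisher exact test and sample odds ratio for a 2x2 table.

    The p-value sums hypergeometric probabilities of all tables (with the
    observed margins) no more probable than the observed one.  A zero margin
    makes the test degenerate: p = 1 and the OR undefined (flagged).
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cell counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        raise ValueError("grand total must be positive")
    if min(a + b, c + d, a + c, b + d) == 0:
        return TwoByTwo(a, b, c, d, float("nan"), (float("nan"),) * 2, 1.0, degenerate=True)

    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")

    corrected = min(a, b, c, d) == 0
    if corrected:
        aa, bb, cc, dd = (v + 0.5 for v in (a, b, c, d))
    else:
        aa, bb, cc, dd = float(a), float(b), float(c), float(d)
    or_sample = (a * d) / (b * c) if not corrected else (aa * dd) / (bb * cc)
    se_log = float(np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd))
    z = stats.norm.ppf(1 - (1 - level) / 2)
    log_or = float(np.log(or_sample))
    ci = (float(np.exp(log_or - z * se_log)), float(np.exp(log_or + z * se_log)))
    return TwoByTwo(
        a, b, c, d, float(or_sample), ci, min(float(p), 1.0), haldane_corrected=corrected
    )


def odds_at_threshold(scores, clusters, cutoff: float = 10) -> TwoByTwo:
    """Dichotomise scores at the (inclusive) cutoff and test the 2x2 association.

    ``clusters`` is a binary Cluster-B indicator (1 = severe) or an array of
    "A"/"B" labels.
    """
    s = np.asarray(scores, dtype=float)
    cl = np.asarray(clusters)
    if cl.dtype.kind in ("U", "O", "S"):
        y = (cl == "B").astype(int)
    else:
        y = cl.astype(int)
    if s.size != y.size:
        raise ValueError("scores and clusters must have the same length")
    exposed = s >= cutoff
    a = int((exposed & (y == 1)).sum())
    b = int((exposed & (y == 0)).sum())
    c = int((~exposed & (y == 1)).sum())
    d = int((~exposed & (y == 0)).sum())
    return fisher_exact_2x2(a, b, c, d)
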