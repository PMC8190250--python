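"""Clinical severity scoring and 1-D two-cluster dichotomisation.

Two complication-based severity systems are supported:

* a mild/moderate/severe weighting where each complication contributes 1, 5
  or 10 points, with severe clinical evolution ("Cluster B") at >= 14 points
  in the study cohort; and
* a 15-item system where each complication scores 0-3 points (the grade value
  is its own weight), with Cluster B at >= 5 points.

Catalogs ship as editable YAML (``visualscore/catalogs``).  The pipeline
dichotomises on the fixed cutoffs by default; :func:`two_means_1d` re-derives
a data-driven boundary (exact 1-D two-means) and :func:`silhouette_1d`
quantifies the separation of the resulting clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import CatalogError, DegenerateClusteringError

CLUSTER_A = "A"
CLUSTER_B = "B"


@dataclass(frozen=True)
class SeverityCatalog:
    """A complication catalog: item ids, grade->weight map, cluster cutoff."""

    name: str
    items: tuple[str, ...]
    grade_weights: dict  # grade (str or int) -> integer weight
    cluster_cutoff: int

    def weight(self, item_id: str, grade) -> int:
        if item_id not in self.items:
            raise CatalogError(f"unknown complication item {item_id!r} for catalog {self.name!r}")
        key = self._norm_grade(grade)
        if key not in self.grade_weights:
            raise CatalogError(
                f"grade {grade!r} not allowed for catalog {self.name!r} "
                f"(allowed: {sorted(map(str, self.grade_weights))})"
            )
        return self.grade_weights[key]

    def _norm_grade(self, grade):
        # integer-graded catalogs accept "2" and 2 alike
        if all(isinstance(g, int) for g in self.grade_weights):
            try:
                return int(grade)
            except (TypeError, ValueError):
                return grade
        return str(grade).strip().lower()


def load_catalog(name_or_path: str) -> SeverityCatalog:
    """Load a severity catalog from a bundled name ("ameratunga", "grimbacher")
    or a path to a YAML file with the same schema."""
    if name_or_path in ("ameratunga", "grimbacher"):
        text = (
            resources.files("visualscore").joinpath(f"catalogs/{name_or_path}.yaml").read_text()
        )
        raw = yaml.safe_load(text)
    else:
        with open(name_or_path) as fh:
            raw = yaml.safe_load(fh)
    weights = {}
    for grade, w in raw["default_grades"].items():
        weights[grade if isinstance(grade, int) else str(grade).lower()] = int(w)
    return SeverityCatalog(
        name=str(raw["name"]),
        items=tuple(raw["items"]),
        grade_weights=weights,
        cluster_cutoff=int(raw["cluster_cutoff"]),
    )


@dataclass(frozen=True)
class SeverityResult:
    patient_id: str
    catalog: str
    total: int
    cluster: str  # "A" | "B"


def score_severity(
    records: Iterable[tuple[str, object]] | pd.DataFrame,
    catalog: SeverityCatalog,
    patient_id: str = "",
) -> SeverityResult:
    """Sum the catalog weights over one patient's complication records.

    ``records`` is an iterable of ``(item_id, grade)`` pairs (or a DataFrame
    with ``item_id``/``grade`` columns).  Each complication may be graded at
    most once.  An empty record list scores 0 points (no manifestations) and
    falls in Cluster A.
    """
    if isinstance(records, pd.DataFrame):
        pairs = list(zip(records["item_id"], records["grade"]))
    else:
        pairs = list(records)
    seen = set()
    total = 0
    for item_id, grade in pairs:
        if item_id in seen:
            raise CatalogError(f"duplicate complication item {item_id!r} (one grade per item)")
        seen.add(item_id)
        total += catalog.weight(item_id, grade)
    cluster = CLUSTER_B if total >= catalog.cluster_cutoff else CLUSTER_A
    return SeverityResult(patient_id=patient_id, catalog=catalog.name, total=total, cluster=cluster)


def score_severity_cohort(
    complications: pd.DataFrame, catalog: SeverityCatalog, patient_ids: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-patient severity totals and cluster labels for one catalog.

    ``complications`` has columns patient_id, catalog, item_id, grade; rows of
    other catalogs are ignored.  ``patient_ids`` fixes the output order and
    ensures complication-free patients appear with total 0.
    """
    sub = complications[complications["catalog"] == catalog.name]
    if patient_ids is None:
        patient_ids = list(dict.fromkeys(sub["patient_id"]))
    grouped = dict(tuple(sub.groupby("patient_id", sort=False)))
    rows = []
    for pid in patient_ids:
        grp = grouped.get(pid)
        recs = [] if grp is None else list(zip(grp["item_id"], grp["grade"]))
        res = score_severity(recs, catalog, patient_id=pid)
        rows.append({"patient_id": pid, "total": res.total, "cluster": res.cluster})
    return pd.DataFrame(rows, columns=["patient_id", "total", "cluster"])


def two_means_1d(scores: Sequence[float]) -> tuple[np.ndarray, float]:
    """Exact two-cluster k-means on a line.

    The optimal 2-partition under within-cluster sum of squares is contiguous
    in sorted order, so it suffices to scan the n-1 sorted split points.
    Returns labels aligned with the input order ("A" for the lower cluster,
    "B" for the upper) and the boundary value (midpoint between the two
    clusters' nearest members).

    Raises
    ------
    DegenerateClusteringError
        If fewer than two distinct values are supplied.
    """
    x = np.asarray(scores, dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise DegenerateClusteringError("two-means requires at least two distinct values")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = xs.size
    csum = np.cumsum(xs)
    csq = np.cumsum(xs**2)

    def wss(lo, hi):  # within-SS of xs[lo:hi]
        s = csum[hi - 1] - (csum[lo - 1] if lo else 0.0)
        q = csq[hi - 1] - (csq[lo - 1] if lo else 0.0)
        return q - s * s / (hi - lo)

    best_k, best = None, np.inf
    for k in range(1, n):
        if xs[k] == xs[k - 1]:
            continue  # splitting inside a tie duplicates a value across clusters
        total = wss(0, k) + wss(k, n)
        if total < best - 1e-12:
            best, best_k = total, k
    if best_k is None:
        raise DegenerateClusteringError("no valid split point")
    labels = np.empty(n, dtype=object)
    labels[order[:best_k]] = CLUSTER_A
    labels[order[best_k:]] = CLUSTER_B
    boundary = (xs[best_k - 1] + xs[best_k]) / 2.0
    return labels, float(boundary)


def silhouette_1d(
    scores: Sequence[float], labels: Sequence[str]
) -> tuple[np.ndarray, dict[str, float], float]:
    """Silhouette widths for a two-cluster partition of scalar scores.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with plain absolute difference as
    the distance; members of singleton clusters get s = 0 by convention.
    Returns per-point widths (input order), per-cluster means, overall mean.
    """
    x = np.asarray(scores, dtype=float)
    lab = np.asarray(labels, dtype=object)
    if x.shape != lab.shape:
        raise ValueError("scores and labels must have the same length")
    uniq = sorted(set(lab.tolist()))
    if len(uniq) != 2:
        raise ValueError(f"exactly 2 clusters required, got {uniq}")
    idx = {c: np.flatnonzero(lab == c) for c in uniq}
    for c in uniq:
        if idx[c].size == 0:
            raise ValueError(f"cluster {c!r} is empty")

    s = np.zeros(x.size)
    for i in range(x.size):
        own, other = (idx[lab[i]], idx[uniq[1] if lab[i] == uniq[0] else uniq[0]])
        if own.size == 1:
            s[i] = 0.0
            continue
        a = np.abs(x[own] - x[i]).sum() / (own.size - 1)
        b = np.abs(x[other] - x[i]).mean()
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    per_cluster = {c: float(s[idx[c]].mean()) for c in uniq}
    return s, per_cluster, float(s.mean())
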