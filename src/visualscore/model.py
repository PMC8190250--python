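"""End-to-end validation model for the VISUAL score.

:class:`VisualScoreModel` is built from the three cohort tables (laboratory
panels, complication records, follow-up) and ``fit()`` runs the complete
validation pipeline, returning a :class:`VisualScoreResults` with:

* per-patient VISUAL totals and risk classes (plus a rejects listing);
* severity totals and Cluster A/B labels for both catalogs, at the fixed
  cutoffs, alongside the data-driven exact two-means boundary and silhouette
  widths for comparison;
* ROC analyses (AUC, ROC01-optimal cutpoint, confusion metrics, bootstrap
  CIs) of the VISUAL total and of the smB component alone against each
  cluster definition;
* McNemar sensitivity/specificity comparisons and a paired bootstrap AUC
  comparison of VISUAL vs the smB-alone classifier;
* logistic odds per VISUAL point and the Fisher 2x2 at the dichotomising
  cutoff, per severity score;
* Kaplan-Meier progression tables by risk group and the Mantel-Cox log-rank
  test.

Identical inputs, configuration and seed produce a byte-identical report.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import association, diagnostics, severity, survival
from .exceptions import ConfigError, SingleClassError, DegenerateClusteringError
from .scoring import ReferenceConfig, score_cohort
from .severity import SeverityCatalog, load_catalog, score_severity_cohort
from .simulate import GeneratorConfig, generate_cohort
from .survival import GROUP_HIGH, GROUP_LOW

SCORE_DEFINITIONS = ("visual_total", "smb_points")


class VisualScoreModel:
    """Validation model of the VISUAL score against clinical severity.

    Parameters
    ----------
    patients
        Laboratory panels, one row per patient (see ``scoring.PatientLabs``
        for the columns).
    complications
        Long table of complication records: patient_id, catalog, item_id,
        grade.
    followup
        Per-patient progression/censoring ages: patient_id,
        age_progression_or_censor, event.
    reference
        Analyte reference ranges (defaults to the published table).
    visual_cutoff
        Dichotomising VISUAL total for the high-risk class (inclusive).
    smb_comparator_pct
        The smB-alone comparator classifier calls a patient severe when
        smb_pct is strictly below this percentage (default 2, the EUROclass
        threshold; 6 or 1 are the other tabulated choices).
    """

    def __init__(
        self,
        patients: pd.DataFrame,
        complications: pd.DataFrame,
        followup: pd.DataFrame | None = None,
        *,
        reference: ReferenceConfig | None = None,
        catalogs: dict[str, SeverityCatalog] | None = None,
        visual_cutoff: int = 10,
        smb_comparator_pct: float = 2.0,
    ):
        self.patients = patients.reset_index(drop=True)
        self.complications = complications.reset_index(drop=True)
        self.followup = None if followup is None else followup.reset_index(drop=True)
        self.reference = reference or ReferenceConfig()
        self.catalogs = catalogs or {
            "ameratunga": load_catalog("ameratunga"),
            "grimbacher": load_catalog("grimbacher"),
        }
        self.visual_cutoff = int(visual_cutoff)
        self.smb_comparator_pct = float(smb_comparator_pct)

    # ------------------------------------------------------------------ #
    @classmethod
    def from_csv(
        cls,
        patients_csv,
        complications_csv,
        followup_csv=None,
        **kwargs,
    ) -> "VisualScoreModel":
        for path in (patients_csv, complications_csv, followup_csv):
            if path is not None and not pathlib.Path(path).exists():
                raise ConfigError(f"input file not found: {path}")
        return cls(
            pd.read_csv(patients_csv),
            pd.read_csv(complications_csv),
            None if followup_csv is None else pd.read_csv(followup_csv),
            **kwargs,
        )

    @classmethod
    def from_simulation(cls, config: GeneratorConfig, **kwargs) -> "VisualScoreModel":
        cohort = generate_cohort(config)
        model = cls(cohort.patients, cohort.complications, cohort.followup, **kwargs)
        model._sim_config = config
        return model

    # ------------------------------------------------------------------ #
    def fit(self, bootstrap_B: int = 2000, seed: int = 0) -> "VisualScoreResults":
        """Run scoring, clustering, diagnostics, association and survival."""
        scored, rejects = score_cohort(self.patients, self.reference, self.visual_cutoff)
        if scored.empty:
            raise ConfigError("no scoreable patients in the cohort")
        pids = list(scored["patient_id"])

        clusters: dict[str, pd.DataFrame] = {}
        clustering_report: dict[str, dict] = {}
        for name, cat in self.catalogs.items():
            tab = score_severity_cohort(self.complications, cat, patient_ids=pids)
            clusters[name] = tab
            clustering_report[name] = self._clustering_block(tab, cat)

        scores = {
            "visual_total": scored["visual_total"].to_numpy(dtype=float),
            "smb_points": scored["points_smb"].to_numpy(dtype=float),
        }
        pred = {
            "visual_total": (scores["visual_total"] >= self.visual_cutoff).astype(int),
            "smb_points": (scored["smb_pct"].to_numpy(dtype=float) < self.smb_comparator_pct).astype(
                int
            ),
        }

        roc_blocks: list[dict] = []
        comparison_blocks: list[dict] = []
        assoc_blocks: list[dict] = []
        for cname, tab in clusters.items():
            y = (tab["cluster"] == severity.CLUSTER_B).to_numpy(dtype=int)
            sub_seed = _subseed(seed, cname)
            for sname in SCORE_DEFINITIONS:
                roc_blocks.append(
                    self._roc_block(sname, cname, scores[sname], pred[sname], y, bootstrap_B, sub_seed)
                )
            comparison_blocks.append(
                self._comparison_block(cname, scores, pred, y, bootstrap_B, sub_seed)
            )
            assoc_blocks.append(self._association_block(cname, scores["visual_total"], y))

        surv_block = None
        followup = None
        if self.followup is not None:
            followup = self.followup.merge(
                scored[["patient_id", "visual_total"]], on="patient_id", how="inner"
            )
            followup["group"] = np.where(
                followup["visual_total"] >= self.visual_cutoff, GROUP_HIGH, GROUP_LOW
            )
            surv_block = self._survival_block(followup)

        return VisualScoreResults(
            model=self,
            scored=scored,
            rejects=rejects,
            clusters=clusters,
            clustering_report=clustering_report,
            roc_blocks=roc_blocks,
            comparison_blocks=comparison_blocks,
            association_blocks=assoc_blocks,
            survival_block=surv_block,
            followup=followup,
            bootstrap_B=bootstrap_B,
            seed=seed,
        )

    # ------------------------------------------------------------------ #
    def _clustering_block(self, tab: pd.DataFrame, cat: SeverityCatalog) -> dict:
        block = {
            "cutoff": cat.cluster_cutoff,
            "n_cluster_a": int((tab["cluster"] == "A").sum()),
            "n_cluster_b": int((tab["cluster"] == "B").sum()),
        }
        try:
            labels, boundary = severity.two_means_1d(tab["total"].to_numpy(dtype=float))
            _, per_cluster, overall = severity.silhouette_1d(
                tab["total"].to_numpy(dtype=float), labels
            )
            block["two_means_boundary"] = boundary
            block["two_means_agrees_with_cutoff"] = bool(
                np.array_equal(labels, tab["cluster"].to_numpy(dtype=object))
            )
            block["silhouette_mean"] = overall
            block["silhouette_per_cluster"] = per_cluster
        except DegenerateClusteringError:
            block["two_means_boundary"] = None
        return block

    def _roc_block(self, sname, cname, s, pred, y, B, seed) -> dict:
        roc = diagnostics.roc_and_auc(s, y)
        cut, cut_metrics = diagnostics.optimal_cutpoint_roc01(s, y)
        at_pred = diagnostics.confusion_metrics(pred, y)
        cis = {}
        for metric in ("sensitivity", "specificity"):
            cis[metric] = diagnostics.bootstrap_ci(
                lambda p_, y_, m=metric: getattr(diagnostics.confusion_metrics(p_, y_), m),
                (pred, y),
                B=B,
                seed=_subseed(seed, f"{sname}:{metric}"),
            )
        cis["auc"] = diagnostics.bootstrap_ci(
            diagnostics.auc_mann_whitney, (s, y), B=B, seed=_subseed(seed, f"{sname}:auc")
        )
        return {
            "score_name": sname,
            "cluster_definition": cname,
            "auc": roc.auc,
            "n_pos": roc.n_pos,
            "n_neg": roc.n_neg,
            "optimal_cutpoint": cut,
            "metrics_at_optimal_cutpoint": cut_metrics.to_dict(),
            "metrics_at_configured_rule": at_pred.to_dict(),
            "bootstrap_ci": {k: list(v) for k, v in cis.items()},
            "roc_points": {
                "threshold": roc.thresholds.tolist(),
                "sensitivity": roc.sensitivity.tolist(),
                "specificity": roc.specificity.tolist(),
            },
        }

    def _comparison_block(self, cname, scores, pred, y, B, seed) -> dict:
        mcn = {
            m.metric: m.to_dict()
            for m in (
                diagnostics.mcnemar_paired(pred["visual_total"], pred["smb_points"], y, "positives"),
                diagnostics.mcnemar_paired(pred["visual_total"], pred["smb_points"], y, "negatives"),
            )
        }
        boot = diagnostics.bootstrap_compare_auc(
            scores["visual_total"],
            scores["smb_points"],
            y,
            B=B,
            seed=_subseed(seed, "auc_compare"),
        )
        return {
            "cluster_definition": cname,
            "classifier_1": f"visual_total >= {self.visual_cutoff}",
            "classifier_2": f"smb_pct < {self.smb_comparator_pct}",
            "mcnemar": mcn,
            "bootstrap_auc": boot.to_dict(),
        }

    def _association_block(self, cname, visual, y) -> dict:
        block = {"severity_score": cname}
        try:
            fit = association.fit_logistic(visual, y)
            block["per_point"] = fit.to_dict()
        except (SingleClassError, association.SeparationError, ValueError) as exc:
            block["per_point"] = {"error": str(exc)}
        t = association.odds_at_threshold(visual, y, cutoff=self.visual_cutoff)
        block["threshold"] = dict(t.to_dict(), cutoff=self.visual_cutoff)
        return block

    def _survival_block(self, followup: pd.DataFrame) -> dict:
        t = followup["age_progression_or_censor"].to_numpy(dtype=float)
        e = followup["event"].to_numpy(dtype=int)
        g = followup["group"].to_numpy(dtype=object)
        block: dict = {"groups": {}}
        for name in (GROUP_HIGH, GROUP_LOW):
            m = g == name
            if not m.any():
                block["groups"][name] = {"n": 0}
                continue
            km = survival.km_estimate(t[m], e[m])
            block["groups"][name] = {
                "n": int(m.sum()),
                "events": int(e[m].sum()),
                "median_age": survival.km_median_time(t[m], e[m]),
                "km_table": km.to_dict(orient="list"),
            }
        if len(set(g.tolist())) == 2:
            block["logrank"] = survival.logrank_test(t, e, g).to_dict()
        return block


def _subseed(seed: int, tag: str) -> int:
    """Derive a stable stream seed below 2**31 from the run seed and a label."""
    h = 2166136261
    for ch in f"{seed}:{tag}".encode():
        h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
    return h % (2**31)


@dataclass
class VisualScoreResults:
    """Fitted validation results; render with :meth:`summary` or :meth:`to_report`."""

    model: VisualScoreModel
    scored: pd.DataFrame
    rejects: pd.DataFrame
    clusters: dict[str, pd.DataFrame]
    clustering_report: dict[str, dict]
    roc_blocks: list[dict]
    comparison_blocks: list[dict]
    association_blocks: list[dict]
    survival_block: dict | None
    followup: pd.DataFrame | None
    bootstrap_B: int
    seed: int

    # -------------------------------------------------------------- #
    def to_report(self) -> dict:
        """Machine-readable report of every pipeline stage (JSON-serialisable)."""
        report = {
            "n_patients": int(len(self.scored)),
            "n_rejected": int(len(self.rejects)),
            "rejects": self.rejects.to_dict(orient="records"),
            "visual_cutoff": self.model.visual_cutoff,
            "smb_comparator_pct": self.model.smb_comparator_pct,
            "bootstrap": {"B": self.bootstrap_B, "seed": self.seed},
            "visual_summary": {
                "mean_total": float(self.scored["visual_total"].mean()),
                "median_total": float(self.scored["visual_total"].median()),
                "n_high_risk": int((self.scored["risk_class"] == "high").sum()),
            },
            "clustering": self.clustering_report,
            "roc": [
                {k: v for k, v in blk.items() if k != "roc_points"} for blk in self.roc_blocks
            ],
            "comparisons": self.comparison_blocks,
            "association": self.association_blocks,
        }
        if self.survival_block is not None:
            surv = {
                "logrank": self.survival_block.get("logrank"),
                "groups": {
                    name: {k: v for k, v in grp.items() if k != "km_table"}
                    for name, grp in self.survival_block["groups"].items()
                },
            }
            report["survival"] = surv
        return report

    def report_json(self) -> str:
        return json.dumps(_jsonable(self.to_report()), indent=2, sort_keys=True)

    def save(self, outdir) -> pathlib.Path:
        """Write report.json plus the per-patient and coordinate side tables."""
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.report_json())
        self.scored.to_csv(out / "scored_patients.csv", index=False)
        if len(self.rejects):
            self.rejects.to_csv(out / "rejected_patients.csv", index=False)
        for name, tab in self.clusters.items():
            tab.to_csv(out / f"severity_{name}.csv", index=False)
        for blk in self.roc_blocks:
            pts = pd.DataFrame(blk["roc_points"])
            pts.to_csv(
                out / f"roc_{blk['score_name']}_{blk['cluster_definition']}.tsv",
                sep="\t",
                index=False,
            )
        if self.survival_block is not None:
            for gname, grp in self.survival_block["groups"].items():
                if "km_table" in grp:
                    pd.DataFrame(grp["km_table"]).to_csv(
                        out / f"km_{gname}.tsv", sep="\t", index=False
                    )
        return out

    # -------------------------------------------------------------- #
    def summary(self) -> str:
        """Human-readable synopsis in the style of a model-results table."""
        lines = []
        w = 72
        lines.append("=" * w)
        lines.append("VISUAL score validation".center(w))
        lines.append("=" * w)
        lines.append(
            f"n patients: {len(self.scored)}    rejected: {len(self.rejects)}    "
            f"cutoff: >= {self.model.visual_cutoff}"
        )
        vs = self.to_report()["visual_summary"]
        lines.append(
            f"VISUAL total: mean {vs['mean_total']:.2f}, median {vs['median_total']:.1f}, "
            f"high-risk {vs['n_high_risk']}/{len(self.scored)}"
        )
        lines.append("-" * w)
        lines.append(
            f"{'score':<14}{'cluster def.':<14}{'AUC':>7}{'cutpt':>7}{'sens':>7}{'spec':>7}"
            f"{'ppv':>7}{'npv':>7}"
        )
        for blk in self.roc_blocks:
            m = blk["metrics_at_configured_rule"]
            lines.append(
                f"{blk['score_name']:<14}{blk['cluster_definition']:<14}{blk['auc']:>7.3f}"
                f"{blk['optimal_cutpoint']:>7.1f}{m['sensitivity']:>7.2f}{m['specificity']:>7.2f}"
                f"{m['ppv']:>7.2f}{m['npv']:>7.2f}"
            )
        lines.append("-" * w)
        for blk in self.association_blocks:
            pp = blk["per_point"]
            th = blk["threshold"]
            if "error" in pp:
                lines.append(f"{blk['severity_score']}: per-point fit failed ({pp['error']})")
            else:
                lines.append(
                    f"{blk['severity_score']}: OR/point {pp['odds_ratio']:.2f} "
                    f"(95% CI {pp['wald_ci'][0]:.2f}-{pp['wald_ci'][1]:.2f}, p={pp['p_wald']:.3g}); "
                    f"OR at >= {th['cutoff']}: {th['odds_ratio']:.2f} (Fisher p={th['fisher_p']:.3g})"
                )
        if self.survival_block is not None and "logrank" in self.survival_block:
            lr = self.survival_block["logrank"]
            lines.append("-" * w)
            lines.append(
                f"log-rank (high vs low risk): chi2={lr['chi_square']:.2f}, p={lr['p_value']:.3g}"
            )
        lines.append("=" * w)
        return "\n".join(lines)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None  # NaN/inf are not valid JSON
    return obj
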