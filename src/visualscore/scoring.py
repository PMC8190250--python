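"""VISUAL score: point categorisation of the five diagnostic analytes.

The VISUAL score summarises five immunological laboratory values measured at
diagnosis of common variable immunodeficiency (CVID): the percentage of
switched-memory B cells (smB, CD19+CD27+IgD-IgM-), serum IgA, serum IgM,
specific antibody responses to polysaccharide and protein vaccines, and the
CD4+ T-cell count.  Each analyte contributes 1 point when normal and up to 4
points with increasing severity of the alteration; the total therefore ranges
from 5 (all normal) to 20 (all maximally altered).  Patients with a total at
or above the cutoff (default 10) form the high-risk class.

Category boundaries follow the published scoring table: lower bounds of the
*better* category are inclusive (smB of exactly 6% scores 1 point, CD4 of
exactly 700/µL scores 1 point, IgA of exactly 0.07 g/L scores 2 points), and
the high-risk call at the total is inclusive as well (total == cutoff is
high risk).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Iterable

import pandas as pd
import yaml

from .exceptions import EmptyCohortError, IncompletePanelError

RESPONSE_VALUES = ("adequate", "inadequate")

#: analyte fields that must be present for a record to be scoreable
REQUIRED_FIELDS = (
    "smb_pct",
    "iga_g_l",
    "igm_g_l",
    "poly_response",
    "protein_response",
    "cd4_per_ul",
)


@dataclass(frozen=True)
class PatientLabs:
    """One patient's diagnostic laboratory panel.

    Parameters
    ----------
    smb_pct
        Switched-memory B cells as a percentage of B cells, in [0, 100].
    iga_g_l, igm_g_l
        Serum immunoglobulin concentrations in g/L, non-negative.
    poly_response, protein_response
        Adequacy ("adequate"/"inadequate") of the specific antibody response
        to pneumococcal polysaccharide and tetanus-toxoid protein vaccines.
    cd4_per_ul
        CD4+ T-cell count per µL, non-negative.
    """

    patient_id: str
    smb_pct: float | None
    iga_g_l: float | None
    igm_g_l: float | None
    poly_response: str | None
    protein_response: str | None
    cd4_per_ul: float | None
    age_at_diagnosis_years: float | None = None

    def missing_fields(self) -> list[str]:
        out = []
        for name in REQUIRED_FIELDS:
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                out.append(name)
        return out

    def validate(self) -> None:
        """Raise on an unscoreable record (missing analytes or out-of-range values)."""
        missing = self.missing_fields()
        if missing:
            raise IncompletePanelError(self.patient_id, missing)
        if not 0.0 <= self.smb_pct <= 100.0:
            raise ValueError(f"smb_pct must be in [0, 100], got {self.smb_pct}")
        for name in ("iga_g_l", "igm_g_l", "cd4_per_ul"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        for name in ("poly_response", "protein_response"):
            if getattr(self, name) not in RESPONSE_VALUES:
                raise ValueError(
                    f"{name} must be one of {RESPONSE_VALUES}, got {getattr(self, name)!r}"
                )


@dataclass(frozen=True)
class ReferenceConfig:
    """Reference ranges and category thresholds for the five analytes.

    All thresholds are overridable; the defaults encode the published scoring
    table.  ``smb_thresholds_pct`` and ``cd4_thresholds_per_ul`` are strictly
    decreasing triples delimiting the 1/2/3/4-point categories.  IgA uses
    three limits (lower normal, 2 SD below normal, undetectable); IgM scores
    4 points only when above the upper normal limit.
    """

    smb_thresholds_pct: tuple[float, float, float] = (6.0, 2.0, 1.0)
    smb_upper_normal_pct: float = 29.0
    iga_lower_normal_g_l: float = 0.7
    iga_2sd_g_l: float = 0.4
    iga_undetectable_g_l: float = 0.07
    igm_normal_range_g_l: tuple[float, float] = (0.4, 2.3)
    cd4_thresholds_per_ul: tuple[float, float, float] = (700.0, 500.0, 200.0)
    cd4_upper_normal_per_ul: float = 1500.0

    def __post_init__(self):
        for name in ("smb_thresholds_pct", "cd4_thresholds_per_ul"):
            t = tuple(getattr(self, name))
            if not (t[0] > t[1] > t[2]):
                raise ValueError(f"{name} must be strictly decreasing, got {t}")
        if not (
            self.iga_undetectable_g_l <= self.iga_2sd_g_l <= self.iga_lower_normal_g_l
        ):
            raise ValueError(
                "IgA limits must satisfy undetectable <= 2SD <= lower normal: got "
                f"{self.iga_undetectable_g_l}, {self.iga_2sd_g_l}, {self.iga_lower_normal_g_l}"
            )
        lo, hi = self.igm_normal_range_g_l
        if not lo < hi:
            raise ValueError(f"igm_normal_range_g_l must be increasing, got {(lo, hi)}")

    @classmethod
    def from_yaml(cls, path) -> "ReferenceConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("smb_thresholds_pct", "cd4_thresholds_per_ul", "igm_normal_range_g_l"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d


@dataclass(frozen=True)
class ComponentPoints:
    """The five per-analyte point values (before summation)."""

    smb: int
    iga: int
    igm: int
    ab: int
    cd4: int
    warnings: tuple[str, ...] = ()

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (self.smb, self.iga, self.igm, self.ab, self.cd4)


@dataclass(frozen=True)
class VisualResult:
    """A scored patient: five component points, their sum and the risk class."""

    patient_id: str
    points_smb: int
    points_iga: int
    points_igm: int
    points_ab: int
    points_cd4: int
    total: int
    risk_class: str  # "high" | "low"
    visual_cutoff: int = 10
    warnings: tuple[str, ...] = ()


def categorize_analytes(labs: PatientLabs, ref: ReferenceConfig | None = None) -> ComponentPoints:
    """Map each analyte of a complete panel to its 1-4 point category.

    Raises
    ------
    IncompletePanelError
        If any of the five analytes is missing (no imputation is attempted).
    """
    ref = ref or ReferenceConfig()
    labs.validate()

    warnings: list[str] = []

    t1, t2, t3 = ref.smb_thresholds_pct
    if labs.smb_pct >= t1:
        smb = 1
        if labs.smb_pct > ref.smb_upper_normal_pct:
            warnings.append(
                f"smb_pct {labs.smb_pct} above upper normal {ref.smb_upper_normal_pct}%"
            )
    elif labs.smb_pct >= t2:
        smb = 2
    elif labs.smb_pct >= t3:
        smb = 3
    else:
        smb = 4

    if labs.iga_g_l >= ref.iga_2sd_g_l:
        iga = 1
    elif labs.iga_g_l >= ref.iga_undetectable_g_l:
        iga = 2
    else:
        iga = 4

    # normal or low IgM contributes the floor of 1 point; only an elevation scores 4
    igm = 4 if labs.igm_g_l > ref.igm_normal_range_g_l[1] else 1

    n_inadequate = [labs.poly_response, labs.protein_response].count("inadequate")
    ab = {0: 1, 1: 2, 2: 4}[n_inadequate]

    c1, c2, c3 = ref.cd4_thresholds_per_ul
    if labs.cd4_per_ul >= c1:
        cd4 = 1
        if labs.cd4_per_ul > ref.cd4_upper_normal_per_ul:
            warnings.append(
                f"cd4_per_ul {labs.cd4_per_ul} above upper normal {ref.cd4_upper_normal_per_ul}/µL"
            )
    elif labs.cd4_per_ul >= c2:
        cd4 = 2
    elif labs.cd4_per_ul >= c3:
        cd4 = 3
    else:
        cd4 = 4

    return ComponentPoints(smb=smb, iga=iga, igm=igm, ab=ab, cd4=cd4, warnings=tuple(warnings))


def score_visual(
    labs: PatientLabs, ref: ReferenceConfig | None = None, cutoff: int = 10
) -> VisualResult:
    """Compute the VISUAL total (sum of the five components) and risk class.

    ``risk_class`` is "high" iff the total is >= ``cutoff`` (the boundary is
    inclusive).
    """
    pts = categorize_analytes(labs, ref)
    total = sum(pts.as_tuple())
    return VisualResult(
        patient_id=labs.patient_id,
        points_smb=pts.smb,
        points_iga=pts.iga,
        points_igm=pts.igm,
        points_ab=pts.ab,
        points_cd4=pts.cd4,
        total=total,
        risk_class="high" if total >= cutoff else "low",
        visual_cutoff=cutoff,
        warnings=pts.warnings,
    )


def labs_from_row(row) -> PatientLabs:
    """Build a :class:`PatientLabs` from a mapping/Series with the CSV column names."""

    def _get(name):
        v = row.get(name)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        if isinstance(v, str):
            v = v.strip()
            return v if v else None
        return v

    return PatientLabs(
        patient_id=str(row.get("patient_id")),
        smb_pct=_get("smb_pct"),
        iga_g_l=_get("iga_g_l"),
        igm_g_l=_get("igm_g_l"),
        poly_response=_get("poly_response"),
        protein_response=_get("protein_response"),
        cd4_per_ul=_get("cd4_per_ul"),
        age_at_diagnosis_years=_get("age_at_diagnosis_years"),
    )


def score_cohort(
    patients: pd.DataFrame | Iterable[PatientLabs],
    ref: ReferenceConfig | None = None,
    cutoff: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every row of a cohort table, preserving the input order.

    Returns
    -------
    (results, rejects)
        ``results`` mirrors the input plus the five point columns,
        ``visual_total`` and ``risk_class``.  ``rejects`` lists rows that
        could not be scored, with a ``reason`` column; no value is imputed.

    Raises
    ------
    EmptyCohortError
        If the input has no rows at all.
    """
    if isinstance(patients, pd.DataFrame):
        records = [labs_from_row(row) for _, row in patients.iterrows()]
    else:
        records = list(patients)
    if not records:
        raise EmptyCohortError("cohort table has no rows")

    rows, rejects = [], []
    for labs in records:
        try:
            res = score_visual(labs, ref, cutoff)
        except (IncompletePanelError, ValueError) as exc:
            rejects.append({"patient_id": labs.patient_id, "reason": str(exc)})
            continue
        row = asdict(labs)
        row.update(
            points_smb=res.points_smb,
            points_iga=res.points_iga,
            points_igm=res.points_igm,
            points_ab=res.points_ab,
            points_cd4=res.points_cd4,
            visual_total=res.total,
            risk_class=res.risk_class,
            warnings="; ".join(res.warnings),
        )
        rows.append(row)

    results = pd.DataFrame(rows)
    rejects_df = pd.DataFrame(rejects, columns=["patient_id", "reason"])
    return results, rejects_df


def vaccine_response_adequate(
    pre_titre: float,
    post_titre: float,
    antigen: str,
    *,
    fold_rise_protein: float = 4.0,
    fold_rise_poly: float = 3.0,
    absolute_protein_iu_ml: float = 0.15,
    absolute_poly_mg_dl: float = 11.0,
) -> bool:
    """Classify a post-vaccination titre rise as adequate or not.

    A protein (tetanus-toxoid) response is adequate on a >= 4-fold rise over
    the pre-vaccination titre or a post titre above 0.15 IU/mL; a
    polysaccharide (pneumococcal) response on a >= 3-fold rise or a post titre
    above 11 mg/dL.  Intended as a convenience when raw titres are available;
    the scoring functions consume the resulting adequate/inadequate label.
    """
    if antigen == "protein":
        fold, absolute = fold_rise_protein, absolute_protein_iu_ml
    elif antigen == "polysaccharide":
        fold, absolute = fold_rise_poly, absolute_poly_mg_dl
    else:
        raise ValueError(f"antigen must be 'protein' or 'polysaccharide', got {antigen!r}")
    if pre_titre < 0 or post_titre < 0:
        raise ValueError("titres must be non-negative")
    if post_titre > absolute:
        return True
    if pre_titre == 0:
        return False
    return post_titre / pre_titre >= fold
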