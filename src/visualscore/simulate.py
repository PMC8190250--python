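"""Synthetic CVID cohort generator.

Emulates the structure of the study cohort (n = 50) so that every pipeline
stage can be exercised without patient-level data:

* per-analyte point categories are drawn independently from the published
  marginal frequencies (smB 24/36/14/26%, IgA 26/24/50%, elevated IgM 6%,
  antibody responses 58% both altered / 28% polysaccharide-only / 14%
  protein-only, CD4 44/12/32/12%);
* a continuous laboratory value is then drawn uniformly inside the category's
  interval, so re-categorising the generated values round-trips exactly;
* severe clinical evolution (Cluster B) is drawn from a logistic link on the
  VISUAL total with a per-point log-odds slope of ln(1.3), the intercept
  calibrated analytically so that P(Cluster B) = 0.56 at the expected total;
* complication records are synthesised so the two severity catalogs
  reproduce totals consistent with the drawn cluster (Cluster A in 8-13 /
  2-4 points, Cluster B in 14-21 / 5-10 for the 1/5/10-weighted and the
  0-3-graded catalog respectively);
* diagnosis ages follow a bounded distribution with median ~32 on (4, 70);
  progressors reach Cluster B shortly after diagnosis (half immediately, the
  rest after an exponential delay, shortened for the high-risk group), and
  non-progressors are censored at their age at last follow-up.

Only the printed marginals plus one association parameter are emulated; the
analytes are drawn independently of each other.  ``latent_severity_rho``
optionally couples the five category draws through a shared latent severity
factor (Gaussian copula); it defaults to 0 (off) because no joint
distribution is published.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

from .exceptions import CalibrationError, EmptyCohortError
from .scoring import ReferenceConfig, labs_from_row, categorize_analytes
from .severity import SeverityCatalog, load_catalog

# category -> (low, high) sampling interval per analyte; chosen strictly inside
# each scoring category so that categorisation round-trips exactly
SMB_INTERVALS = {1: (6.0, 29.0), 2: (2.0, 6.0), 3: (1.0, 2.0), 4: (0.0, 1.0)}
IGA_INTERVALS = {1: (0.7, 4.0), 2: (0.07, 0.4), 4: (0.0, 0.07)}
IGM_INTERVALS = {1: (0.4, 2.3), 4: (2.4, 6.0)}
CD4_INTERVALS = {1: (700.0, 1500.0), 2: (500.0, 700.0), 3: (200.0, 500.0), 4: (50.0, 200.0)}

#: antibody-response pattern -> (poly_response, protein_response, points)
AB_PATTERNS = {
    "both_altered": ("inadequate", "inadequate", 4),
    "poly_only": ("inadequate", "adequate", 2),
    "protein_only": ("adequate", "inadequate", 2),
    "normal": ("adequate", "adequate", 1),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort."""

    n: int = 50
    seed: int = 0
    smb_probs: tuple[float, float, float, float] = (0.24, 0.36, 0.14, 0.26)
    iga_probs: tuple[float, float, float] = (0.26, 0.24, 0.50)  # over points (1, 2, 4)
    igm_elevated_p: float = 0.06
    ab_probs: tuple[float, float, float, float] = (0.58, 0.28, 0.14, 0.0)
    cd4_probs: tuple[float, float, float, float] = (0.44, 0.12, 0.32, 0.12)
    beta_per_point: float = math.log(1.3)
    cluster_b_rate_at_mean: float = 0.56
    ameratunga_range_a: tuple[int, int] = (8, 13)
    ameratunga_range_b: tuple[int, int] = (14, 21)
    grimbacher_range_a: tuple[int, int] = (2, 4)
    grimbacher_range_b: tuple[int, int] = (5, 10)
    age_bounds: tuple[float, float] = (4.0, 70.0)
    age_beta_shape: tuple[float, float] = (2.0, 2.6)  # median ~32 y on (4, 70)
    followup_years_range: tuple[float, float] = (1.0, 31.0)
    progression_p_immediate: float = 0.5
    progression_mean_delay_years: float = 4.0
    progression_hazard_ratio_high: float = 2.0
    visual_cutoff: int = 10
    latent_severity_rho: float = 0.0
    corrupt_intervals: bool = False  # testing hook: breaks the round-trip on purpose

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("cohort size n must be at least 2")
        for name in ("smb_probs", "iga_probs", "ab_probs", "cd4_probs"):
            p = getattr(self, name)
            if abs(sum(p) - 1.0) > 1e-9 or min(p) < 0:
                raise ValueError(f"{name} must be a probability vector summing to 1, got {p}")
        if not 0.0 <= self.igm_elevated_p <= 1.0:
            raise ValueError("igm_elevated_p must be in [0, 1]")
        if not math.isfinite(self.beta_per_point):
            raise ValueError("beta_per_point must be finite")
        if not 0.0 <= self.latent_severity_rho < 1.0:
            raise ValueError("latent_severity_rho must be in [0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


@dataclass
class SyntheticCohort:
    """The three generated tables plus the resolved generator state."""

    patients: pd.DataFrame
    complications: pd.DataFrame
    followup: pd.DataFrame
    intercept: float
    config: GeneratorConfig
    drawn_categories: pd.DataFrame | None = None  # the generator's own category draws

    def save(self, outdir, stem: str = "cohort") -> None:
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.patients.to_csv(out / f"{stem}_patients.csv", index=False)
        self.complications.to_csv(out / f"{stem}_complications.csv", index=False)
        self.followup.to_csv(out / f"{stem}_followup.csv", index=False)
        resolved = self.config.to_dict()
        resolved["resolved_intercept"] = self.intercept
        with open(out / f"{stem}_config.yaml", "w") as fh:
            yaml.safe_dump(resolved, fh, sort_keys=True)


def expected_total(config: GeneratorConfig) -> float:
    """Analytic expectation of the VISUAL total under the category marginals."""
    e_smb = sum(p * pt for p, pt in zip(config.smb_probs, (1, 2, 3, 4)))
    e_iga = sum(p * pt for p, pt in zip(config.iga_probs, (1, 2, 4)))
    e_igm = 1.0 * (1 - config.igm_elevated_p) + 4.0 * config.igm_elevated_p
    e_ab = sum(p * AB_PATTERNS[k][2] for p, k in zip(config.ab_probs, AB_PATTERNS))
    e_cd4 = sum(p * pt for p, pt in zip(config.cd4_probs, (1, 2, 3, 4)))
    return e_smb + e_iga + e_igm + e_ab + e_cd4


def resolve_intercept(config: GeneratorConfig) -> float:
    """Intercept of the severity link: logit(target rate) - beta * E[total]."""
    p = config.cluster_b_rate_at_mean
    if not 0.0 < p < 1.0:
        raise CalibrationError(f"cluster_b_rate_at_mean must be in (0, 1), got {p}")
    return math.log(p / (1 - p)) - config.beta_per_point * expected_total(config)


def _draw_categories(rng, probs, values, n, latent_u=None):
    p = np.asarray(probs, dtype=float)
    cdf = np.cumsum(p)
    u = rng.random(n) if latent_u is None else latent_u
    idx = np.searchsorted(cdf, u, side="right").clip(max=len(values) - 1)
    return np.asarray(values)[idx]


def _uniform_in(rng, intervals, cats, corrupt=False):
    lo = np.array([intervals[c][0] for c in cats])
    hi = np.array([intervals[c][1] for c in cats])
    vals = rng.uniform(lo, hi)
    if corrupt:
        vals = hi + 1.0  # deliberately outside the category (negative control)
    return vals


def _decompose_ameratunga(total: int, items: tuple[str, ...], rng) -> list[tuple[str, str]]:
    """Express a target total as distinct items graded severe/moderate/mild."""
    order = list(rng.permutation(len(items)))
    recs, rem = [], int(total)
    for weight, grade in ((10, "severe"), (5, "moderate"), (1, "mild")):
        while rem >= weight and order:
            recs.append((items[order.pop()], grade))
            rem -= weight
    if rem != 0:
        raise CalibrationError(f"cannot decompose severity total {total} over {len(items)} items")
    return recs


def _decompose_grimbacher(total: int, items: tuple[str, ...], rng) -> list[tuple[str, int]]:
    order = list(rng.permutation(len(items)))
    recs, rem = [], int(total)
    while rem > 0 and order:
        g = min(3, rem)
        recs.append((items[order.pop()], g))
        rem -= g
    if rem != 0:
        raise CalibrationError(f"cannot decompose severity total {total} over {len(items)} items")
    return recs


def generate_cohort(
    config: GeneratorConfig,
    catalogs: dict[str, SeverityCatalog] | None = None,
) -> SyntheticCohort:
    """Draw a full synthetic cohort (labs, complications, follow-up).

    Fully reproducible: the same config (including seed) yields identical
    tables.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    if catalogs is None:
        catalogs = {"ameratunga": load_catalog("ameratunga"), "grimbacher": load_catalog("grimbacher")}
    intercept = resolve_intercept(config)

    if config.latent_severity_rho > 0:
        # Gaussian copula: one latent severity factor shifts all five uniforms
        rho = config.latent_severity_rho
        z = rng.standard_normal((n, 6))
        shared = z[:, :1]
        mixed = math.sqrt(rho) * shared + math.sqrt(1 - rho) * z[:, 1:]
        from scipy.stats import norm

        u = norm.cdf(mixed)
        us = [u[:, j] for j in range(5)]
    else:
        us = [rng.random(n) for _ in range(5)]

    # draws are ordered mild -> severe so a larger latent factor means worse labs
    smb_cat = _draw_categories(rng, config.smb_probs, (1, 2, 3, 4), n, us[0])
    iga_cat = _draw_categories(rng, config.iga_probs, (1, 2, 4), n, us[1])
    igm_cat = np.where(us[2] >= 1.0 - config.igm_elevated_p, 4, 1)
    p_both, p_poly, p_prot, p_norm = config.ab_probs
    ab_key = _draw_categories(
        rng,
        (p_norm, p_poly, p_prot, p_both),
        ["normal", "poly_only", "protein_only", "both_altered"],
        n,
        us[3],
    )
    cd4_cat = _draw_categories(rng, config.cd4_probs, (1, 2, 3, 4), n, us[4])

    smb_pct = _uniform_in(rng, SMB_INTERVALS, smb_cat, config.corrupt_intervals)
    iga = _uniform_in(rng, IGA_INTERVALS, iga_cat, config.corrupt_intervals)
    igm = _uniform_in(rng, IGM_INTERVALS, igm_cat)
    cd4 = _uniform_in(rng, CD4_INTERVALS, cd4_cat)
    poly = np.array([AB_PATTERNS[k][0] for k in ab_key])
    protein = np.array([AB_PATTERNS[k][1] for k in ab_key])
    ab_points = np.array([AB_PATTERNS[k][2] for k in ab_key])

    total = smb_cat + iga_cat + igm_cat + ab_points + cd4_cat

    # severity link and cluster draw
    p_b = 1.0 / (1.0 + np.exp(-(intercept + config.beta_per_point * total)))
    cluster_b = rng.random(n) < p_b

    # ages
    a, b = config.age_beta_shape
    lo, hi = config.age_bounds
    # rounded once here so the follow-up times stay >= the recorded diagnosis age
    diag_age = np.round(lo + (hi - lo) * rng.beta(a, b, size=n), 1)

    pid = np.array([f"P{i + 1:04d}" for i in range(n)])
    patients = pd.DataFrame(
        {
            "patient_id": pid,
            # full precision: rounding could push a draw across a category boundary
            "smb_pct": smb_pct,
            "iga_g_l": iga,
            "igm_g_l": igm,
            "poly_response": poly,
            "protein_response": protein,
            "cd4_per_ul": cd4,
            "age_at_diagnosis_years": np.round(diag_age, 1),
        }
    )

    # severity totals consistent with the drawn cluster, then complication records
    am_lo, am_hi = config.ameratunga_range_a, config.ameratunga_range_b
    gr_lo, gr_hi = config.grimbacher_range_a, config.grimbacher_range_b
    am_total = np.where(
        cluster_b,
        rng.integers(am_hi[0], am_hi[1] + 1, size=n),
        rng.integers(am_lo[0], am_lo[1] + 1, size=n),
    )
    gr_total = np.where(
        cluster_b,
        rng.integers(gr_hi[0], gr_hi[1] + 1, size=n),
        rng.integers(gr_lo[0], gr_lo[1] + 1, size=n),
    )
    comp_rows = []
    for i in range(n):
        for item, grade in _decompose_ameratunga(am_total[i], catalogs["ameratunga"].items, rng):
            comp_rows.append((pid[i], "ameratunga", item, grade))
        for item, grade in _decompose_grimbacher(gr_total[i], catalogs["grimbacher"].items, rng):
            comp_rows.append((pid[i], "grimbacher", item, grade))
    complications = pd.DataFrame(comp_rows, columns=["patient_id", "catalog", "item_id", "grade"])

    # follow-up: progression (to Cluster B) age or censoring age
    high_risk = total >= config.visual_cutoff
    immediate = rng.random(n) < config.progression_p_immediate
    scale = np.where(
        high_risk,
        config.progression_mean_delay_years / config.progression_hazard_ratio_high,
        config.progression_mean_delay_years,
    )
    delay = np.where(immediate, 0.0, rng.exponential(scale))
    censor_after = rng.uniform(*config.followup_years_range, size=n)
    time = np.where(cluster_b, diag_age + delay, diag_age + censor_after)
    followup = pd.DataFrame(
        {
            "patient_id": pid,
            "age_progression_or_censor": np.round(time, 2),
            "event": cluster_b.astype(int),
        }
    )

    drawn = pd.DataFrame(
        {
            "patient_id": pid,
            "smb": smb_cat,
            "iga": iga_cat,
            "igm": igm_cat,
            "ab": ab_points,
            "cd4": cd4_cat,
        }
    )
    return SyntheticCohort(
        patients=patients,
        complications=complications,
        followup=followup,
        intercept=intercept,
        config=config,
        drawn_categories=drawn,
    )


@dataclass(frozen=True)
class RoundtripReport:
    n: int
    n_mismatches: int
    mismatched_rows: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return self.n_mismatches == 0


def roundtrip_check(cohort: SyntheticCohort, ref: ReferenceConfig | None = None) -> RoundtripReport:
    """Verify that re-categorising the generated continuous values reproduces
    the drawn categories for every row."""
    ref = ref or ReferenceConfig()
    if len(cohort.patients) == 0:
        raise EmptyCohortError("empty cohort")
    if cohort.drawn_categories is None:
        raise ValueError("cohort carries no drawn categories to check against")
    mism = []
    drawn = cohort.drawn_categories.set_index("patient_id")
    for _, row in cohort.patients.iterrows():
        labs = labs_from_row(row)
        pts = categorize_analytes(labs, ref)
        want = tuple(int(v) for v in drawn.loc[labs.patient_id, ["smb", "iga", "igm", "ab", "cd4"]])
        if pts.as_tuple() != want:
            mism.append(labs.patient_id)
    return RoundtripReport(n=len(cohort.patients), n_mismatches=len(mism), mismatched_rows=tuple(mism))
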