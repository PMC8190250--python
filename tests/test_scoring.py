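"""Unit and property tests for the five-analyte categorisation and VISUAL total."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from visualscore.exceptions import EmptyCohortError, IncompletePanelError
from visualscore.scoring import (
    ReferenceConfig,
    categorize_analytes,
    score_cohort,
    score_visual,
    vaccine_response_adequate,
)

from conftest import labs_frame, make_labs

# attainable point sets per analyte (category 3 unreachable for IgA and Ab)
ATTAINABLE = {
    "smb": (1, 2, 3, 4),
    "iga": (1, 2, 4),
    "igm": (1, 4),
    "ab": (1, 2, 4),
    "cd4": (1, 2, 3, 4),
}

# a representative input value for each (analyte, points) category
VALUE_FOR = {
    "smb": {1: 10.0, 2: 3.0, 3: 1.5, 4: 0.5},
    "iga": {1: 1.2, 2: 0.2, 4: 0.05},
    "igm": {1: 1.0, 4: 3.0},
    "cd4": {1: 900.0, 2: 600.0, 3: 350.0, 4: 100.0},
}
AB_FOR = {1: ("adequate", "adequate"), 2: ("inadequate", "adequate"), 4: ("inadequate", "inadequate")}


def labs_for(smb=1, iga=1, igm=1, ab=1, cd4=1):
    poly, protein = AB_FOR[ab]
    return make_labs(
        smb_pct=VALUE_FOR["smb"][smb],
        iga_g_l=VALUE_FOR["iga"][iga],
        igm_g_l=VALUE_FOR["igm"][igm],
        poly_response=poly,
        protein_response=protein,
        cd4_per_ul=VALUE_FOR["cd4"][cd4],
    )


@pytest.mark.parametrize(
    "field,value,expected",
    [
        # smB categories: >=6 / [2,6) / [1,2) / <1 percent
        ("smb", 10.0, 1),
        ("smb", 6.0, 1),  # lower bound of normal is inclusive
        ("smb", 5.999, 2),
        ("smb", 2.0, 2),
        ("smb", 1.5, 3),
        ("smb", 1.0, 3),
        ("smb", 0.999, 4),
        ("smb", 0.0, 4),
        # IgA: >= 2SD limit / [0.07, 2SD) / < 0.07 g/L
        ("iga", 1.2, 1),
        ("iga", 0.4, 1),
        ("iga", 0.39, 2),
        ("iga", 0.07, 2),
        ("iga", 0.05, 4),
        # IgM: only an elevation above 2.3 g/L scores (4 points)
        ("igm", 1.0, 1),
        ("igm", 0.02, 1),  # low IgM still contributes the floor of 1
        ("igm", 2.3, 1),
        ("igm", 2.31, 4),
        # CD4: >=700 / [500,700) / [200,500) / <200 per µL
        ("cd4", 900.0, 1),
        ("cd4", 700.0, 1),
        ("cd4", 699.0, 2),
        ("cd4", 500.0, 2),
        ("cd4", 350.0, 3),
        ("cd4", 200.0, 3),
        ("cd4", 199.0, 4),
    ],
)
def test_analyte_categories(field, value, expected):
    labs = make_labs(**{{"smb": "smb_pct", "iga": "iga_g_l", "igm": "igm_g_l", "cd4": "cd4_per_ul"}[field]: value})
    pts = categorize_analytes(labs)
    assert getattr(pts, field) == expected


@pytest.mark.parametrize(
    "poly,protein,expected",
    [
        ("adequate", "adequate", 1),
        ("inadequate", "adequate", 2),
        ("adequate", "inadequate", 2),
        ("inadequate", "inadequate", 4),
    ],
)
def test_antibody_response_categories(poly, protein, expected):
    pts = categorize_analytes(make_labs(poly_response=poly, protein_response=protein))
    assert pts.ab == expected


def test_all_normal_panel_scores_five_low_risk():
    res = score_visual(make_labs())
    assert (res.points_smb, res.points_iga, res.points_igm, res.points_ab, res.points_cd4) == (
        1, 1, 1, 1, 1,
    )
    assert res.total == 5 and res.risk_class == "low"


def test_maximally_altered_panel_scores_twenty_high_risk():
    labs = make_labs(
        smb_pct=0.5,
        iga_g_l=0.05,
        igm_g_l=3.0,
        poly_response="inadequate",
        protein_response="inadequate",
        cd4_per_ul=100.0,
    )
    res = score_visual(labs)
    assert res.total == 20 and res.risk_class == "high"


def test_total_range_is_exactly_5_to_20_over_all_attainable_combinations():
    totals = {
        sum(combo)
        for combo in itertools.product(*(ATTAINABLE[k] for k in ("smb", "iga", "igm", "ab", "cd4")))
    }
    assert min(totals) == 5 and max(totals) == 20


def test_risk_class_boundary_inclusive_at_cutoff():
    # components (2,2,1,2,2) -> 9 -> low; adding one step crosses to high at 10
    assert score_visual(labs_for(2, 2, 1, 2, 2)).total == 9
    assert score_visual(labs_for(2, 2, 1, 2, 2)).risk_class == "low"
    res10 = score_visual(labs_for(3, 2, 1, 2, 2))
    assert res10.total == 10 and res10.risk_class == "high"


def test_single_analyte_degradation_never_decreases_total():
    for analyte, cats in ATTAINABLE.items():
        fixed = {"smb": 2, "iga": 2, "igm": 1, "ab": 2, "cd4": 2}
        prev = None
        for cat in cats:
            args = dict(fixed, **{analyte: cat})
            total = score_visual(labs_for(**args)).total
            if prev is not None:
                assert total >= prev
            prev = total


@settings(max_examples=200, deadline=None)
@given(
    smb=st.floats(0, 100),
    iga=st.floats(0, 8),
    igm=st.floats(0, 6),
    cd4=st.floats(0, 3000),
    ab=st.sampled_from([1, 2, 4]),
)
def test_component_points_stay_in_attainable_sets(smb, iga, igm, cd4, ab):
    poly, protein = AB_FOR[ab]
    pts = categorize_analytes(
        make_labs(smb_pct=smb, iga_g_l=iga, igm_g_l=igm, cd4_per_ul=cd4,
                  poly_response=poly, protein_response=protein)
    )
    assert pts.smb in ATTAINABLE["smb"]
    assert pts.iga in ATTAINABLE["iga"]
    assert pts.igm in ATTAINABLE["igm"]
    assert pts.ab in ATTAINABLE["ab"]
    assert pts.cd4 in ATTAINABLE["cd4"]
    assert 5 <= sum(pts.as_tuple()) <= 20


def test_grid_sweep_is_piecewise_monotone(reference):
    # worsening each continuous analyte sweeps through a monotone point sequence
    sweeps = {
        "smb_pct": np.linspace(0, 2 * reference.smb_upper_normal_pct, 400)[::-1],
        "iga_g_l": np.linspace(0, 2 * reference.iga_lower_normal_g_l, 400)[::-1],
        "cd4_per_ul": np.linspace(0, 2 * reference.cd4_thresholds_per_ul[0], 400)[::-1],
        "igm_g_l": np.linspace(0, 2 * reference.igm_normal_range_g_l[1], 400),
    }
    attr = {"smb_pct": "smb", "iga_g_l": "iga", "cd4_per_ul": "cd4", "igm_g_l": "igm"}
    for field, values in sweeps.items():
        pts = [getattr(categorize_analytes(make_labs(**{field: float(v)})), attr[field]) for v in values]
        assert all(b >= a for a, b in zip(pts, pts[1:])), field


def test_boundary_audit_each_threshold_steps_exactly_one_category(reference):
    eps = 1e-9
    cases = [
        ("smb_pct", "smb", list(reference.smb_thresholds_pct)),
        ("cd4_per_ul", "cd4", list(reference.cd4_thresholds_per_ul)),
        ("iga_g_l", "iga", [reference.iga_2sd_g_l, reference.iga_undetectable_g_l]),
    ]
    order = {"smb": ATTAINABLE["smb"], "cd4": ATTAINABLE["cd4"], "iga": ATTAINABLE["iga"]}
    for field, attr, thresholds in cases:
        for t in thresholds:
            at = getattr(categorize_analytes(make_labs(**{field: t})), attr)
            below = getattr(categorize_analytes(make_labs(**{field: t - eps})), attr)
            seq = order[attr]
            assert seq.index(below) == seq.index(at) + 1, (field, t)
    # IgM boundary: 2.3 is still normal, above it scores 4
    assert categorize_analytes(make_labs(igm_g_l=reference.igm_normal_range_g_l[1])).igm == 1
    assert categorize_analytes(make_labs(igm_g_l=reference.igm_normal_range_g_l[1] + eps)).igm == 4


def test_above_normal_values_warn_but_still_score_one():
    pts = categorize_analytes(make_labs(smb_pct=35.0, cd4_per_ul=1800.0))
    assert pts.smb == 1 and pts.cd4 == 1
    assert len(pts.warnings) == 2


def test_missing_analyte_refuses_to_score():
    labs = make_labs(iga_g_l=None)
    with pytest.raises(IncompletePanelError, match="incomplete panel.*iga_g_l"):
        score_visual(labs)


def test_reference_config_validates_threshold_ordering():
    with pytest.raises(ValueError):
        ReferenceConfig(smb_thresholds_pct=(1.0, 2.0, 6.0))
    with pytest.raises(ValueError):
        ReferenceConfig(iga_undetectable_g_l=0.5, iga_2sd_g_l=0.4)


class TestScoreCohort:
    def test_valid_rows_scored_in_order(self):
        df = labs_frame([make_labs(patient_id=f"P{i}") for i in range(3)])
        results, rejects = score_cohort(df)
        assert list(results["patient_id"]) == ["P0", "P1", "P2"]
        assert len(rejects) == 0

    def test_incomplete_row_is_rejected_not_imputed(self):
        df = labs_frame(
            [make_labs("A"), make_labs("B", iga_g_l=math.nan), make_labs("C")]
        )
        results, rejects = score_cohort(df)
        assert list(results["patient_id"]) == ["A", "C"]
        assert len(rejects) == 1
        assert "incomplete panel" in rejects.iloc[0]["reason"]

    def test_empty_cohort_is_an_error(self):
        with pytest.raises(EmptyCohortError):
            score_cohort(pd.DataFrame(columns=["patient_id"]))

    def test_same_input_same_output(self):
        df = labs_frame([make_labs(patient_id=f"P{i}", smb_pct=1.0 + i) for i in range(5)])
        r1, _ = score_cohort(df)
        r2, _ = score_cohort(df)
        pd.testing.assert_frame_equal(r1, r2)


@pytest.mark.parametrize(
    "pre,post,antigen,expected",
    [
        (0.01, 0.05, "protein", True),   # 5-fold rise
        (0.01, 0.03, "protein", False),  # 3-fold rise, below absolute limit
        (0.01, 0.2, "protein", True),    # above 0.15 IU/mL absolute
        (2.0, 7.0, "polysaccharide", True),   # 3.5-fold rise
        (2.0, 5.0, "polysaccharide", False),
        (0.0, 12.0, "polysaccharide", True),  # absolute threshold rescues zero pre-titre
        (0.0, 5.0, "polysaccharide", False),
    ],
)
def test_vaccine_response_fold_rise_and_absolute_rules(pre, post, antigen, expected):
    assert vaccine_response_adequate(pre, post, antigen) is expected
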