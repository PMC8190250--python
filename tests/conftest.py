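import numpy as np
import pandas as pd
import pytest

from visualscore.scoring import PatientLabs, ReferenceConfig
from visualscore.simulate import GeneratorConfig, generate_cohort


def make_labs(
    patient_id="P1",
    smb_pct=10.0,
    iga_g_l=1.2,
    igm_g_l=1.0,
    poly_response="adequate",
    protein_response="adequate",
    cd4_per_ul=900.0,
    age=30.0,
) -> PatientLabs:
    """A fully normal panel (all components 1 point) unless overridden."""
    return PatientLabs(
        patient_id=patient_id,
        smb_pct=smb_pct,
        iga_g_l=iga_g_l,
        igm_g_l=igm_g_l,
        poly_response=poly_response,
        protein_response=protein_response,
        cd4_per_ul=cd4_per_ul,
        age_at_diagnosis_years=age,
    )


@pytest.fixture(scope="session")
def reference() -> ReferenceConfig:
    return ReferenceConfig()


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-sized synthetic cohort (n=50), one fixed seed."""
    return generate_cohort(GeneratorConfig(n=50, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)


def labs_frame(records: list[PatientLabs]) -> pd.DataFrame:
    from dataclasses import asdict

    return pd.DataFrame([asdict(r) for r in records])
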