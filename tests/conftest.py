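import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from munix_d50.cohort_io import (
    AlsfrsObservation,
    MunixPanel,
    PatientRecord,
    SurvivalRecord,
)
from munix_d50.munix_metrics import apply_floors, control_baseline

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_panel(patient_id, t_munix, munix_by_muscle, cmap_by_muscle, side="less_affected"):
    measurements = tuple(
        apply_floors(m, munix_by_muscle[m], cmap_by_muscle[m], obtainable=True)
        for m in ("APB", "ADM", "TA")
    )
    return MunixPanel(
        patient_id=patient_id,
        t_munix_months=t_munix,
        side=side,
        measurements=measurements,
    )


def make_patient(
    patient_id,
    obs,
    t_munix=12.0,
    munix=None,
    cmap=None,
    side="less_affected",
    survival=(40.0, True),
    metadata=None,
):
    """Small handcrafted patient for IO/exclusion tests."""
    munix = munix or {"APB": 80.0, "ADM": 70.0, "TA": 60.0}
    cmap = cmap or {"APB": 5.0, "ADM": 5.0, "TA": 3.0}
    return PatientRecord(
        patient_id=patient_id,
        observations=tuple(
            AlsfrsObservation(patient_id, t, s) for t, s in sorted(obs)
        ),
        panel=make_panel(patient_id, t_munix, munix, cmap, side),
        survival=SurvivalRecord(patient_id, *survival),
        metadata=metadata or {"gold_coast": True, "juvenile": False},
    )


@pytest.fixture
def simple_controls():
    """Two identical controls: per-muscle means are exact, SDs zero.
    MUNIX sum 440, CMAP sum 25 mV."""
    rows = []
    for cid in ("C0", "C1"):
        for muscle, munix, cmap in (("APB", 160.0, 10.0), ("ADM", 150.0, 10.0), ("TA", 130.0, 5.0)):
            rows.append({"control_id": cid, "muscle": muscle, "munix": munix, "cmap_mV": cmap})
    return pd.DataFrame(rows)


@pytest.fixture
def simple_baseline(simple_controls):
    return control_baseline(simple_controls)


@pytest.fixture
def declining_obs():
    """A clean declining trajectory sampled from the sigmoid (D50=25, dx=6)."""
    from munix_d50.d50_model import sigmoid_value

    t = np.arange(3.0, 31.0, 3.0)
    return list(zip(t, sigmoid_value(t, 25.0, 6.0)))
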