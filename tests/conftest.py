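import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from bbbivivc.records import TransportRecord

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_transport(
    c_receiver=0.10,
    c0=10.0,
    v_receiver=0.6,
    v_donor=0.1,
    area=0.33,
    t=1800.0,
    drug="drugA",
    model="mono",
    replicate=1,
):
    return TransportRecord(
        drug_id=drug,
        model_id=model,
        replicate=replicate,
        t_sample=t,
        c0_donor=c0,
        c_receiver=c_receiver,
        v_receiver=v_receiver,
        v_donor=v_donor,
        membrane_area=area,
    )


@pytest.fixture
def transport_csv(tmp_path):
    """Well-formed 4-replicate transport CSV for one drug."""
    df = pd.DataFrame(
        {
            "drug_id": ["drugA"] * 4,
            "model_id": ["mono"] * 4,
            "replicate": [1, 2, 3, 4],
            "t_sample_s": [1800.0] * 4,
            "C0_uM": [10.0] * 4,
            "C_receiver_uM": [0.10, 0.11, 0.09, 0.10],
            "V_receiver_mL": [0.6] * 4,
            "V_donor_mL": [0.1] * 4,
            "area_cm2": [0.33] * 4,
        }
    )
    path = tmp_path / "transport.csv"
    df.to_csv(path, index=False)
    return path


@pytest.fixture
def teer_csv(tmp_path):
    rows = []
    for day in (2, 4, 6, 7):
        rows.append(("blank_1", "blank", day, 100.0, True))
        rows.append(("blank_2", "blank", day, 100.0, True))
        base = {2: 130.0, 4: 150.0, 6: 180.0, 7: 160.0}[day]
        for rep in (1, 2):
            rows.append((f"mono_{rep}", "mono", day, base + rep, False))
    df = pd.DataFrame(rows, columns=["insert_id", "model_id", "day", "resistance_ohm", "is_blank"])
    df["area_cm2"] = 0.33
    path = tmp_path / "teer.csv"
    df.to_csv(path, index=False)
    return path
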