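import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import eclascreen as ec
from eclascreen.layout_io import Role

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_ecla():
    """Two-antibody screen of 200 clones with two strong dual-antibody kinases."""
    cfg = ec.SimConfig(
        n_clones=200,
        n_blocks=8,
        block_columns=10,
        planted_kinases={
            "etk": {"pTyr100": 8.0, "PY20": 8.0},
            "wzc": {"pTyr100": 6.0, "PY20": 6.0},
        },
        seed=11,
    )
    return ec.simulate_ecla(cfg)


@pytest.fixture(scope="session")
def small_proteome():
    """±ATP experiment: 300 proteins, 10 planted substrates, duplicate assays."""
    planted = {f"sub{i:02d}": e for i, e in enumerate(np.linspace(10.0, 40.0, 10), 1)}
    cfg = ec.SimConfig(
        n_clones=300,
        n_blocks=6,
        block_columns=10,
        planted_substrates=planted,
        antibodies=("pTyr100",),
        n_replicate_assays=2,
        include_qc_channels=False,
        seed=7,
    )
    return ec.simulate_proteome_array(cfg)


def manual_scan(rows, **meta):
    """Build an ArrayScan from (block,row,col,name,role,fg,bg[,flag]) tuples."""
    records = []
    for row in rows:
        flag = row[7] if len(row) > 7 else 0
        records.append(
            ec.SpotRecord(row[0], row[1], row[2], row[3], Role(row[4]), row[5], row[6], flag)
        )
    return ec.ArrayScan.from_records(records, **meta)
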