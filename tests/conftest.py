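import numpy as np
import pandas as pd
import pytest

import neuroctrl as nc


@pytest.fixture(scope="session")
def full_atlas():
    return nc.load_default_atlas()


@pytest.fixture(scope="session")
def toy_atlas():
    return nc.load_toy_atlas()


@pytest.fixture(scope="session")
def toy_study():
    """One deterministic toy cohort with an injected HC-only DMN decline."""
    cohort, ctrl = nc.simulate_study(
        nc.toy_config(seed=1), nc.dmn_decline_spec(), seed=1
    )
    return cohort, ctrl


def make_cohort(n_scz=20, n_hc=20, seed=0, clinical=True):
    """Small hand-rolled cohort table for unit tests (not the generator)."""
    rng = np.random.default_rng(seed)
    rows = []
    for dx, n in (("SCZ", n_scz), ("HC", n_hc)):
        for i in range(n):
            row = {
                "subject_id": f"{dx.lower()}{i:03d}",
                "diagnosis": dx,
                "age": float(rng.uniform(16, 60)),
                "sex": "M" if rng.random() < 0.5 else "F",
                "education": float(rng.uniform(6, 20)),
            }
            if clinical and dx == "SCZ":
                row.update(
                    dup=float(rng.lognormal(2.6, 1.3)),
                    gaf=float(rng.uniform(10, 60)),
                    panss_total=float(rng.uniform(60, 120)),
                    panss_pos=float(rng.uniform(10, 40)),
                    panss_neg=float(rng.uniform(10, 40)),
                    panss_general=float(rng.uniform(20, 70)),
                )
            rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def small_cohort():
    return make_cohort()
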