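import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ratconnectome.regions import RegionTable, packaged_region_table
from ratconnectome.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def table1() -> RegionTable:
    """The packaged atlas parcellation (76 structural / 54 functional)."""
    return packaged_region_table()


def make_toy_table(n=4, all_gm=True):
    """Small hand-built region table for unit tests."""
    rows = []
    for i in range(1, n + 1):
        rows.append(
            {
                "region_name": f"R{i}",
                "hemisphere": "right" if i % 2 else "left",
                "structural_index": i,
                "functional_index": i if all_gm else pd.NA,
                "tissue_class": "GM" if all_gm else "WM",
                "volume_mm3": float(i),
            }
        )
    frame = pd.DataFrame(rows)
    frame["structural_index"] = frame["structural_index"].astype("Int64")
    frame["functional_index"] = frame["functional_index"].astype("Int64")
    return RegionTable(frame)


@pytest.fixture
def toy_table():
    return make_toy_table(4)


@pytest.fixture(scope="session")
def small_cohort():
    """One small generated cohort shared across tests (read-only)."""
    return generate_cohort(
        CohortConfig(
            seed=11,
            n_per_group=4,
            n_regions_structural=20,
            n_regions_functional=12,
            T=150,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
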