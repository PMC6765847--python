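import numpy as np
import pytest

import stratavis as sv
from stratavis.simulate import ITEM_NAMES


@pytest.fixture(scope="session")
def cohort500():
    """Well-separated five-stage cohort used by the heavier tests."""
    return sv.generate_cohort(sv.default_separated_config(500, 1))


@pytest.fixture(scope="session")
def cohort500_layout(cohort500):
    """(table, anchors, normalized matrix, 3D points) for the 15-item layout."""
    specs = sv.select_variables(cohort500, list(ITEM_NAMES), "anchors")
    anchors = sv.make_anchors(specs)
    u = sv.normalize(cohort500, specs)
    points = sv.layout_table(u, anchors, mode="radvis3d")
    return cohort500, anchors, u, points


@pytest.fixture()
def toy_table():
    """Six patients, two items and a stage label, for filter/summary checks."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "diagnosis": ["SMI", "MCI", "AD", "AD", "VCI", "SMI"],
            "item_01": [3.0, 2.0, 0.0, 1.0, 2.0, 3.0],
            "item_02": [2.0, 2.0, 1.0, 0.0, 3.0, 3.0],
        },
        index=pd.Index([f"P{i}" for i in range(6)], name="id"),
    )
    specs = [
        sv.VariableSpec("diagnosis", "categorical", categories=("SMI", "MCI", "VCI", "SVD", "AD")),
        sv.VariableSpec("item_01", "numeric", 0.0, 3.0),
        sv.VariableSpec("item_02", "numeric", 0.0, 3.0),
    ]
    return sv.DataTable(df, specs)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
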