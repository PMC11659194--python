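import numpy as np
import pandas as pd
import pytest

import sweetspots as sw


@pytest.fixture
def registry():
    return sw.default_registry()


@pytest.fixture
def eight_da_table(registry):
    """Hand-built 8-DA table whose quartile classes can be derived by hand.

    Walkability runs 1..8 (high is good) and NO2 runs 8..1 (low is good),
    so under quartile breaks the two class vectors coincide: DAs 0-1 are
    class 1 on both, 2-3 class 2, 4-5 class 3, 6-7 class 4.
    """
    df = pd.DataFrame(
        {
            "walkability": [1.0, 2, 3, 4, 5, 6, 7, 8],
            "no2": [8.0, 7, 6, 5, 4, 3, 2, 1],
            "pct_lico": [40.0, 35, 30, 25, 20, 15, 10, 5],
            "population": [500] * 8,
        },
        index=pd.Index([f"D{i}" for i in range(8)], name="da_id"),
    )
    return sw.DATable(df, 2006, registry, demo_groups=["pct_lico"])


@pytest.fixture
def walk_no2_rules():
    return next(r for r in sw.builtin_rulesets() if r.name == "walkability_no2")


@pytest.fixture
def rng():
    return np.random.default_rng(20160506)
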