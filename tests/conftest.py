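import numpy as np
import pandas as pd
import pytest

from gbmregions import CohortSpec, make_default_archetypes, simulate_cohort
from gbmregions.panel import MARKERS


@pytest.fixture(scope="session")
def archetypes():
    return make_default_archetypes()


@pytest.fixture(scope="session")
def archetype_table(archetypes):
    """Noise-free table of the eight archetype mean profiles (one RoI each)."""
    rows = [
        ["T1", a.name, 0, *[a.marker_means[m] for m in MARKERS]]
        for a in archetypes
    ]
    return pd.DataFrame(rows, columns=["tumor_id", "roi_id", "relapse", *MARKERS])


@pytest.fixture(scope="session")
def default_cohort():
    """Default-condition synthetic cohort (61 tumors, archetype sds, 2% missing)."""
    return simulate_cohort(CohortSpec(seed=7))


@pytest.fixture
def small_table():
    """Tiny clean cohort table for I/O and correlation unit tests."""
    rng = np.random.default_rng(0)
    n = 12
    vals = rng.random((n, len(MARKERS)))
    df = pd.DataFrame(vals, columns=MARKERS)
    df.insert(0, "tumor_id", [f"T{1 + i // 3}" for i in range(n)])
    df.insert(1, "roi_id", [f"R{i}" for i in range(n)])
    df.insert(2, "relapse", 0)
    return df
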