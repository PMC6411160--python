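import numpy as np
import pandas as pd
import pytest

from emspart import SiteBySpeciesMatrix, SurveyTable


@pytest.fixture
def tiny_survey() -> SurveyTable:
    """Two sites, two species, surveyed over 2009-2010 x 2 sessions."""
    rows = []
    counts = {
        ("A", 2009, 1): (2, 0), ("A", 2009, 2): (0, 1),
        ("A", 2010, 1): (1, 0), ("A", 2010, 2): (1, 3),
        ("B", 2009, 1): (0, 5), ("B", 2009, 2): (0, 2),
        ("B", 2010, 1): (0, 0), ("B", 2010, 2): (1, 1),
    }
    for (site, year, sess), (a, b) in counts.items():
        rows.append({"site_id": site, "year": year, "session": sess,
                     "skylark": a, "wren": b})
    return SurveyTable(pd.DataFrame(rows))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def random_incidence(n, s, rng, p=0.4) -> SiteBySpeciesMatrix:
    """Random incidence matrix guaranteed non-empty rows/columns."""
    while True:
        arr = (rng.random((n, s)) < p).astype(float)
        if arr.sum(axis=0).min() > 0 and arr.sum(axis=1).min() > 0:
            return SiteBySpeciesMatrix(
                pd.DataFrame(arr,
                             index=[f"site{i}" for i in range(n)],
                             columns=[f"sp{j}" for j in range(s)]),
                mode="incidence",
            )
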