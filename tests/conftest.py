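import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from kinoset import ActivityMatrix, AssayPanel, KinaseAssay

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def small_panel() -> AssayPanel:
    """Six wild-type human kinases spanning three families."""
    return AssayPanel(
        name="toy-6",
        assays=[
            KinaseAssay("AURKC", "Other"),
            KinaseAssay("BRAF", "TKL"),
            KinaseAssay("CDK2", "CMGC"),
            KinaseAssay("EGFR", "TK"),
            KinaseAssay("GSK3B", "CMGC"),
            KinaseAssay("MAPK14", "CMGC"),
        ],
        concentration=1.0,
    )


@pytest.fixture
def small_matrix(small_panel) -> ActivityMatrix:
    """Three compounds: one selective, one promiscuous, one inactive."""
    values = pd.DataFrame(
        {
            "AURKC": [5.0, 2.0, 100.0],
            "BRAF": [95.0, 4.0, 100.0],
            "CDK2": [88.0, 6.0, 100.0],
            "EGFR": [9.9, 8.0, 100.0],
            "GSK3B": [100.0, 9.0, 100.0],
            "MAPK14": [50.0, 1.0, 100.0],
        },
        index=["SEL1", "PROM1", "INACT1"],
        dtype=float,
    )
    return ActivityMatrix(panel=small_panel, values=values)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
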