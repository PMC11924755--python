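import warnings

import numpy as np
import pandas as pd
import pytest

from ddr_wescore.panel import DDRPanel, PanelEntry, load_default_panel
from ddr_wescore.scoring import ExpressionMatrix
from ddr_wescore.simulate import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def default_panel():
    return load_default_panel(warn=False)


@pytest.fixture
def toy_panel():
    """3 genes in 3 pathways, mixed ESF weights."""
    return DDRPanel(entries=(
        PanelEntry("BRCA1", "HR", 2.0),
        PanelEntry("XRCC1", "BER", 1.0),
        PanelEntry("POLH", "TLS", 1.0),
    ))


@pytest.fixture
def small_zscore_expr():
    """4 genes x 4 samples, declared as pre-computed z-scores."""
    rng = np.random.default_rng(42)
    vals = rng.normal(size=(4, 4))
    vals = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, ddof=1,
                                                                keepdims=True)
    return ExpressionMatrix(
        values=pd.DataFrame(vals, index=["BRCA1", "XRCC1", "POLH", "BG1"],
                            columns=[f"s{i}" for i in range(4)]),
        units="zscore",
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (n=120, delta=1.5, 3 planted clusters)."""
    return generate_cohort(CohortSpec(seed=11))


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*synthetic default panel.*")
        yield
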