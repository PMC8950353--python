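import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_counts() -> pd.DataFrame:
    """3 taxa x 2 samples."""
    return pd.DataFrame(
        [[5, 0], [3, 2], [2, 8]],
        index=pd.Index(["OTU1", "OTU2", "OTU3"], name="TaxonID"),
        columns=["S1", "S2"],
        dtype=np.int64,
    )


@pytest.fixture
def study_metadata() -> pd.DataFrame:
    """One metadata row per plot of the 23-plot design."""
    from morelnet.simulate import STUDY_DESIGN

    rows = [
        {"SampleID": plot, "site": str(site), "plot": plot, "replicate": 1,
         "group_I": gi, "yield_class": yc, "analysis_group": ag}
        for plot, site, gi, yc, ag in STUDY_DESIGN
    ]
    return pd.DataFrame(rows).set_index("SampleID")
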