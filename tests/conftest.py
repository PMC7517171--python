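import numpy as np
import pytest

from chenlife import ChenComplete, load_renal_graft


@pytest.fixture(scope="session")
def graft_times() -> np.ndarray:
    return load_renal_graft()


@pytest.fixture(scope="session")
def complete_fit(graft_times):
    """Joint complete-data MLE of the graft-survival data (shared, expensive-ish)."""
    return ChenComplete(graft_times).fit()
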