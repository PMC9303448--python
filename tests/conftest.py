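import numpy as np
import pandas as pd
import pytest

from trimmedmeans import TrialDataset


def dataset_from_arms(y0, y1, cov0=None, cov1=None, cov_name="u") -> TrialDataset:
    """Build a TrialDataset from per-arm outcome arrays (NaN = missing)."""
    y0 = np.asarray(y0, float)
    y1 = np.asarray(y1, float)
    frame = pd.DataFrame(
        {
            "arm": np.r_[np.zeros(y0.size, int), np.ones(y1.size, int)],
            "y": np.r_[y0, y1],
        }
    )
    if cov0 is not None or cov1 is not None:
        cov0 = np.asarray(cov0, float) if cov0 is not None else np.zeros(y0.size)
        cov1 = np.asarray(cov1, float) if cov1 is not None else np.zeros(y1.size)
        frame[cov_name] = np.r_[cov0, cov1]
    return TrialDataset(frame)


@pytest.fixture
def toy_dataset() -> TrialDataset:
    """Arm 0: {1, 2, 3, 4, missing}; arm 1: {2, 3, 4, 5, 6}."""
    return dataset_from_arms([1, 2, 3, 4, np.nan], [2, 3, 4, 5, 6])
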