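import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture
def small_pval_table() -> pd.DataFrame:
    """Three genes scored by two methods, one gene missing from one method."""
    return pd.DataFrame(
        {
            "gene_id": ["a", "b", "c", "a", "b"],
            "method_id": ["m1", "m1", "m1", "m2", "m2"],
            "p_value": [1e-3, 0.01, 0.5, 0.2, 0.04],
            "evidence_class": "common",
        }
    )


def brute_force_running_sum(scores: np.ndarray, hit_mask: np.ndarray, weight: float) -> np.ndarray:
    """Independent O(N) running-sum profile used as the ES oracle.

    ``scores`` must already be in descending list order.
    """
    n = len(scores)
    k = int(hit_mask.sum())
    w = np.abs(scores) ** weight
    hit_w = np.where(hit_mask, w, 0.0)
    total = hit_w.sum()
    if total > 0:
        steps = np.where(hit_mask, hit_w / total, -1.0 / (n - k))
    else:
        steps = np.where(hit_mask, 1.0 / k, -1.0 / (n - k))
    return np.cumsum(steps)


def brute_force_es(scores: np.ndarray, hit_mask: np.ndarray, weight: float) -> float:
    profile = brute_force_running_sum(scores, hit_mask, weight)
    return float(profile[np.argmax(np.abs(profile))])


@pytest.fixture
def es_oracle():
    return brute_force_es


@pytest.fixture
def running_sum_oracle():
    return brute_force_running_sum
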