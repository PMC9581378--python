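import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from liversig import pipeline, synthio

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cfg():
    return synthio.default_config(seed=11)


@pytest.fixture(scope="session")
def discovery_run(default_cfg, tmp_path_factory):
    """One full discovery run on the default planted bundle, shared."""
    out = tmp_path_factory.mktemp("bundle")
    run_cfg = pipeline.write_bundle(default_cfg, out)
    return pipeline.run_discovery(run_cfg), run_cfg


def midranks(values):
    """Independent midrank computation used by test oracles."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


@pytest.fixture
def tiny_counts():
    """3 genes x 4 samples, two groups, hand-checkable."""
    from liversig import CountMatrix

    counts = pd.DataFrame(
        [[10, 20, 12, 24], [5, 10, 6, 12], [100, 200, 120, 240]],
        index=["gA", "gB", "gC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    groups = pd.Series(
        ["NAS0-1", "NAS0-1", "NAS4-6", "NAS4-6"], index=counts.columns
    )
    return CountMatrix(counts, groups)
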