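import numpy as np
import pandas as pd
import pytest

from somoc.registry import load_builtin_registry
from somoc.synthetic import default_specs, generate_dataset


@pytest.fixture(scope="session")
def registry():
    return load_builtin_registry()


@pytest.fixture(scope="session")
def default_dataset():
    """One realization of the default 17-region synthetic dataset."""
    return generate_dataset(default_specs(), seed=20240901)


def make_samples(som, oc, region="R", **extra) -> pd.DataFrame:
    """Minimal schema-conforming sample table for unit tests."""
    som = np.asarray(som, dtype=float)
    n = som.size
    df = pd.DataFrame({
        "region": region,
        "site": f"{region}-s1",
        "core_id": f"{region}-c0",
        "depth_top": np.arange(n) * 5.0,
        "depth_bottom": (np.arange(n) + 1) * 5.0,
        "som": som,
        "oc": np.asarray(oc, dtype=float),
    })
    for key, val in extra.items():
        df[key] = val
    return df
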