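import numpy as np
import pandas as pd
import pytest

from palmkit import LocalizationTable
from palmkit.simulate import DiffusionConfig, PhotophysicsConfig, PopulationConfig, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def static_emitter_table(rng):
    """Static emitters re-localized in every frame with 10 nm Gaussian noise."""
    n_em, n_frames, sigma = 60, 120, 10.0
    centers = rng.random((n_em, 2)) * 20000
    rows = []
    for f in range(n_frames):
        pts = centers + rng.normal(0, sigma, (n_em, 2))
        rows.extend((f, x, y) for x, y in pts)
    df = pd.DataFrame(rows, columns=["frame", "x", "y"])
    return LocalizationTable(data=df)


def make_config(seed=0, **kwargs):
    """SimConfig factory accepting flat overrides for the nested sections."""
    nested = {}
    for key, cls in (("photophysics", PhotophysicsConfig), ("population", PopulationConfig),
                     ("diffusion", DiffusionConfig)):
        if key in kwargs:
            nested[key] = cls(**kwargs.pop(key)) if isinstance(kwargs[key], dict) else kwargs.pop(key)
    return SimConfig(seed=seed, **nested, **kwargs)
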