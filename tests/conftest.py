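import numpy as np
import pandas as pd
import pytest

from stratodyn.data_model_io import TimeGrid
from stratodyn.synthetic_data import SyntheticConfig


def make_occurrences(rows):
    """Build a minimal valid occurrences frame from (genus, max, min, cat) plus overrides."""
    defaults = {
        "region": "region_01",
        "lithology_affinity": "shallow_mid_siliciclastic",
        "assemblage": "WhiteSea",
        "record_class": "body",
        "lagerstatte": False,
    }
    out = []
    for row in rows:
        genus, max_age, min_age, cat = row[:4]
        extra = row[4] if len(row) > 4 else {}
        out.append(
            {**defaults, "genus": genus, "max_age": max_age, "min_age": min_age,
             "uncertainty_category": cat, **extra}
        )
    return pd.DataFrame(out)


def make_windows(specs):
    """Window frame from (label, older, younger) triples."""
    df = pd.DataFrame(specs, columns=["label", "older", "younger"])
    df["span"] = df["older"] - df["younger"]
    return df


@pytest.fixture
def small_grid():
    return TimeGrid(oldest=575.0, youngest=565.0)


@pytest.fixture
def small_config():
    """Scaled-down synthetic conditions for fast unit tests."""
    return SyntheticConfig(
        n_taxa={"Avalon": 6, "WhiteSea": 6, "Nama": 6, "Cambrian": 12},
        regions={"region_01": 1.0e5, "region_02": 3.0e5, "region_03": 5.0e4},
        n_geochem=120,
        master_seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
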