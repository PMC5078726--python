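import numpy as np
import pytest

import cellchron as cc


@pytest.fixture(scope="session")
def climate_1948_2013():
    """Short seeded climate table covering a 1950-2013 analysis span."""
    return cc.simulate_climate(
        cc.ClimateSimConfig(first_year=1948, last_year=2013, seed=11)
    )


@pytest.fixture(scope="session")
def climate_long():
    """Climate covering the full default tree span."""
    return cc.simulate_climate(cc.ClimateSimConfig(seed=3))


@pytest.fixture(scope="session")
def default_dataset(climate_long):
    """Default synthetic multi-proxy dataset plus ground truth."""
    series, truth = cc.simulate_tree_ring_data(climate_long, cc.TreeSimConfig(seed=4))
    return series, truth


def ld_spec(signal_strength=0.5):
    """Lumen-diameter generating spec with a March-August signal."""
    return cc.ParameterSimSpec(
        trend_kind="linear_positive",
        season=(3, 8),
        signal_strength=signal_strength,
        within_tree_corr=0.45,
        between_tree_corr=0.30,
        noise_sd=0.10,
        site_ar1=0.1,
        trend_params={"base": 22.0, "slope_per_year": 0.0012},
    )


def make_chronology(values, first_year=1950):
    """Wrap a plain vector as a Chronology for analysis-stage tests."""
    values = np.asarray(values, dtype=float)
    return cc.Chronology(
        years=np.arange(first_year, first_year + len(values)),
        values=values,
        sample_depth=np.zeros(len(values), dtype=int),
        min_depth=0,
    )
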