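import pandas as pd
import pytest

from droughtmark import (build_default_design, load_cell_parameters,
                         load_marker_registry)


@pytest.fixture(scope="session")
def design():
    return build_default_design(seed=7)


@pytest.fixture(scope="session")
def params():
    return load_cell_parameters()


@pytest.fixture(scope="session")
def registry():
    return load_marker_registry()


@pytest.fixture(scope="session")
def zero_noise_params(params):
    """Shipped parameters with all SEs forced to zero."""
    out = params.copy()
    out["se"] = 0.0
    return out


def cell_mean(params: pd.DataFrame, marker, genotype, treatment, stage, das):
    row = params[(params["marker"] == marker) & (params["genotype"] == genotype)
                 & (params["treatment"] == treatment)
                 & (params["stage"] == stage) & (params["das"] == das)]
    assert len(row) == 1
    return float(row["mean"].iloc[0])
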