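import logging

import numpy as np
import pandas as pd
import pytest

from mevrank.expression import ExpressionMatrix
from mevrank.synthetic import (
    NetworkFixtureParams,
    PlantedCascade,
    SimulationParams,
    default_gene_universe,
    generate_expression,
)

# the pipeline deliberately logs warnings for degraded inputs; keep test
# output quiet while still letting caplog-based assertions see records
logging.getLogger("mevrank").setLevel(logging.ERROR)


def make_expression(values: np.ndarray, genes, conditions_per_sample, scale="log2"):
    """Small hand-built expression matrix helper."""
    samples = [f"s{i}" for i in range(len(conditions_per_sample))]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples),
        conditions=pd.Series(conditions_per_sample, index=samples),
        scale=scale,
    )


@pytest.fixture(scope="session")
def tiny_params():
    """30-gene study with 3 planted up and 3 planted down genes."""
    universe = default_gene_universe(30)
    return SimulationParams(
        gene_universe=universe,
        planted_up=frozenset(universe[:3]),
        planted_down=frozenset(universe[3:6]),
        seed=11,
    )


@pytest.fixture(scope="session")
def zero_noise_expression(tiny_params):
    """Essentially noiseless matrix: planted effects dominate completely."""
    from dataclasses import replace

    params = replace(tiny_params, noise_sd=1e-9)
    expr, truth = generate_expression(params)
    return expr, truth


@pytest.fixture(scope="session")
def cascade_params():
    return NetworkFixtureParams(
        n_background_nodes=10,
        planted_cascades=(
            PlantedCascade("R1", ("A1", "A2"), "TNF", (1, 1, -1)),
        ),
        background_edge_density=0.2,
        fraction_inhibitory=0.3,
        seed=5,
    )
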