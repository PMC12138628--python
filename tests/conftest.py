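import pytest

from biolube.datasets import (
    esterification_design,
    esterification_factors,
    esterification_results,
)
from biolube.design import map_levels


@pytest.fixture
def factors():
    return esterification_factors()


@pytest.fixture
def l9(factors):
    return esterification_design()


@pytest.fixture
def results():
    return esterification_results()


@pytest.fixture
def conversions(results):
    return [r.mean for r in results]


@pytest.fixture
def physical(l9, factors):
    return map_levels(l9, factors)


# Published reference values for the bundled dataset (frozen from the
# source study's tables; display-precision).
PRINTED_SN = [38.99, 38.69, 36.76, 38.17, 37.33, 37.90, 34.53, 38.27, 36.07]
PRINTED_LEVEL_MEANS = {
    "MR": [38.15, 37.81, 36.29],
    "Cat": [37.23, 38.10, 36.91],
    "BL": [38.39, 37.65, 36.21],
    "t": [37.47, 37.05, 37.74],
}
PRINTED_DELTAS = {"MR": 1.86, "Cat": 1.19, "BL": 2.18, "t": 0.69}
PRINTED_RANKS = {"MR": 2, "Cat": 3, "BL": 1, "t": 4}
PRINTED_MODEL = {"b0": 100.7, "MR": -1.878, "Cat": -0.409, "BL": -0.299, "t": 0.04}
# Cells of the published response table that disagree with recomputation
# by exactly one display ulp (0.01 dB); see notes in the test modules.
DISCREPANT_CELLS = {("BL", 2), ("t", 2)}
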