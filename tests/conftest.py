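import numpy as np
import pytest

from seqbic import ExpressionMatrix, SequenceDatabase, parse_database

WORKED_DB_LINES = ["(bc)a(abc)d", "(ac)", "cad(acd)", "a(ac)c"]


@pytest.fixture
def worked_db() -> SequenceDatabase:
    """The four-sequence database of the worked mining example."""
    return parse_database(WORKED_DB_LINES)


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """4x3 toy matrix whose rows order their columns differently.

    Row x2 = (0, 2, 0) maps to (y1 y3) y2: y1 and y3 co-occur, y2 follows.
    """
    values = np.array(
        [
            [1.0, 2.0, 3.0],   # x1: y1 < y2 < y3
            [0.0, 2.0, 0.0],   # x2: (y1 y3) < y2
            [0.0, 2.0, 1.0],   # x3: y1 < y3 < y2
            [0.0, 3.0, 0.0],   # x4: (y1 y3) < y2
        ]
    )
    return ExpressionMatrix(values, ["x1", "x2", "x3", "x4"], ["y1", "y2", "y3"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
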