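import numpy as np
import pytest

from ivmr.core import HarmonizedInstrument, apply_zero_se_policy, load_fixture


@pytest.fixture(scope="session")
def table1():
    """The packaged 23-instrument LDL-C/T2DM table, verbatim."""
    return load_fixture("ldl_t2dm")


@pytest.fixture(scope="session")
def table1_floored(table1):
    """Same table with the four zero outcome SEs floored at the smallest positive SE."""
    return apply_zero_se_policy(table1, "floor")


def make_instruments(bx, by, sy, sx=None):
    bx, by, sy = map(np.atleast_1d, (bx, by, sy))
    sx = np.full(len(bx), 0.005) if sx is None else np.atleast_1d(sx)
    return [
        HarmonizedInstrument(f"rs{i + 1}", float(bx[i]), float(sx[i]),
                             float(by[i]), float(sy[i]))
        for i in range(len(bx))
    ]


@pytest.fixture
def worked_three_snp():
    """Hand-computed instance: weights (100, 400, 400)/1e-4, ratios (0.2, 0.25, 0.225)."""
    return make_instruments([0.1, 0.2, 0.4], [0.02, 0.05, 0.09], [0.01, 0.01, 0.02])
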