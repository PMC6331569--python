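import numpy as np
import pytest

from invasibility.lv import LVParams

TOY_NEWICK = "((A:1,B:1):1,C:2);"


@pytest.fixture
def toy_newick() -> str:
    return TOY_NEWICK


def make_pair_params(
    a_in: float = 0.5,
    a_ni: float = 0.5,
    K_I: float = 1e9,
    K_N: float = 1e9,
    r: float = 0.5,
) -> LVParams:
    """Two-species invader/native community with the given interaction."""
    return LVParams(
        species_ids=["I", "N"],
        r=np.array([r, r]),
        K=np.array([K_I, K_N]),
        alpha=np.array([[1.0, a_in], [a_ni, 1.0]]),
    )


@pytest.fixture
def pair_params():
    return make_pair_params
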