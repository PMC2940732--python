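import numpy as np
import pytest

from trnaerr import ModelParams, TRNAPool, default_params, ecoli_k12_pool


@pytest.fixture(scope="session")
def ecoli_pool() -> TRNAPool:
    return ecoli_k12_pool()


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return default_params()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)


@pytest.fixture()
def toy_pool() -> TRNAPool:
    """Three species around the ACA (Thr) codon: its perfect cognate UGU,
    the wobble reader GGU (Thr), and the near-cognate UGG (Pro)."""
    return TRNAPool.from_counts("toy", {"UGU": 3, "GGU": 2, "UGG": 5})
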