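from __future__ import annotations

import numpy as np
import pytest

from syndiff import synthetic as S
from syndiff.corpus_io import Record, RecordSet


@pytest.fixture
def toy_records() -> RecordSet:
    return RecordSet(
        [
            Record("r1", frozenset({"headache", "fatigue"}), frozenset({"yin deficiency"})),
            Record("r2", frozenset({"headache", "fatigue"}), frozenset({"qi stagnation"})),
            Record("r3", frozenset({"nausea"}), frozenset({"damp heat"})),
        ]
    )


@pytest.fixture
def small_synth():
    """40-record synthetic dataset for unit-level checks."""
    cfg = S.SynthConfig(n=40, m=4, f_informative=5, f_noise=15, signal=0.4, seed=7)
    return S.generate(cfg)


def random_eval_instance(rng: np.random.Generator, n_max=6, m_max=5, with_ties=True):
    """Random (Y, H, F) with every row owning >= 1 positive label."""
    n = int(rng.integers(1, n_max + 1))
    m = int(rng.integers(2, m_max + 1))
    Y = (rng.random((n, m)) < 0.4).astype(int)
    for i in np.flatnonzero(Y.sum(axis=1) == 0):
        Y[i, rng.integers(m)] = 1
    H = (rng.random((n, m)) < 0.4).astype(int)
    if with_ties and rng.random() < 0.5:
        F = rng.choice([0.0, 0.25, 0.5, 1.0], size=(n, m))
    else:
        F = rng.random((n, m))
    return Y, H, F
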