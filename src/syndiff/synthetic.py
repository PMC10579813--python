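"""Synthetic multi-label clinical-record generator with known ground truth.

Emulates the structure of sparse symptom/syndrome data: long-tailed label
frequencies (Zipf marginals), pairwise label co-occurrence, a minority of
label-informative symptom features among many noise features, and optional
spelling variants to exercise synonym standardization. Every generated
record has at least one symptom and one label, and the informative feature
index set is returned so selection quality can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus_io import FeatureSpace, LabelMatrix, Record, RecordSet, SynonymDictionary

__all__ = ["SynthConfig", "generate", "textualize"]


@dataclass(frozen=True)
class SynthConfig:
    n: int = 200
    f_informative: int = 10
    f_noise: int = 90
    m: int = 6
    labels_per_record: float = 1.8
    label_correlation: float = 0.3
    signal: float = 0.3
    tail: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n, self.f_informative, self.f_noise, self.m) < 1:
            raise ValueError("n, f_informative, f_noise and m must all be >= 1")
        if self.signal < 0:
            raise ValueError("signal must be >= 0")
        if not 0 <= self.label_correlation <= 1:
            raise ValueError("label_correlation must lie in [0, 1]")
        if self.labels_per_record > self.m:
            raise ValueError("labels_per_record cannot exceed the number of labels")


def _draw_labels(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Zipf marginals + per-pair copy mechanism for co-occurrence."""
    z = (np.arange(1, cfg.m + 1)) ** (-cfg.tail)
    q = np.clip(cfg.labels_per_record * z / z.sum(), 0.01, 0.9)
    Y = (rng.random((cfg.n, cfg.m)) < q).astype(np.int8)
    if cfg.label_correlation > 0:
        # consecutive label pairs: with prob rho the second copies the first
        for a in range(0, cfg.m - 1, 2):
            copy = rng.random(cfg.n) < cfg.label_correlation
            Y[copy, a + 1] = Y[copy, a]
    # every record needs >= 1 label
    empty = np.flatnonzero(Y.sum(axis=1) == 0)
    if len(empty):
        Y[empty, rng.choice(cfg.m, size=len(empty), p=q / q.sum())] = 1
    # every label must occur somewhere
    for l in np.flatnonzero(Y.sum(axis=0) == 0):
        Y[rng.integers(cfg.n), l] = 1
    return Y


def generate(cfg: SynthConfig) -> tuple[RecordSet, FeatureSpace, LabelMatrix, set[int]]:
    """Draw a dataset; returns records, matrices and the informative index set.

    Informative features occupy columns ``0 .. f_informative-1``; feature
    ``p`` is tied to label ``p mod m`` and its occurrence probability is
    raised by ``signal`` whenever that label is present. Noise features are
    independent of the labels but share the informative features' base-rate
    distribution, so at ``signal = 0`` the two groups are exchangeable.
    """
    rng = np.random.default_rng(cfg.seed)
    f = cfg.f_informative + cfg.f_noise
    Y = _draw_labels(cfg, rng)

    base = rng.uniform(0.05, 0.15, size=f)
    P = np.tile(base, (cfg.n, 1))
    for p in range(cfg.f_informative):
        P[:, p] = np.clip(base[p] + cfg.signal * Y[:, p % cfg.m], 0.0, 0.95)
    X = (rng.random((cfg.n, f)) < P).astype(float)

    # guarantee >= 1 symptom per record and >= 1 occurrence per feature
    for i in np.flatnonzero(X.sum(axis=1) == 0):
        X[i, rng.integers(f)] = 1.0
    for p in np.flatnonzero(X.sum(axis=0) == 0):
        X[rng.integers(cfg.n), p] = 1.0

    width = len(str(f - 1))
    feature_names = [f"s{p:0{width}d}" for p in range(f)]
    label_names = [f"L{l:02d}" for l in range(cfg.m)]
    records = [
        Record(
            f"g{i:06d}",
            frozenset(feature_names[p] for p in np.flatnonzero(X[i])),
            frozenset(label_names[l] for l in np.flatnonzero(Y[i])),
        )
        for i in range(cfg.n)
    ]
    fs = FeatureSpace(X, feature_names, X.min(axis=0), X.max(axis=0))
    lm = LabelMatrix(Y, label_names, Y.mean(axis=0))
    return RecordSet(records), fs, lm, set(range(cfg.f_informative))


def textualize(
    rs: RecordSet, variant_rate: float, rng: np.random.Generator
) -> tuple[RecordSet, SynonymDictionary]:
    """Replace a fraction of term occurrences with variant spellings.

    Returns the varied records and the dictionary that maps every variant
    back to its standard term, so standardization restores the original
    vectorization exactly.
    """
    if not 0 <= variant_rate <= 1:
        raise ValueError("variant_rate must lie in [0, 1]")
    mapping: dict[str, str] = {}
    out = []
    for r in rs.records:
        terms = set()
        for t in sorted(r.symptoms):
            if rng.random() < variant_rate:
                variant = f"{t}~v{int(rng.integers(2))}"
                mapping[variant] = t
                terms.add(variant)
            else:
                terms.add(t)
        out.append(Record(r.record_id, frozenset(terms), r.labels))
    return RecordSet(out), SynonymDictionary(mapping)
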