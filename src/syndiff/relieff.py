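"""Similarity-weighted multi-label ReliefF feature selection.

Every sample is visited once as a probe (traversal, not random sampling).
For each probe the K most similar samples with the *same label set* form the
hit neighborhood, and for every label class the probe lacks, the K most
similar samples carrying that class form a miss neighborhood. A feature's
weight is decreased by the similarity-weighted mean feature difference to
hits and increased by the prior-weighted mean difference to misses, so
features that separate unlike label sets while staying stable within a label
set rise to the top.

Sample similarity is the reciprocal of the Pearson distance,
``sim = 1 / (1 - rho)``, which lives in ``(1/2, inf)`` and — unlike plain
cosine similarity — is sensitive to the magnitude of feature values, not
only their direction. A cosine variant is kept for ablation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .corpus_io import FeatureSpace, LabelMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SelectorConfig",
    "FeatureWeights",
    "NeighborContext",
    "pcc",
    "sample_similarity",
    "similarity_matrix",
    "find_neighbors",
    "feature_diff",
    "update_weights",
    "select",
    "write_weight_report",
]


@dataclass(frozen=True)
class SelectorConfig:
    """Knobs for the selector.

    ``epsilon`` clamps the correlation below 1 so the similarity
    ``1/(1-rho)`` stays finite on duplicate-direction samples; ``sim_floor``
    is substituted when a sample has zero variance (correlation undefined) —
    it equals the similarity of perfectly anticorrelated samples, i.e. the
    undefined case is treated as maximally dissimilar.
    """

    k: int = 10
    n_select: int | None = None
    similarity: str = "pcc"  # "pcc" | "cosine"
    epsilon: float = 1e-6
    sim_floor: float = 0.5

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.similarity not in ("pcc", "cosine"):
            raise ValueError(f"unknown similarity {self.similarity!r}")


@dataclass
class FeatureWeights:
    """Weight vector plus the descending-weight feature ordering."""

    W: np.ndarray
    order: np.ndarray

    def __post_init__(self) -> None:
        if sorted(self.order) != list(range(len(self.W))):
            raise ValueError("order is not a permutation of feature indices")
        if np.any(np.diff(self.W[self.order]) > 0):
            raise ValueError("W[order] must be non-increasing")

    @classmethod
    def from_weights(cls, W: np.ndarray) -> "FeatureWeights":
        W = np.asarray(W, dtype=float)
        # descending weight, ties by ascending feature index
        order = np.lexsort((np.arange(len(W)), -W))
        return cls(W, order)


@dataclass
class NeighborContext:
    """Hit and miss neighborhoods of one probe sample."""

    probe: int
    label_set: frozenset[int]
    hit: list[tuple[int, float]]
    miss: dict[int, list[tuple[int, float]]] = field(default_factory=dict)


def pcc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient of two equal-length vectors."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("pcc needs two equal-length vectors of length >= 2")
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt(np.sum(xc**2)) * np.sqrt(np.sum(yc**2))
    if denom == 0:
        raise ValueError("pcc undefined: a vector has zero variance")
    return float(np.dot(xc, yc) / denom)


def _sim_from_rho(rho: float, cfg: SelectorConfig) -> float:
    return 1.0 / (1.0 - min(rho, 1.0 - cfg.epsilon))


def sample_similarity(x: np.ndarray, y: np.ndarray, cfg: SelectorConfig = SelectorConfig()) -> float:
    """Similarity of two samples; always finite and strictly positive."""
    if cfg.similarity == "cosine":
        nx, ny = np.linalg.norm(x), np.linalg.norm(y)
        if nx == 0 or ny == 0:
            logger.debug("zero-norm sample, substituting similarity floor")
            return cfg.sim_floor
        cos = float(np.dot(x, y) / (nx * ny))
        return (1.0 + cos) / 2.0 + cfg.sim_floor
    try:
        rho = pcc(x, y)
    except ValueError:
        logger.debug("zero-variance sample, substituting similarity floor")
        return cfg.sim_floor
    return _sim_from_rho(rho, cfg)


def similarity_matrix(X: np.ndarray, cfg: SelectorConfig = SelectorConfig()) -> np.ndarray:
    """Pairwise sample similarities (n x n); diagonal is left at the clamp value."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if cfg.similarity == "cosine":
        norms = np.linalg.norm(X, axis=1)
        ok = norms > 0
        Xn = np.zeros_like(X)
        Xn[ok] = X[ok] / norms[ok, None]
        cos = Xn @ Xn.T
        S = (1.0 + cos) / 2.0 + cfg.sim_floor
        bad = ~ok
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.corrcoef(X)
        rho = np.atleast_2d(rho)
        bad = np.isnan(rho).all(axis=1)
        rho = np.clip(rho, -1.0, 1.0 - cfg.epsilon)
        S = 1.0 / (1.0 - rho)
        S[np.isnan(S)] = cfg.sim_floor
    if bad.any():
        logger.info("similarity_matrix: %d zero-variance samples got the floor value", bad.sum())
        S[bad, :] = cfg.sim_floor
        S[:, bad] = cfg.sim_floor
    return S


def _top_k(candidates: np.ndarray, sims: np.ndarray, k: int) -> list[tuple[int, float]]:
    """Highest-similarity candidates; ties broken by lowest sample index."""
    order = np.lexsort((candidates, -sims))[:k]
    return [(int(candidates[i]), float(sims[i])) for i in order]


def find_neighbors(
    t: int,
    fs: FeatureSpace | np.ndarray,
    lm: LabelMatrix | np.ndarray,
    cfg: SelectorConfig = SelectorConfig(),
    S: np.ndarray | None = None,
) -> NeighborContext:
    """Hit and per-class miss neighborhoods of probe ``t``.

    Hits share the probe's label set exactly; Miss[C] are samples whose label
    set contains class C, for every C the probe lacks. A precomputed
    similarity matrix ``S`` may be passed to avoid recomputation.
    """
    X = fs.X if isinstance(fs, FeatureSpace) else np.asarray(fs, dtype=float)
    Y = lm.Y if isinstance(lm, LabelMatrix) else np.asarray(lm)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    if S is None:
        S = similarity_matrix(X, cfg)
    ls = frozenset(np.flatnonzero(Y[t] == 1).tolist())
    others = np.array([i for i in range(n) if i != t])
    same_mask = np.all(Y[others] == Y[t], axis=1)
    ctx = NeighborContext(probe=t, label_set=ls, hit=[], miss={})
    same = others[same_mask]
    if len(same):
        ctx.hit = _top_k(same, S[t, same], cfg.k)
    else:
        logger.debug("probe %d has a unique label set; hit neighborhood empty", t)
    for c in range(Y.shape[1]):
        if c in ls:
            continue
        cand = others[Y[others, c] == 1]
        if len(cand):
            ctx.miss[c] = _top_k(cand, S[t, cand], cfg.k)
    return ctx


def feature_diff(p: int, i: int, j: int, fs: FeatureSpace) -> float:
    """Range-normalized absolute feature difference in [0, 1]; 0 for constant features."""
    rng = fs.feature_max[p] - fs.feature_min[p]
    if rng == 0:
        return 0.0
    return float(abs(fs.X[i, p] - fs.X[j, p]) / rng)


def update_weights(
    fs: FeatureSpace | np.ndarray,
    lm: LabelMatrix | np.ndarray,
    cfg: SelectorConfig = SelectorConfig(),
) -> FeatureWeights:
    """Compute feature weights by full traversal of the sample set.

    Deterministic for a fixed input ordering: no random sampling is involved.
    Empty hit or miss neighborhoods contribute nothing (their similarity
    normalizer would be zero).
    """
    if isinstance(fs, FeatureSpace):
        X, fmin, fmax = fs.X, fs.feature_min, fs.feature_max
    else:
        X = np.asarray(fs, dtype=float)
        fmin, fmax = X.min(axis=0), X.max(axis=0)
    Y = lm.Y if isinstance(lm, LabelMatrix) else np.asarray(lm)
    priors = lm.priors if isinstance(lm, LabelMatrix) else Y.mean(axis=0)

    n, f = X.shape
    if f == 0:
        raise ValueError("no features")
    if n < 2:
        raise ValueError("need at least 2 samples")
    if Y.shape[0] != n:
        raise ValueError("X and Y row counts differ")

    rng = fmax - fmin
    inv_rng = np.divide(1.0, rng, out=np.zeros_like(rng, dtype=float), where=rng != 0)
    S = similarity_matrix(X, cfg)

    W = np.zeros(f)
    for t in range(n):
        ctx = find_neighbors(t, X, Y, cfg, S=S)
        # mean prior of the probe's label set, clamped away from 1
        ls = sorted(ctx.label_set)
        p_ls = min(float(np.mean(priors[ls])) if ls else 0.0, 1.0 - 1e-12)
        if ctx.hit:
            idx = np.array([i for i, _ in ctx.hit])
            sims = np.array([s for _, s in ctx.hit])
            D = np.abs(X[idx] - X[t]) * inv_rng
            W -= (sims @ D) / (n * sims.sum())
        for c, neighbors in ctx.miss.items():
            idx = np.array([i for i, _ in neighbors])
            sims = np.array([s for _, s in neighbors])
            D = np.abs(X[idx] - X[t]) * inv_rng
            W += (priors[c] / (1.0 - p_ls)) * (sims @ D) / (n * sims.sum())
    return FeatureWeights.from_weights(W)


def select(fw: FeatureWeights, n_select: int) -> list[int]:
    """Indices of the ``n_select`` highest-weight features (ties: lowest index first)."""
    f = len(fw.W)
    if not 1 <= n_select <= f:
        raise ValueError(f"n_select must be in [1, {f}], got {n_select}")
    return fw.order[:n_select].tolist()


def write_weight_report(fw: FeatureWeights, feature_names: list[str], path) -> None:
    """TSV of rank, feature name, weight — descending."""
    from pathlib import Path

    lines = ["rank\tfeature\tweight\n"]
    for rank, p in enumerate(fw.order, start=1):
        lines.append(f"{rank}\t{feature_names[p]}\t{fw.W[p]:.10g}\n")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("".join(lines), encoding="utf-8")
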