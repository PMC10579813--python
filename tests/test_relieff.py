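from __future__ import annotations

import numpy as np
import pytest

import oracles as O
from syndiff import relieff as R
from syndiff import synthetic as S
from syndiff.corpus_io import FeatureSpace, LabelMatrix


def random_selection_instance(rng, n_max=8, f_max=4, m_max=3):
    """Tiny random (X, Y) with per-row labels and occasional degenerate rows.

    f starts at 3: with only two features every pair of samples is perfectly
    (anti)correlated, so neighbor ordering degenerates to tie-breaking on
    ~1e-16 noise and no two independent implementations can agree.
    """
    n = int(rng.integers(2, n_max + 1))
    f = int(rng.integers(3, f_max + 1))
    m = int(rng.integers(1, m_max + 1))
    X = rng.random((n, f))
    if rng.random() < 0.2:  # constant feature column
        X[:, rng.integers(f)] = 0.7
    if rng.random() < 0.2:  # zero-variance sample row
        X[rng.integers(n)] = 0.3
    if rng.random() < 0.2 and n >= 3:  # exact duplicate rows (rho -> 1 clamp)
        X[1] = X[0]
    Y = (rng.random((n, m)) < 0.5).astype(int)
    for i in np.flatnonzero(Y.sum(axis=1) == 0):
        Y[i, rng.integers(m)] = 1
    return X, Y


class TestPcc:
    def test_anticorrelation(self):
        assert R.pcc([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_identity(self):
        assert R.pcc([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_hand_expanded(self):
        assert R.pcc([1, 2, 3], [1, 2, 4]) == pytest.approx(9 / np.sqrt(84), abs=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            R.pcc([1, 1, 1], [1, 2, 3])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            R.pcc([1, 2], [1, 2, 3])


class TestSampleSimilarity:
    def test_closed_forms(self):
        cfg = R.SelectorConfig(epsilon=1e-6)
        # rho = -1 -> 1/2; rho = 0 -> 1
        assert R.sample_similarity(np.array([1.0, 2, 3]), np.array([3.0, 2, 1]), cfg) == pytest.approx(0.5)
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        assert R.sample_similarity(x, y, cfg) == pytest.approx(1.0)

    def test_clamped_at_unit_correlation(self):
        cfg = R.SelectorConfig(epsilon=1e-6)
        v = np.array([1.0, 2.0, 3.0])
        assert R.sample_similarity(v, v, cfg) == pytest.approx(1e6)

    def test_zero_variance_returns_floor(self):
        cfg = R.SelectorConfig(sim_floor=0.5)
        assert R.sample_similarity(np.array([1.0, 1, 1]), np.array([1.0, 2, 3]), cfg) == 0.5

    def test_symmetric_and_positive(self):
        rng = np.random.default_rng(0)
        cfg = R.SelectorConfig()
        for _ in range(50):
            x, y = rng.random(5), rng.random(5)
            sxy = R.sample_similarity(x, y, cfg)
            assert sxy == pytest.approx(R.sample_similarity(y, x, cfg))
            assert sxy > 0

    def test_cosine_mode_positive(self):
        cfg = R.SelectorConfig(similarity="cosine", sim_floor=0.5)
        x = np.array([1.0, 0.0])
        y = np.array([-1.0, 0.0])  # cos = -1
        assert R.sample_similarity(x, y, cfg) == pytest.approx(0.5)
        assert R.sample_similarity(np.zeros(2), y, cfg) == 0.5

    def test_matrix_matches_pairwise(self):
        rng = np.random.default_rng(5)
        X = rng.random((6, 4))
        X[2] = 0.4  # zero-variance row
        for sim_kind in ("pcc", "cosine"):
            cfg = R.SelectorConfig(similarity=sim_kind)
            S_mat = R.similarity_matrix(X, cfg)
            for i in range(6):
                for j in range(6):
                    if i != j:
                        assert S_mat[i, j] == pytest.approx(
                            R.sample_similarity(X[i], X[j], cfg), abs=1e-10
                        )


class TestFindNeighbors:
    def test_forced_by_label_sets(self):
        X = np.array([[0.0, 1.0], [0.1, 0.9], [1.0, 0.0]])
        Y = np.array([[1, 0], [1, 0], [0, 1]])
        ctx = R.find_neighbors(0, X, Y, R.SelectorConfig(k=1))
        assert [i for i, _ in ctx.hit] == [1]
        assert [i for i, _ in ctx.miss[1]] == [2]

    def test_unique_label_set_has_empty_hit(self):
        X = np.random.default_rng(0).random((3, 3))
        Y = np.array([[1, 1], [1, 0], [0, 1]])
        ctx = R.find_neighbors(0, X, Y, R.SelectorConfig(k=2))
        assert ctx.hit == []
        assert not ctx.miss  # both classes are in the probe's label set

    def test_probe_excluded_and_sims_positive(self):
        rng = np.random.default_rng(1)
        X, Y = rng.random((6, 4)), (rng.random((6, 2)) < 0.5).astype(int)
        Y[Y.sum(axis=1) == 0, 0] = 1
        for t in range(6):
            ctx = R.find_neighbors(t, X, Y, R.SelectorConfig(k=2))
            members = [i for i, _ in ctx.hit] + [i for nb in ctx.miss.values() for i, _ in nb]
            assert t not in members
            assert all(s > 0 for _, s in ctx.hit)

    def test_matches_exhaustive_sort_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.random((6, 3))
        Y = (rng.random((6, 2)) < 0.5).astype(int)
        Y[Y.sum(axis=1) == 0, 0] = 1
        cfg = R.SelectorConfig(k=2)
        for t in range(6):
            ctx = R.find_neighbors(t, X, Y, cfg)
            sims = [O.oracle_similarity(X[t], X[i]) for i in range(6)]
            same = [i for i in range(6) if i != t and (Y[i] == Y[t]).all()]
            expect_hit = sorted(same, key=lambda i: (-sims[i], i))[:2]
            assert [i for i, _ in ctx.hit] == expect_hit
            for c in ctx.miss:
                cand = [i for i in range(6) if i != t and Y[i, c] == 1]
                expect = sorted(cand, key=lambda i: (-sims[i], i))[:2]
                assert [i for i, _ in ctx.miss[c]] == expect


class TestFeatureDiff:
    def _fs(self, X):
        return FeatureSpace(X, [f"f{i}" for i in range(X.shape[1])], X.min(0), X.max(0))

    def test_identical_values(self):
        fs = self._fs(np.array([[0.3, 1.0], [0.3, 0.0]]))
        assert R.feature_diff(0, 0, 1, fs) == 0.0

    def test_linear_scaling(self):
        fs = self._fs(np.array([[0.0], [0.5], [1.5], [2.0]]))
        assert R.feature_diff(0, 1, 2, fs) == pytest.approx(0.5)

    def test_constant_column(self):
        fs = self._fs(np.array([[0.7], [0.7]]))
        assert R.feature_diff(0, 0, 1, fs) == 0.0


class TestUpdateWeights:
    def test_constant_feature_weight_zero(self):
        rng = np.random.default_rng(0)
        X = rng.random((6, 3))
        X[:, 1] = 0.5
        Y = (rng.random((6, 2)) < 0.5).astype(int)
        Y[Y.sum(axis=1) == 0, 0] = 1
        fw = R.update_weights(X, Y, R.SelectorConfig(k=2))
        assert fw.W[1] == 0.0

    def test_matches_oracle_on_4x2x2(self):
        rng = np.random.default_rng(1)
        X = rng.random((4, 2))
        Y = np.array([[1, 0], [1, 0], [0, 1], [1, 1]])
        fw = R.update_weights(X, Y, R.SelectorConfig(k=1))
        np.testing.assert_allclose(fw.W, O.oracle_update_weights(X, Y, k=1), atol=1e-10)

    def test_determinism(self):
        rng = np.random.default_rng(2)
        X, Y = random_selection_instance(rng)
        w1 = R.update_weights(X, Y, R.SelectorConfig(k=3)).W
        w2 = R.update_weights(X, Y, R.SelectorConfig(k=3)).W
        assert (w1 == w2).all()

    def test_permutation_covariance(self):
        rng = np.random.default_rng(3)
        X = rng.random((8, 5))
        Y = (rng.random((8, 3)) < 0.5).astype(int)
        Y[Y.sum(axis=1) == 0, 0] = 1
        perm = rng.permutation(5)
        w = R.update_weights(X, Y, R.SelectorConfig(k=2)).W
        w_perm = R.update_weights(X[:, perm], Y, R.SelectorConfig(k=2)).W
        np.testing.assert_allclose(w_perm, w[perm], atol=1e-12)

    def test_oracle_equivalence_random(self):
        rng = np.random.default_rng(4)
        for _ in range(60):
            X, Y = random_selection_instance(rng)
            k = int(rng.integers(1, 4))
            got = R.update_weights(X, Y, R.SelectorConfig(k=k)).W
            np.testing.assert_allclose(got, O.oracle_update_weights(X, Y, k=k), atol=1e-10)

    def test_informative_feature_outranks_noise(self):
        cfg = S.SynthConfig(n=500, f_informative=1, f_noise=20, m=2,
                            labels_per_record=1.0, label_correlation=0.0,
                            signal=0.7, seed=5)
        _, fs, lm, truth = S.generate(cfg)
        fw = R.update_weights(fs, lm, R.SelectorConfig(k=10))
        assert int(fw.order[0]) in truth

    def test_errors(self):
        with pytest.raises(ValueError):
            R.update_weights(np.empty((5, 0)), np.ones((5, 1), dtype=int))
        with pytest.raises(ValueError):
            R.update_weights(np.ones((1, 3)), np.ones((1, 1), dtype=int))


class TestSelect:
    def test_sorted_selection(self):
        fw = R.FeatureWeights.from_weights(np.array([0.2, 0.9, 0.1]))
        assert R.select(fw, 2) == [1, 0]

    def test_full_selection_is_permutation(self):
        fw = R.FeatureWeights.from_weights(np.array([0.2, 0.9, 0.1]))
        assert sorted(R.select(fw, 3)) == [0, 1, 2]

    def test_tie_breaks_to_lowest_index(self):
        fw = R.FeatureWeights.from_weights(np.array([0.5, 0.5]))
        assert R.select(fw, 1) == [0]

    def test_out_of_range(self):
        fw = R.FeatureWeights.from_weights(np.array([0.5, 0.5]))
        for bad in (0, 3):
            with pytest.raises(ValueError):
                R.select(fw, bad)


def test_feature_recovery_synthetic():
    """Planted informative features dominate the top of the ranking."""
    cfg = S.SynthConfig(n=500, f_informative=10, f_noise=90, m=5,
                        labels_per_record=1.5, label_correlation=0.2,
                        signal=0.45, seed=11)
    _, fs, lm, truth = S.generate(cfg)
    fw = R.update_weights(fs, lm, R.SelectorConfig(k=10))
    top10 = set(R.select(fw, 10))
    assert len(top10 & truth) >= 8


def test_weight_report(tmp_path):
    fw = R.FeatureWeights.from_weights(np.array([0.1, 0.7]))
    R.write_weight_report(fw, ["alpha", "beta"], tmp_path / "w.tsv")
    lines = (tmp_path / "w.tsv").read_text().splitlines()
    assert lines[0] == "rank\tfeature\tweight"
    assert lines[1].startswith("1\tbeta")
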