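"""PCA initialisation, batch training, BMU mapping, and lattice round trips."""

import numpy as np
import pytest

from blsomhgt.blsom import (
    InitializationError,
    Lattice,
    LatticeLoadError,
    TrainingConfig,
    bmu,
    bmus,
    load_lattice,
    pca_initialize,
    quantization_error,
    save_lattice,
    train,
)


def planar_data(rng, n=60, dim=8):
    """Data lying exactly in a 2-D affine plane of a higher-dimensional space."""
    b1 = np.zeros(dim); b1[0] = 1.0
    b2 = np.zeros(dim); b2[1] = 1.0
    mean = rng.normal(size=dim)
    return mean + rng.normal(scale=2.0, size=(n, 1)) * b1 + rng.normal(size=(n, 1)) * b2


class TestInitialization:
    def test_weights_lie_in_principal_plane(self, rng):
        X = planar_data(rng)
        lat = pca_initialize(X, I=12)
        mean = X.mean(axis=0)
        _, _, vt = np.linalg.svd(X - mean, full_matrices=False)
        basis = vt[:2]
        W = lat.flat_weights - mean
        residual = W - (W @ basis.T) @ basis
        assert np.abs(residual).max() <= 1e-8

    def test_lattice_aspect_follows_sigma_ratio(self):
        # four points whose sample principal stds are exactly (a, b)
        a, b = 2.0, 1.0
        X = np.array([[a, 0], [-a, 0], [0, b], [0, -b]], dtype=float)
        lat = pca_initialize(X, I=100)
        assert lat.J == 50  # J = round(I * sigma2/sigma1) = round(100 * 0.5)

    def test_isotropic_data_gives_square_lattice(self):
        X = np.array([[1.0, 0], [-1.0, 0], [0, 1.0], [0, -1.0]])
        lat = pca_initialize(X, I=20)
        assert lat.J == 20

    def test_initialization_is_deterministic(self, rng):
        X = rng.normal(size=(50, 6))
        w1 = pca_initialize(X, I=10).weights
        w2 = pca_initialize(X, I=10).weights
        np.testing.assert_array_equal(w1, w2)

    def test_too_few_vectors_rejected(self):
        with pytest.raises(InitializationError):
            pca_initialize(np.zeros((2, 4)), I=5)

    def test_zero_variance_rejected(self):
        with pytest.raises(InitializationError):
            pca_initialize(np.ones((10, 4)), I=5)


class TestBMU:
    def test_single_node_lattice(self):
        lat = Lattice(weights=np.zeros((1, 1, 3)))
        assert bmu(np.array([9.0, -2.0, 4.0]), lat) == (0, 0)

    def test_exact_match_wins(self, rng):
        W = rng.normal(size=(4, 5, 6))
        lat = Lattice(weights=W)
        assert bmu(W[2, 3].copy(), lat) == (2, 3)

    def test_matches_exhaustive_scan_oracle(self, rng):
        W = rng.normal(size=(5, 5, 7))
        lat = Lattice(weights=W)
        for x in rng.normal(size=(100, 7)):
            d = ((W - x) ** 2).sum(axis=2)
            oracle = np.unravel_index(np.argmin(d), d.shape)
            assert bmu(x, lat) == tuple(int(v) for v in oracle)

    def test_tie_breaks_to_smallest_i_then_j(self):
        W = np.zeros((3, 3, 2))  # all nodes equidistant from any query
        lat = Lattice(weights=W)
        assert bmu(np.array([1.0, 1.0]), lat) == (0, 0)

    def test_dimension_mismatch_rejected(self):
        lat = Lattice(weights=np.zeros((2, 2, 3)))
        with pytest.raises(ValueError):
            bmus(np.zeros((1, 4)), lat)


class TestTraining:
    def test_bitwise_determinism(self, rng):
        X = rng.normal(size=(40, 5))
        cfg = TrainingConfig(epochs=20)
        runs = [train(pca_initialize(X, I=6, config=cfg), X, cfg).weights for _ in range(2)]
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_order_independence_under_permutation(self, rng):
        X = rng.normal(size=(50, 4))
        cfg = TrainingConfig(epochs=25)
        lat0 = pca_initialize(X, I=7, config=cfg)
        w_orig = train(lat0, X, cfg).weights
        perm = rng.permutation(len(X))
        w_perm = train(lat0, X[perm], cfg).weights
        np.testing.assert_allclose(w_perm, w_orig, atol=1e-9)

    def test_single_vector_convergence(self, rng):
        x = rng.normal(size=5)
        X = np.vstack([x, x + 1e-3, x - 1e-3])  # init needs >= 3 distinct vectors
        cfg = TrainingConfig(epochs=100)
        lat = train(pca_initialize(X, I=4, config=cfg), x[None, :], cfg)
        i, j = bmu(x, lat)
        assert np.linalg.norm(lat.weights[i, j] - x) < 1e-6

    def test_two_clusters_separate_and_error_decreases(self, rng):
        c1 = rng.normal(loc=0.0, scale=0.05, size=(60, 6))
        c2 = rng.normal(loc=1.0, scale=0.05, size=(60, 6))
        X = np.vstack([c1, c2])
        cfg = TrainingConfig(epochs=60)
        init = pca_initialize(X, I=8, config=cfg)
        lat = train(init, X, cfg)
        assert quantization_error(lat, X) < quantization_error(init, X)
        nodes1 = {tuple(divmod(int(f), lat.J)) for f in bmus(c1, lat)}
        nodes2 = {tuple(divmod(int(f), lat.J)) for f in bmus(c2, lat)}
        assert nodes1.isdisjoint(nodes2)

    def test_trained_epochs_accumulate(self, rng):
        X = rng.normal(size=(20, 3))
        cfg = TrainingConfig(epochs=5)
        lat = train(pca_initialize(X, I=4, config=cfg), X, cfg)
        assert lat.trained_epochs == 5


class TestQuantizationError:
    def test_zero_when_data_equals_weights(self, rng):
        W = rng.normal(size=(3, 4, 5))
        lat = Lattice(weights=W)
        assert quantization_error(lat, W.reshape(-1, 5)) == 0.0

    def test_single_vector_distance(self):
        W = np.zeros((1, 2, 2))
        W[0, 1] = [10.0, 0.0]
        lat = Lattice(weights=W)
        assert quantization_error(lat, np.array([[3.0, 4.0]])) == pytest.approx(5.0)

    def test_matches_brute_force(self, rng):
        W = rng.normal(size=(4, 4, 3))
        lat = Lattice(weights=W)
        X = rng.normal(size=(30, 3))
        brute = np.mean(
            [np.sqrt(((W - x) ** 2).sum(axis=2)).min() for x in X]
        )
        assert quantization_error(lat, X) == pytest.approx(brute, abs=1e-12)


class TestSerialization:
    def test_round_trip_is_byte_identical(self, tmp_path, rng):
        X = rng.normal(size=(30, 4))
        lat = train(pca_initialize(X, I=5), X, TrainingConfig(epochs=5))
        p1, p2 = tmp_path / "a.txt", tmp_path / "b.txt"
        save_lattice(lat, p1)
        save_lattice(load_lattice(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_round_trip_preserves_bmus(self, tmp_path, rng):
        X = rng.normal(size=(30, 4))
        lat = train(pca_initialize(X, I=5), X, TrainingConfig(epochs=5))
        path = tmp_path / "lat.txt"
        save_lattice(lat, path)
        lat2 = load_lattice(path)
        Q = rng.normal(size=(100, 4))
        np.testing.assert_array_equal(bmus(Q, lat), bmus(Q, lat2))
        assert lat2.trained_epochs == lat.trained_epochs
        assert lat2.config == lat.config

    def test_truncated_file_errors(self, tmp_path, rng):
        X = rng.normal(size=(20, 3))
        lat = pca_initialize(X, I=4)
        path = tmp_path / "lat.txt"
        save_lattice(lat, path)
        text = path.read_text().splitlines()
        path.write_text("\n".join(text[: len(text) // 2]))
        with pytest.raises(LatticeLoadError):
            load_lattice(path)

    def test_wrong_magic_errors(self, tmp_path):
        path = tmp_path / "x.txt"
        path.write_text("not a lattice\n")
        with pytest.raises(LatticeLoadError, match="magic"):
            load_lattice(path)
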