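"""Block-model clustering, fitting, and the reference-frame transform."""

import numpy as np
import pytest

import refharm as rh
from refharm.xpn import fit_block_model

from conftest import make_matrix


def make_log2(arr, **kw):
    return make_matrix(arr, scale="log2", **kw)


def labels_agree_up_to_permutation(a, b):
    """Partition equality irrespective of label names."""
    return rh.adjusted_rand_index(a, b) == pytest.approx(1.0)


class TestClusterGenes:
    def test_single_cluster(self, rng):
        P = make_log2(rng.normal(size=(20, 4)))
        labels = rh.cluster_genes(P, P, K=1, seed=0)
        assert set(labels) == {0}

    def test_recovers_two_separated_groups(self, rng):
        truth = np.repeat([0, 1], 30)
        base = np.where(truth[:, None] == 0, -5.0, 5.0)
        P = make_log2(base + rng.normal(0, 0.1, (60, 6)))
        Q = make_log2(base + rng.normal(0, 0.1, (60, 8)), sample_ids=[f"q{i}" for i in range(8)])
        labels = rh.cluster_genes(P, Q, K=2, seed=3)
        assert labels_agree_up_to_permutation(labels, truth)

    def test_deterministic_given_seed(self, rng):
        P = make_log2(rng.normal(size=(40, 5)))
        a = rh.cluster_genes(P, P, K=4, seed=11)
        b = rh.cluster_genes(P, P, K=4, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_k_exceeding_gene_count_errors(self, rng):
        P = make_log2(rng.normal(size=(5, 3)))
        with pytest.raises(ValueError):
            rh.cluster_genes(P, P, K=6, seed=0)


class TestClusterSamplesSpherical:
    def test_single_cluster(self, rng):
        P = make_log2(rng.normal(size=(30, 3)))
        Q = make_log2(rng.normal(size=(30, 4)), sample_ids=[f"q{i}" for i in range(4)])
        labels = rh.cluster_samples_spherical(P, Q, L=1, seed=0)
        assert set(labels) == {0}

    def test_scaled_deviations_cluster_together(self, rng):
        # cosine similarity ignores the magnitude of a sample's deviation
        # from its dataset's gene means, so columns whose centered
        # profiles are positive multiples of each other co-cluster
        m = rng.normal(5, 1, 30)
        d = rng.normal(size=30)
        P = make_log2(np.column_stack([m + d, m + 2 * d, m - d, m - 2 * d]))
        Q = make_log2(
            np.column_stack([m + 3 * d, m - 3 * d]), sample_ids=["q0", "q1"]
        )
        labels = rh.cluster_samples_spherical(P, Q, L=2, seed=2)
        assert labels[0] == labels[1] == labels[4]
        assert labels[2] == labels[3] == labels[5]
        assert labels[0] != labels[2]

    def test_orthogonal_groups_recovered(self, rng):
        u = np.zeros(40)
        u[:20] = 1.0
        v = np.zeros(40)
        v[20:] = 1.0
        cols = [u, u, v, v]
        P = make_log2(np.column_stack(cols) + rng.normal(0, 0.01, (40, 4)))
        Q = make_log2(
            np.column_stack(cols) + rng.normal(0, 0.01, (40, 4)),
            sample_ids=[f"q{i}" for i in range(4)],
        )
        labels = rh.cluster_samples_spherical(P, Q, L=2, seed=5)
        assert labels_agree_up_to_permutation(labels, [0, 0, 1, 1] * 2)

    def test_every_cluster_contains_a_reference_sample(self, rng):
        P = make_log2(rng.normal(size=(25, 12)))
        Q = make_log2(rng.normal(size=(25, 3)), sample_ids=["q0", "q1", "q2"])
        labels = rh.cluster_samples_spherical(P, Q, L=5, seed=9)
        q_labels = set(labels[12:])
        assert set(labels) == q_labels

    def test_l_exceeding_sample_count_errors(self, rng):
        P = make_log2(rng.normal(size=(10, 2)))
        Q = make_log2(rng.normal(size=(10, 2)), sample_ids=["q0", "q1"])
        with pytest.raises(ValueError):
            rh.cluster_samples_spherical(P, Q, L=5, seed=0)


def synth_block_instance(rng, n_genes=60, n_samples=12, K=3, L=2, noise=0.0):
    """Data generated exactly from the block model with the constraints."""
    alpha = rng.integers(0, K, n_genes)
    beta = rng.integers(0, L, n_samples)
    A = rng.normal(5, 2, (K, L))
    b = rng.normal(1, 0.3, n_genes)
    c = rng.normal(0, 0.5, n_genes)
    for k in range(K):  # impose identifiability within each gene cluster
        sel = alpha == k
        if sel.any():
            b[sel] = b[sel] - b[sel].mean() + 1.0
            c[sel] = c[sel] - c[sel].mean()
    X = A[np.ix_(alpha, beta)] * b[:, None] + c[:, None]
    X = X + rng.normal(0, noise, X.shape)
    return X, alpha, beta, A, b, c


class TestFitBlockModel:
    def test_exact_instance_reproduced(self, rng):
        X, alpha, beta, *_ = synth_block_instance(rng)
        model = fit_block_model(X, alpha, beta)
        fitted = model.systematic(beta)
        objective = ((X - fitted) ** 2).sum()
        assert objective <= 1e-10
        np.testing.assert_allclose(fitted, X, rtol=1e-6, atol=1e-8)

    def test_k1_l1_block_mean_is_grand_mean(self, rng):
        X = rng.normal(3, 1, (30, 6))
        model = fit_block_model(X, np.zeros(30, dtype=int), np.zeros(6, dtype=int))
        # with mean(b)=1, mean(c)=0 the single block mean equals the grand mean
        fitted_mean = model.systematic(np.zeros(6, dtype=int)).mean()
        assert fitted_mean == pytest.approx(X.mean(), rel=1e-9)
        assert model.A[0, 0] == pytest.approx(X.mean(), rel=1e-6)

    def test_constant_matrix_zero_residual_scale(self):
        X = np.full((10, 5), 7.0)
        model = fit_block_model(X, np.zeros(10, dtype=int), np.zeros(5, dtype=int))
        np.testing.assert_allclose(model.sigma, 0.0, atol=1e-12)

    def test_identifiability_constraints_hold(self, rng):
        X, alpha, beta, *_ = synth_block_instance(rng, noise=0.3)
        model = fit_block_model(X, alpha, beta)
        for k in np.unique(alpha):
            sel = alpha == k
            assert model.b[sel].mean() == pytest.approx(1.0, abs=1e-8)
            assert model.c[sel].mean() == pytest.approx(0.0, abs=1e-8)

    def test_cluster_map_length_mismatch_errors(self, rng):
        with pytest.raises(ValueError):
            fit_block_model(rng.normal(size=(5, 4)), np.zeros(3), np.zeros(4))


def location_scale_oracle(XP, XQ):
    """K=L=1 limit: per-gene mapping onto the reference mean/sd structure."""
    mP, sP = XP.mean(axis=1, keepdims=True), XP.std(axis=1, keepdims=True)
    mQ, sQ = XQ.mean(axis=1, keepdims=True), XQ.std(axis=1, keepdims=True)
    z = np.where(sP > 0, (XP - mP) / np.where(sP > 0, sP, 1.0), 0.0)
    return mQ + sQ * z


class TestTransformToReference:
    def test_k1_l1_matches_location_scale_oracle(self, rng):
        XP = rng.normal(5, 2, (40, 6))
        XQ = rng.normal(7, 1, (40, 10))
        P = make_log2(XP)
        Q = make_log2(XQ, sample_ids=[f"q{i}" for i in range(10)])
        cfg = rh.HarmonizationConfig(K=1, L=1, n_repeats=1, seed=0)
        out = rh.transform_to_reference(P, Q, cfg)
        np.testing.assert_allclose(
            out.values.to_numpy(), location_scale_oracle(XP, XQ), atol=1e-8
        )

    def test_reference_never_modified(self, rng):
        P = make_log2(rng.normal(size=(30, 4)))
        Q = make_log2(rng.normal(size=(30, 8)), sample_ids=[f"q{i}" for i in range(8)])
        before = Q.values.to_numpy().copy()
        rh.transform_to_reference(P, Q, rh.HarmonizationConfig(K=3, L=2, n_repeats=2, seed=1))
        np.testing.assert_array_equal(Q.values.to_numpy(), before)

    def test_output_finite_even_with_constant_genes(self, rng):
        XP = rng.normal(size=(20, 5))
        XP[0] = 4.0  # zero residual scale in P
        P = make_log2(XP)
        Q = make_log2(rng.normal(size=(20, 6)), sample_ids=[f"q{i}" for i in range(6)])
        out = rh.transform_to_reference(P, Q, rh.HarmonizationConfig(K=2, L=2, n_repeats=2, seed=3))
        assert np.isfinite(out.values.to_numpy()).all()

    def test_repeat_averaging_of_identical_draws_is_identity(self, rng):
        # with K=1, L=1 every repeat draws the same (trivial) clustering
        XP = rng.normal(size=(25, 4))
        XQ = rng.normal(size=(25, 5))
        P = make_log2(XP)
        Q = make_log2(XQ, sample_ids=[f"q{i}" for i in range(5)])
        one = rh.transform_to_reference(P, Q, rh.HarmonizationConfig(K=1, L=1, n_repeats=1, seed=4))
        two = rh.transform_to_reference(P, Q, rh.HarmonizationConfig(K=1, L=1, n_repeats=2, seed=4))
        np.testing.assert_allclose(one.values.to_numpy(), two.values.to_numpy(), atol=1e-12)

    def test_deterministic_given_seed(self, rng):
        P = make_log2(rng.normal(size=(30, 5)))
        Q = make_log2(rng.normal(size=(30, 7)), sample_ids=[f"q{i}" for i in range(7)])
        cfg = rh.HarmonizationConfig(K=4, L=3, n_repeats=3, seed=6)
        a = rh.transform_to_reference(P, Q, cfg)
        b = rh.transform_to_reference(P, Q, cfg)
        np.testing.assert_array_equal(a.values.to_numpy(), b.values.to_numpy())

    def test_non_log2_input_rejected(self, rng):
        P = make_matrix(np.abs(rng.normal(size=(10, 3))))
        Q = make_log2(rng.normal(size=(10, 4)), sample_ids=[f"q{i}" for i in range(4)])
        with pytest.raises(ValueError, match="log2"):
            rh.transform_to_reference(P, Q, rh.HarmonizationConfig(K=1, L=1))

    def test_noise_monotonicity_of_recovery(self, rng):
        """Lower observation noise must track the reference frame better.

        P is drawn from the same block structure as Q at three noise
        levels; per-sample correlation between transformed P and its
        noise-free Q-frame counterpart improves as noise drops.  The
        improvement saturates once cluster assignments are error-free
        (the transform re-inserts each sample's standardized residual at
        the reference's residual scale, a floor independent of the input
        noise), so monotonicity is asserted weakly at the quiet end and
        strictly against the noisiest level.
        """
        n_genes, K, L = 40, 3, 2
        alpha = rng.integers(0, K, n_genes)
        A = rng.normal(6, 2, (K, L))
        truthP = A[alpha][:, rng.integers(0, L, 10)]
        XQ = A[alpha][:, rng.integers(0, L, 12)] + rng.normal(0, 0.05, (n_genes, 12))
        Q = make_log2(XQ, sample_ids=[f"q{i}" for i in range(12)])
        cors = []
        for noise in (10.0, 3.0, 0.5):
            XP = truthP + rng.normal(0, noise, truthP.shape)
            P = make_log2(XP)
            out = rh.transform_to_reference(
                P, Q, rh.HarmonizationConfig(K=K, L=L, n_repeats=3, seed=8)
            ).values.to_numpy()
            cors.append(
                np.mean(
                    [np.corrcoef(out[:, j], truthP[:, j])[0, 1] for j in range(10)]
                )
            )
        assert cors[0] + 0.01 < cors[2]
        assert cors[0] < cors[1] + 0.005
        assert cors[1] < cors[2] + 0.005

    def test_self_harmonization_preserves_profiles(self, rng):
        """P drawn from Q's own generative structure is barely changed."""
        n_genes = 100
        alpha = rng.integers(0, 4, n_genes)
        A = rng.normal(6, 2, (4, 3))
        draw = lambda n: A[alpha][:, rng.integers(0, 3, n)] + rng.normal(0, 0.3, (n_genes, n))
        XQ = draw(15)
        XP = draw(6)
        P = make_log2(XP)
        Q = make_log2(XQ, sample_ids=[f"q{i}" for i in range(15)])
        out = rh.transform_to_reference(
            P, Q, rh.HarmonizationConfig(K=4, L=3, n_repeats=5, seed=10)
        ).values.to_numpy()
        cors = [np.corrcoef(out[:, j], XP[:, j])[0, 1] for j in range(6)]
        assert min(cors) >= 0.95
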