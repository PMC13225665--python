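import numpy as np
import pytest
import scipy.sparse as sp

from mmtissue.compress import (
    CompressionConfig,
    _auto_scheme,
    build_fuzzy_set,
    compress_image,
    dimensionality_scan,
    embed,
    fuzzy_cross_entropy,
    preprocess_histology,
    project_out_of_sample,
    select_dimensionality,
    spectral_landmarks,
    subsample_pixels,
)
from mmtissue.images import MultichannelImage
from mmtissue.synthetic import make_manifold, make_multimodal_pair


class TestSubsampling:
    def test_grid_step_one_returns_all_masked_pixels(self, rng):
        img = MultichannelImage(rng.random((6, 6, 2)), ["a", "b"])
        s = subsample_pixels(img, "grid", grid_step=1)
        assert len(s.coords) == 36

    def test_grid_step_two_on_4x4(self, rng):
        img = MultichannelImage(rng.random((4, 4, 1)), ["a"])
        s = subsample_pixels(img, "grid", grid_step=2)
        got = {tuple(c) for c in s.coords}
        assert got == {(0, 0), (0, 2), (2, 0), (2, 2)}

    def test_random_fraction_count_and_bounds(self, rng):
        img = MultichannelImage(rng.random((20, 20, 1)), ["a"])
        s = subsample_pixels(img, "random", fraction=0.25, seed=1)
        assert len(s.coords) == int(np.ceil(0.25 * 400))
        assert len({tuple(c) for c in s.coords}) == len(s.coords)  # unique

    def test_pseudo_random_contains_grid(self, rng):
        img = MultichannelImage(rng.random((12, 12, 1)), ["a"])
        s = subsample_pixels(img, "pseudo-random", fraction=0.5, grid_step=3, seed=0)
        got = {tuple(c) for c in s.coords}
        for r in range(0, 12, 3):
            for c in range(0, 12, 3):
                assert (r, c) in got
        assert len(s.coords) == int(np.ceil(0.5 * 144))

    @pytest.mark.parametrize(
        "n,expected",
        [
            (30_000, ("none", {})),
            (70_000, ("pseudo-random", {"fraction": 0.55, "grid_step": 2})),
            (120_000, ("pseudo-random", {"fraction": 0.15, "grid_step": 3})),
            (200_000, ("grid", {"grid_step": 3})),
        ],
    )
    def test_auto_defaults_keyed_on_pixel_count(self, n, expected):
        assert _auto_scheme(n) == expected

    def test_mask_respected_and_empty_mask_rejected(self, rng):
        img = MultichannelImage(rng.random((8, 8, 1)), ["a"],
                                mask=np.zeros((8, 8), bool))
        with pytest.raises(ValueError):
            subsample_pixels(img, "grid", grid_step=1)
        img.mask[2:4, 2:4] = True
        s = subsample_pixels(img, "grid", grid_step=1)
        assert len(s.coords) == 4
        assert all(img.mask[r, c] for r, c in s.coords)

    def test_bad_fraction_rejected(self, rng):
        img = MultichannelImage(rng.random((8, 8, 1)), ["a"])
        with pytest.raises(ValueError):
            subsample_pixels(img, "random", fraction=1.5)


class TestFuzzySimplicialSet:
    def test_symmetric_zero_diagonal(self, rng):
        g = build_fuzzy_set(rng.standard_normal((50, 4)), 10)
        assert abs(g.edges - g.edges.T).max() < 1e-7
        assert np.all(g.edges.diagonal() == 0)

    def test_three_equidistant_points_equal_memberships(self):
        # every retained edge of the equilateral triangle has the same
        # membership (n_neighbors counts the point itself, so ties among the
        # equidistant neighbours are broken arbitrarily but symmetrically)
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        g = build_fuzzy_set(pts, 2)
        vals = sp.triu(g.edges, k=1).tocoo().data
        assert len(vals) >= 2
        assert np.allclose(vals, vals[0])

    def test_nearest_neighbor_membership_is_one(self, rng):
        # local-connectivity convention: the closest neighbour of every point
        # has membership exactly 1 in the directed graph, hence 1 after the
        # fuzzy union too
        x = rng.standard_normal((10, 3))
        g = build_fuzzy_set(x, 4)
        d = np.linalg.norm(x[:, None] - x[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        nn = d.argmin(axis=1)
        dense = g.edges.toarray()
        for i in range(10):
            assert dense[i, nn[i]] == pytest.approx(1.0, abs=1e-6)

    def test_channel_permutation_invariance(self, rng):
        x = rng.standard_normal((40, 5))
        g1 = build_fuzzy_set(x, 8)
        g2 = build_fuzzy_set(x[:, ::-1], 8)
        assert abs(g1.edges - g2.edges).max() < 1e-7

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError):
            build_fuzzy_set(np.ones((20, 3)), 5)


class TestSpectralLandmarks:
    def test_k_equal_n_gives_points_themselves(self, rng):
        x = rng.standard_normal((30, 4))
        g = build_fuzzy_set(x, 5)
        lm = spectral_landmarks(g, x, k=30)
        assert np.allclose(lm.centroids, x)

    def test_k_above_n_clamped_with_warning(self, rng):
        x = rng.standard_normal((20, 3))
        g = build_fuzzy_set(x, 5)
        with pytest.warns(UserWarning):
            lm = spectral_landmarks(g, x, k=100)
        assert lm.k == 20

    def test_two_separated_blobs_pure_assignment(self, rng):
        a = rng.standard_normal((40, 5)) * 0.1
        b = rng.standard_normal((40, 5)) * 0.1 + 50.0
        x = np.vstack([a, b])
        g = build_fuzzy_set(x, 10)
        lm = spectral_landmarks(g, x, n_svd=10, k=2, seed=0)
        first = lm.assignment[:40]
        second = lm.assignment[40:]
        assert len(set(first)) == 1 and len(set(second)) == 1
        assert first[0] != second[0]

    def test_default_parameters(self):
        import inspect

        sig = inspect.signature(spectral_landmarks)
        assert sig.parameters["n_svd"].default == 100
        assert sig.parameters["k"].default == 3000


class TestEmbedding:
    def test_same_seed_identical_coordinates(self, rng):
        g = build_fuzzy_set(rng.standard_normal((60, 5)), 10)
        m1 = embed(g, 2, seed=3, n_epochs=50)
        m2 = embed(g, 2, seed=3, n_epochs=50)
        assert np.array_equal(m1.coords, m2.coords)

    def test_separated_blobs_stay_separated(self, rng):
        blobs = [rng.standard_normal((30, 6)) * 0.2 + mu
                 for mu in (0.0, 30.0, -30.0)]
        x = np.vstack(blobs)
        g = build_fuzzy_set(x, 10)
        m = embed(g, 2, seed=0, n_epochs=200)
        cents = [m.coords[i * 30:(i + 1) * 30].mean(axis=0) for i in range(3)]
        radii = [
            np.percentile(
                np.linalg.norm(m.coords[i * 30:(i + 1) * 30] - cents[i], axis=1), 95
            )
            for i in range(3)
        ]
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.linalg.norm(cents[i] - cents[j]) > radii[i] + radii[j]


class TestFuzzyCrossEntropy:
    def test_single_edge_closed_form(self):
        # μ=0.5, ν=0.25: 0.5·ln2 + 0.5·ln(0.5/0.75) ≈ 0.14384
        from mmtissue.compress import EmbeddingModel, FuzzySimplicialSet

        edges = sp.csr_matrix(np.array([[0.0, 0.5], [0.5, 0.0]]))
        g = FuzzySimplicialSet(edges=edges, n_neighbors=1,
                               features=np.zeros((2, 1)))
        a, b = 1.0, 1.0  # ν = 1/(1+d²)
        d = np.sqrt(3.0)  # gives ν = 0.25
        model = EmbeddingModel(dim=1, coords=np.array([[0.0], [d]]),
                               low_dim_curve=(a, b), graph=g)
        expected = 0.5 * np.log(0.5 / 0.25) + 0.5 * np.log(0.5 / 0.75)
        assert fuzzy_cross_entropy(g, model) == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_over_support(self, rng):
        g = build_fuzzy_set(rng.standard_normal((20, 4)), 6)
        model = embed(g, 2, seed=0, n_epochs=50)
        a, b = model.low_dim_curve
        dense = g.edges.toarray()
        total = 0.0
        eps = 1e-8
        for i in range(20):
            for j in range(i + 1, 20):
                mu = float(dense[i, j])
                if mu <= 0:
                    continue
                mu = min(max(mu, eps), 1 - eps)
                d2 = np.sum((model.coords[i] - model.coords[j]) ** 2)
                nu = min(max(1.0 / (1.0 + a * d2**b), eps), 1 - eps)
                total += mu * np.log(mu / nu)
                total += (1 - mu) * np.log((1 - mu) / (1 - nu))
        assert fuzzy_cross_entropy(g, model) == pytest.approx(total, abs=1e-10)

    def test_mismatched_point_counts_rejected(self, rng):
        g = build_fuzzy_set(rng.standard_normal((20, 3)), 5)
        model = embed(g, 2, seed=0, n_epochs=20)
        g2 = build_fuzzy_set(rng.standard_normal((15, 3)), 5)
        with pytest.raises(ValueError):
            fuzzy_cross_entropy(g2, model)


class TestSelectDimensionality:
    def test_constant_entropies_select_first_dim(self):
        res = select_dimensionality(range(1, 8), np.full(7, 3.3))
        assert res.selected_dim == 1
        assert np.all(res.normalized == 0)

    def test_exact_exponential_parameter_recovery(self):
        dims = np.arange(1, 11)
        e = np.exp(-2.0 * dims)
        res = select_dimensionality(dims, e)
        y0, k, c = res.fit
        assert k == pytest.approx(2.0, abs=1e-3)
        assert c == pytest.approx(0.0, abs=1e-3)
        # selection is self-consistent with the stated rule: first dim whose
        # fitted value is inside the 1.96σ band around the asymptote
        model = (y0 - c) * np.exp(-k * dims) + c
        inside = dims[model <= c + 1.96 * res.residual_sd]
        assert res.selected_dim == inside[0]

    def test_too_few_dims_rejected(self):
        with pytest.raises(ValueError):
            select_dimensionality([1, 2, 3], [1.0, 0.5, 0.2])

    def test_non_finite_entropies_rejected(self):
        with pytest.raises(ValueError):
            select_dimensionality(range(1, 6), [1.0, np.nan, 0.2, 0.1, 0.1])

    def test_gaussian_blob_rank3_selects_low_dim(self):
        x = make_manifold(3, 20, 400, noise_sd=0.01, seed=11)
        g = build_fuzzy_set(x, 15)
        res = dimensionality_scan(g, range(1, 9), seed=0, n_epochs=150)
        assert res.selected_dim <= 4


class TestOutOfSampleProjection:
    def test_training_points_project_onto_themselves(self, rng):
        x = rng.standard_normal((80, 5))
        g = build_fuzzy_set(x, 10)
        model = embed(g, 2, seed=0, n_epochs=100)
        proj = project_out_of_sample(model, x)
        diam = np.linalg.norm(
            model.coords.max(axis=0) - model.coords.min(axis=0)
        )
        disp = np.linalg.norm(proj - model.coords, axis=1).mean()
        assert disp < 0.05 * diam

    def test_duplicate_of_training_point_lands_on_it(self, rng):
        x = rng.standard_normal((50, 4))
        g = build_fuzzy_set(x, 8)
        model = embed(g, 2, seed=0, n_epochs=50)
        proj = project_out_of_sample(model, x[7:8])
        assert np.allclose(proj[0], model.coords[7])

    def test_batch_equals_rowwise(self, rng):
        x = rng.standard_normal((50, 4))
        g = build_fuzzy_set(x, 8)
        model = embed(g, 2, seed=0, n_epochs=50)
        new = rng.standard_normal((5, 4))
        batch = project_out_of_sample(model, new)
        single = np.vstack([project_out_of_sample(model, row) for row in new])
        assert np.allclose(batch, single)

    def test_empty_input_rejected(self, rng):
        x = rng.standard_normal((50, 4))
        g = build_fuzzy_set(x, 8)
        model = embed(g, 1, seed=0, n_epochs=20)
        with pytest.raises(ValueError):
            project_out_of_sample(model, np.empty((0, 4)))


class TestCompressImage:
    @pytest.fixture(scope="class")
    def blob_scene(self):
        scene = make_multimodal_pair(
            shape=(40, 40), channels_a=12, channels_b=3, n_regions=3,
            seed=0, noise=0.03,
        )
        img = scene.image_a
        mask = np.ones((40, 40), bool)
        mask[:, :4] = False
        img.mask = mask
        cfg = CompressionConfig(dims=tuple(range(1, 7)), seed=0, n_epochs=150)
        compressed, scan = compress_image(img, cfg)
        return scene, img, compressed, scan

    def test_blob_regions_separate_in_compressed_channels(self, blob_scene):
        scene, img, comp, scan = blob_scene
        labels = scene.region_labels
        mask = img.mask
        within = np.mean(
            [comp.data[(labels == i) & mask].var(axis=0).mean() for i in range(3)]
        )
        means = np.array(
            [comp.data[(labels == i) & mask].mean(axis=0) for i in range(3)]
        )
        between = means.var(axis=0).mean()
        assert between > 2 * within

    def test_background_exactly_zero(self, blob_scene):
        _, img, comp, _ = blob_scene
        assert np.all(comp.data[~img.mask] == 0)
        fg = comp.data[img.mask]
        assert fg.min() == 0.0 and fg.max() == 1.0

    def test_rerun_same_seed_identical(self, blob_scene):
        _, img, comp, _ = blob_scene
        cfg = CompressionConfig(dims=tuple(range(1, 7)), seed=0, n_epochs=150)
        comp2, _ = compress_image(img, cfg)
        assert np.array_equal(comp.data, comp2.data)


class TestHistologyPreprocessing:
    def test_denoise_then_otsu_recovers_clean_mask(self, rng):
        clean = np.zeros((64, 64))
        clean[16:48, 16:48] = 1.0
        noisy = clean.copy()
        u = rng.random((64, 64))
        noisy[u < 0.05] = 1.0
        noisy[u > 0.95] = 0.0
        img = MultichannelImage(
            np.repeat(noisy[:, :, None], 3, axis=2) * 255, ["R", "G", "B"]
        )
        _, mask = preprocess_histology(img, ["median(2)", "otsu"])
        assert (mask == (clean > 0.5)).mean() >= 0.99

    def test_open_close_idempotent_on_clean_disc(self):
        # disc structuring element: a clean disc much larger than the radius
        # passes opening and closing unchanged (sharp corners would not)
        rr, cc = np.meshgrid(np.arange(32), np.arange(32), indexing="ij")
        clean = np.hypot(rr - 16, cc - 16) <= 10
        img = MultichannelImage(np.zeros((32, 32, 1)), ["g"], mask=clean)
        _, mask = preprocess_histology(img, ["open(2)", "close(2)"])
        assert np.array_equal(mask, clean)

    def test_fill_turns_ring_into_disc(self):
        rr, cc = np.meshgrid(np.arange(33), np.arange(33), indexing="ij")
        r = np.hypot(rr - 16, cc - 16)
        ring = (r > 5) & (r < 10)
        img = MultichannelImage(np.zeros((33, 33, 1)), ["g"], mask=ring)
        _, mask = preprocess_histology(img, ["fill"])
        assert mask[16, 16]
        assert np.array_equal(mask, r < 10)

    def test_otsu_on_constant_image_rejected(self):
        img = MultichannelImage(np.full((16, 16, 1), 7.0), ["g"])
        with pytest.raises(ValueError):
            preprocess_histology(img, ["otsu"])
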