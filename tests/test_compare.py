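"""Latent-space embedding, densities, overlap integral, and helical order."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

import idpreweight as ir
from idpreweight.compare import DensityGrid, _ideal_helix, merged_extent


class TestDissimilarityMatrix:
    def test_symmetric_zero_diagonal(self, rng):
        coords = rng.normal(size=(6, 5, 3)) * 5
        D = ir.dissimilarity_matrix(coords)
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(np.diag(D), 0.0, atol=1e-12)
        assert np.all(D >= 0)

    def test_duplicated_frame_has_zero_distance(self, rng):
        base = rng.normal(size=(4, 5, 3)) * 5
        coords = np.concatenate([base, base[:1]])
        D = ir.dissimilarity_matrix(coords)
        assert D[0, 4] == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        coords = rng.normal(size=(5, 6, 3)) * 4
        D = ir.dissimilarity_matrix(coords)
        moved = coords.copy()
        R = Rotation.random(random_state=1).as_matrix()
        moved[2] = moved[2] @ R.T + 7.0
        np.testing.assert_allclose(ir.dissimilarity_matrix(moved), D, atol=1e-10)

    def test_hand_computed_toy(self):
        # 2 frames, 3 residues: verify against the documented formula directly
        sigma0, eps = 1.0, 0.15
        f1 = np.array([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]], dtype=float)
        f2 = np.array([[0, 0, 0], [3.8, 0, 0], [3.8, 3.8, 0]], dtype=float)
        coords = np.stack([f1, f2])
        d_all = np.concatenate([pdist(f1), pdist(f2)])
        d0 = eps * d_all.max()
        q1 = 1 / (1 + np.exp((pdist(f1) - d0) / sigma0))
        q2 = 1 / (1 + np.exp((pdist(f2) - d0) / sigma0))
        expected = np.abs(q1 - q2).mean()
        D = ir.dissimilarity_matrix(coords, sigma0=sigma0, epsilon=eps)
        assert D[0, 1] == pytest.approx(expected, rel=1e-12)


class TestEmbed2d:
    def test_planar_data_recovered_exactly(self, rng):
        # points on a noiseless 2D plane in 10D: pairwise distances preserved
        basis, _ = np.linalg.qr(rng.normal(size=(10, 2)))
        plane_pts = rng.normal(size=(40, 2)) * [3, 1]
        X = plane_pts @ basis.T
        emb = ir.embed_2d(X, method="pca")
        np.testing.assert_allclose(pdist(emb.points), pdist(plane_pts), atol=1e-8)

    def test_component_variance_ordering(self, rng):
        X = rng.normal(size=(100, 5)) * [5, 3, 1, 0.5, 0.1]
        emb = ir.embed_2d(X, method="pca")
        assert emb.points[:, 0].var() >= emb.points[:, 1].var()

    def test_mds_on_euclidean_dissimilarity(self, rng):
        pts = rng.normal(size=(25, 2))
        D = squareform(pdist(pts))
        emb = ir.embed_2d(D, method="elvim_like")
        np.testing.assert_allclose(pdist(emb.points), pdist(pts), atol=1e-8)

    def test_identical_frames_warn_zero_spread(self):
        X = np.ones((5, 4))
        with pytest.warns(UserWarning):
            emb = ir.embed_2d(X, method="pca")
        assert np.allclose(emb.points, 0)

    def test_deterministic(self, rng):
        X = rng.normal(size=(30, 6))
        p1 = ir.embed_2d(X, method="pca").points
        p2 = ir.embed_2d(X, method="pca").points
        np.testing.assert_array_equal(p1, p2)


class TestKdeOnGrid:
    def test_unimodal_mode_at_cluster(self, rng):
        pts = rng.normal(size=(500, 2)) * 0.1 + [2.0, -1.0]
        d = ir.kde_on_grid(pts, pad_bandwidths=3.0)
        i, j = np.unravel_index(np.argmax(d.values), d.values.shape)
        assert d.grid_x1[i] == pytest.approx(2.0, abs=0.1)
        assert d.grid_x2[j] == pytest.approx(-1.0, abs=0.1)

    def test_mass_near_unity_on_padded_grid(self, rng):
        pts = rng.normal(size=(400, 2))
        d = ir.kde_on_grid(pts, grid_size=120, pad_bandwidths=4.0)
        dx = np.diff(d.grid_x1).mean()
        dy = np.diff(d.grid_x2).mean()
        mass = d.values.sum() * dx * dy
        assert 0.98 <= mass <= 1.005

    def test_weighted_scott_bandwidth(self, rng):
        # bandwidth = neff^(-1/6) * weighted per-dimension spread, neff = K*N
        pts = rng.normal(size=(300, 2)) * [2.0, 0.5]
        w = ir.normalize_weights(rng.random(300))
        d = ir.kde_on_grid(pts, weights=w)
        neff = ir.kish_ratio(w) * 300
        mean = w @ pts
        cov = (pts - mean).T * w @ (pts - mean) / (1 - w @ w)
        expected = neff ** (-1 / 6) * np.sqrt(np.diag(cov))
        np.testing.assert_allclose(d.bandwidths, expected, rtol=1e-6)

    def test_zero_weights_rejected(self, rng):
        with pytest.raises(ValueError):
            ir.kde_on_grid(rng.normal(size=(10, 2)), weights=np.zeros(10))


class TestHistogramDensity:
    def test_single_cell_mass_one(self):
        pts = np.full((20, 2), 0.5)
        d = ir.histogram_density(pts, extent=((0, 1), (0, 1)))
        assert d.values.sum() == pytest.approx(1.0)
        assert np.count_nonzero(d.values) == 1

    def test_counting_oracle_shared_edges(self, rng):
        pts1 = rng.uniform(0, 10, size=(200, 2))
        pts2 = rng.uniform(2, 12, size=(150, 2))
        extent = merged_extent(np.vstack([pts1, pts2]))
        d1 = ir.histogram_density(pts1, bins=15, extent=extent)
        H, _, _ = np.histogram2d(
            pts1[:, 0], pts1[:, 1], bins=15, range=list(extent)
        )
        np.testing.assert_allclose(d1.values, H / H.sum())

    def test_total_mass_exactly_one(self, rng):
        pts = rng.normal(size=(99, 2))
        d = ir.histogram_density(pts, weights=rng.random(99))
        assert d.values.sum() == pytest.approx(1.0, abs=1e-12)


class TestOverlapIntegral:
    def test_self_overlap_is_one(self, rng):
        d = ir.kde_on_grid(rng.normal(size=(100, 2)))
        assert ir.overlap_integral(d, d) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_histograms_zero(self):
        extent = ((0.0, 10.0), (0.0, 10.0))
        a = ir.histogram_density(np.full((30, 2), 1.0), bins=60, extent=extent)
        b = ir.histogram_density(np.full((30, 2), 9.0), bins=60, extent=extent)
        assert ir.overlap_integral(a, b) == 0.0

    def test_gaussian_pair_closed_form(self):
        # unit-variance 2D Gaussians centered mu=2 apart: S = exp(-mu^2/4)
        g = np.linspace(-7.0, 9.0, 400)
        X, Y = np.meshgrid(g, g, indexing="ij")
        d1 = np.exp(-(X**2 + Y**2) / 2) / (2 * np.pi)
        d2 = np.exp(-(((X - 2.0) ** 2) + Y**2) / 2) / (2 * np.pi)
        D1 = DensityGrid(g, g, d1, kind="kde")
        D2 = DensityGrid(g, g, d2, kind="kde")
        assert ir.overlap_integral(D1, D2) == pytest.approx(np.exp(-1.0), abs=1e-3)

    def test_scale_invariance_and_symmetry(self, rng):
        pts1 = rng.normal(size=(80, 2))
        pts2 = rng.normal(size=(80, 2)) + 1.0
        extent = merged_extent(np.vstack([pts1, pts2]))
        a = ir.kde_on_grid(pts1, extent=extent)
        b = ir.kde_on_grid(pts2, extent=extent)
        s = ir.overlap_integral(a, b)
        assert 0 <= s <= 1
        assert ir.overlap_integral(b, a) == pytest.approx(s)
        scaled = DensityGrid(b.grid_x1, b.grid_x2, b.values * 37.0, kind="kde")
        assert ir.overlap_integral(a, scaled) == pytest.approx(s, rel=1e-12)

    def test_grid_mismatch_rejected(self, rng):
        a = ir.kde_on_grid(rng.normal(size=(50, 2)), grid_size=40)
        b = ir.kde_on_grid(rng.normal(size=(50, 2)) + 5, grid_size=40)
        with pytest.raises(ValueError):
            ir.overlap_integral(a, b)


class TestSquaredOverlapKishLimit:
    def test_s2_approaches_kish_with_fine_bins(self):
        # reweighted ensemble vs its uniform parent on the same frames:
        # histogram S^2 decreases monotonically to K as bins grow
        rng = np.random.default_rng(99)  # dedicated stream: tight tolerance
        n = 400
        pts = rng.normal(size=(n, 2))
        w = ir.normalize_weights(rng.random(n) ** 3)
        K = ir.kish_ratio(w)
        uniform = np.full(n, 1.0 / n)
        extent = merged_extent(pts)
        s2 = []
        for bins in (10, 32, 100):  # 1e2, ~1e3, 1e4 cells
            a = ir.histogram_density(pts, weights=w, bins=bins, extent=extent)
            b = ir.histogram_density(pts, weights=uniform, bins=bins, extent=extent)
            s2.append(ir.overlap_integral(a, b) ** 2)
        assert s2[0] >= s2[1] >= s2[2] >= K - 1e-9
        assert s2[2] == pytest.approx(K, rel=0.05)

    def test_coarse_bin_caveat_independent_samples(self, rng):
        # independent same-distribution samples: S decays toward zero once
        # bins far exceed the sample size
        pts1 = rng.normal(size=(200, 2))
        pts2 = rng.normal(size=(200, 2))
        extent = merged_extent(np.vstack([pts1, pts2]))
        s = []
        for bins in (5, 20, 80, 320):
            a = ir.histogram_density(pts1, bins=bins, extent=extent)
            b = ir.histogram_density(pts2, bins=bins, extent=extent)
            s.append(ir.overlap_integral(a, b))
        assert all(x >= y for x, y in zip(s, s[1:]))
        assert s[-1] < 0.1


class TestSAlpha:
    def test_ideal_helix_counts_windows(self):
        helix = _ideal_helix(20, 2.3, 1.5, 100.0)
        val = ir.s_alpha(helix)
        assert val == pytest.approx(20 - 6 + 1, rel=0.05)

    def test_extended_chain_near_zero(self):
        chain = np.column_stack(
            [np.arange(20) * 3.8, np.zeros(20), np.zeros(20)]
        )
        assert ir.s_alpha(chain) < 0.5

    def test_monotone_in_helical_fraction(self):
        helix = _ideal_helix(24, 2.3, 1.5, 100.0)
        extended = np.column_stack(
            [np.arange(24) * 3.8, np.zeros(24), np.zeros(24)]
        )
        values = []
        for n_hel in (0, 8, 16, 24):
            chain = extended.copy()
            if n_hel:
                seg = helix[:n_hel] - helix[:n_hel].mean(axis=0)
                chain[:n_hel] = seg + chain[:n_hel].mean(axis=0)
            values.append(ir.s_alpha(chain))
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_too_few_residues(self):
        with pytest.raises(ValueError):
            ir.s_alpha(np.zeros((5, 3)))


class TestCompareEnsembles:
    def test_identical_weight_vectors_full_overlap(self, rng):
        pts = rng.normal(size=(150, 2))
        emb = ir.embed_2d(pts, method="external")
        n = 150
        uniform = np.full(n, 1.0 / n)
        S = ir.compare_ensembles([uniform, uniform.copy()], emb, as_percent=True)
        assert S[0, 0] == pytest.approx(100.0)
        assert S[0, 1] == pytest.approx(100.0, abs=1e-6)

    def test_disjoint_mixture_modes_tiny_overlap(self, rng):
        # two ensembles living on far-apart mixture modes of one embedding
        pts = np.vstack(
            [rng.normal(size=(100, 2)), rng.normal(size=(100, 2)) + 40.0]
        )
        emb = ir.embed_2d(pts, method="external")
        w1 = np.r_[np.full(100, 0.01), np.zeros(100)]
        w2 = np.r_[np.zeros(100), np.full(100, 0.01)]
        S = ir.compare_ensembles([w1, w2], emb, as_percent=True)
        assert S[0, 1] < 2.0
        np.testing.assert_allclose(S, S.T)

    def test_histogram_kind_and_length_check(self, rng):
        pts = rng.normal(size=(50, 2))
        emb = ir.embed_2d(pts, method="external")
        w = np.full(50, 1 / 50)
        S = ir.compare_ensembles([w, w], emb, kind="histogram")
        assert S[0, 1] == pytest.approx(1.0)
        with pytest.raises(ValueError):
            ir.compare_ensembles([np.full(49, 1 / 49)], emb)


class TestDownsampleStride:
    def test_published_bookkeeping(self):
        # three 29,976-frame ensembles, stride-2 thinning, concatenation
        ensembles = [np.arange(29_976) for _ in range(3)]
        thinned = [ir.downsample_stride(e, 2) for e in ensembles]
        assert all(t.size == 14_988 for t in thinned)
        merged = np.concatenate(thinned)
        assert merged.size == 44_964

    def test_keeps_every_other_frame(self):
        x = np.arange(10)
        np.testing.assert_array_equal(ir.downsample_stride(x, 2), [0, 2, 4, 6, 8])
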