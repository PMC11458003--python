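"""Laplacians, eigensegments, Fiedler Fg-Bg cuts, and instance clustering."""

import numpy as np
import pytest

from specseg import (
    DegenerateSpectrumError,
    FeatureMap,
    LabelMap,
    build_affinity,
    eigensegments,
    fgbg_segment,
    fg_fscore,
    instance_segment,
    laplacian,
    median_post,
    orientation_fix,
)

def _block_affinity(sizes, rng, coupling=0.0):
    """Block-diagonal affinity with strong in-block weights."""
    n = sum(sizes)
    w = np.full((n, n), coupling)
    start = 0
    for s in sizes:
        w[start : start + s, start : start + s] = 1.0 + rng.uniform(
            0, 0.1, (s, s)
        )
        start += s
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 1.0)
    return w


class TestLaplacian:
    def test_two_by_two_ones(self):
        lap = laplacian(np.ones((2, 2)), "unnormalized")
        np.testing.assert_allclose(lap, [[1.0, -1.0], [-1.0, 1.0]])

    def test_rows_sum_to_zero(self, rng):
        w = rng.uniform(0, 1, (12, 12))
        w = 0.5 * (w + w.T)
        lap = laplacian(w, "unnormalized")
        np.testing.assert_allclose(lap.sum(axis=1), 0.0, atol=1e-9)

    def test_block_diagonal_null_space_dimension(self, rng):
        w = _block_affinity([4, 5], rng)
        vals = np.linalg.eigvalsh(laplacian(w, "unnormalized"))
        assert np.sum(vals < 1e-8) == 2

    def test_positive_semidefinite(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 20))
            w = rng.uniform(0, 2, (n, n))
            w = 0.5 * (w + w.T)
            for kind in ("unnormalized", "normalized_sym"):
                vals = np.linalg.eigvalsh(laplacian(w, kind))
                assert vals.min() >= -1e-9

    def test_zero_degree_vertex_guarded(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        lap = laplacian(w, "normalized_sym")
        assert np.all(np.isfinite(lap))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="symmetric"):
            laplacian(np.array([[0.0, 1.0], [0.5, 0.0]]))
        with pytest.raises(ValueError, match="nonnegative"):
            laplacian(np.array([[0.0, -1.0], [-1.0, 0.0]]))


class TestEigensegments:
    def test_path_graph_spectrum(self):
        # P3 with unit weights: Laplacian eigenvalues {0, 1, 3}
        w = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
        spec = eigensegments(laplacian(w, "unnormalized"), 3)
        np.testing.assert_allclose(spec.eigenvalues, [0.0, 1.0, 3.0], atol=1e-9)

    def test_matches_dense_brute_force(self, rng):
        # independent oracle: full numpy eigendecomposition
        for _ in range(8):
            n = int(rng.integers(5, 50))
            w = rng.uniform(0, 1, (n, n))
            w = 0.5 * (w + w.T)
            lap = laplacian(w, "normalized_sym")
            spec = eigensegments(lap, min(6, n))
            ref_vals = np.linalg.eigvalsh(lap)
            np.testing.assert_allclose(
                spec.eigenvalues, ref_vals[: spec.n_vectors], atol=1e-8
            )
            # eigenvectors orthonormal and satisfying the eigen equation
            v = spec.eigenvectors
            np.testing.assert_allclose(v.T @ v, np.eye(v.shape[1]), atol=1e-6)
            np.testing.assert_allclose(
                lap @ v, v * spec.eigenvalues[None, :], atol=1e-7
            )

    def test_disconnected_blocks_sign_split(self, rng):
        # tiny coupling avoids the exact two-fold eigenvalue degeneracy of a
        # fully disconnected graph, where the null-space basis is arbitrary
        w = _block_affinity([6, 4], rng, coupling=1e-6)
        spec = eigensegments(laplacian(w, "unnormalized"), 2)
        y1 = spec.fiedler()
        assert np.all(y1[:6] * y1[6:].mean() < 0)  # opposite signs per block
        assert np.ptp(y1[:6]) < 1e-6 and np.ptp(y1[6:]) < 1e-6

    def test_sign_fixing_deterministic(self, rng):
        w = rng.uniform(0, 1, (15, 15))
        w = 0.5 * (w + w.T)
        lap = laplacian(w)
        a = eigensegments(lap, 4)
        b = eigensegments(lap.copy(), 4)
        np.testing.assert_array_equal(a.eigenvectors, b.eigenvectors)
        for i in range(4):
            v = a.eigenvectors[:, i]
            assert v[np.argmax(np.abs(v))] >= 0

    def test_single_vector(self, rng):
        w = rng.uniform(0, 1, (5, 5))
        w = 0.5 * (w + w.T)
        spec = eigensegments(laplacian(w), 1)
        assert spec.n_vectors == 1
        with pytest.raises(ValueError, match="fewer than 2"):
            spec.fiedler()


class TestFgbgSegment:
    def test_recovers_synthetic_foreground(self, small_scene):
        from specseg.channel_selection import ncr_select

        stab, _ = ncr_select(small_scene["features"], 30)
        mask = fgbg_segment(stab, postprocess=False)
        rep = fg_fscore(mask, small_scene["fg"])
        assert rep.f_score >= 0.95

    def test_two_orthogonal_regions_split_exactly(self):
        # two regions with nearly orthogonal features: affinity is block
        # structure, the Fiedler sign split must equal the regions (a tiny
        # shared component avoids exact spectral degeneracy)
        values = np.full((2, 4, 2), 0.01)
        values[:, :2, 0] = 1.0
        values[:, 2:, 1] = 1.0
        mask = fgbg_segment(FeatureMap(values), postprocess=False)
        left = mask.labels[:, :2]
        right = mask.labels[:, 2:]
        assert np.ptp(left) == 0 and np.ptp(right) == 0
        assert left[0, 0] != right[0, 0]

    def test_constant_features_degenerate(self):
        with pytest.raises(DegenerateSpectrumError):
            fgbg_segment(FeatureMap(np.ones((4, 4, 3))))


class TestOrientationFix:
    def test_border_majority_swapped(self):
        lab = np.ones((5, 5), dtype=int)
        lab[2, 2] = 0
        fixed = orientation_fix(LabelMap(lab, semantics="fg_bg"))
        assert fixed.labels[0, 0] == 0 and fixed.labels[2, 2] == 1

    def test_centered_blob_unchanged(self):
        lab = np.zeros((5, 5), dtype=int)
        lab[2, 2] = 1
        fixed = orientation_fix(LabelMap(lab, semantics="fg_bg"))
        np.testing.assert_array_equal(fixed.labels, lab)

    def test_exact_half_border_tie_keeps_input(self):
        lab = np.zeros((4, 4), dtype=int)
        lab[:2, :] = 1  # 6 of 12 border pixels foreground
        mask = LabelMap(lab, semantics="fg_bg")
        border = np.concatenate([lab[0], lab[-1], lab[1:-1, 0], lab[1:-1, -1]])
        assert border.sum() * 2 == border.size
        np.testing.assert_array_equal(orientation_fix(mask).labels, lab)


class TestMedianPost:
    def test_solid_rectangle_unchanged(self):
        lab = np.zeros((12, 12), dtype=int)
        lab[2:10, 2:10] = 1
        out = median_post(LabelMap(lab, semantics="fg_bg"), k=5)
        assert np.array_equal(out.labels[3:9, 3:9], lab[3:9, 3:9])

    def test_isolated_pixel_removed(self):
        lab = np.zeros((9, 9), dtype=int)
        lab[4, 4] = 1
        out = median_post(LabelMap(lab, semantics="fg_bg"), k=5)
        assert out.labels.sum() == 0

    def test_all_foreground_unchanged(self):
        lab = np.ones((7, 7), dtype=int)
        out = median_post(LabelMap(lab, semantics="fg_bg"), k=5)
        np.testing.assert_array_equal(out.labels, lab)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            median_post(LabelMap(np.zeros((4, 4), dtype=int), semantics="fg_bg"), k=4)


class TestInstanceSegment:
    def test_k_one_labels_all_foreground(self, small_scene):
        fmap, fg = small_scene["features"], small_scene["fg"]
        mask = instance_segment(fmap, fg, k_instances=1)
        np.testing.assert_array_equal(mask.labels, fg.labels)

    def test_synthetic_scene_recovered(self, small_scene):
        from specseg import hungarian_miou
        from specseg.channel_selection import dcr_select, ncr_select

        stab, _ = ncr_select(small_scene["features"], 30)
        fin, _ = dcr_select(stab, 20)
        mask = instance_segment(fin, small_scene["fg"], metric="boc", k_instances=3)
        rep = hungarian_miou(mask, small_scene["gt"])
        assert rep.miou >= 0.9

    @pytest.mark.parametrize("n_blocks", [2, 3, 5])
    def test_block_affinity_recovered_exactly(self, n_blocks, rng):
        # construct features whose BoC affinity is (near) block structure:
        # identical tokens within a block, disjoint supports across blocks
        sizes = rng.integers(2, 5, size=n_blocks)
        h, w = 1, int(sizes.sum()) + 2
        values = np.zeros((h, w, n_blocks))
        gt = np.zeros((h, w), dtype=int)
        col = 0
        for b, s in enumerate(sizes):
            # disjoint supports at sub-unit level: cross-block Chebyshev
            # distance stays below the Bray-Curtis ratio, so BoC is block
            values[0, col : col + s, b] = 0.4 + 0.05 * b
            gt[0, col : col + s] = b + 1
            col += s
        # tiny jitter: exactly identical tokens make the trailing
        # eigensegments an arbitrary basis of a degenerate eigenspace
        values += rng.normal(0, 1e-3, values.shape)
        fmap = FeatureMap(values)
        fg = LabelMap((gt > 0).astype(int), semantics="fg_bg")
        # textbook spectral clustering: k blocks need the k-1 nontrivial
        # eigenvectors; trailing eigensegments of a tiny graph are noise
        mask = instance_segment(
            fmap, fg, metric="boc", k_instances=n_blocks,
            n_eigensegments=max(1, n_blocks - 1),
        )
        # exact recovery up to label permutation
        from specseg import hungarian_miou

        assert hungarian_miou(mask, LabelMap(gt)).miou == pytest.approx(1.0)

    def test_auto_k_matches_block_count(self, rng):
        sizes = [5, 4, 6]
        h, w = 1, sum(sizes) + 2
        values = np.zeros((h, w, 3))
        gt = np.zeros((h, w), dtype=int)
        col = 0
        for b, s in enumerate(sizes):
            values[0, col : col + s, b] = 0.5
            gt[0, col : col + s] = b + 1
            col += s
        values += rng.normal(0, 1e-3, values.shape)
        fmap = FeatureMap(values)
        fg = LabelMap((gt > 0).astype(int), semantics="fg_bg")
        mask = instance_segment(
            fmap, fg, metric="boc", k_instances="auto", n_eigensegments=2
        )
        assert mask.instance_labels().size == 3
        from specseg import hungarian_miou

        assert hungarian_miou(mask, LabelMap(gt)).miou == pytest.approx(1.0)

    def test_permutation_equivariance(self, rng):
        # permuting grid columns permutes output labels identically
        from specseg import hungarian_miou

        values = np.zeros((1, 9, 2))
        values[0, :4, 0] = 0.5
        values[0, 4:8, 1] = 0.5
        values += np.random.default_rng(0).normal(0, 1e-3, values.shape)
        gt = np.array([[1, 1, 1, 1, 2, 2, 2, 2, 0]])
        fg = LabelMap((gt > 0).astype(int), semantics="fg_bg")
        base = instance_segment(
            FeatureMap(values), fg, k_instances=2, n_eigensegments=1
        )
        perm = rng.permutation(9)
        pvalues = values[:, perm, :]
        pgt = gt[:, perm]
        pfg = LabelMap((pgt > 0).astype(int), semantics="fg_bg")
        permuted = instance_segment(
            FeatureMap(pvalues), pfg, k_instances=2, n_eigensegments=1
        )
        assert (
            hungarian_miou(
                permuted, LabelMap(base.labels[:, perm], semantics="instance")
            ).miou
            == 1.0
        )

    def test_foreground_smaller_than_k(self, small_scene):
        fmap = small_scene["features"]
        fg = LabelMap(np.zeros((12, 16), dtype=int), semantics="fg_bg")
        fg.labels[0, :2] = 1
        with pytest.raises(ValueError, match="fewer than k"):
            instance_segment(fmap, fg, k_instances=5)

    def test_deterministic_repeat(self, small_scene):
        from specseg.channel_selection import dcr_select, ncr_select

        stab, _ = ncr_select(small_scene["features"], 30)
        fin, _ = dcr_select(stab, 20)
        a = instance_segment(fin, small_scene["fg"], k_instances=3, seed=1)
        b = instance_segment(fin, small_scene["fg"], k_instances=3, seed=1)
        np.testing.assert_array_equal(a.labels, b.labels)
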