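import numpy as np
import pytest

from salamorph.morphometrics import (
    ConsensusFrame,
    LandmarkConfiguration,
    align_pair,
    build_mask,
    build_pixel_matrix,
    centroid_size,
    gpa_consensus,
    tps_evaluate,
    tps_fit,
    warp_to_consensus,
)
from salamorph.synthetic import HEAD_TEMPLATE, PatchGeometry, render_v_patch

RNG = np.random.default_rng(42)


def rand_config(n=33, rng=RNG):
    return rng.normal(size=(n, 2)) * 3.0


def rotation(angle):
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s], [s, c]])


class TestCentroidSize:
    def test_square_closed_form(self):
        sq = np.array([[0, 0], [2, 0], [2, 2], [0, 2]], dtype=float)
        assert centroid_size(sq) == pytest.approx(2 * np.sqrt(2), abs=1e-12)

    @pytest.mark.parametrize("s", [0.1, 1.0, 7.5])
    def test_homogeneity(self, s):
        pts = rand_config()
        assert centroid_size(s * pts) == pytest.approx(s * centroid_size(pts), rel=1e-12)

    def test_brute_force_oracle(self):
        pts = rand_config()
        cent = pts.mean(axis=0)
        brute = np.sqrt(sum((p - cent) @ (p - cent) for p in pts))
        assert centroid_size(pts) == pytest.approx(brute, abs=1e-12)

    def test_degenerate(self):
        with pytest.raises(ValueError):
            centroid_size(np.ones((5, 2)))


class TestAlignPair:
    def test_exact_recovery_of_rotation(self):
        pts = rand_config()
        target = pts @ rotation(np.pi / 2).T + np.array([5.0, -3.0])
        res = align_pair(pts, target)
        assert res.distance <= 1e-9
        assert abs(res.angle) == pytest.approx(np.pi / 2, abs=1e-9)

    def test_reflection_disallowed(self):
        pts = rand_config()
        reflected = pts * np.array([-1.0, 1.0])
        assert align_pair(pts, reflected).distance > 1e-3

    def test_rotation_grid_oracle(self):
        """Exhaustive search over 3600 rotation angles (with optimal scale per
        angle) cannot beat the SVD solution by more than 1e-6."""
        moving, target = rand_config(12), rand_config(12)
        res = align_pair(moving, target)
        x = moving - moving.mean(0)
        x /= centroid_size(x)
        y = target - target.mean(0)
        y /= centroid_size(y)
        best = np.inf
        for ang in np.linspace(0, 2 * np.pi, 3600, endpoint=False):
            xr = x @ rotation(ang).T
            beta = (xr * y).sum()  # optimal scale at this angle (||xr|| = 1)
            best = min(best, np.linalg.norm(beta * xr - y))
        assert res.distance == pytest.approx(best, abs=1e-6)
        assert res.distance <= best + 1e-9


class TestGpa:
    def test_zero_variance_sample(self):
        """Copies of one shape under random similarity transforms align exactly."""
        rng = np.random.default_rng(1)
        base = HEAD_TEMPLATE
        configs = []
        for i in range(6):
            ang = rng.uniform(-np.pi, np.pi)
            s = rng.uniform(0.5, 2.0)
            t = rng.uniform(-10, 10, 2)
            configs.append(LandmarkConfiguration(points=s * base @ rotation(ang).T + t, id=str(i)))
        cons = gpa_consensus(configs)
        assert np.all(cons.procrustes_distances <= 1e-8)
        assert align_pair(cons.mean, base).distance <= 1e-7

    def test_mean_invariants(self, default_head):
        _, _, _, cons = default_head
        assert np.linalg.norm(cons.mean.mean(axis=0)) <= 1e-9
        assert centroid_size(cons.mean) == pytest.approx(1.0, abs=1e-9)

    def test_idempotence(self):
        rng = np.random.default_rng(2)
        configs = [
            LandmarkConfiguration(points=HEAD_TEMPLATE + rng.normal(0, 0.05, HEAD_TEMPLATE.shape), id=str(i))
            for i in range(8)
        ]
        cons = gpa_consensus(configs)
        rerun = gpa_consensus([LandmarkConfiguration(points=a, id=str(i)) for i, a in enumerate(cons.aligned)])
        assert align_pair(rerun.mean, cons.mean).distance <= 1e-7

    def test_consensus_beats_specimen_anchors(self):
        """Sum of squared distances to the GPA mean is no worse than aligning
        everyone to any single specimen."""
        rng = np.random.default_rng(3)
        shapes = [HEAD_TEMPLATE[:8] + rng.normal(0, 0.2, (8, 2)) for _ in range(3)]
        configs = [LandmarkConfiguration(points=s, id=str(i)) for i, s in enumerate(shapes)]
        cons = gpa_consensus(configs)
        ss_consensus = float(np.sum(cons.procrustes_distances**2))
        for anchor in shapes:
            a = anchor - anchor.mean(0)
            a /= centroid_size(a)
            ss_anchor = sum(align_pair(s, a).distance ** 2 for s in shapes)
            assert ss_consensus <= ss_anchor + 1e-8

    def test_invariance_to_input_similarity_transforms(self):
        rng = np.random.default_rng(4)
        shapes = [HEAD_TEMPLATE + rng.normal(0, 0.03, HEAD_TEMPLATE.shape) for _ in range(5)]
        d0 = gpa_consensus([LandmarkConfiguration(points=s, id=str(i)) for i, s in enumerate(shapes)]).procrustes_distances
        moved = [
            s @ rotation(rng.uniform(-np.pi, np.pi)).T * rng.uniform(0.5, 2.0) + rng.uniform(-5, 5, 2)
            for s in shapes
        ]
        d1 = gpa_consensus([LandmarkConfiguration(points=s, id=str(i)) for i, s in enumerate(moved)]).procrustes_distances
        np.testing.assert_allclose(d0, d1, atol=1e-8)


class TestTps:
    def test_identity(self):
        src = rand_config(10)
        m = tps_fit(src, src)
        assert m.bending_energy <= 1e-9
        np.testing.assert_allclose(m.weights, 0, atol=1e-9)
        np.testing.assert_allclose(m.affine, [[0, 0], [1, 0], [0, 1]], atol=1e-9)

    def test_affine_null_space(self):
        src = rand_config(10)
        A = np.array([[1.2, 0.3], [-0.1, 0.8]])
        tgt = src @ A.T + np.array([2.0, -1.0])
        m = tps_fit(src, tgt)
        assert m.bending_energy <= 1e-9

    def test_side_conditions(self):
        src, tgt = rand_config(15), rand_config(15)
        m = tps_fit(src, tgt)
        np.testing.assert_allclose(m.weights.sum(axis=0), 0, atol=1e-8)
        np.testing.assert_allclose(src.T @ m.weights, 0, atol=1e-7)

    def test_square_with_displaced_corner_interpolates(self):
        src = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        tgt = src.copy()
        tgt[2] = [1.3, 1.4]
        m = tps_fit(src, tgt)
        np.testing.assert_allclose(tps_evaluate(m, src), tgt, atol=1e-9)
        assert m.bending_energy > 1e-6

    def test_affine_map_preserves_midpoints(self):
        src = rand_config(8)
        tgt = src @ np.array([[2.0, 0.1], [0.0, 1.5]]).T + 3.0
        m = tps_fit(src, tgt)
        a, b = np.array([[0.2, 0.7]]), np.array([[1.4, -0.3]])
        mid = tps_evaluate(m, (a + b) / 2)
        np.testing.assert_allclose(mid, (tps_evaluate(m, a) + tps_evaluate(m, b)) / 2, atol=1e-8)

    def test_dense_grid_vs_naive_loop(self):
        src, tgt = rand_config(12), rand_config(12)
        m = tps_fit(src, tgt)
        xs, ys = np.meshgrid(np.linspace(-3, 3, 10), np.linspace(-3, 3, 10))
        grid = np.column_stack([xs.ravel(), ys.ravel()])
        fast = tps_evaluate(m, grid)
        naive = np.empty_like(fast)
        for i, p in enumerate(grid):
            val = m.affine[0] + m.affine[1] * p[0] + m.affine[2] * p[1]
            for j, q in enumerate(src):
                r2 = float((p - q) @ (p - q))
                if r2 > 0:
                    val = val + m.weights[j] * r2 * np.log(r2)
            naive[i] = val
        np.testing.assert_allclose(fast, naive, atol=1e-10)

    def test_nonaffine_target_has_positive_bending(self):
        src = rand_config(10)
        tgt = src + np.column_stack([np.sin(src[:, 0]), np.zeros(10)])
        assert tps_fit(src, tgt).bending_energy > 1e-6

    def test_duplicate_source_points_rejected(self):
        src = np.array([[0, 0], [0, 0], [1, 1], [2, 0]], dtype=float)
        with pytest.raises(ValueError, match="distinct"):
            tps_fit(src, src)


def _template_frame(rows=96, cols=72):
    base = HEAD_TEMPLATE - HEAD_TEMPLATE.mean(axis=0)
    base = base / centroid_size(base)
    return ConsensusFrame.fit(base, rows, cols)


class TestWarp:
    def test_identity_warp(self):
        frame = _template_frame()
        config = LandmarkConfiguration(points=frame.landmarks)
        img = render_v_patch(config, PatchGeometry(), (frame.rows, frame.cols))
        np.testing.assert_array_equal(warp_to_consensus(img, config, frame), img)

    def test_all_ones_image(self):
        frame = _template_frame()
        config = LandmarkConfiguration(points=frame.landmarks)
        img = np.ones((frame.rows, frame.cols), dtype=np.uint8)
        assert warp_to_consensus(img, config, frame).all()

    def test_similarity_round_trip(self):
        """Render on the template, transform landmarks+image by a known
        similarity, warp back: >= 98% of mask pixels must agree."""
        frame = _template_frame()
        ref_config = LandmarkConfiguration(points=frame.landmarks)
        reference = render_v_patch(ref_config, PatchGeometry(), (frame.rows, frame.cols))

        ang = np.deg2rad(15.0)
        big = (256, 256)
        center_src = frame.landmarks.mean(axis=0)
        center_dst = np.array([128.0, 128.0])
        moved = (frame.landmarks - center_src) @ rotation(ang).T * 1.3 + center_dst
        moved_img = render_v_patch(LandmarkConfiguration(points=moved), PatchGeometry(), big)

        back = warp_to_consensus(moved_img, LandmarkConfiguration(points=moved), frame)
        mask = build_mask(frame)
        agree = np.mean(back[mask[:, 0], mask[:, 1]] == reference[mask[:, 0], mask[:, 1]])
        assert agree >= 0.98

    def test_frame_too_small(self):
        frame = _template_frame()
        tiny = ConsensusFrame(rows=16, cols=16, scale=frame.scale, cx=frame.cx, cy=frame.cy,
                              landmarks=frame.landmarks)
        with pytest.raises(ValueError):
            warp_to_consensus(np.ones((64, 64), dtype=np.uint8), frame.landmarks, tiny)


def _square_frame(shift=0.0):
    corners = np.array(
        [[0.5, 0.5], [10.5, 0.5], [10.5, 10.5], [0.5, 10.5]]
    ) + shift
    return ConsensusFrame(rows=14, cols=14, scale=1.0, cx=0.0, cy=0.0, landmarks=corners)


def _brute_force_even_odd(outline, rows, cols):
    """Ray-casting even-odd point-in-polygon over every pixel center."""
    hits = []
    n = len(outline)
    for r in range(rows):
        for c in range(cols):
            x, y = float(c), float(r)
            inside = False
            for i in range(n):
                x1, y1 = outline[i]
                x2, y2 = outline[(i + 1) % n]
                if (y1 > y) != (y2 > y):
                    xi = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
                    if x < xi:
                        inside = not inside
            if inside:
                hits.append((r, c))
    return np.array(hits)


class TestMask:
    def test_square_covering_100_centers(self):
        mask = build_mask(_square_frame(), n_landmarks=0)
        assert len(mask) == 100
        np.testing.assert_array_equal(
            mask, _brute_force_even_odd(_square_frame().landmarks, 14, 14)
        )

    def test_brute_force_oracle_on_head_outline(self):
        frame = _template_frame(48, 40)
        mask = build_mask(frame)
        oracle = _brute_force_even_odd(frame.landmarks[9:], 48, 40)
        np.testing.assert_array_equal(mask, oracle)

    def test_convex_outline_bounded_by_frame(self):
        frame = _template_frame()
        assert len(build_mask(frame)) <= frame.rows * frame.cols

    def test_translation_equivariance(self):
        m0 = build_mask(_square_frame(), n_landmarks=0)
        m1 = build_mask(_square_frame(shift=1.0), n_landmarks=0)
        np.testing.assert_array_equal(m1, m0 + 1)

    def test_self_intersecting_outline_rejected(self):
        bowtie = np.array([[0.0, 0.0], [10.0, 10.0], [10.0, 0.0], [0.0, 10.0]])
        frame = ConsensusFrame(rows=14, cols=14, scale=1.0, cx=0.0, cy=0.0, landmarks=bowtie)
        with pytest.raises(ValueError, match="self-intersecting"):
            build_mask(frame, n_landmarks=0)


class TestPixelMatrix:
    def test_all_ones(self):
        frame = _square_frame()
        mask = np.array([[1, 1], [2, 3], [5, 5], [9, 9], [10, 2]])
        imgs = [np.ones((14, 14), dtype=np.uint8)] * 2
        pm = build_pixel_matrix(imgs, mask, frame)
        np.testing.assert_array_equal(pm.values, np.ones((2, 5)))

    def test_column_means_equal_pixel_frequencies(self):
        frame = _square_frame()
        mask = build_mask(frame, n_landmarks=0)
        rng = np.random.default_rng(0)
        imgs = [(rng.random((14, 14)) > 0.6).astype(np.uint8) for _ in range(7)]
        pm = build_pixel_matrix(imgs, mask, frame)
        # counting oracle: foreground frequency per mask pixel, straight from the images
        for j, (r, c) in enumerate(mask):
            freq = sum(int(img[r, c]) for img in imgs) / len(imgs)
            assert pm.values[:, j].mean() == pytest.approx(freq)

    def test_permutation_of_individuals_permutes_rows(self):
        frame = _square_frame()
        mask = np.array([[1, 1], [2, 2]])
        rng = np.random.default_rng(1)
        imgs = [(rng.random((14, 14)) > 0.5).astype(np.uint8) for _ in range(4)]
        a = build_pixel_matrix(imgs, mask, frame).values
        b = build_pixel_matrix(imgs[::-1], mask, frame).values
        np.testing.assert_array_equal(b, a[::-1])

    def test_frame_mismatch(self):
        frame = _square_frame()
        with pytest.raises(ValueError, match="shape"):
            build_pixel_matrix([np.ones((5, 5), dtype=np.uint8)], np.array([[1, 1]]), frame)
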