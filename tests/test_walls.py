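import itertools

import numpy as np
import pytest

from angio3d.centerline import CenterlineCurve
from angio3d.image import Image2D
from angio3d.walls import (DPParams, NormalGrid, build_normal_grid, dp_optimal_path,
                           extract_vessel_walls, transition_score, _orientation_diff)


def random_grid(rng, n_stages, n_nodes):
    pos = rng.uniform(0, 50, size=(n_stages, n_nodes, 2))
    e_gm = rng.random((n_stages, n_nodes))
    return NormalGrid(
        positions=pos,
        normals=np.tile([1.0, 0.0], (n_stages, 1)),
        e_m=e_gm / e_gm.max(),
        e_gm=e_gm,
        e_hm=rng.random((n_stages, n_nodes)),
        e_gd=rng.uniform(0, np.pi, size=(n_stages, n_nodes)),
    )


def oracle_objective(grid, params, path):
    """Independent arithmetic evaluation of the accumulated objective."""
    b, eps = params.beta, params.epsilon
    total = grid.e_m[0, path[0]]
    for i in range(1, len(path)):
        rc = grid.e_gm[i, path[i]] / (grid.e_hm[i, path[i]] + eps)
        rp = grid.e_gm[i - 1, path[i - 1]] / (grid.e_hm[i - 1, path[i - 1]] + eps)
        dd = float(_orientation_diff(grid.e_gd[i, path[i]], grid.e_gd[i - 1, path[i - 1]]))
        total += grid.e_m[i, path[i]] - b * abs(rc - rp) - (1 - b) * dd**2
    return total


def oracle_best_path(grid, params):
    """Exhaustive enumeration over all interior node choices."""
    n, k = grid.n_stages, grid.n_nodes
    first = int(np.argmax(grid.e_gm[0]))
    last = int(np.argmax(grid.e_gm[-1]))
    best, best_path = -np.inf, None
    for mid in itertools.product(range(k), repeat=max(n - 2, 0)):
        path = (first, *mid, last) if n > 1 else (first,)
        c = oracle_objective(grid, params, path)
        if c > best:
            best, best_path = c, path
    return np.array(best_path), best


class TestTransitionScore:
    def test_identical_features_reduce_to_reward(self):
        node = {"e_m": 0.7, "e_gm": 0.4, "e_hm": 0.2, "e_gd": 1.0}
        p = DPParams(beta=0.6, epsilon=1e-6)
        assert transition_score(node, dict(node), p) == pytest.approx(0.7)

    def test_beta_one_drops_direction_term(self):
        prev = {"e_m": 0.5, "e_gm": 0.9, "e_hm": 0.3, "e_gd": 0.0}
        cur = {"e_m": 0.8, "e_gm": 0.5, "e_hm": 0.1, "e_gd": 1.4}
        p = DPParams(beta=1.0, epsilon=1e-6)
        expected = 0.8 - abs(0.5 / (0.1 + 1e-6) - 0.9 / (0.3 + 1e-6))
        assert transition_score(prev, cur, p) == pytest.approx(expected)

    def test_hand_filled_table(self):
        # independent arithmetic oracle for the full formula
        prev = {"e_m": 0.8, "e_gm": 0.8, "e_hm": 0.1, "e_gd": 0.0}
        cur = {"e_m": 0.6, "e_gm": 0.6, "e_hm": 0.2, "e_gd": np.pi / 4}
        p = DPParams(beta=0.75, epsilon=1e-6)
        ratio_c = 0.6 / (0.2 + 1e-6)
        ratio_p = 0.8 / (0.1 + 1e-6)
        expected = 0.6 - 0.75 * abs(ratio_c - ratio_p) - 0.25 * (np.pi / 4) ** 2
        assert transition_score(prev, cur, p) == pytest.approx(expected, rel=1e-12)

    def test_orientation_wrap(self):
        # orientations are modulo pi: 0.05 and pi-0.05 are 0.1 apart
        assert float(_orientation_diff(0.05, np.pi - 0.05)) == pytest.approx(0.1)


class TestDPOracle:
    def test_single_node_per_stage(self):
        rng = np.random.default_rng(0)
        grid = random_grid(rng, 6, 1)
        wall = dp_optimal_path(grid, DPParams(0.5, 1e-3))
        assert wall.node_indices.tolist() == [0] * 6
        assert wall.objective == pytest.approx(
            oracle_objective(grid, DPParams(0.5, 1e-3), [0] * 6))

    @pytest.mark.parametrize("beta", [0.0, 0.5, 0.75, 1.0])
    def test_matches_bruteforce(self, beta):
        rng = np.random.default_rng(int(beta * 100) + 1)
        params = DPParams(beta, 1e-3)
        for _ in range(12):
            n = int(rng.integers(3, 7))
            k = int(rng.integers(2, 6))
            grid = random_grid(rng, n, k)
            wall = dp_optimal_path(grid, params)
            opath, obest = oracle_best_path(grid, params)
            assert wall.objective == pytest.approx(obest, rel=1e-10)
            assert wall.node_indices.tolist() == opath.tolist()

    def test_empty_stage_error(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError):
            dp_optimal_path(random_grid(rng, 1, 3), DPParams())

    def test_reward_bump_on_optimal_path(self):
        rng = np.random.default_rng(5)
        params = DPParams(0.75, 1e-3)
        grid = random_grid(rng, 6, 4)
        wall = dp_optimal_path(grid, params)
        i = 3
        grid.e_m[i, wall.node_indices[i]] += 0.25
        wall2 = dp_optimal_path(grid, params)
        assert wall2.objective >= wall.objective + 0.25 - 1e-12

    def test_beta_zero_minimizes_direction_changes(self):
        # constant reward, constant ratio: only the direction term discriminates
        rng = np.random.default_rng(11)
        grid = random_grid(rng, 6, 5)
        grid.e_m[:] = 0.5
        grid.e_gm[:] = 0.7
        grid.e_hm[:] = 0.2
        params = DPParams(0.0, 1e-3)
        wall = dp_optimal_path(grid, params)
        path, best = oracle_best_path(grid, params)
        assert wall.node_indices.tolist() == path.tolist()
        # the optimum is exactly the min-sum-of-squared-direction-change path
        dirsum = sum(float(_orientation_diff(grid.e_gd[i, wall.node_indices[i]],
                                             grid.e_gd[i - 1, wall.node_indices[i - 1]]))**2
                     for i in range(1, 6))
        assert wall.objective == pytest.approx(6 * 0.5 - dirsum)

    def test_beta_one_takes_per_stage_max_reward(self):
        rng = np.random.default_rng(12)
        grid = random_grid(rng, 7, 5)
        grid.e_gm[:] = 0.7    # constant gradient: ratio term vanishes
        grid.e_hm[:] = 0.2
        wall = dp_optimal_path(grid, DPParams(1.0, 1e-3))
        greedy = grid.e_m.argmax(axis=1)
        greedy[0] = greedy[-1] = 0  # endpoint nodes tie on e_gm -> smallest index
        assert wall.node_indices.tolist() == greedy.tolist()


class TestNormalGrid:
    def _straight_setup(self, half_width=6):
        rng = np.random.default_rng(2)
        pix = np.clip(0.5 + 0.2 * rng.random((64, 64)), 0, 1)
        img = Image2D(pix)
        pts = np.column_stack([np.full(20, 32.0), np.linspace(10, 50, 20)])
        arc = np.linspace(0, 40, 20)
        return img, CenterlineCurve(pts, arc)

    def test_straight_centerline_normals(self):
        img, curve = self._straight_setup()
        left, right = build_normal_grid(img, curve)
        assert np.allclose(np.abs(left.normals[:, 0]), 1.0)
        assert np.allclose(left.normals[:, 1], 0.0)
        # offsets 1..K at unit spacing, opposite sides
        assert np.allclose(left.positions[0, :, 0], 32.0 - np.arange(1, 11))
        assert np.allclose(right.positions[0, :, 0], 32.0 + np.arange(1, 11))

    def test_constant_image_zero_features(self):
        img = Image2D(np.full((64, 64), 0.4))
        pts = np.column_stack([np.full(10, 32.0), np.linspace(20, 44, 10)])
        curve = CenterlineCurve(pts, np.linspace(0, 24, 10))
        left, right = build_normal_grid(img, curve)
        assert np.all(left.e_gm == 0) and np.all(left.e_hm == 0)
        assert np.all(right.e_gm == 0) and np.all(right.e_hm == 0)

    def test_fully_outside_error(self):
        img, _ = self._straight_setup()
        pts = np.column_stack([np.full(10, 2.0), np.linspace(10, 50, 10)])
        curve = CenterlineCurve(pts, np.linspace(0, 40, 10))
        with pytest.raises(ValueError, match="outside"):
            build_normal_grid(img, curve, half_width=10, spacing=3.0)

    def test_clamped_flagged(self):
        img, _ = self._straight_setup()
        pts = np.column_stack([np.full(10, 6.0), np.linspace(10, 50, 10)])
        curve = CenterlineCurve(pts, np.linspace(0, 40, 10))
        left, right = build_normal_grid(img, curve)
        assert left.clamped.any() or right.clamped.any()

    def test_feature_scale_invariance(self):
        # affine intensity change leaves normalized features, hence the DP
        # result, unchanged
        img, curve = self._straight_setup()
        left0, _ = build_normal_grid(img, curve)
        img2 = Image2D(np.clip(img.pixels * 0.5 + 0.1, 0, 1))
        left1, _ = build_normal_grid(img2, curve)
        assert np.allclose(left0.e_gm, left1.e_gm, atol=1e-9)
        assert np.allclose(left0.e_hm, left1.e_hm, atol=1e-9)
        w0 = dp_optimal_path(left0)
        w1 = dp_optimal_path(left1)
        assert w0.node_indices.tolist() == w1.node_indices.tolist()


class TestExtractWalls:
    def test_phantom_straight_vessel(self, geom_pair):
        from angio3d.phantom import make_phantom, render_views
        from tests.conftest import extract_view_centerline
        from scipy.spatial import cKDTree

        geomA, geomB = geom_pair
        r = 4 * 0.3 / (1000.0 / 700.0)  # half-width ~4 px on the detector
        ves = make_phantom("line", r0=r, start=(-18.0, 0.0, -14.0), end=(18.0, 0.0, 14.0))
        imgA, _, gt = render_views(ves, geomA, geomB, seed=3, noise_sigma=0.015)
        cl = extract_view_centerline(imgA, gt, 0)
        walls = extract_vessel_walls(imgA, cl, spacing=0.6)
        for w in walls:
            errs = [cKDTree(gtw).query(w.points)[0].mean() for gtw in gt.walls_px[0]]
            assert min(errs) < 1.0  # mean absolute offset error

    def test_default_beta(self):
        assert DPParams().beta == 0.75

    def test_runtime_scales(self):
        import time

        rng = np.random.default_rng(0)
        grid = random_grid(rng, 500, 10)
        t0 = time.perf_counter()
        dp_optimal_path(grid, DPParams())
        assert time.perf_counter() - t0 < 1.0


def test_dpparams_validation():
    with pytest.raises(ValueError):
        DPParams(beta=1.5)
    with pytest.raises(ValueError):
        DPParams(epsilon=0.0)
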