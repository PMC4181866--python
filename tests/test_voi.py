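import numpy as np
import pytest

from locsrr.errors import CoverageError, DegenerateGeometryError
from locsrr.forward import ForwardOperator, HRImage, LRStack
from locsrr.geometry import (
    AcquisitionGeometry,
    RigidTransform,
    VoxelGrid,
    make_acquisition_set,
    rotation_about_y,
)
from locsrr.solver import SRRConfig, reconstruct, reconstruct_voi, voi_core_slices
from locsrr.voi import (
    VOI,
    backproject_landmark,
    fit_rigid_landmarks,
    pca_reformation,
    project_point,
    propagate_and_extract_voi,
    voi_from_signal,
)


class TestBackprojection:
    def test_two_orthogonal_views_recover_point(self):
        p = np.array([3.0, -2.0, 5.0])
        obs = [(0.0, project_point(p, 0.0)), (90.0, project_point(p, 90.0))]
        assert np.allclose(backproject_landmark(obs), p, atol=1e-9)

    def test_oblique_views_recover_point(self):
        p = np.array([-1.2, 0.7, 2.9])
        obs = [(30.0, project_point(p, 30.0)), (115.0, project_point(p, 115.0))]
        assert np.allclose(backproject_landmark(obs), p, atol=1e-9)

    def test_point_on_rotation_axis_has_same_in_view_coordinates(self):
        p = np.array([0.0, 4.2, 0.0])
        uv0 = project_point(p, 0.0)
        uv1 = project_point(p, 137.0)
        assert np.allclose(uv0, uv1, atol=1e-12)

    def test_parallel_views_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            backproject_landmark([(10.0, (0, 0)), (190.0, (1, 1))])
        with pytest.raises(DegenerateGeometryError):
            backproject_landmark([(45.0, (0, 0)), (45.0, (1, 1))])


class TestRigidLandmarkFit:
    def test_identity_for_identical_sets(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0.3, 0.2, 1.7]])
        T = fit_rigid_landmarks(pts, pts)
        assert np.allclose(T.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(T.translation, 0, atol=1e-12)

    def test_recovers_known_transform(self, rng):
        for _ in range(5):
            pts = rng.normal(size=(6, 3))
            R = rotation_about_y(rng.uniform(0, 180)) @ np.array(
                [[1, 0, 0], [0, np.cos(0.3), -np.sin(0.3)], [0, np.sin(0.3), np.cos(0.3)]]
            )
            t = rng.normal(size=3)
            T_true = RigidTransform(R, t)
            T_fit = fit_rigid_landmarks(pts, T_true.apply(pts))
            assert np.allclose(T_fit.rotation, R, atol=1e-9)
            assert np.allclose(T_fit.translation, t, atol=1e-9)

    def test_collinear_points_rejected(self):
        line = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2], [3, 3, 3]], dtype=float)
        with pytest.raises(DegenerateGeometryError):
            fit_rigid_landmarks(line, line + 1.0)


class TestVoiFromSignal:
    def test_empty_when_all_below_threshold(self):
        grid = VoxelGrid.centered((10, 10, 10), 1.0)
        assert voi_from_signal(np.zeros((10, 10, 10)), grid, 0.5) == []

    def test_single_blob_bounding_box_plus_margin(self):
        grid = VoxelGrid((10, 10, 10), (1.0, 1.0, 1.0), origin=(0, 0, 0))
        img = np.zeros((10, 10, 10))
        img[2:5, 3:6, 4:5] = 1.0
        (v,) = voi_from_signal(img, grid, 0.5, margin_mm=1.5)
        assert v.min_mm == pytest.approx((2 - 1.5, 3 - 1.5, 4 - 1.5))
        assert v.max_mm == pytest.approx((4 + 1.5, 5 + 1.5, 4 + 1.5))

    def test_two_blobs_match_exhaustive_scan(self, rng):
        grid = VoxelGrid((16, 16, 16), (0.5, 0.5, 0.5), origin=(-4, -4, -4))
        img = np.zeros((16, 16, 16))
        img[1:4, 2:4, 3:6] = 2.0
        img[10:14, 9:12, 8:10] = 3.0
        vois = voi_from_signal(img, grid, 1.0)
        assert len(vois) == 2
        # brute-force oracle: per-voxel scan for each component's extremes
        mask = img > 1.0
        from scipy import ndimage

        labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
        boxes = set()
        for lab in range(1, n + 1):
            idx = np.argwhere(labels == lab)
            lo = tuple(idx.min(axis=0) * 0.5 + np.array([-4, -4, -4]))
            hi = tuple(idx.max(axis=0) * 0.5 + np.array([-4, -4, -4]))
            boxes.add((lo, hi))
        got = {(v.min_mm, v.max_mm) for v in vois}
        assert got == boxes


def _stack(angle=0.0, n=16, nz=4, data=None):
    geo = AcquisitionGeometry(angle, 0.5, 2.0, shape=(n, n, nz))
    if data is None:
        data = np.arange(n * n * nz, dtype=float).reshape(n, n, nz)
    return LRStack(geo, data)


class TestPropagateExtract:
    def test_identity_crop_is_direct_subarray(self):
        s = _stack()
        voi = VOI((-2.0, -2.0, -2.0), (2.0, 2.0, 2.0))
        (c,) = propagate_and_extract_voi(voi, [s], extra_pad_mm=0.0)
        grid = s.grid()
        lo = np.floor(grid.world_to_voxel(np.array(voi.min_mm))).astype(int)
        hi = np.ceil(grid.world_to_voxel(np.array(voi.max_mm))).astype(int) + 1
        expected = s.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        assert np.array_equal(c.data, expected)

    def test_rotated_frame_swaps_box_axes(self):
        # at 90 degrees the stack frame's x' axis is world -z and z' is
        # world x, so an elongated world box swaps extents in the crop
        s = _stack(angle=90.0, n=24, nz=24)
        voi = VOI((-4.0, -1.0, -1.0), (4.0, 1.0, 1.0))  # long along world x
        (c,) = propagate_and_extract_voi(voi, [s], extra_pad_mm=0.0)
        corners = voi.corners
        R_inv = rotation_about_y(90.0).T
        local = corners @ R_inv.T
        span = local.max(axis=0) - local.min(axis=0)
        assert span[2] == pytest.approx(8.0)  # world-x extent now along z'
        assert span[0] == pytest.approx(2.0)
        # the crop's physical extent along z' (spacing 2.0) must cover the
        # 8 mm box length, while x' (spacing 0.5) only covers the 2 mm width
        assert c.data.shape[2] * 2.0 >= 8.0
        assert c.data.shape[0] * 0.5 <= 4.0

    def test_voi_outside_fov(self):
        s = _stack()
        far = VOI((100.0, 100.0, 100.0), (101.0, 101.0, 101.0))
        with pytest.raises(CoverageError):
            propagate_and_extract_voi(far, [s])
        partial = VOI((2.0, 2.0, 0.0), (20.0, 20.0, 20.0))
        with pytest.raises(CoverageError):
            propagate_and_extract_voi(partial, [s], pad_policy="error")
        # clip policy crops the overlapping part instead
        (c,) = propagate_and_extract_voi(partial, [s], pad_policy="clip")
        assert c.data.size > 0


class TestPcaReformation:
    @staticmethod
    def _ellipsoid_mask(grid, semi, R=np.eye(3)):
        idx = np.stack(
            np.meshgrid(*[np.arange(s) for s in grid.shape], indexing="ij"), axis=-1
        )
        pts = idx * np.asarray(grid.spacing) + np.asarray(grid.origin)
        local = pts @ R  # rotate world into ellipsoid frame
        return np.sum((local / np.asarray(semi)) ** 2, axis=-1) <= 1.0

    def test_axis_aligned_ellipsoid_gives_axis_rotation(self):
        grid = VoxelGrid.centered((40, 40, 40), 0.25)
        mask = self._ellipsoid_mask(grid, (4.0, 2.0, 1.0))
        T, voi = pca_reformation(mask, grid)
        assert np.allclose(np.abs(T.rotation), np.eye(3), atol=1e-6)
        lo, hi = np.asarray(voi.min_mm), np.asarray(voi.max_mm)
        assert np.all(np.diff(hi - lo) < 0)  # extents descending

    def test_recovers_30_degree_rotation(self):
        grid = VoxelGrid.centered((48, 48, 48), 0.25)
        th = np.deg2rad(30.0)
        Rz = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        mask = self._ellipsoid_mask(grid, (4.5, 2.0, 1.0), R=Rz)
        T, _ = pca_reformation(mask, grid)
        # brute-force covariance eigendecomposition oracle
        pts = np.argwhere(mask) * 0.25 + np.asarray(grid.origin)
        pts = pts - pts.mean(axis=0)
        evals, evecs = np.linalg.eigh(pts.T @ pts / len(pts))
        principal = evecs[:, np.argmax(evals)]
        angle = np.degrees(
            np.arccos(np.clip(abs(principal @ T.rotation[0]), -1, 1))
        )
        assert angle < 1.0
        # and the recovered major axis is within a degree of the constructed one
        major_true = Rz @ np.array([1.0, 0.0, 0.0])
        angle_true = np.degrees(
            np.arccos(np.clip(abs(major_true @ T.rotation[0]), -1, 1))
        )
        assert angle_true < 1.0

    def test_sphere_obeys_sign_convention(self):
        grid = VoxelGrid.centered((24, 24, 24), 0.5)
        mask = self._ellipsoid_mask(grid, (3.0, 3.0, 3.0))
        T, _ = pca_reformation(mask, grid)
        for i in range(2):
            nz = np.nonzero(np.abs(T.rotation[i]) > 1e-12)[0]
            assert T.rotation[i][nz[0]] > 0
        assert np.linalg.det(T.rotation) == pytest.approx(1.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            pca_reformation(np.zeros((4, 4, 4), bool), VoxelGrid.centered((4, 4, 4), 1.0))


class TestLocalVersusGlobal:
    def test_local_reconstruction_matches_global_in_core(self, rng):
        # an interior VOI of a structured scene: local padded SRR must agree
        # with the whole-volume SRR inside the core to 1%
        n = 48
        hr = VoxelGrid.centered((n, n, n), 0.13)
        x = np.linspace(-1, 1, n)
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        scene = np.where(X**2 + Z**2 < 0.8, 1.0, 0.0)
        for cx, cy, cz, r in [(-0.2, 0.1, 0.2, 0.1), (0.25, -0.2, -0.1, 0.15)]:
            scene = np.where(
                (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 < r**2, 0.05, scene
            )
        image = HRImage(hr, scene)
        base = AcquisitionGeometry(0.0, 0.13, 0.52, shape=(n, n, 12))
        stacks, ops = [], []
        for geo in make_acquisition_set(2, base):
            op = ForwardOperator(hr, geo)
            stacks.append(op.apply(image))
            ops.append(op)
        cfg = SRRConfig(tol=1e-8, max_iter=80)
        whole = reconstruct(stacks, ops, cfg)
        voi = VOI((-1.0, -1.0, -1.0), (1.0, 1.0, 1.0))
        local = reconstruct_voi(voi, stacks, hr, cfg)
        core_local = local.image.data[voi_core_slices(voi, local.image.grid)]
        core_whole = whole.image.data[voi_core_slices(voi, hr)]
        assert core_local.shape == core_whole.shape
        rel = np.linalg.norm(core_local - core_whole) / np.linalg.norm(core_whole)
        assert rel < 0.01

    def test_voxel_count_accounting_predicts_work_ratio(self):
        # per-iteration solver work scales with the reconstruction size, so
        # the whole-to-VOI voxel ratio is the expected speedup factor
        n = 48
        hr = VoxelGrid.centered((n, n, n), 0.13)
        voi = VOI((-1.0, -1.0, -1.0), (1.0, 1.0, 1.0))
        base = AcquisitionGeometry(0.0, 0.13, 0.52, shape=(n, n, 12))
        stack = LRStack(base, np.ones(base.shape))
        local = reconstruct_voi(voi, [stack], hr, SRRConfig(max_iter=1, tol=1e-1))
        ratio = hr.num_voxels / local.image.grid.num_voxels
        predicted = np.prod(hr.shape) / np.prod(local.image.grid.shape)
        assert ratio == pytest.approx(predicted)
        assert ratio > 3.0  # local problem is substantially smaller
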