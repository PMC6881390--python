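import numpy as np
import pytest

from skullnav.geometry import (
    FrameMismatchError,
    LandmarkSet,
    TriangleMesh,
    ValidationError,
)
from skullnav.phantom import PhantomSpec, make_phantom, simulate_session
from skullnav.registration import NavigationSession, RegistrationError
from skullnav.surface import (
    navigation_error,
    point_to_mesh_distance,
    register_scan,
    summarize_distances,
)

from .conftest import random_landmarks, random_rigid


def eberly_point_triangle_distance(p, a, b, c):
    """Independent scalar oracle: Eberly's region-based closed form."""
    E0 = b - a
    E1 = c - a
    D = a - p
    aa = E0 @ E0
    bb = E0 @ E1
    cc = E1 @ E1
    dd = E0 @ D
    ee = E1 @ D
    det = aa * cc - bb * bb
    s = bb * ee - cc * dd
    t = bb * dd - aa * ee
    if s + t <= det:
        if s < 0:
            if t < 0:  # region 4
                if dd < 0:
                    t = 0.0
                    s = np.clip(-dd / aa, 0.0, 1.0)
                else:
                    s = 0.0
                    t = np.clip(-ee / cc, 0.0, 1.0)
            else:  # region 3
                s = 0.0
                t = np.clip(-ee / cc, 0.0, 1.0)
        elif t < 0:  # region 5
            t = 0.0
            s = np.clip(-dd / aa, 0.0, 1.0)
        else:  # region 0
            s /= det
            t /= det
    else:
        if s < 0:  # region 2
            tmp0 = bb + dd
            tmp1 = cc + ee
            if tmp1 > tmp0:
                s = np.clip((tmp1 - tmp0) / (aa - 2 * bb + cc), 0.0, 1.0)
                t = 1 - s
            else:
                s = 0.0
                t = np.clip(-ee / cc, 0.0, 1.0)
        elif t < 0:  # region 6
            tmp0 = bb + ee
            tmp1 = aa + dd
            if tmp1 > tmp0:
                t = np.clip((tmp1 - tmp0) / (aa - 2 * bb + cc), 0.0, 1.0)
                s = 1 - t
            else:
                t = 0.0
                s = np.clip(-dd / aa, 0.0, 1.0)
        else:  # region 1
            s = np.clip((cc + ee - bb - dd) / (aa - 2 * bb + cc), 0.0, 1.0)
            t = 1 - s
    closest = a + s * E0 + t * E1
    return float(np.linalg.norm(p - closest))


def brute_force_oracle(points, mesh):
    tri = mesh.triangles()
    out = np.empty(len(points))
    for i, p in enumerate(points):
        out[i] = min(
            eberly_point_triangle_distance(p, t[0], t[1], t[2]) for t in tri
        )
    return out


def random_mesh(rng, n_faces=200):
    from skullnav.phantom import icosphere

    v, f = icosphere(2)
    v = v * rng.uniform(20, 40) + rng.uniform(-5, 5, size=3)
    keep = rng.choice(len(f), size=min(n_faces, len(f)), replace=False)
    return TriangleMesh(v, f[np.sort(keep)])


class TestPointToMeshDistance:
    def test_point_on_vertex(self, tetrahedron):
        d = point_to_mesh_distance(tetrahedron.vertices[2][None, :], tetrahedron)
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_point_above_triangle_interior(self):
        # big triangle in z=0 plane; query 2 mm along its normal above the interior
        mesh = TriangleMesh(
            np.array([[-100.0, -100, 0], [100, -100, 0], [0, 150, 0]]),
            np.array([[0, 1, 2]]),
        )
        d = point_to_mesh_distance(np.array([[0.0, 0.0, 2.0]]), mesh)
        assert d[0] == pytest.approx(2.0, abs=1e-12)

    def test_point_beyond_edge_and_vertex_regions(self):
        mesh = TriangleMesh(
            np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]), np.array([[0, 1, 2]])
        )
        # vertex region beyond corner (1, 0, 0)
        d = point_to_mesh_distance(np.array([[2.0, -1.0, 0.0]]), mesh)
        assert d[0] == pytest.approx(np.sqrt(2.0), abs=1e-12)
        # edge region beside hypotenuse
        d = point_to_mesh_distance(np.array([[1.0, 1.0, 0.0]]), mesh)
        assert d[0] == pytest.approx(np.sqrt(2) / 2, abs=1e-12)

    @pytest.mark.parametrize("method", ["bruteforce", "accelerated"])
    def test_matches_independent_oracle(self, rng, method):
        mesh = random_mesh(rng, n_faces=200)
        pts = rng.uniform(-60, 60, size=(500, 3))
        got = point_to_mesh_distance(pts, mesh, method=method)
        expected = brute_force_oracle(pts, mesh)
        assert np.allclose(got, expected, atol=1e-9)

    def test_accelerated_equals_bruteforce(self, rng):
        mesh = random_mesh(rng)
        pts = rng.uniform(-50, 50, size=(300, 3))
        a = point_to_mesh_distance(pts, mesh, method="accelerated")
        b = point_to_mesh_distance(pts, mesh, method="bruteforce")
        assert np.allclose(a, b, atol=1e-9)

    def test_invariant_under_common_rigid_transform(self, rng):
        mesh = random_mesh(rng, n_faces=80)
        pts = rng.uniform(-50, 50, size=(50, 3))
        base = point_to_mesh_distance(pts, mesh)
        T = random_rigid(rng)
        moved_mesh = mesh.transformed(T)
        moved = point_to_mesh_distance(T.apply(pts), moved_mesh)
        assert np.allclose(moved, base, atol=1e-9)

    def test_frame_mismatch(self, tetrahedron):
        tetrahedron.frame = "scan"
        pts = LandmarkSet(["A", "B", "C"], np.eye(3), frame="tracker")
        with pytest.raises(FrameMismatchError):
            point_to_mesh_distance(pts, tetrahedron)


class TestErrorSummary:
    def test_quartile_ordering_and_mean(self, rng):
        d = np.abs(rng.normal(0, 1, size=1000))
        s = summarize_distances(d, "frontal")
        assert 0 <= s.q1 <= s.median <= s.q3 <= s.max
        assert s.mean == pytest.approx(d.mean(), rel=1e-12)
        assert s.n_points == 1000

    def test_linear_interpolation_quartiles(self):
        s = summarize_distances(np.array([1.0, 2.0, 3.0, 4.0]))
        # numpy "linear" (type 7): q1 = 1.75, median = 2.5, q3 = 3.25
        assert s.q1 == pytest.approx(1.75)
        assert s.median == pytest.approx(2.5)
        assert s.q3 == pytest.approx(3.25)

    def test_negative_distances_rejected(self):
        with pytest.raises(ValidationError):
            summarize_distances(np.array([-1.0, 2.0]))


class TestRegisterScan:
    def test_identity(self, rng):
        pins = random_landmarks(rng, n=6, prefix="P")
        T = register_scan(pins, pins)
        assert np.allclose(T.rotation, np.eye(3), atol=1e-12)

    def test_recovers_displacement(self, rng):
        pins = random_landmarks(rng, n=6, prefix="P")
        motion = random_rigid(rng)
        T = register_scan(pins, pins.transformed(motion))
        assert np.allclose(T.rotation, motion.rotation, atol=1e-9)
        assert np.allclose(T.translation, motion.translation, atol=1e-8)

    def test_two_pins_rejected(self, rng):
        pins = random_landmarks(rng, n=2, prefix="P")
        with pytest.raises(RegistrationError):
            register_scan(pins, pins)


class TestNavigationError:
    def test_zero_noise_zero_error(self):
        spec = PhantomSpec(seed=11, tracking_noise_sigma_mm=0.0)
        sim = simulate_session(make_phantom(spec))
        summaries = navigation_error(sim.session, sim.scan_mesh, sim.scan_pins)
        assert summaries["pooled"].mean == pytest.approx(0.0, abs=1e-9)
        assert summaries["pooled"].q3 == pytest.approx(0.0, abs=1e-9)

    def test_normal_displacement_recovered(self):
        # displace every recorded point 0.5 mm along the outward normal of
        # its owning triangle; on the convex vault the closest surface
        # point is then the original sample, so every distance is 0.5
        from skullnav.surface import _points_to_triangles

        spec = PhantomSpec(
            seed=12,
            tracking_noise_sigma_mm=0.0,
            motion_schedule=(),
            n_recorded_per_region=20,
        )
        case = make_phantom(spec)
        sim = simulate_session(case)
        session = sim.session
        t_true = case.image_to_tracker
        mesh = case.postop_mesh
        tri = mesh.triangles()
        normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        outward = np.einsum("fi,fi->f", normals, tri.mean(axis=1)) > 0
        normals[~outward] *= -1
        for rec in session.recorded:
            pts_image = t_true.inverse().apply(rec.points.points)
            owner = np.argmin(_points_to_triangles(pts_image, tri), axis=1)
            moved = t_true.apply(pts_image + 0.5 * normals[owner])
            rec.points = LandmarkSet(rec.points.labels, moved, frame="tracker")
        summaries = navigation_error(session, sim.scan_mesh, sim.scan_pins)
        assert summaries["pooled"].mean == pytest.approx(0.5, abs=1e-6)

    def test_pooled_mean_is_count_weighted_region_mean(self):
        spec = PhantomSpec(seed=13, tracking_noise_sigma_mm=0.4)
        sim = simulate_session(make_phantom(spec))
        summaries = navigation_error(sim.session, sim.scan_mesh, sim.scan_pins)
        regions = [s for k, s in summaries.items() if k != "pooled"]
        weighted = sum(s.mean * s.n_points for s in regions) / sum(
            s.n_points for s in regions
        )
        assert summaries["pooled"].mean == pytest.approx(weighted, rel=1e-12)

    def test_error_monotone_in_noise(self):
        means = []
        for sigma in (0.0, 0.3, 1.0):
            vals = []
            for seed in range(3):
                spec = PhantomSpec(
                    seed=20 + seed,
                    tracking_noise_sigma_mm=sigma,
                    n_recorded_per_region=30,
                )
                sim = simulate_session(make_phantom(spec))
                s = navigation_error(sim.session, sim.scan_mesh, sim.scan_pins)
                vals.append(s["pooled"].mean)
            means.append(np.mean(vals))
        assert means[0] <= means[1] <= means[2]

    def test_no_recorded_points_rejected(self):
        spec = PhantomSpec(seed=14, tracking_noise_sigma_mm=0.0)
        sim = simulate_session(make_phantom(spec))
        empty = NavigationSession("empty", primary=sim.session.primary)
        empty.pin_reference = sim.session.pin_reference
        with pytest.raises(RegistrationError, match="recorded"):
            navigation_error(empty, sim.scan_mesh, sim.scan_pins)
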