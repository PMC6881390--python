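"""Synthetic skull phantom and navigation-session simulator.

Generates complete cases with no external data: a smooth ellipsoidal
cranial-vault surrogate, craniometric landmarks constructed to realize a
requested interfrontal angle and transverse forehead width exactly, guide
and pin fiducials on the surface, noisy tracked recordings, head-motion
events with re-registration, and a "scanned" copy of the postoperative
geometry in its own frame. Anatomical realism is not a goal; metric
realism is — every downstream module depends only on landmarks and
surface geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import LandmarkSet, RigidTransform, TriangleMesh, ValidationError
from .io import read_landmarks, read_mesh, write_landmarks, write_mesh
from .registration import (
    NavigationSession,
    record_points,
    register_primary,
    register_secondary,
)

__all__ = [
    "MotionEvent",
    "PhantomSpec",
    "SyntheticCase",
    "SimulatedSession",
    "icosphere",
    "make_phantom",
    "simulate_tracked_points",
    "simulate_session",
    "write_case",
    "read_case",
]

CRANIO_LABELS = ("LFL", "RFL", "MSL")


@dataclass(frozen=True)
class MotionEvent:
    """A rigid head movement: translation magnitude (mm) and rotation (deg)."""

    translation_mm: float = 5.0
    rotation_deg: float = 3.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic case (all stochastic choices seeded)."""

    seed: int = 0
    plan_angle_deg: float = 134.0
    plan_width_mm: float = 92.0
    preop_angle_deg: float = 110.0
    preop_width_mm: float = 82.0
    undercorrection_deg: float = 4.0
    undercorrection_mm: float = 2.0
    tracking_noise_sigma_mm: float = 0.25
    n_guide_points: int = 6
    n_pins: int = 6
    motion_schedule: tuple[MotionEvent, ...] = (MotionEvent(),)
    n_recorded_per_region: int = 40
    subdivisions: int = 3

    def __post_init__(self) -> None:
        for name in ("plan_angle_deg", "preop_angle_deg"):
            a = getattr(self, name)
            if not (0 < a < 180):
                raise ValidationError(f"{name} must be in (0, 180), got {a}")
        if not (0 < self.plan_angle_deg - self.undercorrection_deg < 180):
            raise ValidationError("postop angle (plan - undercorrection) out of range")
        for name in ("plan_width_mm", "preop_width_mm"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.plan_width_mm - self.undercorrection_mm <= 0:
            raise ValidationError("postop width (plan - undercorrection) must be > 0")
        if self.undercorrection_deg < 0 or self.undercorrection_mm < 0:
            raise ValidationError("undercorrection must be >= 0")
        if self.tracking_noise_sigma_mm < 0:
            raise ValidationError("tracking noise sigma must be >= 0")
        if self.n_guide_points < 3 or self.n_pins < 3:
            raise ValidationError("need at least 3 guide points and 3 pins")
        if self.n_recorded_per_region < 1:
            raise ValidationError("n_recorded_per_region must be >= 1")

    @property
    def postop_angle_deg(self) -> float:
        return self.plan_angle_deg - self.undercorrection_deg

    @property
    def postop_width_mm(self) -> float:
        return self.plan_width_mm - self.undercorrection_mm

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "plan_angle_deg": self.plan_angle_deg,
            "plan_width_mm": self.plan_width_mm,
            "preop_angle_deg": self.preop_angle_deg,
            "preop_width_mm": self.preop_width_mm,
            "undercorrection_deg": self.undercorrection_deg,
            "undercorrection_mm": self.undercorrection_mm,
            "tracking_noise_sigma_mm": self.tracking_noise_sigma_mm,
            "n_guide_points": self.n_guide_points,
            "n_pins": self.n_pins,
            "motion_schedule": [
                {"translation_mm": m.translation_mm, "rotation_deg": m.rotation_deg}
                for m in self.motion_schedule
            ],
            "n_recorded_per_region": self.n_recorded_per_region,
            "subdivisions": self.subdivisions,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["motion_schedule"] = tuple(
            MotionEvent(m["translation_mm"], m["rotation_deg"])
            for m in d.get("motion_schedule", [])
        )
        return cls(**d)


@dataclass
class SyntheticCase:
    """All ground-truth pieces of one generated case (image frame)."""

    spec: PhantomSpec
    preop_mesh: TriangleMesh
    plan_mesh: TriangleMesh
    postop_mesh: TriangleMesh
    guide_points: LandmarkSet
    pins: LandmarkSet
    landmarks: dict[str, LandmarkSet]  # stage -> LFL/RFL/MSL
    image_to_tracker: RigidTransform
    image_to_scan: RigidTransform


@dataclass
class SimulatedSession:
    """A simulated navigation session plus its gold-standard scan inputs."""

    session: NavigationSession
    scan_mesh: TriangleMesh
    scan_pins: LandmarkSet
    true_transforms: dict[int, RigidTransform]  # repetition index -> image->tracker
    true_surface_points: dict[str, LandmarkSet]  # image frame, on postop surface


# ---------------------------------------------------------------------------
# geometry construction

def icosphere(subdivisions: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Unit icosphere via repeated subdivision of an icosahedron."""
    phi = (1 + np.sqrt(5)) / 2
    v = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    f = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    for _ in range(subdivisions):
        mid_cache: dict[tuple[int, int], int] = {}
        verts = list(v)
        new_faces = []

        def midpoint(i: int, j: int) -> int:
            key = (min(i, j), max(i, j))
            if key not in mid_cache:
                m = verts[i] + verts[j]
                m /= np.linalg.norm(m)
                mid_cache[key] = len(verts)
                verts.append(m)
            return mid_cache[key]

        for a, b, c in f:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]]
        v = np.asarray(verts)
        f = np.asarray(new_faces, dtype=np.int64)
    return v, f


def _vault_axes(width: float) -> tuple[float, float, float]:
    # left-right, anterior-posterior, superior-inferior semi-axes
    return 0.62 * width, 0.72 * width, 0.55 * width


def _vault_mesh(width: float, subdivisions: int, frame: str = "image") -> TriangleMesh:
    a, b, c = _vault_axes(width)
    v, f = icosphere(subdivisions)
    return TriangleMesh(v * np.array([a, b, c]), f, frame=frame)


def _solve_cranio_landmarks(angle_deg: float, width_mm: float) -> LandmarkSet:
    """LFL/RFL on the vault surface, MSL on the midline realizing the
    requested interfrontal angle and width exactly by construction."""
    a, b, c = _vault_axes(width_mm)
    z1 = 0.12 * c
    rad = 1.0 - (width_mm / (2 * a)) ** 2 - (z1 / c) ** 2
    if rad <= 0:
        raise ValidationError(
            f"infeasible geometry: width {width_mm} mm too large for vault scale"
        )
    y1 = b * np.sqrt(rad)
    lfl = np.array([-width_mm / 2, y1, z1])
    rfl = np.array([width_mm / 2, y1, z1])
    half = np.deg2rad(angle_deg) / 2
    h = (width_mm / 2) / np.tan(half)
    alpha = np.deg2rad(40.0)  # forward-and-up midline direction
    msl = np.array([0.0, y1 + h * np.cos(alpha), z1 + h * np.sin(alpha)])
    return LandmarkSet(list(CRANIO_LABELS), np.stack([lfl, rfl, msl]), frame="image")


def _farthest_point_sample(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    idx = [int(rng.integers(len(points)))]
    d = np.linalg.norm(points - points[idx[0]], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        idx.append(nxt)
        d = np.minimum(d, np.linalg.norm(points - points[nxt], axis=1))
    return np.array(idx)


def _random_rotation(rng: np.random.Generator, max_deg: float) -> RigidTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    return RigidTransform.from_axis_angle(axis, float(rng.uniform(-max_deg, max_deg)))


def make_phantom(spec: PhantomSpec) -> SyntheticCase:
    """Build a complete synthetic case deterministically from its spec."""
    rng = np.random.default_rng(spec.seed)

    preop = _vault_mesh(spec.preop_width_mm, spec.subdivisions)
    plan = _vault_mesh(spec.plan_width_mm, spec.subdivisions)
    postop = _vault_mesh(spec.postop_width_mm, spec.subdivisions)

    landmarks = {
        "preop": _solve_cranio_landmarks(spec.preop_angle_deg, spec.preop_width_mm),
        "plan": _solve_cranio_landmarks(spec.plan_angle_deg, spec.plan_width_mm),
        "postop": _solve_cranio_landmarks(spec.postop_angle_deg, spec.postop_width_mm),
    }

    a, b, c = _vault_axes(spec.preop_width_mm)
    v = preop.vertices
    frontal = np.nonzero((v[:, 1] > 0.35 * b) & (v[:, 2] > 0.1 * c))[0]
    posterior = np.nonzero(v[:, 1] < -0.15 * b)[0]
    gi = frontal[_farthest_point_sample(v[frontal], spec.n_guide_points, rng)]
    pi = posterior[_farthest_point_sample(v[posterior], spec.n_pins, rng)]
    guides = LandmarkSet([f"G{i+1}" for i in range(len(gi))], v[gi], frame="image")
    pins = LandmarkSet([f"P{i+1}" for i in range(len(pi))], v[pi], frame="image")

    rot = _random_rotation(rng, 30.0)
    image_to_tracker = RigidTransform(rot.rotation, rng.uniform(-80, 80, size=3))
    rot_s = _random_rotation(rng, 60.0)
    image_to_scan = RigidTransform(rot_s.rotation, rng.uniform(-50, 50, size=3))

    return SyntheticCase(
        spec=spec,
        preop_mesh=preop,
        plan_mesh=plan,
        postop_mesh=postop,
        guide_points=guides,
        pins=pins,
        landmarks=landmarks,
        image_to_tracker=image_to_tracker,
        image_to_scan=image_to_scan,
    )


# ---------------------------------------------------------------------------
# simulation

def simulate_tracked_points(
    true_points: LandmarkSet,
    true_transform: RigidTransform,
    sigma: float,
    seed: int | np.random.Generator,
) -> LandmarkSet:
    """Pointer recordings: transform plus iid Gaussian noise per axis."""
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pts = true_transform.apply(true_points.points)
    if sigma > 0:
        pts = pts + rng.normal(0.0, sigma, size=pts.shape)
    return LandmarkSet(list(true_points.labels), pts, frame="tracker")


def _motion_transform(
    event: MotionEvent, about: np.ndarray, rng: np.random.Generator
) -> RigidTransform:
    """Random rigid motion of the stated magnitudes, rotating about ``about``."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    R = RigidTransform.from_axis_angle(axis, event.rotation_deg)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    t = about - R.rotation @ about + direction * event.translation_mm
    return RigidTransform(R.rotation, t)


def _sample_surface_points(
    mesh: TriangleMesh, mask: np.ndarray, n: int, rng: np.random.Generator, label_prefix: str
) -> LandmarkSet:
    """Uniform-by-area barycentric samples on the faces selected by ``mask``."""
    faces = mesh.faces[mask]
    if len(faces) == 0:
        raise ValidationError("region mask selects no faces")
    tri = mesh.vertices[faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    choice = rng.choice(len(faces), size=n, p=areas / areas.sum())
    r1 = np.sqrt(rng.uniform(size=n))
    r2 = rng.uniform(size=n)
    bary = np.stack([1 - r1, r1 * (1 - r2), r1 * r2], axis=1)
    pts = np.einsum("nk,nki->ni", bary, tri[choice])
    return LandmarkSet(
        [f"{label_prefix}{i+1}" for i in range(n)], pts, frame="image"
    )


def region_face_masks(mesh: TriangleMesh, width: float) -> dict[str, np.ndarray]:
    """Frontal / supraorbital face masks by centroid position."""
    a, b, c = _vault_axes(width)
    cent = mesh.triangles().mean(axis=1)
    frontal = (cent[:, 1] > 0.35 * b) & (cent[:, 2] > 0.15 * c)
    supraorbital = (cent[:, 1] > 0.45 * b) & (cent[:, 2] <= 0.15 * c) & (cent[:, 2] > -0.05 * c)
    return {"frontal": frontal, "supraorbital": supraorbital}


def simulate_session(
    case: SyntheticCase,
    spec: PhantomSpec | None = None,
    reregister_after_motion: bool = True,
) -> SimulatedSession:
    """Run the full intraoperative sequence on a synthetic case.

    Order of events: primary registration on guide points, one pin
    recording under the primary (the secondary reference), an initial
    secondary, then for each scheduled motion event a head movement
    followed (optionally) by a re-registration, with navigation points
    recorded on the postoperative surface after each registration.
    """
    spec = spec or case.spec
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    sigma = spec.tracking_noise_sigma_mm
    t_true = case.image_to_tracker
    session = NavigationSession(case_id=f"phantom-{spec.seed}")
    true_transforms: dict[int, RigidTransform] = {}

    guide_tracker = simulate_tracked_points(case.guide_points, t_true, sigma, rng)
    register_primary(case.guide_points, guide_tracker, session)
    true_transforms[1] = t_true

    pins_tracker = simulate_tracked_points(case.pins, t_true, sigma, rng)
    session.pin_reference = pins_tracker.transformed(
        session.primary.transform.inverse(), frame="image"
    )

    masks = region_face_masks(case.postop_mesh, spec.postop_width_mm)
    true_surface_points = {
        region: _sample_surface_points(
            case.postop_mesh, mask, spec.n_recorded_per_region, rng, region[:2].upper()
        )
        for region, mask in masks.items()
    }

    def do_secondary() -> None:
        tracked = simulate_tracked_points(case.pins, t_true, sigma, rng)
        reg = register_secondary(session.pin_reference, tracked, session)
        true_transforms[reg.repetition_index] = t_true

    def do_recordings() -> None:
        for region, true_pts in true_surface_points.items():
            rec = simulate_tracked_points(true_pts, t_true, sigma, rng)
            record_points(session, region, rec)

    do_secondary()
    do_recordings()
    head_center = t_true.apply(np.zeros(3))
    for event in spec.motion_schedule:
        motion = _motion_transform(event, head_center, rng)
        t_true = motion.compose(t_true)
        if reregister_after_motion:
            do_secondary()
        do_recordings()

    scan_mesh = case.postop_mesh.transformed(case.image_to_scan, frame="scan")
    scan_pins = case.pins.transformed(case.image_to_scan, frame="scan")
    return SimulatedSession(
        session=session,
        scan_mesh=scan_mesh,
        scan_pins=scan_pins,
        true_transforms=true_transforms,
        true_surface_points=true_surface_points,
    )


# ---------------------------------------------------------------------------
# case directory output

def write_case(case: SyntheticCase, outdir) -> None:
    """Write the case as STL/OBJ meshes + landmark CSVs + spec JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_mesh(case.preop_mesh, outdir / "preop.stl")
    write_mesh(case.plan_mesh, outdir / "plan.stl")
    write_mesh(case.postop_mesh, outdir / "postop.stl")
    scan = case.postop_mesh.transformed(case.image_to_scan, frame="scan")
    write_mesh(scan, outdir / "postop_scan.obj")
    write_landmarks(case.guide_points, outdir / "guide_points.csv")
    write_landmarks(case.pins, outdir / "pins.csv")
    write_landmarks(
        case.pins.transformed(case.image_to_scan, frame="scan"),
        outdir / "scan_pins.csv",
    )
    for stage, lms in case.landmarks.items():
        write_landmarks(lms, outdir / f"landmarks_{stage}.csv")
    with open(outdir / "case.json", "w") as fh:
        json.dump(
            {
                "spec": case.spec.to_dict(),
                "image_to_tracker": case.image_to_tracker.to_dict(),
                "image_to_scan": case.image_to_scan.to_dict(),
            },
            fh,
            indent=2,
        )


def read_case(indir) -> SyntheticCase:
    """Reconstruct a :class:`SyntheticCase` from a ``write_case`` directory."""
    indir = Path(indir)
    meta_path = indir / "case.json"
    if not meta_path.is_file():
        raise IOError(f"not a case directory (missing case.json): {indir}")
    with open(meta_path) as fh:
        meta = json.load(fh)
    spec = PhantomSpec.from_dict(meta["spec"])
    landmarks = {
        stage: read_landmarks(indir / f"landmarks_{stage}.csv")
        for stage in ("preop", "plan", "postop")
    }
    meshes = {}
    for name in ("preop", "plan", "postop"):
        m = read_mesh(indir / f"{name}.stl")
        m.frame = "image"
        meshes[name] = m
    return SyntheticCase(
        spec=spec,
        preop_mesh=meshes["preop"],
        plan_mesh=meshes["plan"],
        postop_mesh=meshes["postop"],
        guide_points=read_landmarks(indir / "guide_points.csv"),
        pins=read_landmarks(indir / "pins.csv"),
        landmarks=landmarks,
        image_to_tracker=RigidTransform.from_dict(meta["image_to_tracker"]),
        image_to_scan=RigidTransform.from_dict(meta["image_to_scan"]),
    )
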