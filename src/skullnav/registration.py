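"""Closed-form rigid point-set registration and session bookkeeping.

Implements the two-step intraoperative scheme: a primary registration on
guide landmarks, then repeatable secondary registrations on bone pins so
that head motion between recordings can be compensated. The solver is the
SVD-based least-squares rigid fit (Kabsch) with the determinant sign fix,
which is optimal for label-matched correspondences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import LandmarkSet, RigidTransform, ValidationError

__all__ = [
    "RegistrationError",
    "RegistrationResult",
    "RecordedPoints",
    "NavigationSession",
    "fit_rigid",
    "register_primary",
    "register_secondary",
    "record_points",
    "summarize_sessions",
]


class RegistrationError(ValueError):
    """Raised when a registration problem is degenerate or under-determined."""


@dataclass
class RegistrationResult:
    """Fitted transform plus per-fiducial residuals for one registration.

    ``rmse`` is the root of the mean squared residual (fiducial
    registration error). ``duration_s`` is optional human task-timing
    metadata carried through to reports, never computed.
    """

    transform: RigidTransform
    residuals: np.ndarray
    rmse: float
    n_fiducials: int
    step: str = "primary"
    repetition_index: int = 1
    labels: list[str] = field(default_factory=list)
    duration_s: float | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.residuals, float)
        if self.step not in ("primary", "secondary"):
            raise ValidationError(f"step must be primary|secondary, got {self.step!r}")
        if self.n_fiducials != len(r) or self.n_fiducials < 3:
            raise ValidationError("n_fiducials must equal len(residuals) and be >= 3")
        expected = float(np.sqrt(np.mean(r**2)))
        if not np.isclose(self.rmse, expected, rtol=1e-12, atol=1e-15):
            raise ValidationError("rmse inconsistent with residuals")
        self.residuals = r

    def to_dict(self) -> dict:
        return {
            "step": self.step,
            "repetition_index": self.repetition_index,
            "rmse_mm": self.rmse,
            "n_fiducials": self.n_fiducials,
            "residuals_mm": self.residuals.tolist(),
            "labels": list(self.labels),
            "duration_s": self.duration_s,
            "transform": self.transform.to_dict(),
        }


@dataclass
class RecordedPoints:
    """Navigation points recorded in the tracker frame for one region,
    stamped with the repetition index of the registration then in force."""

    region: str
    points: LandmarkSet
    registration_index: int


@dataclass
class NavigationSession:
    """One case's registrations and recorded navigation points."""

    case_id: str
    primary: RegistrationResult | None = None
    secondaries: list[RegistrationResult] = field(default_factory=list)
    pin_reference: LandmarkSet | None = None
    recorded: list[RecordedPoints] = field(default_factory=list)

    @property
    def registrations(self) -> list[RegistrationResult]:
        return ([self.primary] if self.primary else []) + list(self.secondaries)

    def current(self) -> RegistrationResult:
        """The registration currently in force (latest secondary, else primary)."""
        if self.secondaries:
            return self.secondaries[-1]
        if self.primary is None:
            raise RegistrationError(f"session {self.case_id!r} has no registration yet")
        return self.primary

    def transform_in_force(self, registration_index: int) -> RigidTransform:
        for reg in self.registrations:
            if reg.repetition_index == registration_index:
                return reg.transform
        raise RegistrationError(
            f"no registration with repetition_index {registration_index}"
        )

    def recorded_by_region(self) -> dict[str, list[RecordedPoints]]:
        out: dict[str, list[RecordedPoints]] = {}
        for rec in self.recorded:
            out.setdefault(rec.region, []).append(rec)
        return out


def fit_rigid(source: LandmarkSet, target: LandmarkSet) -> RegistrationResult:
    """Least-squares rigid transform mapping ``source`` points onto ``target``.

    Correspondence is by label. The returned rotation is always proper
    (no scaling, no reflection); residuals are the per-fiducial distances
    after applying the fitted transform.
    """
    common, src, tgt = source.match(target)
    unmatched = sorted(
        (set(source.labels) | set(target.labels)) - set(common)
    )
    if len(common) < 3:
        raise RegistrationError(
            f"need >= 3 label-matched fiducials, got {len(common)}"
            + (f" (unmatched: {unmatched})" if unmatched else "")
        )
    src_mean = src.mean(axis=0)
    tgt_mean = tgt.mean(axis=0)
    src_c = src - src_mean
    tgt_c = tgt - tgt_mean
    # collinear configurations leave rotation about the line unconstrained
    if np.linalg.matrix_rank(src_c, tol=1e-9 * max(1.0, np.abs(src_c).max())) < 2:
        raise RegistrationError(
            "degenerate fiducial configuration: source points are collinear "
            "(rank < 2 after centering)"
        )
    H = src_c.T @ tgt_c
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d if d != 0 else 1.0])
    R = Vt.T @ D @ U.T
    t = tgt_mean - R @ src_mean
    transform = RigidTransform(R, t)
    residuals = np.linalg.norm(transform.apply(src) - tgt, axis=1)
    rmse = float(np.sqrt(np.mean(residuals**2)))
    return RegistrationResult(
        transform=transform,
        residuals=residuals,
        rmse=rmse,
        n_fiducials=len(common),
        labels=common,
    )


def register_primary(
    guide_points_image: LandmarkSet,
    guide_points_tracker: LandmarkSet,
    session: NavigationSession | None = None,
    duration_s: float | None = None,
) -> RegistrationResult:
    """Primary registration from guide landmarks (image frame -> tracker frame)."""
    result = fit_rigid(guide_points_image, guide_points_tracker)
    result.step = "primary"
    result.repetition_index = 1
    result.duration_s = duration_s
    if session is not None:
        session.primary = result
    return result


def register_secondary(
    pins_reference: LandmarkSet,
    pins_tracker: LandmarkSet,
    session: NavigationSession,
    duration_s: float | None = None,
) -> RegistrationResult:
    """Secondary registration from pin fiducials; appended to the session.

    ``pins_reference`` is the pin set recorded once under the primary
    registration, mapped into the image frame. The result becomes the
    transform in force for subsequently recorded points.
    """
    if session.primary is None:
        raise RegistrationError("secondary registration requires a primary first")
    result = fit_rigid(pins_reference, pins_tracker)
    result.step = "secondary"
    result.repetition_index = 1 + 1 + len(session.secondaries)
    result.duration_s = duration_s
    session.secondaries.append(result)
    return result


def record_points(session: NavigationSession, region: str, points: LandmarkSet) -> RecordedPoints:
    """Stamp tracker-frame points with the registration currently in force."""
    rec = RecordedPoints(region, points, session.current().repetition_index)
    session.recorded.append(rec)
    return rec


def _sd(values: np.ndarray, population: bool) -> float:
    values = np.asarray(values, float)
    if len(values) < 2 and not population:
        return float("nan")
    return float(np.std(values, ddof=0 if population else 1))


def summarize_sessions(sessions: list[NavigationSession]) -> pd.DataFrame:
    """Per-case and pooled registration RMSE summary.

    Per case: the primary RMSE, the mean and sample SD of secondary RMSE
    over repetitions, and the repetition count. The pooled row averages
    primary RMSE unweighted across cases, while the pooled secondary mean
    weights each case's secondary mean by its repetition count. Both
    sample and population SDs are reported for pooled rows because the
    convention differs between software packages.
    """
    if not sessions:
        raise ValidationError("no sessions to summarize")
    rows = []
    for s in sessions:
        if s.primary is None or not s.secondaries:
            raise ValidationError(
                f"session {s.case_id!r} needs a primary and >= 1 secondary"
            )
        sec = np.array([r.rmse for r in s.secondaries])
        rows.append(
            {
                "case": s.case_id,
                "primary_rmse_mm": s.primary.rmse,
                "secondary_rmse_mean_mm": float(sec.mean()),
                "secondary_rmse_sd_mm": _sd(sec, population=False),
                "n_secondary": len(sec),
            }
        )
    df = pd.DataFrame(rows)
    counts = df["n_secondary"].to_numpy(float)
    sec_means = df["secondary_rmse_mean_mm"].to_numpy(float)
    all_secondary = np.concatenate(
        [[r.rmse for r in s.secondaries] for s in sessions]
    )
    pooled = {
        "case": "pooled",
        "primary_rmse_mm": float(df["primary_rmse_mm"].mean()),
        "secondary_rmse_mean_mm": float(np.average(sec_means, weights=counts)),
        "secondary_rmse_sd_mm": _sd(all_secondary, population=False),
        "n_secondary": int(counts.sum()),
    }
    df = pd.concat([df, pd.DataFrame([pooled])], ignore_index=True)
    df.attrs["primary_rmse_sd_sample_mm"] = _sd(
        df["primary_rmse_mm"].to_numpy(float)[:-1], population=False
    )
    df.attrs["primary_rmse_sd_population_mm"] = _sd(
        df["primary_rmse_mm"].to_numpy(float)[:-1], population=True
    )
    df.attrs["secondary_rmse_sd_population_mm"] = _sd(all_secondary, population=True)
    return df
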