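"""Craniometric outcome metrics from three labeled landmarks.

The interfrontal angle is the angle at the metopic-suture landmark (MSL)
between the segments to the left (LFL) and right (RFL) frontal landmarks;
the transverse forehead width is the LFL-RFL distance. Outcome error is
the absolute plan-vs-postop difference of each metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import LandmarkSet, ValidationError

__all__ = [
    "CraniometricLandmarks",
    "CraniometricMeasures",
    "interfrontal_angle",
    "transverse_forehead_width",
    "measure",
    "outcome_error",
    "outcome_table",
]

STAGES = ("preop", "plan", "postop")


@dataclass(frozen=True)
class CraniometricLandmarks:
    """LFL / RFL / MSL landmark triple in millimetres."""

    lfl: np.ndarray
    rfl: np.ndarray
    msl: np.ndarray

    def __post_init__(self) -> None:
        for name in ("lfl", "rfl", "msl"):
            v = np.asarray(getattr(self, name), float).reshape(3)
            if not np.all(np.isfinite(v)):
                raise ValidationError(f"{name} must be finite")
            object.__setattr__(self, name, v)
        if np.allclose(self.lfl, self.rfl):
            raise ValidationError("LFL and RFL coincide")
        if np.allclose(self.msl, self.lfl) or np.allclose(self.msl, self.rfl):
            raise ValidationError("MSL coincides with a lateral landmark")

    @classmethod
    def from_landmark_set(cls, landmarks: LandmarkSet) -> "CraniometricLandmarks":
        return cls(landmarks["LFL"], landmarks["RFL"], landmarks["MSL"])


@dataclass(frozen=True)
class CraniometricMeasures:
    interfrontal_angle_deg: float
    transverse_width_mm: float
    stage: str

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if not (0 < self.interfrontal_angle_deg <= 180):
            raise ValidationError("interfrontal angle must be in (0, 180]")
        if self.transverse_width_mm <= 0:
            raise ValidationError("transverse width must be > 0")


def interfrontal_angle(lm: CraniometricLandmarks) -> float:
    """Angle (degrees) at MSL between MSL->LFL and MSL->RFL.

    Computed with atan2 of the cross-product norm and the dot product,
    which stays accurate near 0 and 180 degrees where acos loses precision.
    """
    u = lm.lfl - lm.msl
    v = lm.rfl - lm.msl
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValidationError("zero-length frontal segment")
    angle = np.degrees(np.arctan2(np.linalg.norm(np.cross(u, v)), np.dot(u, v)))
    return float(angle)


def transverse_forehead_width(lm: CraniometricLandmarks) -> float:
    """Euclidean LFL-RFL distance in millimetres."""
    width = float(np.linalg.norm(lm.lfl - lm.rfl))
    if width == 0:
        raise ValidationError("coincident lateral landmarks")
    return width


def measure(lm: CraniometricLandmarks, stage: str) -> CraniometricMeasures:
    """Both metrics for one stage."""
    return CraniometricMeasures(
        interfrontal_angle_deg=interfrontal_angle(lm),
        transverse_width_mm=transverse_forehead_width(lm),
        stage=stage,
    )


def outcome_error(
    plan: CraniometricMeasures, postop: CraniometricMeasures
) -> tuple[float, float]:
    """Absolute plan-vs-postop differences: (angle error deg, width error mm)."""
    if plan.stage != "plan" or postop.stage != "postop":
        raise ValidationError(
            f"expected stages (plan, postop), got ({plan.stage!r}, {postop.stage!r})"
        )
    return (
        abs(plan.interfrontal_angle_deg - postop.interfrontal_angle_deg),
        abs(plan.transverse_width_mm - postop.transverse_width_mm),
    )


def outcome_table(
    cases: list[tuple[str, CraniometricMeasures, CraniometricMeasures, CraniometricMeasures]],
) -> pd.DataFrame:
    """Per-case stage metrics and outcome errors, with mean errors in attrs.

    ``cases`` holds (case_id, preop, plan, postop) tuples. The
    ``undercorrected`` flag marks cases whose postoperative angle and
    width both fall short of the plan.
    """
    if not cases:
        raise ValidationError("no cases")
    rows = []
    for case_id, preop, plan, postop in cases:
        for m, expected in ((preop, "preop"), (plan, "plan"), (postop, "postop")):
            if m.stage != expected:
                raise ValidationError(
                    f"case {case_id!r}: expected stage {expected!r}, got {m.stage!r}"
                )
        angle_err, width_err = outcome_error(plan, postop)
        rows.append(
            {
                "case": case_id,
                "angle_preop_deg": preop.interfrontal_angle_deg,
                "angle_plan_deg": plan.interfrontal_angle_deg,
                "angle_postop_deg": postop.interfrontal_angle_deg,
                "width_preop_mm": preop.transverse_width_mm,
                "width_plan_mm": plan.transverse_width_mm,
                "width_postop_mm": postop.transverse_width_mm,
                "angle_error_deg": angle_err,
                "width_error_mm": width_err,
                "undercorrected": (
                    postop.interfrontal_angle_deg < plan.interfrontal_angle_deg
                    and postop.transverse_width_mm < plan.transverse_width_mm
                ),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["mean_angle_error_deg"] = float(df["angle_error_deg"].mean())
    df.attrs["mean_width_error_mm"] = float(df["width_error_mm"].mean())
    return df
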