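"""Anatomical landmarks and small vector-geometry helpers.

Landmarks (head center, neck axis, shaft axis) drive stance alignment, lesion
placement and fracture-region labelling.  For synthetic phantoms they come
from ground truth; for real scans they must be supplied by the user.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Landmarks", "unit", "angle_between_deg", "rotation_matrix"]


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length direction vector")
    return v / n


def angle_between_deg(a: np.ndarray, b: np.ndarray) -> float:
    c = float(np.clip(np.dot(unit(a), unit(b)), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation about ``axis`` by ``angle_deg`` (right-handed)."""
    k = unit(axis)
    t = np.radians(angle_deg)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


@dataclass
class Landmarks:
    """Proximal-femur landmark set in world mm.

    ``neck_dir`` points from the neck base toward the head center;
    ``shaft_dir`` points distal → proximal.  The CCD angle is the angle at the
    axis intersection between the neck axis (toward the head) and the shaft
    axis (toward distal).
    """

    head_center: np.ndarray
    neck_base: np.ndarray
    neck_dir: np.ndarray
    shaft_point: np.ndarray  # a distal point on the shaft axis
    shaft_dir: np.ndarray
    head_radius: float
    neck_length: float

    def __post_init__(self) -> None:
        self.head_center = np.asarray(self.head_center, dtype=float)
        self.neck_base = np.asarray(self.neck_base, dtype=float)
        self.shaft_point = np.asarray(self.shaft_point, dtype=float)
        self.neck_dir = unit(self.neck_dir)
        self.shaft_dir = unit(self.shaft_dir)

    @property
    def junction(self) -> np.ndarray:
        """Head–neck junction: neck-axis point on the head sphere surface."""
        return self.head_center - self.head_radius * self.neck_dir

    @property
    def ccd_angle(self) -> float:
        return angle_between_deg(self.neck_dir, -self.shaft_dir)

    def inferomedial_dir(self) -> np.ndarray:
        """In-plane direction from the neck axis toward the shaft's distal side."""
        d = -self.shaft_dir  # toward distal
        perp = d - np.dot(d, self.neck_dir) * self.neck_dir
        return unit(perp)

    def superolateral_dir(self) -> np.ndarray:
        return -self.inferomedial_dir()

    def transformed(self, R: np.ndarray, center: np.ndarray) -> "Landmarks":
        center = np.asarray(center, dtype=float)

        def pt(p):
            return R @ (p - center) + center

        return Landmarks(
            head_center=pt(self.head_center),
            neck_base=pt(self.neck_base),
            neck_dir=R @ self.neck_dir,
            shaft_point=pt(self.shaft_point),
            shaft_dir=R @ self.shaft_dir,
            head_radius=self.head_radius,
            neck_length=self.neck_length,
        )

    def to_json(self, path: str | Path) -> None:
        d = {
            "head_center_mm": self.head_center.tolist(),
            "neck_base_mm": self.neck_base.tolist(),
            "neck_dir": self.neck_dir.tolist(),
            "shaft_point_mm": self.shaft_point.tolist(),
            "shaft_dir": self.shaft_dir.tolist(),
            "head_radius_mm": self.head_radius,
            "neck_length_mm": self.neck_length,
        }
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "Landmarks":
        d = json.loads(Path(path).read_text())
        return cls(
            head_center=d["head_center_mm"],
            neck_base=d["neck_base_mm"],
            neck_dir=d["neck_dir"],
            shaft_point=d["shaft_point_mm"],
            shaft_dir=d["shaft_dir"],
            head_radius=d["head_radius_mm"],
            neck_length=d["neck_length_mm"],
        )
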