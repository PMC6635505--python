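"""Synthetic QCT volumes of a parametric proximal femur with calibration inserts.

The generator stands in for a cadaveric scan: a constructive-solid femur
(head sphere + neck cylinder at the CCD angle + vertical shaft cylinder) is
immersed in saline above a row of calibration-phantom insert cylinders of
known equivalent BMD.  The femoral-neck cortex is angularly graded — thick on
the inferomedial side, thin superolaterally — reproducing the asymmetry that
makes inferomedial osteolytic lesions mechanically worse than superolateral
ones.  Each material has a known BMD; HU values follow the affine scanner map
``HU = hu_slope * BMD + hu_intercept`` plus Gaussian noise, with partial
volume at boundaries approximated by 2×2×2 sub-voxel sampling.

Ground truth (landmarks, bone mask, region atlas, true calibration, insert
ROIs) is returned alongside, replacing the manual inputs an operator would
provide for a real scan (ROI selection, marker annotation).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .calib import DensityImage
from .geometry import Landmarks, unit

__all__ = [
    "PhantomSpec",
    "PhantomGroundTruth",
    "PhantomGeometryError",
    "default_spec",
    "generate_phantom",
    "phantom_region_atlas",
    "REGION_LABELS",
]

#: Atlas label encoding (0 = not bone).
REGION_LABELS = {1: "subcapital", 2: "neck", 3: "intertrochanteric"}

#: Fractions of the junction→neck-base distance separating subcapital/neck and
#: neck/intertrochanteric zones (configurable via phantom_region_atlas).  The
#: neck region extends to the neck base (fraction 1.0); everything distal of
#: the base — trochanters and shaft — is intertrochanteric.
ATLAS_FRACTIONS = (0.35, 1.0)


class PhantomGeometryError(ValueError):
    """Spec violates an invariant or describes a non-constructible femur."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric femur + phantom description (all lengths mm, BMD mg HA/cm³)."""

    head_radius: float = 26.0
    neck_radius: float = 17.0
    neck_length: float = 55.0
    shaft_radius: float = 16.0
    shaft_length: float = 80.0
    ccd_angle: float = 125.0
    cortical_thickness_inferomedial: float = 3.5
    cortical_thickness_superolateral: float = 1.0
    shaft_cortical_thickness: float = 5.0
    trabecular_bmd: float = 200.0
    cortical_bmd: float = 1100.0
    saline_bmd: float = 0.0
    insert_bmds: tuple[float, ...] = (0.0, 100.0, 200.0, 400.0, 800.0)
    hu_slope: float = 1.2  # HU per (mg HA/cm³)
    hu_intercept: float = -5.0  # HU
    noise_sd: float = 10.0  # HU
    voxel_spacing: tuple[float, float, float] = (0.33, 0.33, 1.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        pos = {
            "head_radius": self.head_radius,
            "neck_radius": self.neck_radius,
            "neck_length": self.neck_length,
            "shaft_radius": self.shaft_radius,
            "shaft_length": self.shaft_length,
            "cortical_thickness_inferomedial": self.cortical_thickness_inferomedial,
            "cortical_thickness_superolateral": self.cortical_thickness_superolateral,
            "shaft_cortical_thickness": self.shaft_cortical_thickness,
        }
        for name, v in pos.items():
            if v <= 0:
                raise PhantomGeometryError(f"{name} must be > 0, got {v}")
        if max(self.cortical_thickness_inferomedial,
               self.cortical_thickness_superolateral) >= self.neck_radius:
            raise PhantomGeometryError("cortical thicknesses must be < neck_radius")
        if not (90.0 < self.ccd_angle < 180.0):
            raise PhantomGeometryError(
                f"ccd_angle must lie in (90, 180) degrees, got {self.ccd_angle}")
        if len(set(self.insert_bmds)) < 2:
            raise PhantomGeometryError("insert_bmds needs >= 2 distinct values")
        if self.trabecular_bmd >= self.cortical_bmd:
            raise PhantomGeometryError("trabecular_bmd must be < cortical_bmd")
        if any(s <= 0 for s in self.voxel_spacing):
            raise PhantomGeometryError("voxel_spacing components must be > 0")
        if self.neck_length <= self.head_radius:
            raise PhantomGeometryError(
                "neck does not reach the head: neck_length must exceed head_radius")

    # -- derived geometry (world mm; shaft vertical along +z) ----------------

    @property
    def neck_base(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.shaft_length])

    @property
    def neck_dir(self) -> np.ndarray:
        # angle of the neck axis from +z is 180° − CCD (CCD measured to the
        # distal shaft direction)
        t = np.radians(180.0 - self.ccd_angle)
        return np.array([np.sin(t), 0.0, np.cos(t)])

    @property
    def head_center(self) -> np.ndarray:
        return self.neck_base + self.neck_length * self.neck_dir

    def landmarks(self) -> Landmarks:
        return Landmarks(
            head_center=self.head_center,
            neck_base=self.neck_base,
            neck_dir=self.neck_dir,
            shaft_point=np.zeros(3),
            shaft_dir=np.array([0.0, 0.0, 1.0]),
            head_radius=self.head_radius,
            neck_length=self.neck_length,
        )

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        import yaml

        d = yaml.safe_load(Path(path).read_text())
        if "insert_bmds" in d:
            d["insert_bmds"] = tuple(d["insert_bmds"])
        if "voxel_spacing" in d:
            d["voxel_spacing"] = tuple(d["voxel_spacing"])
        return cls(**d)


def default_spec(scale: float = 1.0,
                 voxel_spacing: tuple[float, float, float] | None = None,
                 **overrides) -> PhantomSpec:
    """Default adult proximal femur, optionally geometrically scaled.

    ``scale`` multiplies every length/thickness (densities, calibration and
    noise are unchanged); ``voxel_spacing`` overrides the native QCT spacing.
    Used to build reduced-size test problems from one parameterisation.
    """
    base = PhantomSpec()
    kw = {}
    for f in dataclasses.fields(PhantomSpec):
        v = getattr(base, f.name)
        if f.name in (
            "head_radius", "neck_radius", "neck_length", "shaft_radius",
            "shaft_length", "cortical_thickness_inferomedial",
            "cortical_thickness_superolateral", "shaft_cortical_thickness",
        ):
            v = v * scale
        kw[f.name] = v
    if voxel_spacing is not None:
        kw["voxel_spacing"] = tuple(voxel_spacing)
    kw.update(overrides)
    return PhantomSpec(**kw)


def sample_spec(rng: np.random.Generator | int,
                scale: float = 1.0,
                voxel_spacing: tuple[float, float, float] | None = None) -> PhantomSpec:
    """Draw a random anatomically plausible femur variation.

    Geometry (±15%), CCD angle (120–135°), cortical thicknesses (±30%) and
    densities (trabecular 140–260, cortical 950–1250 mg HA/cm³) vary around
    the defaults; calibration and noise stay at their defaults.  Used for
    randomized batches (e.g. the stiffness–strength correlation study).
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    g = lambda lo, hi: float(rng.uniform(lo, hi))
    return default_spec(
        scale=scale * g(0.85, 1.15),
        voxel_spacing=voxel_spacing,
        ccd_angle=g(120.0, 135.0),
        cortical_thickness_inferomedial=3.5 * scale * g(0.7, 1.3),
        cortical_thickness_superolateral=1.0 * scale * g(0.7, 1.3),
        shaft_cortical_thickness=5.0 * scale * g(0.8, 1.2),
        trabecular_bmd=g(140.0, 260.0),
        cortical_bmd=g(950.0, 1250.0),
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )


@dataclass
class PhantomGroundTruth:
    """Everything an operator would supply manually, known exactly here."""

    landmarks: Landmarks
    bone_mask: np.ndarray  # bool, fine grid
    region_atlas: np.ndarray  # uint8, fine grid (REGION_LABELS, 0 = not bone)
    hu_slope: float
    hu_intercept: float
    insert_rois: list[np.ndarray] = field(default_factory=list)  # eroded pure masks
    insert_bmds: tuple[float, ...] = ()
    spec: PhantomSpec | None = None

    def save(self, out_dir: str | Path) -> None:
        from . import calib

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.landmarks.to_json(out_dir / "landmarks.json")
        meta = {
            "hu_slope": self.hu_slope,
            "hu_intercept": self.hu_intercept,
            "insert_bmds": list(self.insert_bmds),
            "region_labels": {str(k): v for k, v in REGION_LABELS.items()},
        }
        (out_dir / "ground_truth.json").write_text(json.dumps(meta, indent=2))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


class _FemurGeometry:
    """Vectorized material classification for the constructive-solid femur."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        self.nb = spec.neck_base
        self.nd = spec.neck_dir
        self.hc = spec.head_center
        # inferomedial direction around the neck axis: component of the distal
        # shaft direction (−z) perpendicular to the neck axis
        d = np.array([0.0, 0.0, -1.0])
        self.e_inf = unit(d - np.dot(d, self.nd) * self.nd)
        self.e_perp2 = unit(np.cross(self.nd, self.e_inf))
        # insert cylinders (axis along y) below the femur; the calibration
        # phantom is fixed hardware, so its dimensions do not scale with bone
        self.insert_radius = 6.0
        self.insert_halflen = 18.0
        n = len(spec.insert_bmds)
        x_lo = -spec.shaft_radius
        x_hi = float(self.hc[0] + spec.head_radius)
        needed = n * (2 * self.insert_radius + 4.0)
        span = x_hi - x_lo
        if span < needed:  # widen the row symmetrically for small femora
            pad = (needed - span) / 2.0
            x_lo, x_hi = x_lo - pad, x_hi + pad
        centers = np.linspace(x_lo + self.insert_radius, x_hi - self.insert_radius, n)
        self.insert_z = -(4.0 + self.insert_radius)
        self.insert_x = centers

    def bounds(self, margin: float = 4.0) -> tuple[np.ndarray, np.ndarray]:
        sp = self.spec
        lo = np.array([
            min(-sp.shaft_radius, self.insert_x[0] - self.insert_radius) - margin,
            -(max(sp.head_radius, sp.shaft_radius, self.insert_halflen) + margin),
            self.insert_z - self.insert_radius - margin,
        ])
        hi = np.array([
            max(self.hc[0] + sp.head_radius, sp.shaft_radius,
                self.insert_x[-1] + self.insert_radius) + margin,
            max(sp.head_radius, sp.shaft_radius, self.insert_halflen) + margin,
            self.hc[2] + sp.head_radius + margin,
        ])
        return lo, hi

    def classify(self, X, Y, Z):
        """Return (bmd, is_bone) arrays for world-coordinate sample points."""
        sp = self.spec
        bmd = np.full(X.shape, sp.saline_bmd, dtype=np.float32)

        # inserts
        for xc, b in zip(self.insert_x, sp.insert_bmds):
            in_ins = (((X - xc) ** 2 + (Z - self.insert_z) ** 2)
                      <= self.insert_radius ** 2) & (np.abs(Y) <= self.insert_halflen)
            bmd[in_ins] = b

        # head sphere
        dh2 = (X - self.hc[0]) ** 2 + (Y - self.hc[1]) ** 2 + (Z - self.hc[2]) ** 2
        in_head = dh2 <= sp.head_radius ** 2
        core_head = dh2 <= (sp.head_radius - sp.cortical_thickness_superolateral) ** 2

        # shaft cylinder
        rs2 = X ** 2 + Y ** 2
        in_shaft = (rs2 <= sp.shaft_radius ** 2) & (Z >= 0.0) & (Z <= sp.shaft_length)
        core_shaft = in_shaft & (rs2 <= (sp.shaft_radius - sp.shaft_cortical_thickness) ** 2)

        # neck cylinder with angularly graded cortex
        px, py, pz = X - self.nb[0], Y - self.nb[1], Z - self.nb[2]
        s_ax = px * self.nd[0] + py * self.nd[1] + pz * self.nd[2]
        qx = px - s_ax * self.nd[0]
        qy = py - s_ax * self.nd[1]
        qz = pz - s_ax * self.nd[2]
        rho2 = qx ** 2 + qy ** 2 + qz ** 2
        in_neck = (s_ax >= 0) & (s_ax <= sp.neck_length) & (rho2 <= sp.neck_radius ** 2)
        rho = np.sqrt(rho2, where=in_neck, out=np.zeros_like(rho2))
        with np.errstate(invalid="ignore", divide="ignore"):
            cosphi = np.where(rho > 0,
                              (qx * self.e_inf[0] + qy * self.e_inf[1]
                               + qz * self.e_inf[2]) / np.maximum(rho, 1e-12),
                              1.0)
        t_sl = sp.cortical_thickness_superolateral
        t_im = sp.cortical_thickness_inferomedial
        thickness = t_sl + (t_im - t_sl) * 0.5 * (1.0 + cosphi)
        core_neck = in_neck & (rho <= sp.neck_radius - thickness)

        is_bone = in_head | in_shaft | in_neck
        core = core_head | core_shaft | core_neck
        bmd[is_bone] = sp.cortical_bmd
        bmd[core] = sp.trabecular_bmd
        return bmd, is_bone


def _fine_grid(spec: PhantomSpec):
    geom = _FemurGeometry(spec)
    lo, hi = geom.bounds()
    sp = np.asarray(spec.voxel_spacing)
    n = np.ceil((hi - lo) / sp).astype(int)
    origin = lo + sp / 2.0
    return geom, origin, n


def generate_phantom(spec: PhantomSpec) -> tuple[DensityImage, PhantomGroundTruth]:
    """Generate the HU volume and its exact ground truth.

    Partial volume at material boundaries is approximated by averaging a
    2×2×2 sub-voxel sampling of the constructive geometry; Gaussian HU noise
    (sd = ``spec.noise_sd``) is added reproducibly from ``spec.rng_seed``.
    """
    geom, origin, n = _fine_grid(spec)
    nx, ny, nz = (int(v) for v in n)
    sp = np.asarray(spec.voxel_spacing)

    # refined (2x) axes: voxel center ± spacing/4
    def refined_axis(o, s, count):
        c = o + s * np.arange(count)
        return np.stack([c - s / 4, c + s / 4], axis=1).ravel()

    xr = refined_axis(origin[0], sp[0], nx).astype(np.float32)
    yr = refined_axis(origin[1], sp[1], ny).astype(np.float32)
    zr = refined_axis(origin[2], sp[2], nz).astype(np.float32)

    bmd_fine = np.empty((nx, ny, nz), dtype=np.float32)
    bone_frac = np.empty((nx, ny, nz), dtype=np.float32)
    chunk = max(1, int(4e6 // (len(xr) * len(yr))))  # fine-z slices per slab
    for z0 in range(0, nz, chunk):
        z1 = min(nz, z0 + chunk)
        Zr = zr[2 * z0:2 * z1]
        X = xr[:, None, None]
        Y = yr[None, :, None]
        Z = Zr[None, None, :]
        bmd_r, bone_r = geom.classify(*np.broadcast_arrays(X, Y, Z))
        nzc = z1 - z0
        bmd_fine[:, :, z0:z1] = bmd_r.reshape(nx, 2, ny, 2, nzc, 2).mean(axis=(1, 3, 5))
        bone_frac[:, :, z0:z1] = bone_r.astype(np.float32).reshape(
            nx, 2, ny, 2, nzc, 2).mean(axis=(1, 3, 5))

    hu = spec.hu_slope * bmd_fine.astype(np.float64) + spec.hu_intercept
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        hu = hu + rng.normal(0.0, spec.noise_sd, size=hu.shape)

    image = DensityImage(values=hu, spacing=tuple(sp), origin=tuple(origin), unit="HU")
    bone_mask = bone_frac >= 0.5

    # eroded, purely-inside insert ROIs (avoid partial-volume rim)
    from scipy import ndimage

    insert_rois = []
    Xc = (origin[0] + sp[0] * np.arange(nx))[:, None, None]
    Yc = (origin[1] + sp[1] * np.arange(ny))[None, :, None]
    Zc = (origin[2] + sp[2] * np.arange(nz))[None, None, :]
    shrink = 1.5 * float(np.max(sp))
    for xc in geom.insert_x:
        roi = (((Xc - xc) ** 2 + (Zc - geom.insert_z) ** 2)
               <= (geom.insert_radius - shrink) ** 2) \
            & (np.abs(Yc) <= geom.insert_halflen - shrink)
        insert_rois.append(np.broadcast_to(roi, (nx, ny, nz)).copy())

    atlas = phantom_region_atlas(spec, bone_mask=bone_mask, origin=tuple(origin))
    gt = PhantomGroundTruth(
        landmarks=spec.landmarks(),
        bone_mask=bone_mask,
        region_atlas=atlas,
        hu_slope=spec.hu_slope,
        hu_intercept=spec.hu_intercept,
        insert_rois=insert_rois,
        insert_bmds=tuple(spec.insert_bmds),
        spec=spec,
    )
    return image, gt


def phantom_region_atlas(
    spec: PhantomSpec,
    bone_mask: np.ndarray | None = None,
    origin: tuple[float, float, float] | None = None,
    fractions: tuple[float, float] = ATLAS_FRACTIONS,
) -> np.ndarray:
    """Label every bone voxel subcapital (1) / neck (2) / intertrochanteric (3).

    Labels follow the signed distance of the voxel's projection onto the neck
    axis from the head–neck junction (positive toward the shaft), cut at
    ``fractions`` of the junction→neck-base distance.  Head voxels (negative
    distance) are subcapital; trochanter/shaft voxels fall beyond the second
    cut.  The three labels exactly partition the bone mask.
    """
    if bone_mask is None or origin is None:
        image, gt = generate_phantom(dataclasses.replace(spec, noise_sd=0.0))
        if bone_mask is None:
            return gt.region_atlas
        origin = image.origin  # pragma: no cover
    lm = spec.landmarks()
    toward_shaft = -lm.neck_dir
    junction = lm.junction
    L_eff = spec.neck_length - spec.head_radius
    s1, s2 = fractions[0] * L_eff, fractions[1] * L_eff

    nx, ny, nz = bone_mask.shape
    sp = np.asarray(spec.voxel_spacing)
    idx = np.argwhere(bone_mask)
    pts = np.asarray(origin) + idx * sp
    s = (pts - junction) @ toward_shaft
    labels = np.where(s < s1, 1, np.where(s < s2, 2, 3)).astype(np.uint8)
    atlas = np.zeros(bone_mask.shape, dtype=np.uint8)
    atlas[idx[:, 0], idx[:, 1], idx[:, 2]] = labels
    return atlas


def element_region_labels(
    centers: np.ndarray,
    landmarks: Landmarks,
    fractions: tuple[float, float] = ATLAS_FRACTIONS,
) -> np.ndarray:
    """Region label (1/2/3) for arbitrary points, e.g. coarse element centers."""
    toward_shaft = -landmarks.neck_dir
    L_eff = landmarks.neck_length - landmarks.head_radius
    s1, s2 = fractions[0] * L_eff, fractions[1] * L_eff
    s = (np.atleast_2d(centers) - landmarks.junction) @ toward_shaft
    return np.where(s < s1, 1, np.where(s < s2, 2, 3)).astype(np.uint8)
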