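"""Image I/O, HU → BMD calibration and densitometric summaries.

A quantitative CT scan carries a calibration phantom with inserts of known
equivalent bone mineral density (BMD, mg HA/cm³).  A linear law fitted to the
insert ROI means converts the Hounsfield-unit (HU) grayscale to BMD; the
calibrated range is clamped to suppress residual air and metal/beam artefacts.
From a calibrated image and a bone mask the usual densitometric summaries
(vBMD, BMC) follow.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "DensityImage",
    "CalibrationLaw",
    "DensitometryResult",
    "CalibrationError",
    "ImageReadError",
    "BMD_CLAMP",
    "read_image",
    "write_image",
    "fit_calibration",
    "apply_calibration",
    "compute_densitometry",
]

#: BMD clamp applied after calibration, mg HA/cm³ (restricts residual air and
#: other artefacts); overridable per call.
BMD_CLAMP = (-100.0, 1400.0)


class CalibrationError(ValueError):
    """Degenerate or implausible calibration input."""


class ImageReadError(IOError):
    """File unreadable or geometry metadata missing/inconsistent."""


@dataclass
class DensityImage:
    """3-D scalar grid with voxel geometry.

    ``values`` is indexed ``[x, y, z]`` (x = left–right, y = anterior–
    posterior, z = caudal–cranial).  World coordinates follow the voxel-center
    convention: ``world = origin + index * spacing``.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
    spacing : 3-tuple of mm, all > 0
    origin : 3-tuple of mm
    unit : {"HU", "mgHA_cm3"}
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit: str = "HU"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        if self.unit not in ("HU", "mgHA_cm3"):
            raise ValueError(f"unknown unit {self.unit!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Voxel index (possibly fractional) → world mm, voxel-center convention."""
        return np.asarray(self.origin) + np.asarray(idx, dtype=float) * np.asarray(self.spacing)

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def copy_with(self, **kw) -> "DensityImage":
        return replace(self, **kw)


@dataclass(frozen=True)
class CalibrationLaw:
    """Linear HU → BMD law: ``bmd = slope * hu + intercept``.

    slope is in (mg HA/cm³) per HU and must be positive (denser tissue is
    brighter on CT); ``fit_r2`` is the coefficient of determination of the
    insert regression and ``n_points`` the number of inserts used.
    """

    slope: float
    intercept: float
    fit_r2: float = 1.0
    n_points: int = 2

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise CalibrationError(
                f"implausible calibration: slope must be > 0, got {self.slope:g}"
            )
        if self.n_points < 2:
            raise CalibrationError("calibration needs at least 2 insert points")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "slope_mgHAcm3_per_HU": self.slope,
                    "intercept_mgHAcm3": self.intercept,
                    "fit_r2": self.fit_r2,
                    "n_points": self.n_points,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationLaw":
        d = json.loads(Path(path).read_text())
        return cls(
            slope=d["slope_mgHAcm3_per_HU"],
            intercept=d["intercept_mgHAcm3"],
            fit_r2=d.get("fit_r2", 1.0),
            n_points=d.get("n_points", 2),
        )


@dataclass(frozen=True)
class DensitometryResult:
    vBMD: float  # mg/cm³, mean over the mask
    BMC: float  # g
    mask_volume: float  # cm³


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _sitk_to_image(img) -> DensityImage:
    import SimpleITK as sitk

    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    values = np.ascontiguousarray(arr.transpose(2, 1, 0))
    return DensityImage(
        values=values,
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
        unit="HU",
    )


def _read_dicom_series(path: Path) -> DensityImage:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".dcm", ".ima", ""))
    slices = []
    for p in files:
        if not p.is_file():
            continue
        try:
            ds = pydicom.dcmread(p)
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if len(slices) < 2:
        raise ImageReadError(f"fewer than 2 readable DICOM slices under {path}")
    for attr in ("ImagePositionPatient", "PixelSpacing"):
        for ds in slices:
            if not hasattr(ds, attr):
                raise ImageReadError(f"DICOM slice missing geometry field {attr}")
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    dz = np.diff(zs)
    if np.any(dz <= 0):
        raise ImageReadError("DICOM series has duplicate slice positions")
    if np.ptp(dz) > 1e-3 * dz.mean():
        raise ImageReadError(
            f"DICOM series has inconsistent slice spacing (field ImagePositionPatient): "
            f"range {dz.min():g}–{dz.max():g} mm"
        )
    ps = slices[0].PixelSpacing
    stack = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        inter = float(getattr(ds, "RescaleIntercept", 0.0))
        stack.append(arr * slope + inter)
    vol = np.stack(stack, axis=0)  # (z, rows=y, cols=x)
    values = np.ascontiguousarray(vol.transpose(2, 1, 0))
    origin = [float(v) for v in slices[0].ImagePositionPatient]
    return DensityImage(
        values=values,
        spacing=(float(ps[1]), float(ps[0]), float(dz.mean())),
        origin=tuple(origin),
        unit="HU",
    )


def read_image(path: str | Path, format: str | None = None) -> DensityImage:
    """Read NIfTI (.nii/.nii.gz), MetaImage (.mha/.mhd) or a DICOM directory.

    The unit is assumed HU unless a JSON sidecar ``<path>.unit.json`` declares
    otherwise (written by :func:`write_image` for calibrated volumes).
    """
    import SimpleITK as sitk

    path = Path(path)
    if not path.exists():
        raise ImageReadError(f"no such file or directory: {path}")
    fmt = format
    if fmt is None:
        if path.is_dir():
            fmt = "dicom"
        elif path.name.endswith((".nii", ".nii.gz")):
            fmt = "nifti"
        elif path.suffix in (".mha", ".mhd"):
            fmt = "metaimage"
        else:
            raise ImageReadError(f"cannot infer image format from {path.name!r}")
    if fmt == "dicom":
        img = _read_dicom_series(path)
    else:
        try:
            img = _sitk_to_image(sitk.ReadImage(str(path)))
        except RuntimeError as exc:  # pragma: no cover - sitk message passthrough
            raise ImageReadError(f"failed to read {path}: {exc}") from exc
    sidecar = path.with_name(path.name + ".unit.json")
    if sidecar.exists():
        img.unit = json.loads(sidecar.read_text()).get("unit", img.unit)
    return img


def write_image(image: DensityImage, path: str | Path) -> None:
    """Write NIfTI or MetaImage; a sidecar records a non-HU unit."""
    import SimpleITK as sitk

    path = Path(path)
    out = sitk.GetImageFromArray(np.ascontiguousarray(image.values.transpose(2, 1, 0)))
    out.SetSpacing(image.spacing)
    out.SetOrigin(image.origin)
    sitk.WriteImage(out, str(path))
    if image.unit != "HU":
        path.with_name(path.name + ".unit.json").write_text(json.dumps({"unit": image.unit}))


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


def fit_calibration(
    image: DensityImage,
    insert_rois: Sequence[np.ndarray],
    known_bmds: Sequence[float],
) -> CalibrationLaw:
    """Ordinary least squares of known insert BMD on mean ROI HU.

    Regressing on ROI *means* (not voxelwise) suppresses image noise; with k
    inserts the fit has k points.  A non-positive slope is rejected as an
    implausible calibration.
    """
    if image.unit != "HU":
        raise CalibrationError("calibration must be fitted on an HU image")
    if len(insert_rois) != len(known_bmds):
        raise CalibrationError("insert_rois and known_bmds length mismatch")
    if len(insert_rois) < 2:
        raise CalibrationError("need at least 2 insert ROIs")
    seen = np.zeros(image.shape, dtype=bool)
    mean_hu = []
    for roi in insert_rois:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != image.shape:
            raise CalibrationError("ROI grid does not match image grid")
        if not roi.any():
            raise CalibrationError("empty insert ROI")
        if (seen & roi).any():
            raise CalibrationError("insert ROIs overlap")
        seen |= roi
        mean_hu.append(float(image.values[roi].mean()))
    hu = np.asarray(mean_hu, dtype=float)
    bmd = np.asarray(known_bmds, dtype=float)
    if np.ptp(hu) == 0:
        raise CalibrationError("degenerate calibration input: all ROI mean HU equal")
    slope, intercept = np.polyfit(hu, bmd, 1)
    pred = slope * hu + intercept
    ss_res = float(np.sum((bmd - pred) ** 2))
    ss_tot = float(np.sum((bmd - bmd.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationLaw(slope=float(slope), intercept=float(intercept),
                          fit_r2=r2, n_points=len(hu))


def apply_calibration(
    image: DensityImage,
    law: CalibrationLaw,
    clamp: tuple[float, float] = BMD_CLAMP,
) -> DensityImage:
    """Map HU → BMD and clamp to ``clamp`` (default −100…1400 mg HA/cm³)."""
    if image.unit != "HU":
        raise CalibrationError("image is already calibrated; refusing double calibration")
    lo, hi = clamp
    bmd = np.clip(law.slope * image.values.astype(np.float64) + law.intercept, lo, hi)
    return image.copy_with(values=bmd, unit="mgHA_cm3")


def compute_densitometry(image: DensityImage, mask: np.ndarray) -> DensitometryResult:
    """vBMD (masked mean, mg/cm³), mask volume (cm³) and BMC (g)."""
    if image.unit != "mgHA_cm3":
        raise ValueError("densitometry requires a calibrated (mgHA_cm3) image")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask grid does not match image grid")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    vbmd = float(image.values[mask].mean())
    vol_cm3 = n * image.voxel_volume_mm3 / 1000.0
    bmc_g = vbmd * vol_cm3 / 1000.0  # mg → g
    return DensitometryResult(vBMD=vbmd, BMC=bmc_g, mask_volume=vol_cm3)
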