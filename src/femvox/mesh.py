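"""From calibrated image to homogenized voxel hexahedral mesh.

Processing order: calibrate → clamp (module calib) → stance alignment →
fill-algorithm segmentation → coarsening to 3 mm → BMD→BV/TV mapping →
voxel-to-hexahedron conversion with polyurethane embedding and steel plate.
Virtual osteolytic lesions (angular wedge of the neck milled to saline) are
inserted on the calibrated fine image before alignment, mirroring physical
milling before the second scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .calib import DensityImage
from .geometry import Landmarks, angle_between_deg, rotation_matrix, unit

__all__ = [
    "BoneMask",
    "HexMesh",
    "LesionSpec",
    "EmbeddingConfig",
    "SegmentationError",
    "MeshError",
    "MATERIAL_BONE",
    "MATERIAL_PU",
    "MATERIAL_STEEL",
    "segment_bone",
    "align_one_legged_stance",
    "coarsen",
    "bmd_to_bvtv",
    "build_hex_mesh",
    "insert_lesion",
    "wedge_angle_deg",
    "write_vtu",
    "write_text_mesh",
]

MATERIAL_BONE, MATERIAL_PU, MATERIAL_STEEL = 0, 1, 2
MATERIAL_NAMES = {MATERIAL_BONE: "bone", MATERIAL_PU: "polyurethane",
                  MATERIAL_STEEL: "steel"}

#: BMD → BV/TV linear law (percent scale): BV/TV[%] = 0.093·BMD + 1.077.
BVTV_SLOPE = 0.093
BVTV_INTERCEPT = 1.077
#: Elements whose BV/TV falls below this are treated as void and removed.
RHO_MIN = 0.01


class SegmentationError(ValueError):
    pass


class MeshError(ValueError):
    pass


@dataclass
class BoneMask:
    """Binary segmentation aligned to a DensityImage grid (6-connectivity)."""

    mask: np.ndarray
    connectivity: int = 6

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def segment_bone(image: DensityImage, threshold: float) -> BoneMask:
    """Fill-algorithm segmentation of the external bone contour.

    Binarize at ``threshold`` (mg HA/cm³), flood-fill the background from the
    image border (6-connectivity) and take everything unreachable as bone —
    marrow cavities are thereby included.  Only the largest connected
    component is kept.
    """
    if image.unit != "mgHA_cm3":
        raise SegmentationError("segmentation expects a calibrated image")
    binary = image.values >= threshold
    if not binary.any():
        raise SegmentationError(
            f"no voxels at or above threshold {threshold:g} mg HA/cm3")
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    # background reachable from the border without crossing bone
    bg = ~binary
    labels, n = ndimage.label(bg, structure=structure)
    border_labels = set()
    for axis in range(3):
        for sl in (0, -1):
            idx = [slice(None)] * 3
            idx[axis] = sl
            border_labels.update(np.unique(labels[tuple(idx)]))
    border_labels.discard(0)
    reachable = np.isin(labels, sorted(border_labels))
    mask = ~reachable
    # largest connected component
    comp, nc = ndimage.label(mask, structure=structure)
    if nc == 0:
        raise SegmentationError(f"empty mask at threshold {threshold:g}")
    if nc > 1:
        sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, nc + 1))
        mask = comp == (1 + int(np.argmax(sizes)))
    return BoneMask(mask=mask)


# ---------------------------------------------------------------------------
# one-legged-stance alignment
# ---------------------------------------------------------------------------


def align_one_legged_stance(
    image: DensityImage,
    landmarks: Landmarks,
    target_angle_deg: float = 20.0,
    crop_mask: np.ndarray | None = None,
    margin_mm: float = 6.0,
    fill_value: float = 0.0,
    order: int = 1,
) -> tuple[DensityImage, Landmarks]:
    """Rigidly rotate so the shaft axis makes 20° with the vertical load axis.

    The rotation lies in the plane spanned by shaft and neck axes; its sense
    is chosen so the femoral head moves toward the vertical through the distal
    shaft (the stance configuration).  The image is resampled trilinearly and
    the landmarks transformed consistently.
    """
    s = landmarks.shaft_dir
    nvec = landmarks.neck_dir
    cross = np.cross(s, nvec)
    if np.linalg.norm(cross) < 1e-9:
        raise ValueError("degenerate landmarks: shaft and neck axes are collinear")
    k = unit(cross)
    z = np.array([0.0, 0.0, 1.0])
    # signed angle from shaft_dir to z about k (exact when z lies in the plane)
    alpha = np.degrees(np.arctan2(np.dot(np.cross(s, z), k), np.dot(s, z)))
    candidates = [alpha - target_angle_deg, alpha + target_angle_deg]
    center = np.asarray(landmarks.shaft_point, dtype=float)

    def head_offset(theta):
        R = rotation_matrix(k, theta)
        hc = R @ (landmarks.head_center - center) + center
        return np.hypot(hc[0] - center[0], hc[1] - center[1])

    theta = min(candidates, key=head_offset)
    if abs(theta) < 1e-9:
        return image.copy_with(values=image.values.copy()), landmarks.transformed(
            np.eye(3), center)
    R = rotation_matrix(k, theta)
    new_lm = landmarks.transformed(R, center)
    assert abs(angle_between_deg(new_lm.shaft_dir, z) - target_angle_deg) < 1e-6

    sp = np.asarray(image.spacing)
    origin = np.asarray(image.origin)
    if crop_mask is not None:
        idx = np.argwhere(crop_mask)
        lo_i, hi_i = idx.min(axis=0), idx.max(axis=0)
    else:
        lo_i = np.zeros(3)
        hi_i = np.asarray(image.shape) - 1
    corner_pts = []
    for ix in (lo_i[0], hi_i[0]):
        for iy in (lo_i[1], hi_i[1]):
            for iz in (lo_i[2], hi_i[2]):
                corner_pts.append(origin + np.array([ix, iy, iz]) * sp)
    corner_pts = np.array(corner_pts)
    rot_pts = (R @ (corner_pts - center).T).T + center
    lo_w = rot_pts.min(axis=0) - margin_mm
    hi_w = rot_pts.max(axis=0) + margin_mm
    out_shape = np.maximum(1, np.ceil((hi_w - lo_w) / sp).astype(int))
    out_origin = lo_w + sp / 2.0

    # map output index -> input index
    Rt = R.T
    M = (Rt * sp[None, :]) / sp[:, None]
    offset = (Rt @ (out_origin - center) + center - origin) / sp
    values = ndimage.affine_transform(
        image.values.astype(np.float64), M, offset=offset,
        output_shape=tuple(out_shape), order=order, mode="constant",
        cval=fill_value)
    out = DensityImage(values=values, spacing=tuple(sp),
                       origin=tuple(out_origin), unit=image.unit)
    return out, new_lm


# ---------------------------------------------------------------------------
# coarsening and BV/TV
# ---------------------------------------------------------------------------


def coarsen(
    image: DensityImage,
    mask: np.ndarray | BoneMask,
    target_spacing: float | tuple[float, float, float] = 3.0,
    fill_fraction: float = 0.5,
) -> tuple[DensityImage, np.ndarray]:
    """Coarsen to the model voxel size (default 3×3×3 mm).

    Each coarse voxel takes the mean of the *masked* fine voxels whose centers
    fall inside it; it enters the coarse mask iff its masked-volume fraction
    is at least ``fill_fraction``.
    """
    if isinstance(mask, BoneMask):
        mask = mask.mask
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask grid does not match image grid")
    tsp = np.broadcast_to(np.asarray(target_spacing, dtype=float), (3,)).copy()
    fsp = np.asarray(image.spacing)
    if np.any(tsp < fsp - 1e-12):
        raise ValueError(
            f"target spacing {tuple(tsp)} must be >= native spacing {image.spacing}")
    corner = np.asarray(image.origin) - fsp / 2.0
    nx, ny, nz = image.shape
    ci = [np.clip((( (np.arange(n) + 0.5) * fsp[a]) // tsp[a]).astype(int), 0, None)
          for a, n in enumerate((nx, ny, nz))]
    n_coarse = [int(c.max()) + 1 for c in ci]
    flat = (ci[0][:, None, None] * (n_coarse[1] * n_coarse[2])
            + ci[1][None, :, None] * n_coarse[2]
            + ci[2][None, None, :])
    m = mask.ravel()
    f = flat.ravel()[m]
    vals = image.values.ravel()[m].astype(np.float64)
    size = int(np.prod(n_coarse))
    counts = np.bincount(f, minlength=size)
    sums = np.bincount(f, weights=vals, minlength=size)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    fine_vol = float(np.prod(fsp))
    coarse_vol = float(np.prod(tsp))
    frac = counts * fine_vol / coarse_vol
    cmask = (frac >= fill_fraction).reshape(n_coarse)
    cvals = means.reshape(n_coarse)
    cimg = DensityImage(
        values=cvals,
        spacing=tuple(tsp),
        origin=tuple(corner + tsp / 2.0),
        unit=image.unit,
    )
    return cimg, cmask


def bmd_to_bvtv(bmd, rho_min: float = RHO_MIN):
    """BMD (mg HA/cm³) → bone volume fraction ρ ∈ [rho_min, 1].

    The linear law BV/TV = 0.093·BMD + 1.077 is on a *percent* scale (it gives
    ≈19.7 at a typical trabecular BMD of 200 mg HA/cm³); the result is divided
    by 100 and clamped to [rho_min, 1].
    """
    p = BVTV_SLOPE * np.asarray(bmd, dtype=np.float64) + BVTV_INTERCEPT
    rho = np.clip(p / 100.0, rho_min, 1.0)
    if np.isscalar(bmd):
        return float(rho)
    return rho


# ---------------------------------------------------------------------------
# hexahedral mesh
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EmbeddingConfig:
    """Cranial embedding: PU conforming to the head surface, steel plate on top.

    Columns of the coarse grid whose topmost bone voxel lies within
    ``conform_range`` voxels of the global cranial-most bone layer are filled
    with polyurethane up to a flat level, topped by ``steel_layers`` of steel.
    """

    pu_layers: int = 1
    steel_layers: int = 1
    conform_range: int = 2
    E_pu: float = 1360.0  # MPa
    nu_pu: float = 0.3
    E_steel: float = 210000.0  # MPa
    nu_steel: float = 0.3


@dataclass
class HexMesh:
    """Voxel mesh: 8-node hexahedra on a regular grid.

    ``material`` holds MATERIAL_BONE/PU/STEEL per element; ``rho`` the BV/TV
    of bone elements (NaN otherwise); ``provenance`` the coarse voxel index.
    """

    nodes: np.ndarray  # (n_nodes, 3) mm
    elements: np.ndarray  # (n_e, 8) node indices, VTK hexahedron ordering
    material: np.ndarray  # (n_e,) int
    rho: np.ndarray  # (n_e,) float
    provenance: np.ndarray  # (n_e, 3) coarse voxel ijk
    spacing: tuple[float, float, float]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_centers(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)


_HEX_CORNERS = np.array([
    [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
    [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
])


def _voxels_to_mesh(voxels: np.ndarray, origin: np.ndarray, spacing: np.ndarray,
                    material: np.ndarray, rho: np.ndarray) -> HexMesh:
    corner_ijk = voxels[:, None, :] + _HEX_CORNERS[None, :, :]  # (n_e, 8, 3)
    flat = corner_ijk.reshape(-1, 3)
    # unique grid nodes
    mins = flat.min(axis=0)
    dims = flat.max(axis=0) - mins + 1
    lin = ((flat[:, 0] - mins[0]) * dims[1] + (flat[:, 1] - mins[1])) * dims[2] \
        + (flat[:, 2] - mins[2])
    uniq, inv = np.unique(lin, return_inverse=True)
    ii = uniq // (dims[1] * dims[2])
    jj = (uniq // dims[2]) % dims[1]
    kk = uniq % dims[2]
    node_ijk = np.stack([ii, jj, kk], axis=1) + mins
    corner_world = origin - spacing / 2.0
    nodes = corner_world + node_ijk * spacing
    elements = inv.reshape(-1, 8).astype(np.int64)
    return HexMesh(nodes=nodes, elements=elements, material=material.copy(),
                   rho=rho.copy(), provenance=voxels.copy(),
                   spacing=tuple(spacing))


def build_hex_mesh(
    coarse_image: DensityImage,
    coarse_mask: np.ndarray,
    embedding: EmbeddingConfig | None = EmbeddingConfig(),
    rho_min: float = RHO_MIN,
    connectivity_cleanup: bool = True,
) -> HexMesh:
    """Convert masked coarse voxels to hexahedra with BV/TV material density.

    Bone voxels whose mapped BV/TV falls below ``rho_min`` are void and
    dropped (zero-stiffness elements would make the system singular).  If an
    embedding is requested, polyurethane fills the gap between the cranial
    head surface and a flat steel plate, exactly as in the experimental setup.
    """
    coarse_mask = np.asarray(coarse_mask, dtype=bool)
    if not coarse_mask.any():
        raise MeshError("empty coarse mask")
    p = BVTV_SLOPE * coarse_image.values + BVTV_INTERCEPT
    keep = coarse_mask & (p / 100.0 >= rho_min)
    if not keep.any():
        raise MeshError("all masked voxels below rho_min; nothing to mesh")
    vox = np.argwhere(keep)
    rho_bone = np.minimum(p[keep.nonzero()] / 100.0, 1.0)
    material = np.full(len(vox), MATERIAL_BONE, dtype=np.int8)

    extra_vox, extra_mat = [], []
    if embedding is not None:
        nz = keep.shape[2]
        any_col = keep.any(axis=2)
        if not any_col.any():
            raise MeshError("mask has no cranial surface to embed")
        # topmost bone layer per column
        zi = np.arange(nz)
        top = np.where(any_col, (keep * zi[None, None, :]).max(axis=2), -1)
        z_top = int(top.max())
        cols = np.argwhere(any_col & (top >= z_top - embedding.conform_range))
        if len(cols) == 0:
            raise MeshError("mask has no cranial surface to embed")
        plate_base = z_top + embedding.pu_layers  # PU occupies ... plate_base
        for (i, j) in cols:
            t = int(top[i, j])
            for z in range(t + 1, plate_base + 1):
                extra_vox.append((i, j, z))
                extra_mat.append(MATERIAL_PU)
            for z in range(plate_base + 1, plate_base + 1 + embedding.steel_layers):
                extra_vox.append((i, j, z))
                extra_mat.append(MATERIAL_STEEL)
    if extra_vox:
        vox = np.vstack([vox, np.array(extra_vox)])
        material = np.concatenate([material, np.array(extra_mat, dtype=np.int8)])
    rho = np.full(len(vox), np.nan)
    rho[: len(rho_bone)] = rho_bone

    if connectivity_cleanup:
        # elements sharing any node (26-connected voxels) form one component
        mins = vox.min(axis=0)
        dims = vox.max(axis=0) - mins + 1
        dense = np.zeros(dims, dtype=bool)
        rel = vox - mins
        dense[rel[:, 0], rel[:, 1], rel[:, 2]] = True
        comp, ncomp = ndimage.label(dense, structure=np.ones((3, 3, 3), dtype=int))
        if ncomp > 1:
            lab = comp[rel[:, 0], rel[:, 1], rel[:, 2]]
            sizes = np.bincount(lab)
            sizes[0] = 0
            keep_el = lab == int(np.argmax(sizes))
            warnings.warn(
                f"mesh had {ncomp} disconnected components; keeping largest "
                f"({int(keep_el.sum())}/{len(vox)} elements)")
            vox, material, rho = vox[keep_el], material[keep_el], rho[keep_el]

    return _voxels_to_mesh(vox, np.asarray(coarse_image.origin),
                           np.asarray(coarse_image.spacing), material, rho)


# ---------------------------------------------------------------------------
# virtual lesion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LesionSpec:
    """Virtual osteolytic lesion: angular wedge of the femoral neck.

    ``circumferential_fraction`` of the full circumference (default 1/3,
    i.e. a 120° wedge) centered on the superolateral or inferomedial
    direction, over ``axial_range`` mm along the neck axis measured from the
    head–neck junction toward the shaft (default: the whole neck), milled from
    the surface inward to ``depth`` × the local radius (1.0 = to the axis).
    Removed bone is replaced by saline (total bone removal — the osteolytic
    worst case).
    """

    site: str = "inferomedial"
    circumferential_fraction: float = 1.0 / 3.0
    axial_range: tuple[float, float] | None = None
    depth: float = 1.0

    def __post_init__(self) -> None:
        if self.site not in ("superolateral", "inferomedial"):
            raise ValueError(f"unknown lesion site {self.site!r}")
        if not (0.0 < self.circumferential_fraction <= 1.0):
            raise ValueError("circumferential_fraction must be in (0, 1]")
        if not (0.0 < self.depth <= 1.0):
            raise ValueError("depth must be in (0, 1]")


def wedge_angle_deg(spec: LesionSpec) -> float:
    """Full angle subtended by the lesion wedge."""
    return 360.0 * spec.circumferential_fraction


def insert_lesion(
    image: DensityImage,
    mask: np.ndarray | None,
    landmarks: Landmarks,
    lesion: LesionSpec,
    saline_bmd: float = 0.0,
) -> tuple[DensityImage, np.ndarray | None]:
    """Mill the lesion wedge out of the (fine, calibrated) image.

    Wedge voxels are set to ``min(value, saline_bmd)`` (never increased) and
    removed from the mask when one is supplied.  A wedge that removes no
    voxels raises a warning, not an error.
    """
    e_site = (landmarks.superolateral_dir() if lesion.site == "superolateral"
              else landmarks.inferomedial_dir())
    a = landmarks.neck_dir
    toward_shaft = -a
    junction = landmarks.junction
    if lesion.axial_range is None:
        s0, s1 = 0.0, landmarks.neck_length - landmarks.head_radius
    else:
        s0, s1 = lesion.axial_range

    sp = np.asarray(image.spacing)
    origin = np.asarray(image.origin)
    nxyz = image.shape
    X = (origin[0] + sp[0] * np.arange(nxyz[0]))[:, None, None]
    Y = (origin[1] + sp[1] * np.arange(nxyz[1]))[None, :, None]
    Z = (origin[2] + sp[2] * np.arange(nxyz[2]))[None, None, :]
    px, py, pz = X - junction[0], Y - junction[1], Z - junction[2]
    s_ax = px * toward_shaft[0] + py * toward_shaft[1] + pz * toward_shaft[2]
    proj = px * a[0] + py * a[1] + pz * a[2]
    qx, qy, qz = px - proj * a[0], py - proj * a[1], pz - proj * a[2]
    rho = np.sqrt(qx ** 2 + qy ** 2 + qz ** 2)
    # voxels exactly on the axis have no azimuth; count them with the wedge
    # only when it is at least a half-space (they vanish as the angle does)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosphi = np.where(rho > 1e-9,
                          (qx * e_site[0] + qy * e_site[1] + qz * e_site[2])
                          / np.maximum(rho, 1e-12), 0.0)
    half_angle = np.radians(180.0 * lesion.circumferential_fraction)
    in_wedge = (s_ax >= s0) & (s_ax <= s1) & (cosphi >= np.cos(half_angle))

    if lesion.depth < 1.0:
        target = mask if mask is not None else (image.values > saline_bmd)
        sel = in_wedge & target
        if sel.any():
            rmax = float(rho[sel].max())
            in_wedge &= rho >= (1.0 - lesion.depth) * rmax

    scope = in_wedge if mask is None else (in_wedge & np.asarray(mask, dtype=bool))
    n_removed = int(scope.sum())
    if n_removed == 0:
        warnings.warn("lesion wedge removed zero voxels")
    values = image.values.copy()
    values[scope] = np.minimum(values[scope], saline_bmd)
    new_mask = None if mask is None else (np.asarray(mask, dtype=bool) & ~in_wedge)
    return image.copy_with(values=values), new_mask


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def write_vtu(mesh: HexMesh, path: str | Path,
              cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Minimal ASCII VTU (unstructured grid of VTK_HEXAHEDRON cells)."""
    path = Path(path)
    n_n, n_e = mesh.n_nodes, mesh.n_elements
    data = dict(cell_data or {})
    data.setdefault("material", mesh.material.astype(float))
    data.setdefault("rho", np.nan_to_num(mesh.rho, nan=0.0))

    def arr_to_text(a, fmt="{:.9g}"):
        return " ".join(fmt.format(v) for v in np.asarray(a).ravel())

    parts = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n_n}" NumberOfCells="{n_e}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        arr_to_text(mesh.nodes),
        "</DataArray>", "</Points>", "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        arr_to_text(mesh.elements, "{:d}"),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        arr_to_text(8 * (np.arange(n_e) + 1), "{:d}"),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        arr_to_text(np.full(n_e, 12), "{:d}"),
        "</DataArray>", "</Cells>", "<CellData>",
    ]
    for name, arr in data.items():
        parts += [
            f'<DataArray type="Float64" Name="{name}" format="ascii">',
            arr_to_text(arr), "</DataArray>",
        ]
    parts += ["</CellData>", "</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    path.write_text("\n".join(parts))


def read_vtu(path: str | Path) -> HexMesh:
    """Read a hexahedral ASCII VTU written by :func:`write_vtu`."""
    import xml.etree.ElementTree as ET

    root = ET.parse(Path(path)).getroot()
    piece = root.find(".//Piece")
    arrays: dict[str, np.ndarray] = {}
    for da in piece.iter("DataArray"):
        name = da.get("Name") or "points"
        arrays[name] = np.fromstring(da.text.strip().replace("\n", " "),
                                     sep=" ")
    nodes = arrays["points"].reshape(-1, 3)
    elements = arrays["connectivity"].astype(np.int64).reshape(-1, 8)
    if not np.all(arrays["types"] == 12):
        raise MeshError("VTU contains non-hexahedral cells")
    material = arrays.get("material", np.zeros(len(elements))).astype(np.int8)
    rho = arrays.get("rho", np.full(len(elements), np.nan))
    rho = np.where((material == MATERIAL_BONE) & (rho > 0), rho, np.nan) \
        if "rho" in arrays else rho
    # voxel edge lengths from the first element
    e0 = nodes[elements[0]]
    spacing = tuple(float(e0[:, a].max() - e0[:, a].min()) for a in range(3))
    centers = nodes[elements].mean(axis=1)
    prov = np.round((centers - centers.min(axis=0)) / spacing).astype(int)
    return HexMesh(nodes=nodes, elements=elements, material=material,
                   rho=rho, provenance=prov, spacing=spacing)


def write_text_mesh(mesh: HexMesh, path: str | Path) -> None:
    """Plain-text node/element format: header counts, nodes, then elements."""
    path = Path(path)
    lines = [f"# femvox hex mesh: {mesh.n_nodes} nodes, {mesh.n_elements} elements",
             f"{mesh.n_nodes} {mesh.n_elements}"]
    for p in mesh.nodes:
        lines.append(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}")
    for e, m, r in zip(mesh.elements, mesh.material, mesh.rho):
        rr = 0.0 if np.isnan(r) else r
        lines.append(" ".join(str(i) for i in e) + f" {m} {rr:.6f}")
    path.write_text("\n".join(lines))
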