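"""Centerline extraction, ligament length, subregions, and insertion boxes.

The ligament's 3D centerline is computed from its binary mask by a
slab-centroid construction: the principal axis of the voxel point cloud
defines a provisional longitudinal direction, voxels are binned into
equal-width slabs along it, per-slab centroids are smoothed by a cubic
spline, and the polyline is extended along its end tangents to the mask
boundary. This is robust on strongly anisotropic voxels (0.4 x 0.4 x 3.2
mm) and thin multi-slice masks, where voxel skeletonization is brittle.

Arc length along the centerline parameterizes the 25/50/25% partition
into proximal (PR, femoral), central (CR) and distal (DR, tibial)
subregions, and locates the insertion-site box ROIs: 0.5 x 1.0 cm²
(height x width) rectangles on the central parasagittal slice, oriented
parallel to the cortical bone interface with a quarter of the height on
the bone side.

All coordinates are physical mm in (z, y, x) order; voxel centers sit at
``index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage
from scipy.interpolate import splev, splprep
from scipy.spatial import cKDTree

__all__ = [
    "Centerline",
    "SubregionPartition",
    "InsertionBox",
    "InsertionSite",
    "compute_centerline",
    "measure_length",
    "partition_subregions",
    "place_insertion_box",
    "central_pcl_slice",
]


class GeometryError(ValueError):
    pass


@dataclass
class Centerline:
    """Ordered 3D polyline with arc-length parameterization.

    ``points`` are physical (z, y, x) mm, proximal (femoral) end first;
    ``cumulative_arclength`` is nondecreasing, starting at 0.
    """

    points: np.ndarray
    cumulative_arclength: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[0] < 2 or self.points.shape[1] != 3:
            raise GeometryError("centerline needs >= 2 points of dimension 3")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        self.cumulative_arclength = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def total_length(self) -> float:
        return float(self.cumulative_arclength[-1])


class InsertionSite(str, Enum):
    FEMORAL = "femoral"
    TIBIAL = "tibial"


SUBREGION_NAMES = {1: "PR", 2: "CR", 3: "DR"}


@dataclass
class SubregionPartition:
    """Voxel assignment to PR/CR/DR (1/2/3; 0 outside the ligament)."""

    assignment: np.ndarray
    boundaries: tuple[float, float] = (0.25, 0.75)

    def mask_for(self, name: str) -> np.ndarray:
        code = {v: k for k, v in SUBREGION_NAMES.items()}[name]
        return self.assignment == code


def _connected_or_raise(mask: np.ndarray) -> None:
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labeled, n = ndimage.label(mask, structure=structure)
    if n != 1:
        sizes = np.bincount(labeled.ravel())[1:]
        raise GeometryError(
            f"mask has {n} connected components (sizes {sorted(sizes, reverse=True)}); expected 1"
        )


def _inside(mask: np.ndarray, spacing: np.ndarray, pt: np.ndarray) -> bool:
    idx = np.rint(pt / spacing).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.array(mask.shape)):
        return False
    return bool(mask[tuple(idx)])


def compute_centerline(
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    n_slabs: int | None = None,
    smoothing: float | None = None,
    proximal_reference: np.ndarray | None = None,
    n_samples: int = 400,
) -> Centerline:
    """Extract the ligament centerline from a binary mask.

    Parameters
    ----------
    mask : 3D boolean array
        Single 26-connected component, >= 2 voxels long.
    spacing : (dz, dy, dx) mm
    n_slabs : slab count along the principal axis; default one slab per
        mm of extent (at least 10).
    smoothing : spline smoothing factor passed to ``splprep``; default
        scales with the slab count and in-plane voxel size.
    proximal_reference : optional (z, y, x) mm point (e.g. the femoral
        bone centroid); the centerline is oriented so its first point is
        the end nearer this reference.
    """
    mask = np.asarray(mask, dtype=bool)
    spacing = np.asarray(spacing, dtype=np.float64)
    if mask.sum() < 4:
        raise GeometryError("mask too small for centerline extraction")
    _connected_or_raise(mask)
    coords = np.argwhere(mask) * spacing  # (N, 3) physical mm

    center = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - center, full_matrices=False)
    axis = vt[0]
    t = (coords - center) @ axis
    extent = t.max() - t.min()
    if extent < 2 * min(spacing):
        raise GeometryError("mask is thinner than 2 voxels along its principal axis")
    if n_slabs is None:
        n_slabs = max(10, int(round(extent / 1.0)))

    def slab_spline(param: np.ndarray, n_bins: int) -> np.ndarray:
        edges = np.linspace(param.min(), param.max(), n_bins + 1)
        which = np.clip(np.digitize(param, edges) - 1, 0, n_bins - 1)
        centroids = []
        for b in range(n_bins):
            sel = which == b
            if sel.any():
                centroids.append(coords[sel].mean(axis=0))
        centroids = np.asarray(centroids)
        if len(centroids) < 2:
            raise GeometryError("fewer than 2 nonempty slabs; mask too short")
        if len(centroids) < 4:
            return centroids
        s = smoothing if smoothing is not None else len(centroids) * 0.3**2
        k = min(3, len(centroids) - 1)
        tck, _ = splprep(centroids.T, k=k, s=s)
        return np.asarray(splev(np.linspace(0, 1, n_samples), tck)).T

    # pass 1: slabs perpendicular to the global principal axis (biased at
    # oblique ends); pass 2: re-bin by arc length of the nearest pass-1
    # point, so sections become perpendicular to the local tube axis
    pts = slab_spline(t, n_slabs)
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    _, idx = cKDTree(pts).query(coords)
    s_vox = arc[idx]
    pts = slab_spline(s_vox, max(10, int(round(arc[-1]))))

    # extend along end tangents to the mask boundary (slab centroids stop
    # half a slab short of the true ends)
    step = 0.1
    head_tan = pts[0] - pts[1]
    head_tan /= max(np.linalg.norm(head_tan), 1e-12)
    tail_tan = pts[-1] - pts[-2]
    tail_tan /= max(np.linalg.norm(tail_tan), 1e-12)
    head_ext = []
    p = pts[0].copy()
    for _ in range(200):
        q = p + head_tan * step
        if not _inside(mask, spacing, q):
            break
        head_ext.append(q)
        p = q
    tail_ext = []
    p = pts[-1].copy()
    for _ in range(200):
        q = p + tail_tan * step
        if not _inside(mask, spacing, q):
            break
        tail_ext.append(q)
        p = q
    if head_ext:
        pts = np.vstack([head_ext[::-1], pts])
    if tail_ext:
        pts = np.vstack([pts, tail_ext])

    if proximal_reference is not None:
        ref = np.asarray(proximal_reference, dtype=np.float64)
        if np.linalg.norm(pts[-1] - ref) < np.linalg.norm(pts[0] - ref):
            pts = pts[::-1].copy()
    return Centerline(points=pts, cumulative_arclength=np.zeros(len(pts)))


def measure_length(cl: Centerline) -> float:
    """Total centerline arc length in mm (proximal to distal insertion)."""
    return cl.total_length


def partition_subregions(
    mask: np.ndarray,
    cl: Centerline,
    spacing: tuple[float, float, float],
    boundaries: tuple[float, float] = (0.25, 0.75),
) -> SubregionPartition:
    """Assign every ligament voxel to PR/CR/DR by arc-length fraction.

    Each voxel takes the arc-length fraction s of its nearest centerline
    point: PR for s < 0.25, CR for 0.25 <= s < 0.75, DR for s >= 0.75,
    so boundary ties fall to the central region. PR abuts the femoral
    (proximal) insertion by the centerline's orientation.
    """
    mask = np.asarray(mask, dtype=bool)
    spacing = np.asarray(spacing, dtype=np.float64)
    coords = np.argwhere(mask) * spacing
    tree = cKDTree(cl.points)
    _, idx = tree.query(coords)
    s = cl.cumulative_arclength[idx] / max(cl.total_length, 1e-12)
    lo, hi = boundaries
    code = np.where(s < lo, 1, np.where(s < hi, 2, 3))
    assignment = np.zeros(mask.shape, dtype=np.int8)
    assignment[mask] = code
    return SubregionPartition(assignment=assignment, boundaries=boundaries)


@dataclass
class InsertionBox:
    """Oriented rectangular ROI over a ligament-bone insertion site.

    Lives on one parasagittal slice. ``u_axis`` (width, 10 mm) runs
    parallel to the cortical interface; ``v_axis`` (height, 5 mm) points
    from bone into ligament; 25% of the height lies bone-side.
    Coordinates are in-plane physical (y, x) mm.
    """

    site: InsertionSite
    slice_index: int
    center: np.ndarray
    u_axis: np.ndarray
    v_axis: np.ndarray
    height: float = 5.0
    width: float = 10.0
    bone_fraction: float = 0.25

    @property
    def angle_deg(self) -> float:
        """Orientation of the interface-parallel axis, degrees in (y, x)."""
        return float(np.degrees(np.arctan2(self.u_axis[0], self.u_axis[1])))

    def enclosed_mask(self, shape: tuple[int, int, int],
                      spacing: tuple[float, float, float]) -> np.ndarray:
        """Rasterize the box onto the volume grid (single slice)."""
        _, dy, dx = spacing
        ny, nx = shape[1], shape[2]
        yy, xx = np.meshgrid(np.arange(ny) * dy, np.arange(nx) * dx, indexing="ij")
        rel = np.stack([yy - self.center[0], xx - self.center[1]], axis=-1)
        du = rel @ self.u_axis
        dv = rel @ self.v_axis
        inside = (np.abs(du) <= self.width / 2) & (np.abs(dv) <= self.height / 2)
        out = np.zeros(shape, dtype=bool)
        out[self.slice_index] = inside
        return out

    def to_dict(self) -> dict:
        return {
            "site": self.site.value,
            "slice_index": int(self.slice_index),
            "center_yx_mm": self.center.tolist(),
            "u_axis": self.u_axis.tolist(),
            "v_axis": self.v_axis.tolist(),
            "height_mm": self.height,
            "width_mm": self.width,
            "bone_fraction": self.bone_fraction,
        }


def central_pcl_slice(pcl_mask: np.ndarray) -> int:
    """Central parasagittal slice = the slice of largest PCL cross-section."""
    areas = pcl_mask.reshape(pcl_mask.shape[0], -1).sum(axis=1)
    if areas.max() == 0:
        raise GeometryError("PCL mask is empty")
    best = np.flatnonzero(areas == areas.max())
    return int(best[len(best) // 2])


def place_insertion_box(
    pcl_mask: np.ndarray,
    bone_mask: np.ndarray,
    site: InsertionSite,
    spacing: tuple[float, float, float],
    slice_index: int | None = None,
    centerline: Centerline | None = None,
    height: float = 5.0,
    width: float = 10.0,
    bone_fraction: float = 0.25,
    window: float = 10.0,
) -> InsertionBox:
    """Place the standardized insertion-site box on the central slice.

    The interface-parallel axis is the least-squares line through the
    bone-boundary pixels within ``window`` mm of the ligament endpoint;
    the box center is offset from the interface so ``bone_fraction`` of
    its height lies on the bone side.
    """
    pcl_mask = np.asarray(pcl_mask, dtype=bool)
    bone_mask = np.asarray(bone_mask, dtype=bool)
    spacing = np.asarray(spacing, dtype=np.float64)
    _, dy, dx = spacing
    if slice_index is None:
        slice_index = central_pcl_slice(pcl_mask)
    pcl2d = pcl_mask[slice_index]
    bone2d = bone_mask[slice_index]
    if not pcl2d.any() or not bone2d.any():
        raise GeometryError(f"PCL or bone absent on slice {slice_index}")

    # ligament endpoint near this bone: centerline end if available, else
    # the PCL pixel closest to the bone
    if centerline is not None:
        end3d = centerline.points[0] if site == InsertionSite.FEMORAL else centerline.points[-1]
        endpoint = end3d[1:]
    else:
        pc = np.argwhere(pcl2d) * (dy, dx)
        bc = np.argwhere(bone2d) * (dy, dx)
        d = cKDTree(bc).query(pc)[0]
        endpoint = pc[np.argmin(d)]

    # bone boundary: bone pixels adjacent to non-bone
    eroded = ndimage.binary_erosion(bone2d)
    boundary = bone2d & ~eroded
    bpts = np.argwhere(boundary) * (dy, dx)
    dists = np.linalg.norm(bpts - endpoint, axis=1)
    near = bpts[dists <= window]
    if len(near) < 2:
        raise GeometryError(
            f"no bone boundary within {window} mm of the {site.value} ligament endpoint"
        )

    bmean = near.mean(axis=0)
    _, _, vt = np.linalg.svd(near - bmean, full_matrices=False)
    u = vt[0] / np.linalg.norm(vt[0])
    v = np.array([-u[1], u[0]])
    # orient v from bone into ligament
    pc = np.argwhere(pcl2d) * (dy, dx)
    sel = np.linalg.norm(pc - endpoint, axis=1) <= window
    pcl_near = pc[sel].mean(axis=0) if sel.any() else pc.mean(axis=0)
    bone_all = np.argwhere(bone2d) * (dy, dx)
    sel_b = np.linalg.norm(bone_all - endpoint, axis=1) <= window
    bone_near = bone_all[sel_b].mean(axis=0) if sel_b.any() else bone_all.mean(axis=0)
    if (pcl_near - bone_near) @ v < 0:
        v = -v

    # interface anchor: endpoint projected onto the fitted boundary line,
    # shifted half a pixel toward the ligament (the true cortical edge lies
    # between the bone and non-bone pixel centers)
    anchor = bmean + ((endpoint - bmean) @ u) * u
    half_pixel = 0.5 * (abs(v[0]) * dy + abs(v[1]) * dx)
    center = anchor + (height / 2 - bone_fraction * height + half_pixel) * v

    # bounds check
    ny, nx = pcl2d.shape
    corners = [center + su * (width / 2) * u + sv * (height / 2) * v
               for su in (-1, 1) for sv in (-1, 1)]
    for c in corners:
        if not (0 <= c[0] <= (ny - 1) * dy and 0 <= c[1] <= (nx - 1) * dx):
            raise GeometryError(f"insertion box extends outside the image at {c}")

    return InsertionBox(
        site=site, slice_index=int(slice_index), center=center, u_axis=u, v_axis=v,
        height=height, width=width, bone_fraction=bone_fraction,
    )
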