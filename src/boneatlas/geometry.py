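"""Mesh, landmark and volume containers with their I/O and conversions.

Conventions used throughout the package:

* All coordinates are world millimetres.
* Volumes are axis-aligned regular grids with voxel-centre indexing:
  the world coordinate of voxel ``(i, j, k)`` is ``origin + spacing * (i, j, k)``.
  Array index order is ``(x, y, z)``.
* Signed surface distances are negative where the query point lies *inside*
  the reference mesh.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import GeometryError, MeshIOError, ValidationError

log = logging.getLogger(__name__)

# voxelization / distance-model defaults (humerus-scale features are >= a few mm)
DEFAULT_SPACING = 1.0
DEFAULT_PADDING = 4
DEFAULT_SMOOTH_SIGMA = 1.0
HISTOGRAM_RANGE = (-6.0, 6.0)
HISTOGRAM_BIN_WIDTH = 0.5


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

@dataclass
class LandmarkSet:
    """Ordered, named 3D points (mm) tied to one shape/space."""

    names: list[str]
    points: np.ndarray  # (n, 3) float
    frame: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(len(self.names), 3)
        if len(set(self.names)) != len(self.names):
            raise ValidationError("landmark names must be unique")
        if not np.all(np.isfinite(self.points)):
            raise ValidationError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return len(self.names)

    def with_points(self, points: np.ndarray, frame: str | None = None) -> "LandmarkSet":
        return LandmarkSet(list(self.names), np.asarray(points, dtype=float),
                           self.frame if frame is None else frame)

    def flatten(self) -> np.ndarray:
        """Row-major (x1,y1,z1,x2,...) vector, the PCA feature layout."""
        return self.points.reshape(-1)


def read_landmarks(path: str | Path, frame: str = "") -> LandmarkSet:
    """Read a ``name,x,y,z`` CSV. Extra columns are ignored with a warning."""
    df = pd.read_csv(path)
    required = ["name", "x", "y", "z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MeshIOError(f"{path}: missing landmark columns {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        log.warning("%s: ignoring extra landmark columns %s", path, extra)
    names = [str(n) for n in df["name"]]
    try:
        pts = df[["x", "y", "z"]].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise MeshIOError(f"{path}: non-numeric landmark coordinates") from exc
    if not np.all(np.isfinite(pts)):
        raise MeshIOError(f"{path}: non-finite landmark coordinates")
    if len(set(names)) != len(names):
        raise MeshIOError(f"{path}: duplicate landmark names")
    return LandmarkSet(names, pts, frame=frame)


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    df = pd.DataFrame({
        "name": landmarks.names,
        "x": landmarks.points[:, 0],
        "y": landmarks.points[:, 1],
        "z": landmarks.points[:, 2],
    })
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# meshes (trimesh.Trimesh is the in-memory container)
# ---------------------------------------------------------------------------

def read_stl(path: str | Path) -> trimesh.Trimesh:
    """Read a binary or ASCII STL; duplicate vertices are merged on read.

    Binary files are size-validated first so truncation fails loudly instead
    of yielding a partial mesh.
    """
    path = Path(path)
    if not path.exists():
        raise MeshIOError(f"{path}: no such file")
    raw = path.read_bytes()
    if len(raw) < 15:
        raise MeshIOError(f"{path}: truncated STL (only {len(raw)} bytes)")
    is_ascii = raw[:6].lower().startswith(b"solid") and b"facet" in raw[:500]
    if not is_ascii:
        if len(raw) < 84:
            raise MeshIOError(f"{path}: truncated binary STL header at byte {len(raw)}")
        (n_tri,) = struct.unpack("<I", raw[80:84])
        expected = 84 + 50 * n_tri
        if len(raw) < expected:
            raise MeshIOError(
                f"{path}: truncated binary STL at byte {len(raw)} (expected {expected})")
    try:
        mesh = trimesh.load(path, file_type="stl", process=True)
    except Exception as exc:  # pragma: no cover - trimesh error text varies
        raise MeshIOError(f"{path}: STL parse error: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise MeshIOError(f"{path}: STL contains no triangles")
    mesh.merge_vertices()
    return mesh


def write_stl(mesh: trimesh.Trimesh, path: str | Path) -> None:
    """Write little-endian binary STL."""
    Path(path).write_bytes(mesh.export(file_type="stl"))


def mesh_volume(mesh: trimesh.Trimesh) -> float:
    """Enclosed volume (mm^3) by the divergence theorem.

    Requires a watertight mesh; an inward-oriented one is accepted with a
    warning and reported as positive.
    """
    if not mesh.is_watertight:
        raise GeometryError("mesh_volume requires a watertight mesh")
    vol = float(mesh.volume)
    if vol < 0:
        log.warning("mesh has inward orientation; reporting |volume|")
        vol = -vol
    return vol


# ---------------------------------------------------------------------------
# surface queries (closest point, containment) — cKDTree-backed
# ---------------------------------------------------------------------------

def _closest_point_on_triangles(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each triangle for each (point, triangle) pair.

    ``points``: (n, 3); ``tri``: (n, 3, 3). Vectorized region-based projection.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = points - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = points - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = points - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(points)
    done = np.zeros(len(points), dtype=bool)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m

    # edge AB
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    denom = np.where(d1 - d3 == 0, 1.0, d1 - d3)
    v = (d1 / denom)[m]
    out[m] = a[m] + v[:, None] * ab[m]
    done |= m

    # edge AC
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    denom = np.where(d2 - d6 == 0, 1.0, d2 - d6)
    w = (d2 / denom)[m]
    out[m] = a[m] + w[:, None] * ac[m]
    done |= m

    # edge BC
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    denom = np.where(denom == 0, 1.0, denom)
    w = ((d4 - d3) / denom)[m]
    out[m] = b[m] + w[:, None] * (c[m] - b[m])
    done |= m

    # interior
    m = ~done
    denom = va + vb + vc
    denom = np.where(denom == 0, 1.0, denom)
    v = (vb / denom)[m]
    w = (vc / denom)[m]
    out[m] = a[m] + v[:, None] * ab[m] + w[:, None] * ac[m]
    return out


def _tri_radii(tris: np.ndarray) -> np.ndarray:
    c = tris.mean(axis=1)
    return np.linalg.norm(tris - c[:, None, :], axis=2).max(axis=1)


def _split_triangles(tris: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split each triangle across the midpoint of its longest edge."""
    a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
    edges = np.stack([np.linalg.norm(b - a, axis=1),
                      np.linalg.norm(c - b, axis=1),
                      np.linalg.norm(a - c, axis=1)], axis=1)
    longest = edges.argmax(axis=1)
    out1 = np.empty_like(tris)
    out2 = np.empty_like(tris)
    for e, (p, q, r) in enumerate(((0, 1, 2), (1, 2, 0), (2, 0, 1))):
        m = longest == e
        mid = 0.5 * (tris[m, p] + tris[m, q])
        out1[m, 0], out1[m, 1], out1[m, 2] = tris[m, p], mid, tris[m, r]
        out2[m, 0], out2[m, 1], out2[m, 2] = mid, tris[m, q], tris[m, r]
    return out1, out2


class SurfaceQuery:
    """Closest-point and containment queries against one triangle mesh.

    A cKDTree over triangle centroids proposes candidates; an exact
    point-triangle projection refines them.  A second radius-bounded pass
    guarantees the true closest triangle was considered.
    """

    def __init__(self, mesh: trimesh.Trimesh):
        if len(mesh.faces) == 0:
            raise GeometryError("empty mesh")
        self.mesh = mesh
        self.triangles = mesh.vertices[mesh.faces]  # (M, 3, 3)
        # Oversized triangles (e.g. cap fans) are split for the query index:
        # the distance to a triangle equals the min over its sub-triangles,
        # so exactness is unaffected while the search bound stays tight.
        tris = self.triangles
        radius = _tri_radii(tris)
        target = max(4.0 * np.median(radius), 1e-12)
        while radius.max() > target:
            big = radius > target
            tris = np.concatenate([tris[~big], *_split_triangles(tris[big])])
            radius = _tri_radii(tris)
        self._query_triangles = tris
        self.centroids = tris.mean(axis=1)
        self._max_tri_radius = float(radius.max())
        self.tree = cKDTree(self.centroids)

    def closest_point(self, points: np.ndarray, k: int = 8, exact: bool = True
                      ) -> tuple[np.ndarray, np.ndarray]:
        """Return (closest surface points, unsigned distances).

        With ``exact`` the result is guaranteed optimal: a point is finished
        once its best candidate distance cannot be beaten by any triangle
        whose centroid lies beyond the farthest candidate queried; stragglers
        are re-queried with a growing candidate set.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(points)
        best_pt = np.empty_like(points)
        best_d = np.full(n, np.inf)
        active = np.arange(n)
        k = min(k, len(self.centroids))
        while len(active):
            dk, idx = self.tree.query(points[active], k=k)
            idx = idx.reshape(len(active), -1)
            dk = dk.reshape(len(active), -1)
            m = idx.shape[1]
            rep = np.repeat(points[active], m, axis=0)
            cand = self._closest_point_batch(rep, idx.reshape(-1))
            d = np.linalg.norm(rep - cand, axis=1).reshape(len(active), m)
            sel = d.argmin(axis=1)
            rows = np.arange(len(active))
            best_d[active] = d[rows, sel]
            best_pt[active] = cand.reshape(len(active), m, 3)[rows, sel]
            if not exact or k >= len(self.centroids):
                break
            # a farther triangle can only win if its centroid is within
            # best_d + max triangle circumradius of the query point
            unresolved = best_d[active] + self._max_tri_radius > dk[:, -1]
            active = active[unresolved]
            k = min(4 * k, len(self.centroids))
        return best_pt, best_d

    def _closest_point_batch(self, points: np.ndarray, tri_idx: np.ndarray) -> np.ndarray:
        return _closest_point_on_triangles(points, self._query_triangles[tri_idx])

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Point-in-mesh by +z ray-crossing parity (orientation-independent)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        # tiny irrational nudge avoids exact edge/vertex ray hits
        eps = 1e-7 * (1.0 + np.abs(points[:, :2]).max())
        q = points.copy()
        q[:, 0] += eps * 0.7548776662
        q[:, 1] += eps * 0.5698402910
        crossings = np.zeros(len(q), dtype=np.int64)
        tri = self.triangles
        chunk = max(1, int(2e6 // max(len(q), 1)))
        for start in range(0, len(tri), chunk):
            t = tri[start:start + chunk]
            crossings += _count_ray_crossings(q, t)
        return (crossings % 2) == 1


def _count_ray_crossings(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Number of +z ray crossings of each point against a triangle block."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    px = points[:, 0][:, None]
    py = points[:, 1][:, None]
    # signed areas of the projected triangle against the query point
    d0 = (b[:, 0] - a[:, 0]) * (py - a[:, 1]) - (b[:, 1] - a[:, 1]) * (px - a[:, 0])
    d1 = (c[:, 0] - b[:, 0]) * (py - b[:, 1]) - (c[:, 1] - b[:, 1]) * (px - b[:, 0])
    d2 = (a[:, 0] - c[:, 0]) * (py - c[:, 1]) - (a[:, 1] - c[:, 1]) * (px - c[:, 0])
    inside = ((d0 > 0) & (d1 > 0) & (d2 > 0)) | ((d0 < 0) & (d1 < 0) & (d2 < 0))
    area2 = d0 + d1 + d2
    area2 = np.where(area2 == 0, 1.0, area2)
    # barycentric interpolation of z on the triangle plane
    zhit = (d1 * a[:, 2] + d2 * b[:, 2] + d0 * c[:, 2]) / area2
    above = zhit > points[:, 2][:, None]
    return np.count_nonzero(inside & above, axis=1)


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

@dataclass
class ScalarVolume:
    """Axis-aligned regular scalar grid; array index order is (x, y, z)."""

    origin: np.ndarray    # (3,) mm, world coordinate of voxel (0,0,0)
    spacing: np.ndarray   # (3,) mm/voxel
    values: np.ndarray    # (nx, ny, nz)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.spacing <= 0):
            raise GeometryError("voxel spacing must be positive")
        if self.values.ndim != 3:
            raise GeometryError("volume values must be a 3D array")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.origin) / self.spacing

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def grid_world_coords(self) -> np.ndarray:
        """(nx, ny, nz, 3) world coordinates of every voxel centre."""
        axes = [self.origin[d] + self.spacing[d] * np.arange(self.dims[d])
                for d in range(3)]
        g = np.meshgrid(*axes, indexing="ij")
        return np.stack(g, axis=-1)

    def sample(self, points: np.ndarray, order: int = 1, outside: float = 0.0
               ) -> np.ndarray:
        """Trilinear interpolation at world points; outside the grid -> `outside`."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = self.world_to_index(pts)
        return ndimage.map_coordinates(self.values, idx.T, order=order,
                                       mode="constant", cval=outside)

    def like(self, values: np.ndarray) -> "ScalarVolume":
        return ScalarVolume(self.origin.copy(), self.spacing.copy(), values)

    def same_grid(self, other: "ScalarVolume", tol: float = 1e-9) -> bool:
        return (self.dims == other.dims
                and np.allclose(self.origin, other.origin, atol=tol)
                and np.allclose(self.spacing, other.spacing, atol=tol))


def save_nrrd(volume: ScalarVolume, path: str | Path) -> None:
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(
        volume.values.transpose(2, 1, 0).astype(np.float32)))
    img.SetOrigin(tuple(volume.origin))
    img.SetSpacing(tuple(volume.spacing))
    sitk.WriteImage(img, str(path), useCompression=False)


def load_nrrd(path: str | Path) -> ScalarVolume:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(float)
    return ScalarVolume(np.array(img.GetOrigin()), np.array(img.GetSpacing()), arr)


# ---------------------------------------------------------------------------
# mesh <-> volume conversion
# ---------------------------------------------------------------------------

def voxelize(mesh: trimesh.Trimesh,
             spacing: float | np.ndarray = DEFAULT_SPACING,
             padding: int = DEFAULT_PADDING,
             smooth_sigma: float | None = None) -> ScalarVolume:
    """Binary occupancy of a watertight mesh at voxel centres.

    Occupancy is decided by +z ray-crossing parity per grid column, the
    discrete analogue of the even-odd rule. ``smooth_sigma`` (mm) optionally
    Gaussian-smooths the binary field into the pseudo-intensity in [0, 1]
    used as the registration substrate.
    """
    if not mesh.is_watertight:
        raise GeometryError("voxelize requires a watertight mesh")
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float).reshape(-1), (3,)).copy()
    if np.any(spacing <= 0):
        raise GeometryError("spacing must be positive")
    # cell-centred grid: voxel cells tile the padded AABB and sample points
    # sit at cell midpoints, so axis-aligned faces fall between centres
    lo = mesh.bounds[0]
    hi = mesh.bounds[1]
    n_cells = np.ceil((hi - lo) / spacing - 1e-9).astype(int)
    dims = n_cells + 2 * padding
    origin = lo - (padding - 0.5) * spacing

    nx, ny, nz = dims
    xs = origin[0] + spacing[0] * np.arange(nx)
    ys = origin[1] + spacing[1] * np.arange(ny)
    zs = origin[2] + spacing[2] * np.arange(nz)

    # column centres, nudged off exact edges
    cx, cy = np.meshgrid(xs, ys, indexing="ij")
    cols = np.stack([cx.ravel(), cy.ravel()], axis=1)
    eps = 1e-7 * max(1.0, np.abs(cols).max())
    cols = cols + eps * np.array([0.7548776662, 0.5698402910])

    tri = mesh.vertices[mesh.faces]
    values = np.zeros((nx, ny, nz), dtype=float)
    occ = _columns_occupancy(cols, tri, zs)
    values[:] = occ.reshape(nx, ny, nz)

    vol = ScalarVolume(origin, spacing, values)
    if smooth_sigma is not None and smooth_sigma > 0:
        sig = smooth_sigma / spacing
        vol.values = np.clip(ndimage.gaussian_filter(vol.values, sigma=sig), 0.0, 1.0)
    return vol


def _columns_occupancy(cols: np.ndarray, tri: np.ndarray, zs: np.ndarray) -> np.ndarray:
    """Per-column z-interval fill by triangle-crossing parity.

    Returns an (n_cols, nz) float array of {0, 1}.
    """
    n_cols = len(cols)
    nz = len(zs)
    col_ids: list[np.ndarray] = []
    z_hits: list[np.ndarray] = []
    chunk = max(1, int(4e6 // max(n_cols, 1)))
    px = cols[:, 0][:, None]
    py = cols[:, 1][:, None]
    for start in range(0, len(tri), chunk):
        t = tri[start:start + chunk]
        a, b, c = t[:, 0], t[:, 1], t[:, 2]
        d0 = (b[:, 0] - a[:, 0]) * (py - a[:, 1]) - (b[:, 1] - a[:, 1]) * (px - a[:, 0])
        d1 = (c[:, 0] - b[:, 0]) * (py - b[:, 1]) - (c[:, 1] - b[:, 1]) * (px - b[:, 0])
        d2 = (a[:, 0] - c[:, 0]) * (py - c[:, 1]) - (a[:, 1] - c[:, 1]) * (px - c[:, 0])
        inside = ((d0 > 0) & (d1 > 0) & (d2 > 0)) | ((d0 < 0) & (d1 < 0) & (d2 < 0))
        if not inside.any():
            continue
        area2 = d0 + d1 + d2
        area2 = np.where(area2 == 0, 1.0, area2)
        zhit = (d1 * a[:, 2] + d2 * b[:, 2] + d0 * c[:, 2]) / area2
        ci, ti = np.nonzero(inside)
        col_ids.append(ci)
        z_hits.append(zhit[ci, ti])

    occ = np.zeros((n_cols, nz), dtype=float)
    if not col_ids:
        return occ
    ci = np.concatenate(col_ids)
    zh = np.concatenate(z_hits)
    order = np.lexsort((zh, ci))
    ci, zh = ci[order], zh[order]
    boundaries = np.nonzero(np.diff(ci))[0] + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(ci)]])
    for s, e in zip(starts, ends):
        col = ci[s]
        crossings = zh[s:e]
        if len(crossings) % 2 != 0:
            # degenerate grazing hit; drop the closest duplicate pair
            crossings = _fix_odd_crossings(crossings)
            if len(crossings) % 2 != 0:
                continue
        for lo, hi in zip(crossings[0::2], crossings[1::2]):
            occ[col] += (zs > lo) & (zs < hi)
    return np.clip(occ, 0.0, 1.0)


def _fix_odd_crossings(crossings: np.ndarray) -> np.ndarray:
    """Drop the single tightest duplicate from a degenerate crossing list."""
    if len(crossings) < 2:
        return crossings[:0]
    gaps = np.diff(crossings)
    j = int(gaps.argmin())
    return np.delete(crossings, j if gaps[j] < 1e-9 else len(crossings) - 1)


def soft_occupancy(volume: ScalarVolume, width: float = 4.0) -> ScalarVolume:
    """Signed-distance ramp intensity from a binary occupancy volume.

    Values rise linearly from 0 (``width`` mm outside the surface) through
    0.5 (on the surface) to 1 (``width`` mm inside), saturating beyond.  The
    0.5 isosurface coincides with the binary interface, while intensity
    gradients extend ``width`` mm to each side — a much longer-range
    registration force than a thin smoothed-binary shell provides.
    """
    binary = volume.values > 0.5
    if not binary.any() or binary.all():
        raise GeometryError("soft_occupancy needs a volume with an interface")
    d_out = ndimage.distance_transform_edt(~binary, sampling=volume.spacing)
    d_in = ndimage.distance_transform_edt(binary, sampling=volume.spacing)
    signed = d_in - d_out  # positive inside
    vals = np.clip(0.5 + 0.5 * signed / width, 0.0, 1.0)
    return volume.like(vals)


def extract_surface(volume: ScalarVolume, iso: float = 0.5) -> trimesh.Trimesh:
    """Marching-cubes isosurface in world mm; largest connected component kept."""
    from skimage.measure import marching_cubes

    vmin, vmax = float(volume.values.min()), float(volume.values.max())
    if not (vmin < iso < vmax):
        raise GeometryError(
            f"iso level {iso} outside volume value range [{vmin}, {vmax}]")
    verts, faces, _, _ = marching_cubes(volume.values, level=iso,
                                        spacing=tuple(volume.spacing))
    verts = verts + volume.origin
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    parts = mesh.split(only_watertight=False)
    if len(parts) > 1:
        mesh = max(parts, key=lambda m: len(m.vertices))
    if mesh.volume < 0:
        mesh.invert()
    return mesh


# ---------------------------------------------------------------------------
# distance models
# ---------------------------------------------------------------------------

@dataclass
class DistanceModel:
    """Per-vertex signed distances of a carrier mesh to a reference mesh."""

    signed_distances: np.ndarray      # (n_carrier_vertices,), mm
    bin_edges: np.ndarray             # histogram over [-6, 6] + open end bins
    counts: np.ndarray
    hausdorff: float                  # symmetric, mm
    display_range: tuple[float, float] = HISTOGRAM_RANGE

    def modal_bin_center(self) -> float:
        """Centre of the most populated finite histogram bin."""
        finite = self.counts[1:-1]
        j = int(finite.argmax()) + 1
        return 0.5 * (self.bin_edges[j] + self.bin_edges[j + 1])


def distance_model(carrier: trimesh.Trimesh, reference: trimesh.Trimesh
                   ) -> DistanceModel:
    """Signed distances of carrier vertices to the reference surface.

    Sign is negative where a carrier vertex lies inside the reference mesh.
    Both meshes must already share a common frame (run ICP first).  Also
    reports the symmetric Hausdorff distance (max of both directed maxima).
    """
    if len(carrier.vertices) == 0 or len(reference.vertices) == 0:
        raise GeometryError("distance_model requires non-empty meshes")
    q_ref = SurfaceQuery(reference)
    _, d = q_ref.closest_point(carrier.vertices)
    inside = q_ref.contains(carrier.vertices)
    signed = np.where(inside, -d, d)

    q_car = SurfaceQuery(carrier)
    _, d_rev = q_car.closest_point(reference.vertices)
    hausdorff = float(max(d.max(), d_rev.max()))

    lo, hi = HISTOGRAM_RANGE
    inner = np.arange(lo, hi + 1e-9, HISTOGRAM_BIN_WIDTH)
    edges = np.concatenate([[-np.inf], inner, [np.inf]])
    counts, _ = np.histogram(signed, bins=edges)
    return DistanceModel(signed, edges, counts, hausdorff)
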