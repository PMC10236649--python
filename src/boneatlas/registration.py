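"""Registration engines: rigid ICP on meshes, affine and deformable on volumes.

The deformable engine is a multi-resolution Gaussian-regularized
demons-style method with Jacobian monitoring — a desk-scale diffeomorphic-style
registration that preserves the structure of symmetric-normalization
pipelines (smooth dense displacement fields, invertibility checks) at
tractable cost.

Direction conventions
---------------------
``affine_register(moving, fixed)`` and ``deformable_register`` return
transforms mapping FIXED-space coordinates into MOVING space (the pull-back /
resampling convention).  A :class:`SubjectTransform` with the template as
fixed image therefore maps template-space points into subject space, which is
exactly what both template resampling and forward landmark transport need.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage
from scipy.linalg import expm, logm
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .errors import RegistrationError
from .geometry import ScalarVolume, SurfaceQuery

log = logging.getLogger(__name__)

FOREGROUND_EPS = 0.05


# ---------------------------------------------------------------------------
# transform types
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """x -> R x + t with R orthonormal, det +1."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, first: "RigidTransform") -> "RigidTransform":
        """self o first (apply ``first``, then ``self``)."""
        return RigidTransform(self.rotation @ first.rotation,
                              self.rotation @ first.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m


@dataclass
class AffineTransform:
    """x -> L x + t with L invertible."""

    linear: np.ndarray
    translation: np.ndarray
    converged: bool = True

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.linear)) < 1e-6:
            raise RegistrationError("affine linear part is (near-)singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "AffineTransform":
        m = np.asarray(m, dtype=float)
        return cls(m[:3, :3], m[:3, 3])

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.linear.T + self.translation

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.linear)
        return AffineTransform(inv, -inv @ self.translation)

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.linear
        m[:3, 3] = self.translation
        return m


@dataclass
class DisplacementField:
    """Dense vectors u (mm) on a reference grid; maps x -> x + u(x)."""

    origin: np.ndarray
    spacing: np.ndarray
    u: np.ndarray  # (nx, ny, nz, 3)
    jacobian_positive_fraction: float = 1.0

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 4 or self.u.shape[-1] != 3:
            raise RegistrationError("displacement field must be (nx,ny,nz,3)")

    @classmethod
    def zeros_like(cls, vol: ScalarVolume) -> "DisplacementField":
        return cls(vol.origin.copy(), vol.spacing.copy(), np.zeros(vol.dims + (3,)))

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.u.shape[:3]

    @property
    def max_abs(self) -> float:
        return float(np.linalg.norm(self.u, axis=-1).max()) if self.u.size else 0.0

    def sample_u(self, points: np.ndarray) -> np.ndarray:
        """Trilinear u at world points; clamped (nearest) outside the grid."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = ((pts - self.origin) / self.spacing).T
        out = np.empty((len(pts), 3))
        for d in range(3):
            out[:, d] = ndimage.map_coordinates(self.u[..., d], idx, order=1,
                                                mode="nearest")
        return out

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts + self.sample_u(pts)

    def in_domain(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = (pts - self.origin) / self.spacing
        dims = np.array(self.dims)
        return np.all((idx >= -0.5) & (idx <= dims - 0.5), axis=1)

    def scaled(self, s: float) -> "DisplacementField":
        return DisplacementField(self.origin.copy(), self.spacing.copy(), self.u * s)


@dataclass
class SubjectTransform:
    """Affine + dense field mapping template-space points to subject space.

    ``order='field_first'`` (the forward registration output) applies
    x -> A(x + u(x)); ``order='affine_first'`` (the inverse representation)
    applies x -> A(x) + u(A(x)).  Both parts live on the template grid.
    """

    affine: AffineTransform
    field: DisplacementField | None = None
    order: str = "field_first"

    def apply_points(self, points: np.ndarray, warn_outside: bool = True
                     ) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.field is None:
            return self.affine.apply(pts)
        if self.order == "field_first":
            inside = self.field.in_domain(pts)
            out = self.affine.apply(self.field.apply(pts))
            fallback = self.affine.apply(pts)
        else:
            mid = self.affine.apply(pts)
            inside = self.field.in_domain(mid)
            out = self.field.apply(mid)
            fallback = mid
        if not inside.all():
            if warn_outside:
                log.warning("%d point(s) outside field domain; affine-only fallback",
                            int((~inside).sum()))
            out = np.where(inside[:, None], out, fallback)
        return out

    def scaled(self, s: float) -> "SubjectTransform":
        """Geodesic-style fractional transform: field*s, affine^s (matrix log)."""
        try:
            m = logm(self.affine.matrix)
            if np.iscomplexobj(m) and np.abs(m.imag).max() > 1e-8:
                raise ValueError("complex matrix log")
            aff = AffineTransform.from_matrix(expm(s * m.real))
        except Exception:
            log.warning("matrix log failed; scaling affine linearly")
            aff = AffineTransform.from_matrix(
                (1 - s) * np.eye(4) + s * self.affine.matrix)
        fld = self.field.scaled(s) if self.field is not None else None
        return SubjectTransform(aff, fld, self.order)


def warp_points(points: np.ndarray, transform) -> np.ndarray:
    """Apply a RigidTransform / AffineTransform / DisplacementField /
    SubjectTransform to world points."""
    if isinstance(transform, SubjectTransform):
        return transform.apply_points(points)
    return transform.apply(points)


def warp_volume(vol: ScalarVolume, transform, out_grid: ScalarVolume | None = None,
                order: int = 1) -> ScalarVolume:
    """Pull-back resampling: output voxel at x takes value vol(phi(x)).

    ``order`` selects the interpolant (1 = trilinear; 3 = cubic spline,
    less diffusive under repeated resampling).
    """
    grid = out_grid if out_grid is not None else vol
    coords = grid.grid_world_coords().reshape(-1, 3)
    mapped = warp_points(coords, transform) if transform is not None else coords
    vals = vol.sample(mapped, order=order).reshape(grid.dims)
    return ScalarVolume(grid.origin.copy(), grid.spacing.copy(), vals)


def resample_to_grid(vol: ScalarVolume, grid: ScalarVolume) -> ScalarVolume:
    return warp_volume(vol, None, out_grid=grid)


# ---------------------------------------------------------------------------
# rigid ICP on meshes
# ---------------------------------------------------------------------------

def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid fit mapping src onto dst (no scaling)."""
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    h = (src - mu_s).T @ (dst - mu_d)
    u, s, vt = np.linalg.svd(h)
    if s[-1] < 1e-12 * max(s[0], 1.0):
        raise RegistrationError("degenerate correspondence: rank-deficient "
                                "cross-covariance in rigid fit")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = mu_d - r @ mu_s
    return RigidTransform(r, t)


def _clamp_rotation(r: np.ndarray, max_deg: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    rot = Rotation.from_matrix(r)
    vec = rot.as_rotvec()
    angle = np.linalg.norm(vec)
    limit = np.deg2rad(max_deg)
    if angle <= limit:
        return r
    return Rotation.from_rotvec(vec * (limit / angle)).as_matrix()


def icp_align(moving: trimesh.Trimesh, fixed: trimesh.Trimesh,
              max_iter: int = 60, tol: float = 1e-5,
              subsample: int = 1000, seed: int = 0,
              trim: float = 1.0, normal_cos: float | None = None,
              max_rotation_deg: float | None = None
              ) -> tuple[RigidTransform, trimesh.Trimesh, float]:
    """Iterative closest point: rigid-only alignment of moving onto fixed.

    Pairs (subsampled) moving vertices with their closest points on the fixed
    surface, solves the rigid fit by SVD, and iterates until the RMS residual
    change falls below ``tol``.  Returns the cumulative transform, the aligned
    copy of ``moving`` and the final RMS residual (mm).

    Robustness options for populations whose *shape differences* (not pose)
    would otherwise drag the fit into spurious axial rotations:
    ``trim`` keeps only the best-matching fraction of pairs for the fit;
    ``normal_cos`` rejects pairs whose surface normals disagree beyond the
    given cosine; ``max_rotation_deg`` is a trust region appropriate when
    the acquisition protocol bounds the true pose offset.
    """
    if len(moving.vertices) == 0 or len(fixed.vertices) == 0:
        raise RegistrationError("icp_align requires non-empty meshes")
    query = SurfaceQuery(fixed)
    pts = np.asarray(moving.vertices, dtype=float)
    normals = np.asarray(moving.vertex_normals, dtype=float) \
        if normal_cos is not None else None
    if subsample and subsample < len(pts):
        rng = np.random.default_rng(seed)
        sel = rng.choice(len(pts), size=subsample, replace=False)
        pts = pts[sel]
        if normals is not None:
            normals = normals[sel]
    if normal_cos is not None:
        fixed_tree = cKDTree(np.asarray(fixed.vertices))
        fixed_normals = np.asarray(fixed.vertex_normals, dtype=float)

    transform = RigidTransform.identity()
    prev_rms = np.inf
    rms = np.inf
    for _ in range(max_iter):
        cur = transform.apply(pts)
        # approximate pairing (k-NN candidates) is ample for ICP and much faster
        closest, d = query.closest_point(cur, exact=False)
        rms = float(np.sqrt(np.mean(d ** 2)))
        keep = np.ones(len(pts), dtype=bool)
        if normal_cos is not None:
            _, vidx = fixed_tree.query(closest)
            ndot = np.einsum("ij,ij->i", normals @ transform.rotation.T,
                             fixed_normals[vidx])
            gated = ndot > normal_cos
            if gated.sum() >= 100:
                keep = gated
        if trim < 1.0:
            thr = np.quantile(d[keep], trim)
            keep &= d <= thr
        transform = _kabsch(pts[keep], closest[keep])
        if max_rotation_deg is not None:
            clamped = _clamp_rotation(transform.rotation, max_rotation_deg)
            if clamped is not transform.rotation:
                # re-fit the translation for the clamped rotation
                mu_s = pts[keep].mean(axis=0)
                mu_d = closest[keep].mean(axis=0)
                transform = RigidTransform(clamped, mu_d - clamped @ mu_s)
        if abs(prev_rms - rms) < tol:
            break
        prev_rms = rms
    aligned = moving.copy()
    aligned.vertices = transform.apply(np.asarray(moving.vertices))
    return transform, aligned, rms


# ---------------------------------------------------------------------------
# volume pyramid helpers
# ---------------------------------------------------------------------------

def _downsample(vol: ScalarVolume, factor: int) -> ScalarVolume:
    if factor == 1:
        return vol
    sm = ndimage.gaussian_filter(vol.values, sigma=0.5 * factor)
    vals = sm[::factor, ::factor, ::factor]
    return ScalarVolume(vol.origin.copy(), vol.spacing * factor, vals)


def _volume_moments(vol: ScalarVolume) -> tuple[float, np.ndarray, np.ndarray]:
    w = vol.values
    total = float(w.sum())
    if total <= 0:
        raise RegistrationError("cannot register an all-zero volume")
    coords = vol.grid_world_coords().reshape(-1, 3)
    wf = w.reshape(-1)
    mu = (coords * wf[:, None]).sum(axis=0) / total
    diff = coords - mu
    cov = (diff * wf[:, None]).T @ diff / total
    return total, mu, cov


# ---------------------------------------------------------------------------
# affine registration
# ---------------------------------------------------------------------------

def affine_register(moving: ScalarVolume, fixed: ScalarVolume,
                    factors: tuple[int, ...] = (4, 2),
                    max_iter: int = 60,
                    init: AffineTransform | None = None,
                    linear_bound: float = 0.3,
                    translation_bound: float | None = None) -> AffineTransform:
    """Affine transform mapping fixed-space points into moving space.

    Initialized by the better (coarse SSD) of identity and intensity
    moment matching, then refined by multi-resolution bounded L-BFGS on the
    sum of squared intensity differences (SSD) with an analytic gradient.
    The refinement is box-bounded around the initializer (``linear_bound``
    per matrix entry, ``translation_bound`` mm, default 10% of the volume
    extent): elongated near-symmetric shapes otherwise admit pathological
    far-away SSD minima (axis flips, shaft-onto-shaft shears), and gross
    pose is the job of the upstream rigid prealignment.  Guarantees the
    returned transform's full-resolution SSD does not exceed the
    initialization's.
    """
    if float(moving.values.sum()) == 0 or float(fixed.values.sum()) == 0:
        raise RegistrationError("cannot register an all-zero volume")
    if init is None:
        _, mu_m, cov_m = _volume_moments(moving)
        _, mu_f, cov_f = _volume_moments(fixed)
        lm = _sym_sqrt(cov_m)
        lf_inv = np.linalg.inv(_sym_sqrt(cov_f))
        linear0 = lm @ lf_inv
        t0 = mu_m - linear0 @ mu_f
        moment_init = AffineTransform(linear0, t0)
        # moment matching can mislead on pre-aligned inputs; start from the
        # better of the two candidates
        coarse_m = _downsample(moving, factors[0])
        coarse_f = _downsample(fixed, factors[0])
        candidates = [moment_init, AffineTransform.identity()]
        ssds = [_affine_ssd(coarse_m, coarse_f, c) for c in candidates]
        init = candidates[int(np.argmin(ssds))]

    if translation_bound is None:
        translation_bound = 0.1 * float(np.max(np.array(fixed.dims) * fixed.spacing))
    # optimize in shape-centred coordinates y = c + L (x - c) + t so that the
    # per-entry bounds on L limit the transform's effect uniformly over the
    # shape; in corner-origin world coordinates a small shear entry times a
    # large coordinate would slip metres of tangential (SSD-invisible) motion
    _, c_fixed, _ = _volume_moments(fixed)
    lin0 = init.linear
    tc0 = init.apply(c_fixed) - c_fixed
    p0 = np.concatenate([lin0.reshape(-1), tc0])
    lo = p0 - np.concatenate([np.full(9, linear_bound),
                              np.full(3, translation_bound)])
    hi = p0 + np.concatenate([np.full(9, linear_bound),
                              np.full(3, translation_bound)])
    bounds = list(zip(lo, hi))
    params = p0.copy()

    def to_affine(p: np.ndarray) -> AffineTransform:
        lin = p[:9].reshape(3, 3)
        return AffineTransform(lin, c_fixed + p[9:] - lin @ c_fixed)

    for factor in factors:
        mv = _downsample(moving, factor)
        fx = _downsample(fixed, factor)
        grads = np.stack(np.gradient(mv.values, *mv.spacing), axis=-1)
        coords = fx.grid_world_coords().reshape(-1, 3)
        fvals = fx.values.reshape(-1)
        # restrict to voxels that can carry signal for either image (with a
        # dilated margin so shrink-away moves are still penalized)
        warped0 = warp_volume(mv, to_affine(params), out_grid=fx).values
        informative = (fx.values > 0.01) | (warped0 > 0.01)
        informative = ndimage.binary_dilation(informative, iterations=3)
        keep = informative.reshape(-1)
        coords_all, fvals_all = coords[keep], fvals[keep]
        coords_c = coords_all - c_fixed

        def cost(p: np.ndarray) -> tuple[float, np.ndarray]:
            lin = p[:9].reshape(3, 3)
            t = p[9:]
            y = coords_c @ lin.T + (c_fixed + t)
            idx = ((y - mv.origin) / mv.spacing).T
            w = ndimage.map_coordinates(mv.values, idx, order=1, mode="constant")
            diff = w - fvals_all
            g = np.empty_like(y)
            for d in range(3):
                g[:, d] = ndimage.map_coordinates(grads[..., d], idx, order=1,
                                                  mode="constant")
            wg = diff[:, None] * g
            grad_lin = 2.0 * wg.T @ coords_c
            grad_t = 2.0 * wg.sum(axis=0)
            return float(np.sum(diff ** 2)), np.concatenate(
                [grad_lin.reshape(-1), grad_t])

        res = minimize(cost, params, jac=True, method="L-BFGS-B",
                       bounds=bounds, options={"maxiter": max_iter, "ftol": 1e-10})
        params = res.x

    refined = to_affine(params)
    ssd_init = _affine_ssd(moving, fixed, init)
    ssd_ref = _affine_ssd(moving, fixed, refined)
    if ssd_ref > ssd_init:
        log.warning("affine refinement failed to reduce full-resolution SSD "
                    "(%.4g -> %.4g); keeping initialization", ssd_init, ssd_ref)
        init.converged = False
        return init
    refined.converged = True
    return refined


def _affine_ssd(moving: ScalarVolume, fixed: ScalarVolume,
                transform: AffineTransform) -> float:
    warped = warp_volume(moving, transform, out_grid=fixed)
    return float(np.sum((warped.values - fixed.values) ** 2))


def _sym_sqrt(m: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(m)
    w = np.clip(w, 1e-12, None)
    return v @ np.diag(np.sqrt(w)) @ v.T


# ---------------------------------------------------------------------------
# deformable (demons-style) registration
# ---------------------------------------------------------------------------

def deformable_register(moving: ScalarVolume, fixed: ScalarVolume,
                        levels: int = 3,
                        iters_per_level: int | tuple[int, ...] = (40, 25, 10),
                        update_sigma: float = 2.0,
                        total_sigma: float = 1.5,
                        check_jacobian: bool = True) -> DisplacementField:
    """Dense displacement field on the fixed grid mapping fixed-space points
    toward moving space.

    Multi-resolution demons: at each level the normalized intensity-difference
    force is smoothed with ``update_sigma`` (mm), composed into the running
    field, and the total field smoothed with ``total_sigma`` (mm).  SSD is
    tracked and the best field kept.  The Jacobian determinant of the final
    map is monitored on the foreground (logged, stored on the result).
    """
    if not fixed.same_grid(moving, tol=1e-6):
        raise RegistrationError("deformable_register requires a shared grid "
                                "(affine-resample first)")
    if float(moving.values.sum()) == 0 and float(fixed.values.sum()) == 0:
        raise RegistrationError("cannot register two all-zero volumes")
    if isinstance(iters_per_level, int):
        iters = (iters_per_level,) * levels
    else:
        iters = tuple(iters_per_level)
        if len(iters) != levels:
            raise RegistrationError("iters_per_level length must equal levels")

    extent = float(np.max(np.array(fixed.dims) * fixed.spacing))
    u_prev: np.ndarray | None = None
    for li, factor in enumerate(2 ** np.arange(levels - 1, -1, -1)):
        mv = _downsample(moving, int(factor))
        fx = _downsample(fixed, int(factor))
        dims = fx.dims
        if u_prev is None:
            u = np.zeros(dims + (3,))
        else:
            u = _resize_field(u_prev, dims)
        u, warped = _demons_level(mv, fx, u, iters[li], update_sigma,
                                  total_sigma, extent)
        u_prev = u

    fld = DisplacementField(fixed.origin.copy(), fixed.spacing.copy(),
                            u_prev.astype(float))
    # the finest-level warped moving image, free to reuse by callers
    fld.warped = np.asarray(warped, dtype=float)
    if check_jacobian:
        fld.jacobian_positive_fraction = _positive_jacobian_fraction(fld, fixed)
        if fld.jacobian_positive_fraction < 0.99:
            log.warning("deformable field folds on %.1f%% of foreground voxels",
                        100 * (1 - fld.jacobian_positive_fraction))
    return fld


def _demons_level(mv: ScalarVolume, fx: ScalarVolume, u: np.ndarray,
                  n_iter: int, update_sigma: float, total_sigma: float,
                  extent: float) -> np.ndarray:
    spacing = fx.spacing
    sig_up = update_sigma / spacing
    sig_tot = total_sigma / spacing
    base_idx = np.stack(np.meshgrid(*[np.arange(n, dtype=np.float32)
                                      for n in fx.dims],
                                    indexing="ij"), axis=-1)
    fvals = fx.values.astype(np.float32)
    mvals = mv.values.astype(np.float32)
    inv_spacing = (1.0 / spacing).astype(np.float32)
    u = u.astype(np.float32)

    def warp(uu: np.ndarray) -> np.ndarray:
        idx = base_idx + uu * inv_spacing
        return ndimage.map_coordinates(mvals, np.moveaxis(idx, -1, 0),
                                       order=1, mode="constant")

    w = warp(u)
    best_ssd = float(np.sum((w - fvals) ** 2))
    best_u = u.copy()
    for _ in range(n_iter):
        diff = w - fvals
        g = np.stack(np.gradient(w, *spacing), axis=-1)
        gnorm2 = np.sum(g ** 2, axis=-1)
        denom = gnorm2 + diff ** 2
        scale = np.where(denom > 1e-12,
                         -diff / np.where(denom > 1e-12, denom, 1.0), 0.0)
        delta = g * scale[..., None]
        for d in range(3):
            delta[..., d] = ndimage.gaussian_filter(delta[..., d], sigma=sig_up[d])
        # compose: u_new(x) = delta(x) + u(x + delta(x))
        idx = np.moveaxis(base_idx + delta * inv_spacing, -1, 0)
        u_comp = np.empty_like(u)
        for d in range(3):
            u_comp[..., d] = ndimage.map_coordinates(u[..., d], idx, order=1,
                                                     mode="nearest")
        u = u_comp + delta
        for d in range(3):
            u[..., d] = ndimage.gaussian_filter(u[..., d], sigma=sig_tot[d])
        umax = float(np.sqrt((u ** 2).sum(axis=-1).max()))
        if umax > 0.5 * extent:
            raise RegistrationError(
                f"displacement field exploded (max |u| = {umax:.1f} mm "
                f"> half the volume extent {extent:.1f} mm)")
        w = warp(u)
        ssd = float(np.sum((w - fvals) ** 2))
        if ssd < best_ssd:
            best_ssd = ssd
            best_u = u.copy()
    return best_u, warp(best_u)


def _resize_field(u: np.ndarray, dims: tuple[int, int, int]) -> np.ndarray:
    out = np.empty(dims + (3,))
    zoom = [dims[d] / u.shape[d] for d in range(3)]
    for d in range(3):
        out[..., d] = ndimage.zoom(u[..., d], zoom, order=1, grid_mode=False,
                                   mode="nearest")
    return out


def _positive_jacobian_fraction(fld: DisplacementField, fixed: ScalarVolume
                                ) -> float:
    phi = fixed.grid_world_coords() + fld.u
    jac = np.empty(fixed.dims + (3, 3))
    for d in range(3):
        grads = np.gradient(phi[..., d], *fixed.spacing)
        for e in range(3):
            jac[..., d, e] = grads[e]
    det = np.linalg.det(jac)
    fg = fixed.values > FOREGROUND_EPS
    if fg.sum() == 0:
        return 1.0
    return float((det[fg] > 0).mean())


# ---------------------------------------------------------------------------
# field inversion and transform averaging
# ---------------------------------------------------------------------------

def invert_field(fld: DisplacementField, iters: int = 30, tol: float = 0.05,
                 foreground: np.ndarray | None = None,
                 coarse_factor: int = 1) -> DisplacementField:
    """Fixed-point inverse: v_{n+1}(x) = -u(x + v_n(x)).

    Convergence is measured as the mean round-trip error
    ``|phi(phi^{-1}(x)) - x|`` (restricted to ``foreground`` voxels when
    given); failure to reach ``tol`` raises with the achieved residual.
    ``coarse_factor`` > 1 solves on a decimated grid (the inverse of a smooth
    field is smooth; useful where many inverses feed an average).
    """
    if coarse_factor > 1:
        sub = DisplacementField(fld.origin.copy(), fld.spacing * coarse_factor,
                                fld.u[::coarse_factor, ::coarse_factor,
                                      ::coarse_factor])
        fg = (foreground[::coarse_factor, ::coarse_factor, ::coarse_factor]
              if foreground is not None else None)
        inv_c = invert_field(sub, iters=iters, tol=tol, foreground=fg)
        return DisplacementField(fld.origin.copy(), fld.spacing.copy(),
                                 _resize_field(inv_c.u, fld.dims))
    coords = np.stack(np.meshgrid(
        *[fld.origin[d] + fld.spacing[d] * np.arange(fld.dims[d]) for d in range(3)],
        indexing="ij"), axis=-1).reshape(-1, 3)
    if foreground is not None:
        mask = foreground.reshape(-1)
    else:
        mask = np.ones(len(coords), dtype=bool)
    v = np.zeros_like(coords)
    residual = np.inf
    omega = 1.0  # damping kicks in if the plain iteration stalls
    prev_residual = np.inf
    for _ in range(iters):
        v = (1.0 - omega) * v - omega * fld.sample_u(coords + v)
        round_trip = fld.sample_u(coords + v) + v
        residual = float(np.linalg.norm(round_trip[mask], axis=1).mean())
        if residual < tol:
            break
        if residual > 0.95 * prev_residual:
            omega = 0.5
        prev_residual = residual
    if residual >= tol:
        raise RegistrationError(
            f"field inversion did not converge (residual {residual:.4f} mm "
            f"> tol {tol} mm after {iters} iterations)")
    inv = DisplacementField(fld.origin.copy(), fld.spacing.copy(),
                            v.reshape(fld.dims + (3,)))
    return inv


def invert_subject_transform(t: SubjectTransform, iters: int = 30,
                             tol: float = 0.05,
                             foreground: np.ndarray | None = None,
                             coarse_factor: int = 1) -> SubjectTransform:
    """Inverse of a field-first transform, represented affine-first.

    (A o (id+u))^{-1} = (id+u)^{-1} o A^{-1}: apply the inverse affine, then
    the inverted field (which lives on the template grid).
    """
    if t.order != "field_first":
        raise RegistrationError("expected a field_first transform")
    inv_aff = t.affine.inverse()
    inv_fld = (invert_field(t.field, iters=iters, tol=tol, foreground=foreground,
                            coarse_factor=coarse_factor)
               if t.field is not None else None)
    return SubjectTransform(inv_aff, inv_fld, order="affine_first")


def average_transforms(transforms: list[SubjectTransform]) -> SubjectTransform:
    """Componentwise mean of displacement fields; log-Euclidean mean of the
    affine parts (arithmetic fallback with a warning if any matrix log fails)."""
    if not transforms:
        raise RegistrationError("cannot average an empty transform list")
    orders = {t.order for t in transforms}
    if len(orders) > 1:
        raise RegistrationError("cannot average transforms of mixed order")
    logs = []
    try:
        for t in transforms:
            m = logm(t.affine.matrix)
            if np.iscomplexobj(m) and np.abs(m.imag).max() > 1e-8:
                raise ValueError("complex matrix log")
            logs.append(m.real)
        mean_aff = AffineTransform.from_matrix(expm(np.mean(logs, axis=0)))
    except Exception:
        log.warning("log-Euclidean affine averaging failed; using arithmetic mean")
        mean_aff = AffineTransform.from_matrix(
            np.mean([t.affine.matrix for t in transforms], axis=0))

    fields = [t.field for t in transforms if t.field is not None]
    mean_fld = None
    if fields:
        ref = fields[0]
        for f in fields[1:]:
            if f.dims != ref.dims or not np.allclose(f.origin, ref.origin) \
                    or not np.allclose(f.spacing, ref.spacing):
                raise RegistrationError("fields must share one grid to average")
        mean_fld = DisplacementField(ref.origin.copy(), ref.spacing.copy(),
                                     np.mean([f.u for f in fields], axis=0))
    return SubjectTransform(mean_aff, mean_fld, order=transforms[0].order)


# ---------------------------------------------------------------------------
# on-disk representation
# ---------------------------------------------------------------------------

def save_field(fld: DisplacementField, path) -> None:
    """Displacement field as an NRRD vector volume (mm)."""
    import SimpleITK as sitk

    arr = np.ascontiguousarray(fld.u.transpose(2, 1, 0, 3).astype(np.float32))
    img = sitk.GetImageFromArray(arr, isVector=True)
    img.SetOrigin(tuple(fld.origin))
    img.SetSpacing(tuple(fld.spacing))
    sitk.WriteImage(img, str(path), useCompression=False)


def load_field(path) -> DisplacementField:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    u = sitk.GetArrayFromImage(img).transpose(2, 1, 0, 3).astype(float)
    return DisplacementField(np.array(img.GetOrigin()),
                             np.array(img.GetSpacing()), u)


def save_transform(t: SubjectTransform, json_path, field_path=None) -> None:
    """Transform as JSON (affine 3x4 row-major) plus an NRRD field file."""
    import json
    from pathlib import Path

    json_path = Path(json_path)
    data = {
        "affine_3x4_row_major": np.hstack(
            [t.affine.linear, t.affine.translation[:, None]]).reshape(-1).tolist(),
        "order": t.order,
        "field": None,
    }
    if t.field is not None:
        if field_path is None:
            field_path = json_path.with_suffix(".nrrd")
        save_field(t.field, field_path)
        data["field"] = Path(field_path).name
    json_path.write_text(json.dumps(data, indent=2))


def load_transform(json_path) -> SubjectTransform:
    import json
    from pathlib import Path

    json_path = Path(json_path)
    data = json.loads(json_path.read_text())
    m = np.asarray(data["affine_3x4_row_major"], dtype=float).reshape(3, 4)
    affine = AffineTransform(m[:, :3], m[:, 3])
    fld = (load_field(json_path.parent / data["field"])
           if data.get("field") else None)
    return SubjectTransform(affine, fld, order=data.get("order", "field_first"))
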