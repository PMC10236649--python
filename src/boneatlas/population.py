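"""Synthetic humerus-like shape populations with known ground truth.

The real clinical datasets this pipeline targets (segmented humerus surfaces
with expert landmark annotations) are confidential, so this module generates
stand-in populations whose statistical structure is fully known: a smooth
long-bone-like base solid, a small number of latent deformation modes, rigid
pose jitter, vertex noise, and 11 named landmarks carried through every
deformation analytically (landmarks receive NO noise, so landmark-transfer
error downstream isolates pipeline error).

The base solid is a generalized surface of revolution: the cross-section at
height z is an ellipse with semi-axes ``a(z), b(z)`` and centre
``(cx(z), 0)``.  Its exact volume is pi * integral a(z) b(z) dz, available
in closed form piece by piece (spherical head cap, circular neck frustum,
cylindrical shaft, elliptical distal frustum), which the mesh construction
is tested against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

from .errors import ValidationError
from .geometry import LandmarkSet, write_landmarks, write_stl
from .registration import RigidTransform

# canonical proportions at reference length 300 mm (adult humerus scale)
REF_LENGTH = 300.0
REF_HEAD_RADIUS = 22.0
REF_NECK_RADIUS = 13.0
REF_SHAFT_RADIUS = 9.0    # shaft semi-axis along x
REF_SHAFT_B = 7.0         # shaft semi-axis along y (prism-like real shaft)
REF_TWIST = 0.6           # total axial twist (rad) of section orientation
REF_NECK_DROP = 15.0      # axial extent of the neck frustum
REF_FLARE_HEIGHT = 40.0   # axial extent of the distal flare
REF_DISTAL_A = 28.0       # distal semi-axis along x (epicondylar half-width)
REF_DISTAL_B = 11.0       # distal semi-axis along y
REF_HEAD_OFFSET = 8.0     # medial offset of the head centre
REF_DISTAL_OFFSET = 16.0  # lateral offset of the distal flare centre
REF_TUBERCLE_AMP = 0.38   # relative radius bump of the tubercle analogue
REF_TUBERCLE_THETA = 0.8  # azimuth (rad) of the tubercle bump
# The wide, laterally offset condylar flare, the offset head and the
# tubercle bump below the head mirror real humeral anatomy and are what
# anchors the bone's azimuth: on a plain surface of revolution both rigid
# ICP and intensity registration have a one-parameter family of
# near-optimal axial rotations (bend modes, not pose, then decide the
# azimuth — observed as tens-of-degrees spurious rotations when the
# asymmetries were weak).

N_BASIS_FIELDS = 7
LANDMARK_NAMES = [
    "head_apex",
    "head_equator_lateral", "head_equator_medial",
    "surgical_neck_anterior", "surgical_neck_posterior",
    "midshaft_lateral", "midshaft_medial",
    "epicondyle_lateral", "epicondyle_medial",
    "trochlea_analog", "capitulum_analog",
]


# ---------------------------------------------------------------------------
# population specification
# ---------------------------------------------------------------------------

@dataclass
class PopulationSpec:
    """Study conditions for one synthetic arm.

    Defaults mirror one arm of the motivating study: sample sizes of 50
    ("female") or 43 ("male") per arm, a handful of smooth global deformation
    modes with millimetre-scale amplitudes, small rigid pose jitter and
    sub-voxel vertex noise.
    """

    n_subjects: int = 50
    n_modes: int = 5
    mode_amplitudes: tuple[float, ...] = (5.0, 4.0, 3.0, 2.5, 2.0)
    pose_rotation_sd: float = 2.0     # degrees
    pose_translation_sd: float = 2.0  # mm
    vertex_noise_sd: float = 0.05     # mm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValidationError("n_subjects must be >= 2")
        if self.n_modes < 0:
            raise ValidationError("n_modes must be >= 0")
        if len(self.mode_amplitudes) < self.n_modes:
            raise ValidationError("need one amplitude per mode")
        if any(a < 0 for a in self.mode_amplitudes) or self.vertex_noise_sd < 0 \
                or self.pose_rotation_sd < 0 or self.pose_translation_sd < 0:
            raise ValidationError("standard deviations must be non-negative")


def scaled_spec(spec: PopulationSpec, factor: float) -> PopulationSpec:
    """Uniformly scale the millimetre quantities of a spec.

    The deformation-mode amplitudes, vertex noise and pose translation jitter
    are lengths tied to the bone's physical size; a desk-scale run on a
    ``factor``-scaled base shape uses the same *relative* variability by
    scaling them together (rotation jitter and counts are scale-free).
    """
    return PopulationSpec(
        n_subjects=spec.n_subjects,
        n_modes=spec.n_modes,
        mode_amplitudes=tuple(a * factor for a in spec.mode_amplitudes),
        pose_rotation_sd=spec.pose_rotation_sd,
        pose_translation_sd=spec.pose_translation_sd * factor,
        vertex_noise_sd=spec.vertex_noise_sd * factor,
        seed=spec.seed,
    )


@dataclass
class PopulationSample:
    mesh: trimesh.Trimesh
    landmarks: LandmarkSet
    latent_coeffs: np.ndarray
    pose: RigidTransform


# ---------------------------------------------------------------------------
# base shape
# ---------------------------------------------------------------------------

def _profile_pieces(length: float) -> dict:
    s = length / REF_LENGTH
    head_r = REF_HEAD_RADIUS * s
    zc = length - head_r                      # head sphere centre
    neck_r = REF_NECK_RADIUS * s
    z_head_lo = zc - np.sqrt(head_r ** 2 - neck_r ** 2)
    z_shaft_top = z_head_lo - REF_NECK_DROP * s
    z_flare = REF_FLARE_HEIGHT * s
    return {
        "scale": s, "head_r": head_r, "zc": zc, "neck_r": neck_r,
        "shaft_r": REF_SHAFT_RADIUS * s, "z_head_lo": z_head_lo,
        "z_shaft_top": z_shaft_top, "z_flare": z_flare,
        "shaft_b": REF_SHAFT_B * s,
        "distal_a": REF_DISTAL_A * s, "distal_b": REF_DISTAL_B * s,
        "head_offset": REF_HEAD_OFFSET * s,
        "distal_offset": REF_DISTAL_OFFSET * s, "length": length,
    }


def _cross_section(z: np.ndarray, p: dict) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Semi-axes a(z), b(z) and centre offset cx(z) of the elliptical section."""
    z = np.asarray(z, dtype=float)
    a = np.empty_like(z)
    b = np.empty_like(z)
    cx = np.zeros_like(z)

    head = z >= p["z_head_lo"]
    arg = np.clip(p["head_r"] ** 2 - (z[head] - p["zc"]) ** 2, 0.0, None)
    a[head] = b[head] = np.sqrt(arg)
    frac = (z[head] - p["z_head_lo"]) / max(p["length"] - p["z_head_lo"], 1e-9)
    cx[head] = p["head_offset"] * frac ** 2

    neck = (~head) & (z >= p["z_shaft_top"])
    t = (z[neck] - p["z_shaft_top"]) / max(p["z_head_lo"] - p["z_shaft_top"], 1e-9)
    a[neck] = p["shaft_r"] + (p["neck_r"] - p["shaft_r"]) * t
    b[neck] = p["shaft_b"] + (p["neck_r"] - p["shaft_b"]) * t

    shaft = (~head) & (~neck) & (z >= p["z_flare"])
    a[shaft] = p["shaft_r"]
    b[shaft] = p["shaft_b"]

    flare = z < p["z_flare"]
    t = 1.0 - z[flare] / max(p["z_flare"], 1e-9)
    a[flare] = p["shaft_r"] + (p["distal_a"] - p["shaft_r"]) * t
    b[flare] = p["shaft_b"] + (p["distal_b"] - p["shaft_b"]) * t
    cx[flare] = p["distal_offset"] * t ** 2
    return a, b, cx


def _section_twist(z: np.ndarray, p: dict) -> np.ndarray:
    """In-plane rotation of the section axes: humeral-torsion analogue."""
    return REF_TWIST * np.asarray(z, dtype=float) / p["length"]


def _tubercle_amp(z: np.ndarray, p: dict) -> np.ndarray:
    """Axial window of the tubercle bump (raised-cosine over the neck band)."""
    z = np.asarray(z, dtype=float)
    z_hi = p["zc"]                       # head centre height
    z_lo = p["z_shaft_top"]
    amp = np.zeros_like(z)
    band = (z > z_lo) & (z < z_hi)
    u = (z[band] - z_lo) / (z_hi - z_lo)
    amp[band] = REF_TUBERCLE_AMP * np.sin(np.pi * u) ** 2
    return amp


def _azimuth_bump(theta: np.ndarray) -> np.ndarray:
    """Azimuthal profile of the tubercle, in [0, 1], peaked at its azimuth."""
    return ((1.0 + np.cos(theta - REF_TUBERCLE_THETA)) / 2.0) ** 3


def _section_xy(z: float, theta: np.ndarray, p: dict
                ) -> tuple[np.ndarray, np.ndarray]:
    """Exact cross-section curve at height z (the generating solid)."""
    a, b, cx = _cross_section(np.array([z]), p)
    lam = 1.0 + _tubercle_amp(np.array([z]), p)[0] * _azimuth_bump(theta)
    ex = a[0] * np.cos(theta) * lam
    ey = b[0] * np.sin(theta) * lam
    psi = _section_twist(np.array([z]), p)[0]
    x = cx[0] + ex * np.cos(psi) - ey * np.sin(psi)
    y = ex * np.sin(psi) + ey * np.cos(psi)
    return x, y


def analytic_base_volume(length: float = REF_LENGTH) -> float:
    """Volume (mm^3) of the generating solid, independent of any mesh.

    Cross-section areas come from the exact parametric section curve
    (Green's-theorem integral over a dense angular grid); the axial integral
    uses composite Simpson quadrature split at the profile's breakpoints.
    """
    p = _profile_pieces(length)
    theta = np.linspace(0.0, 2 * np.pi, 4097)

    def area(z: float) -> float:
        x, y = _section_xy(z, theta, p)
        return 0.5 * abs(np.trapezoid(x * np.gradient(y, theta)
                                      - y * np.gradient(x, theta), theta))

    total = 0.0
    breaks = [0.0, p["z_flare"], p["z_shaft_top"], p["z_head_lo"], length]
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        zs = np.linspace(lo, hi, 401)
        total += np.trapezoid([area(z) for z in zs], zs)
    return float(total)


def make_base_shape(resolution: int = 2, length: float = REF_LENGTH
                    ) -> tuple[trimesh.Trimesh, LandmarkSet]:
    """Deterministic watertight long-bone-like mesh with 11 named landmarks.

    ``resolution`` >= 1 controls tessellation density (ring/segment counts
    double per level).  Landmarks sit exactly on mesh vertices at fixed
    parametric locations: head apex, head equator (x2), surgical neck (x2),
    mid-shaft (x2), epicondyle analogues (x2) and trochlea/capitulum
    analogues (x2).
    """
    if resolution < 1:
        raise ValidationError("resolution must be >= 1")
    p = _profile_pieces(length)
    mult = 2 ** (resolution - 1)
    n_theta = 32 * mult

    # ring heights: uniform polar angle over the head cap (good volume
    # convergence), uniform z elsewhere
    n_head = 14 * mult
    ang = np.linspace(np.arcsin(np.clip((p["z_head_lo"] - p["zc"]) / p["head_r"],
                                        -1, 1)),
                      np.pi / 2, n_head + 1)[:-1]
    z_head = p["zc"] + p["head_r"] * np.sin(ang)
    z_neck = np.linspace(p["z_shaft_top"], p["z_head_lo"], 4 * mult, endpoint=False)
    z_shaft = np.linspace(p["z_flare"], p["z_shaft_top"], 12 * mult, endpoint=False)
    z_flare = np.linspace(0.0, p["z_flare"], 7 * mult, endpoint=False)
    z_rings = np.concatenate([z_flare, z_shaft, z_neck, np.sort(z_head)])

    theta = 2 * np.pi * np.arange(n_theta) / n_theta
    a, b, cx = _cross_section(z_rings, p)
    tub = _tubercle_amp(z_rings, p)
    bump = _azimuth_bump(theta)
    n_rings = len(z_rings)

    psi = _section_twist(z_rings, p)
    verts = np.empty((n_rings * n_theta + 2, 3))
    ct, st = np.cos(theta), np.sin(theta)
    for i in range(n_rings):
        base = i * n_theta
        lam = 1.0 + tub[i] * bump
        ex = a[i] * ct * lam
        ey = b[i] * st * lam
        verts[base:base + n_theta, 0] = cx[i] + ex * np.cos(psi[i]) - ey * np.sin(psi[i])
        verts[base:base + n_theta, 1] = ex * np.sin(psi[i]) + ey * np.cos(psi[i])
        verts[base:base + n_theta, 2] = z_rings[i]
    bottom_center = n_rings * n_theta
    apex = bottom_center + 1
    verts[bottom_center] = (cx[0], 0.0, z_rings[0])
    verts[apex] = (p["head_offset"], 0.0, length)

    faces = []
    for i in range(n_rings - 1):
        for j in range(n_theta):
            j2 = (j + 1) % n_theta
            v00 = i * n_theta + j
            v01 = i * n_theta + j2
            v10 = (i + 1) * n_theta + j
            v11 = (i + 1) * n_theta + j2
            faces.append((v00, v01, v11))
            faces.append((v00, v11, v10))
    for j in range(n_theta):  # bottom cap (z = 0, outward normal -z)
        j2 = (j + 1) % n_theta
        faces.append((bottom_center, j2, j))
    top_base = (n_rings - 1) * n_theta
    for j in range(n_theta):  # apex fan
        j2 = (j + 1) % n_theta
        faces.append((apex, top_base + j, top_base + j2))

    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    if mesh.volume < 0:
        mesh.invert()

    landmarks = _place_landmarks(mesh, z_rings, n_theta, p, apex)
    return mesh, landmarks


def _ring_vertex(z_rings: np.ndarray, n_theta: int, z_target: float,
                 theta_target: float) -> int:
    i = int(np.argmin(np.abs(z_rings - z_target)))
    j = int(np.round(theta_target / (2 * np.pi) * n_theta)) % n_theta
    return i * n_theta + j


def _place_landmarks(mesh: trimesh.Trimesh, z_rings: np.ndarray, n_theta: int,
                     p: dict, apex_idx: int) -> LandmarkSet:
    z_mid = 0.5 * (p["z_flare"] + p["z_shaft_top"])
    z_neck = p["z_shaft_top"]
    picks = [
        ("head_apex", None, None, apex_idx),
        ("head_equator_lateral", p["zc"], 0.0, None),
        ("head_equator_medial", p["zc"], np.pi, None),
        ("surgical_neck_anterior", z_neck, np.pi / 2, None),
        ("surgical_neck_posterior", z_neck, 3 * np.pi / 2, None),
        ("midshaft_lateral", z_mid, 0.0, None),
        ("midshaft_medial", z_mid, np.pi, None),
        ("epicondyle_lateral", 0.0, 0.0, None),
        ("epicondyle_medial", 0.0, np.pi, None),
        ("trochlea_analog", 0.0, np.pi / 2 + 0.6, None),
        ("capitulum_analog", 0.0, np.pi / 2 - 0.6, None),
    ]
    names, pts = [], []
    for name, z, th, direct in picks:
        idx = direct if direct is not None else _ring_vertex(z_rings, n_theta, z, th)
        names.append(name)
        pts.append(mesh.vertices[idx])
    return LandmarkSet(names, np.asarray(pts, dtype=float), frame="base")


# ---------------------------------------------------------------------------
# deformation basis
# ---------------------------------------------------------------------------

class DeformationBasis:
    """Seven smooth global displacement fields on the base shape.

    Raw fields (bend-x, bend-y, torsion, head-bulge, shaft-thickness,
    length-scale, distal-flare) are parameterized by the normalized axial
    coordinate, orthogonalized against the six infinitesimal rigid-body
    fields and against each other over the base vertices, and normalized to
    unit RMS displacement — so a latent coefficient of c mm produces c mm RMS
    surface displacement.  The orthogonalized fields remain closed-form
    (linear combinations of the raw fields), so the exact deformation map can
    be evaluated at arbitrary points, in particular at the landmarks.
    """

    def __init__(self, base_mesh: trimesh.Trimesh, length: float,
                 anchor_points: np.ndarray | None = None):
        """``anchor_points`` (default: the 11 landmark positions via the
        caller, else all vertices) define the inner product used for
        orthonormalization.  Orthonormality in the landmark space is what
        lets landmark-cloud PCA recover the planted amplitude spectrum."""
        self.length = float(length)
        self.r_ref = REF_SHAFT_RADIUS * length / REF_LENGTH
        v = np.asarray(base_mesh.vertices, dtype=float)
        self.center = v.mean(axis=0)
        n = len(v)
        anchors = v if anchor_points is None else \
            np.asarray(anchor_points, dtype=float)
        m = len(anchors)

        raw_a = self._raw_fields(anchors)              # (7, m, 3)
        rigid_a = self._rigid_fields(anchors)          # (6, m, 3)
        flat = raw_a.reshape(N_BASIS_FIELDS, -1)
        q, rfac = np.linalg.qr(rigid_a.reshape(6, -1).T, mode="reduced")

        # Gram-Schmidt at the anchor points: project out the rigid span,
        # then previously accepted fields.  Each orthogonalized field keeps
        # a closed form  sum_m w_m * raw_m(x)  -  sum_p beta_p * rigid_p(x).
        self.raw_weights = np.zeros((N_BASIS_FIELDS, N_BASIS_FIELDS))
        self.rigid_weights = np.zeros((N_BASIS_FIELDS, 6))
        ortho: list[np.ndarray] = []
        for j in range(N_BASIS_FIELDS):
            w = np.zeros(N_BASIS_FIELDS)
            w[j] = 1.0
            c = q.T @ flat[j]
            beta = np.linalg.solve(rfac, c)
            f = flat[j] - q @ c
            for k, g in enumerate(ortho):
                proj = (g @ f) / (g @ g)
                f = f - proj * g
                w = w - proj * self.raw_weights[k]
                beta = beta - proj * self.rigid_weights[k]
            rms = np.sqrt(np.mean(np.sum(f.reshape(m, 3) ** 2, axis=1)))
            if rms < 1e-9:
                raise ValidationError("degenerate deformation basis")
            ortho.append(f / rms)
            self.raw_weights[j] = w / rms
            self.rigid_weights[j] = beta / rms
        # evaluate the orthonormalized combinations on the mesh vertices
        raw_v = self._raw_fields(v)
        rigid_v = self._rigid_fields(v)
        self._vertex_fields = (
            np.tensordot(self.raw_weights, raw_v, axes=(1, 0))
            - np.tensordot(self.rigid_weights, rigid_v, axes=(1, 0)))

    def _raw_fields(self, pts: np.ndarray) -> np.ndarray:
        """Fields ordered by the variance rank seen in long-bone populations:
        overall size/length and robustness (thickness) dominate, regional
        bulges follow, bending and torsion are minor."""
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        s = np.clip(z / self.length, 0.0, 1.0)
        zero = np.zeros_like(x)
        rr = self.r_ref

        def gauss(c: float, w: float) -> np.ndarray:
            return np.exp(-((s - c) / w) ** 2)

        fields = np.stack([
            np.stack([zero, zero, (s - 0.5) * rr], axis=1),                    # length scale
            np.stack([gauss(0.5, 0.20) * x, gauss(0.5, 0.20) * y, zero],
                     axis=1),                                                  # shaft thickness
            np.stack([gauss(0.93, 0.10) * x, gauss(0.93, 0.10) * y, zero],
                     axis=1),                                                  # head bulge
            np.stack([gauss(0.0, 0.12) * x, gauss(0.0, 0.12) * y, zero],
                     axis=1),                                                  # distal flare
            np.stack([np.sin(np.pi * s) * rr, zero, zero], axis=1),            # bend-x
            np.stack([zero, np.sin(np.pi * s) * rr, zero], axis=1),            # bend-y
            np.stack([-(s - 0.5) * y, (s - 0.5) * x, zero], axis=1),           # torsion
        ])
        return fields

    def _rigid_fields(self, pts: np.ndarray) -> np.ndarray:
        n = len(pts)
        d = pts - self.center
        f = np.zeros((6, n, 3))
        f[0, :, 0] = 1.0
        f[1, :, 1] = 1.0
        f[2, :, 2] = 1.0
        f[3] = np.cross([1.0, 0, 0], d)
        f[4] = np.cross([0, 1.0, 0], d)
        f[5] = np.cross([0, 0, 1.0], d)
        return f

    @property
    def n_fields(self) -> int:
        return N_BASIS_FIELDS

    def vertex_displacement(self, coeffs: np.ndarray) -> np.ndarray:
        """(N, 3) displacement at base vertices for latent coefficients (mm)."""
        coeffs = np.asarray(coeffs, dtype=float)
        return np.tensordot(coeffs, self._vertex_fields[:len(coeffs)], axes=(0, 0))

    def displacement_at(self, points: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
        """Exact displacement of the orthogonalized fields at arbitrary points."""
        coeffs = np.asarray(coeffs, dtype=float)
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        raw = self._raw_fields(pts)                          # (7, m, 3)
        rigid = self._rigid_fields(pts)                      # (6, m, 3)
        w = coeffs @ self.raw_weights[:len(coeffs)]
        beta = coeffs @ self.rigid_weights[:len(coeffs)]
        return (np.tensordot(w, raw, axes=(0, 0))
                - np.tensordot(beta, rigid, axes=(0, 0)))


# ---------------------------------------------------------------------------
# population generation
# ---------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator, sd_deg: float) -> np.ndarray:
    if sd_deg == 0:
        return np.eye(3)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.normal(0.0, sd_deg))
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def make_population(base_mesh: trimesh.Trimesh, base_landmarks: LandmarkSet,
                    spec: PopulationSpec, length: float | None = None
                    ) -> list[PopulationSample]:
    """Draw a population: per subject, latent mode coefficients, rigid pose
    jitter and iid vertex noise (landmarks are deformed by the exact same
    smooth map and pose, without noise)."""
    if spec.n_modes > N_BASIS_FIELDS:
        raise ValidationError(
            f"n_modes={spec.n_modes} exceeds the {N_BASIS_FIELDS} available "
            "deformation basis fields")
    if length is None:
        length = float(base_mesh.vertices[:, 2].max())
    basis = DeformationBasis(base_mesh, length,
                             anchor_points=base_landmarks.points)
    rng = np.random.default_rng(spec.seed)
    amps = np.asarray(spec.mode_amplitudes[:spec.n_modes], dtype=float)
    verts0 = np.asarray(base_mesh.vertices, dtype=float)
    lm_idx = _landmark_vertex_indices(base_mesh, base_landmarks)

    samples: list[PopulationSample] = []
    for i in range(spec.n_subjects):
        coeffs = rng.normal(0.0, 1.0, size=spec.n_modes) * amps \
            if spec.n_modes else np.zeros(0)
        rot = _random_rotation(rng, spec.pose_rotation_sd)
        trans = rng.normal(0.0, spec.pose_translation_sd, size=3) \
            if spec.pose_translation_sd else np.zeros(3)
        pose = RigidTransform(rot, trans)

        disp = basis.vertex_displacement(coeffs) if spec.n_modes else 0.0
        deformed = verts0 + disp
        posed = pose.apply(deformed)
        noise = rng.normal(0.0, spec.vertex_noise_sd, size=posed.shape) \
            if spec.vertex_noise_sd else 0.0
        mesh = trimesh.Trimesh(vertices=posed + noise,
                               faces=base_mesh.faces.copy(), process=False)

        lm_points = posed[lm_idx]  # landmarks = same map, no noise
        landmarks = base_landmarks.with_points(lm_points, frame=f"subject_{i:03d}")
        samples.append(PopulationSample(mesh, landmarks, coeffs, pose))
    return samples


def _landmark_vertex_indices(mesh: trimesh.Trimesh, landmarks: LandmarkSet
                             ) -> np.ndarray:
    """Landmarks are placed on base vertices; recover their indices."""
    from scipy.spatial import cKDTree

    d, idx = cKDTree(mesh.vertices).query(landmarks.points)
    if np.any(d > 1e-6):
        raise ValidationError("landmarks are not on base mesh vertices")
    return idx


def landmark_displacement(base_mesh: trimesh.Trimesh, base_landmarks: LandmarkSet,
                          coeffs: np.ndarray, length: float | None = None
                          ) -> np.ndarray:
    """Exact deformation-map displacement at the landmark points (no pose)."""
    if length is None:
        length = float(base_mesh.vertices[:, 2].max())
    basis = DeformationBasis(base_mesh, length,
                             anchor_points=base_landmarks.points)
    idx = _landmark_vertex_indices(base_mesh, base_landmarks)
    return basis.vertex_displacement(coeffs)[idx]


# ---------------------------------------------------------------------------
# on-disk representation
# ---------------------------------------------------------------------------

def write_population(samples: list[PopulationSample], spec: PopulationSpec,
                     outdir: str | Path) -> Path:
    """STL + landmark CSV per subject plus a JSON manifest; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, s in enumerate(samples):
        stem = f"subject_{i:03d}"
        write_stl(s.mesh, outdir / f"{stem}.stl")
        write_landmarks(s.landmarks, outdir / f"{stem}_landmarks.csv")
        entries.append({
            "id": stem,
            "mesh": f"{stem}.stl",
            "landmarks": f"{stem}_landmarks.csv",
            "latent_coeffs": [float(c) for c in s.latent_coeffs],
            "pose_rotation": np.asarray(s.pose.rotation).tolist(),
            "pose_translation": np.asarray(s.pose.translation).tolist(),
        })
    manifest = {
        "spec": {
            "n_subjects": spec.n_subjects, "n_modes": spec.n_modes,
            "mode_amplitudes": list(spec.mode_amplitudes),
            "pose_rotation_sd": spec.pose_rotation_sd,
            "pose_translation_sd": spec.pose_translation_sd,
            "vertex_noise_sd": spec.vertex_noise_sd, "seed": spec.seed,
        },
        "subjects": entries,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
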