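"""Template evaluation: explained shape variance and inter-template distance.

Explained variance follows the standard point-distribution-model recipe:
the 11 template landmarks are propagated to every training subject through
the per-subject template->subject transforms, each subject's landmark cloud
is flattened to a 33-vector, and PCA of the sample covariance yields
per-mode explained-variance fractions (eigenvalue over eigenvalue sum).
For n subjects at most n-1 modes carry variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .errors import ValidationError
from .geometry import DistanceModel, LandmarkSet, SurfaceQuery, distance_model
from .registration import SubjectTransform, icp_align

LANDMARK_DIM = 3


@dataclass
class PCAResult:
    eigenvalues: np.ndarray          # descending, length = feature dim
    modes: np.ndarray                # (dim, dim) orthonormal columns
    explained_fraction: np.ndarray
    cumulative_fraction: np.ndarray
    n_subjects: int

    def n_nontrivial_modes(self, rel_tol: float = 1e-10) -> int:
        if self.eigenvalues[0] <= 0:
            return 0
        return int(np.sum(self.eigenvalues > rel_tol * self.eigenvalues[0]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mode": np.arange(1, len(self.eigenvalues) + 1),
            "eigenvalue": self.eigenvalues,
            "explained_fraction": self.explained_fraction,
            "cumulative_fraction": self.cumulative_fraction,
        })


def transfer_landmarks_to_training(template_landmarks: LandmarkSet,
                                   transforms: list[SubjectTransform]
                                   ) -> list[LandmarkSet]:
    """Propagate template landmarks into every training subject's space."""
    clouds = []
    for i, t in enumerate(transforms):
        pts = t.apply_points(template_landmarks.points)
        clouds.append(template_landmarks.with_points(pts, frame=f"subject_{i:03d}"))
    return clouds


def procrustes_align_clouds(clouds: list[LandmarkSet], max_iter: int = 5
                            ) -> list[LandmarkSet]:
    """Generalized Procrustes alignment (rigid, no scaling) of landmark
    configurations to their evolving mean — the standard preliminary of a
    point-distribution model, removing per-cloud residual pose."""
    from .registration import _kabsch

    pts = [np.asarray(c.points, dtype=float) for c in clouds]
    mean = pts[0].copy()
    for _ in range(max_iter):
        pts = [_kabsch(p, mean).apply(p) for p in pts]
        new_mean = np.mean(pts, axis=0)
        done = np.abs(new_mean - mean).max() < 1e-10
        mean = new_mean
        if done:
            break
    return [c.with_points(p) for c, p in zip(clouds, pts)]


def pca_explained_variance(clouds: list[LandmarkSet],
                           procrustes: bool = False) -> PCAResult:
    """Covariance PCA of flattened landmark clouds (raw mm, no
    standardization).

    With ``procrustes`` the clouds are first rigidly aligned to their mean
    (generalized Procrustes), so the spectrum reflects shape variation only;
    without it, residual per-subject pose differences count as variation.
    """
    if len(clouds) < 2:
        raise ValidationError("PCA needs at least two landmark clouds")
    names = clouds[0].names
    for c in clouds[1:]:
        if c.names != names:
            raise ValidationError("landmark names/order differ between clouds")
    if procrustes:
        clouds = procrustes_align_clouds(clouds)
    x = np.stack([c.flatten() for c in clouds])          # (n, 33)
    n, dim = x.shape
    xc = x - x.mean(axis=0)
    # SVD of the centred data: eigenvalues of the sample covariance
    u, s, vt = np.linalg.svd(xc, full_matrices=True)
    eig = np.zeros(dim)
    eig[:len(s)] = s ** 2 / (n - 1)
    modes = vt.T
    total = eig.sum()
    frac = eig / total if total > 0 else np.zeros(dim)
    return PCAResult(eig, modes, frac, np.cumsum(frac), n)


def project_landmarks_to_surface(landmarks: LandmarkSet,
                                 surface: trimesh.Trimesh,
                                 frame: str = "template") -> LandmarkSet:
    """Closest-point projection; defines template landmarks on synthetic runs
    (standing in for manual annotation of the template by an expert)."""
    q = SurfaceQuery(surface)
    closest, _ = q.closest_point(landmarks.points)
    return landmarks.with_points(closest, frame=frame)


def annotate_template(base_mesh: trimesh.Trimesh, base_landmarks: LandmarkSet,
                      template_surface: trimesh.Trimesh) -> LandmarkSet:
    """Place known landmarks on a template surface (expert stand-in).

    The template lives in the population's common frame, which generally
    differs from the canonical base frame by a rigid pose; projecting raw
    base landmarks would leave a tangential bias.  ICP aligns the base mesh
    onto the template surface first, then the rigidly carried landmarks are
    projected onto the surface.
    """
    rigid, _, _ = icp_align(base_mesh, template_surface)
    moved = base_landmarks.with_points(rigid.apply(base_landmarks.points))
    return project_landmarks_to_surface(moved, template_surface)


def compare_templates(template_surface: trimesh.Trimesh,
                      mean_shape: trimesh.Trimesh) -> DistanceModel:
    """ICP-align the template surface to the mean shape, then compute the
    signed distance model (carrier = aligned template surface)."""
    _, aligned, _ = icp_align(template_surface, mean_shape)
    return distance_model(aligned, mean_shape)


def write_pca_csv(result: PCAResult, path: str | Path) -> None:
    result.to_frame().to_csv(path, index=False, float_format="%.10g")


def write_distance_histogram_csv(model: DistanceModel, path: str | Path) -> None:
    edges = model.bin_edges
    df = pd.DataFrame({
        "bin_low_mm": edges[:-1],
        "bin_high_mm": edges[1:],
        "count": model.counts,
    })
    df.to_csv(path, index=False)


def plot_scree(result: PCAResult, path: str | Path, n_modes: int = 15) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = min(n_modes, len(result.eigenvalues))
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(np.arange(1, k + 1), 100 * result.cumulative_fraction[:k],
            marker="o", lw=1.2)
    ax.axhline(99, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("mode")
    ax.set_ylabel("cumulative explained variance (%)")
    ax.set_ylim(0, 101)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_distance_histogram(model: DistanceModel, path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    centers = 0.5 * (model.bin_edges[1:-2] + model.bin_edges[2:-1])
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(centers, model.counts[1:-1], width=0.45)
    ax.set_xlabel("signed distance (mm)")
    ax.set_ylabel("vertex count")
    ax.set_xlim(*model.display_range)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
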