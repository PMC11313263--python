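"""Point-distribution statistical shape model.

Builds an atlas — template (mean shape), PCA shape modes, per-subject
mode scores and cumulative inertia — from a population of corresponded
point sets.  Registration is translation-only (barycentre alignment):
no rotation or scaling is removed, so size and orientation remain part
of the modelled variability and mode 1 behaves as a size mode.

The deformation model is a point-distribution model: subject
displacements from the pointwise mean are stacked and decomposed by
PCA (divisor n-1).  A diffeomorphic/currents atlas would model the
same quantities (template, modes, inertia, scores) without needing
correspondence; here correspondence is available by construction from
the synthetic generator, so PCA on displacements preserves the
analysis semantics exactly and is testable against a brute-force
covariance decomposition.

An optional resolution kernel mimics the "feature size" control of
kernel-based shape models: per-subject displacement fields are
smoothed over the template with a Gaussian of width ``resolution_lambda_W``
before PCA, suppressing features finer than the kernel.  The stiffness
parameter of deformation-based models has no analogue in a PDM; it is
accepted and recorded with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CorrespondenceError, InvalidParameterError
from .mesh_io import mesh_surface_area
from .morphometrics import section_equivalent_diameter
from .synthetic import Centreline, ShapePopulation, grid_to_mesh

__all__ = [
    "KernelParams",
    "ShapeAtlas",
    "barycentre_register",
    "shape_vectors",
    "compute_atlas",
    "cumulative_inertia",
    "n_modes_for",
    "shape_at",
    "reconstruct_subject",
    "template_diameters",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class KernelParams:
    """Deformation-kernel metadata: stiffness and resolution widths (mm)."""

    stiffness_lambda_V: float
    resolution_lambda_W: float

    def __post_init__(self) -> None:
        if self.stiffness_lambda_V <= 0 or self.resolution_lambda_W <= 0:
            raise InvalidParameterError("kernel widths must be > 0")


@dataclass
class ShapeAtlas:
    """Template + PCA shape modes of a corresponded population.

    ``modes`` rows are orthonormal vectors over flattened (x, y, z, ...)
    coordinates; ``eigenvalues`` (mm²) are the per-mode displacement
    variances in non-increasing order; ``scores`` (n_subjects x n_modes,
    mm) have zero column means.
    """

    template: np.ndarray          # (p, 3)
    modes: np.ndarray             # (k, 3p)
    eigenvalues: np.ndarray       # (k,)
    scores: np.ndarray            # (n, k)
    grid_shape: tuple[int, int]
    kernel: KernelParams | None = None

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    @property
    def cumulative_inertia_curve(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total <= 0:
            raise InvalidParameterError("atlas has no shape variance")
        return np.cumsum(self.eigenvalues) / total

    def save(self, out_dir: str | Path) -> None:
        """Serialise atlas to a directory of open text/CSV files."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savetxt(out / "template_points.csv", self.template, delimiter=",",
                   header="x_mm,y_mm,z_mm", comments="")
        np.savetxt(out / "modes.csv", self.modes, delimiter=",")
        meta = pd.DataFrame({
            "mode": np.arange(1, self.n_modes + 1),
            "eigenvalue_mm2": self.eigenvalues,
            "cumulative_inertia": self.cumulative_inertia_curve,
        })
        meta.to_csv(out / "inertia.csv", index=False)
        pd.DataFrame(
            self.scores,
            columns=[f"mode_{i + 1}" for i in range(self.scores.shape[1])],
        ).to_csv(out / "scores.csv", index=False)


def barycentre_register(population: ShapePopulation) -> ShapePopulation:
    """Translate each subject so its point-set barycentre sits at the origin.

    Translation only — the paper-style rigid step aligns barycentres and
    deliberately keeps rotation and scale in the shape variability.
    Idempotent.
    """
    if population.n_subjects == 0:
        raise InvalidParameterError("empty population")
    centred = population.points - population.points.mean(axis=(1, 2), keepdims=True)
    return population.with_points(centred)


def shape_vectors(population: ShapePopulation) -> np.ndarray:
    """Subjects x (3 * points) matrix of flattened coordinates.

    Row i is subject i's (x, y, z, x, y, z, ...) sequence in the shared
    grid order; the clustering stage consumes these rows directly.
    """
    pts = population.points
    if pts.ndim != 4:
        raise CorrespondenceError("population points must share one grid shape")
    return pts.reshape(population.n_subjects, -1).astype(np.float64)


def _gaussian_smooth_displacements(
    disp: np.ndarray, template_flat: np.ndarray, lambda_w: float
) -> np.ndarray:
    """Smooth each subject's displacement field over the template geometry."""
    pts = template_flat.reshape(-1, 3)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    w = np.exp(-0.5 * d2 / lambda_w**2)
    w /= w.sum(axis=1, keepdims=True)
    n = disp.shape[0]
    fields = disp.reshape(n, -1, 3)
    return np.einsum("pq,nqc->npc", w, fields).reshape(n, -1)


def compute_atlas(
    population: ShapePopulation, kernel: KernelParams | None = None
) -> ShapeAtlas:
    """Template + PCA modes of the registered population.

    Mode 1's sign is fixed so its scores correlate non-negatively with
    subject surface area (the size convention: positive score = larger
    aorta); remaining modes are oriented so their largest-magnitude
    loading is positive.
    """
    n = population.n_subjects
    if n < 2:
        raise InvalidParameterError(f"atlas needs >= 2 subjects, got {n}")
    X = shape_vectors(population)
    template_flat = X.mean(axis=0)
    disp = X - template_flat
    if kernel is not None:
        log.warning(
            "stiffness lambda_V=%.3g mm recorded but unused: a point-distribution "
            "model has no deformation-elasticity analogue", kernel.stiffness_lambda_V
        )
        disp = _gaussian_smooth_displacements(
            disp, template_flat, kernel.resolution_lambda_W
        )
    k = min(n - 1, X.shape[1])
    u, s, vt = np.linalg.svd(disp, full_matrices=False)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    eigenvalues = s**2 / (n - 1)
    scores = u * s
    modes = vt
    areas = np.array([population.subject_area(i) for i in range(n)])
    if np.std(scores[:, 0]) > 0 and np.std(areas) > 0:
        if np.corrcoef(scores[:, 0], areas)[0, 1] < 0:
            scores[:, 0] *= -1.0
            modes[0] *= -1.0
    for m in range(1, k):
        lead = modes[m, np.argmax(np.abs(modes[m]))]
        if lead < 0:
            scores[:, m] *= -1.0
            modes[m] *= -1.0
    return ShapeAtlas(
        template=template_flat.reshape(-1, 3),
        modes=modes,
        eigenvalues=eigenvalues,
        scores=scores,
        grid_shape=population.grid_shape,
        kernel=kernel,
    )


def cumulative_inertia(atlas: ShapeAtlas, m: int) -> float:
    """Fraction of total shape variance carried by the first ``m`` modes."""
    if not 1 <= m <= atlas.n_modes:
        raise InvalidParameterError(f"m must be in [1, {atlas.n_modes}], got {m}")
    return float(atlas.cumulative_inertia_curve[m - 1])


def n_modes_for(atlas_or_inertia: ShapeAtlas | np.ndarray, threshold: float) -> int:
    """Smallest mode count whose cumulative inertia reaches ``threshold``.

    Accepts an atlas or a precomputed cumulative-inertia sequence, so a
    reported inertia table can be queried directly.
    """
    if not 0.0 < threshold <= 1.0:
        raise InvalidParameterError("threshold must lie in (0, 1]")
    if isinstance(atlas_or_inertia, ShapeAtlas):
        curve = atlas_or_inertia.cumulative_inertia_curve
    else:
        curve = np.asarray(atlas_or_inertia, dtype=float)
    hits = np.nonzero(curve >= threshold - 1e-12)[0]
    if len(hits) == 0:
        return len(curve)
    return int(hits[0]) + 1


def shape_at(atlas: ShapeAtlas, mode: int, k_sd: float) -> np.ndarray:
    """Template deformed along one mode by ``k_sd`` standard deviations."""
    if not 0 <= mode < atlas.n_modes:
        raise InvalidParameterError(f"mode index out of range: {mode}")
    flat = atlas.template.reshape(-1) + (
        k_sd * np.sqrt(atlas.eigenvalues[mode]) * atlas.modes[mode]
    )
    return flat.reshape(-1, 3)


def reconstruct_subject(atlas: ShapeAtlas, i: int) -> np.ndarray:
    """Subject i rebuilt from all modes and scores (exact up to round-off)."""
    flat = atlas.template.reshape(-1) + atlas.scores[i] @ atlas.modes
    return flat.reshape(-1, 3)


def template_diameters(
    atlas: ShapeAtlas, centreline: Centreline, landmarks: np.ndarray
) -> np.ndarray:
    """Equivalent circular diameters of the template at arc-parameter landmarks.

    At each landmark the template surface is intersected with the plane
    perpendicular to the centreline; the diameter is ``2 sqrt(A / pi)``
    of the section area.
    """
    landmarks = np.asarray(landmarks, dtype=float)
    if np.any((landmarks < 0) | (landmarks > 1)):
        raise InvalidParameterError("landmarks must lie in [0, 1]")
    na, nc = atlas.grid_shape
    mesh = grid_to_mesh(atlas.template.reshape(na, nc, 3))
    out = np.empty(len(landmarks))
    for i, t in enumerate(landmarks):
        out[i] = section_equivalent_diameter(
            mesh, centreline.point_at(t), centreline.tangent_at(t)
        )
    return out


def subject_surface_areas(population: ShapePopulation) -> np.ndarray:
    """Convenience: total grid-mesh surface area per subject (mm²)."""
    return np.array([
        mesh_surface_area(population.subject_mesh(i))
        for i in range(population.n_subjects)
    ])
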