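"""Synthetic aortic cohort generator.

Emulates a surgical aortic-valve cohort (AVR / Ozaki / Ross /
valve-sparing groups) as populations of tubular surface meshes with
ground-truth correspondence, so the shape-model, clustering and
morphometry stages can be tested without patient imaging.

Geometry
--------
Each aorta is a tube of circular cross-sections swept along a
"question-mark" centreline: a vertical ascending segment, a
semicircular arch, and a descending segment with a sinusoidal
out-of-plane perturbation (descending tortuosity).  The radius profile
interpolates root / mid-ascending / distal-ascending / descending
radii and adds a Gaussian sinus bulge just above the annulus.  Sweeping
uses parallel-transport frames, which are torsion-free and stable on
straight segments (a Frenet frame is undefined there).  The swept grid
(``n_axial`` rings x ``n_circumferential`` points, fixed ordering)
gives exact point correspondence across subjects by construction.

Cohort structure
----------------
Per subject a latent standard-normal size variable drives (a) the
target ascending surface area (group-specific mean/SD), (b) height and
age at configurable correlation strengths, and (c) allometric shape
changes — dilatation ratio, relative arch width and descending
tortuosity all increase with absolute size.  The shape-size coupling
matters because correlation-distance clustering is invariant to
uniform scaling of a subject's coordinates: a small aorta must also be
*shaped* differently (thinner, straighter descending tract) for the
clustering stage to see it, which is exactly how the first shape mode
of real aortic cohorts behaves (small/thin versus large/dilated with a
curved descending aorta).

Each subject's mesh is rescaled so its realised ascending surface area
equals the drawn target exactly (before measurement noise), hence
realised group means/SDs match the configured targets up to sampling
error in the normal draw.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import CorrespondenceError, InvalidParameterError
from .mesh_io import SurfaceMesh, mesh_surface_area, write_stl

__all__ = [
    "AortaParams",
    "Centreline",
    "GroupSpec",
    "CohortConfig",
    "ShapePopulation",
    "SubjectTruth",
    "generate_centreline",
    "generate_aorta_mesh",
    "grid_to_mesh",
    "sample_population",
    "trim_to_ascending",
    "trim_population",
    "preop_cohort",
    "postop_cohort",
    "bsa",
    "GROUPS",
]

GROUPS = ("AVR", "Ozaki", "Ross", "VS")


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AortaParams:
    """Morphological degrees of freedom of one synthetic aorta (mm / counts).

    Defaults describe a typical adult aorta: ascending diameter around
    30 mm with a sinus bulge, a 30 mm-radius arch and a 200 mm
    descending tract with mild tortuosity.
    """

    root_radius: float = 16.0
    mid_asc_radius: float = 15.0
    distal_asc_radius: float = 13.5
    desc_radius: float = 11.0
    sinus_bulge_amplitude: float = 3.0
    sinus_bulge_width: float = 0.03
    asc_length: float = 90.0
    arch_radius: float = 30.0
    desc_length: float = 200.0
    desc_tortuosity_amplitude: float = 6.0
    desc_tortuosity_cycles: float = 1.5
    n_axial: int = 80
    n_circumferential: int = 24

    def __post_init__(self) -> None:
        for name in ("root_radius", "mid_asc_radius", "distal_asc_radius",
                     "desc_radius", "asc_length", "arch_radius", "desc_length"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.sinus_bulge_amplitude < 0 or self.sinus_bulge_width <= 0:
            raise InvalidParameterError("sinus bulge amplitude must be >= 0, width > 0")
        if self.desc_tortuosity_amplitude < 0:
            raise InvalidParameterError("desc_tortuosity_amplitude must be >= 0")
        if self.n_axial < 20:
            raise InvalidParameterError(f"n_axial must be >= 20, got {self.n_axial}")
        if self.n_circumferential < 8:
            raise InvalidParameterError(
                f"n_circumferential must be >= 8, got {self.n_circumferential}"
            )

    # -- derived arc-length fractions ------------------------------------
    @property
    def total_length(self) -> float:
        return self.asc_length + math.pi * self.arch_radius + self.desc_length

    @property
    def asc_fraction(self) -> float:
        """Arc-length fraction of the ascending segment (innominate cut)."""
        return self.asc_length / self.total_length

    @property
    def arch_end_fraction(self) -> float:
        return (self.asc_length + math.pi * self.arch_radius) / self.total_length

    @property
    def mid_asc_fraction(self) -> float:
        return 0.5 * self.asc_fraction

    @property
    def mid_desc_fraction(self) -> float:
        return (self.asc_length + math.pi * self.arch_radius
                + 0.5 * self.desc_length) / self.total_length

    def scaled(self, factor: float) -> "AortaParams":
        """Uniformly scale every length-valued field by ``factor``."""
        if factor <= 0:
            raise InvalidParameterError("scale factor must be > 0")
        mm_fields = ("root_radius", "mid_asc_radius", "distal_asc_radius",
                     "desc_radius", "sinus_bulge_amplitude", "asc_length",
                     "arch_radius", "desc_length", "desc_tortuosity_amplitude")
        return dataclasses.replace(
            self, **{f: getattr(self, f) * factor for f in mm_fields}
        )


@dataclass(frozen=True)
class Centreline:
    """Ordered centreline points (mm) with normalised arc parameters in [0, 1]."""

    points: np.ndarray            # (n, 3)
    arc_params: np.ndarray        # (n,), strictly increasing, 0 -> 1

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        t = np.asarray(self.arc_params, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
            raise InvalidParameterError("centreline needs >= 2 points of shape (n, 3)")
        if len(t) != len(pts):
            raise InvalidParameterError("arc_params must align with points")
        if not (np.all(np.diff(t) > 0) and abs(t[0]) < 1e-12 and abs(t[-1] - 1) < 1e-12):
            raise InvalidParameterError("arc_params must increase strictly from 0 to 1")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "arc_params", t)

    def __len__(self) -> int:
        return len(self.points)

    def point_at(self, t: float) -> np.ndarray:
        return np.array(
            [np.interp(t, self.arc_params, self.points[:, k]) for k in range(3)]
        )

    def tangent_at(self, t: float) -> np.ndarray:
        tt = np.clip(t, self.arc_params[1], self.arc_params[-2])
        i = int(np.searchsorted(self.arc_params, tt)) - 1
        i = max(0, min(i, len(self.points) - 2))
        d = self.points[i + 1] - self.points[i]
        return d / np.linalg.norm(d)


# ---------------------------------------------------------------------------
# centreline and mesh construction
# ---------------------------------------------------------------------------

#: fixed share of axial rings per anatomical segment (ascending, arch,
#: descending) — ring i is the same anatomical station in every subject,
#: which is what makes correspondence anatomical rather than merely
#: positional, and makes the innominate cut an exact shared ring index.
RING_FRACTIONS = (0.30, 0.25, 0.45)


def _segment_ring_counts(n_axial: int) -> tuple[int, int, int]:
    n_asc = max(2, round(RING_FRACTIONS[0] * n_axial))
    n_arch = max(2, round(RING_FRACTIONS[1] * n_axial))
    return n_asc, n_arch, n_axial - n_asc - n_arch


def generate_centreline(params: AortaParams) -> Centreline:
    """Root-to-diaphragm centreline: vertical ascent, semicircular arch,
    descending segment with sinusoidal out-of-plane tortuosity.

    Rings are allocated to the three anatomical segments in fixed
    proportions (:data:`RING_FRACTIONS`) and sampled uniformly within
    each segment, so ring ``i`` sits at the same anatomical station in
    every subject regardless of that subject's segment lengths.
    """
    L = params.total_length
    n_asc, n_arch, n_desc = _segment_ring_counts(params.n_axial)
    a0, a1 = params.asc_length, params.asc_length + math.pi * params.arch_radius
    s = np.concatenate([
        np.linspace(0.0, a0, n_asc, endpoint=False),
        np.linspace(a0, a1, n_arch, endpoint=False),
        np.linspace(a1, L, n_desc, endpoint=True),
    ])
    pts = np.empty((params.n_axial, 3))
    a, R, d = params.asc_length, params.arch_radius, params.desc_length
    for i, si in enumerate(s):
        if si <= a:
            pts[i] = (0.0, 0.0, si)
        elif si <= a + math.pi * R:
            theta = (si - a) / R
            pts[i] = (R - R * math.cos(theta), 0.0, a + R * math.sin(theta))
        else:
            u = si - a - math.pi * R
            y = params.desc_tortuosity_amplitude * math.sin(
                2.0 * math.pi * params.desc_tortuosity_cycles * u / d
            )
            pts[i] = (2.0 * R, y, a - u)
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    if chord[-1] <= 0:
        raise InvalidParameterError("degenerate centreline (zero length)")
    return Centreline(pts, chord / chord[-1])


def _parallel_transport_frames(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normal/binormal frames along a polyline via discrete parallel transport."""
    tangents = np.gradient(points, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    n = len(points)
    normals = np.empty_like(points)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, tangents[0])) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    v = ref - np.dot(ref, tangents[0]) * tangents[0]
    normals[0] = v / np.linalg.norm(v)
    for i in range(1, n):
        t0, t1 = tangents[i - 1], tangents[i]
        axis = np.cross(t0, t1)
        s = np.linalg.norm(axis)
        c = float(np.clip(np.dot(t0, t1), -1.0, 1.0))
        if s < 1e-12:
            normals[i] = normals[i - 1]
            continue
        axis = axis / s
        ang = math.atan2(s, c)
        v = normals[i - 1]
        # Rodrigues rotation of the previous normal about the turning axis
        normals[i] = (v * math.cos(ang) + np.cross(axis, v) * math.sin(ang)
                      + axis * np.dot(axis, v) * (1.0 - math.cos(ang)))
        normals[i] -= np.dot(normals[i], t1) * t1
        normals[i] /= np.linalg.norm(normals[i])
    binormals = np.cross(tangents, normals)
    return normals, binormals


def radius_profile(params: AortaParams, t: np.ndarray) -> np.ndarray:
    """Cross-section radius at arc parameter(s) ``t``.

    Piecewise-linear through the four control radii plus a Gaussian
    sinus bulge whose peak sits one bulge-width above the annulus.
    Linearity guarantees that raising any control radius raises the
    profile over its whole support (surface-area monotonicity).
    """
    t = np.asarray(t, dtype=np.float64)
    knots = np.array([0.0, params.mid_asc_fraction, params.asc_fraction,
                      params.arch_end_fraction, 1.0])
    values = np.array([params.root_radius, params.mid_asc_radius,
                       params.distal_asc_radius, params.desc_radius,
                       params.desc_radius])
    base = np.interp(t, knots, values)
    w = params.sinus_bulge_width
    bulge = params.sinus_bulge_amplitude * np.exp(-0.5 * ((t - w) / w) ** 2)
    return base + bulge


def generate_aorta_mesh(
    centreline: Centreline, params: AortaParams
) -> tuple[SurfaceMesh, np.ndarray]:
    """Sweep circular sections along the centreline.

    Returns the open-ended triangulated tube and the corresponded point
    grid of shape ``(n_axial, n_circumferential, 3)`` — identical index
    semantics for every subject built from the same grid resolution.
    """
    if len(centreline) != params.n_axial:
        raise InvalidParameterError(
            f"centreline has {len(centreline)} points, params expect {params.n_axial}"
        )
    radii = radius_profile(params, centreline.arc_params)
    if np.any(radii <= 0):
        raise InvalidParameterError("radius profile non-positive somewhere along tube")
    normals, binormals = _parallel_transport_frames(centreline.points)
    phi = np.linspace(0.0, 2.0 * math.pi, params.n_circumferential, endpoint=False)
    ring = np.stack([np.cos(phi), np.sin(phi)], axis=1)  # (nc, 2)
    grid = (centreline.points[:, None, :]
            + radii[:, None, None] * (ring[None, :, 0:1] * normals[:, None, :]
                                      + ring[None, :, 1:2] * binormals[:, None, :]))
    return grid_to_mesh(grid), grid


def grid_to_mesh(grid: np.ndarray) -> SurfaceMesh:
    """Triangulate an (n_axial, n_circ, 3) ring grid into an open tube."""
    na, nc, _ = grid.shape
    idx = np.arange(na * nc).reshape(na, nc)
    nxt = np.roll(idx, -1, axis=1)
    a, b = idx[:-1], nxt[:-1]
    c, d = idx[1:], nxt[1:]
    f1 = np.stack([a, b, d], axis=-1).reshape(-1, 3)
    f2 = np.stack([a, d, c], axis=-1).reshape(-1, 3)
    return SurfaceMesh(grid.reshape(-1, 3), np.concatenate([f1, f2]))


def trim_to_ascending(
    points: np.ndarray, centreline: Centreline, cut_param: float
) -> np.ndarray:
    """Keep the axial rings with arc parameter <= ``cut_param``.

    Emulates cutting the model with a plane perpendicular to the
    centreline at the innominate artery.  Ring-index selection keeps
    correspondence: the same rings are retained for every subject when
    the same mask is applied (see :func:`trim_population`).
    """
    if not (0.0 < cut_param < 1.0):
        raise InvalidParameterError(f"cut_param must be in (0, 1), got {cut_param}")
    mask = centreline.arc_params <= cut_param + 1e-9
    if mask.sum() < 2:
        raise InvalidParameterError("cut_param retains fewer than 2 rings")
    return points[mask]


# ---------------------------------------------------------------------------
# cohort configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """Per-surgical-group targets: size n, ascending surface area (mm²),
    covariate distributions (age yr, height cm, weight kg) and a group
    shape signature.

    The signature multipliers are dimensionless factors on the base
    anatomy's proportions — ascending elongation, relative arch width,
    sinus prominence.  They encode the study observation that e.g. the
    Ross group's aortas were not merely small but elongated with a wide
    arch: proportion differences are what correlation-distance
    clustering can see (it is blind to uniform scale).
    """

    n_subjects: int
    area_mean: float
    area_sd: float
    age_mean: float
    age_sd: float
    height_mean: float
    height_sd: float
    weight_mean: float
    weight_sd: float
    asc_elongation: float = 1.0
    arch_width_factor: float = 1.0
    sinus_factor: float = 1.0
    bav_fraction: float = 0.7

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InvalidParameterError("n_subjects must be >= 1")
        for f in ("area_sd", "age_sd", "height_sd", "weight_sd"):
            if getattr(self, f) < 0:
                raise InvalidParameterError(f"{f} must be >= 0")
        if self.area_mean <= 0:
            raise InvalidParameterError("area_mean must be > 0")
        for f in ("asc_elongation", "arch_width_factor", "sinus_factor"):
            if getattr(self, f) <= 0:
                raise InvalidParameterError(f"{f} must be > 0")
        if not 0.0 <= self.bav_fraction <= 1.0:
            raise InvalidParameterError("bav_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class CohortConfig:
    """Full cohort recipe; deterministic given ``seed``.

    ``size_height_corr`` / ``size_age_corr`` set the correlation between
    the latent size draw and the height / age draws.

    Shape-size coupling: proportional (relative) dilatation is a
    *pathological* feature concentrated in the large-size tail —
    normal-range aortas share similar proportions while dilated ones
    diverge — so ``dilatation_per_sd`` and ``taper_per_sd`` act on the
    rectified latent size ``max(u, 0)``; ``baseline_dilatation_per_sd``
    is the small linear allometry present across the whole range.
    ``bav_mid_dilatation`` is the discrete bicuspid-valve aortopathy
    phenotype (log-scale mid/distal ascending dilatation applied to BAV
    subjects).  ``noise_mm`` is isotropic per-vertex measurement noise
    emulating segmentation error.
    """

    groups: dict[str, GroupSpec]
    base_params: AortaParams = AortaParams()
    size_height_corr: float = 0.4
    size_age_corr: float = 0.4
    noise_mm: float = 0.5
    dilatation_per_sd: float = 0.10
    baseline_dilatation_per_sd: float = 0.02
    arch_width_per_sd: float = 0.10
    taper_per_sd: float = 0.04
    tortuosity_per_sd: float = 0.45
    bav_mid_dilatation: float = 0.12
    shape_jitter: float = 0.02
    bsa_formula: str = "mosteller"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise InvalidParameterError("cohort needs at least one group")
        for c in (self.size_height_corr, self.size_age_corr):
            if not -1.0 <= c <= 1.0:
                raise InvalidParameterError("correlations must lie in [-1, 1]")
        if self.noise_mm < 0:
            raise InvalidParameterError("noise_mm must be >= 0")
        if self.bsa_formula not in ("mosteller", "dubois"):
            raise InvalidParameterError("bsa_formula must be 'mosteller' or 'dubois'")

    @property
    def population_area_stats(self) -> tuple[float, float]:
        """Cohort-level mean/SD of ascending area implied by the group mix."""
        ns = np.array([g.n_subjects for g in self.groups.values()], dtype=float)
        mu = np.array([g.area_mean for g in self.groups.values()])
        sd = np.array([g.area_sd for g in self.groups.values()])
        w = ns / ns.sum()
        m = float(np.sum(w * mu))
        var = float(np.sum(w * (sd**2 + (mu - m) ** 2)))
        return m, math.sqrt(var)


def preop_cohort(seed: int = 0, **overrides) -> CohortConfig:
    """Default pre-operative cohort: 15 AVR, 15 Ozaki, 13 Ross, 4 VS with
    the study cohort's ascending-area and anthropometric distributions."""
    groups = {
        "AVR": GroupSpec(15, 10989.0, 2711.0, 46.0, 19.0, 174.7, 6.4, 81.8, 16.6,
                         bav_fraction=8 / 14),
        "Ozaki": GroupSpec(15, 13421.0, 2726.0, 51.0, 12.0, 176.3, 10.9, 88.0, 18.8,
                           bav_fraction=10 / 13),
        # Ross aortas: elongated ascending segment and wide aortic arch,
        # the group's characteristic pre-operative morphology
        "Ross": GroupSpec(13, 9031.0, 2125.0, 31.0, 11.0, 167.0, 9.5, 73.1, 15.9,
                          asc_elongation=1.30, arch_width_factor=1.25,
                          bav_fraction=10 / 12),
        "VS": GroupSpec(4, 14658.0, 3125.0, 56.0, 7.0, 174.3, 9.0, 78.3, 19.9,
                        bav_fraction=0.0),
    }
    return CohortConfig(groups=groups, seed=seed, **overrides)


def postop_cohort(seed: int = 0, **overrides) -> CohortConfig:
    """Default post-operative cohort: 12 AVR, 10 Ozaki, 10 Ross, 3 VS."""
    groups = {
        "AVR": GroupSpec(12, 10794.0, 1977.0, 49.5, 17.2, 177.8, 4.7, 85.2, 16.7,
                         bav_fraction=5 / 7),
        "Ozaki": GroupSpec(10, 9695.0, 1640.0, 49.9, 10.8, 173.4, 13.2, 85.8, 21.4,
                           bav_fraction=7 / 9),
        # post-operatively the Ross aortas keep an elongated ascending
        # segment and show a slightly enlarged sinus
        "Ross": GroupSpec(10, 8029.0, 2118.0, 31.0, 14.2, 163.6, 10.1, 76.3, 15.9,
                          asc_elongation=1.30, sinus_factor=1.4,
                          bav_fraction=3 / 7),
        "VS": GroupSpec(3, 9212.0, 1761.0, 47.3, 27.3, 184.0, 7.1, 75.5, 16.3,
                        bav_fraction=0.0),
    }
    return CohortConfig(groups=groups, seed=seed, **overrides)


def bsa(height_cm: float, weight_kg: float, formula: str = "mosteller") -> float:
    """Body surface area in m² (Mosteller default, Du Bois alternative)."""
    if formula == "mosteller":
        return math.sqrt(height_cm * weight_kg / 3600.0)
    if formula == "dubois":
        return 0.007184 * height_cm**0.725 * weight_kg**0.425
    raise InvalidParameterError(f"unknown BSA formula {formula!r}")


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectTruth:
    """Ground truth stored per subject: generating parameters and centreline."""

    params: AortaParams
    centreline: Centreline
    latent_size: float


@dataclass
class ShapePopulation:
    """Corresponded synthetic cohort.

    ``points`` is (n_subjects, n_axial, n_circ, 3) in mm with identical
    index semantics for every subject; ``covariates`` carries one row
    per subject aligned with ``group_labels`` and ``ground_truth``.
    """

    points: np.ndarray
    group_labels: np.ndarray
    covariates: pd.DataFrame
    ground_truth: list[SubjectTruth] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.points.ndim != 4 or self.points.shape[-1] != 3:
            raise CorrespondenceError(
                f"points must be (n, n_axial, n_circ, 3), got {self.points.shape}"
            )
        n = len(self.points)
        if len(self.group_labels) != n or len(self.covariates) != n:
            raise CorrespondenceError("labels/covariates misaligned with subjects")
        if self.ground_truth and len(self.ground_truth) != n:
            raise CorrespondenceError("ground_truth misaligned with subjects")

    @property
    def n_subjects(self) -> int:
        return len(self.points)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.points.shape[1], self.points.shape[2]

    def subject_mesh(self, i: int) -> SurfaceMesh:
        return grid_to_mesh(self.points[i])

    def subject_area(self, i: int) -> float:
        return mesh_surface_area(self.subject_mesh(i))

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.points)

    def with_points(self, points: np.ndarray) -> "ShapePopulation":
        return ShapePopulation(points, self.group_labels, self.covariates,
                               self.ground_truth)

    def write_stl_dir(self, out_dir: str | Path) -> pd.DataFrame:
        """Write one binary STL per subject plus a manifest CSV; returns it."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for i in range(self.n_subjects):
            sid = self.covariates["subject_id"].iloc[i]
            fname = f"{sid}.stl"
            write_stl(self.subject_mesh(i), out_dir / fname)
            rows.append(fname)
        manifest = self.covariates.copy()
        manifest["stl_file"] = rows
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        return manifest


def _subject_params(
    config: CohortConfig, base: AortaParams, spec: GroupSpec, u: float,
    is_bav: bool, rng: np.random.Generator,
) -> AortaParams:
    """Perturb the base anatomy for one subject.

    Combines the group shape signature (elongation / arch width / sinus
    multipliers), the discrete bicuspid-aortopathy phenotype
    (mid/distal ascending dilatation for BAV subjects), allometric
    coupling to the latent absolute size ``u`` (SD units), and
    independent log-normal jitter.
    """
    j = config.shape_jitter
    u_pos = max(u, 0.0)  # pathological dilatation lives in the large tail
    dil = math.exp(config.dilatation_per_sd * u_pos
                   + config.baseline_dilatation_per_sd * u + j * rng.normal())
    taper_f = math.exp(config.taper_per_sd * u_pos)
    bav_f = math.exp(config.bav_mid_dilatation) if is_bav else 1.0
    arch_f = spec.arch_width_factor * math.exp(
        config.arch_width_per_sd * u + 1.2 * j * rng.normal()
    )
    tort = max(0.0, base.desc_tortuosity_amplitude * (1.0 + config.tortuosity_per_sd * u)
               + 1.0 * rng.normal())
    return dataclasses.replace(
        base,
        root_radius=base.root_radius * dil * math.exp(0.8 * j * rng.normal()),
        mid_asc_radius=base.mid_asc_radius * dil * taper_f * bav_f
        * math.exp(0.8 * j * rng.normal()),
        distal_asc_radius=base.distal_asc_radius * dil * taper_f * bav_f
        * math.exp(0.8 * j * rng.normal()),
        desc_radius=base.desc_radius * dil * math.exp(0.8 * j * rng.normal()),
        sinus_bulge_amplitude=max(
            0.5, spec.sinus_factor * base.sinus_bulge_amplitude * (1.0 + 0.2 * u)
            + 0.5 * rng.normal()
        ),
        asc_length=base.asc_length * spec.asc_elongation
        * math.exp(0.5 * j * rng.normal()),
        arch_radius=base.arch_radius * arch_f,
        desc_tortuosity_amplitude=tort,
    )


def _ascending_area(params: AortaParams, centreline: Centreline,
                    grid: np.ndarray) -> float:
    asc = trim_to_ascending(grid, centreline, params.asc_fraction)
    return mesh_surface_area(grid_to_mesh(asc))


def sample_population(config: CohortConfig) -> ShapePopulation:
    """Draw a full synthetic cohort; bit-for-bit deterministic given the seed.

    Per subject: latent size -> target ascending area + correlated
    covariates -> allometric shape parameters -> mesh, rescaled so the
    realised ascending area equals the target exactly, then perturbed
    with isotropic vertex noise of ``config.noise_mm``.
    """
    rng = np.random.default_rng(config.seed)
    pop_mean, pop_sd = config.population_area_stats
    base = config.base_params

    grids, labels, truths, rows = [], [], [], []
    idx = 0
    for gname, spec in config.groups.items():
        for _ in range(spec.n_subjects):
            z = rng.normal()
            area_target = spec.area_mean + spec.area_sd * z
            if area_target < 0.05 * spec.area_mean:
                area_target = 0.05 * spec.area_mean  # guard absurd left tail
            # covariates correlated with the size draw
            rh, ra = config.size_height_corr, config.size_age_corr
            zh = rh * z + math.sqrt(max(0.0, 1 - rh**2)) * rng.normal()
            za = ra * z + math.sqrt(max(0.0, 1 - ra**2)) * rng.normal()
            height = max(140.0, spec.height_mean + spec.height_sd * zh)
            age = max(16.0, spec.age_mean + spec.age_sd * za)
            zw = 0.5 * zh + math.sqrt(0.75) * rng.normal()
            weight = max(40.0, spec.weight_mean + spec.weight_sd * zw)

            u = (area_target - pop_mean) / pop_sd  # absolute size, SD units
            is_bav = bool(rng.random() < spec.bav_fraction)
            params = _subject_params(config, base, spec, u, is_bav, rng)
            centreline = generate_centreline(params)
            _, grid = generate_aorta_mesh(centreline, params)
            realised = _ascending_area(params, centreline, grid)
            f = math.sqrt(area_target / realised)
            params = params.scaled(f)
            centreline = generate_centreline(params)
            _, grid = generate_aorta_mesh(centreline, params)
            if config.noise_mm > 0:
                grid = grid + rng.normal(0.0, config.noise_mm, grid.shape)
            area_final = _ascending_area(params, centreline, grid)

            grids.append(grid)
            labels.append(gname)
            truths.append(SubjectTruth(params, centreline, u))
            rows.append({
                "subject_id": f"{gname}_{idx:03d}",
                "group": gname,
                "age": age,
                "height_cm": height,
                "weight_kg": weight,
                "bsa_m2": bsa(height, weight, config.bsa_formula),
                "bmi": weight / (height / 100.0) ** 2,
                "valve_type": "BAV" if is_bav else "TAV",
                "surface_area_mm2": area_final,
                "seed": config.seed,
            })
            idx += 1
    return ShapePopulation(
        points=np.stack(grids),
        group_labels=np.asarray(labels),
        covariates=pd.DataFrame(rows),
        ground_truth=truths,
    )


def trim_population(population: ShapePopulation, cut_param: float) -> ShapePopulation:
    """Trim every subject to the ascending aorta with one shared ring mask.

    The mask is taken from the first subject's ground-truth centreline
    (rings are at common relative stations across subjects), so the
    retained ring-index set is identical for all — correspondence is
    preserved exactly.
    """
    if not population.ground_truth:
        raise CorrespondenceError("trim_population requires generator ground truth")
    cl = population.ground_truth[0].centreline
    mask = cl.arc_params <= cut_param
    if mask.sum() < 2:
        raise InvalidParameterError("cut_param retains fewer than 2 rings")
    return population.with_points(population.points[:, mask])
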