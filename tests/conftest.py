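"""Shared fixtures: small meshes, small cohorts, seeded populations."""

from __future__ import annotations

import numpy as np
import pytest

from aorta_ssm.mesh_io import SurfaceMesh
from aorta_ssm.synthetic import (
    AortaParams,
    Centreline,
    generate_aorta_mesh,
    generate_centreline,
    preop_cohort,
    sample_population,
)


@pytest.fixture(scope="session")
def small_params() -> AortaParams:
    """Coarse but valid anatomy, cheap enough for dense sweeps."""
    return AortaParams(n_axial=40, n_circumferential=16)


@pytest.fixture(scope="session")
def small_population():
    """A 12-subject cohort at coarse resolution (seeded, session-cached)."""
    cfg = preop_cohort(seed=42)
    groups = {
        name: _shrink(spec, n)
        for (name, spec), n in zip(cfg.groups.items(), (4, 4, 3, 1))
    }
    import dataclasses

    cfg = dataclasses.replace(
        cfg, groups=groups,
        base_params=AortaParams(n_axial=40, n_circumferential=12),
    )
    return sample_population(cfg)


def _shrink(spec, n):
    import dataclasses

    return dataclasses.replace(spec, n_subjects=n)


@pytest.fixture(scope="session")
def unit_cube() -> SurfaceMesh:
    """Closed unit cube, outward-oriented, 12 triangles."""
    v = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
                 dtype=float)
    f = np.array([
        [0, 1, 3], [0, 3, 2],          # x = 0 (inward normal -x)
        [4, 6, 7], [4, 7, 5],          # x = 1
        [0, 4, 5], [0, 5, 1],          # y = 0
        [2, 3, 7], [2, 7, 6],          # y = 1
        [0, 2, 6], [0, 6, 4],          # z = 0
        [1, 5, 7], [1, 7, 3],          # z = 1
    ])
    return SurfaceMesh(v, f)


def straight_centreline(length: float, n: int) -> Centreline:
    """Straight vertical centreline with uniform rings (test helper)."""
    pts = np.zeros((n, 3))
    pts[:, 2] = np.linspace(0.0, length, n)
    return Centreline(pts, np.linspace(0.0, 1.0, n))


def cylinder_grid(radius: float, length: float, n_axial: int, n_circ: int):
    """Open cylinder as (mesh, grid) via the tube generator on a straight axis."""
    import dataclasses

    params = AortaParams(
        root_radius=radius, mid_asc_radius=radius, distal_asc_radius=radius,
        desc_radius=radius, sinus_bulge_amplitude=0.0, sinus_bulge_width=0.01,
        asc_length=length, arch_radius=1e-6, desc_length=1e-6,
        desc_tortuosity_amplitude=0.0, n_axial=n_axial, n_circumferential=n_circ,
    )
    cl = straight_centreline(length, n_axial)
    return generate_aorta_mesh(cl, params)


@pytest.fixture(scope="session")
def default_centreline(small_params):
    return generate_centreline(small_params)
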