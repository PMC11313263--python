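"""Shape model: registration, PCA atlas, inertia, template diameters."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from aorta_ssm.errors import InvalidParameterError
from aorta_ssm.ssm import (
    barycentre_register,
    compute_atlas,
    cumulative_inertia,
    n_modes_for,
    reconstruct_subject,
    shape_at,
    shape_vectors,
    template_diameters,
)
from aorta_ssm.synthetic import ShapePopulation

from conftest import cylinder_grid, straight_centreline
from oracles import naive_pca


def make_population(points: np.ndarray) -> ShapePopulation:
    n = len(points)
    cov = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "group": ["AVR"] * n,
    })
    return ShapePopulation(points, np.array(["AVR"] * n), cov)


def random_population(n, na, nc, seed, scale=10.0):
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(na, nc, 3)) * scale
    pts = base[None] + rng.normal(size=(n, na, nc, 3))
    return make_population(pts)


class TestRegistration:
    def test_barycentre_at_origin(self, small_population):
        reg = barycentre_register(small_population)
        bary = reg.points.mean(axis=(1, 2))
        assert np.abs(bary).max() < 1e-10

    def test_translation_invariance(self):
        pop = random_population(3, 8, 6, seed=1)
        shifted = pop.with_points(pop.points + np.array([5.0, -3.0, 2.0]))
        a = barycentre_register(pop).points
        b = barycentre_register(shifted).points
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_idempotent(self):
        pop = random_population(3, 8, 6, seed=2)
        once = barycentre_register(pop)
        twice = barycentre_register(once)
        np.testing.assert_allclose(once.points, twice.points, atol=1e-12)


class TestAtlas:
    def test_identical_shapes_zero_variance(self):
        pop = random_population(1, 10, 6, seed=3)
        pts = np.repeat(pop.points, 5, axis=0)
        atlas = compute_atlas(barycentre_register(make_population(pts)))
        np.testing.assert_allclose(
            atlas.template, barycentre_register(make_population(pts)).points[0].reshape(-1, 3),
            atol=1e-10,
        )
        assert atlas.eigenvalues.max() < 1e-12

    def test_two_subjects_closed_form(self):
        # two subjects: one nonzero eigenvalue, scores +/- half the
        # inter-subject distance, eigenvalue = d^2/2 with divisor n-1
        pop = random_population(2, 6, 5, seed=4)
        reg = barycentre_register(pop)
        atlas = compute_atlas(reg)
        X = shape_vectors(reg)
        d = np.linalg.norm(X[0] - X[1])
        assert atlas.n_modes == 1  # n - 1 modes for n subjects
        assert atlas.eigenvalues[0] == pytest.approx(d**2 / 2, rel=1e-10)
        np.testing.assert_allclose(np.abs(atlas.scores[:, 0]), d / 2, rtol=1e-10)

    def test_matches_bruteforce_covariance_oracle(self):
        pop = random_population(8, 5, 4, seed=5)  # 8 subjects, 60 coords
        reg = barycentre_register(pop)
        atlas = compute_atlas(reg)
        w, v = naive_pca(shape_vectors(reg))
        k = atlas.n_modes
        np.testing.assert_allclose(atlas.eigenvalues, w[:k], rtol=1e-8)
        for m in range(k):
            dot = abs(float(atlas.modes[m] @ v[:, m]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_variance_conservation(self):
        pop = random_population(9, 6, 5, seed=6)
        reg = barycentre_register(pop)
        atlas = compute_atlas(reg)
        X = shape_vectors(reg)
        total = ((X - X.mean(axis=0)) ** 2).sum() / (len(X) - 1)
        assert atlas.eigenvalues.sum() == pytest.approx(total, rel=1e-10)

    def test_rotation_equivariance(self):
        # no rotation is removed by registration, so rotating the whole
        # population rotates the template identically
        pop = random_population(6, 6, 5, seed=7)
        reg = barycentre_register(pop)
        theta = 0.7
        R = np.array([[math.cos(theta), -math.sin(theta), 0],
                      [math.sin(theta), math.cos(theta), 0],
                      [0, 0, 1]])
        rotated = reg.with_points(reg.points @ R.T)
        t1 = compute_atlas(reg).template @ R.T
        t2 = compute_atlas(rotated).template
        np.testing.assert_allclose(t1, t2, atol=1e-10)

    def test_full_reconstruction(self):
        pop = random_population(7, 6, 5, seed=8)
        reg = barycentre_register(pop)
        atlas = compute_atlas(reg)
        for i in range(7):
            np.testing.assert_allclose(
                reconstruct_subject(atlas, i), reg.points[i].reshape(-1, 3),
                atol=1e-8,
            )

    def test_template_recovery_with_isotropic_noise(self):
        rng = np.random.default_rng(9)
        truth = rng.normal(size=(8, 5, 3)) * 20
        truth -= truth.mean(axis=(0, 1))
        noise = 1.0
        n = 60
        pts = truth[None] + rng.normal(0, noise, size=(n, 8, 5, 3))
        atlas = compute_atlas(barycentre_register(make_population(pts)))
        err = np.abs(atlas.template - truth.reshape(-1, 3)).max()
        assert err < 3 * noise / math.sqrt(n) * 3  # per-coordinate 3 SE margin

    def test_needs_two_subjects(self):
        pop = random_population(1, 5, 4, seed=10)
        with pytest.raises(InvalidParameterError):
            compute_atlas(pop)


class TestInertiaAndModes:
    def test_cumulative_inertia_arithmetic_and_bounds(self):
        pop = random_population(6, 6, 5, seed=11)
        atlas = compute_atlas(barycentre_register(pop))
        curve = atlas.cumulative_inertia_curve
        assert np.all(np.diff(curve) >= -1e-12)
        assert curve[-1] == pytest.approx(1.0, abs=1e-9)
        assert cumulative_inertia(atlas, atlas.n_modes) == pytest.approx(1.0)

    def test_n_modes_for_reported_inertia_sequence(self):
        # querying a reported cumulative-inertia table directly
        curve = np.array([0.24, 0.36, 0.47, 0.57, 0.68, 0.80, 1.0])
        assert n_modes_for(curve, 0.5) == 4
        assert n_modes_for(curve, 1.0) == 7
        assert n_modes_for(np.array([1.0, 1.0, 1.0]), 0.7) == 1

    def test_shape_at_identity_and_linearity(self):
        pop = random_population(6, 6, 5, seed=12)
        atlas = compute_atlas(barycentre_register(pop))
        np.testing.assert_allclose(shape_at(atlas, 0, 0.0), atlas.template)
        mid = (shape_at(atlas, 0, 2.0) + shape_at(atlas, 0, -2.0)) / 2
        np.testing.assert_allclose(mid, atlas.template, atol=1e-10)

    def test_mode1_sign_follows_size(self, small_population):
        reg = barycentre_register(small_population)
        atlas = compute_atlas(reg)
        areas = np.array([reg.subject_area(i) for i in range(reg.n_subjects)])
        assert np.corrcoef(atlas.scores[:, 0], areas)[0, 1] > 0

    def test_mode1_score_tracks_ground_truth_size(self):
        # parameter recovery on a generator cohort at study scale
        import aorta_ssm as a

        pop = a.sample_population(a.preop_cohort(seed=21))
        reg = barycentre_register(pop)
        atlas = compute_atlas(reg)
        areas = pop.covariates["surface_area_mm2"].to_numpy()
        assert abs(np.corrcoef(atlas.scores[:, 0], areas)[0, 1]) >= 0.9


class TestShapeVectors:
    def test_shape_contract_and_identical_rows(self):
        pop = random_population(4, 6, 5, seed=13)
        V = shape_vectors(pop)
        assert V.shape == (4, 6 * 5 * 3)
        pts = np.repeat(pop.points[:1], 2, axis=0)
        V2 = shape_vectors(make_population(pts))
        np.testing.assert_array_equal(V2[0], V2[1])

    def test_pipeline_translation_invariance(self):
        pop = random_population(4, 6, 5, seed=14)
        shifted_pts = pop.points.copy()
        shifted_pts[2] += np.array([40.0, -7.0, 3.0])
        a = shape_vectors(barycentre_register(pop))
        b = shape_vectors(barycentre_register(pop.with_points(shifted_pts)))
        np.testing.assert_allclose(a[2], b[2], atol=1e-10)


class TestTemplateDiameters:
    def test_cylinder_diameter(self):
        r = 18.095
        _, grid = cylinder_grid(radius=r, length=100.0, n_axial=40, n_circ=64)
        pop = make_population(np.repeat(grid[None], 2, axis=0))
        atlas = compute_atlas(barycentre_register(pop))
        cl = straight_centreline(100.0, 40)
        cl = dataclasses.replace(cl, points=cl.points - grid.reshape(-1, 3).mean(0))
        d = template_diameters(atlas, cl, np.array([0.25, 0.5, 0.75]))
        np.testing.assert_allclose(d, 2 * r, rtol=5e-3)

    def test_cone_diameters_decrease_along_axis(self):
        n_ax, n_c, L = 40, 48, 100.0
        z = np.linspace(0, L, n_ax)
        radii = np.linspace(20.0, 5.0, n_ax)
        phi = np.linspace(0, 2 * np.pi, n_c, endpoint=False)
        grid = np.stack([
            radii[:, None] * np.cos(phi)[None, :],
            radii[:, None] * np.sin(phi)[None, :],
            np.broadcast_to(z[:, None], (n_ax, n_c)),
        ], axis=-1)
        pop = make_population(np.repeat(grid[None], 2, axis=0))
        reg = barycentre_register(pop)
        atlas = compute_atlas(reg)
        cl = straight_centreline(L, n_ax)
        cl = dataclasses.replace(cl, points=cl.points - grid.reshape(-1, 3).mean(0))
        d = template_diameters(atlas, cl, np.array([0.2, 0.5, 0.8]))
        assert d[0] > d[1] > d[2]

    def test_ascending_vs_whole_trim_consistency(self):
        # same landmark measured on the ascending-only and whole-aorta
        # trims of one synthetic subject agrees within 2%
        import aorta_ssm as a
        from aorta_ssm.morphometrics import (
            extract_centreline,
            section_equivalent_diameter,
        )
        from aorta_ssm.synthetic import grid_to_mesh, trim_to_ascending

        p = a.AortaParams(n_axial=80, n_circumferential=32)
        cl = a.generate_centreline(p)
        _, grid = a.generate_aorta_mesh(cl, p)
        asc = trim_to_ascending(grid, cl, p.asc_fraction)
        t_mid = p.mid_asc_fraction
        whole_cl = extract_centreline(grid)
        asc_cl = extract_centreline(asc)
        d_whole = section_equivalent_diameter(
            grid_to_mesh(grid), whole_cl.point_at(t_mid), whole_cl.tangent_at(t_mid)
        )
        # mid-ascending sits halfway along the ascending-only trim
        d_asc = section_equivalent_diameter(
            grid_to_mesh(asc), asc_cl.point_at(0.5), asc_cl.tangent_at(0.5)
        )
        assert d_asc == pytest.approx(d_whole, rel=0.02)

    def test_landmarks_out_of_range_rejected(self, small_population):
        atlas = compute_atlas(barycentre_register(small_population))
        cl = small_population.ground_truth[0].centreline
        with pytest.raises(InvalidParameterError):
            template_diameters(atlas, cl, np.array([1.2]))
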