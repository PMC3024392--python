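"""Alignment, mean model, deviation coding, vertex regression, maps."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import lipidshape as ls
from lipidshape.meshes import ellipsoid_surface, fibonacci_sphere, vertex_normals
from lipidshape.shape import perturbed_lipid_value


def _random_rotation(rng):
    A = rng.standard_normal((3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def _cohort_from_arrays(coords_by_phase, faces, labels, groups):
    meta = pd.DataFrame(
        {"group": groups},
        index=pd.Index([f"s{i}" for i in range(len(groups))], name="subject_id"))
    return ls.HeartSurfaceCohort(coords=coords_by_phase, faces=faces,
                                 labels=labels, meta=meta)


@pytest.fixture(scope="module")
def noiseless_cohort(small_cohort_spec):
    spec = dataclasses.replace(small_cohort_spec, n_cases=5, n_controls=5,
                               noise_sd=0.0)
    rng = np.random.default_rng(31)
    lipid = np.r_[rng.normal(0.7, 0.24, 5), rng.normal(1.4, 0.24, 5)]
    cohort, truth = ls.generate_heart_cohort(spec, lipid, seed=8)
    return cohort, truth, lipid


class TestKabsch:
    def test_recovers_random_rigid_transform(self):
        rng = np.random.default_rng(2)
        pts = rng.standard_normal((50, 3)) * 10
        R_true = _random_rotation(rng)
        t_true = rng.standard_normal(3) * 5
        moved = pts @ R_true.T + t_true
        R, t = ls.kabsch(moved, pts)
        np.testing.assert_allclose(R @ R_true, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(moved @ R.T + t, pts, atol=1e-9)

    def test_matches_scipy_oracle(self):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(5)
        a = rng.standard_normal((30, 3))
        b = rng.standard_normal((30, 3))
        R, _ = ls.kabsch(a, b)
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        ref, _ = Rotation.align_vectors(bc, ac)  # maps a-frame into b-frame
        np.testing.assert_allclose(R, ref.as_matrix(), atol=1e-10)

    def test_no_reflection(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal((20, 3))
        b = a.copy()
        b[:, 0] = -b[:, 0]  # mirrored target
        R, _ = ls.kabsch(a, b)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)


class TestRigidAlign:
    def test_exact_recovery_of_transformed_copy(self, noiseless_cohort):
        cohort, _, _ = noiseless_cohort
        rng = np.random.default_rng(3)
        moved = {p: c.copy() for p, c in cohort.coords.items()}
        for j in range(cohort.n_subjects):
            R = _random_rotation(rng)
            t = rng.standard_normal(3) * 20
            for p in moved:
                moved[p][j] = moved[p][j] @ R.T + t
        mis = _cohort_from_arrays(moved, cohort.faces, cohort.labels,
                                  cohort.meta["group"].values)
        aligned = ls.rigid_align(mis, reference=cohort.coords["ED"][0])
        for p in cohort.coords:
            rmsd = np.sqrt(((aligned.coords[p] - cohort.coords[p]) ** 2).mean())
            assert rmsd < 1e-9

    def test_already_aligned_identity(self, noiseless_cohort):
        cohort, _, _ = noiseless_cohort
        aligned = ls.rigid_align(cohort, reference=cohort.coords["ED"][0])
        np.testing.assert_allclose(aligned.coords["ED"], cohort.coords["ED"], atol=1e-8)


class TestMeanModel:
    def test_identical_subjects_mean_is_subject(self, small_cohort_spec):
        spec = dataclasses.replace(small_cohort_spec, n_cases=2, n_controls=2,
                                   slope_magnitude=0.0, noise_sd=0.0)
        cohort, truth = ls.generate_heart_cohort(spec, np.ones(4), seed=4)
        mm = ls.mean_model(cohort, groups=(2,))
        for p in mm.coords:
            np.testing.assert_allclose(mm.coords[p], cohort.coords[p][0], atol=1e-12)

    def test_sphere_normals_radial(self):
        # default LV point budget; coarser lattices degrade near the poles
        v, f = fibonacci_sphere(906)
        n = vertex_normals(v, f)
        cosang = np.einsum("ij,ij->i", n, v / np.linalg.norm(v, axis=1, keepdims=True))
        assert np.all(cosang > np.cos(np.radians(2.0)))

    def test_mirrored_pair_mean_is_midpoint(self, noiseless_cohort):
        cohort, truth, _ = noiseless_cohort
        base = truth.base_model
        nrm = base.normals
        coords = {}
        for p in base.coords:
            up = base.coords[p] + 1.5 * nrm[p]
            dn = base.coords[p] - 1.5 * nrm[p]
            coords[p] = np.stack([up, dn])
        pair = _cohort_from_arrays(coords, base.faces, base.labels, [2, 2])
        mm = ls.mean_model(pair, groups=(2,))
        for p in mm.coords:
            np.testing.assert_allclose(mm.coords[p], base.coords[p], atol=1e-10)


class TestShapeDeviations:
    def test_subject_equal_to_mean_is_zero(self, small_cohort_spec):
        spec = dataclasses.replace(small_cohort_spec, n_cases=1, n_controls=2,
                                   slope_magnitude=0.0, noise_sd=0.0)
        cohort, _ = ls.generate_heart_cohort(spec, np.ones(3), seed=4)
        mm = ls.mean_model(cohort, groups=(2,))
        dev = ls.shape_deviations(cohort, mm)
        for p in dev:
            np.testing.assert_allclose(dev[p], 0.0, atol=1e-10)

    def test_uniform_normal_offset_reads_back(self, noiseless_cohort):
        cohort, truth, _ = noiseless_cohort
        base = truth.base_model
        coords = {p: np.stack([base.coords[p] + 2.0 * base.normals[p],
                               base.coords[p]]) for p in base.coords}
        two = _cohort_from_arrays(coords, base.faces, base.labels, [1, 2])
        dev = ls.shape_deviations(two, base)
        for p in dev:
            np.testing.assert_allclose(dev[p][0], 2.0, atol=1e-10)

    def test_tangential_displacement_invisible(self, noiseless_cohort):
        cohort, truth, _ = noiseless_cohort
        base = truth.base_model
        rng = np.random.default_rng(6)
        coords = {}
        for p in base.coords:
            raw = rng.standard_normal(base.coords[p].shape)
            n = base.normals[p]
            tangent = raw - (np.einsum("ik,ik->i", raw, n))[:, None] * n
            coords[p] = np.stack([base.coords[p] + tangent, base.coords[p]])
        two = _cohort_from_arrays(coords, base.faces, base.labels, [1, 2])
        dev = ls.shape_deviations(two, base)
        for p in dev:
            np.testing.assert_allclose(dev[p][0], 0.0, atol=1e-10)


class TestVertexRegression:
    def test_noiseless_recovery(self, noiseless_cohort):
        cohort, truth, lipid = noiseless_cohort
        mm = ls.mean_model(cohort, groups=(2,))
        dev = ls.shape_deviations(cohort, mm)
        field = ls.fit_vertex_regression(dev, lipid, reference_values=lipid[5:])
        for p in ("ED", "ES"):
            assert np.abs(field.slope[p] - truth.slope[p]).max() < 1e-9
            assert np.abs(field.intercept[p] - truth.intercept[p]).max() < 1e-9

    def test_two_subjects_interpolate_exactly(self, noiseless_cohort):
        _, truth, _ = noiseless_cohort
        base = truth.base_model
        rng = np.random.default_rng(12)
        d1 = rng.standard_normal(len(base.labels))
        d2 = rng.standard_normal(len(base.labels))
        coords = {p: np.stack([base.coords[p] + d1[:, None] * base.normals[p],
                               base.coords[p] + d2[:, None] * base.normals[p]])
                  for p in base.coords}
        pair = _cohort_from_arrays(coords, base.faces, base.labels, [1, 2])
        dev = ls.shape_deviations(pair, base)
        with pytest.raises(ValueError, match="3 subjects"):
            ls.fit_vertex_regression(dev, np.r_[1.0, 3.0])

    def test_null_slopes_shrink(self, small_cohort_spec):
        spec = dataclasses.replace(small_cohort_spec, n_cases=30, n_controls=30,
                                   slope_magnitude=0.0, noise_sd=0.5)
        rng = np.random.default_rng(13)
        lipid = rng.normal(1.0, 0.3, 60)
        cohort, _ = ls.generate_heart_cohort(spec, lipid, seed=13)
        mm = ls.mean_model(cohort, groups=(2,))
        field = ls.fit_vertex_regression(ls.shape_deviations(cohort, mm), lipid)
        for p in field.slope:
            assert np.abs(field.slope[p]).mean() < 0.5  # ~ sigma/(sqrt(n)*sd_l)

    def test_zero_lipid_variance_refused(self, noiseless_cohort):
        cohort, truth, _ = noiseless_cohort
        dev = ls.shape_deviations(cohort, truth.base_model)
        with pytest.raises(ValueError, match="zero variance"):
            ls.fit_vertex_regression(dev, np.ones(cohort.n_subjects))


class TestReconstruction:
    def test_mean_lipid_zero_intercept_returns_mean(self, noiseless_cohort):
        cohort, truth, lipid = noiseless_cohort
        mm = ls.mean_model(cohort, groups=(2,))
        field = ls.fit_vertex_regression(ls.shape_deviations(cohort, mm),
                                         lipid, reference_values=lipid[5:])
        # intercept centered on the control mean -> reconstruction at the
        # control-mean lipid equals the mean model
        rec = ls.reconstruct_shape(field, mm, float(lipid[5:].mean()))
        for p in rec:
            np.testing.assert_allclose(rec[p], mm.coords[p], atol=1e-9)

    def test_reconstruction_at_subject_value_matches_subject(self, noiseless_cohort):
        cohort, truth, lipid = noiseless_cohort
        mm = ls.mean_model(cohort, groups=(2,))
        field = ls.fit_vertex_regression(ls.shape_deviations(cohort, mm),
                                         lipid, reference_values=lipid[5:])
        j = 2
        rec = ls.reconstruct_shape(field, mm, float(lipid[j]))
        for p in rec:
            assert np.abs(rec[p] - cohort.coords[p][j]).max() < 1e-9

    def test_zero_slope_field_independent_of_lipid(self, noiseless_cohort):
        _, truth, _ = noiseless_cohort
        base = truth.base_model
        n = len(base.labels)
        field = ls.VertexRegressionField(
            lipid="x", intercept={p: np.zeros(n) for p in base.coords},
            slope={p: np.zeros(n) for p in base.coords}, lipid_mean=1.0, lipid_sd=0.2)
        r1 = ls.reconstruct_shape(field, base, -10.0)
        r2 = ls.reconstruct_shape(field, base, 10.0)
        for p in r1:
            np.testing.assert_allclose(r1[p], r2[p], atol=0)

    def test_deviation_reconstruction_isometry(self, noiseless_cohort):
        """reconstruct(shape_deviations(S)) == S for surfaces that differ
        from the mean only along the normals."""
        cohort, truth, lipid = noiseless_cohort
        mm = ls.mean_model(cohort, groups=(2,))
        dev = ls.shape_deviations(cohort, mm)
        for j in range(cohort.n_subjects):
            for p in cohort.coords:
                rebuilt = mm.coords[p] + dev[p][j][:, None] * mm.normals[p]
                assert np.abs(rebuilt - cohort.coords[p][j]).max() < 1e-9


class TestWallThickness:
    def test_concentric_spheres(self):
        v1, f1 = ellipsoid_surface(906, (20.0, 20.0, 20.0))
        v2, f2 = ellipsoid_surface(906, (30.0, 30.0, 30.0))
        th = ls.wall_thickness(v1, vertex_normals(v1, f1), v2, f2)
        assert not np.isnan(th).any()
        np.testing.assert_allclose(th, 10.0, atol=0.05)

    def test_concentric_ellipsoids_match_quadric_oracle(self):
        axes_in, axes_out = (18.0, 22.0, 30.0), (27.0, 31.0, 39.0)
        v1, f1 = ellipsoid_surface(400, axes_in)
        n1 = vertex_normals(v1, f1)
        th = ls.wall_thickness(v1, n1, *ellipsoid_surface(4000, axes_out))
        # analytic ray-quadric intersection: solve |(o + t d) / a|^2 = 1
        a = np.asarray(axes_out)
        O, D = v1 / a, n1 / a
        A = np.einsum("ij,ij->i", D, D)
        B = 2 * np.einsum("ij,ij->i", O, D)
        C = np.einsum("ij,ij->i", O, O) - 1.0
        t_exact = (-B + np.sqrt(B * B - 4 * A * C)) / (2 * A)
        # the 4000-point faceted ellipsoid sits slightly inside the quadric
        np.testing.assert_allclose(th, t_exact, atol=0.1)
        assert np.median(np.abs(th - t_exact)) < 0.05

    def test_coincident_surfaces_zero(self):
        v, f = ellipsoid_surface(300, (20.0, 20.0, 25.0))
        th = ls.wall_thickness(v, vertex_normals(v, f), v, f)
        np.testing.assert_allclose(th, 0.0, atol=1e-9)

    def test_miss_is_flagged(self):
        v1, f1 = ellipsoid_surface(100, (20.0, 20.0, 20.0))
        n1 = vertex_normals(v1, f1)
        # tiny far-away target: every outward ray misses
        v2, f2 = ellipsoid_surface(50, (1.0, 1.0, 1.0), center=(500.0, 0, 0))
        th = ls.wall_thickness(v1, n1, v2, f2)
        assert np.isnan(th).all()


@pytest.fixture(scope="module")
def fitted(small_cohort_spec):
    spec = dataclasses.replace(small_cohort_spec, n_cases=6, n_controls=6,
                               noise_sd=0.0)
    rng = np.random.default_rng(44)
    lipid = np.r_[rng.normal(0.7, 0.24, 6), rng.normal(1.4, 0.24, 6)]
    cohort, truth = ls.generate_heart_cohort(spec, lipid, seed=44)
    mm = ls.mean_model(cohort, groups=(2,))
    field = ls.fit_vertex_regression(ls.shape_deviations(cohort, mm), lipid,
                                     reference_values=lipid[6:])
    return spec, truth, mm, field


class TestMaps:
    def test_identical_phases_zero_maps(self, fitted):
        spec, truth, mm, field = fitted
        base = truth.base_model
        frozen = ls.MeanModel(
            coords={"ED": base.coords["ED"], "ES": base.coords["ED"]},
            normals={"ED": base.normals["ED"], "ES": base.normals["ED"]},
            faces=base.faces, labels=base.labels)
        model = {"ED": base.coords["ED"], "ES": base.coords["ED"]}
        thick, motion = ls.thickening_and_motion_maps(model, model, frozen)
        np.testing.assert_allclose(motion, 0.0, atol=1e-12)
        ok = ~np.isnan(thick)
        np.testing.assert_allclose(thick[ok], 0.0, atol=1e-9)

    def test_swap_antisymmetry(self, fitted):
        spec, truth, mm, field = fitted
        low = ls.reconstruct_shape(field, mm, perturbed_lipid_value(field, -1.0))
        high = ls.reconstruct_shape(field, mm, field.lipid_mean)
        t1, m1 = ls.thickening_and_motion_maps(low, high, mm)
        t2, m2 = ls.thickening_and_motion_maps(high, low, mm)
        np.testing.assert_allclose(m1, -m2, atol=1e-12)
        ok = ~np.isnan(t1) & ~np.isnan(t2)
        np.testing.assert_allclose(t1[ok], -t2[ok], atol=1e-9)

    def test_planted_septal_effect_recovered(self, fitted):
        spec, truth, mm, field = fitted
        low = ls.reconstruct_shape(field, mm, perturbed_lipid_value(field, -1.0))
        high = ls.reconstruct_shape(field, mm, field.lipid_mean)
        thick, motion = ls.thickening_and_motion_maps(low, high, mm)
        lv = mm.labels == "lv_endo"
        patch = truth.slope["ES"][lv] != 0
        # lipid decrease reduces systolic function inside the planted patch
        assert np.nanmean(thick[patch]) < -0.05
        assert np.nanmean(motion[patch]) < -0.05
        # and leaves the rest of the ventricle untouched (noiseless cohort)
        assert np.nanmax(np.abs(thick[~patch])) < 1e-6
        assert np.nanmax(np.abs(motion[~patch])) < 1e-6

    def test_map_export(self, fitted, tmp_path):
        spec, truth, mm, field = fitted
        low = ls.reconstruct_shape(field, mm, perturbed_lipid_value(field, -1.0))
        high = ls.reconstruct_shape(field, mm, field.lipid_mean)
        thick, motion = ls.thickening_and_motion_maps(low, high, mm)
        from lipidshape.shape import export_maps
        export_maps(tmp_path, mm, thick, motion)
        vtk = (tmp_path / "lv_endo_maps.vtk").read_text()
        assert "POINT_DATA" in vtk and "thickening_diff_mm" in vtk
        csv = pd.read_csv(tmp_path / "lv_endo_motion_diff.csv")
        assert len(csv) == int((mm.labels == "lv_endo").sum())
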