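"""Simulator ground truth: analytic curvature, rasterisation, microscope model."""

import numpy as np
import pytest

from laminaq.synthetic import (
    PHENOTYPE_TEMPLATES,
    NucleusPhenotype,
    apply_microscope,
    ellipsoid_gaussian_curvature,
    make_surface,
    rasterize,
    simulate_population,
)


class TestMakeSurface:
    def test_sphere_curvature_is_inverse_radius_squared(self):
        R = 2000.0
        truth = make_surface(NucleusPhenotype(semiaxes=(R, R, R)), seed=1)
        np.testing.assert_allclose(truth.k_grid, 1.0 / R**2, rtol=1e-12)

    def test_ellipsoid_pole_curvature_closed_form(self):
        a, b, c = 2200.0, 1900.0, 1400.0
        truth = make_surface(NucleusPhenotype(semiaxes=(a, b, c)), seed=2)
        k_pole = truth.curvature(np.array([[0.0, 0.0, 1.0]]))[0]
        assert k_pole == pytest.approx(c**2 / (a**2 * b**2), rel=1e-3)

    def test_deterministic_per_seed(self):
        pheno = PHENOTYPE_TEMPLATES["senescent"]
        t1 = make_surface(pheno, seed=7)
        t2 = make_surface(pheno, seed=7)
        t3 = make_surface(pheno, seed=8)
        np.testing.assert_array_equal(t1.r_grid, t2.r_grid)
        assert not np.array_equal(t1.r_grid, t3.r_grid)

    @pytest.mark.parametrize("label", ["fresh", "senescent", "apoptotic"])
    def test_gauss_bonnet_total_curvature(self, label):
        # quadrature error of the finite-difference curvature grows with fold
        # depth; 5% accommodates the strongly folded apoptotic template
        truth = make_surface(PHENOTYPE_TEMPLATES[label], seed=5)
        assert truth.total_curvature() == pytest.approx(4 * np.pi, rel=0.05)

    def test_gauss_bonnet_ellipsoid_within_one_percent(self):
        truth = make_surface(NucleusPhenotype(semiaxes=(2200.0, 1900.0, 1400.0)), seed=2)
        assert truth.total_curvature() == pytest.approx(4 * np.pi, rel=0.01)

    def test_ellipsoid_volume_quadrature(self):
        a, b, c = 2200.0, 1900.0, 1400.0
        truth = make_surface(NucleusPhenotype(semiaxes=(a, b, c)), seed=2)
        assert truth.enclosed_volume == pytest.approx(4 / 3 * np.pi * a * b * c, rel=1e-3)

    def test_extreme_perturbation_rejected(self):
        pheno = NucleusPhenotype(
            semiaxes=(2000.0, 2000.0, 2000.0),
            wrinkle_amplitude=0.45, wrinkle_degree_max=12,
            n_blebs=8, bleb_amplitude=-1.2,
        )
        with pytest.raises(ValueError, match="self-intersect"):
            make_surface(pheno, seed=0)

    def test_invalid_phenotypes_rejected(self):
        with pytest.raises(ValueError):
            make_surface(NucleusPhenotype(wrinkle_amplitude=0.6), seed=0)
        with pytest.raises(ValueError):
            make_surface(NucleusPhenotype(lamina_to_nucleoplasm_ratio=0.9), seed=0)
        with pytest.raises(ValueError):
            make_surface(NucleusPhenotype(hotspot_gain=0.5), seed=0)

    def test_mesh_closed_genus_zero(self):
        truth = make_surface(PHENOTYPE_TEMPLATES["apoptotic"], seed=3)
        mesh, k = truth.to_mesh(subdivisions=4)
        assert mesh.is_watertight and mesh.euler_number == 2
        assert len(k) == len(mesh.vertices)


class TestRasterize:
    def test_sphere_shell_volume_analytic(self):
        R, t = 5000.0, 300.0
        pheno = NucleusPhenotype(semiaxes=(R, R, R), shell_thickness=t,
                                 lamina_to_nucleoplasm_ratio=4.0)
        truth = make_surface(pheno, seed=1)
        stack = rasterize(truth, pheno, spacing=(100.0, 100.0, 100.0), shape=(128, 128, 128))
        lamina_value = 100.0 * 4.0
        shell_voxels = int(np.sum(stack.voxels == lamina_value))
        shell_volume = shell_voxels * stack.voxel_volume_nm3
        # exact volume of the shell between radii R - t and R; the thin-shell
        # approximation 4 pi R^2 t is itself ~t/R = 6% high
        exact = 4.0 / 3.0 * np.pi * (R**3 - (R - t) ** 3)
        assert shell_volume == pytest.approx(exact, rel=0.02)
        assert shell_volume == pytest.approx(4 * np.pi * R**2 * t, rel=0.08)

    def test_uniform_shell_without_hotspots(self):
        pheno = NucleusPhenotype(semiaxes=(1500.0, 1500.0, 1500.0))
        truth = make_surface(pheno, seed=1)
        stack = rasterize(truth, pheno, spacing=(50.0, 50.0, 50.0), shape=(80, 80, 80))
        shell_values = stack.voxels[stack.voxels > 100.0]
        assert len(np.unique(shell_values)) == 1

    def test_lamina_to_nucleoplasm_ratio(self):
        pheno = NucleusPhenotype(semiaxes=(1500.0, 1500.0, 1500.0),
                                 lamina_to_nucleoplasm_ratio=4.0)
        truth = make_surface(pheno, seed=1)
        stack = rasterize(truth, pheno, spacing=(50.0, 50.0, 50.0), shape=(80, 80, 80))
        shell = stack.voxels[stack.voxels > 100.0]
        interior = stack.voxels[(stack.voxels > 0) & (stack.voxels <= 100.0)]
        assert shell.mean() / interior.mean() == pytest.approx(4.0, rel=0.01)

    def test_shell_thinner_than_sampling_errors(self):
        pheno = NucleusPhenotype(semiaxes=(1500.0,) * 3, shell_thickness=150.0)
        truth = make_surface(pheno, seed=1)
        with pytest.raises(ValueError, match="under-sampled"):
            rasterize(truth, pheno, spacing=(100.0, 100.0, 100.0), shape=(64, 64, 64))

    def test_shell_connected_and_hole_free(self):
        pheno = PHENOTYPE_TEMPLATES["senescent"]
        truth = make_surface(pheno, seed=9)
        stack = rasterize(truth, pheno)
        shell = stack.voxels >= 100.0 * pheno.lamina_to_nucleoplasm_ratio
        from scipy import ndimage

        _, n = ndimage.label(shell)  # default structure = 6-connectivity
        assert n == 1
        filled = ndimage.binary_fill_holes(shell)
        foreground = stack.voxels > 0
        np.testing.assert_array_equal(filled, foreground)


class TestMicroscope:
    def test_identity_limit(self):
        rng = np.random.default_rng(0)
        from laminaq.stack_io import ImageStack

        stack = ImageStack(rng.uniform(0, 200, (16, 16, 16)), (50.0,) * 3)
        out = apply_microscope(stack, psf_sigma=(0.0, 0.0, 0.0), photon_scale=np.inf,
                               read_noise_sd=0.0, background=0.0, seed=1)
        np.testing.assert_allclose(out.voxels, stack.voxels)

    def test_blur_preserves_constant(self):
        from laminaq.stack_io import ImageStack

        stack = ImageStack(np.full((16, 16, 16), 55.0), (50.0,) * 3)
        out = apply_microscope(stack, psf_sigma=(250.0, 100.0, 100.0), photon_scale=np.inf,
                               read_noise_sd=0.0, background=0.0, seed=1)
        np.testing.assert_allclose(out.voxels, 55.0, rtol=1e-9)

    def test_poisson_moments(self):
        from laminaq.stack_io import ImageStack

        c, p = 50.0, 2.0
        stack = ImageStack(np.full((64, 64, 64), c), (50.0,) * 3)
        out = apply_microscope(stack, psf_sigma=(0.0,) * 3, photon_scale=p,
                               read_noise_sd=0.0, background=0.0, seed=3)
        assert out.voxels.mean() == pytest.approx(c, rel=0.05)
        assert out.voxels.var() == pytest.approx(c / p, rel=0.05)

    def test_deterministic_per_seed(self):
        pheno = _half_scale(PHENOTYPE_TEMPLATES["fresh"])
        truth = make_surface(pheno, seed=1)
        stack = rasterize(truth, pheno, shape=(64, 96, 96))
        a = apply_microscope(stack, seed=4)
        b = apply_microscope(stack, seed=4)
        np.testing.assert_array_equal(a.voxels, b.voxels)


def _half_scale(pheno):
    import dataclasses

    return dataclasses.replace(pheno, semiaxes=tuple(a / 2 for a in pheno.semiaxes))


class TestSimulatePopulation:
    def test_counts_and_determinism(self):
        phenos = {k: _half_scale(PHENOTYPE_TEMPLATES[k]) for k in ("fresh", "senescent")}
        cells = simulate_population(phenos, n_per_label=3, jitter=0.1, seed=11,
                                    shape=(64, 72, 72))
        assert len(cells) == 6
        labels = [t.label for _, t in cells]
        assert labels.count("fresh") == 3 and labels.count("senescent") == 3
        again = simulate_population(phenos, n_per_label=3, jitter=0.1, seed=11,
                                    shape=(64, 72, 72))
        for (s1, _), (s2, _) in zip(cells, again):
            np.testing.assert_array_equal(s1.voxels, s2.voxels)

    def test_zero_jitter_same_template_parameters(self):
        cells = simulate_population({"fresh": _half_scale(PHENOTYPE_TEMPLATES["fresh"])},
                                    n_per_label=2, jitter=0.0, seed=12, shape=(48, 64, 64))
        # same template, but wrinkle phases differ (per-cell seeds)
        (s1, t1), (s2, t2) = cells
        assert t1.enclosed_volume == pytest.approx(t2.enclosed_volume, rel=0.05)
        assert not np.array_equal(t1.r_grid, t2.r_grid)


def test_closed_form_matches_implicit_gradient():
    """Cross-check the ellipsoid curvature formula against an independent
    implicit-surface evaluation K = det(H)-based formula via finite differences."""
    a, b, c = 2200.0, 1900.0, 1400.0
    rng = np.random.default_rng(0)
    u = rng.normal(size=(200, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    r = 1.0 / np.sqrt((u[:, 0] / a) ** 2 + (u[:, 1] / b) ** 2 + (u[:, 2] / c) ** 2)
    pts = u * r[:, None]
    k_formula = ellipsoid_gaussian_curvature(pts, (a, b, c))
    # independent oracle: product of principal curvatures from the shape
    # operator of the graph z = f(x, y) in a frame aligned with the normal
    grad = 2 * pts / np.array([a**2, b**2, c**2])
    n = grad / np.linalg.norm(grad, axis=1, keepdims=True)
    h = 1e-3
    k_num = np.empty(len(pts))
    for i, (p0, nv) in enumerate(zip(pts, n)):
        e1 = np.cross(nv, [0, 0, 1.0] if abs(nv[2]) < 0.9 else [1.0, 0, 0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(nv, e1)

        def height(s, t):
            # project p0 + s e1 + t e2 back to the surface along the normal
            q = p0 + s * e1 + t * e2
            A = np.sum(nv**2 / np.array([a**2, b**2, c**2]))
            B = 2 * np.sum(q * nv / np.array([a**2, b**2, c**2]))
            C = np.sum(q**2 / np.array([a**2, b**2, c**2])) - 1.0
            disc = np.sqrt(B**2 - 4 * A * C)
            # numerically stable smaller-magnitude root
            return 2 * C / (-B - np.copysign(disc, B))

        d = h * min(a, b, c)
        fxx = (height(d, 0) - 2 * height(0, 0) + height(-d, 0)) / d**2
        fyy = (height(0, d) - 2 * height(0, 0) + height(0, -d)) / d**2
        fxy = (height(d, d) - height(d, -d) - height(-d, d) + height(-d, -d)) / (4 * d**2)
        k_num[i] = fxx * fyy - fxy**2
    np.testing.assert_allclose(k_num, k_formula, rtol=1e-3)
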