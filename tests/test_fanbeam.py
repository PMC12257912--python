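"""Forward projector and the classical FBP chain."""

import numpy as np
import pytest

from cret.fbp import (backproject_fbp, cosine_weight, fbp_reconstruct,
                      ramp_filter, view_detector_coords)
from cret.geometry import FanBeamGeometry, GridSpec, Sinogram
from cret.phantoms import (Ellipse, hu_to_mu, make_phantom, mu_to_hu,
                           project_ellipses_analytic)
from cret.projector import forward_project, project_phantom


def small_geom(n_views=90, n_det=256, pitch=1.0):
    return FanBeamGeometry(800.0, 1200.0, n_det, pitch, n_views)


class TestForwardProject:
    def test_central_ray_chord_of_centered_disk(self):
        # uniform disk mu0, radius R at isocenter: central ray = 2 R mu0
        g = small_geom(n_views=4)
        grid = GridSpec.centered(256, 0.5)
        X, Y = grid.pixel_centers()
        mu0, R = 0.02, 40.0
        mu = np.where(X**2 + Y**2 <= R**2, mu0, 0.0)
        sino = forward_project(mu, grid, g)
        central = sino.data[:, 127:129].max(axis=1)  # even detector count
        assert central == pytest.approx(2 * R * mu0, rel=0.01)

    def test_ray_missing_object_is_zero(self):
        g = small_geom(n_views=2)
        grid = GridSpec.centered(64, 1.0)
        mu = np.zeros((64, 64))
        mu[28:36, 28:36] = 0.02
        sino = forward_project(mu, grid, g)
        assert sino.data[:, 0] == pytest.approx(0.0, abs=1e-12)

    def test_off_center_rays_match_analytic_chords(self):
        # numeric integration vs closed-form chords for an off-center disk
        g = small_geom(n_views=16)
        grid = GridSpec.centered(256, 0.5)
        disk = Ellipse((20.0, -10.0), (30.0, 30.0), 0.0, 1000.0)
        X, Y = grid.pixel_centers()
        # linearly antialiased edge so the comparison probes the integrator,
        # not the rasterization of a binary mask
        r = np.hypot(X - 20.0, Y + 10.0)
        mu = 0.02 * np.clip((30.0 - r) / grid.spacing + 0.5, 0.0, 1.0)
        num = forward_project(mu, grid, g).data
        ana = project_ellipses_analytic([disk], g).data
        solid = ana > 0.5 * ana.max()  # rays well inside the disk
        rel = np.abs(num[solid] - ana[solid]) / ana[solid]
        assert rel.max() < 0.01

    def test_truncation_flagged(self):
        g = FanBeamGeometry(800.0, 1200.0, 16, 1.0, 4)  # tiny FOV
        grid = GridSpec.centered(64, 2.0)
        mu = np.full((64, 64), 0.01)
        with pytest.warns(UserWarning, match="field of view"):
            sino = forward_project(mu, grid, g)
        assert sino.meta.get("truncated") is True


class TestCosineWeight:
    def test_weight_properties(self):
        g = small_geom(n_views=1, n_det=255)  # odd: exact central sample
        s = Sinogram(np.ones((1, 255)), g)
        w = cosine_weight(s).data[0]
        assert w[127] == pytest.approx(1.0)
        assert np.allclose(w, w[::-1])  # even in u
        assert np.all(np.diff(w[127:]) < 0)  # strictly decreasing in |u|

    def test_stage_enforced(self):
        g = small_geom(n_views=1)
        s = cosine_weight(Sinogram(np.ones((1, 256)), g))
        with pytest.raises(ValueError, match="stage"):
            cosine_weight(s)


class TestRampFilter:
    def test_constant_row_killed(self):
        g = small_geom(n_views=1, n_det=512, pitch=3.6)
        z = ramp_filter(Sinogram(np.ones((1, 512)), g, stage="cos_weighted"))
        assert np.abs(z.data[0, 128:384]).max() < 1e-3

    def test_impulse_gives_ramlak_kernel(self):
        # FFT path vs the closed-form discrete kernel (spatial-domain oracle)
        g = small_geom(n_views=1, n_det=64, pitch=3.6)
        imp = np.zeros((1, 64))
        imp[0, 32] = 1.0
        z = ramp_filter(Sinogram(imp, g, stage="cos_weighted")).data[0]
        d = g.iso_pitch
        expected = np.zeros(64)
        for j in range(64):
            k = j - 32
            if k == 0:
                expected[j] = 1.0 / (4.0 * d**2)
            elif k % 2 != 0:
                expected[j] = -1.0 / (np.pi * k * d) ** 2
        assert np.abs(z - expected * d).max() < 1e-10

    def test_linearity(self):
        g = small_geom(n_views=3, n_det=64)
        rng = np.random.default_rng(0)
        x = Sinogram(rng.normal(size=(3, 64)), g, stage="cos_weighted")
        y = Sinogram(rng.normal(size=(3, 64)), g, stage="cos_weighted")
        combo = Sinogram(2.0 * x.data - 3.0 * y.data, g, stage="cos_weighted")
        assert np.allclose(ramp_filter(combo).data,
                           2.0 * ramp_filter(x).data - 3.0 * ramp_filter(y).data,
                           atol=1e-12)

    def test_requires_weighted_stage(self):
        g = small_geom(n_views=1)
        with pytest.raises(ValueError, match="stage"):
            ramp_filter(Sinogram(np.ones((1, 256)), g))


class TestBackprojection:
    def test_zero_sinogram_gives_zero_image(self):
        g = small_geom(n_views=8)
        z = Sinogram(np.zeros((8, 256)), g, stage="filtered")
        img = backproject_fbp(z, GridSpec.centered(32, 1.0))
        assert np.array_equal(img.data, np.zeros((32, 32)))

    def test_single_view_constant_z_follows_inverse_square(self):
        g = small_geom(n_views=1)
        z = Sinogram(np.ones((1, 256)), g, stage="filtered")
        grid = GridSpec.centered(33, 2.0)
        img = backproject_fbp(z, grid)
        X, Y = grid.pixel_centers()
        sx, sy = 0.0, g.source_to_iso  # view 0 source on +y
        L2 = (X - sx) ** 2 + (Y - sy) ** 2
        expected = 0.5 * (2 * np.pi / 1) * g.source_to_iso**2 / L2
        assert np.allclose(img.data, expected, rtol=1e-12)

    def test_linear_in_z(self):
        g = small_geom(n_views=8, n_det=64)
        rng = np.random.default_rng(1)
        a = Sinogram(rng.normal(size=(8, 64)), g, stage="filtered")
        b = Sinogram(rng.normal(size=(8, 64)), g, stage="filtered")
        c = Sinogram(1.5 * a.data + 0.5 * b.data, g, stage="filtered")
        grid = GridSpec.centered(16, 1.0)
        assert np.allclose(backproject_fbp(c, grid).data,
                           1.5 * backproject_fbp(a, grid).data
                           + 0.5 * backproject_fbp(b, grid).data, atol=1e-12)

    def test_cross_index_convention(self):
        # z row is a linear ramp: cross-weighted interpolation reproduces the
        # continuous coordinate exactly; the swapped convention does not.
        g = small_geom(n_views=1, n_det=64, pitch=3.6)
        z = Sinogram(np.arange(64, dtype=float)[None, :], g, stage="filtered")
        grid = GridSpec.centered(9, 5.0)
        img = backproject_fbp(z, grid)
        X, Y = grid.pixel_centers()
        k, L2 = view_detector_coords(g, 0.0, X, Y)
        w = 0.5 * 2 * np.pi * g.source_to_iso**2 / L2
        assert np.allclose(img.data, w * k, rtol=1e-10)
        i0 = np.floor(k)
        swapped = w * ((k - i0) * i0 + (1 - (k - i0)) * (i0 + 1))
        assert not np.allclose(img.data, swapped, rtol=1e-3)

    def test_rotation_equivariance(self):
        # rotating the object by 90 deg rotates the reconstruction (full scan,
        # N divisible by 4 so the view set is invariant)
        ph = make_phantom("shepp_logan", 64, 1.0, 0)
        g = small_geom(n_views=120, n_det=256, pitch=1.0)
        rot = [Ellipse((-e.center[1], e.center[0]), e.semi_axes,
                       e.angle + np.pi / 2, e.hu_delta) for e in ph.ellipses]
        rec = fbp_reconstruct(project_ellipses_analytic(ph.ellipses, g), ph.grid)
        rec_rot = fbp_reconstruct(project_ellipses_analytic(rot, g), ph.grid)
        diff = rec_rot.data - np.rot90(rec.data)
        scale = rec.data.max() - rec.data.min()
        assert np.sqrt(np.mean(diff**2)) < 0.01 * scale

    def test_more_views_reduce_error(self, sl96):
        # RMSE decreases monotonically 15 -> 30 -> 60 views (small mirror of
        # the full-scale sanity check in the acceptance suite, which runs the
        # view-rich regime 90..720 where detector sampling is not limiting)
        X, Y = sl96.grid.pixel_centers()
        interior = np.hypot(X, Y) < 0.85 * sl96.extent / 2
        rmses = []
        for n in (15, 30, 60):
            g = FanBeamGeometry(800.0, 1200.0, 256, 1.0, n)
            p = project_ellipses_analytic(sl96.ellipses, g)
            hu = mu_to_hu(fbp_reconstruct(p, sl96.grid).data)
            rmses.append(np.sqrt(np.mean((hu[interior] - sl96.values[interior]) ** 2)))
        assert rmses[0] > rmses[1] > rmses[2]
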