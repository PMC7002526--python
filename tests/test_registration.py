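import numpy as np
import pytest

from acoct.metrics import HFMaskSpec, r_hf
from acoct.phantom_simulator import (Phantom, make_speckle_phantom,
                                     simulate_angular_set, simulate_bscan,
                                     simulation_model)
from acoct.registration import (AngularImageSet, RegistrationModel,
                                SurfaceNotFoundError, TargetGrid, build_models,
                                correct_bulk_motion, detect_surface,
                                estimate_focus, fuse, register_image)

EXTENT = ((-160.0, 160.0), (0.0, 330.0))
OFFSETS_11 = np.linspace(-2500.0, 2500.0, 11)


def _grid(n_v=440, surface_row=30.0, ri=1.34, pitch=0.976):
    zmax = (n_v - surface_row) / ri
    return TargetGrid.from_extent((-110.0, 110.0), (3.0, zmax - 3.0),
                                  pitch, 1.0 / ri)


class TestDetectSurface:
    def test_flat_surface(self, geometry):
        ph = Phantom(np.empty((0, 3)), EXTENT).with_surface_line(amplitude=2.0)
        st = simulate_bscan(ph, geometry, 0.0, n_u=128, n_v=200,
                            focus_depth=120.0, surface_row=40.0,
                            noise_level=0.02, seed=0)
        surf = detect_surface(st.magnitude_mean())
        assert np.all(np.abs(surf - 40.0) <= 2.0)

    def test_tilted_surface_slope_recovered(self, geometry):
        ph = Phantom(np.empty((0, 3)), EXTENT, surface_slope=0.075,
                     ).with_surface_line(amplitude=2.0)
        st = simulate_bscan(ph, geometry, 0.0, n_u=128, n_v=220,
                            focus_depth=120.0, surface_row=40.0, seed=0)
        surf = detect_surface(st.magnitude_mean())
        cols = np.arange(20, 108)
        slope_px = np.polyfit(cols, surf[cols], 1)[0]
        # physical slope 0.075 -> image slope = slope * pitch_u / pitch_v
        # (the surface row is set by the air path, no RI factor)
        expected = 0.075 * geometry.scan_step
        assert slope_px == pytest.approx(expected, rel=0.10)

    def test_pure_noise_raises(self):
        rng = np.random.default_rng(0)
        with pytest.raises(SurfaceNotFoundError):
            detect_surface(rng.rayleigh(1.0, (100, 100)))


class TestRegisterImage:
    def test_identity_model_unchanged(self, geometry):
        # d = 0, telecentric galvo: the map is pure per-axis scaling, so
        # resampling on the matched grid reproduces the image
        from acoct.beam_optics import BeamGeometry

        geo = BeamGeometry(galvo_lens_distance=36000.0)
        rng = np.random.default_rng(1)
        img = rng.random((60, 40))
        m = RegistrationModel(geometry=geo, offset_d=0.0, focus_pixel_u=19.5,
                              focus_physical=(0.0, 50.0),
                              pixel_pitch_u=geo.scan_step, pixel_pitch_v=1.0,
                              surface_row=0.0)
        ri = geo.refractive_index
        grid = TargetGrid(x=geo.scan_step * (np.arange(40) - 19.5),
                          z=np.arange(60) / ri)
        reg, mask = register_image(img, m, grid)
        np.testing.assert_allclose(reg[mask], img[mask], atol=1e-9)

    def test_inverse_round_trip(self, geometry):
        m = RegistrationModel(geometry=geometry, offset_d=-2500.0,
                              focus_pixel_u=127.5, focus_physical=(0.0, 150.0),
                              pixel_pitch_u=geometry.scan_step,
                              pixel_pitch_v=1.0, surface_row=30.0)
        rng = np.random.default_rng(2)
        u = rng.uniform(0, 255, 1000)
        v = rng.uniform(32, 439, 1000)
        x, z = m.forward(u, v)
        u2, v2 = m.inverse(x, z)
        assert np.max(np.hypot(u2 - u, v2 - v)) < 0.1

    def test_cross_angle_bead_alignment(self, geometry):
        # the core claim: beads at +-300 um (optical) from focus land at the
        # same physical spot from every incident angle after registration
        from tests.conftest import grid_bead_phantom

        ph = grid_bead_phantom(seed=3).with_surface_line(amplitude=0.1)
        stacks = simulate_angular_set(ph, geometry, OFFSETS_11, n_u=256,
                                      n_v=440, focus_depth=150.0,
                                      surface_row=30.0, seed=0)
        grid = _grid()
        pitch_x = grid.x[1] - grid.x[0]
        pitch_z = grid.z[1] - grid.z[0]
        beads = ph.scatterers[ph.scatterers[:, 2] >= 1.0]
        positions = {i: [] for i in range(len(beads))}
        for st in stacks:
            model = simulation_model(ph, geometry, st.offset_d, 256, 150.0)
            reg, mask = register_image(st.magnitude_mean(), model, grid)
            for i, (bx, bz, _) in enumerate(beads):
                ix = int(round((bx - grid.x[0]) / pitch_x))
                iz = int(round((bz - grid.z[0]) / pitch_z))
                sub = reg[max(iz - 8, 0):iz + 9, max(ix - 8, 0):ix + 9]
                if sub.size == 0 or sub.max() < 0.2:
                    continue  # bead outside this angle's footprint
                pz, px = np.unravel_index(np.argmax(sub), sub.shape)
                zz, xx = np.mgrid[0:sub.shape[0], 0:sub.shape[1]]
                w = sub**2
                positions[i].append((
                    (xx * w).sum() / w.sum() + max(ix - 8, 0),
                    (zz * w).sum() / w.sum() + max(iz - 8, 0)))
        checked = 0
        for i, pos in positions.items():
            if len(pos) < 8:
                continue
            pos = np.asarray(pos)
            assert np.ptp(pos[:, 0]) <= 2.0, f"bead {i} lateral spread"
            assert np.ptp(pos[:, 1]) <= 2.0, f"bead {i} axial spread"
            assert pos[:, 0].std() < 1.0 and pos[:, 1].std() < 1.0
            checked += 1
        assert checked >= 8

    def test_quadratic_terms_matter(self, geometry):
        # full model beats the rotation+translation-only truncation when the
        # galvo is not at the back focal plane
        ph = make_speckle_phantom(4.0, EXTENT, seed=5).with_surface_line()
        stacks = simulate_angular_set(ph, geometry, OFFSETS_11[::2], n_u=192,
                                      n_v=300, focus_depth=120.0,
                                      surface_row=30.0, seed=1)
        grid = TargetGrid.from_extent((-80.0, 80.0), (5.0, 190.0), 0.976,
                                      1.0 / geometry.refractive_index)
        scores = {}
        for mode in ("full", "linear"):
            regs = []
            for st in stacks:
                model = simulation_model(ph, geometry, st.offset_d, 192, 120.0)
                if mode == "linear":
                    model = RegistrationModel(
                        **{**model.__dict__, "mode": "linear"})
                regs.append(register_image(st.magnitude_mean(), model, grid))
            comp = fuse(regs)
            m = comp.magnitude.copy()
            m[~comp.valid_mask] = m[comp.valid_mask].mean()
            scores[mode] = r_hf(m, HFMaskSpec())
        assert scores["full"] > scores["linear"]


class TestFuse:
    def test_identical_inputs(self):
        rng = np.random.default_rng(0)
        img = rng.random((30, 30))
        mask = np.ones_like(img, bool)
        comp = fuse([(img, mask)] * 11)
        np.testing.assert_allclose(comp.magnitude, img)
        assert np.all(comp.contributing_count == 11)

    def test_speckle_std_reduction_two_angles(self):
        rng = np.random.default_rng(1)
        a = rng.rayleigh(1.0, (200, 200))
        b = rng.rayleigh(1.0, (200, 200))
        mask = np.ones_like(a, bool)
        comp = fuse([(a, mask), (b, mask)])
        assert comp.magnitude.std() == pytest.approx(a.std() / np.sqrt(2), rel=0.15)

    def test_all_masked_pixel_invalid(self):
        img = np.ones((4, 4))
        mask = np.ones((4, 4), bool)
        mask[0, 0] = False
        comp = fuse([(img, mask), (img, mask)])
        assert comp.contributing_count[0, 0] == 0
        assert not comp.valid_mask[0, 0]

    def test_never_increases_background_stats(self):
        rng = np.random.default_rng(2)
        imgs = [(rng.rayleigh(1.0, (100, 100)), np.ones((100, 100), bool))
                for _ in range(6)]
        comp = fuse(imgs)
        means = [im.mean() for im, _ in imgs]
        stds = [im.std() for im, _ in imgs]
        assert comp.magnitude.mean() <= max(means) + 1e-12
        assert comp.magnitude.std() <= max(stds)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            fuse([])


def beads_in_speckle_phantom(seed=8):
    """Bright beads over weak speckle -- cross-angle-persistent structure
    plus a realistic background, like the experimental agar-bead sample."""
    extent = ((-120.0, 120.0), (0.0, 200.0))
    spk = make_speckle_phantom(3.0, extent, seed=seed)
    spk.scatterers[:, 2] *= 0.25
    rng = np.random.default_rng(seed + 1)
    n = 12
    beads = np.column_stack([
        rng.uniform(-70, 70, n),
        np.linspace(25, 170, n) + rng.uniform(-5, 5, n),
        np.full(n, 3.0)])
    return Phantom(np.vstack([spk.scatterers, beads]), extent,
                   ).with_surface_line(amplitude=2.0)


FOCUS_DEPTH = 120.0


@pytest.fixture(scope="module")
def angular_set(geometry):
    ph = beads_in_speckle_phantom()
    stacks = simulate_angular_set(ph, geometry, OFFSETS_11[::2], n_u=160,
                                  n_v=260, focus_depth=FOCUS_DEPTH,
                                  surface_row=30.0, noise_level=0.01, seed=2)
    aset = AngularImageSet(images=[s.magnitude_mean() for s in stacks],
                           offsets_d=OFFSETS_11[::2], geometry=geometry,
                           pixel_pitch_v=1.0)
    truth = simulation_model(ph, geometry, 0.0, 160, FOCUS_DEPTH)
    return aset, (truth.focus_pixel_u, truth.focus_pixel_v)


class TestEstimateFocus:
    FOCUS_DEPTH = FOCUS_DEPTH

    def test_recovers_true_focus(self, angular_set, geometry):
        aset, (u_true, v_true) = angular_set
        (u_f, v_f), surface_row = estimate_focus(aset)
        assert abs(u_f - u_true) <= 2
        # the focus row is referenced to the detected surface; compare the
        # implied physical focus depth (2 axial-pixel tolerance)
        ri = geometry.refractive_index
        z_f = (v_f - surface_row) / ri
        assert abs(z_f - self.FOCUS_DEPTH) <= 2.0 / ri
        assert surface_row == pytest.approx(30.0, abs=2.5)

    def test_symmetric_set_centred_focus_column(self, angular_set):
        aset, (u_true, _) = angular_set
        (u_f, _), _ = estimate_focus(aset, coarse_only=True)
        assert abs(u_f - u_true) <= 2

    def test_focus_is_local_max_of_r_hf(self, angular_set, geometry):
        aset, _ = angular_set
        (u_f, v_f), surface_row = estimate_focus(aset)

        def score(v_c):
            models = build_models(geometry, aset.offsets_d, (u_f, v_c),
                                  surface_row)
            grid = TargetGrid.from_extent((-75.0, 75.0), (10.0, 165.0), 0.976,
                                          1.0 / geometry.refractive_index)
            comp = fuse([register_image(img, m, grid)
                         for img, m in zip(aset.images, models)])
            m = comp.magnitude.copy()
            m[~comp.valid_mask] = m[comp.valid_mask].mean()
            return r_hf(m)

        assert score(v_f) >= score(v_f + 10)

    def test_featureless_images_raise(self, geometry):
        rng = np.random.default_rng(0)
        imgs = []
        for _ in range(5):
            im = np.full((80, 60), 0.001)
            im[40:] = 1.0  # surface-like step but zero texture below
            imgs.append(im + 1e-6 * rng.random((80, 60)))
        aset = AngularImageSet(images=imgs, offsets_d=OFFSETS_11[3:8],
                               geometry=geometry, pixel_pitch_v=1.0)
        with pytest.raises(Exception):
            estimate_focus(aset)

    def test_too_few_images(self, geometry):
        aset = AngularImageSet(images=[np.ones((10, 10))] * 2,
                               offsets_d=np.array([0.0, 1.0]),
                               geometry=geometry)
        with pytest.raises(ValueError):
            estimate_focus(aset)


class TestBulkMotion:
    @staticmethod
    def _image_with_surface(row, seed=0):
        rng = np.random.default_rng(seed)
        img = 0.02 * rng.random((120, 80))
        img[row:row + 3] = 2.0
        img[row + 3:] += 0.3 * rng.random((120 - row - 3, 80))
        return img

    def test_injected_shift_detected_and_removed(self):
        imgs = [self._image_with_surface(40, s) for s in range(5)]
        imgs[2] = self._image_with_surface(43, 2)
        aligned, shifts = correct_bulk_motion(imgs)
        assert shifts == [0, 0, 3, 0, 0]
        surf = detect_surface(aligned[2])
        assert np.median(surf) == pytest.approx(40, abs=1.5)

    def test_zero_shift_set(self):
        imgs = [self._image_with_surface(40, s) for s in range(4)]
        _, shifts = correct_bulk_motion(imgs)
        assert shifts == [0, 0, 0, 0]

    def test_alternating_shifts(self):
        rows = [41, 39, 41, 39, 40]
        imgs = [self._image_with_surface(r, s) for s, r in enumerate(rows)]
        _, shifts = correct_bulk_motion(imgs)
        assert shifts == [1, -1, 1, -1, 0]

    def test_large_shift_warns(self):
        imgs = [self._image_with_surface(40, s) for s in range(3)]
        imgs[1] = self._image_with_surface(70, 1)
        with pytest.warns(UserWarning, match="bulk-motion"):
            correct_bulk_motion(imgs, max_shift=10)
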