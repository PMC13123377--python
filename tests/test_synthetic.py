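"""Generator ground-truth properties: balance, kernel, determinism."""
import numpy as np
import pytest

from embryotfm import (
    GelProperties,
    PeakTrainSpec,
    TractionField,
    forward_displacement,
    gen_indentation_curve,
    gen_peak_series,
    gen_trajectory,
    gen_yap_cell_image,
    hertz_force,
    make_contractile_traction,
    make_scene,
    render_bead_images,
    scene_for_stiffness,
)
from embryotfm.fields import DisplacementField


class TestContractileTraction:
    def test_zero_peak_gives_zero_field(self):
        t = make_contractile_traction(peak=0.0)
        assert np.all(t.tx == 0.0) and np.all(t.ty == 0.0)

    def test_force_balance(self, annulus_traction):
        # |Σ T·dA| ≤ 1e-6 × Σ|T|·dA for a contractile, self-balanced scene
        assert annulus_traction.net_force_imbalance() <= 1e-6

    def test_offcenter_annulus_still_balanced(self):
        t = make_contractile_traction(center=(70.0, 110.0))
        assert t.net_force_imbalance() <= 1e-6

    def test_mirror_symmetry(self):
        """Mirror-image geometry produces a mirror-symmetric field."""
        left = make_contractile_traction(shape=(64, 64), spacing=2.0,
                                         center=(40.0, 63.0))
        right = make_contractile_traction(shape=(64, 64), spacing=2.0,
                                          center=(86.0, 63.0))
        # reflect 'right' about the vertical midline: x -> (2*63 - x)
        assert np.allclose(left.tx, -right.tx[:, ::-1], atol=1e-9)
        assert np.allclose(left.ty, right.ty[:, ::-1], atol=1e-9)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            make_contractile_traction(shape=(2, 64))
        with pytest.raises(ValueError):
            make_contractile_traction(r_inner=50.0, r_outer=40.0)


class TestForwardDisplacement:
    def test_zero_traction_zero_displacement(self, gel):
        t = make_contractile_traction(peak=0.0)
        u = forward_displacement(t, gel)
        assert np.all(u.u == 0.0) and np.all(u.v == 0.0)

    def test_single_mode_matches_closed_form(self, gel):
        """ũ = G̃ T̃ evaluated analytically at one (kx, ky)."""
        n, d = 64, 2.0
        x = np.arange(n) * d
        kx0 = 2 * np.pi * 3 / (n * d)
        ky0 = 2 * np.pi * 5 / (n * d)
        X, Y = np.meshgrid(x, x)
        phase = np.cos(kx0 * X + ky0 * Y)
        t = TractionField(x, x, 50.0 * phase, 20.0 * phase)
        u = forward_displacement(t, gel, pad_factor=1)

        E, nu = gel.youngs_modulus, gel.poisson_ratio
        k2 = kx0 ** 2 + ky0 ** 2
        pref = 2 * (1 + nu) / (E * k2 ** 1.5)
        gxx = pref * ((1 - nu) * k2 + nu * ky0 ** 2)
        gyy = pref * ((1 - nu) * k2 + nu * kx0 ** 2)
        gxy = -pref * nu * kx0 * ky0
        ue = (gxx * 50 + gxy * 20) * phase
        ve = (gxy * 50 + gyy * 20) * phase
        assert np.max(np.abs(u.u - ue)) < 1e-10 * np.max(np.abs(ue))
        assert np.max(np.abs(u.v - ve)) < 1e-10 * np.max(np.abs(ve))

    def test_linearity_in_traction_and_compliance(self, annulus_traction, gel):
        u1 = forward_displacement(annulus_traction, gel)
        t2 = TractionField(annulus_traction.x, annulus_traction.y,
                           2 * annulus_traction.tx, 2 * annulus_traction.ty)
        u2 = forward_displacement(t2, gel)
        assert np.allclose(u2.u, 2 * u1.u, rtol=1e-12)
        stiff = GelProperties(2 * gel.youngs_modulus, gel.poisson_ratio)
        u_half = forward_displacement(annulus_traction, stiff)
        assert np.allclose(u_half.u, 0.5 * u1.u, rtol=1e-12)

    def test_invalid_gel_rejected(self):
        with pytest.raises(ValueError):
            GelProperties(youngs_modulus=-5.0)
        with pytest.raises(ValueError):
            GelProperties(youngs_modulus=1000.0, poisson_ratio=0.7)


class TestBeadRendering:
    def test_zero_displacement_identical_images(self, clean_scene):
        disp = forward_displacement(clean_scene.traction_truth,
                                    clean_scene.gel)
        zero = DisplacementField(disp.x, disp.y, np.zeros_like(disp.u),
                                 np.zeros_like(disp.v))
        clean_scene.drift_per_frame[:] = 0.0
        ref, stack = render_bead_images(clean_scene, zero)
        assert np.array_equal(ref, stack[0])

    def test_uniform_displacement_shifts_spots(self, clean_scene):
        """1.0 μm at 0.5 μm/px moves every spot +2 px in x."""
        disp = forward_displacement(clean_scene.traction_truth,
                                    clean_scene.gel)
        uni = DisplacementField(disp.x, disp.y, np.full_like(disp.u, 1.0),
                                np.zeros_like(disp.v))
        clean_scene.drift_per_frame[:] = 0.0
        ref, stack = render_bead_images(clean_scene, uni)
        rolled = np.roll(ref, 2, axis=1)
        # margin excludes beads whose spot tails are truncated at the frame
        inner = (slice(16, -16), slice(16, -16))
        assert np.allclose(rolled[inner].astype(float),
                           stack[0][inner].astype(float), atol=2.0)

    def test_fixed_seed_bit_reproducible(self):
        a = make_scene(seed=7)
        b = make_scene(seed=7)
        ra, sa = render_bead_images(a)
        rb, sb = render_bead_images(b)
        assert np.array_equal(ra, rb) and np.array_equal(sa, sb)

    def test_unbalanced_truth_rejected(self, clean_scene):
        t = clean_scene.traction_truth
        bad = TractionField(t.x, t.y, t.tx + 5.0, t.ty)
        with pytest.raises(ValueError, match="balanced"):
            make_scene(seed=0).__class__(
                traction_truth=bad, gel=clean_scene.gel,
                bead_positions_reference=clean_scene.bead_positions_reference,
                drift_per_frame=clean_scene.drift_per_frame,
                pixel_size=0.5, seed=0,
            )


class TestStiffnessProgram:
    def test_total_force_conserved_and_peak_falls(self):
        maxes, totals = [], []
        for E in (1000.0, 4000.0, 10000.0):
            s = scene_for_stiffness(E, seed=0)
            t = s.traction_truth
            totals.append(np.sum(t.magnitude) * t.node_area * 1e-3)
            maxes.append(t.magnitude.max())
        assert np.allclose(totals, totals[0], rtol=1e-6)
        assert maxes[0] > maxes[1] > maxes[2]


class TestPeakSeries:
    def test_zero_jitter_exact_period(self):
        spec = PeakTrainSpec(jitter_sd=0.0, mean_period=10.0,
                             sampling_interval=1.0)
        _, peaks = gen_peak_series(spec, seed=0)
        assert np.allclose(np.diff(peaks), 10.0)

    def test_zero_amplitude_is_ramp_plus_baseline(self):
        spec = PeakTrainSpec(peak_amplitude=0.0)
        ts, _ = gen_peak_series(spec, seed=0)
        expected = spec.baseline * np.clip(ts.times / spec.ramp_duration, 0, 1)
        assert np.allclose(ts.values, expected)

    def test_interval_mean_matches_spec(self):
        """Sample mean of inter-peak intervals is consistent with the
        configured 10-min period (within 3 SEM over ~200 peaks)."""
        spec = PeakTrainSpec(jitter_sd=1.0, mean_period=10.0,
                             duration=2100.0, sampling_interval=1.0)
        _, peaks = gen_peak_series(spec, seed=3)
        iv = np.diff(peaks)
        assert iv.size > 150
        sem = iv.std(ddof=1) / np.sqrt(iv.size)
        assert abs(iv.mean() - 10.0) < 3 * sem + 1e-9

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PeakTrainSpec(mean_period=0.0)
        with pytest.raises(ValueError):
            PeakTrainSpec(duration=1.0, sampling_interval=5.0)


class TestTrajectoryGenerator:
    def test_zero_speed_stationary(self):
        traj = gen_trajectory(0.0, 10.0, 50, seed=0)
        assert np.all(traj.positions == traj.positions[0])

    def test_infinite_persistence_straight_line(self):
        traj = gen_trajectory(0.5, np.inf, 100, seed=1)
        d = np.diff(traj.positions, axis=0)
        # all steps parallel: cross products vanish
        cross = d[:-1, 0] * d[1:, 1] - d[:-1, 1] * d[1:, 0]
        assert np.max(np.abs(cross)) < 1e-9

    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError):
            gen_trajectory(-1.0, 10.0, 10)


class TestIndentationGenerator:
    def test_hertz_spot_value(self):
        """F(δ=1 μm; E=1 kPa, ν=0.5, R=3 μm) ≈ 3.08 nN (closed form)."""
        f = hertz_force(np.array([1.0]), 1000.0, 0.5, 3.0)[0]
        assert f == pytest.approx(3.079, rel=1e-3)

    def test_zero_depth_zero_force(self):
        curve = gen_indentation_curve(1000.0, contact_offset=0.5)
        pre = curve.delta <= 0.5
        assert np.all(curve.force[pre] == 0.0)

    def test_force_linear_in_modulus(self):
        c1 = gen_indentation_curve(1000.0)
        c2 = gen_indentation_curve(2000.0)
        post = c1.force > 0
        assert np.allclose(c2.force[post], 2 * c1.force[post], rtol=1e-12)


class TestYapGenerator:
    @staticmethod
    def _masks():
        cell = np.zeros((40, 40), dtype=bool)
        cell[5:35, 5:35] = True
        nuc = np.zeros_like(cell)
        nuc[15:25, 15:25] = True
        return cell, nuc

    def test_uniform_intensity_ratio_is_area_ratio(self):
        cell, nuc = self._masks()
        _, truth = gen_yap_cell_image(10.0, 10.0, nuc, cell)
        a_nuc = nuc.sum()
        a_cell = cell.sum()
        assert truth["ratio"] == pytest.approx(a_nuc / (a_cell - a_nuc))

    def test_zero_cytoplasm_flagged_degenerate(self):
        cell, nuc = self._masks()
        _, truth = gen_yap_cell_image(10.0, 0.0, nuc, cell)
        assert truth["degenerate"] and np.isinf(truth["ratio"])

    def test_nucleus_outside_cell_rejected(self):
        cell, nuc = self._masks()
        with pytest.raises(ValueError):
            gen_yap_cell_image(10.0, 5.0, cell, nuc)  # swapped
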