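"""FTTC inversion, regularization selection and force metrics."""
import warnings

import numpy as np
import pytest

from embryotfm import (
    DisplacementField,
    GelProperties,
    PA_UM2_TO_NN,
    TractionField,
    forward_displacement,
    fttc_inverse,
    make_contractile_traction,
    noise_floor,
    select_lambda,
    traction_metrics,
)
from embryotfm.traction import _residual_norm


def _invert(field, gel, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fttc_inverse(field, gel, **kw)


class TestFttcInverse:
    def test_zero_displacement_zero_traction(self, gel):
        x = np.arange(32) * 2.0
        field = DisplacementField(x, x, np.zeros((32, 32)), np.zeros((32, 32)))
        t = _invert(field, gel, lam=0.0)
        assert np.allclose(t.tx, 0.0) and np.allclose(t.ty, 0.0)

    def test_round_trip_against_forward_oracle(self, annulus_traction, gel):
        """Noise-free dense displacement inverts to the source traction
        with relative L2 error far below 5%."""
        u = forward_displacement(annulus_traction, gel)
        rec = _invert(u, gel, lam=0.0)
        num = np.sum((rec.tx - annulus_traction.tx) ** 2
                     + (rec.ty - annulus_traction.ty) ** 2)
        den = np.sum(annulus_traction.tx ** 2 + annulus_traction.ty ** 2)
        assert np.sqrt(num / den) < 0.05

    def test_traction_linear_in_modulus(self, annulus_traction, gel):
        u = forward_displacement(annulus_traction, gel)
        t1 = _invert(u, gel, lam=0.0)
        stiff = GelProperties(2 * gel.youngs_modulus, gel.poisson_ratio)
        t2 = _invert(u, stiff, lam=0.0)
        assert np.allclose(t2.tx, 2 * t1.tx, rtol=1e-9, atol=1e-9)

    def test_net_force_free(self, annulus_traction, gel):
        u = forward_displacement(annulus_traction, gel)
        rec = _invert(u, gel, lam=1e-4)
        assert rec.net_force_imbalance() < 1e-12

    def test_monotone_regularization_residual(self, annulus_traction, gel):
        """Round-trip data residual is non-decreasing in λ."""
        u = forward_displacement(annulus_traction, gel)
        lams = [1e-5, 1e-4, 1e-3, 1e-2, 1e-1]
        resid = [
            _residual_norm(u, gel, _invert(u, gel, lam=lam)) for lam in lams
        ]
        assert np.all(np.diff(resid) >= -1e-9)

    def test_wiener_mode_runs_and_recovers(self, annulus_traction, gel):
        rng = np.random.default_rng(0)
        u = forward_displacement(annulus_traction, gel)
        noisy = DisplacementField(
            u.x, u.y,
            u.u + rng.normal(0, 0.02, u.u.shape),
            u.v + rng.normal(0, 0.02, u.v.shape),
        )
        t = _invert(noisy, gel, filter_mode="wiener")
        corr = np.corrcoef(t.magnitude.ravel(),
                           annulus_traction.magnitude.ravel())[0, 1]
        assert corr > 0.8

    def test_invalid_arguments(self, annulus_traction, gel):
        u = forward_displacement(annulus_traction, gel)
        with pytest.raises(ValueError):
            fttc_inverse(u, gel, lam=-1.0)
        with pytest.raises(ValueError):
            fttc_inverse(u, gel, filter_mode="butterworth")

    def test_lambda_zero_warns(self, annulus_traction, gel):
        u = forward_displacement(annulus_traction, gel)
        with pytest.warns(UserWarning, match="lambda"):
            fttc_inverse(u, gel, lam=0.0)


class TestSelectLambda:
    def test_fixed_strategy_returns_value(self, annulus_traction, gel):
        u = forward_displacement(annulus_traction, gel)
        assert select_lambda(u, gel, strategy="fixed", value=1e-3) == 1e-3

    def test_lcurve_near_sweep_optimum(self, clean_scene):
        """L-curve choice is within 2x of the best round-trip error on the
        same 20-point λ grid (exhaustive sweep oracle)."""
        from embryotfm import compute_displacement_field, render_bead_images
        from scipy.interpolate import RegularGridInterpolator

        scene = clean_scene
        disp = forward_displacement(scene.traction_truth, scene.gel)
        scene.drift_per_frame[:] = 0.0
        ref, stack = render_bead_images(scene, disp)
        field = compute_displacement_field(stack[0], ref, pixel_size=0.5)

        truth = scene.traction_truth
        itx = RegularGridInterpolator((truth.y, truth.x), truth.tx)
        ity = RegularGridInterpolator((truth.y, truth.x), truth.ty)
        X, Y = np.meshgrid(field.x, field.y)
        pts = np.column_stack([Y.ravel(), X.ravel()])
        txt = itx(pts).reshape(X.shape)
        tyt = ity(pts).reshape(X.shape)

        scale = 2 * (1 + scene.gel.poisson_ratio) / (
            scene.gel.youngs_modulus
            * (2 * np.pi / (field.spacing * field.u.shape[0]))
        )
        grid = scale * np.logspace(-4, 0, 20)

        def rt_error(lam):
            t = _invert(field, scene.gel, lam=lam)
            return np.sqrt(
                np.sum((t.tx - txt) ** 2 + (t.ty - tyt) ** 2)
                / np.sum(txt ** 2 + tyt ** 2)
            )

        errors = np.array([rt_error(lam) for lam in grid])
        lam_sel = select_lambda(field, scene.gel, strategy="lcurve",
                                lam_grid=grid)
        assert rt_error(lam_sel) <= 2.0 * errors.min()

    def test_noise_matched_orders_with_signal(self, gel):
        """A pure-noise field draws a larger λ than a high-signal field
        carrying the same noise."""
        rng = np.random.default_rng(4)
        t = make_contractile_traction(shape=(48, 48), spacing=4.0, peak=300.0)
        u = forward_displacement(t, gel)
        noise_u = rng.normal(0, 0.02, u.u.shape)
        noise_v = rng.normal(0, 0.02, u.v.shape)
        bg = np.zeros(u.u.shape, dtype=bool)
        bg[:4, :] = bg[-4:, :] = True

        pure = DisplacementField(u.x, u.y, noise_u, noise_v)
        signal = DisplacementField(u.x, u.y, u.u + noise_u, u.v + noise_v)
        lam_pure = select_lambda(pure, gel, strategy="noise", noise_region=bg)
        lam_signal = select_lambda(signal, gel, strategy="noise",
                                   noise_region=bg)
        assert lam_pure >= lam_signal

    def test_noise_strategy_requires_region(self, annulus_traction, gel):
        u = forward_displacement(annulus_traction, gel)
        with pytest.raises(ValueError, match="noise_region"):
            select_lambda(u, gel, strategy="noise")

    def test_gcv_regularizes_noisy_field(self, annulus_traction, gel):
        rng = np.random.default_rng(9)
        u = forward_displacement(annulus_traction, gel)
        noisy = DisplacementField(
            u.x, u.y,
            u.u + rng.normal(0, 0.05, u.u.shape),
            u.v + rng.normal(0, 0.05, u.v.shape),
        )
        lam = select_lambda(noisy, gel, strategy="gcv")
        rec = _invert(noisy, gel, lam=lam)
        raw = _invert(noisy, gel, lam=1e-12)
        truth_max = annulus_traction.magnitude.max()
        assert abs(rec.magnitude.max() - truth_max) \
            < abs(raw.magnitude.max() - truth_max)


class TestTractionMetrics:
    def test_uniform_field_unit_algebra(self):
        """100 Pa over 10,000 μm² integrates to 1,000 nN."""
        x = np.arange(50) * 2.0  # node area 4 μm²
        tx = np.full((50, 50), 100.0)
        t = TractionField(x, x, tx, np.zeros_like(tx))
        mask = np.zeros((50, 50), dtype=bool)
        mask.ravel()[:2500] = True  # 2500 nodes × 4 μm² = 10,000 μm²
        m = traction_metrics(t, mask)
        assert m.mean_traction == pytest.approx(100.0)
        assert m.contact_area == pytest.approx(10_000.0)
        assert m.total_force == pytest.approx(1_000.0)

    def test_unit_conversion_constant(self):
        assert PA_UM2_TO_NN == 1e-3

    def test_single_node_max_equals_mean(self):
        x = np.arange(8) * 1.0
        tx = np.zeros((8, 8))
        tx[3, 4] = 55.0
        t = TractionField(x, x, tx, np.zeros_like(tx))
        mask = tx > 0
        m = traction_metrics(t, mask)
        assert m.max_traction == m.mean_traction == pytest.approx(55.0)

    def test_empty_mask_rejected(self):
        x = np.arange(8) * 1.0
        t = TractionField(x, x, np.ones((8, 8)), np.zeros((8, 8)))
        with pytest.raises(ValueError, match="empty"):
            traction_metrics(t, np.zeros((8, 8), dtype=bool))

    def test_ramp_series_monotone_max(self):
        """Scaling a fixed pattern by a ramp gives a monotone max series."""
        base = make_contractile_traction(shape=(32, 32), spacing=4.0)
        mask = base.magnitude > 0
        maxes = []
        for amp in np.linspace(0.2, 1.0, 5):
            t = TractionField(base.x, base.y, amp * base.tx, amp * base.ty)
            maxes.append(traction_metrics(t, mask).max_traction)
        assert np.all(np.diff(maxes) > 0)


class TestNoiseFloor:
    def test_zero_background_zero_floor(self):
        x = np.arange(16) * 2.0
        t = TractionField(x, x, np.zeros((16, 16)), np.zeros((16, 16)))
        bg = np.ones((16, 16), dtype=bool)
        assert noise_floor(t, bg) == 0.0

    def test_half_normal_closed_form(self):
        """|T| of isotropic Gaussian noise is Rayleigh-distributed; the
        mean+2SD floor matches the closed form within 10% at 10⁴ nodes."""
        rng = np.random.default_rng(12)
        sigma = 1.0
        n = 100
        x = np.arange(n) * 2.0
        tx = rng.normal(0, sigma, (n, n))
        ty = rng.normal(0, sigma, (n, n))
        t = TractionField(x, x, tx, ty)
        bg = np.ones((n, n), dtype=bool)
        mean = sigma * np.sqrt(np.pi / 2)
        sd = sigma * np.sqrt(2 - np.pi / 2)
        expected = mean + 2 * sd
        assert noise_floor(t, bg) == pytest.approx(expected, rel=0.10)

    def test_floor_ignores_embryo_region(self):
        rng = np.random.default_rng(3)
        n = 32
        x = np.arange(n) * 2.0
        tx = rng.normal(0, 1.0, (n, n))
        t1 = TractionField(x, x, tx.copy(), np.zeros((n, n)))
        tx2 = tx.copy()
        tx2[10:20, 10:20] = 500.0  # embryo region
        t2 = TractionField(x, x, tx2, np.zeros((n, n)))
        bg = np.ones((n, n), dtype=bool)
        bg[8:22, 8:22] = False
        assert noise_floor(t1, bg) == noise_floor(t2, bg)

    def test_empty_background_rejected(self):
        x = np.arange(8) * 1.0
        t = TractionField(x, x, np.ones((8, 8)), np.zeros((8, 8)))
        with pytest.raises(ValueError):
            noise_floor(t, np.zeros((8, 8), dtype=bool))
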