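import numpy as np
import pytest

from pwftomo import (
    CoherenceModel,
    ComplexPhaseMap,
    ImagingGeometry,
    IntensityImage2D,
    SolverParams,
    forward,
    loss,
    preconditioned_update,
    rmse_image,
    solve,
    wirtinger_gradient,
)
from pwftomo.coherence import iotf, regularization_window, stf_window
from pwftomo.diffuser import DiffuserTransmission
from pwftomo.simulate import (
    default_config,
    default_phantom,
    make_diffuser_screen,
    simulate_dataset,
)
from pwftomo.solver import background_border_mask, gradient_normalization


def _random_instance(geometry, rng, psi_scale=0.1):
    t = DiffuserTransmission(
        np.exp(1j * rng.standard_normal(geometry.shape)), geometry
    )
    psi = psi_scale * (
        rng.standard_normal(geometry.shape)
        + 1j * rng.standard_normal(geometry.shape)
    )
    y = IntensityImage2D(np.abs(rng.standard_normal(geometry.shape)) + 0.5, geometry)
    return t, psi, y


class TestForward:
    def test_empty_system_gives_unit_intensity(self, geometry32):
        # delta-like IPSF: tiny coherence lengths make the IOTF ~ 1
        model = CoherenceModel(1e-9, 1e-9)
        t = DiffuserTransmission(np.ones(geometry32.shape, complex), geometry32)
        psi = ComplexPhaseMap(np.zeros(geometry32.shape, complex), geometry32)
        out = forward(psi, t, model, geometry32)
        assert np.allclose(out.values, 1.0, atol=1e-10)

    def test_uniform_attenuation_scales_intensity(self, geometry32):
        model = CoherenceModel(1e-9, 1e-9)
        t = DiffuserTransmission(np.ones(geometry32.shape, complex), geometry32)
        c = -0.3 + 0.7j  # global phase drops out in |.|^2
        psi = ComplexPhaseMap(np.full(geometry32.shape, c), geometry32)
        out = forward(psi, t, model, geometry32)
        assert np.allclose(out.values, np.exp(2 * c.real), atol=1e-10)

    def test_energy_bookkeeping_with_phantom(self, phantom64):
        cfg = default_config(seed=0, n=64, n_angles=1)
        ds = simulate_dataset(phantom64, cfg)
        psi_true = ds.truth_psi[0]
        # mean intensity equals mean transmitted power (unitary propagation,
        # unit-modulus diffuser, DC-preserving IOTF)
        expected = np.mean(np.exp(2 * psi_true.real))
        assert ds.projections[0].mean() == pytest.approx(expected, rel=0.01)

    def test_shape_mismatch_rejected(self, geometry32, geometry64):
        model = CoherenceModel(2e-6, 2e-6)
        t = DiffuserTransmission(np.ones(geometry64.shape, complex), geometry64)
        psi = ComplexPhaseMap(np.zeros(geometry32.shape, complex), geometry32)
        with pytest.raises(ValueError):
            forward(psi, t, model, geometry32)


class TestLoss:
    def test_zero_at_exact_fit_without_regularizer(self, geometry32, rng):
        model = CoherenceModel(2e-6, 2.6e-6)
        t, psi_values, _ = _random_instance(geometry32, rng)
        psi = ComplexPhaseMap(psi_values, geometry32)
        y = forward(psi, t, model, geometry32)
        params = SolverParams(alpha=0j)
        assert loss(psi, t, model, geometry32, y, params) == pytest.approx(
            0.0, abs=1e-18
        )

    def test_zero_state_has_no_regularizer_term(self, geometry32, rng):
        model = CoherenceModel(2e-6, 2.6e-6)
        t, _, y = _random_instance(geometry32, rng)
        psi0 = ComplexPhaseMap(np.zeros(geometry32.shape, complex), geometry32)
        params_reg = SolverParams(alpha=0.1 + 0.01j)
        params_none = SolverParams(alpha=0j)
        assert loss(psi0, t, model, geometry32, y, params_reg) == pytest.approx(
            loss(psi0, t, model, geometry32, y, params_none)
        )

    def test_matches_direct_summation_oracle(self, rng):
        # independent oracle: explicit DFT matrices and elementwise sums on
        # a tiny 8x8 instance
        geom = ImagingGeometry(nx=8, ny=8, pitch=650e-9, wavelength=0.124e-9,
                               L1=3e-3, L2=20e-3)
        model = CoherenceModel(2e-6, 2.6e-6)
        t, psi_values, y = _random_instance(geom, rng)
        psi = ComplexPhaseMap(psi_values, geom)
        params = SolverParams(alpha=0.3 + 0.2j)

        n = 8
        dft = np.exp(-2j * np.pi * np.outer(np.arange(n), np.arange(n)) / n)
        idft = np.conj(dft) / n

        def dft2(a):
            return dft @ a @ dft.T

        def idft2(a):
            return idft @ a @ idft.T

        lam = geom.wavelength
        u1 = np.fft.fftfreq(n, geom.pitch)
        uu, vv = np.meshgrid(u1, u1)
        s2 = 1 - (lam * uu) ** 2 - (lam * vv) ** 2

        def kernel(d):
            return np.where(
                s2 > 0, np.exp(1j * 2 * np.pi * (d / lam) * np.sqrt(np.abs(s2))), 0
            )

        x = np.exp(psi_values)
        after1 = idft2(kernel(geom.L1) * dft2(x))
        w = idft2(kernel(geom.L2) * dft2(t.values * after1))
        intensity = np.abs(w) ** 2
        iotf_w = np.exp(
            -(np.pi / 2) * (uu**2 * model.x_coh**2 + vv**2 * model.y_coh**2)
        )
        f = idft2(iotf_w * dft2(intensity)).real
        data = np.sum((y.values - f) ** 2)
        ortho_re = dft2(psi_values.real) / n
        ortho_im = dft2(psi_values.imag) / n
        gamma2 = 1 - np.exp(
            -np.pi * 1.0 * (uu**2 * model.x_coh**2 + vv**2 * model.y_coh**2)
        )
        reg = params.alpha.real * np.sum(gamma2 * np.abs(ortho_re) ** 2) + (
            params.alpha.imag * np.sum(gamma2 * np.abs(ortho_im) ** 2)
        )
        oracle = data + reg
        value = loss(psi, t, model, geom, y, params)
        assert value == pytest.approx(oracle, rel=1e-10)


class TestWirtingerGradient:
    def test_zero_at_global_minimum(self, geometry32, rng):
        model = CoherenceModel(2e-6, 2.6e-6)
        t, psi_values, _ = _random_instance(geometry32, rng)
        psi = ComplexPhaseMap(psi_values, geometry32)
        y = forward(psi, t, model, geometry32)
        grad = wirtinger_gradient(psi, t, model, geometry32, y)
        assert np.abs(grad).max() < 1e-12

    def test_finite_difference_agreement_50_instances(self, geometry32):
        # the build's gating check: directional derivatives match
        # 2 Re<G, dpsi> to < 1e-5 relative on random 32x32 instances
        model = CoherenceModel(2e-6, 2.6e-6)
        worst = 0.0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            t, psi_values, y = _random_instance(geometry32, rng)
            psi = ComplexPhaseMap(psi_values, geometry32)
            grad = wirtinger_gradient(psi, t, model, geometry32, y)
            direction = rng.standard_normal(geometry32.shape) + (
                1j * rng.standard_normal(geometry32.shape)
            )
            eps = 1e-6

            def data_loss(values):
                f = forward(
                    ComplexPhaseMap(values, geometry32), t, model, geometry32
                ).values
                return np.sum((y.values - f) ** 2)

            fd = (
                data_loss(psi_values + eps * direction)
                - data_loss(psi_values - eps * direction)
            ) / (2 * eps)
            analytic = 2 * np.real(np.vdot(grad, direction))
            worst = max(worst, abs(fd - analytic) / abs(fd))
        assert worst < 1e-5

    def test_degenerate_case_reduces_to_real_channel(self, rng):
        # t = 1, L1 = L2 = 0, delta-like IPSF: f = exp(2 Re psi) and the
        # gradient must be purely real with the closed form -2 e exp(2 Re psi)
        geom = ImagingGeometry(nx=16, ny=16, pitch=650e-9,
                               wavelength=0.124e-9, L1=0.0, L2=0.0)
        model = CoherenceModel(1e-12, 1e-12)  # IOTF = 1 to float precision
        t = DiffuserTransmission(np.ones(geom.shape, complex), geom)
        psi_values = 0.2 * (
            rng.standard_normal(geom.shape) + 1j * rng.standard_normal(geom.shape)
        )
        psi = ComplexPhaseMap(psi_values, geom)
        y = IntensityImage2D(rng.random(geom.shape) + 0.5, geom)
        grad = wirtinger_gradient(psi, t, model, geom, y)
        f = np.exp(2 * psi_values.real)
        expected = -2 * (y.values - f) * f
        assert np.abs(grad.imag).max() < 1e-10
        assert np.allclose(grad.real, expected, rtol=1e-8, atol=1e-10)


class TestPreconditionedUpdate:
    def test_zero_gradient_only_anchors_background(self, geometry32, rng):
        params = SolverParams(alpha=0j, nonnegative_attenuation=False)
        psi_values = -0.1 * rng.random(geometry32.shape) + (
            1j * rng.standard_normal(geometry32.shape)
        )
        psi = ComplexPhaseMap(psi_values, geometry32)
        out = preconditioned_update(
            psi, np.zeros(geometry32.shape, complex), params, geometry32
        )
        mask = background_border_mask(geometry32, params.background_fraction)
        shift = psi_values.imag[mask].mean()
        assert np.allclose(out.values.real, psi_values.real, atol=1e-15)
        assert np.allclose(out.values.imag, psi_values.imag - shift, atol=1e-12)

    def test_inverse_laplacian_equivalence(self, geometry32, rng):
        # applying the spectral quadratic (u^2 + v^2) to the filtered
        # phase-channel step recovers the raw gradient minus its DC part
        params = SolverParams(alpha=0j, nonnegative_attenuation=False,
                              background_mask=np.ones(geometry32.shape, bool))
        grad_im = rng.standard_normal(geometry32.shape)
        psi = ComplexPhaseMap(np.zeros(geometry32.shape, complex), geometry32)
        out = preconditioned_update(psi, 1j * grad_im, params, geometry32)
        step = -(out.values.imag - psi.values.imag)
        step = step - step.mean()  # remove the anchoring offset
        u, v = np.meshgrid(
            np.fft.fftfreq(geometry32.nx), np.fft.fftfreq(geometry32.ny)
        )
        recovered = np.fft.ifft2((u**2 + v**2) * np.fft.fft2(step)).real
        target = grad_im - grad_im.mean()
        rel = np.abs(recovered - target).max() / np.abs(target).max()
        assert rel < 1e-8

    def test_dc_gradient_produces_no_update(self, geometry32):
        params = SolverParams(alpha=0j, nonnegative_attenuation=False,
                              background_mask=np.ones(geometry32.shape, bool))
        psi = ComplexPhaseMap(np.zeros(geometry32.shape, complex), geometry32)
        out = preconditioned_update(
            psi, 1j * np.full(geometry32.shape, 5.0), params, geometry32
        )
        assert np.abs(out.values.imag).max() < 1e-12


class TestSolve:
    def test_exact_reference_converges_immediately(self, phantom64):
        cfg = default_config(seed=5, n=64, n_angles=1)
        ds = simulate_dataset(phantom64, cfg)
        geom = cfg.geometry
        screen = make_diffuser_screen(cfg)
        measured = IntensityImage2D(ds.reference, geom)
        params = SolverParams(alpha=0j, max_iter=10, min_iter=1)
        result = solve(measured, screen, cfg.coherence, geom, params)
        assert result.converged and result.iterations == 1
        assert np.abs(result.psi.values).max() < 1e-6

    def test_monotone_loss_without_momentum(self, phantom64):
        cfg = default_config(seed=5, n=64, n_angles=1)
        ds = simulate_dataset(phantom64, cfg)
        geom = cfg.geometry
        screen = make_diffuser_screen(cfg)
        measured = IntensityImage2D(ds.projections[0], geom)
        params = SolverParams(alpha=0.1 + 0.01j, eta=0.3, nesterov=False,
                              max_iter=60, min_iter=60)
        result = solve(measured, screen, cfg.coherence, geom, params)
        assert np.all(np.diff(result.loss_history) <= 1e-12)

    def test_phase_recovery_within_5_percent_in_transfer_band(self):
        # parameter-recovery oracle on a 128^2 noiseless instance: the
        # retrieved phase matches the ground truth after band-limiting both
        # to the sample-transfer-function support
        cfg = default_config(seed=1, n=128, n_angles=1)
        ds = simulate_dataset(default_phantom(), cfg)
        geom = cfg.geometry
        screen = make_diffuser_screen(cfg)
        measured = IntensityImage2D(ds.projections[0], geom)
        params = SolverParams(alpha=0.1 + 0j, max_iter=600, min_iter=600)
        result = solve(measured, screen, cfg.coherence, geom, params,
                       reference_mean=float(ds.reference.mean()))
        mask = background_border_mask(geom, params.background_fraction)
        truth = ds.truth_psi[0].imag
        truth = truth - truth[mask].mean()
        stf = stf_window(cfg.coherence, geom, params.gamma)
        band = lambda a: np.fft.ifft2(stf * np.fft.fft2(a)).real
        recovered = band(result.psi.values.imag)
        target = band(truth)
        rel = np.sqrt(np.mean((recovered - target) ** 2)) / np.ptp(target)
        assert rel < 0.05

    def test_divergence_raises_with_iteration_number(self, phantom64):
        cfg = default_config(seed=5, n=64, n_angles=1)
        ds = simulate_dataset(phantom64, cfg)
        geom = cfg.geometry
        screen = make_diffuser_screen(cfg)
        measured = IntensityImage2D(ds.projections[0], geom)
        # deliberately unstable: enormous step size
        params = SolverParams(alpha=0j, eta=1e6, max_iter=50, min_iter=50,
                              nonnegative_attenuation=False)
        with pytest.raises((FloatingPointError, ValueError)):
            with np.errstate(over="ignore", invalid="ignore"):
                solve(measured, screen, cfg.coherence, geom, params)


class TestRmseImage:
    def test_exact_fit_gives_zero(self, geometry32, rng):
        model = CoherenceModel(2e-6, 2.6e-6)
        t = DiffuserTransmission(
            np.exp(1j * rng.standard_normal(geometry32.shape)), geometry32
        )
        psi = ComplexPhaseMap(
            -0.1 * rng.random(geometry32.shape) + 0j, geometry32
        )
        y = forward(psi, t, model, geometry32)
        image = rmse_image(y, psi, t, model, geometry32, reference_mean=1.0)
        assert np.abs(image).max() < 1e-8

    def test_single_pixel_residual_in_percent(self, geometry32, rng):
        model = CoherenceModel(2e-6, 2.6e-6)
        t = DiffuserTransmission(
            np.exp(1j * rng.standard_normal(geometry32.shape)), geometry32
        )
        psi = ComplexPhaseMap(np.zeros(geometry32.shape, complex), geometry32)
        f = forward(psi, t, model, geometry32)
        perturbed = f.values.copy()
        perturbed[5, 7] += 0.05 * 2.0  # reference mean will be 2.0
        image = rmse_image(
            IntensityImage2D(perturbed, geometry32), psi, t, model,
            geometry32, reference_mean=2.0,
        )
        assert image[5, 7] == pytest.approx(5.0, rel=1e-9)
        image[5, 7] = 0.0
        assert np.abs(image).max() < 1e-9

    def test_normalization_scale(self, geometry32, rng):
        c = gradient_normalization(np.array([[2.0]]))
        assert c == pytest.approx(32.0)
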