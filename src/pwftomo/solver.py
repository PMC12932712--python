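"""Preconditioned Wirtinger flow (PWF) phase retrieval.

The unknown is the complex phase ``psi = log x`` of the sample's exit
field ``x``: its real part is (minus) the attenuation and its imaginary
part the unwrapped phase, so phase wrapping never enters.  A single
measured speckle intensity ``y`` is explained by the physics-based forward
model

    f(psi) = |P2{ t * P1{ e^psi } }|^2  (*)  IPSF

where ``P1, P2`` are angular-spectrum propagators over the sample-diffuser
and diffuser-detector distances, ``t`` is the diffuser transmission, and
the IPSF convolution (applied as an IOTF window in the Fourier domain)
models the partial coherence of the source.

The solver minimizes ``sum_r (y - f(psi))^2`` plus a Tikhonov penalty
weighted by the regularization window ``Gamma^2 = 1 - STF`` (the
oversampling-ratio constraint), using the Wirtinger gradient of the
non-holomorphic data term.  A speckle system senses the phase *gradient*
rather than the phase, so the plain gradient is badly conditioned across
spatial frequencies; the inverse-quadratic (inverse Laplacian) filter
``1/(u^2 + v^2)`` applied to the phase-channel update equalizes the
convergence rates and, as the cheapest direction in the induced metric,
steers the explanation of the data into the smooth phase rather than into
spurious attenuation structure.  Nesterov momentum accelerates the
iteration; it stops once successive retrieved fields are essentially
perfectly correlated.

Two numerical conventions make the fixed step size ``eta = 1`` meaningful
on any dataset:

* the data gradient is normalized by the curvature estimate
  ``8 max(y)^2`` (the largest eigenvalue scale of the Gauss-Newton
  Hessian of an intensity least-squares fit), so ``eta = 1`` sits safely
  inside the stable-step region;
* the preconditioner frequencies are in cycles per pixel, with the DC
  component re-anchored each iteration by zeroing the mean background
  phase.

An optional (default-on) non-positivity projection of ``Re(psi)`` encodes
that a passive sample cannot amplify the beam; it suppresses spurious
sign-alternating attenuation structure that could otherwise mimic
phase-displacement signatures in the intensity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .coherence import CoherenceModel, iotf, regularization_window
from .diffuser import DiffuserTransmission
from .optics import (
    ComplexField2D,
    ImagingGeometry,
    IntensityImage2D,
    _angular_spectrum_kernel,
    propagate,
    propagate_adjoint,
)

logger = logging.getLogger(__name__)


@dataclass
class ComplexPhaseMap:
    """The solver state ``psi``: Re = -attenuation, Im = unwrapped phase."""

    values: np.ndarray
    geometry: ImagingGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.shape != self.geometry.shape:
            raise ValueError("phase map shape does not match geometry")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phase map contains non-finite values")

    def check_physical(self, atol: float = 1e-6) -> None:
        """Warn if the attenuation channel implies gain (Re(psi) > 0)."""
        if np.max(self.values.real) > atol:
            warnings.warn(
                "phase map has Re(psi) > 0 (negative attenuation) in "
                f"{int(np.count_nonzero(self.values.real > atol))} pixels",
                RuntimeWarning,
                stacklevel=2,
            )


@dataclass
class SolverParams:
    """Tunable parameters of the PWF iteration.

    ``alpha`` is complex: its real part weights the Tikhonov penalty on
    the attenuation channel and its imaginary part the penalty on the
    phase channel.  Both are signal-to-noise dependent choices; the
    defaults are tuned for noisy full-frame beamline data.  ``tol`` is the
    stopping threshold on the normalized correlation between successive
    retrieved fields, evaluated only after ``min_iter`` iterations so a
    cold start cannot trigger it spuriously.
    """

    gamma: float = 1.0
    alpha: complex = 0.1 + 0.01j
    eta: float = 1.0
    tol: float = 10.0 ** (-0.00001)
    max_iter: int = 2000
    min_iter: int = 50
    nesterov: bool = True
    nonnegative_attenuation: bool = True
    background_fraction: float = 0.05
    background_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if not (0.0 < self.tol < 1.0):
            raise ValueError("tol must lie in (0, 1)")
        if self.alpha.real < 0 or self.alpha.imag < 0:
            raise ValueError("alpha components must be non-negative")


@dataclass
class PWFResult:
    """Outcome of a PWF run."""

    psi: ComplexPhaseMap
    iterations: int
    loss_history: np.ndarray
    rmse_image: np.ndarray
    converged: bool
    extras: dict = field(default_factory=dict)


def background_border_mask(
    geometry: ImagingGeometry, fraction: float = 0.05
) -> np.ndarray:
    """Boolean mask selecting a border of the given fractional width."""
    wy = max(1, int(round(fraction * geometry.ny)))
    wx = max(1, int(round(fraction * geometry.nx)))
    mask = np.zeros(geometry.shape, dtype=bool)
    mask[:wy, :] = mask[-wy:, :] = True
    mask[:, :wx] = mask[:, -wx:] = True
    return mask


def _resolve_background_mask(
    params: SolverParams, geometry: ImagingGeometry
) -> np.ndarray:
    if params.background_mask is not None:
        mask = np.asarray(params.background_mask, dtype=bool)
        if mask.shape != geometry.shape:
            raise ValueError("background mask shape does not match geometry")
        return mask
    return background_border_mask(geometry, params.background_fraction)


def preconditioner_filter(geometry: ImagingGeometry) -> np.ndarray:
    """Inverse-quadratic filter ``1/(u^2 + v^2)``, zero at DC.

    Frequencies are in cycles per pixel (dimensionless), so the filter is
    independent of the physical pitch; the DC component it cannot supply is
    anchored separately by zeroing the mean background phase.
    """
    u, v = np.meshgrid(np.fft.fftfreq(geometry.nx), np.fft.fftfreq(geometry.ny))
    q2 = u**2 + v**2
    pinv = np.zeros(geometry.shape)
    np.divide(1.0, q2, out=pinv, where=q2 > 0)
    return pinv


def gradient_normalization(measured: np.ndarray) -> float:
    """Curvature estimate ``8 max(y)^2`` normalizing the data gradient.

    The Gauss-Newton Hessian of ``sum (y - |w|^2)^2`` has per-pixel scale
    ``8 I^2``; dividing the gradient by its maximum makes the fixed step
    ``eta = 1`` stable for any intensity normalization.
    """
    return 8.0 * float(np.max(measured)) ** 2


def _forward_parts(
    psi_values: np.ndarray,
    t: DiffuserTransmission,
    iotf_window: np.ndarray,
    geometry: ImagingGeometry,
    kernels: tuple[np.ndarray, np.ndarray] | None = None,
):
    """Forward model with intermediates needed by the gradient."""
    x = np.exp(psi_values)
    if kernels is None:
        h1 = _angular_spectrum_kernel(geometry, geometry.L1)
        h2 = _angular_spectrum_kernel(geometry, geometry.L2)
    else:
        h1, h2 = kernels
    after_l1 = np.fft.ifft2(h1 * np.fft.fft2(x))
    w = np.fft.ifft2(h2 * np.fft.fft2(t.values * after_l1))
    intensity = np.abs(w) ** 2
    f = np.fft.ifft2(iotf_window * np.fft.fft2(intensity)).real
    return f, w, x


def forward(
    psi: ComplexPhaseMap,
    t: DiffuserTransmission,
    model: CoherenceModel,
    geometry: ImagingGeometry,
) -> IntensityImage2D:
    """Predicted speckle intensity for a sample phase map.

    ``|P2{t P1{e^psi}}|^2`` blurred by the coherence IPSF; the blur is
    applied as the IOTF window in the Fourier domain, which is exactly
    equivalent on the periodic grid.
    """
    if psi.geometry.shape != t.geometry.shape:
        raise ValueError("phase map and diffuser shapes do not match")
    f, _, _ = _forward_parts(psi.values, t, iotf(model, geometry), geometry)
    return IntensityImage2D(f, geometry)


def _filtered(values: np.ndarray, window: np.ndarray) -> np.ndarray:
    return np.fft.ifft2(window * np.fft.fft2(values)).real


def loss(
    psi: ComplexPhaseMap,
    t: DiffuserTransmission,
    model: CoherenceModel,
    geometry: ImagingGeometry,
    measured: IntensityImage2D,
    params: SolverParams,
) -> float:
    """Data misfit plus Tikhonov penalty.

    ``sum_r (y - f(psi))^2 + sum_k Gamma^2 (Re(alpha) |F{Re psi}|^2 +
    Im(alpha) |F{Im psi}|^2)`` with a Parseval-normalized Fourier
    transform.
    """
    f, _, _ = _forward_parts(psi.values, t, iotf(model, geometry), geometry)
    data = float(np.sum((measured.values - f) ** 2))
    reg_window = regularization_window(model, geometry, params.gamma)
    spec_re = np.fft.fft2(psi.values.real, norm="ortho")
    spec_im = np.fft.fft2(psi.values.imag, norm="ortho")
    reg = float(
        params.alpha.real * np.sum(reg_window * np.abs(spec_re) ** 2)
        + params.alpha.imag * np.sum(reg_window * np.abs(spec_im) ** 2)
    )
    return data + reg


def wirtinger_gradient(
    psi: ComplexPhaseMap,
    t: DiffuserTransmission,
    model: CoherenceModel,
    geometry: ImagingGeometry,
    measured: IntensityImage2D,
) -> np.ndarray:
    """Wirtinger gradient ``G = dL_data/dpsi*`` of the data term.

    Exact adjoint chain through the forward model: the directional
    derivative of the data term satisfies
    ``L(psi + eps dpsi) - L(psi) = 2 eps Re<G, dpsi> + O(eps^2)``.
    """
    iotf_window = iotf(model, geometry)
    f, w, x = _forward_parts(psi.values, t, iotf_window, geometry)
    e = measured.values - f
    # IOTF is a real diagonal Fourier filter -> self-adjoint
    b = _filtered(-2.0 * e, iotf_window)
    back_l2 = propagate_adjoint(ComplexField2D(b * w, geometry), geometry.L2).values
    back_l1 = propagate_adjoint(
        ComplexField2D(np.conj(t.values) * back_l2, geometry), geometry.L1
    ).values
    return np.conj(x) * back_l1


def preconditioned_update(
    psi: ComplexPhaseMap,
    gradient: np.ndarray,
    params: SolverParams,
    geometry: ImagingGeometry,
    reg_window: np.ndarray | None = None,
    background_mask: np.ndarray | None = None,
) -> ComplexPhaseMap:
    """One preconditioned, regularized descent step.

    The attenuation (real) channel takes a plain gradient step, optionally
    projected onto ``Re(psi) <= 0``; the phase (imaginary) channel's update
    — data gradient plus its Tikhonov term — is filtered by the
    inverse-quadratic preconditioner before being applied.  The background
    phase is re-anchored to zero mean afterwards, supplying the DC
    component the preconditioner leaves undetermined.
    """
    if gradient.shape != psi.geometry.shape:
        raise ValueError("gradient shape does not match geometry")
    grad_re = gradient.real
    grad_im = gradient.imag
    if reg_window is not None:
        grad_re = grad_re + params.alpha.real * _filtered(
            psi.values.real, reg_window
        )
        grad_im = grad_im + params.alpha.imag * _filtered(
            psi.values.imag, reg_window
        )
    pinv = preconditioner_filter(geometry)
    new_re = psi.values.real - params.eta * grad_re
    if params.nonnegative_attenuation:
        new_re = np.minimum(new_re, 0.0)
    step_im = np.fft.ifft2(pinv * np.fft.fft2(grad_im)).real
    new_im = psi.values.imag - params.eta * step_im
    if background_mask is None:
        background_mask = _resolve_background_mask(params, geometry)
    new_im = new_im - new_im[background_mask].mean()
    return ComplexPhaseMap(new_re + 1j * new_im, psi.geometry)


def rmse_image(
    measured: IntensityImage2D,
    psi: ComplexPhaseMap,
    t: DiffuserTransmission,
    model: CoherenceModel,
    geometry: ImagingGeometry,
    reference_mean: float,
) -> np.ndarray:
    """Per-pixel residual ``|y - f(psi)|`` in % of the reference mean."""
    if reference_mean <= 0:
        raise ValueError("reference mean must be positive")
    f, _, _ = _forward_parts(psi.values, t, iotf(model, geometry), geometry)
    return np.abs(measured.values - f) / reference_mean * 100.0


def solve(
    measured: IntensityImage2D,
    t: DiffuserTransmission,
    model: CoherenceModel,
    geometry: ImagingGeometry,
    params: SolverParams | None = None,
    reference_mean: float | None = None,
) -> PWFResult:
    """Run the PWF iteration from ``psi = 0``.

    Nesterov momentum (restarted whenever the loss jumps by more than an
    order of magnitude) accelerates the preconditioned updates; iteration
    stops when the normalized correlation between the current and previous
    retrieved fields ``e^psi`` exceeds ``params.tol`` (after ``min_iter``
    iterations), or at ``max_iter``.

    ``reference_mean`` normalizes the returned RMSE image (defaults to the
    mean of the measured speckle).
    """
    if params is None:
        params = SolverParams()
    if measured.geometry.shape != t.geometry.shape:
        raise ValueError("measured image and diffuser shapes do not match")
    iotf_window = iotf(model, geometry)
    reg_window = regularization_window(model, geometry, params.gamma)
    background_mask = _resolve_background_mask(params, geometry)
    pinv = preconditioner_filter(geometry)
    kernels = (
        _angular_spectrum_kernel(geometry, geometry.L1),
        _angular_spectrum_kernel(geometry, geometry.L2),
    )
    h1c, h2c = np.conj(kernels[0]), np.conj(kernels[1])
    t_conj = np.conj(t.values)
    y = measured.values
    scale = gradient_normalization(y) / params.eta

    psi = np.zeros(geometry.shape, dtype=complex)
    z = psi  # Nesterov look-ahead point
    t_momentum = 1.0
    loss_history: list[float] = []
    prev_field = np.exp(psi)
    prev_loss = np.inf
    converged = False
    iterations = 0

    for iteration in range(1, params.max_iter + 1):
        f, w, x = _forward_parts(z, t, iotf_window, geometry, kernels)
        e = y - f
        data_loss = float(np.sum(e**2))
        spec_re = np.fft.fft2(z.real, norm="ortho")
        spec_im = np.fft.fft2(z.imag, norm="ortho")
        reg_loss = float(
            params.alpha.real * np.sum(reg_window * np.abs(spec_re) ** 2)
            + params.alpha.imag * np.sum(reg_window * np.abs(spec_im) ** 2)
        )
        total_loss = data_loss + reg_loss
        if not np.isfinite(total_loss):
            raise FloatingPointError(
                "PWF diverged: loss became non-finite at iteration "
                f"{iteration}; last finite iteration was {iteration - 1}"
            )
        loss_history.append(total_loss)

        # Wirtinger gradient of the data term at the look-ahead point
        b = _filtered(-2.0 * e, iotf_window)
        back_l2 = np.fft.ifft2(h2c * np.fft.fft2(b * w))
        back_l1 = np.fft.ifft2(h1c * np.fft.fft2(t_conj * back_l2))
        grad = np.conj(x) * back_l1

        grad_re = (
            grad.real + params.alpha.real * _filtered(z.real, reg_window)
        ) / scale
        grad_im = (
            grad.imag + params.alpha.imag * _filtered(z.imag, reg_window)
        ) / scale
        new_re = z.real - grad_re
        if params.nonnegative_attenuation:
            new_re = np.minimum(new_re, 0.0)
        new_im = z.imag - np.fft.ifft2(pinv * np.fft.fft2(grad_im)).real
        new_im = new_im - new_im[background_mask].mean()
        psi_new = new_re + 1j * new_im

        field = np.exp(psi_new)
        norm_product = np.linalg.norm(field) * np.linalg.norm(prev_field)
        correlation = (
            np.abs(np.vdot(field, prev_field)) / norm_product
            if norm_product > 0
            else 0.0
        )

        if params.nesterov:
            if total_loss > 10.0 * prev_loss:
                # momentum overshot badly: restart from the new iterate
                logger.debug("momentum restart at iteration %d", iteration)
                t_momentum = 1.0
                z = psi_new
            else:
                t_next = (1.0 + np.sqrt(1.0 + 4.0 * t_momentum**2)) / 2.0
                z = psi_new + ((t_momentum - 1.0) / t_next) * (psi_new - psi)
                t_momentum = t_next
        else:
            z = psi_new

        psi = psi_new
        prev_field = field
        prev_loss = total_loss
        iterations = iteration
        if iteration >= params.min_iter and correlation > params.tol:
            converged = True
            break

    result_psi = ComplexPhaseMap(psi, geometry)
    result_psi.check_physical()
    ref_mean = reference_mean if reference_mean is not None else float(y.mean())
    residual = rmse_image(measured, result_psi, t, model, geometry, ref_mean)
    return PWFResult(
        psi=result_psi,
        iterations=iterations,
        loss_history=np.asarray(loss_history),
        rmse_image=residual,
        converged=converged,
    )
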