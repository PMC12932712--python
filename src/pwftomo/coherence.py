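"""Partial-coherence calibration and transfer-function generators.

A partially coherent source blurs the measured intensity with a Gaussian
intensity point spread function (IPSF) whose widths are the horizontal and
vertical spatial coherence lengths at the detector.  The coherence lengths
are calibrated from the reference speckle through the Siegert relation
``g2 = 1 + |g1|^2``: the intensity autocorrelation of fully developed
speckle carries the squared field coherence, so a Gaussian fit to
``g2(dx) = 1 + c exp(-pi dx^2 / x_coh^2)`` yields ``x_coh`` directly.

The same model generates, on a given sampling geometry:

* ``ipsf`` / ``iotf`` — the intensity blur kernel and its transfer function,
* ``stf_window`` — the Gaussian sample transfer function bounding the
  retrievable bandwidth for a chosen oversampling ratio ``gamma``,
* ``regularization_window`` — its complement, which weights the Tikhonov
  penalty of the phase-retrieval solver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .optics import ImagingGeometry, IntensityImage2D, make_frequency_grids

#: Dimensionless prefactor of the expected-resolution closed form: the
#: resolution at the STF = 0.1 bandwidth boundary is this multiple of the
#: coherence length (natural logarithm).
RESOLUTION_PREFACTOR = np.sqrt(np.pi) / (2.0 * np.log(10.0))


@dataclass(frozen=True)
class CoherenceModel:
    """Separable Gaussian spatial-coherence model at the detector plane."""

    x_coh: float  # horizontal coherence length, metres
    y_coh: float  # vertical coherence length, metres

    def __post_init__(self) -> None:
        if self.x_coh <= 0 or self.y_coh <= 0:
            raise ValueError("coherence lengths must be positive")


@dataclass(frozen=True)
class ModeCount:
    """Measured (M) and reconstructed (N) spatial-mode counts."""

    M: float
    N: float
    gamma: float

    def __post_init__(self) -> None:
        if self.M <= 0 or self.N <= 0:
            raise ValueError("mode counts must be positive")


def g2_autocorrelation(image: IntensityImage2D, axis: str) -> np.ndarray:
    """Second-order normalized autocorrelation ``g2`` along one axis.

    ``g2(lag) = <I(s) I(s+lag)> / <I>^2`` computed 1D along the chosen axis
    via FFT (circular) and averaged over the orthogonal axis.  Lags are
    restricted to a quarter of the axis length to keep the circular wrap
    bias negligible.

    Parameters
    ----------
    image : IntensityImage2D
        Flat-field-corrected speckle image.
    axis : {"horizontal", "vertical"}
        "horizontal" correlates along x (columns), "vertical" along y.
    """
    if axis not in ("horizontal", "vertical"):
        raise ValueError("axis must be 'horizontal' or 'vertical'")
    values = image.values if axis == "horizontal" else image.values.T
    n = values.shape[1]
    if n < 64:
        raise ValueError("need at least 64 pixels along the correlation axis")
    mean = values.mean()
    if mean <= 0:
        raise ValueError("image mean must be positive for g2 normalization")
    spectra = np.abs(np.fft.fft(values, axis=1)) ** 2
    corr = np.fft.ifft(spectra.mean(axis=0)).real / n
    g2 = corr / mean**2
    return g2[: n // 4]


def fit_coherence_length(g2_profile: np.ndarray, lag_pitch: float) -> float:
    """Coherence length from a Siegert ``g2`` lag profile.

    Least-squares fit of ``1 + c exp(-pi lag^2 / ell^2)`` with the contrast
    amplitude ``c`` free (detector binning and residual coherence push
    ``g2(0)`` below the ideal value of 2, so ``c`` must not be pinned to 1).

    Returns the fitted ``ell`` in the units of ``lag_pitch``.
    """
    g2_profile = np.asarray(g2_profile, dtype=float)
    lags = np.arange(g2_profile.size) * lag_pitch
    contrast = g2_profile[0] - 1.0
    if contrast <= 1e-12:
        raise ValueError(
            "g2 profile has no contrast at zero lag; cannot fit a coherence "
            f"length (g2(0) = {g2_profile[0]:.6g})"
        )
    # initial width: lag where the excess correlation drops to 1/e
    excess = g2_profile - 1.0
    below = np.nonzero(excess < contrast / np.e)[0]
    ell0 = np.sqrt(np.pi) * lags[below[0]] if below.size else lags[-1]
    ell0 = max(ell0, lag_pitch)

    def model(x, c, ell):
        return 1.0 + c * np.exp(-np.pi * x**2 / ell**2)

    try:
        popt, _ = curve_fit(
            model, lags, g2_profile, p0=[contrast, ell0],
            bounds=([0.0, lag_pitch * 1e-6], [np.inf, np.inf]), maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy diagnostics vary
        raise ValueError(f"coherence-length fit failed: {exc}") from exc
    return float(popt[1])


def calibrate_coherence(reference: IntensityImage2D) -> CoherenceModel:
    """Calibrate both coherence lengths from a reference speckle image."""
    x_coh = fit_coherence_length(
        g2_autocorrelation(reference, "horizontal"), reference.geometry.pitch
    )
    y_coh = fit_coherence_length(
        g2_autocorrelation(reference, "vertical"), reference.geometry.pitch
    )
    return CoherenceModel(x_coh=x_coh, y_coh=y_coh)


def ipsf(model: CoherenceModel, geometry: ImagingGeometry) -> np.ndarray:
    """Intensity point spread function sampled on the grid (origin centred).

    ``IPSF(x, y) = 2/(x_coh y_coh) exp(-2 pi (x^2/x_coh^2 + y^2/y_coh^2))``;
    the continuous integral is 1, so the discrete sum times ``pitch^2`` is
    approximately 1 for well-resolved kernels.  The origin sits at pixel
    ``(ny//2, nx//2)``; apply ``np.fft.ifftshift`` before an FFT.
    """
    if model.x_coh < 2 * geometry.pitch or model.y_coh < 2 * geometry.pitch:
        warnings.warn(
            "coherence length below 2 pixels: IPSF is under-resolved on "
            "this grid", RuntimeWarning, stacklevel=2,
        )
    x = (np.arange(geometry.nx) - geometry.nx // 2) * geometry.pitch
    y = (np.arange(geometry.ny) - geometry.ny // 2) * geometry.pitch
    xx, yy = np.meshgrid(x, y)
    return (2.0 / (model.x_coh * model.y_coh)) * np.exp(
        -2.0 * np.pi * (xx**2 / model.x_coh**2 + yy**2 / model.y_coh**2)
    )


def iotf(model: CoherenceModel, geometry: ImagingGeometry) -> np.ndarray:
    """Intensity optical transfer function on the unshifted DFT grid.

    ``IOTF(u, v) = exp(-(pi/2)(u^2 x_coh^2 + v^2 y_coh^2))`` — the
    continuous Fourier transform of :func:`ipsf`; ``IOTF(0, 0) = 1``.
    """
    u, v = make_frequency_grids(geometry)
    return np.exp(
        -(np.pi / 2.0) * (u**2 * model.x_coh**2 + v**2 * model.y_coh**2)
    )


def count_modes(
    model: CoherenceModel, geometry: ImagingGeometry, gamma: float
) -> ModeCount:
    """Space-bandwidth-product mode counts for an oversampling ratio.

    The measured mode count is ``M = (FOV_x/x_coh) (FOV_y/y_coh)`` and the
    reconstructed count ``N = M / gamma``.  Both are reported unrounded.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    M = (geometry.fov_x / model.x_coh) * (geometry.fov_y / model.y_coh)
    return ModeCount(M=M, N=M / gamma, gamma=gamma)


def stf_window(
    model: CoherenceModel, geometry: ImagingGeometry, gamma: float
) -> np.ndarray:
    """Sample transfer function ``exp(-pi gamma (u^2 x_coh^2 + v^2 y_coh^2))``.

    A soft Gaussian bound on the retrievable sample bandwidth; equals 1 at
    DC and decays monotonically with frequency.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    u, v = make_frequency_grids(geometry)
    return np.exp(
        -np.pi * gamma * (u**2 * model.x_coh**2 + v**2 * model.y_coh**2)
    )


def regularization_window(
    model: CoherenceModel, geometry: ImagingGeometry, gamma: float
) -> np.ndarray:
    """Tikhonov weight ``Gamma^2 = 1 - STF``: zero at DC, -> 1 at high k."""
    return 1.0 - stf_window(model, geometry, gamma)


def expected_resolution(model: CoherenceModel) -> tuple[float, float, float]:
    """Expected (horizontal, vertical, rms) resolutions in metres.

    Assuming the sample spectrum is retrievable out to the STF = 0.1
    boundary, the resolution is ``sqrt(pi) x_coh / (2 ln 10) ~ 0.385 x_coh``
    (and likewise vertically); the third value is the root mean square of
    the two.
    """
    rx = RESOLUTION_PREFACTOR * model.x_coh
    ry = RESOLUTION_PREFACTOR * model.y_coh
    rms = float(np.sqrt((rx**2 + ry**2) / 2.0))
    return float(rx), float(ry), rms


def write_calibration_report(
    path, model: CoherenceModel, contrast: float | None = None
) -> None:
    """Write a small key-value text report of a coherence calibration."""
    rx, ry, rms = expected_resolution(model)
    lines = [
        f"x_coh_m: {model.x_coh:.6e}",
        f"y_coh_m: {model.y_coh:.6e}",
        f"expected_resolution_x_m: {rx:.6e}",
        f"expected_resolution_y_m: {ry:.6e}",
        f"expected_resolution_rms_m: {rms:.6e}",
    ]
    if contrast is not None:
        lines.insert(2, f"fit_contrast: {contrast:.6f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
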