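"""Grids, frequency conventions and angular-spectrum free-space propagation.

All quantities carry SI units: lengths in metres, spatial frequencies in
cycles per metre.  The row index of every 2D array corresponds to the
vertical coordinate *y* and the column index to the horizontal coordinate
*x*.  Fourier-domain arrays follow the unshifted DFT ordering, i.e. element
``[0, 0]`` is the zero-frequency (DC) component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ImagingGeometry:
    """Sampling geometry shared by propagation, forward model and tomography.

    Parameters
    ----------
    nx, ny : int
        Pixel counts along x (columns) and y (rows).
    pitch : float
        Sampling period of the detector grid in metres.
    wavelength : float
        X-ray wavelength in metres.
    L1, L2 : float
        Free-space propagation distances in metres: sample -> diffuser
        (``L1``) and diffuser -> detector (``L2``).
    """

    nx: int
    ny: int
    pitch: float
    wavelength: float
    L1: float = 0.0
    L2: float = 0.0

    def __post_init__(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise ValueError("nx and ny must be >= 2")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.L1 < 0 or self.L2 < 0:
            raise ValueError("propagation distances must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def fov_x(self) -> float:
        return self.nx * self.pitch

    @property
    def fov_y(self) -> float:
        return self.ny * self.pitch


@dataclass
class ComplexField2D:
    """A sampled complex scalar field (dimensionless amplitude)."""

    values: np.ndarray
    geometry: ImagingGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"field shape {self.values.shape} does not match geometry "
                f"shape {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains non-finite values")


@dataclass
class IntensityImage2D:
    """A sampled real intensity image (detector counts or normalized)."""

    values: np.ndarray
    geometry: ImagingGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"image shape {self.values.shape} does not match geometry "
                f"shape {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")


def make_frequency_grids(geometry: ImagingGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Discrete Fourier frequency grids ``(u, v)`` in cycles per metre.

    Both arrays have shape ``(ny, nx)`` in unshifted DFT ordering: the
    element ``[0, 0]`` is (0, 0), and the spacing along x is
    ``1/(nx*pitch)``.
    """
    u1 = np.fft.fftfreq(geometry.nx, d=geometry.pitch)
    v1 = np.fft.fftfreq(geometry.ny, d=geometry.pitch)
    u, v = np.meshgrid(u1, v1)
    return u, v


def _angular_spectrum_kernel(geometry: ImagingGeometry, distance: float) -> np.ndarray:
    """Angular-spectrum transfer function H(u, v) for the given distance.

    ``H = exp(i 2*pi (d/lambda) sqrt(1 - (lambda u)^2 - (lambda v)^2))``;
    evanescent components are zeroed.
    """
    lam = geometry.wavelength
    u, v = make_frequency_grids(geometry)
    s2 = 1.0 - (lam * u) ** 2 - (lam * v) ** 2
    propagating = s2 > 0.0
    kernel = np.zeros(geometry.shape, dtype=complex)
    kernel[propagating] = np.exp(
        1j * 2.0 * np.pi * (distance / lam) * np.sqrt(s2[propagating])
    )
    return kernel


def _check_kernel_sampling(geometry: ImagingGeometry, distance: float) -> None:
    # Largest phase increment of H between adjacent frequency samples occurs
    # at the band edge; if it exceeds pi the kernel is aliased.
    lam = geometry.wavelength
    for n in (geometry.nx, geometry.ny):
        umax = 1.0 / (2.0 * geometry.pitch)
        s2 = 1.0 - (lam * umax) ** 2
        if s2 <= 0:
            continue
        dphi = (
            2.0 * np.pi * abs(distance) * lam * umax / np.sqrt(s2)
        ) / (n * geometry.pitch)
        if dphi > np.pi:
            safe = abs(distance) * dphi / np.pi
            warnings.warn(
                "angular-spectrum kernel is aliased at the band edge; "
                f"pad the grid by a factor >= {safe / abs(distance):.1f} or "
                "reduce the propagation distance",
                RuntimeWarning,
                stacklevel=3,
            )
            return


def propagate(field: ComplexField2D, distance: float) -> ComplexField2D:
    """Free-space propagation over ``distance`` metres (angular spectrum).

    Negative distances back-propagate.  Evanescent spatial frequencies are
    clipped to zero so that the adjoint stays exact.
    """
    if not np.all(np.isfinite(field.values)):
        raise ValueError("cannot propagate a non-finite field")
    if distance == 0.0:
        return ComplexField2D(field.values.copy(), field.geometry)
    _check_kernel_sampling(field.geometry, distance)
    kernel = _angular_spectrum_kernel(field.geometry, distance)
    out = np.fft.ifft2(kernel * np.fft.fft2(field.values))
    return ComplexField2D(out, field.geometry)


def propagate_adjoint(field: ComplexField2D, distance: float) -> ComplexField2D:
    """Exact adjoint of :func:`propagate` for the same distance.

    Diagonal in the Fourier basis, so the adjoint is the conjugated kernel:
    ``<propagate(x, d), y> == <x, propagate_adjoint(y, d)>`` holds to
    floating-point precision (evanescent clipping included).
    """
    if not np.all(np.isfinite(field.values)):
        raise ValueError("cannot propagate a non-finite field")
    if distance == 0.0:
        return ComplexField2D(field.values.copy(), field.geometry)
    kernel = np.conj(_angular_spectrum_kernel(field.geometry, distance))
    out = np.fft.ifft2(kernel * np.fft.fft2(field.values))
    return ComplexField2D(out, field.geometry)
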