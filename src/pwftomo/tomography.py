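"""Frame preprocessing, filtered back projection and background flattening.

Per-angle retrieved phase maps are assembled into sinograms and inverted
slice by slice (one slice per vertical detector row) with the standard
parallel-beam filtered back projection (Ram-Lak filter, linear
interpolation).  The raw FBP output is in radians per pixel of path; a
single constant ``lambda / p / (2 pi)`` converts it to the refractive-index
decrement ``delta`` (phase channel) or absorption index ``beta``
(attenuation channel), with ``n = 1 - delta + i beta``.

Sign conventions: a sample with ``delta > 0`` advances the phase so the
retrieved ``Im(psi) = -k delta T`` is negative; the phase sinogram is
therefore ``-Im(psi)`` and the attenuation sinogram ``-Re(psi)``, making
both reconstructed volumes non-negative for physical samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import iradon

from .optics import ImagingGeometry, IntensityImage2D
from .solver import ComplexPhaseMap

logger = logging.getLogger(__name__)


@dataclass
class ProjectionSeries:
    """Per-angle retrieved phase maps sharing one geometry."""

    angles: np.ndarray  # degrees, strictly increasing
    phase_maps: list[ComplexPhaseMap]
    geometry: ImagingGeometry

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if len(self.phase_maps) < 2:
            raise ValueError("need at least two projections")
        if self.angles.size != len(self.phase_maps):
            raise ValueError("angle count does not match projection count")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        for pm in self.phase_maps:
            if pm.geometry.shape != self.geometry.shape:
                raise ValueError("projection geometry mismatch")


@dataclass
class Tomogram:
    """Paired refractive-index volumes with their voxel pitch (metres)."""

    delta: np.ndarray
    beta: np.ndarray
    voxel_pitch: float

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.delta.shape != self.beta.shape:
            raise ValueError("delta and beta shapes differ")
        if not (np.all(np.isfinite(self.delta)) and np.all(np.isfinite(self.beta))):
            raise ValueError("tomogram contains non-finite values")


def preprocess(
    raw: IntensityImage2D, dark: IntensityImage2D, flat: IntensityImage2D
) -> IntensityImage2D:
    """Dark-frame subtraction and flat-field correction.

    ``(raw - dark) / (flat - dark)``; non-positive denominators (dead or
    unilluminated pixels) are replaced by the median positive denominator
    and counted in the log.
    """
    denominator = flat.values - dark.values
    if not np.any(denominator > 0):
        raise ValueError("flat field carries no signal above the dark frame")
    bad = denominator <= 0
    n_bad = int(np.count_nonzero(bad))
    if n_bad > 0.01 * denominator.size:
        raise ValueError(
            f"flat-dark is non-positive on {n_bad} pixels (> 1% of frame)"
        )
    if n_bad:
        logger.info("replacing %d non-positive flat-field pixels", n_bad)
        denominator = denominator.copy()
        denominator[bad] = np.median(denominator[~bad])
    return IntensityImage2D((raw.values - dark.values) / denominator, raw.geometry)


def reconstruct_fbp(
    series: ProjectionSeries, channel: str, axis_offset: float = 0.0
) -> np.ndarray:
    """Slice-by-slice Ram-Lak FBP of one retrieved channel.

    ``channel`` is ``"phase"`` (sinograms ``-Im(psi)``) or ``"attenuation"``
    (sinograms ``-Re(psi)``).  ``axis_offset`` is the measured
    rotation-axis displacement in pixels; every projection is shifted back
    by that amount (subpixel via Fourier shift) before back projection.  Returns a volume of shape ``(ny, nx, nx)``
    indexed ``[vertical, z, x]`` in the unit-spacing FBP convention; apply
    :func:`to_refractive_index` to obtain delta or beta.
    """
    if channel not in ("phase", "attenuation"):
        raise ValueError("channel must be 'phase' or 'attenuation'")
    if series.angles[-1] - series.angles[0] < 90.0:
        warnings.warn(
            "angular range below 90 degrees: expect severe limited-angle "
            "artifacts", RuntimeWarning, stacklevel=2,
        )
    ny, nx = series.geometry.shape
    stack = np.empty((len(series.phase_maps), ny, nx))
    for i, pm in enumerate(series.phase_maps):
        stack[i] = -pm.values.imag if channel == "phase" else -pm.values.real
    if axis_offset != 0.0:
        shift_kernel = np.exp(
            2j * np.pi * np.fft.fftfreq(nx) * axis_offset
        )
        stack = np.fft.ifft(
            shift_kernel * np.fft.fft(stack, axis=2), axis=2
        ).real
    volume = np.empty((ny, nx, nx))
    for row in range(ny):
        sinogram = stack[:, row, :].T  # (detector, angle)
        volume[row] = iradon(
            sinogram, theta=series.angles, filter_name="ramp",
            interpolation="linear", circle=True, output_size=nx,
        )
    return volume


def to_refractive_index(volume: np.ndarray, geometry: ImagingGeometry) -> np.ndarray:
    """Convert a unit-spacing FBP volume to delta or beta.

    Multiplies by ``lambda / p / (2 pi)`` where ``p`` is the reconstruction
    pixel pitch, turning per-pixel phase (or attenuation) density into the
    dimensionless refractive-index component.
    """
    return volume * geometry.wavelength / (geometry.pitch * 2.0 * np.pi)


def reconstruct_tomogram(series: ProjectionSeries) -> Tomogram:
    """Convenience wrapper: FBP of both channels, converted to delta/beta."""
    delta = to_refractive_index(reconstruct_fbp(series, "phase"), series.geometry)
    beta = to_refractive_index(
        reconstruct_fbp(series, "attenuation"), series.geometry
    )
    return Tomogram(delta=delta, beta=beta, voxel_pitch=series.geometry.pitch)


def default_background_mask(shape: tuple[int, int, int],
                            support_fraction: float = 0.9) -> np.ndarray:
    """Voxels outside a centred cylinder of the given fractional width."""
    _, nz, nx = shape
    z = np.arange(nz) - nz // 2
    x = np.arange(nx) - nx // 2
    zz, xx = np.meshgrid(z, x, indexing="ij")
    outside = np.hypot(zz, xx) > support_fraction * nx / 2.0
    return np.broadcast_to(outside, shape)


def flatten_background(volume: np.ndarray, background_mask: np.ndarray) -> np.ndarray:
    """Remove per-slice 2D quadratic background fitted over masked voxels.

    Fits ``a + b x + c y + d x^2 + e x y + f y^2`` by least squares over the
    background voxels of each slice and subtracts the fit from the whole
    slice; the masked-region mean after flattening is zero to numerical
    precision (a least-squares property).
    """
    volume = np.asarray(volume, dtype=float)
    background_mask = np.asarray(background_mask, dtype=bool)
    if background_mask.shape != volume.shape:
        raise ValueError("mask shape does not match volume")
    out = np.empty_like(volume)
    nz, nx = volume.shape[1:]
    yy, xx = np.meshgrid(
        np.arange(nz, dtype=float), np.arange(nx, dtype=float), indexing="ij"
    )
    design_full = np.column_stack([
        np.ones(volume[0].size), xx.ravel(), yy.ravel(),
        xx.ravel() ** 2, (xx * yy).ravel(), yy.ravel() ** 2,
    ])
    for k in range(volume.shape[0]):
        mask = background_mask[k].ravel()
        if mask.sum() < 0.01 * mask.size:
            raise ValueError(f"background mask covers < 1% of slice {k}")
        design = design_full[mask]
        coeffs, _, rank, _ = np.linalg.lstsq(
            design, volume[k].ravel()[mask], rcond=None
        )
        if rank < 6:
            raise ValueError(
                f"degenerate background mask in slice {k}: quadratic fit is "
                "rank-deficient"
            )
        out[k] = volume[k] - (design_full @ coeffs).reshape(nz, nx)
    return out


def crowther_min_angles(diameter: float, resolution: float) -> int:
    """Minimum projection count over 0-180 degrees (Crowther criterion).

    ``round(pi * D / (2 d))`` for a sample of diameter ``D`` at target
    resolution ``d``.
    """
    if diameter <= 0 or resolution <= 0:
        raise ValueError("diameter and resolution must be positive")
    return int(round(np.pi * diameter / (2.0 * resolution)))
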