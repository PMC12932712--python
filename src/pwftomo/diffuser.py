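"""Diffuser transmission estimation from the reference speckle.

The forward model needs the complex transmission ``t`` of the diffuser, but
only the reference speckle *intensity* is measured.  The estimate proceeds
in three steps: (i) Wiener-deconvolve the partial-coherence blur using the
calibrated IOTF, recovering the coherent reference intensity at the
detector; (ii) take the square root and fix the unknown phase to zero (the
retrieved sample field is insensitive to this convention for weakly
scattering samples in a near-field setup); (iii) numerically back-propagate
the resulting field from the detector to the diffuser plane over ``-L2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .coherence import CoherenceModel, iotf
from .optics import ComplexField2D, ImagingGeometry, IntensityImage2D, propagate

logger = logging.getLogger(__name__)


@dataclass
class DiffuserTransmission:
    """Complex transmission of the diffuser at its own plane."""

    values: np.ndarray
    geometry: ImagingGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.shape != self.geometry.shape:
            raise ValueError("transmission shape does not match geometry")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("transmission contains non-finite values")


def wiener_deconvolve(
    image: IntensityImage2D, otf: np.ndarray, nsr: float
) -> IntensityImage2D:
    """Wiener deconvolution by a real transfer function.

    Applies ``otf / (otf^2 + nsr)`` in the Fourier domain.  With ``nsr = 0``
    this is plain inverse filtering wherever ``otf > 0`` (frequencies with
    ``otf == 0`` are left at zero).
    """
    if nsr < 0:
        raise ValueError("noise-to-signal ratio must be non-negative")
    otf = np.asarray(otf, dtype=float)
    if otf[0, 0] <= 0:
        raise ValueError("otf must be positive at DC")
    denom = otf**2 + nsr
    wiener = np.divide(otf, denom, out=np.zeros_like(otf), where=denom > 0)
    out = np.fft.ifft2(wiener * np.fft.fft2(image.values)).real
    return IntensityImage2D(out, image.geometry)


def estimate_transmission(
    reference: IntensityImage2D,
    model: CoherenceModel,
    geometry: ImagingGeometry,
    nsr: float = 1e-2,
) -> DiffuserTransmission:
    """Estimate the diffuser transmission from the reference speckle.

    The reference must be flat-field corrected (mean ~ 1).  Deconvolved
    intensities below zero are clipped before the square root; the clipped
    pixel count is logged.
    """
    deconvolved = wiener_deconvolve(reference, iotf(model, geometry), nsr)
    # count only meaningful negatives, not float round-off around zero
    floor = -1e-12 * np.abs(deconvolved.values).max()
    n_clipped = int(np.count_nonzero(deconvolved.values < floor))
    if n_clipped:
        logger.info(
            "clipped %d negative pixels after Wiener deconvolution", n_clipped
        )
    amplitude = np.sqrt(np.clip(deconvolved.values, 0.0, None))
    field = ComplexField2D(amplitude.astype(complex), geometry)
    back = propagate(field, -geometry.L2)
    t = DiffuserTransmission(back.values, geometry)
    t.n_clipped = n_clipped
    return t
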