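"""Fourier shell correlation (FSC) and resolution estimation.

FSC compares two independent reconstructions of the same object shell by
shell in 3D Fourier space: ``FSC(kappa) = Re<g1~* g2~> / sqrt(<|g1~|^2>
<|g2~|^2>)`` over ``||k|| = kappa``.  Writing each volume as shared signal
plus independent noise gives ``FSC = S/(S+N)`` per shell, so requiring the
signal correlation ``sqrt(S/(S+N))`` to exceed a floor ``c`` corresponds to
an FSC threshold of ``c^2`` — a floor of 1/2 yields the 1/4 criterion used
here (no half-set averaging is assumed, unlike the classic 1/7 rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class FSCCurve:
    """Shell-wise correlation with the criterion threshold attached."""

    shell_radii: np.ndarray  # cycles per metre (shell centres)
    correlation: np.ndarray
    voxels_per_shell: np.ndarray
    threshold: float = 0.25

    def __post_init__(self) -> None:
        self.shell_radii = np.asarray(self.shell_radii, dtype=float)
        self.correlation = np.asarray(self.correlation, dtype=float)
        if np.any(np.diff(self.shell_radii) <= 0):
            raise ValueError("shell radii must be increasing")


@dataclass(frozen=True)
class ResolutionEstimate:
    """Resolution in metres; ``crossed`` is False when the curve never
    drops below the threshold (the Nyquist bound is returned instead)."""

    resolution: float
    crossed: bool


def fsc_curve(
    vol1: np.ndarray,
    vol2: np.ndarray,
    voxel_pitch: float,
    shell_width: float = 1.0,
) -> FSCCurve:
    """Fourier shell correlation of two equally-shaped real volumes.

    Shells are ``shell_width`` Fourier voxels wide on the unshifted DFT
    radius; the real part of the cross term is used, making the curve scale
    invariant and exactly 1 for identical volumes.
    """
    vol1 = np.asarray(vol1, dtype=float)
    vol2 = np.asarray(vol2, dtype=float)
    if vol1.shape != vol2.shape:
        raise ValueError(f"volume shapes differ: {vol1.shape} vs {vol2.shape}")
    if shell_width < 1.0:
        raise ValueError("shell width must be at least one Fourier voxel")
    f1 = np.fft.fftn(vol1)
    f2 = np.fft.fftn(vol2)
    # radius measured in Fourier voxels of the largest axis so an isotropic
    # physical frequency maps to one shell index
    n_ref = max(vol1.shape)
    grids = np.meshgrid(
        *[np.fft.fftfreq(n) * n_ref for n in vol1.shape], indexing="ij"
    )
    radius = np.sqrt(sum(g**2 for g in grids))
    shell_index = np.floor(radius / shell_width).astype(int)
    n_shells = int(shell_index.max()) + 1
    flat = shell_index.ravel()
    cross = np.bincount(flat, (f1.conj() * f2).real.ravel(), minlength=n_shells)
    p1 = np.bincount(flat, np.abs(f1).ravel() ** 2, minlength=n_shells)
    p2 = np.bincount(flat, np.abs(f2).ravel() ** 2, minlength=n_shells)
    counts = np.bincount(flat, minlength=n_shells)
    # keep shells up to the Nyquist radius of the reference axis
    keep = np.arange(n_shells) <= n_ref // 2
    denom = np.sqrt(p1[keep] * p2[keep])
    correlation = np.divide(
        cross[keep], denom, out=np.zeros(int(keep.sum())), where=denom > 0
    )
    radii = (np.arange(int(keep.sum())) + 0.5) * shell_width / (n_ref * voxel_pitch)
    return FSCCurve(
        shell_radii=radii,
        correlation=correlation,
        voxels_per_shell=counts[keep],
    )


def resolution_at_threshold(
    curve: FSCCurve, threshold: float = 0.25, voxel_pitch: float | None = None
) -> ResolutionEstimate:
    """Resolution from the first threshold crossing (linear interpolation).

    The DC shell is excluded.  If the curve never drops below the
    threshold, the Nyquist resolution ``2 * voxel_pitch`` (derived from the
    outermost shell radius when ``voxel_pitch`` is not given) is returned
    with ``crossed=False``.
    """
    corr = curve.correlation
    radii = curve.shell_radii
    for i in range(1, corr.size):
        if corr[i] < threshold:
            if i == 1 or corr[i - 1] <= threshold:
                kappa = radii[i]
            else:
                frac = (corr[i - 1] - threshold) / (corr[i - 1] - corr[i])
                kappa = radii[i - 1] + frac * (radii[i] - radii[i - 1])
            return ResolutionEstimate(resolution=1.0 / kappa, crossed=True)
    nyquist = (
        2.0 * voxel_pitch if voxel_pitch is not None else 1.0 / radii[-1]
    )
    return ResolutionEstimate(resolution=nyquist, crossed=False)


def derive_threshold(correlation_floor: float) -> float:
    """FSC threshold implied by a signal-correlation floor.

    With ``FSC = S/(S+N)`` and signal correlation ``sqrt(S/(S+N))``,
    requiring the latter to be at least ``c`` gives ``FSC >= c^2``; the 1/2
    floor yields the 1/4 criterion.
    """
    if not (0.0 < correlation_floor <= 1.0):
        raise ValueError("correlation floor must lie in (0, 1]")
    return correlation_floor**2


def write_fsc_csv(path, curve: FSCCurve) -> None:
    """Write an FSC curve as CSV: radius, fsc, voxels_per_shell."""
    with open(path, "w") as fh:
        fh.write("radius_cycles_per_m,fsc,voxels_per_shell\n")
        for r, c, n in zip(
            curve.shell_radii, curve.correlation, curve.voxels_per_shell
        ):
            fh.write(f"{r:.8e},{c:.8f},{int(n)}\n")
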