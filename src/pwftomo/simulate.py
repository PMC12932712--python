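"""Synthetic speckle-tomography datasets with known ground truth.

Emulates the full acquisition: a thin complex sample (spheres and an
optional cylinder, mimicking glass beads on a support stick), a random
diffuser phase screen, angular-spectrum propagation over the
sample-diffuser and diffuser-detector distances, intensity formation,
Gaussian partial-coherence blur consistent with the Siegert relation, shot
noise, and a 0-180 degree parallel-beam rotation series.

The sample enters as a thin-object exit field: a component of projected
thickness ``T(x, y)`` with refractive index ``n = 1 - delta + i beta``
multiplies the beam by ``exp(psi)`` with ``psi = -(2 pi / lambda)
(beta + i delta) T`` — projected thicknesses are analytic (sphere chords
and cylinder chords), so the ground truth has no ray-marching error.

Coordinates: x is horizontal (columns), y vertical (rows, the rotation
axis), z the beam direction at angle 0; rotating the sample by ``theta``
moves a point ``(cx, cz)`` to projected position
``cx cos(theta) - cz sin(theta)`` on the detector (the sign matches the
parallel-beam convention of ``skimage.transform.radon``/``iradon``, so
reconstructed volumes land where the phantom put them).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coherence import CoherenceModel, iotf
from .diffuser import DiffuserTransmission
from .io import SpeckleDataset, phantom_to_json
from .optics import ImagingGeometry
from .solver import ComplexPhaseMap, _forward_parts


@dataclass(frozen=True)
class Sphere:
    """A homogeneous sphere: centre ``(x, y, z)`` in metres."""

    center: tuple[float, float, float]
    radius: float
    delta: float
    beta: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")
        if self.delta < 0 or self.beta < 0:
            raise ValueError("delta and beta must be non-negative")


@dataclass(frozen=True)
class Cylinder:
    """A cylinder parallel to the rotation (y) axis, centred at (x, z)."""

    center_xz: tuple[float, float]
    radius: float
    delta: float
    beta: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("cylinder radius must be positive")
        if self.delta < 0 or self.beta < 0:
            raise ValueError("delta and beta must be non-negative")


@dataclass(frozen=True)
class Phantom:
    """Collection of spheres plus an optional support cylinder."""

    spheres: tuple[Sphere, ...] = ()
    cylinder: Cylinder | None = None

    def check_fits(self, geometry: ImagingGeometry) -> None:
        """Verify every component stays inside the reconstruction cylinder."""
        half = min(geometry.fov_x, geometry.fov_y) / 2.0
        for s in self.spheres:
            if np.hypot(s.center[0], s.center[2]) + s.radius > half:
                raise ValueError("sphere extends outside the field of view")
        if self.cylinder is not None:
            c = self.cylinder
            if np.hypot(*c.center_xz) + c.radius > half:
                raise ValueError("cylinder extends outside the field of view")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic acquisition."""

    geometry: ImagingGeometry
    coherence: CoherenceModel
    diffuser_grain: float  # phase-screen correlation length, metres
    diffuser_phase_std: float  # phase-screen standard deviation, radians
    photon_count: float = np.inf  # mean photons/pixel; inf = noiseless
    angles: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    seed: int = 0
    read_noise_std: float = 0.0  # dark-frame noise, normalized units

    def __post_init__(self) -> None:
        if self.photon_count <= 0:
            raise ValueError("photon count must be positive")
        object.__setattr__(
            self, "angles", np.asarray(self.angles, dtype=float)
        )


def project_phantom(
    phantom: Phantom, angle: float, geometry: ImagingGeometry
) -> ComplexPhaseMap:
    """Analytic ground-truth complex phase map at one rotation angle.

    The projected thickness of a sphere is the chord ``2 sqrt(R^2 - rho^2)``
    and of a y-parallel cylinder ``2 sqrt(R^2 - dx^2)``; the complex phase
    is ``psi = -(2 pi / lambda) (beta + i delta) T`` summed over components.
    """
    theta = np.deg2rad(angle)
    x = (np.arange(geometry.nx) - geometry.nx // 2) * geometry.pitch
    y = (np.arange(geometry.ny) - geometry.ny // 2) * geometry.pitch
    xx, yy = np.meshgrid(x, y)
    k = 2.0 * np.pi / geometry.wavelength
    psi = np.zeros(geometry.shape, dtype=complex)
    for s in phantom.spheres:
        cx, cy, cz = s.center
        x_proj = cx * np.cos(theta) - cz * np.sin(theta)
        rho2 = (xx - x_proj) ** 2 + (yy - cy) ** 2
        chord = 2.0 * np.sqrt(np.clip(s.radius**2 - rho2, 0.0, None))
        psi -= k * (s.beta + 1j * s.delta) * chord
    if phantom.cylinder is not None:
        c = phantom.cylinder
        x_proj = c.center_xz[0] * np.cos(theta) - c.center_xz[1] * np.sin(theta)
        dx2 = (xx - x_proj) ** 2
        chord = 2.0 * np.sqrt(np.clip(c.radius**2 - dx2, 0.0, None))
        psi -= k * (c.beta + 1j * c.delta) * chord
    return ComplexPhaseMap(psi, geometry)


def make_diffuser_screen(config: SimulationConfig) -> DiffuserTransmission:
    """Random unit-amplitude phase screen ``exp(i phi)``.

    ``phi`` is a stationary Gaussian random field with the requested
    standard deviation and Gaussian autocorrelation
    ``exp(-pi dr^2 / grain^2)``, produced by spectral filtering of white
    noise (so the screen is periodic, matching the FFT-based propagators).
    Deterministic for a fixed seed.
    """
    geometry = config.geometry
    if config.diffuser_grain < 2.0 * geometry.pitch:
        raise ValueError("diffuser grain must be at least two pixels")
    rng = np.random.default_rng(config.seed)
    white = rng.standard_normal(geometry.shape)
    if config.diffuser_phase_std == 0.0:
        return DiffuserTransmission(
            np.ones(geometry.shape, dtype=complex), geometry
        )
    u1 = np.fft.fftfreq(geometry.nx, d=geometry.pitch)
    v1 = np.fft.fftfreq(geometry.ny, d=geometry.pitch)
    u, v = np.meshgrid(u1, v1)
    # amplitude filter = sqrt of the target power spectrum
    ell = config.diffuser_grain
    filt = np.exp(-np.pi * ell**2 * (u**2 + v**2) / 2.0)
    phi = np.fft.ifft2(filt * np.fft.fft2(white)).real
    phi *= config.diffuser_phase_std / phi.std()
    screen = DiffuserTransmission(np.exp(1j * phi), geometry)
    screen.phase_field = phi  # unwrapped screen phase, for diagnostics
    return screen


def _apply_noise(frame: np.ndarray, config: SimulationConfig, rng) -> np.ndarray:
    if not np.isfinite(config.photon_count):
        return frame
    counts = rng.poisson(np.clip(frame, 0.0, None) * config.photon_count)
    return counts / config.photon_count


def simulate_dataset(phantom: Phantom, config: SimulationConfig) -> SpeckleDataset:
    """Generate a complete synthetic acquisition with ground truth.

    Frames follow the acquisition order of a real measurement: dark frame,
    flat field, reference speckle (no sample), then one sample speckle per
    rotation angle.  Shot noise (Poisson at ``photon_count``) is applied
    last; with an infinite photon count every frame is noiseless.  The
    ground-truth phase map for every angle is stored alongside the frames.
    """
    phantom.check_fits(config.geometry)
    geometry = config.geometry
    rng = np.random.default_rng(config.seed + 1)
    screen = make_diffuser_screen(config)
    iotf_window = iotf(config.coherence, geometry)

    dark = np.zeros(geometry.shape)
    if config.read_noise_std > 0:
        dark = dark + rng.normal(0.0, config.read_noise_std, geometry.shape)
    flat = _apply_noise(np.ones(geometry.shape), config, rng)

    reference, _, _ = _forward_parts(
        np.zeros(geometry.shape, dtype=complex), screen, iotf_window, geometry
    )
    reference = _apply_noise(reference, config, rng)

    projections = np.empty((config.angles.size,) + geometry.shape)
    truth = np.empty((config.angles.size,) + geometry.shape, dtype=complex)
    for i, angle in enumerate(config.angles):
        psi = project_phantom(phantom, angle, geometry)
        truth[i] = psi.values
        frame, _, _ = _forward_parts(psi.values, screen, iotf_window, geometry)
        projections[i] = _apply_noise(frame, config, rng)

    return SpeckleDataset(
        dark=dark, flat=flat, reference=reference, projections=projections,
        angles=config.angles, geometry=geometry, coherence=config.coherence,
        truth_psi=truth, phantom_json=phantom_to_json(phantom),
    )


def default_geometry(n: int = 128) -> ImagingGeometry:
    """Desk-scale version of the synchrotron geometry (same physics)."""
    return ImagingGeometry(
        nx=n, ny=n, pitch=650e-9, wavelength=0.124e-9, L1=3e-3, L2=20e-3
    )


def default_coherence() -> CoherenceModel:
    """Desk-scale coherence lengths (two / two-and-a-half pixels).

    The beamline's calibrated coherence lengths span about five pixels; on
    a 128-pixel frame that blur would erase most of the speckle bandwidth
    that carries the sample information.  The simulated source is therefore
    proportionally more coherent, preserving the experiment's ratio of
    retrievable speckle structure to frame size.
    """
    return CoherenceModel(x_coh=1.3e-6, y_coh=1.625e-6)


def default_phantom() -> Phantom:
    """Three soda-lime-like glass beads inside the reconstruction cylinder.

    ``delta = 6.0e-6`` and ``beta = 4.5e-8`` are representative of glass at
    10 keV; bead radii of 6-8 um give peak phase shifts of a few radians on
    the 83 um default field of view, with refraction displacements well
    below one speckle grain (the small-displacement regime in which the
    forward model is informative).
    """
    return Phantom(spheres=(
        Sphere(center=(-15e-6, -12e-6, 5e-6), radius=8e-6,
               delta=6.0e-6, beta=4.5e-8),
        Sphere(center=(10e-6, 1e-6, -8e-6), radius=6e-6,
               delta=6.0e-6, beta=4.5e-8),
        Sphere(center=(2e-6, 13e-6, 12e-6), radius=7e-6,
               delta=6.0e-6, beta=4.5e-8),
    ))


def default_config(
    seed: int = 0,
    n: int = 128,
    n_angles: int = 60,
    photon_count: float = np.inf,
) -> SimulationConfig:
    """Default desk-scale study conditions: 128^2 frames, 60 angles.

    The diffuser emulates stacked fine-grit sandpaper: a deep phase screen
    (std 6 rad) with a 3.4 um correlation length.  The resulting coherent
    speckle decorrelates well below the grain scale, so the Siegert
    calibration of the blurred reference recovers the configured coherence
    lengths, while the observed speckle (contrast ~ 0.5) retains the
    fine structure that makes phase retrieval well posed.
    """
    return SimulationConfig(
        geometry=default_geometry(n),
        coherence=default_coherence(),
        diffuser_grain=3.38e-6,
        diffuser_phase_std=6.0,
        photon_count=photon_count,
        angles=np.linspace(0.0, 180.0, n_angles, endpoint=False),
        seed=seed,
    )
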