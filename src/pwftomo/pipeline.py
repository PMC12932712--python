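"""End-to-end reconstruction: dataset -> phase maps -> tomogram -> FSC.

Chains the stages a full experiment runs through: preprocessing (dark /
flat correction), Siegert coherence calibration on the reference speckle,
diffuser-transmission estimation, per-angle PWF phase retrieval, filtered
back projection of both channels, conversion to refractive-index units and
quadratic background flattening.

For synthetic datasets the diffuser can alternatively be taken from the
simulation itself (``diffuser="known"``), which removes the zero-phase
estimation as an error source and validates the solver and tomography
stages under zero model mismatch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .coherence import CoherenceModel, calibrate_coherence
from .diffuser import DiffuserTransmission, estimate_transmission
from .io import SpeckleDataset
from .optics import ImagingGeometry, IntensityImage2D
from .simulate import SimulationConfig, make_diffuser_screen
from .solver import ComplexPhaseMap, PWFResult, SolverParams, solve
from .tomography import (
    ProjectionSeries,
    Tomogram,
    default_background_mask,
    flatten_background,
    preprocess,
    reconstruct_tomogram,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything the full reconstruction produces."""

    tomogram: Tomogram
    coherence: CoherenceModel
    phase_maps: list[ComplexPhaseMap]
    solver_results: list[PWFResult]
    diffuser: DiffuserTransmission


def default_solver_params(max_iter: int = 1400) -> SolverParams:
    """Solver settings for the noiseless desk-scale simulations.

    The regularization weight is a signal-to-noise dependent heuristic;
    noiseless synthetic data need no damping of the phase channel and only
    a light attenuation-channel penalty (``alpha = 0.01``), and a fixed
    iteration budget is used instead of the correlation-based stop, for
    reproducibility.
    """
    return SolverParams(
        alpha=0.01 + 0.0j, max_iter=max_iter, min_iter=max_iter
    )


def run_pipeline(
    dataset: SpeckleDataset,
    params: SolverParams | None = None,
    diffuser: str = "estimated",
    coherence: str = "calibrated",
    nsr: float = 1e-2,
    flatten: bool = True,
    simulation_config: SimulationConfig | None = None,
    progress: bool = False,
) -> PipelineResult:
    """Reconstruct delta and beta volumes from a speckle dataset.

    Parameters
    ----------
    dataset : SpeckleDataset
        Raw frames (dark, flat, reference, per-angle sample speckles).
    params : SolverParams, optional
        PWF settings; defaults to :func:`default_solver_params`.
    diffuser : {"estimated", "known"}
        "estimated" derives the transmission from the reference speckle
        with the zero-phase convention (the only option for experimental
        data); "known" regenerates the simulation's phase screen, which
        requires ``simulation_config`` (or dataset coherence + config
        metadata) and is available for synthetic data only.
    coherence : {"calibrated", "configured"}
        Calibrate from the reference speckle, or trust the coherence model
        stored in the dataset.
    nsr : float
        Wiener noise-to-signal parameter for the transmission estimate.
    flatten : bool
        Apply per-slice quadratic background flattening to the volumes.
    """
    geometry: ImagingGeometry = dataset.geometry
    dark = IntensityImage2D(dataset.dark, geometry)
    flat = IntensityImage2D(dataset.flat, geometry)
    reference = preprocess(
        IntensityImage2D(dataset.reference, geometry), dark, flat
    )

    if coherence == "calibrated":
        model = calibrate_coherence(reference)
        logger.info(
            "calibrated coherence: x_coh=%.3g m, y_coh=%.3g m",
            model.x_coh, model.y_coh,
        )
    elif coherence == "configured":
        if dataset.coherence is None:
            raise ValueError("dataset carries no configured coherence model")
        model = dataset.coherence
    else:
        raise ValueError("coherence must be 'calibrated' or 'configured'")

    if diffuser == "estimated":
        transmission = estimate_transmission(reference, model, geometry, nsr)
    elif diffuser == "known":
        if simulation_config is None:
            raise ValueError(
                "diffuser='known' needs the simulation config that "
                "generated the dataset"
            )
        transmission = make_diffuser_screen(simulation_config)
    else:
        raise ValueError("diffuser must be 'estimated' or 'known'")

    if params is None:
        params = default_solver_params()

    reference_mean = float(reference.values.mean())
    phase_maps: list[ComplexPhaseMap] = []
    results: list[PWFResult] = []
    for i in range(dataset.angles.size):
        frame = preprocess(
            IntensityImage2D(dataset.projections[i], geometry), dark, flat
        )
        result = solve(
            frame, transmission, model, geometry, params,
            reference_mean=reference_mean,
        )
        phase_maps.append(result.psi)
        results.append(result)
        if progress:
            print(
                f"angle {i + 1}/{dataset.angles.size}: "
                f"{result.iterations} iterations, "
                f"loss {result.loss_history[-1]:.3e}",
                flush=True,
            )

    series = ProjectionSeries(
        angles=dataset.angles, phase_maps=phase_maps, geometry=geometry
    )
    tomogram = reconstruct_tomogram(series)
    if flatten:
        mask = default_background_mask(tomogram.delta.shape)
        tomogram = Tomogram(
            delta=flatten_background(tomogram.delta, mask),
            beta=flatten_background(tomogram.beta, mask),
            voxel_pitch=tomogram.voxel_pitch,
        )
    return PipelineResult(
        tomogram=tomogram,
        coherence=model,
        phase_maps=phase_maps,
        solver_results=results,
        diffuser=transmission,
    )


def run_phase_retrieval_single(
    dataset: SpeckleDataset,
    angle_index: int,
    params: SolverParams | None = None,
    nsr: float = 1e-2,
) -> tuple[ComplexPhaseMap, np.ndarray]:
    """Calibrate, estimate the diffuser and retrieve one projection.

    Returns the retrieved phase map and its RMSE image (percent of the
    reference-speckle mean).
    """
    geometry = dataset.geometry
    dark = IntensityImage2D(dataset.dark, geometry)
    flat = IntensityImage2D(dataset.flat, geometry)
    reference = preprocess(
        IntensityImage2D(dataset.reference, geometry), dark, flat
    )
    model = calibrate_coherence(reference)
    transmission = estimate_transmission(reference, model, geometry, nsr)
    frame = preprocess(
        IntensityImage2D(dataset.projections[angle_index], geometry), dark, flat
    )
    result = solve(
        frame, transmission, model, geometry,
        params or default_solver_params(),
        reference_mean=float(reference.values.mean()),
    )
    return result.psi, result.rmse_image


def bead_interior_means(
    tomogram: Tomogram, phantom, interior_fraction: float = 0.7
) -> list[dict]:
    """Mean reconstructed delta and beta inside each phantom bead.

    Voxels within ``interior_fraction`` of each sphere radius are averaged,
    avoiding the partial-volume shell at the bead boundary.
    """
    n_y, n_z, n_x = tomogram.delta.shape
    p = tomogram.voxel_pitch
    y = (np.arange(n_y) - n_y // 2) * p
    z = (np.arange(n_z) - n_z // 2) * p
    x = (np.arange(n_x) - n_x // 2) * p
    X3 = x[None, None, :]
    Y3 = y[:, None, None]
    Z3 = z[None, :, None]
    rows = []
    for sphere in phantom.spheres:
        cx, cy, cz = sphere.center
        mask = ((X3 - cx) ** 2 + (Y3 - cy) ** 2 + (Z3 - cz) ** 2) < (
            interior_fraction * sphere.radius
        ) ** 2
        rows.append({
            "radius": sphere.radius,
            "delta_true": sphere.delta,
            "beta_true": sphere.beta,
            "delta_recovered": float(tomogram.delta[mask].mean()),
            "beta_recovered": float(tomogram.beta[mask].mean()),
        })
    return rows
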