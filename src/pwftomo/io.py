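"""Dataset container and on-disk formats.

A :class:`SpeckleDataset` bundles everything one tomographic acquisition
produces: dark frame, flat field, reference speckle (diffuser only), the
per-angle sample speckle stack, the rotation angles and the imaging
geometry — plus, for synthetic data, the ground-truth phase maps.

Native container is a single HDF5 file (datasets ``/dark``, ``/flat``,
``/reference``, ``/projections``, ``/angles``, ``/truth/psi``; geometry and
coherence as root attributes).  A directory of multi-page TIFFs with a
``metadata.yaml`` sidecar is accepted for interoperability with beamline
exports.  Round trips through either format are lossless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from .coherence import CoherenceModel
from .optics import ImagingGeometry

_GEOMETRY_KEYS = ("nx", "ny", "pitch", "wavelength", "L1", "L2")


@dataclass
class SpeckleDataset:
    """One acquisition: calibration frames, reference and sample speckles."""

    dark: np.ndarray
    flat: np.ndarray
    reference: np.ndarray
    projections: np.ndarray  # (n_angles, ny, nx)
    angles: np.ndarray  # degrees, strictly increasing
    geometry: ImagingGeometry
    coherence: CoherenceModel | None = None
    truth_psi: np.ndarray | None = None  # (n_angles, ny, nx) complex
    phantom_json: str | None = None

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.projections = np.asarray(self.projections)
        shape = self.geometry.shape
        for name in ("dark", "flat", "reference"):
            frame = np.asarray(getattr(self, name))
            if frame.shape != shape:
                raise ValueError(f"frame '{name}' has shape {frame.shape}, "
                                 f"expected {shape}")
            setattr(self, name, frame)
        if self.projections.ndim != 3 or self.projections.shape[1:] != shape:
            raise ValueError(
                f"projection stack shape {self.projections.shape} is not "
                f"(n_angles, {shape[0]}, {shape[1]})"
            )
        if self.projections.shape[0] != self.angles.size:
            raise ValueError("projection count does not match angle count")
        if self.angles.size >= 2 and np.any(np.diff(self.angles) <= 0):
            raise ValueError("/angles must be strictly increasing")


def _geometry_to_attrs(geometry: ImagingGeometry) -> dict:
    return {
        "nx": geometry.nx, "ny": geometry.ny, "pitch": geometry.pitch,
        "wavelength": geometry.wavelength, "L1": geometry.L1,
        "L2": geometry.L2,
    }


def _geometry_from_mapping(mapping, source: str) -> ImagingGeometry:
    missing = [k for k in _GEOMETRY_KEYS if k not in mapping]
    if missing:
        raise ValueError(
            f"missing geometry metadata in {source}: {', '.join(missing)}"
        )
    return ImagingGeometry(
        nx=int(mapping["nx"]), ny=int(mapping["ny"]),
        pitch=float(mapping["pitch"]),
        wavelength=float(mapping["wavelength"]),
        L1=float(mapping["L1"]), L2=float(mapping["L2"]),
    )


def write_dataset(dataset: SpeckleDataset, path) -> None:
    """Write a dataset to HDF5 (extension ``.h5``/``.hdf5``) losslessly."""
    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("dark", data=dataset.dark)
        fh.create_dataset("flat", data=dataset.flat)
        fh.create_dataset("reference", data=dataset.reference)
        fh.create_dataset("projections", data=dataset.projections)
        fh.create_dataset("angles", data=dataset.angles)
        for key, value in _geometry_to_attrs(dataset.geometry).items():
            fh.attrs[key] = value
        if dataset.coherence is not None:
            fh.attrs["x_coh"] = dataset.coherence.x_coh
            fh.attrs["y_coh"] = dataset.coherence.y_coh
        if dataset.truth_psi is not None:
            fh.create_dataset("truth/psi", data=dataset.truth_psi)
        if dataset.phantom_json is not None:
            fh.attrs["phantom"] = dataset.phantom_json


def _read_hdf5(path: Path) -> SpeckleDataset:
    with h5py.File(path, "r") as fh:
        geometry = _geometry_from_mapping(dict(fh.attrs), str(path))
        angles = np.asarray(fh["angles"])
        frames = {
            name: np.asarray(fh[name])
            for name in ("dark", "flat", "reference", "projections")
        }
        coherence = None
        if "x_coh" in fh.attrs and "y_coh" in fh.attrs:
            coherence = CoherenceModel(
                float(fh.attrs["x_coh"]), float(fh.attrs["y_coh"])
            )
        truth = np.asarray(fh["truth/psi"]) if "truth/psi" in fh else None
        phantom = fh.attrs.get("phantom")
    return SpeckleDataset(
        dark=frames["dark"], flat=frames["flat"],
        reference=frames["reference"], projections=frames["projections"],
        angles=angles, geometry=geometry, coherence=coherence,
        truth_psi=truth, phantom_json=phantom,
    )


def _read_tiff_dir(path: Path) -> SpeckleDataset:
    sidecar = path / "metadata.yaml"
    if not sidecar.exists():
        raise ValueError(
            f"missing geometry: TIFF directory {path} has no metadata.yaml "
            "sidecar"
        )
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    geometry = _geometry_from_mapping(meta.get("geometry", {}), str(sidecar))
    angles = np.asarray(meta["angles"], dtype=float)
    frames = {}
    for name in ("dark", "flat", "reference", "projections"):
        frame_path = path / f"{name}.tif"
        if not frame_path.exists():
            raise ValueError(f"missing frame file {frame_path}")
        frames[name] = tifffile.imread(frame_path)
    coherence = None
    if "coherence" in meta:
        coherence = CoherenceModel(
            float(meta["coherence"]["x_coh"]), float(meta["coherence"]["y_coh"])
        )
    return SpeckleDataset(
        dark=frames["dark"], flat=frames["flat"],
        reference=frames["reference"], projections=frames["projections"],
        angles=angles, geometry=geometry, coherence=coherence,
    )


def write_dataset_tiff(dataset: SpeckleDataset, path) -> None:
    """Write a dataset as a directory of TIFFs plus a metadata sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path / "dark.tif", dataset.dark)
    tifffile.imwrite(path / "flat.tif", dataset.flat)
    tifffile.imwrite(path / "reference.tif", dataset.reference)
    tifffile.imwrite(path / "projections.tif", dataset.projections)
    meta = {
        "geometry": _geometry_to_attrs(dataset.geometry),
        "angles": [float(a) for a in dataset.angles],
    }
    if dataset.coherence is not None:
        meta["coherence"] = {
            "x_coh": dataset.coherence.x_coh,
            "y_coh": dataset.coherence.y_coh,
        }
    with open(path / "metadata.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)


def read_dataset(path) -> SpeckleDataset:
    """Read a dataset from an HDF5 file or a TIFF directory."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dataset path does not exist: {path}")
    if path.is_dir():
        return _read_tiff_dir(path)
    return _read_hdf5(path)


def write_volume(path, delta: np.ndarray, beta: np.ndarray,
                 voxel_pitch: float, angles: np.ndarray | None = None) -> None:
    """Write reconstructed volumes to HDF5 (/delta, /beta, /angles, /pitch)."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("delta", data=np.asarray(delta, dtype=np.float32))
        fh.create_dataset("beta", data=np.asarray(beta, dtype=np.float32))
        fh.create_dataset("pitch", data=float(voxel_pitch))
        if angles is not None:
            fh.create_dataset("angles", data=np.asarray(angles, dtype=float))


def read_volume(path) -> tuple[np.ndarray, np.ndarray, float]:
    """Read ``(delta, beta, voxel_pitch)`` from an HDF5 volume file."""
    with h5py.File(path, "r") as fh:
        return (
            np.asarray(fh["delta"]), np.asarray(fh["beta"]),
            float(np.asarray(fh["pitch"])),
        )


def phantom_to_json(phantom) -> str:
    """Serialize a phantom description to JSON (for dataset provenance)."""
    spheres = [
        {"center": list(map(float, s.center)), "radius": float(s.radius),
         "delta": float(s.delta), "beta": float(s.beta)}
        for s in phantom.spheres
    ]
    payload = {"spheres": spheres}
    if phantom.cylinder is not None:
        c = phantom.cylinder
        payload["cylinder"] = {
            "center_xz": list(map(float, c.center_xz)),
            "radius": float(c.radius), "delta": float(c.delta),
            "beta": float(c.beta),
        }
    return json.dumps(payload)
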