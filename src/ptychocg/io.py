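"""Dataset container, HDF5 persistence and image export.

A dataset lives in a single HDF5 file:

=================  =========================================================
``/data``          ``(n, S, S)`` real, non-negative diffraction intensities
``/probe``         ``(S, S)`` complex probe
``/positions``     ``(n, 2)`` integer 0-based (row, col) top-left corners
``/ground_truth``  optional ``(H, W)`` complex reference object
attributes         ``H``, ``W``, ``format_version``, optional ``spec`` (YAML)
=================  =========================================================

Complex arrays are stored natively; round trips are bit-exact.  The position
convention is recorded in the file attributes to prevent dialect drift.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import yaml

from ._exceptions import DataError, FormatError
from .operators import validate_geometry

__all__ = ["Dataset", "write_dataset", "read_dataset", "export_images",
           "FORMAT_VERSION"]

FORMAT_VERSION = "1"


@dataclass
class Dataset:
    """In-memory ptychography dataset (measurements + geometry + optional
    ground truth and the simulation spec that produced it)."""

    data: np.ndarray
    probe: np.ndarray
    positions: np.ndarray
    shape: tuple
    ground_truth: np.ndarray | None = None
    spec: dict | None = field(default=None)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.probe = np.asarray(self.probe)
        self.positions = np.asarray(self.positions)
        self.shape = (int(self.shape[0]), int(self.shape[1]))
        self.validate()

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def S(self) -> int:
        return self.probe.shape[0]

    def validate(self):
        pos = validate_geometry(self.shape, self.probe, self.positions)
        if self.data.shape != (len(pos), self.S, self.S):
            raise FormatError(
                f"/data shape {self.data.shape} inconsistent with "
                f"{(len(pos), self.S, self.S)} from /positions and /probe"
            )
        if np.any(self.data < 0):
            raise DataError("/data contains negative intensities")
        if self.ground_truth is not None and (
            np.shape(self.ground_truth) != self.shape
        ):
            raise FormatError(
                f"/ground_truth shape {np.shape(self.ground_truth)} does not "
                f"match object shape {self.shape}"
            )


def write_dataset(path, dataset: Dataset):
    """Write a dataset to HDF5 (lossless, bit-exact round trip)."""
    dataset.validate()
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=dataset.data)
        fh.create_dataset("probe", data=np.asarray(dataset.probe, dtype=complex))
        fh.create_dataset("positions", data=dataset.positions.astype(np.int64))
        if dataset.ground_truth is not None:
            fh.create_dataset(
                "ground_truth", data=np.asarray(dataset.ground_truth, dtype=complex)
            )
        fh.attrs["H"] = dataset.shape[0]
        fh.attrs["W"] = dataset.shape[1]
        fh.attrs["format_version"] = FORMAT_VERSION
        fh.attrs["position_convention"] = "0-based (row, col) top-left corner"
        if dataset.spec is not None:
            fh.attrs["spec"] = yaml.safe_dump(dataset.spec)
    return path


def read_dataset(path) -> Dataset:
    """Read and validate a dataset file; errors name the offending member."""
    with h5py.File(path, "r") as fh:
        version = fh.attrs.get("format_version")
        if version is None:
            raise FormatError("attribute 'format_version' is missing")
        if str(version) != FORMAT_VERSION:
            raise FormatError(
                f"unknown format_version {version!r} (supported: {FORMAT_VERSION})"
            )
        for member in ("data", "probe", "positions"):
            if member not in fh:
                raise FormatError(f"dataset member '/{member}' is missing")
        for attr in ("H", "W"):
            if attr not in fh.attrs:
                raise FormatError(f"attribute {attr!r} is missing")
        spec_raw = fh.attrs.get("spec")
        return Dataset(
            data=fh["data"][()],
            probe=fh["probe"][()],
            positions=fh["positions"][()],
            shape=(int(fh.attrs["H"]), int(fh.attrs["W"])),
            ground_truth=fh["ground_truth"][()] if "ground_truth" in fh else None,
            spec=yaml.safe_load(spec_raw) if spec_raw is not None else None,
        )


def export_images(obj, prefix):
    """Export amplitude and phase of a complex object image.

    Writes lossless float32 TIFFs (``<prefix>_amplitude.tif``,
    ``<prefix>_phase.tif``; phase wrapped to (-pi, pi]), 16-bit PNG previews,
    and a JSON sidecar recording the scaling applied to the previews.
    Returns the list of written paths.
    """
    import imageio.v3 as iio
    import tifffile

    obj = np.asarray(obj)
    if not np.all(np.isfinite(obj)):
        raise DataError("cannot export an object with non-finite values")
    amp = np.abs(obj).astype(np.float32)
    phase = np.angle(obj).astype(np.float32)  # (-pi, pi] by convention
    paths = []
    meta = {}
    for name, img in (("amplitude", amp), ("phase", phase)):
        tif = f"{prefix}_{name}.tif"
        tifffile.imwrite(tif, img)
        paths.append(tif)
        lo, hi = float(img.min()), float(img.max())
        scale = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
        png = f"{prefix}_{name}.png"
        iio.imwrite(png, (scale * 65535).astype(np.uint16))
        paths.append(png)
        meta[name] = {"png_min": lo, "png_max": hi}
    sidecar = f"{prefix}_scale.json"
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=2)
    paths.append(sidecar)
    return paths
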