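"""Voxel-grid containers, NIfTI-1 I/O, and the Dice overlap metric.

The fusion algorithm itself is purely grid-topological: every internal
computation works on 0-based ``(i, j, k)`` voxel indices. Physical geometry
(voxel spacing, affine) is carried along only so that volumes can be written
back to disk correctly and so that volumes can be reported in mm^3.

Candidate labels are expected to already live on the target grid; no
resampling or registration is performed here (that is the job of the
upstream multi-atlas pipeline).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence, Union

import nibabel as nib
import numpy as np

__all__ = [
    "IntensityVolume",
    "LabelVolume",
    "CandidateLabelSet",
    "read_volume",
    "write_volume",
    "dice",
    "as_array",
]


def _default_affine(spacing: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class IntensityVolume:
    """A 3-D grayscale image on a regular voxel grid.

    Parameters
    ----------
    data : ndarray of shape (nx, ny, nz)
        Scalar intensities in arbitrary units. All values must be finite.
    spacing : tuple of float
        Per-axis voxel size in mm. Retained for I/O and volumetry only.
    affine : ndarray of shape (4, 4), optional
        Voxel-to-world transform. Defaults to a diagonal built from
        ``spacing``.
    """

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensity volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.affine is None:
            self.affine = _default_affine(self.spacing)

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class LabelVolume:
    """A 3-D binary segmentation: background 0, structure 1."""

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got ndim={arr.ndim}")
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"label volume has values outside {{0, 1}}: {vals[:10]}")
        self.data = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.affine is None:
            self.affine = _default_affine(self.spacing)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def volume_mm3(self) -> float:
        return float(self.data.sum()) * float(np.prod(self.spacing))


VolumeLike = Union[IntensityVolume, LabelVolume, np.ndarray]


def as_array(vol: VolumeLike) -> np.ndarray:
    """Return the underlying ndarray of a volume container (or pass through)."""
    if isinstance(vol, (IntensityVolume, LabelVolume)):
        return vol.data
    return np.asarray(vol)


@dataclass
class CandidateLabelSet:
    """An ordered collection of J candidate segmentations with vote weights.

    Weights default to uniform; they must be non-negative with a positive
    sum. All candidates must share one grid shape.
    """

    labels: list
    weights: np.ndarray = None

    def __post_init__(self):
        if len(self.labels) < 1:
            raise ValueError("need at least one candidate segmentation")
        self.labels = [
            lab if isinstance(lab, LabelVolume) else LabelVolume(lab)
            for lab in self.labels
        ]
        shapes = {lab.shape for lab in self.labels}
        if len(shapes) != 1:
            raise ValueError(f"candidate shapes differ: {shapes}")
        if self.weights is None:
            self.weights = np.ones(len(self.labels))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.labels),):
            raise ValueError("one weight per candidate is required")
        if (self.weights < 0).any():
            raise ValueError("weights must be non-negative")
        if self.weights.sum() <= 0:
            raise ValueError("weights must have a positive sum")

    @property
    def J(self) -> int:
        return len(self.labels)

    @property
    def shape(self) -> tuple:
        return self.labels[0].shape


def read_volume(path, kind: str = "auto"):
    """Read a NIfTI-1 volume from ``path``.

    Parameters
    ----------
    path : str or Path
        A readable ``.nii`` / ``.nii.gz`` file.
    kind : {"auto", "intensity", "label"}
        With ``"auto"``, a volume whose values are all in {0, 1} is returned
        as a :class:`LabelVolume`, anything else as an
        :class:`IntensityVolume`. ``"label"`` raises if any value falls
        outside {0, 1}.
    """
    if not os.path.exists(str(path)):
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got ndim={data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    affine = np.asarray(img.affine)
    is_binary = np.isin(np.unique(data), (0, 1)).all()
    if kind == "label" and not is_binary:
        raise ValueError(f"{path}: requested a label volume but values lie outside {{0, 1}}")
    if kind == "intensity":
        return IntensityVolume(data, spacing, affine)
    if is_binary:
        return LabelVolume(data, spacing, affine)
    return IntensityVolume(data, spacing, affine)


def write_volume(vol: VolumeLike, path) -> None:
    """Write a volume to NIfTI-1. Label volumes are stored as uint8."""
    if isinstance(vol, LabelVolume):
        data = vol.data.astype(np.uint8)
        affine = vol.affine
    elif isinstance(vol, IntensityVolume):
        data = vol.data.astype(np.float32)
        affine = vol.affine
    else:
        arr = np.asarray(vol)
        if np.isin(np.unique(arr), (0, 1)).all():
            data = arr.astype(np.uint8)
        else:
            data = arr.astype(np.float32)
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def dice(a: VolumeLike, b: VolumeLike) -> float:
    """Dice similarity coefficient, DSC = 2|A∩B| / (|A| + |B|).

    ``A`` and ``B`` are the foreground (label 1) voxel sets. Raises if the
    shapes differ or if both volumes are empty (the coefficient is
    undefined there, and silently returning 0 would hide the degenerate
    comparison).
    """
    aa = as_array(a).astype(bool)
    bb = as_array(b).astype(bool)
    if aa.shape != bb.shape:
        raise ValueError(f"shape mismatch: {aa.shape} vs {bb.shape}")
    denom = int(aa.sum()) + int(bb.sum())
    if denom == 0:
        raise ValueError("Dice is undefined when both volumes are empty")
    return 2.0 * int((aa & bb).sum()) / denom
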