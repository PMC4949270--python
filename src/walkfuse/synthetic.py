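"""Synthetic phantoms: hippocampus-like blobs and boundary-perturbed
candidate ensembles.

The phantom is a smoothly deformed ellipsoid (implicit-surface threshold of
an ellipsoidal quadric plus a band-limited Gaussian random field) with
per-class Gaussian intensities, an optional linear intensity drift per
axis, and an optional reversed structure/background contrast emulating the
unmyelinated neonatal setting.

Candidate segmentations emulate the error structure of atlas propagation:
each candidate is the ground truth warped by a smooth random displacement
field (spatially correlated, surface-localized error), optionally dilated
or eroded by a voxel, with sparse label flips near the boundary. All
disagreements with the truth are confined to a declared band around the
truth surface — the core of the structure and the far background are
unanimous, which is exactly the regime in which confidence partitioning is
meaningful. A shared displacement component applied to a subset of
candidates can emulate correlated (systematic) atlas errors; it defaults
to zero.

Everything is a pure function of (spec, seed). What this generator does
NOT model: MR physics beyond additive Gaussian noise (no Rician noise, no
nonlinear bias fields, no partial-volume mixtures) and registration
failures larger than the boundary band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import CandidateLabelSet, IntensityVolume, LabelVolume

__all__ = ["PhantomSpec", "CandidateSpec", "make_phantom", "make_candidates"]


@dataclass
class PhantomSpec:
    """Geometry, intensity model, and seed for one phantom volume.

    Defaults give a 64^3 grid with ellipsoid semi-axes (14, 9, 7) voxels —
    a hippocampus-like aspect ratio at a desk-scale grid — and T1-like
    contrast: structure N(110, 12^2) vs background N(60, 12^2).
    """

    shape: tuple = (64, 64, 64)
    semi_axes: tuple = (14.0, 9.0, 7.0)
    center: tuple = None
    deform_amplitude: float = 0.3
    deform_scale: float = 8.0  # smoothing sigma of the deformation field, voxels
    mu_fg: float = 110.0
    sigma_fg: float = 12.0
    mu_bg: float = 60.0
    sigma_bg: float = 12.0
    drift: tuple = (0.0, 0.0, 0.0)  # intensity added linearly along each axis
    contrast_reversed: bool = False
    seed: int = 0


@dataclass
class CandidateSpec:
    """Perturbation model for a candidate-label ensemble.

    ``displacement`` is the RMS magnitude (voxels) of each candidate's
    smooth random warp of the truth surface; ``dilate_erode_max`` allows a
    uniform random morphological dilation/erosion of up to that many
    voxels; ``flip_rate`` adds isolated label noise within the boundary
    band. ``band`` is the half-width (voxels) of the zone around the truth
    surface outside which candidates are forced to agree with the truth;
    by default it is derived from the perturbation magnitudes.
    """

    n_candidates: int = 9
    displacement: float = 2.0
    smooth_sigma: float = 6.0  # spatial scale of the displacement fields
    dilate_erode_max: int = 1
    flip_rate: float = 0.02
    band: int = None
    systematic_magnitude: float = 0.0
    systematic_fraction: float = 0.5
    seed: int = 0

    def effective_band(self) -> int:
        if self.band is not None:
            return int(self.band)
        return int(
            math.ceil(self.displacement + self.systematic_magnitude)
            + self.dilate_erode_max
            + 1
        )


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Unit-RMS band-limited Gaussian random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    std = f.std()
    return f / std if std > 0 else f


def make_phantom(spec: PhantomSpec):
    """Generate ``(IntensityVolume, LabelVolume)`` for one phantom.

    The truth mask is {x : q(x) + a * e(x) <= 1} with q the ellipsoidal
    quadric and e a unit-RMS smooth random field; with zero amplitude this
    is the exact discrete ellipsoid. Raises if the structure reaches the
    grid border.
    """
    shape = tuple(int(n) for n in spec.shape)
    rng = np.random.default_rng(spec.seed)
    center = spec.center or tuple((n - 1) / 2.0 for n in shape)
    for a, c, n in zip(spec.semi_axes, center, shape):
        if c - a < 0 or c + a > n - 1:
            raise ValueError("ellipsoid geometry exceeds the grid")

    idx = np.indices(shape, dtype=float)
    q = sum(((idx[a] - center[a]) / spec.semi_axes[a]) ** 2 for a in range(3))
    if spec.deform_amplitude > 0:
        q = q + spec.deform_amplitude * _smooth_field(rng, shape, spec.deform_scale)
    truth = q <= 1.0
    border = np.zeros(shape, dtype=bool)
    for a in range(3):
        sl0 = [slice(None)] * 3
        sl0[a] = 0
        sl1 = [slice(None)] * 3
        sl1[a] = -1
        border[tuple(sl0)] = True
        border[tuple(sl1)] = True
    if (truth & border).any():
        raise ValueError("phantom structure touches the grid border")

    mu_fg, mu_bg = spec.mu_fg, spec.mu_bg
    if spec.contrast_reversed:
        mu_fg, mu_bg = mu_bg, mu_fg
    fg_field = rng.normal(mu_fg, spec.sigma_fg, shape)
    bg_field = rng.normal(mu_bg, spec.sigma_bg, shape)
    intensity = np.where(truth, fg_field, bg_field)
    for a, slope in enumerate(spec.drift):
        if slope != 0.0 and shape[a] > 1:
            ramp = np.arange(shape[a], dtype=float) / (shape[a] - 1)
            intensity = intensity + slope * ramp.reshape(
                [-1 if i == a else 1 for i in range(3)]
            )
    return (
        IntensityVolume(intensity),
        LabelVolume(truth.astype(np.uint8)),
    )


def boundary_band_mask(truth, band: int) -> np.ndarray:
    """Voxels within ``band`` (Euclidean) of the truth surface."""
    t = truth.data.astype(bool) if isinstance(truth, LabelVolume) else np.asarray(truth, bool)
    # distance to the boundary: for inside voxels, depth below the surface;
    # for outside voxels, distance to the structure
    d_in = ndimage.distance_transform_edt(t)
    d_out = ndimage.distance_transform_edt(~t)
    dist = np.where(t, d_in, d_out)
    return dist <= band


def make_candidates(truth, spec: CandidateSpec) -> CandidateLabelSet:
    """Generate J boundary-perturbed candidate segmentations of ``truth``.

    Each candidate differs from the truth only inside the boundary band;
    weights are uniform. Deterministic given ``spec.seed``.
    """
    t = truth.data.astype(bool) if isinstance(truth, LabelVolume) else np.asarray(truth, bool)
    shape = t.shape
    band = spec.effective_band()
    if band >= min(shape) // 2:
        raise ValueError("perturbation band exceeds the grid")
    rng = np.random.default_rng(spec.seed)
    band_mask = boundary_band_mask(t, band)
    idx = np.indices(shape, dtype=float)
    tf = t.astype(float)
    struct6 = ndimage.generate_binary_structure(3, 1)

    systematic = None
    shared_subset = np.zeros(spec.n_candidates, dtype=bool)
    if spec.systematic_magnitude > 0:
        systematic = np.stack(
            [
                spec.systematic_magnitude * _smooth_field(rng, shape, spec.smooth_sigma)
                for _ in range(3)
            ]
        )
        shared_subset = rng.random(spec.n_candidates) < spec.systematic_fraction

    labels = []
    for j in range(spec.n_candidates):
        disp = np.stack(
            [
                spec.displacement * _smooth_field(rng, shape, spec.smooth_sigma)
                for _ in range(3)
            ]
        )
        if systematic is not None and shared_subset[j]:
            disp = disp + systematic
        cand = (
            ndimage.map_coordinates(tf, idx + disp, order=1, mode="nearest") > 0.5
        )
        if spec.dilate_erode_max > 0:
            r = int(rng.integers(-spec.dilate_erode_max, spec.dilate_erode_max + 1))
            if r > 0:
                cand = ndimage.binary_dilation(cand, struct6, iterations=r)
            elif r < 0:
                cand = ndimage.binary_erosion(cand, struct6, iterations=-r)
        if spec.flip_rate > 0:
            flips = band_mask & (rng.random(shape) < spec.flip_rate)
            cand = cand ^ flips
        cand = np.where(band_mask, cand, t)
        labels.append(LabelVolume(cand.astype(np.uint8)))
    return CandidateLabelSet(labels)
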