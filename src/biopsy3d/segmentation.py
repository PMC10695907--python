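"""Seeded region-growing segmentation and connected-component labeling.

A specimen is extracted from the grayscale volume by growing from a
user-supplied seed voxel.  The acceptance band is fixed before growth: the
mean and standard deviation of the intensities in a small cubic
neighborhood around the seed define the interval
``[mu - k*sigma, mu + k*sigma]``, and the grown region is the connected set
of in-band voxels containing the seed.  Because the band never updates, the
result is deterministic and independent of visit order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .morphology import connectivity_structure
from .volumes import BinaryMask, VoxelVolume

__all__ = [
    "SeedPoint",
    "SegmentationParams",
    "LabeledMask",
    "region_grow",
    "label_components",
    "extract_specimen",
]


@dataclass(frozen=True)
class SeedPoint:
    """A voxel index ``(z, y, x)`` inside the volume."""

    z: int
    y: int
    x: int

    def __post_init__(self) -> None:
        if min(self.z, self.y, self.x) < 0:
            raise ValueError(f"seed indices must be non-negative, got {self}")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.z, self.y, self.x)


@dataclass(frozen=True)
class SegmentationParams:
    """Region-growing parameters.

    Attributes
    ----------
    tolerance_k : float
        Half-width of the acceptance band in multiples of the seed
        neighborhood's intensity SD.
    neighborhood_radius : int
        Radius of the cubic seed neighborhood, ``(2r+1)**3`` voxels.
    connectivity : int
        Foreground connectivity (6, 18 or 26) for growth and labeling.
    min_component_voxels : int
        Components smaller than this are discarded when labeling.
    """

    tolerance_k: float = 3.5
    neighborhood_radius: int = 2
    connectivity: int = 26
    min_component_voxels: int = 27

    def __post_init__(self) -> None:
        if not self.tolerance_k > 0:
            raise ValueError(f"tolerance_k must be > 0, got {self.tolerance_k}")
        if self.neighborhood_radius < 1:
            raise ValueError("neighborhood_radius must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ValueError(f"connectivity must be 6, 18 or 26, got {self.connectivity}")
        if self.min_component_voxels < 0:
            raise ValueError("min_component_voxels must be >= 0")


@dataclass(frozen=True)
class LabeledMask:
    """Integer-labeled components; 0 is background, labels run 1..n_labels."""

    data: np.ndarray
    n_labels: int
    voxel_edge_um: float

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("labeled data must be 3D")
        if self.n_labels < 0:
            raise ValueError("n_labels must be >= 0")


def region_grow(volume: VoxelVolume, seed: SeedPoint,
                params: SegmentationParams = SegmentationParams()) -> BinaryMask:
    """Grow a specimen mask from a seed with a fixed intensity band.

    The band is computed once from the ``(2r+1)^3`` neighborhood of the seed
    (which must lie fully inside the volume).  With a zero-SD neighborhood
    the band degenerates to exact-value matching.  The seed voxel is always
    part of the result.
    """
    z, y, x = seed.as_tuple()
    nz, ny, nx = volume.dims
    if not (z < nz and y < ny and x < nx):
        raise ValueError(f"seed {seed} outside volume of dims {volume.dims}")
    r = params.neighborhood_radius
    if (z - r < 0 or y - r < 0 or x - r < 0
            or z + r >= nz or y + r >= ny or x + r >= nx):
        raise ValueError(
            f"seed neighborhood of radius {r} around {seed} is truncated by "
            f"the volume border (dims {volume.dims})")

    neigh = volume.data[z - r:z + r + 1, y - r:y + r + 1, x - r:x + r + 1]
    neigh = neigh.astype(np.float64)
    mu = float(neigh.mean())
    sigma = float(neigh.std())
    lo, hi = mu - params.tolerance_k * sigma, mu + params.tolerance_k * sigma

    data = volume.data
    in_band = (data >= lo) & (data <= hi)
    in_band[z, y, x] = True  # seed always included
    structure = connectivity_structure(params.connectivity)
    labels, _ = ndimage.label(in_band, structure=structure)
    grown = labels == labels[z, y, x]
    return BinaryMask(data=grown, voxel_edge_um=volume.voxel_edge_um)


def label_components(mask: BinaryMask, connectivity: int = 26,
                     min_component_voxels: int = 0) -> LabeledMask:
    """Label maximal connected foreground components.

    Labels are assigned in decreasing voxel-count order; ties are broken by
    the lexicographically smallest ``(z, y, x)`` voxel of the component.
    Components smaller than ``min_component_voxels`` are dropped.
    """
    structure = connectivity_structure(connectivity)
    raw, n_raw = ndimage.label(mask.data, structure=structure)
    if n_raw == 0:
        return LabeledMask(data=np.zeros(mask.dims, dtype=np.int32), n_labels=0,
                           voxel_edge_um=mask.voxel_edge_um)
    counts = np.bincount(raw.ravel(), minlength=n_raw + 1)
    # first flat index (C order) of each label = lexicographically smallest voxel
    flat = raw.ravel()
    first_seen = np.full(n_raw + 1, flat.size, dtype=np.int64)
    nonzero = np.flatnonzero(flat)
    # reversed so earlier indices overwrite later ones
    first_seen[flat[nonzero[::-1]]] = nonzero[::-1]
    order = sorted(
        (lab for lab in range(1, n_raw + 1) if counts[lab] >= max(min_component_voxels, 1)),
        key=lambda lab: (-counts[lab], first_seen[lab]),
    )
    remap = np.zeros(n_raw + 1, dtype=np.int32)
    for new, old in enumerate(order, start=1):
        remap[old] = new
    return LabeledMask(data=remap[raw], n_labels=len(order),
                       voxel_edge_um=mask.voxel_edge_um)


def extract_specimen(labeled: LabeledMask, label: int) -> BinaryMask:
    """Return the boolean mask of one labeled component."""
    if not (1 <= label <= labeled.n_labels):
        raise ValueError(f"label {label} out of range 1..{labeled.n_labels}")
    return BinaryMask(data=labeled.data == label, voxel_edge_um=labeled.voxel_edge_um)
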