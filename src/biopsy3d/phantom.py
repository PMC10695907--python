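"""Synthetic biopsy phantoms with analytically known ground truth.

Real specimens are paraffin-embedded myocardial cylinders imaged at 2 µm
isotropic voxels: a bright tissue phase in a darker background, with
internal ruptures (thin cracks and larger voids), surface coarseness
(protrusions left by the forceps expulsion), localized high-density pinch
foci at the forceps contact sites, and additive noise.  The generator
rasterizes these features analytically — an ellipsoidal body, ellipsoidal
cavities, planar slits, one-voxel-thick spikes, spherical density boosts —
so every voxel count the pipeline later measures is known exactly at
generation time.

The body is regularized at rasterization by one morphological
opening-of-closing with the default 3x3x3 cube, which makes the surface
regular at the kernel scale: opening the defect-free body removes nothing
and closing it adds nothing.  The expected integrity ratios are then exact:
closing fills thin cracks and hole filling fills enclosed voids, so the
expected inner integrity is ``T / (T + voids + cracks)``; opening removes
exactly the spike voxels, so the expected outer integrity is
``1 - spikes / (T + voids + cracks)`` up to a small surface margin.

Group presets mimic the designed contrast between a gentle cutting design
(control-like and B1-like: few small defects) and a crushing one (B2-like:
more and larger voids, cracks, many surface spikes, more pinch foci).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .morphology import CUBE_27, fill_holes, morph_close, morph_open
from .volumes import BinaryMask, VoxelVolume

__all__ = [
    "Ellipsoid",
    "Slit",
    "Spike",
    "Pinch",
    "PhantomSpec",
    "PhantomTruth",
    "CohortSpecimen",
    "PhantomSpecError",
    "generate_phantom",
    "generate_group_cohort",
    "deepest_tissue_voxel",
    "PRESETS",
]


class PhantomSpecError(ValueError):
    """A phantom spec violates one of its geometric or contrast invariants."""


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: center and semi-axes in ``(z, y, x)`` voxels."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]


@dataclass(frozen=True)
class Slit:
    """Planar crack: a thin box of ``thickness`` (1-2) voxels along ``normal_axis``."""

    center: tuple[float, float, float]
    normal_axis: int  # 0 = z, 1 = y, 2 = x
    thickness: int
    half_extent: int  # in-plane half edge


@dataclass(frozen=True)
class Spike:
    """One-voxel-thick surface protrusion of ``length`` voxels.

    The spike runs along ``axis`` in ``direction`` (+1 or -1), starting just
    outside the outermost body voxel on the line fixed by ``transverse``
    (the two non-axis coordinates, in ``(z, y, x)`` order with ``axis``
    removed).
    """

    axis: int
    direction: int
    transverse: tuple[int, int]
    length: int


@dataclass(frozen=True)
class Pinch:
    """Spherical high-density focus (grayscale only; the mask is unchanged)."""

    center: tuple[float, float, float]
    radius: float
    intensity_boost: float


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameter set of one synthetic specimen.

    Intensities are on an 8-bit-like scale; only the contrast-to-noise
    ratio matters.  A contrast below ``6 * noise_sd`` is rejected so every
    generated phantom is segmentable by construction.
    """

    grid_dims: tuple[int, int, int] = (72, 56, 56)
    voxel_edge_um: float = 2.0
    body: Ellipsoid = Ellipsoid(center=(35.5, 27.5, 27.5), semi_axes=(24.0, 14.0, 14.0))
    tissue_intensity: float = 200.0
    background_intensity: float = 50.0
    noise_sd: float = 5.0
    voids: tuple[Ellipsoid, ...] = ()
    thin_cracks: tuple[Slit, ...] = ()
    spikes: tuple[Spike, ...] = ()
    pinches: tuple[Pinch, ...] = ()
    rng_seed: int = 0


@dataclass(frozen=True)
class PhantomTruth:
    """Exact designed voxel counts and the integrity ratios they imply."""

    true_tissue_voxels: int
    true_enclosed_void_voxels: int
    true_thin_crack_voxels: int
    true_spike_voxels: int
    expected_inner_integrity: float
    expected_outer_integrity_lower_bound: float
    true_volume_mm3: float


#: margin subtracted from the expected outer ratio to form its lower bound
_OUTER_MARGIN = 0.005

#: a void narrower than this semi-axis would be (partly) closed by the kernel
_WIDE_VOID_MIN_SEMI_AXIS = 2.0


def _grids(dims):
    return np.ogrid[0:dims[0], 0:dims[1], 0:dims[2]]


def _rasterize_ellipsoid(dims, ell: Ellipsoid) -> np.ndarray:
    zz, yy, xx = _grids(dims)
    cz, cy, cx = ell.center
    az, ay, ax = ell.semi_axes
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _rasterize_slit(dims, slit: Slit) -> np.ndarray:
    if slit.thickness not in (1, 2):
        raise PhantomSpecError(f"thin_cracks: thickness must be 1 or 2, got {slit.thickness}")
    lo = [int(round(c)) - slit.half_extent for c in slit.center]
    hi = [int(round(c)) + slit.half_extent + 1 for c in slit.center]
    axis = slit.normal_axis
    lo[axis] = int(round(slit.center[axis]))
    hi[axis] = lo[axis] + slit.thickness
    out = np.zeros(dims, dtype=bool)
    out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return out


def _rasterize_sphere(dims, center, radius) -> np.ndarray:
    zz, yy, xx = _grids(dims)
    cz, cy, cx = center
    return (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2


def _dilate_cube(mask: np.ndarray) -> np.ndarray:
    from scipy import ndimage
    return ndimage.binary_dilation(mask, structure=np.ones((3, 3, 3), bool))


def _spike_voxels(body: np.ndarray, spike: Spike, dims) -> list[tuple[int, int, int]]:
    if spike.axis not in (0, 1, 2):
        raise PhantomSpecError(f"spikes: axis must be 0, 1 or 2, got {spike.axis}")
    if spike.direction not in (-1, 1):
        raise PhantomSpecError(f"spikes: direction must be +-1, got {spike.direction}")
    if spike.length < 1:
        raise PhantomSpecError(f"spikes: length must be >= 1, got {spike.length}")
    other = [a for a in range(3) if a != spike.axis]
    idx = [0, 0, 0]
    idx[other[0]], idx[other[1]] = spike.transverse
    line = body[tuple(slice(None) if a == spike.axis else idx[a] for a in range(3))]
    hits = np.flatnonzero(line)
    if hits.size == 0:
        raise PhantomSpecError(
            f"spikes: line {spike.transverse} along axis {spike.axis} misses the body")
    anchor = int(hits[-1]) if spike.direction > 0 else int(hits[0])
    voxels = []
    for step in range(1, spike.length + 1):
        pos = anchor + spike.direction * step
        if not 0 <= pos < dims[spike.axis]:
            raise PhantomSpecError("spikes: spike extends beyond the grid")
        v = list(idx)
        v[spike.axis] = pos
        voxels.append(tuple(v))
    return voxels


def _validate_spec(spec: PhantomSpec) -> None:
    dims = spec.grid_dims
    if len(dims) != 3 or min(dims) < 1:
        raise PhantomSpecError(f"grid_dims must be three positive integers, got {dims}")
    if not spec.voxel_edge_um > 0:
        raise PhantomSpecError("voxel_edge_um must be > 0")
    if spec.noise_sd < 0:
        raise PhantomSpecError("noise_sd must be >= 0")
    contrast = spec.tissue_intensity - spec.background_intensity
    if spec.noise_sd > 0 and contrast < 6 * spec.noise_sd:
        raise PhantomSpecError(
            f"tissue/background contrast {contrast} is below 6 * noise_sd "
            f"({6 * spec.noise_sd}); phantom would not be segmentable by construction")
    for axis in range(3):
        lo = spec.body.center[axis] - spec.body.semi_axes[axis]
        hi = spec.body.center[axis] + spec.body.semi_axes[axis]
        if lo < 3 or hi > dims[axis] - 4:
            raise PhantomSpecError(
                f"body: must keep a >= 3-voxel background margin on axis {axis} "
                f"(extent [{lo:.1f}, {hi:.1f}] in dim {dims[axis]})")


def generate_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, BinaryMask, PhantomTruth]:
    """Rasterize one phantom: grayscale volume, ground-truth mask, exact truth.

    Deterministic given ``spec.rng_seed``.  Raises :class:`PhantomSpecError`
    naming the offending field when a spec invariant is violated (defect
    outside the body, insufficient margin or contrast, ...).
    """
    _validate_spec(spec)
    dims = spec.grid_dims

    ideal = _rasterize_ellipsoid(dims, spec.body)
    # regularize the surface at the kernel scale: open(close(.)) with the cube
    edge = spec.voxel_edge_um
    body = morph_open(morph_close(BinaryMask(ideal, edge), CUBE_27), CUBE_27).data

    tissue = body.copy()
    n_void = 0
    for i, void in enumerate(spec.voids):
        if min(void.semi_axes) < _WIDE_VOID_MIN_SEMI_AXIS:
            raise PhantomSpecError(
                f"voids[{i}]: semi-axes {void.semi_axes} are below the kernel "
                f"half-width; model narrow defects as thin_cracks")
        vmask = _rasterize_ellipsoid(dims, void)
        if not vmask.any():
            raise PhantomSpecError(f"voids[{i}]: rasterizes to zero voxels")
        if (_dilate_cube(vmask) & ~body).any():
            raise PhantomSpecError(f"voids[{i}]: not strictly inside the body")
        n_void += int((vmask & tissue).sum())
        tissue &= ~vmask

    n_crack = 0
    for i, slit in enumerate(spec.thin_cracks):
        smask = _rasterize_slit(dims, slit)
        if not smask.any():
            raise PhantomSpecError(f"thin_cracks[{i}]: rasterizes to zero voxels")
        if (_dilate_cube(smask) & ~body).any():
            raise PhantomSpecError(f"thin_cracks[{i}]: not strictly inside the body")
        n_crack += int((smask & tissue).sum())
        tissue &= ~smask

    n_spike = 0
    for i, spike in enumerate(spec.spikes):
        try:
            voxels = _spike_voxels(body, spike, dims)
        except PhantomSpecError as exc:
            raise PhantomSpecError(f"spikes[{i}]: {exc}") from None
        for v in voxels:
            if not tissue[v]:
                tissue[v] = True
                n_spike += 1

    gray = np.full(dims, spec.background_intensity, dtype=np.float64)
    gray[tissue] = spec.tissue_intensity
    for i, pinch in enumerate(spec.pinches):
        pmask = _rasterize_sphere(dims, pinch.center, pinch.radius)
        if (pmask & ~tissue).any():
            raise PhantomSpecError(f"pinches[{i}]: not strictly inside the tissue")
        gray[pmask] += pinch.intensity_boost

    rng = np.random.default_rng(spec.rng_seed)
    if spec.noise_sd > 0:
        gray += rng.normal(0.0, spec.noise_sd, size=dims)

    n_tissue = int(tissue.sum())
    repaired = n_tissue + n_void + n_crack
    expected_inner = n_tissue / repaired if repaired else 1.0
    expected_outer_lb = 1.0 - (n_spike / repaired if repaired else 0.0) - _OUTER_MARGIN
    truth = PhantomTruth(
        true_tissue_voxels=n_tissue,
        true_enclosed_void_voxels=n_void,
        true_thin_crack_voxels=n_crack,
        true_spike_voxels=n_spike,
        expected_inner_integrity=expected_inner,
        expected_outer_integrity_lower_bound=expected_outer_lb,
        true_volume_mm3=n_tissue * edge ** 3 * 1e-9,
    )
    volume = VoxelVolume(data=gray.astype(np.float32), voxel_edge_um=edge)
    return volume, BinaryMask(data=tissue, voxel_edge_um=edge), truth


# ---------------------------------------------------------------------------
# group presets


@dataclass(frozen=True)
class CohortSpecimen:
    """One generated cohort member with its truth and simulated observer scores."""

    specimen_id: str
    preset: str
    spec: PhantomSpec
    volume: VoxelVolume
    truth_mask: BinaryMask
    truth: PhantomTruth
    observer_scores: tuple[int, int, int]
    seed_point: tuple[int, int, int]


def _gentle_defects(rng, body: Ellipsoid):
    """Few small defects: the control-like and B1-like damage profile."""
    voids = []
    if rng.random() < 0.5:
        semi = tuple(rng.uniform(2.0, 3.0, size=3))
        voids.append(Ellipsoid(center=_interior_point(rng, body, max(semi)),
                               semi_axes=semi))
    spikes = _random_spikes(rng, body, n=int(rng.integers(0, 2)), lengths=(2, 4))
    pinches = _random_pinches(rng, body, n=int(rng.integers(0, 2)),
                              radii=(2.0, 3.0), boosts=(40.0, 50.0))
    return tuple(voids), (), tuple(spikes), tuple(pinches)


def _crushing_defects(rng, body: Ellipsoid):
    """Many larger defects: the B2-like (grind-anvil) damage profile."""
    voids = []
    for _ in range(int(rng.integers(2, 5))):
        semi = tuple(rng.uniform(2.5, 4.5, size=3))
        voids.append(Ellipsoid(center=_interior_point(rng, body, max(semi)),
                               semi_axes=semi))
    cracks = []
    for _ in range(int(rng.integers(1, 3))):
        half_extent = int(rng.integers(3, 6))
        half_diag = float(np.sqrt(2 * (half_extent + 1.5) ** 2 + 2.5 ** 2))
        cracks.append(Slit(center=_interior_point(rng, body, half_diag),
                           normal_axis=int(rng.integers(0, 3)),
                           thickness=int(rng.integers(1, 3)),
                           half_extent=half_extent))
    spikes = _random_spikes(rng, body, n=int(rng.integers(25, 41)), lengths=(4, 8))
    pinches = _random_pinches(rng, body, n=int(rng.integers(1, 3)),
                              radii=(2.5, 3.5), boosts=(40.0, 60.0))
    return tuple(voids), tuple(cracks), tuple(spikes), tuple(pinches)


def _interior_point(rng, body: Ellipsoid, defect_radius: float) -> tuple[float, float, float]:
    """Uniform point in the body such that a defect of ``defect_radius``
    voxels around it stays strictly inside (sufficient containment bound in
    the body's normalized coordinates, with 2 voxels of dilation margin)."""
    frac_max = max(0.05, 0.92 - (defect_radius + 2.0) / min(body.semi_axes))
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    radius = frac_max * rng.random() ** (1.0 / 3.0)
    return tuple(body.center[a] + radius * body.semi_axes[a] * direction[a]
                 for a in range(3))


def _random_spikes(rng, body: Ellipsoid, n: int, lengths) -> list[Spike]:
    spikes = []
    for _ in range(n):
        axis = int(rng.integers(1, 3))  # transverse (y or x) faces only
        other = [a for a in range(3) if a != axis]
        transverse = tuple(
            int(round(body.center[a] + 0.5 * body.semi_axes[a] * rng.uniform(-1, 1)))
            for a in other)
        spikes.append(Spike(axis=axis, direction=int(rng.choice([-1, 1])),
                            transverse=transverse,
                            length=int(rng.integers(lengths[0], lengths[1] + 1))))
    return spikes


def _random_pinches(rng, body: Ellipsoid, n: int, radii, boosts) -> list[Pinch]:
    pinches = []
    for _ in range(n):
        # forceps contact sites sit toward the specimen ends
        z = body.center[0] + 0.55 * body.semi_axes[0] * rng.choice([-1, 1])
        y = body.center[1] + 0.2 * body.semi_axes[1] * rng.uniform(-1, 1)
        x = body.center[2] + 0.2 * body.semi_axes[2] * rng.uniform(-1, 1)
        pinches.append(Pinch(center=(z, y, x), radius=float(rng.uniform(*radii)),
                             intensity_boost=float(rng.uniform(*boosts))))
    return pinches


def _preset_spec(preset: str, rng, seed: int) -> PhantomSpec:
    dims = (72, 56, 56)
    center = tuple((d - 1) / 2.0 for d in dims)
    if preset == "b1_like":
        semi = (float(rng.uniform(23.0, 28.0)), float(rng.uniform(13.0, 16.5)),
                float(rng.uniform(13.0, 16.5)))
    elif preset == "cn_like":
        semi = (float(rng.uniform(20.0, 26.0)), float(rng.uniform(12.0, 15.0)),
                float(rng.uniform(12.0, 15.0)))
    elif preset == "b2_like":
        # same central body size as the control profile, wider spread
        semi = (float(rng.uniform(18.0, 28.0)), float(rng.uniform(11.0, 16.0)),
                float(rng.uniform(11.0, 16.0)))
    else:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    body = Ellipsoid(center=center, semi_axes=semi)
    maker = _crushing_defects if preset == "b2_like" else _gentle_defects
    voids, cracks, spikes, pinches = maker(rng, body)
    return PhantomSpec(grid_dims=dims, body=body, voids=voids, thin_cracks=cracks,
                       spikes=spikes, pinches=pinches, rng_seed=seed)


PRESETS = ("b1_like", "b2_like", "cn_like")


def deepest_tissue_voxel(mask: np.ndarray) -> tuple[int, int, int]:
    """The tissue voxel farthest from any background voxel (first in C order
    on ties): a robust region-growing seed whose neighborhood statistics are
    uncontaminated by defects or background."""
    from scipy import ndimage

    depth = ndimage.distance_transform_cdt(mask, metric="chessboard")
    idx = np.unravel_index(int(np.argmax(depth)), mask.shape)
    return tuple(int(i) for i in idx)

#: true compression severity implied by the number of designed pinch foci
def _true_compression(n_pinches: int) -> int:
    return min(2, n_pinches)


def generate_group_cohort(preset: str, n_specimens: int,
                          base_seed: int) -> list[CohortSpecimen]:
    """Generate a cohort of phantoms from one damage-profile preset.

    Specimen ``i`` uses seed ``base_seed + i`` for both its parameter draws
    and its noise, so cohorts are reproducible specimen by specimen.
    Observer compression scores are simulated as the designed severity
    (number of pinch foci, capped at 2) with 10% per-observer disagreement
    of one level in either direction.
    """
    if n_specimens < 1:
        raise ValueError("n_specimens must be >= 1")
    out = []
    for i in range(n_specimens):
        seed = base_seed + i
        rng = np.random.default_rng(seed)
        # re-draw defect placements that land infeasibly (rare)
        generated = None
        for _ in range(20):
            spec = _preset_spec(preset, rng, seed)
            try:
                generated = generate_phantom(spec)
                break
            except PhantomSpecError:
                continue
        if generated is None:
            raise PhantomSpecError(
                f"could not draw a feasible {preset} spec for seed {seed}")
        volume, mask, truth = generated
        seed_point = deepest_tissue_voxel(mask.data)
        true_score = _true_compression(len(spec.pinches))
        scores = tuple(
            int(np.clip(true_score + rng.choice([-1, 0, 1], p=[0.1, 0.8, 0.1]), 0, 2))
            for _ in range(3))
        out.append(CohortSpecimen(
            specimen_id=f"{preset}-{i:03d}", preset=preset, spec=spec,
            volume=volume, truth_mask=mask, truth=truth,
            observer_scores=scores,  # type: ignore[arg-type]
            seed_point=seed_point))
    return out
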